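# Methods

This note records the model, the numerical choices, what the synthetic data
generator does and does not emulate, and the design decisions taken where
the published description of the method is ambiguous or internally
inconsistent. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signals and the synthetic cohort

A VAG record is a single-channel, uncalibrated acceleration signal from the
patella during a ~4 s leg swing (135° → 0° → 135°), digitized at
`fs = 2 kHz` with 12-bit resolution, i.e. `N = 8000` samples. The clinical
cohort this package stands in for contained 51 normal and 38 abnormal
records; the abnormal records show higher amplitude variability, more and
larger transient bursts, and more broadband noise.

The generator (`vagfusion.signals.generate_synthetic_cohort`) emulates
exactly those contrasts:

| parameter | normal | abnormal | unit | rationale |
|---|---|---|---|---|
| smooth swing | 2 sinusoids in 0.5–2 Hz, envelope-modulated, amp ≈ 1 | same | a.u. | leg-swing acceleration profile |
| transient bursts | Poisson rate 2 / record | rate 20 / record, amplitude ×1.5 | — | cartilage-friction clicks; raised-cosine, 5–20 ms wide |
| broadband noise sd | 0.05 | 0.25 | a.u. | abnormal records are "much more noisy"; 0.25 puts ~10 % of signal energy in noise, enough to drive the MP atom count up by an order of magnitude without swamping the swing |
| powerline 50 Hz | — | amp 0.05 | a.u. | mains interference on the noisier records |
| quantization | off by default (12-bit available) | | | float identities stay exact in tests |

What the generator does **not** emulate: muscle-contraction interference
with realistic spectra, grade-dependent pathology severity, inter-subject
anatomical variability, or any overlap structure that makes the clinical
classes hard to separate. Consequently the synthetic classes are *much*
more separable than real data: classifiers routinely reach 100 % accuracy
and `A_z = 1`. A green cohort-level test therefore establishes that the
pipeline's machinery is correct and that the engineered class contrasts
propagate into the features — not that any accuracy level would transfer
to clinical records. The published headline numbers (88.76 % accuracy,
`A_z = 0.9515`) depend on the private data set and are out of scope.

Record lengths are configurable; cohort-level tests run at 1024 samples to
keep the matching pursuit affordable (the method is identical, only the
dictionary is smaller).

## Matching pursuit (Natom)

The dictionary holds every periodized wavelet-packet basis vector of a
dyadic-length signal at levels `1..L` (default `L = log2 N`), built from
the Daubechies db8 filter; each level is an exact orthonormal basis, so the
dictionary has `N·L` unit-norm atoms. The db8 filter itself is constructed
by spectral factorization of the binomial half-band polynomial
(extremal-phase root selection); orthonormality (`Σh = √2`,
`Σ h[n]h[n+2k] = δ_k`) is verified in tests rather than assumed. Dirac
(level-0) atoms are excluded, consistent with a dictionary size of
`N log2 N`.

Per iteration, inner products with all atoms are obtained by running the
packet transform on the residual (`O(N log N)` instead of materializing the
`N·L × N` matrix, which is retained only as a small-`N` test oracle). The
arg-max over `|⟨residual, d⟩|` breaks ties toward the lowest
`(level, node, translate)` for reproducibility. The stop rule is
`SNR = 10 log10(Σx²/Σr²) ≥ 15 dB`, the residual treated as noise (the
published account names the SNR indicator but not its formula; this is the
standard reading). Safety stops: `max_iter` (default 2000) and exact
residual vanishing. `Natom` is the iteration count at the stop.

Signals of non-dyadic length are zero-padded to the next power of two
(8000 → 8192); padding preserves energy and the dyadic tree structure.
Whether the original work padded, truncated, or used a non-dyadic variant
is unstated, so printed atom counts (145/784) could not be replicated even
with the original data.

## Turns count (TCFT)

The signal is linearly mapped to `[0, 1]` (constant signals are rejected
rather than zeroed), low-passed with a 10th-order Butterworth at 50 Hz
(unit DC gain, implemented in second-order sections), and the output
advanced by 100 samples — the published delay calibration, kept verbatim
and configurable, although it does not equal the filter's computed group
delay. A candidate turn is a strict sign change of consecutive
differences; it is counted when its amplitude differs by strictly more
than 0.2 from the reference.

The reference is the **previous candidate turning point** (first candidate:
the first sample). The published wording says "the preceding sample", but
that reading is provably degenerate: a unit-range signal band-limited to
~50 Hz at 2 kHz has one-sample increments bounded near 0.096 (numerically,
the worst-case one-sample step of this filter to any `[0,1]` input), so a
0.2 threshold would count zero turns on every filtered record —
contradicting the nonzero published turn counts and the significance of
the TCFT feature. The successive-extrema reference is Willison's classical
turns-count variant, remains meaningful after filtering, and agrees
with the per-sample reading on the worked examples used in the tests
(where every interior sample is an extremum). The literal per-sample rule
is retained as `mode="sample"` for study.

## Statistical features

- **FF1/FF2**: Hjorth form factor `(σ_x″/σ_x′)/(σ_x′/σ_x)` on each half of
  the normalized record (population σ; the ratio is scale-invariant). The
  source work names the feature but not the formula; this is the standard
  Hjorth complexity/mobility ratio.
- **VMS**: non-overlapping segments of 50 ms (100 samples at 2 kHz,
  configurable; the original segmentation is in earlier cited work and not
  restated), mean square per segment, unbiased (n−1) variance across
  segments.
- **μ**: mean of the Gaussian Parzen density of the amplitudes, bandwidth
  by Silverman's rule unless given. Computed by quadrature of the first
  moment on a 4097-point grid spanning ±8 bandwidths (the zero-mean-kernel
  identity `μ = sample mean` is used as the test oracle, not as the
  implementation). The exponent is floored at −45 because far-tail kernel
  mass (< 1e-19) is irrelevant while subnormal `exp` results are
  pathologically slow.
- **FD**: Welch periodogram (`nperseg = min(1024, N/4)`), least-squares
  slope of `log10 PSD` vs `log10 f` over 10–500 Hz (excluding DC and the
  filter roll-off region), `FD = (5 − β)/2`, unclipped.

Feature screening uses the classic pooled-variance two-sided Student
t-test with `P < 0.01` as the significance convention; degenerate
zero-variance groups take the limit conventions `p = 1` (equal means) or
`p = 0` (unequal).

## LS-SVM

Training solves the dense KKT system
`[[0, 1ᵀ], [1, Ω + I/γ]]·[b; α] = [0; y]` with the plain kernel Gram matrix
`Ω` and ±1 labels on the right-hand side (of the two classic equivalent
formulations, this keeps decision values label-comparable). Defaults:
polynomial kernel `(u·v + 1)²`, `γ = 5`. Features are standardized with
training-set statistics stored in the results object; every leave-one-out
fold and bootstrap resample re-estimates them. The solver is a direct
dense solve with partial pivoting (n is at most a few hundred); a relative
KKT residual above 1e-6 or a singular factorization raises an error with
the condition number. `Σα = 0` and a small KKT residual are asserted in
the tests. Ties in the sign rule (`g = 0`) classify as +1 (abnormal), the
clinically conservative choice.

## Ensembles and the DWF rule

Bagging: K = 5 component LS-SVMs, each trained on a with-replacement
resample of the full training-set size; single-class resamples are redrawn
(at most 100 attempts). Aggregation is the simple average. Testing uses
the full cohort, matching the published protocol (no leave-one-out for the
ensembles).

DWF combines component outputs with per-signal weights
`w_k = e_k⁻¹/Σ_j e_j⁻¹` (computed through the published double-sum form and
verified against the simplification) and reports the closed-form ensemble
squared error `1/(Σ_j e_j⁻¹)²`, which satisfies `e_k²/e²_DWF ≥ 1`. Three
deliberate choices:

- **Error magnitudes.** Applied to signed errors the weight formula can go
  negative or divide by zero (e.g. `e = (1, −1)`), violating the stated
  nonnegativity constraint; the default transforms errors to `|e_k|`
  (`error_transform="absolute"`), with the literal signed variant kept for
  study.
- **Zero errors.** Components with `|e_k| ≤ ε` (default 1e-12) receive all
  the weight, split equally — the limit of `w ∝ 1/e`; the ensemble error
  degenerates to 0 and is flagged with a warning.
- **The K² discrepancy.** Substituting the closed-form weights into the
  weighted double sum yields `K²/(Σe⁻¹)²`, i.e. K² times the published
  closed form, and the published weights are not a stationary point of the
  stated constrained quadratic program for distinct errors. The package
  implements the printed formulas as printed and exposes both quantities
  (`dwf_ensemble_error`, `dwf_weighted_square_error`) instead of guessing
  the intended algebra.

Oracle vs estimated: the published protocol computes the per-signal error
`e_k = l − g_k` from the **true label at test time**, which is not
deployable; all headline-style DWF results correspond to this `oracle`
mode. The `estimated` mode substitutes each component's out-of-bag mean
absolute error (constant per model) and is the deployable counterpart.

## Fixed-size subset selection

The quadratic Rényi entropy `−log((1/n²)ΣΣ κ(x_i−x_j))` is estimated with
the Gaussian Parzen kernel's self-convolution (variance `2h²` per
dimension), bandwidth by Silverman's multivariate rule on standardized
features (the source cites a reference without parameters; standardization
is the package's choice). Selection starts from a random 15-subset and
accepts a random swap iff the entropy strictly increases; termination
after 500 proposals or 100 consecutive rejections, whichever is first (the
published account says only that the entropy "becomes stable"). Selection
ignores class labels; a selected subset containing a single class cannot
train a component and is skipped with the remaining components carrying
the fusion.

## Evaluation

Empirical (trapezoidal) ROC over all distinct thresholds with simultaneous
steps on ties — equal, to floating precision, to the rank-sum estimator
with half credit for ties, which the tests verify by brute force. The
positive class is abnormal (+1). The area's standard error is
Hanley–McNeil (`Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`); the original report does
not name its SE estimator, so printed SEs cannot adjudicate the choice.
The binormal-fit alternative is deliberately out of scope.

## Reproducibility

Every stochastic component (generator, bootstrap, subset search) takes an
explicit integer seed and is bit-reproducible given it; the pipeline
writes the seed and a configuration hash into every artifact, and
`summary.json` is byte-identical across reruns of the same configuration.
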
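"""Quadratic Rényi entropy and active selection of fixed-size training subsets.

The quadratic Rényi entropy of a sample, ``H2 = -log integral p(x)^2 dx``,
is estimated through a Gaussian Parzen density: the integral of the squared
density is the mean over all sample pairs of the kernel self-convolution, a
Gaussian with per-dimension variance ``2 h^2``:

    H2 = -log( (1/n^2) sum_i sum_j N(x_i - x_j; 0, 2 h^2 I) ).

Diverse, well-spread subsets have high entropy, so a small training subset
(published size: 15) is chosen by a swap-accept search: start from a random
subset, repeatedly propose replacing a random working member with a random
candidate, and accept the swap iff the entropy strictly increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "quadratic_renyi_entropy",
    "silverman_bandwidth_nd",
    "active_select_fixed_size",
    "SelectionTrace",
]


def silverman_bandwidth_nd(X: np.ndarray) -> float:
    """Silverman's multivariate rule ``(4/(d+2))^(1/(d+4)) n^(-1/(d+4)) sigma``
    with ``sigma`` the mean per-dimension standard deviation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    sigma = float(np.mean(np.std(X, axis=0, ddof=1))) if n > 1 else 1.0
    if sigma <= 0:
        sigma = 1.0
    return (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0)) * sigma


def quadratic_renyi_entropy(X: np.ndarray, bandwidth: float) -> float:
    """Parzen estimate of the quadratic Rényi entropy of the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    n, d = X.shape
    var = 2.0 * bandwidth**2
    if n == 1:
        sq = np.zeros((1, 1))
    else:
        sq = squareform(pdist(X, "sqeuclidean"))
    kernels = np.exp(-sq / (2.0 * var)) / (2.0 * np.pi * var) ** (d / 2.0)
    return float(-np.log(kernels.mean()))


@dataclass
class SelectionTrace:
    """Outcome of the swap-accept subset search.

    ``entropies[s]`` is the working-subset entropy after step ``s`` (entry 0
    is the initial subset); ``steps`` rows are
    ``(step, proposed_in, proposed_out, accepted, entropy)``.
    """

    selected_indices: np.ndarray
    entropies: np.ndarray
    accepted_swaps: int
    seed: int
    steps: list[tuple[int, int, int, bool, float]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.steps,
            columns=["step", "proposed_in", "proposed_out", "accepted", "entropy"],
        )


def active_select_fixed_size(
    X: np.ndarray,
    m: int = 15,
    max_steps: int = 500,
    seed: int = 0,
    bandwidth: float | None = None,
    standardize: bool = True,
    patience: int = 100,
) -> SelectionTrace:
    """Entropy-maximizing selection of an ``m``-subset of the rows of ``X``.

    Starts from a random ``m``-subset; each step proposes swapping one
    random working member for one random candidate and accepts iff the
    quadratic Rényi entropy strictly increases. Stops after ``max_steps``
    proposals or ``patience`` consecutive rejections. Deterministic given
    ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"subset size m={m} must be in [1, n={n}]")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if standardize:
        sd = np.std(X, axis=0, ddof=1) if n > 1 else np.ones(X.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - X.mean(axis=0)) / sd
    if bandwidth is None:
        bandwidth = silverman_bandwidth_nd(X)
    rng = np.random.default_rng(seed)
    if m == n:
        h = quadratic_renyi_entropy(X, bandwidth)
        return SelectionTrace(np.arange(n), np.array([h]), 0, seed)
    working = rng.choice(n, size=m, replace=False)
    candidates = np.setdiff1d(np.arange(n), working)
    h = quadratic_renyi_entropy(X[working], bandwidth)
    entropies = [h]
    steps: list[tuple[int, int, int, bool, float]] = []
    accepted = 0
    rejections = 0
    for step in range(1, max_steps + 1):
        ci = rng.integers(0, candidates.size)
        wi = rng.integers(0, m)
        cand, work = int(candidates[ci]), int(working[wi])
        trial = working.copy()
        trial[wi] = cand
        h_trial = quadratic_renyi_entropy(X[trial], bandwidth)
        accept = h_trial > h
        if accept:
            working = trial
            candidates[ci] = work
            h = h_trial
            accepted += 1
            rejections = 0
        else:
            rejections += 1
        entropies.append(h)
        steps.append((step, cand, work, bool(accept), h))
        if rejections >= patience:
            break
    return SelectionTrace(
        selected_indices=np.sort(working),
        entropies=np.array(entropies),
        accepted_swaps=accepted,
        seed=seed,
        steps=steps,
    )
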
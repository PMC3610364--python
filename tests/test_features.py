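"""Butterworth prefilter, turns count, statistical features, feature vector."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from vagfusion import (
    VagSignal,
    butterworth_lowpass,
    count_turns_fixed_threshold,
    extract_feature_vector,
    ff_halves,
    form_factor,
    fractal_dimension_psd,
    parzen_pdf_mean,
    variance_of_mean_squared,
)
from vagfusion.features import FeatureConfig

FS = 2000.0


class TestButterworth:
    def test_unit_dc_gain(self):
        y = butterworth_lowpass(np.ones(4000), FS)
        assert y[2000] == pytest.approx(1.0, abs=1e-9)

    def test_minus_3db_at_cutoff(self):
        sos = sps.butter(10, 50.0, btype="lowpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[50.0], fs=FS)
        assert abs(h[0]) == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-6)

    def test_200hz_attenuated_60db(self):
        t = np.arange(8000) / FS
        y = butterworth_lowpass(np.sin(2 * np.pi * 200.0 * t), FS)
        steady = y[2000:5000]
        assert np.max(np.abs(steady)) < 1e-3  # >= 60 dB down

    def test_delay_advance_and_zero_tail(self):
        x = np.zeros(1000)
        x[100] = 1.0
        raw = butterworth_lowpass(x, FS, delay_samples=0)
        adv = butterworth_lowpass(x, FS, delay_samples=100)
        np.testing.assert_allclose(adv[:900], raw[100:], atol=1e-15)
        np.testing.assert_array_equal(adv[900:], np.zeros(100))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(np.ones(100), FS, fc=1000.0)


class TestTurnsCount:
    def test_worked_example_three_turns(self):
        assert count_turns_fixed_threshold([0, 0.5, 0.1, 0.6, 0.55], 0.2) == 3

    def test_worked_example_zero_turns(self):
        assert count_turns_fixed_threshold([0, 0.15, 0.05, 0.25, 0.1], 0.2) == 0

    def test_worked_examples_in_literal_sample_mode(self):
        # Every interior sample of these arrays is an extremum, so the
        # successive-extrema and preceding-sample readings agree.
        assert count_turns_fixed_threshold([0, 0.5, 0.1, 0.6, 0.55], 0.2, "sample") == 3
        assert count_turns_fixed_threshold([0, 0.15, 0.05, 0.25, 0.1], 0.2, "sample") == 0

    def test_monotone_ramp_has_no_turns(self):
        assert count_turns_fixed_threshold(np.linspace(0, 1, 50), 0.2) == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            count_turns_fixed_threshold([0.0, 1.0], 0.2)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.25, 1.0), min_size=3, max_size=30),
        st.floats(-5, 5),
        st.sampled_from(["extremum", "sample"]),
    )
    def test_shift_invariant_and_reversal_on_alternating(self, steps, shift, mode):
        """Counts depend only on amplitude differences; a strictly
        alternating signal with all steps above threshold counts every
        interior sample in either direction."""
        x = np.zeros(len(steps) + 1)
        for i, s in enumerate(steps):
            x[i + 1] = x[i] + (s if i % 2 == 0 else -s)
        n = count_turns_fixed_threshold(x, 0.2, mode)
        assert n == count_turns_fixed_threshold(x + shift, 0.2, mode)
        assert n == len(x) - 2
        assert count_turns_fixed_threshold(x[::-1], 0.2, mode) == n


class TestFormFactor:
    def test_pure_sinusoid_close_to_one(self):
        t = np.arange(4000) / FS
        assert form_factor(np.sin(2 * np.pi * 10 * t)) == pytest.approx(1.0, abs=1e-2)

    def test_two_tone_exceeds_one(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 100 * t)
        assert form_factor(x) > 1.0

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            form_factor(np.ones(100))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(-100, 100).filter(lambda c: abs(c) > 1e-3))
    def test_scale_invariance(self, c):
        gen = np.random.default_rng(0)
        x = gen.normal(size=200)
        assert form_factor(c * x) == pytest.approx(form_factor(x), rel=1e-9)

    def test_halves_split_at_midpoint(self):
        t = np.arange(4000) / FS
        x = np.concatenate(
            [np.sin(2 * np.pi * 10 * t[:2000]),
             np.sin(2 * np.pi * 10 * t[:2000]) + 0.5 * np.sin(2 * np.pi * 200 * t[:2000])]
        )
        ff1, ff2 = ff_halves(x)
        assert ff1 == pytest.approx(form_factor(x[:2000]))
        assert ff2 == pytest.approx(form_factor(x[2000:]))
        assert ff2 > ff1


class TestVms:
    def test_identical_segments_zero(self):
        x = np.tile([1.0, -2.0, 3.0], 4)
        assert variance_of_mean_squared(x, 3) == 0.0

    def test_hand_example_unbiased(self):
        assert variance_of_mean_squared([1.0, 1.0, 2.0, 2.0], 2) == pytest.approx(4.5)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError):
            variance_of_mean_squared(np.arange(10.0), 10)
        with pytest.raises(ValueError):
            variance_of_mean_squared(np.arange(10.0), 11)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_quartic_scaling(self, c):
        gen = np.random.default_rng(1)
        x = gen.normal(size=120)
        assert variance_of_mean_squared(c * x, 20) == pytest.approx(
            c**4 * variance_of_mean_squared(x, 20), rel=1e-9
        )


class TestParzenMean:
    def test_single_sample(self):
        assert parzen_pdf_mean([0.3], 0.1) == pytest.approx(0.3, abs=1e-8)

    def test_symmetric_about_half(self):
        x = np.array([0.2, 0.8, 0.4, 0.6, 0.5])
        assert parzen_pdf_mean(x, 0.05) == pytest.approx(0.5, abs=1e-8)

    def test_quadrature_equals_sample_mean(self, rng):
        x = rng.uniform(0, 1, 500)
        assert parzen_pdf_mean(x) == pytest.approx(float(x.mean()), abs=1e-6)

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            parzen_pdf_mean([0.1, 0.2], 0.0)


class TestFractalDimension:
    @staticmethod
    def _power_law_noise(beta, n, seed):
        gen = np.random.default_rng(seed)
        freqs = np.fft.rfftfreq(n, d=1 / FS)
        amp = np.zeros_like(freqs)
        amp[1:] = freqs[1:] ** (-beta / 2.0)
        phases = np.exp(2j * np.pi * gen.uniform(size=freqs.size))
        return np.fft.irfft(amp * phases, n=n)

    @pytest.mark.parametrize(
        "beta,expected,tol",
        [(2.0, 1.5, 0.1), (3.0, 1.0, 0.1), (0.0, 2.5, 0.15)],
    )
    def test_recovers_spectral_exponent(self, beta, expected, tol):
        x = self._power_law_noise(beta, 1 << 15, seed=11)
        assert fractal_dimension_psd(x, FS) == pytest.approx(expected, abs=tol)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            fractal_dimension_psd(np.random.default_rng(0).normal(size=256), FS,
                                  fit_band=(10.0, 1500.0))


class TestFeatureVector:
    def test_deterministic_order_and_repeatability(self, small_cohort, feature_config):
        sig = small_cohort[0]
        v1 = extract_feature_vector(sig, feature_config)
        v2 = extract_feature_vector(sig, feature_config)
        np.testing.assert_array_equal(v1.as_array(), v2.as_array())
        assert v1.as_array().shape == (7,)
        assert v1.NAMES == ("natom", "tcft", "ff1", "ff2", "vms", "mu", "fd")
        assert v1.as_array()[0] == v1.natom and v1.as_array()[1] == v1.tcft

    def test_class_contrast_on_small_cohort(self, small_cohort, feature_config):
        """Abnormal records need more MP atoms and show more significant turns."""
        natoms = {"normal": [], "abnormal": []}
        tcfts = {"normal": [], "abnormal": []}
        for sig in small_cohort:
            v = extract_feature_vector(sig, feature_config)
            natoms[sig.label].append(v.natom)
            tcfts[sig.label].append(v.tcft)
        assert np.mean(natoms["abnormal"]) > np.mean(natoms["normal"])
        assert np.mean(tcfts["abnormal"]) > np.mean(tcfts["normal"])

    def test_detrend_flag_changes_natom_input(self, small_cohort):
        sig = VagSignal(small_cohort[0].samples + 5.0, fs=small_cohort[0].fs,
                        label=small_cohort[0].label, id="offset")
        base = extract_feature_vector(sig, FeatureConfig())
        det = extract_feature_vector(sig, FeatureConfig(detrend=True))
        # statistical features unaffected by the flag
        np.testing.assert_allclose(base.as_array()[2:], det.as_array()[2:])
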
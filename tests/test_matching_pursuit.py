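"""Wavelet filters, packet dictionary, and greedy matching pursuit."""

import numpy as np
import pytest

from vagfusion.matching_pursuit import (
    build_dictionary,
    mp_decompose,
    natom_feature,
    next_pow2,
    pad_to_pow2,
    reconstruct,
    snr_db,
)
from vagfusion.wavelets import daubechies_filter, qmf_highpass


class TestDaubechiesFilters:
    @pytest.mark.parametrize("p", [1, 2, 4, 8])
    def test_orthonormal_scaling_filter(self, p):
        h = daubechies_filter(p)
        assert h.size == 2 * p
        assert h.sum() == pytest.approx(np.sqrt(2.0), abs=1e-12)
        for k in range(p):
            expected = 1.0 if k == 0 else 0.0
            assert np.dot(h[: h.size - 2 * k], h[2 * k :]) == pytest.approx(
                expected, abs=1e-10
            )

    def test_qmf_orthogonal_to_lowpass(self):
        h = daubechies_filter(8)
        g = qmf_highpass(h)
        assert np.dot(h, g) == pytest.approx(0.0, abs=1e-12)
        assert abs(g.sum()) < 1e-10


class TestDictionary:
    def test_db1_small_dictionary_explicit(self):
        d = build_dictionary(8, "db1", 3)
        mat = d.as_matrix()
        assert mat.shape == (24, 8)  # N*L = 8*3 atoms
        norms = np.linalg.norm(mat, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-12

    def test_each_level_is_orthonormal_basis(self):
        d = build_dictionary(32, "db8", 5)
        mat = d.as_matrix()
        for level in range(5):
            block = mat[level * 32 : (level + 1) * 32]
            np.testing.assert_allclose(block @ block.T, np.eye(32), atol=1e-10)

    def test_depth_and_length_validation(self):
        with pytest.raises(ValueError):
            build_dictionary(8, "db1", 4)  # depth > log2 N
        with pytest.raises(ValueError):
            build_dictionary(12)  # not a power of two
        assert build_dictionary(8, "db1").size == 24

    def test_analyze_coefficients_are_inner_products(self, rng):
        d = build_dictionary(16, "db2")
        mat = d.as_matrix()
        x = rng.normal(size=16)
        levels = d.analyze(x)
        flat = np.concatenate([lvl.ravel() for lvl in levels])
        np.testing.assert_allclose(flat, mat @ x, atol=1e-10)


class TestSnr:
    def test_residual_equal_signal_is_zero_db(self):
        x = np.array([1.0, 2.0, 3.0])
        assert snr_db(x, x) == pytest.approx(0.0)

    def test_energy_ratio_ten_gives_ten_db(self):
        x = np.sqrt(10.0) * np.ones(4)
        r = np.ones(4)
        assert snr_db(x, r) == pytest.approx(10.0)

    def test_zero_residual_is_infinite(self):
        assert snr_db(np.ones(4), np.zeros(4)) == np.inf

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            snr_db(np.zeros(4), np.ones(4))


class TestMatchingPursuit:
    def test_single_atom_identity(self):
        d = build_dictionary(32, "db8")
        x = d.atom(2, 1, 3)
        dec = mp_decompose(x, d)
        assert dec.n_iterations == 1
        assert dec.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        assert np.dot(dec.residual, dec.residual) < 1e-18
        assert dec.stop_reason == "zero_residual"

    def test_two_atom_composite_same_level(self):
        d = build_dictionary(32, "db8")
        a = d.atom(3, 2, 1)
        b = d.atom(3, 5, 0)
        dec = mp_decompose(1.0 * a + 0.5 * b, d)
        assert dec.atoms[:2] == [(3, 2, 1), (3, 5, 0)]
        np.testing.assert_allclose(dec.coefficients[:2], [1.0, 0.5], atol=1e-10)
        assert dec.n_iterations == 2

    def test_three_atom_composite_natom(self):
        d = build_dictionary(64, "db8")
        x = (
            1.0 * d.atom(2, 0, 3)
            + 0.9 * d.atom(2, 1, 7)
            + 0.8 * d.atom(2, 3, 11)
        )
        assert natom_feature(x) == 3

    def test_brute_force_oracle_equivalence(self, rng):
        """Full greedy trace equals an explicit-matrix argmax oracle."""
        d = build_dictionary(64, "db8")
        mat = d.as_matrix()
        for _ in range(3):
            x = rng.normal(size=64)
            dec = mp_decompose(x, d, snr_stop_db=15.0)
            r = x.copy()
            for sel, coef in zip(dec.atoms, dec.coefficients):
                ip = mat @ r
                best = int(np.argmax(np.abs(ip)))
                assert d._flat_to_index(best) == sel
                assert ip[best] == pytest.approx(coef, abs=1e-9)
                r -= ip[best] * mat[best]
            np.testing.assert_allclose(r, dec.residual, atol=1e-9)

    def test_energy_conservation_and_monotone_snr(self, rng):
        d = build_dictionary(128, "db8")
        x = rng.normal(size=128)
        dec = mp_decompose(x, d, snr_stop_db=25.0)
        # ||R^m||^2 = a_m^2 + ||R^{m+1}||^2 reconstructed backwards
        energy = float(np.dot(dec.residual, dec.residual))
        energies = [energy]
        for coef in dec.coefficients[::-1]:
            energy += coef**2
            energies.append(energy)
        energies = energies[::-1]  # ||R^0||^2 ... ||R^M||^2
        assert energies[0] == pytest.approx(float(np.dot(x, x)), rel=1e-9)
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12)  # residual energy non-increasing
        finite = dec.snr_trace_db[np.isfinite(dec.snr_trace_db)]
        assert np.all(np.diff(finite) >= -1e-9)

    def test_stop_rule_reaches_snr(self, rng):
        d = build_dictionary(256, "db8")
        x = rng.normal(size=256)
        dec = mp_decompose(x, d, snr_stop_db=15.0, max_iter=256)
        assert dec.stop_reason == "snr_reached"
        assert snr_db(x, dec.residual) >= 15.0

    def test_max_iter_returns_not_raises(self, rng):
        d = build_dictionary(64, "db8")
        x = rng.normal(size=64)
        dec = mp_decompose(x, d, snr_stop_db=60.0, max_iter=5)
        assert dec.stop_reason == "max_iter"
        assert dec.n_iterations == 5

    def test_zero_signal_rejected(self):
        d = build_dictionary(8, "db1")
        with pytest.raises(ValueError):
            mp_decompose(np.zeros(8), d)


class TestReconstruct:
    def test_empty_decomposition_is_zero(self):
        d = build_dictionary(8, "db1")
        from vagfusion.matching_pursuit import MPDecomposition

        dec = MPDecomposition(
            atoms=[],
            coefficients=np.array([]),
            residual=np.zeros(8),
            snr_trace_db=np.array([]),
            stop_reason="max_iter",
            dictionary=d,
        )
        np.testing.assert_array_equal(reconstruct(dec), np.zeros(8))

    def test_bookkeeping_identity_and_stop_snr(self, rng):
        d = build_dictionary(128, "db8")
        x = rng.normal(size=128)
        dec = mp_decompose(x, d, snr_stop_db=15.0)
        recon = reconstruct(dec)
        assert np.linalg.norm(x - (recon + dec.residual)) / np.linalg.norm(x) < 1e-9
        assert snr_db(x, x - recon) >= 15.0

    def test_bad_atom_index_rejected(self):
        d = build_dictionary(8, "db1", 2)
        with pytest.raises(IndexError):
            d.atom(3, 0, 0)


class TestPadding:
    def test_next_pow2(self):
        assert next_pow2(8000) == 8192
        assert next_pow2(1024) == 1024
        assert next_pow2(1) == 1

    def test_pad_preserves_energy(self, rng):
        x = rng.normal(size=100)
        p = pad_to_pow2(x)
        assert p.size == 128
        assert np.dot(p, p) == pytest.approx(np.dot(x, x))
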
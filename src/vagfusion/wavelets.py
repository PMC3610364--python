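"""Orthogonal Daubechies filters and the periodized wavelet-packet transform.

The matching-pursuit dictionary is built from wavelet-packet bases, so the
package carries its own minimal, exactly-orthogonal transform machinery:

* ``daubechies_filter(p)`` constructs the length-``2p`` extremal-phase
  Daubechies scaling filter by spectral factorization of the binomial
  half-band polynomial (root selection inside the unit circle).
* Analysis/synthesis steps use circular (periodized) convolution, so for any
  even block length the two-channel filter bank is an exact orthogonal
  transform and every derived packet atom has unit Euclidean norm.

Conventions: the analysis step computes ``a[k] = sum_m h[m] c[(2k+m) mod n]``
(and the same with the quadrature-mirror highpass ``g``); synthesis is its
exact adjoint. Child nodes are ordered in the natural (Paley) order: node
``p`` at one level produces nodes ``2p`` (lowpass) and ``2p+1`` (highpass).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "daubechies_filter",
    "qmf_highpass",
    "parse_wavelet_name",
    "wp_analysis_step",
    "wp_synthesis_single_node",
]


@lru_cache(maxsize=None)
def _daubechies_cached(p: int) -> tuple[float, ...]:
    if p == 1:  # Haar
        s = 1.0 / math.sqrt(2.0)
        return (s, s)
    # Binomial polynomial P(y) = sum_k C(p-1+k, k) y^k of the half-band
    # autocorrelation; its roots in y map to reciprocal pairs in z via
    # y = (2 - z - 1/z)/4.  Keeping the root of each pair inside the unit
    # circle yields the extremal-phase (minimum-phase) factor.
    binom = np.array([math.comb(p - 1 + k, k) for k in range(p)], dtype=float)
    yroots = np.roots(binom[::-1])
    zroots = []
    for y in yroots:
        r = np.roots([1.0, 4.0 * y - 2.0, 1.0])
        zroots.append(r[np.argmin(np.abs(r))])
    h = np.real(np.poly([-1.0] * p + zroots))
    h *= math.sqrt(2.0) / h.sum()
    return tuple(float(v) for v in h)


def daubechies_filter(vanishing_moments: int) -> np.ndarray:
    """Length-``2p`` orthonormal Daubechies scaling (lowpass) filter.

    Satisfies ``sum h = sqrt(2)`` and the double-shift orthonormality
    ``sum_n h[n] h[n+2k] = delta_k``.
    """
    p = int(vanishing_moments)
    if p < 1:
        raise ValueError("vanishing_moments must be >= 1")
    return np.array(_daubechies_cached(p))


def qmf_highpass(h: np.ndarray) -> np.ndarray:
    """Quadrature-mirror highpass ``g[n] = (-1)^n h[L-1-n]`` of a scaling filter."""
    h = np.asarray(h, dtype=float)
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


def parse_wavelet_name(name: str) -> int:
    """Map a wavelet name ('db8', 'haar', ...) to its number of vanishing moments."""
    name = name.strip().lower()
    if name == "haar":
        return 1
    if name.startswith("db"):
        try:
            p = int(name[2:])
        except ValueError:
            raise ValueError(f"unrecognized wavelet name: {name!r}") from None
        if p < 1:
            raise ValueError(f"unrecognized wavelet name: {name!r}")
        return p
    raise ValueError(f"unrecognized wavelet name: {name!r}")


@lru_cache(maxsize=64)
def _analysis_indices(n: int, taps: int) -> np.ndarray:
    # idx[m, k] = (2k + m) mod n, for one periodized decimation step
    k2 = 2 * np.arange(n // 2)
    return (k2[None, :] + np.arange(taps)[:, None]) % n


@lru_cache(maxsize=64)
def _synthesis_indices(half: int, shifts: int) -> np.ndarray:
    # idx[s, j] = (j - s) mod half, for the adjoint (upsampling) step
    j = np.arange(half)
    return (j[None, :] - np.arange(shifts)[:, None]) % half


def wp_analysis_step(c: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """One periodized analysis step applied to every node at a level.

    ``c`` has shape ``(nodes, n)`` with even ``n``; returns ``(2*nodes, n//2)``
    in natural order (children ``2p``, ``2p+1`` of parent ``p``).
    """
    nodes, n = c.shape
    idx = _analysis_indices(n, len(h))
    gathered = c[:, idx]                      # (nodes, taps, n//2)
    filt = np.vstack([h, g])                  # (2, taps)
    ad = np.einsum("rf,nfk->nrk", filt, gathered)
    return ad.reshape(2 * nodes, n // 2)


def wp_synthesis_single_node(coef: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Adjoint of one analysis channel for a single node (sibling all-zero).

    Given node coefficients ``coef`` (length ``half``) and one channel filter
    (``h`` for an even-indexed child, ``g`` for odd), returns the parent-level
    contribution ``out[(2k+m) mod n] += filt[m] coef[k]`` of length ``2*half``.
    """
    half = coef.size
    n = 2 * half
    taps = len(filt)
    shifts = (taps - 1) // 2 + 1
    shifted = coef[_synthesis_indices(half, shifts)]   # (shifts, half)
    out = np.empty((half, 2))
    out[:, 0] = np.einsum("f,fj->j", filt[0::2], shifted[: (taps + 1) // 2])
    out[:, 1] = np.einsum("f,fj->j", filt[1::2], shifted[: taps // 2])
    return out.reshape(n)
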
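"""Greedy matching pursuit over a wavelet-packet dictionary with an SNR stop.

The dictionary collects, for a dyadic signal length ``N`` and decomposition
depth ``L``, every wavelet-packet basis vector at levels ``1..L`` (periodized,
so each level is a complete orthonormal basis of R^N); its size is ``N * L``.
Matching pursuit repeatedly projects the residual onto the whole dictionary,
subtracts the best-matching atom, and stops once the reconstruction
signal-to-noise ratio reaches a target (default 15 dB). The number of
iterations at the stop is the ``Natom`` feature: noisy, artifact-laden
records need many more atoms than smooth ones to reach the same SNR.

Inner products with all ``N*L`` atoms are computed per iteration by running
the packet transform on the residual (each level is orthonormal, so level
coefficients *are* the inner products); the explicit atom matrix is only ever
materialized for small-N verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wavelets import (
    daubechies_filter,
    parse_wavelet_name,
    qmf_highpass,
    wp_analysis_step,
    wp_synthesis_single_node,
)

__all__ = [
    "WaveletPacketDictionary",
    "MPDecomposition",
    "build_dictionary",
    "mp_decompose",
    "snr_db",
    "reconstruct",
    "natom_feature",
    "next_pow2",
    "pad_to_pow2",
]


def next_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1 << (int(n) - 1).bit_length()


def pad_to_pow2(x: np.ndarray) -> np.ndarray:
    """Zero-pad a signal at the end to the next power-of-two length."""
    x = np.asarray(x, dtype=float)
    n = next_pow2(x.size)
    if n == x.size:
        return x.copy()
    out = np.zeros(n)
    out[: x.size] = x
    return out


class WaveletPacketDictionary:
    """Dictionary of periodized wavelet-packet atoms at levels ``1..depth``.

    Parameters
    ----------
    n : int
        Signal length; must be a power of two (callers zero-pad).
    wavelet : str
        Daubechies family name, e.g. ``"db8"`` (default) or ``"haar"``.
    depth : int, optional
        Deepest packet level; defaults to ``log2(n)``.

    Atoms are indexed by ``(level, node, translate)`` with
    ``1 <= level <= depth``, ``0 <= node < 2**level`` (natural order) and
    ``0 <= translate < n / 2**level``. Every atom has unit Euclidean norm.
    """

    def __init__(self, n: int, wavelet: str = "db8", depth: int | None = None):
        n = int(n)
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(f"signal length must be a power of two >= 2, got {n}")
        max_depth = n.bit_length() - 1
        if depth is None:
            depth = max_depth
        depth = int(depth)
        if not 1 <= depth <= max_depth:
            raise ValueError(
                f"depth must be in [1, log2(n)] = [1, {max_depth}], got {depth}"
            )
        self.n = n
        self.wavelet = wavelet
        self.depth = depth
        p = parse_wavelet_name(wavelet)
        self.h = daubechies_filter(p)
        self.g = qmf_highpass(self.h)

    @property
    def size(self) -> int:
        """Number of atoms, ``n * depth``."""
        return self.n * self.depth

    def analyze(self, x: np.ndarray) -> list[np.ndarray]:
        """Packet coefficients of ``x`` at every level.

        Returns a list of ``depth`` arrays; entry ``l-1`` has shape
        ``(2**l, n/2**l)`` and holds the inner products of ``x`` with the
        level-``l`` atoms, indexed ``[node, translate]``.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"expected signal of shape ({self.n},), got {x.shape}")
        c = x.reshape(1, -1)
        levels = []
        for _ in range(self.depth):
            c = wp_analysis_step(c, self.h, self.g)
            levels.append(c)
        return levels

    def atom(self, level: int, node: int, translate: int) -> np.ndarray:
        """Materialize one unit-norm atom as a length-``n`` vector."""
        if not 1 <= level <= self.depth:
            raise IndexError(f"level {level} outside [1, {self.depth}]")
        if not 0 <= node < (1 << level):
            raise IndexError(f"node {node} outside [0, {1 << level})")
        width = self.n >> level
        if not 0 <= translate < width:
            raise IndexError(f"translate {translate} outside [0, {width})")
        vec = np.zeros(width)
        vec[translate] = 1.0
        p = node
        for _ in range(level):
            filt = self.h if p % 2 == 0 else self.g
            vec = wp_synthesis_single_node(vec, filt)
            p //= 2
        return vec

    def as_matrix(self) -> np.ndarray:
        """Explicit ``(n*depth, n)`` atom matrix, rows ordered by
        ``(level, node, translate)``. For small-n verification only."""
        rows = np.empty((self.size, self.n))
        r = 0
        for level in range(1, self.depth + 1):
            for node in range(1 << level):
                for translate in range(self.n >> level):
                    rows[r] = self.atom(level, node, translate)
                    r += 1
        return rows

    def _flat_to_index(self, flat: int) -> tuple[int, int, int]:
        level, rem = divmod(flat, self.n)
        width = self.n >> (level + 1)
        node, translate = divmod(rem, width)
        return level + 1, node, translate


def build_dictionary(
    n: int, wavelet: str = "db8", depth: int | None = None
) -> WaveletPacketDictionary:
    """Construct a :class:`WaveletPacketDictionary` (see class docs)."""
    return WaveletPacketDictionary(n, wavelet=wavelet, depth=depth)


def snr_db(x: np.ndarray, residual: np.ndarray) -> float:
    """Reconstruction SNR ``10 log10(sum x^2 / sum residual^2)`` in dB.

    The residual of the pursuit is treated as noise; a zero residual gives
    ``+inf``.
    """
    x = np.asarray(x, dtype=float)
    residual = np.asarray(residual, dtype=float)
    ex = float(np.dot(x, x))
    if ex == 0.0:
        raise ValueError("snr_db undefined for an all-zero signal")
    er = float(np.dot(residual, residual))
    if er == 0.0:
        return float("inf")
    return 10.0 * np.log10(ex / er)


@dataclass
class MPDecomposition:
    """Result of a matching-pursuit run.

    ``atoms[m]`` is the ``(level, node, translate)`` index selected at
    iteration ``m`` and ``coefficients[m]`` the signed inner product of the
    residual with that atom; ``residual`` is the final remainder, so
    ``reconstruct(...) + residual`` reproduces the input to float precision.
    """

    atoms: list[tuple[int, int, int]]
    coefficients: np.ndarray
    residual: np.ndarray
    snr_trace_db: np.ndarray
    stop_reason: str  # {"snr_reached", "max_iter", "zero_residual"}
    dictionary: WaveletPacketDictionary = field(repr=False)

    @property
    def n_iterations(self) -> int:
        return len(self.atoms)

    def to_frame(self):
        """Per-iteration table with columns iter,level,node,translate,coefficient,snr_db."""
        import pandas as pd

        lv, nd, tr = (
            zip(*self.atoms) if self.atoms else ((), (), ())
        )
        return pd.DataFrame(
            {
                "iter": np.arange(self.n_iterations),
                "level": lv,
                "node": nd,
                "translate": tr,
                "coefficient": self.coefficients,
                "snr_db": self.snr_trace_db,
            }
        )


def mp_decompose(
    x: np.ndarray,
    dictionary: WaveletPacketDictionary,
    snr_stop_db: float = 15.0,
    max_iter: int = 2000,
) -> MPDecomposition:
    """Greedy matching pursuit of ``x`` over ``dictionary``.

    At each iteration the atom maximizing ``|<residual, d>|`` over the whole
    dictionary is selected (ties broken by lowest ``(level, node, translate)``),
    its projection subtracted, and the pursuit stops at the first iteration
    where the SNR of the reconstruction reaches ``snr_stop_db`` (or at
    ``max_iter``, or when the residual energy vanishes).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (dictionary.n,):
        raise ValueError(
            f"signal length {x.size} does not match dictionary length {dictionary.n}"
        )
    energy_x = float(np.dot(x, x))
    if energy_x == 0.0:
        raise ValueError("cannot decompose an all-zero signal")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    residual = x.copy()
    atoms: list[tuple[int, int, int]] = []
    coefficients: list[float] = []
    snr_trace: list[float] = []
    stop_reason = "max_iter"
    for _ in range(max_iter):
        levels = dictionary.analyze(residual)
        flat = np.concatenate([lvl.ravel() for lvl in levels])
        best = int(np.argmax(np.abs(flat)))
        coef = float(flat[best])
        level, node, translate = dictionary._flat_to_index(best)
        residual -= coef * dictionary.atom(level, node, translate)
        atoms.append((level, node, translate))
        coefficients.append(coef)
        er = float(np.dot(residual, residual))
        if er <= 1e-28 * energy_x:
            snr_trace.append(float("inf"))
            stop_reason = "zero_residual"
            break
        snr = 10.0 * float(np.log10(energy_x / er))
        snr_trace.append(snr)
        if snr >= snr_stop_db:
            stop_reason = "snr_reached"
            break
    return MPDecomposition(
        atoms=atoms,
        coefficients=np.array(coefficients),
        residual=residual,
        snr_trace_db=np.array(snr_trace),
        stop_reason=stop_reason,
        dictionary=dictionary,
    )


def reconstruct(
    decomp: MPDecomposition, dictionary: WaveletPacketDictionary | None = None
) -> np.ndarray:
    """Sum of the selected atoms weighted by their coefficients."""
    dictionary = dictionary or decomp.dictionary
    out = np.zeros(dictionary.n)
    for (level, node, translate), coef in zip(decomp.atoms, decomp.coefficients):
        out += coef * dictionary.atom(level, node, translate)
    return out


_DICT_CACHE: dict[tuple[int, str, int | None], WaveletPacketDictionary] = {}


def _cached_dictionary(
    n: int, wavelet: str, depth: int | None
) -> WaveletPacketDictionary:
    key = (n, wavelet, depth)
    if key not in _DICT_CACHE:
        _DICT_CACHE[key] = WaveletPacketDictionary(n, wavelet=wavelet, depth=depth)
    return _DICT_CACHE[key]


def natom_feature(
    x: np.ndarray,
    snr_stop_db: float = 15.0,
    wavelet: str = "db8",
    depth: int | None = None,
    max_iter: int = 2000,
) -> int:
    """Number of matching-pursuit atoms needed to reach the SNR stop.

    The signal is zero-padded to the next power of two (wavelet-packet trees
    need dyadic length; padding preserves energy), decomposed, and the
    iteration count ``M`` returned.
    """
    padded = pad_to_pow2(x)
    dictionary = _cached_dictionary(padded.size, wavelet, depth)
    decomp = mp_decompose(
        padded, dictionary, snr_stop_db=snr_stop_db, max_iter=max_iter
    )
    return decomp.n_iterations
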
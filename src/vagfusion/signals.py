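"""Domain types, amplitude normalization, file I/O and the synthetic cohort.

A vibroarthrographic (VAG) record is a single-channel acceleration signal
captured at the patella while the subject swings the lower leg (roughly 135°
to full extension and back over ~4 s), digitized at 2 kHz. Records from
degenerated joints show higher amplitude variability, more and larger
transient bursts (cartilage friction, crepitus) and more broadband noise
than records from healthy knees; the synthetic generator emulates exactly
those contrasts so the downstream features and classifiers can be exercised
without the (non-public) clinical data.

Signal files are one float per line; a cohort is described by a CSV manifest
with columns ``id,path,label``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VagSignal",
    "CohortParams",
    "normalize_amplitude",
    "generate_synthetic_cohort",
    "read_signal_file",
    "read_manifest",
    "write_cohort",
    "write_features",
    "read_features",
    "FEATURE_COLUMNS",
]

LABELS = ("normal", "abnormal", "unknown")

#: Feature table column order: identifier, class label, then the 7 features.
FEATURE_COLUMNS = ["id", "label", "natom", "tcft", "ff1", "ff2", "vms", "mu", "fd"]


@dataclass
class VagSignal:
    """One labeled vibration record.

    samples are in uncalibrated acceleration units (a.u.); ``label`` is one
    of ``normal`` / ``abnormal`` / ``unknown``. The clinical positive class
    (disease) is ``abnormal``, encoded ``+1`` by :attr:`y`; ``normal`` is
    ``-1``.
    """

    samples: np.ndarray
    fs: float = 2000.0
    label: str = "unknown"
    id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"signal {self.id!r} contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )

    @property
    def y(self) -> int:
        """±1 class encoding (+1 abnormal/diseased, −1 normal)."""
        if self.label == "unknown":
            raise ValueError(f"signal {self.id!r} has no class label")
        return 1 if self.label == "abnormal" else -1

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def normalize_amplitude(signal: VagSignal) -> VagSignal:
    """Linearly rescale a record so its amplitude spans exactly [0, 1].

    Preserves the ordering (hence all variability structure) of the samples.
    A constant signal has no amplitude information and raises ``ValueError``
    rather than silently mapping to zeros, which would corrupt downstream
    turns counts.
    """
    lo = float(np.min(signal.samples))
    hi = float(np.max(signal.samples))
    if hi <= lo:
        raise ValueError(
            f"cannot normalize constant signal {signal.id!r} (zero amplitude range)"
        )
    return replace(signal, samples=(signal.samples - lo) / (hi - lo))


@dataclass
class CohortParams:
    """Stated world of the synthetic two-class VAG cohort.

    Defaults mirror the clinical acquisition (2 kHz, 4 s, 51 normal vs 38
    abnormal records) and the qualitative class contrast: the abnormal class
    gets about tenfold more transient bursts, 1.5x larger burst amplitudes,
    fivefold higher broadband noise and a small 50 Hz powerline component.
    """

    n_normal: int = 51
    n_abnormal: int = 38
    seed: int = 0
    n_samples: int = 8000
    fs: float = 2000.0
    base_band: tuple[float, float] = (0.5, 2.0)
    transient_rate_normal: float = 2.0
    transient_rate_abnormal: float = 20.0
    transient_amp: float = 1.0
    noise_sd_normal: float = 0.05
    noise_sd_abnormal: float = 0.25
    powerline_hz: float = 50.0
    powerline_amp: float = 0.05
    quantization_bits: int = 12
    quantize: bool = False

    def __post_init__(self):
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.transient_rate_normal < 0 or self.transient_rate_abnormal < 0:
            raise ValueError("transient rates must be >= 0")
        if self.noise_sd_normal < 0 or self.noise_sd_abnormal < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


#: Abnormal transient bursts are drawn with this fixed amplitude multiplier
#: relative to ``transient_amp`` (the diseased class shows larger as well as
#: more frequent bursts).
ABNORMAL_TRANSIENT_SCALE = 1.5


def _one_signal(rng: np.random.Generator, p: CohortParams, abnormal: bool) -> np.ndarray:
    n, fs = p.n_samples, p.fs
    t = np.arange(n) / fs
    duration = n / fs
    # Smooth swing component: two sinusoids drawn from the base band with a
    # slow envelope, emulating the leg-swing acceleration profile.
    f1, f2 = rng.uniform(*p.base_band, size=2)
    a1 = rng.uniform(0.7, 1.0)
    a2 = rng.uniform(0.3, 0.5)
    ph = rng.uniform(0, 2 * np.pi, size=2)
    env = 0.6 + 0.4 * np.sin(np.pi * t / duration) ** 2
    x = env * (a1 * np.sin(2 * np.pi * f1 * t + ph[0]) + a2 * np.sin(2 * np.pi * f2 * t + ph[1]))
    # Transient bursts: raised-cosine pulses 5-20 ms wide, random sign.
    rate = p.transient_rate_abnormal if abnormal else p.transient_rate_normal
    amp_scale = p.transient_amp * (ABNORMAL_TRANSIENT_SCALE if abnormal else 1.0)
    n_bursts = rng.poisson(rate)
    for _ in range(n_bursts):
        width = int(round(rng.uniform(0.005, 0.020) * fs))
        width = max(width, 2)
        start = rng.integers(0, max(n - width, 1))
        amp = amp_scale * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
        k = np.arange(width)
        x[start : start + width] += amp * 0.5 * (1 - np.cos(2 * np.pi * k / width))
    # Broadband instrumentation/muscle noise; abnormal records are noisier.
    sd = p.noise_sd_abnormal if abnormal else p.noise_sd_normal
    x += rng.normal(0.0, sd, size=n)
    # Powerline interference contaminates the noisy (abnormal) records.
    if abnormal and p.powerline_amp > 0:
        x += p.powerline_amp * np.sin(2 * np.pi * p.powerline_hz * t + rng.uniform(0, 2 * np.pi))
    if p.quantize:
        x = _quantize(x, p.quantization_bits)
    return x


def _quantize(x: np.ndarray, bits: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return x
    levels = (1 << bits) - 1
    step = (hi - lo) / levels
    return lo + np.round((x - lo) / step) * step


def generate_synthetic_cohort(params: CohortParams) -> list[VagSignal]:
    """Deterministically generate the two-class synthetic cohort.

    Returns ``n_normal`` signals labeled ``normal`` followed by
    ``n_abnormal`` labeled ``abnormal``; bit-identical for equal ``params``.
    """
    rng = np.random.default_rng(params.seed)
    signals: list[VagSignal] = []
    for i in range(params.n_normal):
        signals.append(
            VagSignal(
                _one_signal(rng, params, abnormal=False),
                fs=params.fs,
                label="normal",
                id=f"normal-{i + 1:03d}",
            )
        )
    for i in range(params.n_abnormal):
        signals.append(
            VagSignal(
                _one_signal(rng, params, abnormal=True),
                fs=params.fs,
                label="abnormal",
                id=f"abnormal-{i + 1:03d}",
            )
        )
    return signals


class ManifestError(ValueError):
    """Raised for malformed manifests or signal files."""


def read_signal_file(path: str | os.PathLike, fs: float = 2000.0,
                     label: str = "unknown", id: str = "") -> VagSignal:
    """Read a one-float-per-line signal file (or a PCM WAV file).

    Raises :class:`ManifestError` naming the file and line on a non-numeric
    entry.
    """
    path = Path(path)
    if path.suffix.lower() == ".wav":
        from scipy.io import wavfile

        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        return VagSignal(np.asarray(data, dtype=float), fs=float(rate),
                         label=label, id=id or path.stem)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ManifestError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from None
    return VagSignal(np.array(values), fs=fs, label=label, id=id or path.stem)


def read_manifest(path: str | os.PathLike, fs: float = 2000.0) -> list[VagSignal]:
    """Load a cohort from a ``id,path,label`` CSV manifest.

    Relative signal paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    table = pd.read_csv(path, comment="#", dtype=str)
    required = {"id", "path", "label"}
    if not required.issubset(table.columns):
        raise ManifestError(
            f"{path}: manifest must have columns id,path,label, got {list(table.columns)}"
        )
    signals = []
    for _, row in table.iterrows():
        label = str(row["label"]).strip()
        if label not in LABELS:
            raise ManifestError(
                f"{path}: unknown label {label!r} for id {row['id']!r}"
            )
        sig_path = Path(row["path"])
        if not sig_path.is_absolute():
            sig_path = path.parent / sig_path
        if not sig_path.exists():
            raise ManifestError(f"{path}: signal file not found: {sig_path}")
        signals.append(
            read_signal_file(sig_path, fs=fs, label=label, id=str(row["id"]))
        )
    return signals


def write_cohort(directory: str | os.PathLike, signals: list[VagSignal],
                 header: str | None = None) -> Path:
    """Write signals as one-column text files plus a manifest CSV.

    Samples are printed with 12 significant digits, enough for the
    write/read round trip used in the tests. Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sig in signals:
        fname = f"{sig.id}.txt"
        np.savetxt(directory / fname, sig.samples, fmt="%.12g")
        rows.append({"id": sig.id, "path": fname, "label": sig.label})
    manifest = directory / "manifest.csv"
    with open(manifest, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(rows, columns=["id", "path", "label"]).to_csv(fh, index=False)
    return manifest


def write_features(path: str | os.PathLike, table: pd.DataFrame,
                   header: str | None = None) -> None:
    """Write a feature table CSV with the canonical column order."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table[FEATURE_COLUMNS].to_csv(fh, index=False)


def read_features(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_features`."""
    table = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"{path}: feature table missing columns {missing}")
    return table
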
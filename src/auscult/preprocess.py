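"""Signal conditioning: bandpass, resampling, truncation, amplitude normalization.

Raw auscultation recordings arrive at heterogeneous sample rates (4-44.1 kHz) and
durations (seconds to minutes). The pipeline reduces every recording to a fixed-length
``CleanSignal``: 2500 samples at 1 kHz, amplitudes strictly inside (-1, 1).

Order of operations: the mean is removed and the 25-400 Hz band is isolated at the
*native* rate first, then the signal is resampled to 1 kHz (so nothing between 400 and
500 Hz can alias), truncated/padded to 2.5 s, and max-normalized. The bandpass is a
2nd-order Butterworth applied forward-backward (zero phase); applying the filter twice
squares its magnitude response, which is accounted for in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .vocab import require_known

TARGET_RATE = 1000
TARGET_LEN = 2500
BAND_LOW = 25.0
BAND_HIGH = 400.0
NORM_EPS = 1e-12       # absolute guard: keeps the all-zero signal at zero
NORM_EPS_REL = 1e-6    # relative guard: keeps the peak strictly below 1.0 at any
                       # input scale AND after a float32 serialization round-trip
MIN_REAL_RATE = 1000


class DataError(ValueError):
    """Raised for corrupt or out-of-contract input data."""


class InvalidRateError(DataError):
    """Raised when a sample rate cannot support the requested operation."""


@dataclass
class RawRecord:
    """One mono audio recording with its class label."""

    samples: np.ndarray
    rate: int
    label: str
    source_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DataError(f"{self.source_id}: samples must be a nonempty 1-D sequence")
        if self.rate < 1:
            raise InvalidRateError(f"{self.source_id}: rate must be positive")
        require_known(self.label)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class CleanSignal:
    """Fixed-length (2500 samples @ 1 kHz) normalized signal."""

    samples: np.ndarray
    label: str
    source_id: str
    synthetic: bool = False
    rate: int = field(default=TARGET_RATE)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (TARGET_LEN,):
            raise DataError(
                f"{self.source_id}: CleanSignal needs exactly {TARGET_LEN} samples, "
                f"got {self.samples.shape}"
            )
        if self.rate != TARGET_RATE:
            raise InvalidRateError(f"{self.source_id}: CleanSignal rate must be {TARGET_RATE}")
        amax = float(np.max(np.abs(self.samples))) if self.samples.size else 0.0
        if not np.isfinite(self.samples).all() or amax >= 1.0:
            raise DataError(f"{self.source_id}: samples must be finite and inside (-1, 1)")


def bandpass(rec: RawRecord, low: float = BAND_LOW, high: float = BAND_HIGH,
             order: int = 2) -> RawRecord:
    """Zero-phase Butterworth bandpass at the record's native rate.

    The mean is subtracted first; the 25 Hz high-pass edge makes this nearly redundant
    but it stabilizes the third-order cumulant estimator downstream.
    """
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if rec.rate <= 2 * high:
        raise InvalidRateError(
            f"{rec.source_id}: rate {rec.rate} Hz cannot represent content up to {high} Hz"
        )
    if not np.isfinite(rec.samples).all():
        raise DataError(f"{rec.source_id}: non-finite samples")
    x = rec.samples - rec.samples.mean()
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    # padlen guard for very short records
    padlen = min(3 * (2 * sos.shape[0] + 1), x.size - 1)
    y = sps.sosfiltfilt(sos, x, padlen=padlen)
    return replace(rec, samples=y)


def resample_to_1khz(rec: RawRecord) -> RawRecord:
    """Polyphase resampling to 1 kHz; assumes content is already below 500 Hz."""
    if rec.rate == TARGET_RATE:
        return replace(rec, samples=rec.samples.copy())
    frac = Fraction(TARGET_RATE, int(rec.rate))
    y = sps.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return replace(rec, samples=y, rate=TARGET_RATE)


def fix_length(rec: RawRecord, n: int = TARGET_LEN) -> RawRecord:
    """Keep the first ``n`` samples; zero-pad shorter records at the end."""
    if rec.rate != TARGET_RATE:
        raise InvalidRateError(f"{rec.source_id}: fix_length expects a {TARGET_RATE} Hz record")
    if rec.samples.size == 0:
        raise DataError(f"{rec.source_id}: empty record")
    x = rec.samples[:n]
    if x.size < n:
        x = np.concatenate([x, np.zeros(n - x.size)])
    return replace(rec, samples=x)


def normalize_amplitude(rec: RawRecord, synthetic: bool = False) -> CleanSignal:
    """Scale by the peak magnitude (plus a tiny epsilon) into the open interval (-1, 1)."""
    if rec.samples.shape != (TARGET_LEN,) or rec.rate != TARGET_RATE:
        raise DataError(f"{rec.source_id}: normalize expects {TARGET_LEN} samples at {TARGET_RATE} Hz")
    if not np.isfinite(rec.samples).all():
        raise DataError(f"{rec.source_id}: non-finite samples")
    peak = float(np.max(np.abs(rec.samples)))
    # relative + absolute epsilon: scale-invariant, zero-safe, and strictly < 1
    # even when peak is huge (a purely absolute epsilon underflows against it)
    y = rec.samples / (peak * (1.0 + NORM_EPS_REL) + NORM_EPS)
    return CleanSignal(samples=y, label=rec.label, source_id=rec.source_id, synthetic=synthetic)


def clean(rec: RawRecord, low: float = BAND_LOW, high: float = BAND_HIGH,
          order: int = 2) -> CleanSignal:
    """Full conditioning chain: bandpass -> resample -> fix_length -> normalize."""
    return normalize_amplitude(fix_length(resample_to_1khz(bandpass(rec, low, high, order))))


# ---------------------------------------------------------------------------
# External interfaces: WAV files, CSV manifests, float32 signal dumps
# ---------------------------------------------------------------------------

def load_wav(path: str | Path, label: str, source_id: str | None = None) -> RawRecord:
    """Read a RIFF WAV (PCM16/PCM32/float, mono or stereo collapsed by channel mean)."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise DataError(f"{path}: unreadable WAV ({exc})") from exc
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if not np.isfinite(data).all():
        raise DataError(f"{path}: non-finite samples")
    if rate < MIN_REAL_RATE:
        raise InvalidRateError(f"{path}: rate {rate} Hz below the minimum {MIN_REAL_RATE} Hz")
    return RawRecord(samples=data, rate=int(rate),
                     label=label, source_id=source_id or path.stem)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a ``path,label[,synthetic]`` CSV manifest."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise DataError(f"manifest {path} lacks columns {sorted(missing)}")
    if "synthetic" not in df.columns:
        df["synthetic"] = 0
    for lab in df["label"].unique():
        require_known(str(lab))
    return df


def load_dataset(manifest: str | Path) -> list[RawRecord]:
    """Load every WAV referenced by a manifest, resolving relative paths against it."""
    mpath = Path(manifest)
    df = load_manifest(mpath)
    records = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = mpath.parent / p
        records.append(load_wav(p, str(row.label)))
    return records


def save_clean(sig: CleanSignal, stem: str | Path) -> None:
    """Persist a CleanSignal as a float32 binary array plus a JSON sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), sig.samples.astype(np.float32))
    meta = {"rate": sig.rate, "label": sig.label, "source_id": sig.source_id,
            "synthetic": int(sig.synthetic)}
    stem.with_suffix(".json").write_text(json.dumps(meta))


def load_clean(stem: str | Path) -> CleanSignal:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    x = np.load(stem.with_suffix(".npy")).astype(np.float64)
    return CleanSignal(samples=x, label=meta["label"], source_id=meta["source_id"],
                       synthetic=bool(meta["synthetic"]))
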
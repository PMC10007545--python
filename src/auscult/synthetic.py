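"""Deterministic surrogate heart and lung sound generator.

These waveforms exist so the whole pipeline can be exercised and tested without any
external corpus. They aim for *spectral separability between classes*, not clinical
realism: each class gets a distinct combination of event timing, frequency band and
tonality, all inside 20-450 Hz so the content survives the 25-400 Hz bandpass.

Heart surrogates: S1/S2 transient pairs at ~1.2 Hz with jitter, plus class-specific
murmurs — AS mid-systolic 150-400 Hz, MR holosystolic 100-300 Hz, MS diastolic
25-120 Hz rumble, MVP mid-systolic click plus a late systolic murmur, N none.

Lung surrogates: breath-cycle (~0.25 Hz) amplitude-modulated band noise, plus
adventitious overlays — P dense fine crackles, BO sparse coarse crackles, BA
clustered crackles, COPD a sustained expiratory wheeze, URTI an intermittent
higher-pitched wheeze, H plain breath sound.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .preprocess import RawRecord
from .vocab import CLASSES, HEART_CLASSES, LUNG_CLASSES, ORIGINAL_COUNTS, require_known

HEART_RATE_HZ = 8000           # the real heart corpus is distributed at 8 kHz
LUNG_RATES_HZ = (4000, 10000, 44100)  # rates cycled across lung records

DEFAULT_HEART_DURATION = (3.0, 6.0)
DEFAULT_LUNG_DURATION = (10.0, 15.0)


def _band_noise(rng, n, rate, low, high):
    noise = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfilt(sos, noise)


def _add_burst(x, t, center, width, freq, amp=1.0, phase=0.0):
    """Add a Gaussian-windowed tone burst in place (S1/S2/click/crackle block).

    Only the +/-5 sigma support is evaluated; the tails are numerically zero.
    """
    rate = 1.0 / (t[1] - t[0])
    lo = max(0, int((center - 5 * width) * rate))
    hi = min(t.size, int((center + 5 * width) * rate) + 1)
    if hi <= lo:
        return
    tt = t[lo:hi] - center
    x[lo:hi] += amp * np.exp(-0.5 * (tt / width) ** 2) * np.sin(2 * np.pi * freq * tt + phase)


def _window(t, start, stop, rise=0.02):
    """Smooth on/off gate between start and stop seconds."""
    from scipy.special import expit
    return expit((t - start) / rise) * expit((stop - t) / rise)


def gen_heart(cls: str, duration: float = 4.0, rate: int = HEART_RATE_HZ,
              seed: int | np.random.SeedSequence = 0) -> RawRecord:
    """Surrogate phonocardiogram for one of the five heart classes."""
    require_known(cls)
    if cls not in HEART_CLASSES:
        raise ValueError(f"{cls!r} is not a heart class {HEART_CLASSES}")
    if duration < 2.5:
        raise ValueError("duration must be >= 2.5 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)

    cycle = 1.0 / 1.2  # ~72 bpm
    t0 = 0.05
    while t0 < duration:
        cyc = cycle * (1.0 + 0.05 * rng.standard_normal())
        s1 = t0 + 0.02
        s2 = t0 + 0.38 * cyc
        _add_burst(x, t, s1, 0.022, 38.0 + 4.0 * rng.standard_normal())
        _add_burst(x, t, s2, 0.016, 52.0 + 4.0 * rng.standard_normal(), amp=0.8)
        sys_start, sys_stop = s1 + 0.05, s2 - 0.03
        dia_start, dia_stop = s2 + 0.05, t0 + 0.95 * cyc
        if cls == "AS":      # mid-systolic, high band
            m = _band_noise(rng, n, rate, 150, 400) * _window(t, sys_start, sys_stop)
            mid = 0.5 * (sys_start + sys_stop)
            x += 0.9 * m * np.exp(-0.5 * ((t - mid) / (0.25 * (sys_stop - sys_start))) ** 2)
        elif cls == "MR":    # holosystolic, mid band
            x += 0.7 * _band_noise(rng, n, rate, 100, 300) * _window(t, s1 + 0.02, s2 + 0.02)
        elif cls == "MS":    # diastolic low-frequency rumble
            x += 0.8 * _band_noise(rng, n, rate, 25, 120) * _window(t, dia_start, dia_stop)
        elif cls == "MVP":   # mid-systolic click + late systolic murmur
            click_t = 0.5 * (sys_start + sys_stop)
            _add_burst(x, t, click_t, 0.003, 300.0, amp=0.9)
            x += 0.5 * _band_noise(rng, n, rate, 150, 300) * _window(t, click_t, sys_stop)
        t0 += cyc
    x += 0.02 * rng.standard_normal(n)
    return RawRecord(samples=x, rate=rate, label=cls,
                     source_id=f"synth-heart-{cls}")


def gen_lung(cls: str, duration: float = 12.0, rate: int = 4000,
             seed: int | np.random.SeedSequence = 0) -> RawRecord:
    """Surrogate respiratory recording for one of the six lung classes."""
    require_known(cls)
    if cls not in LUNG_CLASSES:
        raise ValueError(f"{cls!r} is not a lung class {LUNG_CLASSES}")
    if duration < 2.5:
        raise ValueError("duration must be >= 2.5 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    breath_T = 4.0  # ~0.25 Hz breathing cycle
    phase = 2 * np.pi * t / breath_T
    insp = np.clip(np.sin(phase), 0.0, None) ** 2          # inspiration half
    exp_ = np.clip(-np.sin(phase), 0.0, None) ** 2         # expiration half
    x = (0.35 + 0.65 * insp + 0.35 * exp_) * _band_noise(rng, n, rate, 60, 250)

    def crackles(count_per_cycle, width, freq, amp, window, cluster=False):
        burst_sum = np.zeros(n)
        n_cycles = int(duration / breath_T) + 1
        for c in range(n_cycles):
            base = c * breath_T
            if cluster:
                centers = base + 0.2 * breath_T + 0.08 * np.arange(count_per_cycle) \
                    + 0.02 * rng.standard_normal(count_per_cycle)
            else:
                centers = base + window[0] * breath_T + (window[1] - window[0]) \
                    * breath_T * rng.random(count_per_cycle)
            for ct in centers:
                if 0 < ct < duration:
                    _add_burst(burst_sum, t, ct, width, freq, amp=amp,
                               phase=2 * np.pi * rng.random())
        return burst_sum

    if cls == "P":        # dense fine crackles during inspiration
        x += crackles(25, 0.004, 320.0, 0.9, (0.05, 0.45))
    elif cls == "BO":     # sparse coarse crackles
        x += crackles(8, 0.012, 120.0, 1.1, (0.05, 0.45))
    elif cls == "BA":     # clustered crackles
        x += crackles(6, 0.007, 210.0, 1.0, (0.1, 0.4), cluster=True)
    elif cls == "COPD":   # prolonged expiratory wheeze
        f0 = 190.0 + 15.0 * rng.standard_normal()
        tone = np.sin(2 * np.pi * f0 * t + 0.5 * np.sin(2 * np.pi * 2.0 * t))
        x += 0.9 * tone * exp_
    elif cls == "URTI":   # intermittent high wheeze (random cycles only)
        f0 = 360.0 + 15.0 * rng.standard_normal()
        tone = np.sin(2 * np.pi * f0 * t + 0.4 * np.sin(2 * np.pi * 3.0 * t))
        n_cycles = int(duration / breath_T) + 1
        gate = np.zeros(n)
        for c in range(n_cycles):
            if rng.random() < 0.5:
                gate += _window(t, c * breath_T + 0.55 * breath_T,
                                c * breath_T + 0.95 * breath_T)
        x += 0.8 * tone * gate * (0.3 + exp_)
    x += 0.01 * rng.standard_normal(n)
    return RawRecord(samples=x, rate=rate, label=cls,
                     source_id=f"synth-lung-{cls}")


def gen_record(cls: str, seed, rate: int | None = None,
               duration: float | None = None) -> RawRecord:
    """One surrogate record with class-appropriate defaults and a seeded duration."""
    rng = np.random.default_rng(seed)
    if cls in HEART_CLASSES:
        dur = duration or rng.uniform(*DEFAULT_HEART_DURATION)
        return gen_heart(cls, dur, rate or HEART_RATE_HZ, rng)
    dur = duration or rng.uniform(*DEFAULT_LUNG_DURATION)
    return gen_lung(cls, dur, rate or 4000, rng)


def gen_dataset(counts: int | dict[str, int] | str = "imbalanced", seed: int = 0,
                out_dir: str | Path | None = None,
                audio: bool = True) -> tuple[list[RawRecord], pd.DataFrame]:
    """Generate a labelled surrogate dataset and its manifest.

    ``counts`` is a per-class dict, an integer (records per class), or the preset
    ``"imbalanced"`` reproducing the skewed per-class counts of the real corpora
    (1917 records). Lung records cycle through 4/10/44.1 kHz; heart records are
    8 kHz. If ``out_dir`` is given, 16-bit PCM WAVs and ``manifest.csv`` are written
    there and the manifest paths point at the files. ``audio=False`` skips waveform
    synthesis and returns an empty record list with the full manifest (bookkeeping
    only, e.g. for inspecting the imbalance profile of a large preset).
    """
    if counts == "imbalanced":
        plan = dict(ORIGINAL_COUNTS)
    elif isinstance(counts, int):
        if counts < 1:
            raise ValueError("counts must be >= 1")
        plan = {c: counts for c in CLASSES}
    else:
        plan = {require_known(c): int(k) for c, k in counts.items()}

    records, rows = [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for ci, cls in enumerate(CLASSES):
        if cls not in plan:
            continue
        for i in range(plan[cls]):
            fname = f"synth-{cls}-{i:04d}.wav"
            rows.append({"path": fname, "label": cls, "synthetic": 0})
            if not audio:
                continue
            child = np.random.SeedSequence(entropy=seed, spawn_key=(ci, i))
            rate = None if cls in HEART_CLASSES else LUNG_RATES_HZ[i % len(LUNG_RATES_HZ)]
            rec = gen_record(cls, child, rate=rate)
            rec.source_id = f"synth-{cls}-{i:04d}"
            records.append(rec)
            if out_dir is not None:
                peak = np.max(np.abs(rec.samples)) + 1e-12
                pcm = np.round(rec.samples / peak * 0.9 * 32767).astype(np.int16)
                wavfile.write(out_dir / fname, rec.rate, pcm)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return records, manifest
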
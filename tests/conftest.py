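import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from auscult.preprocess import CleanSignal, TARGET_LEN

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_clean(samples, label="N", source_id="test", synthetic=False):
    """Helper: wrap a raw array (scaled into (-1,1)) as a CleanSignal."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < TARGET_LEN:
        x = np.concatenate([x, np.zeros(TARGET_LEN - x.size)])
    x = x[:TARGET_LEN]
    peak = np.abs(x).max()
    if peak >= 1.0:
        x = x / (peak + 1e-12)
    return CleanSignal(samples=x, label=label, source_id=source_id, synthetic=synthetic)


def qpc_segments(n_seg, seg_len, coupled, seed, f1=0.05, f2=0.08):
    """Classical quadratic-phase-coupling construction: three cosines per segment
    with phases drawn fresh each segment; the third phase is the sum of the first
    two iff ``coupled``."""
    rng = np.random.default_rng(seed)
    t = np.arange(seg_len)
    segs = []
    for _ in range(n_seg):
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        p3 = p1 + p2 if coupled else rng.uniform(0, 2 * np.pi)
        segs.append(np.cos(2 * np.pi * f1 * t + p1)
                    + np.cos(2 * np.pi * f2 * t + p2)
                    + np.cos(2 * np.pi * (f1 + f2) * t + p3))
    return segs
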
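import numpy as np
import pytest

from affecthr.types import SubjectParams

# Hand-enumerable beat sequence used throughout the HR tests:
# pre-stimulus IBI 0.8 s -> baseline 75 bpm; post-stimulus IBIs
# 0.7, 0.8, 0.9, 0.9, 0.95 s assigned at 0.3, 1.1, 2.0, 2.9, 3.85 s.
WORKED_BEATS = np.array([-2.0, -1.2, -0.4, 0.3, 1.1, 2.0, 2.9, 3.85])


@pytest.fixture
def worked_beats():
    return WORKED_BEATS.copy()


@pytest.fixture
def default_params():
    return SubjectParams(subject_id=0)


def brute_force_bins(beat_times, onset):
    """Independent overlap-enumeration oracle for the HR-change bins.

    Explicitly constructs every consecutive-beat IBI span and intersects it
    with each half-second bin; shares no code with the implementation.
    """
    beat_times = list(beat_times)
    pairs = [
        (beat_times[i], beat_times[i] - beat_times[i - 1]) for i in range(1, len(beat_times))
    ]
    pre = [d for (t, d) in pairs if onset - 1.0 <= t < onset]
    baseline = 60.0 / (sum(pre) / len(pre)) if pre else None
    post = [(t, d) for (t, d) in pairs if onset < t <= onset + 4.0]
    bins, valid = [], []
    for k in range(8):
        lo, hi = onset + 0.5 * k, onset + 0.5 * (k + 1)
        total, weighted = 0.0, 0.0
        for t, d in post:
            span_lo, span_hi = t - d, t
            ov = min(span_hi, hi) - max(span_lo, lo)
            if ov > 0:
                total += ov
                weighted += ov * d
        if total > 0 and baseline is not None:
            bins.append(60.0 / (weighted / total) - baseline)
            valid.append(True)
        else:
            bins.append(float("nan"))
            valid.append(False)
    return baseline, bins, valid


@pytest.fixture
def bf_bins():
    return brute_force_bins
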
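"""Canonical double-gamma hemodynamic response function.

h(t) = g(t; 6, 1) - g(t; 16, 1) / 6  with g a gamma density (shape, rate):
response peak near 6 s, undershoot near 16 s, undershoot ratio 1/6. The
kernel is normalised to unit peak so that a beta of 1 produces a signal
excursion of 1 at the response peak.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

PEAK_SHAPE = 6.0
UNDERSHOOT_SHAPE = 16.0
RATE = 1.0
UNDERSHOOT_RATIO = 1.0 / 6.0
DURATION_S = 32.0  # kernel support used for convolution


def double_gamma(t: np.ndarray) -> np.ndarray:
    """Evaluate the unit-peak double-gamma HRF at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, PEAK_SHAPE, scale=1.0 / RATE) - UNDERSHOOT_RATIO * stats.gamma.pdf(
        t, UNDERSHOOT_SHAPE, scale=1.0 / RATE
    )
    h = np.where(t < 0, 0.0, h)
    peak = stats.gamma.pdf(PEAK_SHAPE - 1.0, PEAK_SHAPE, scale=1.0 / RATE) - (
        UNDERSHOOT_RATIO * stats.gamma.pdf(PEAK_SHAPE - 1.0, UNDERSHOOT_SHAPE, scale=1.0 / RATE)
    )
    return h / peak


def boxcar_hrf_regressor(
    sample_times: np.ndarray, onset: float, duration: float, dt: float = 0.05
) -> np.ndarray:
    """Unit boxcar [onset, onset+duration) convolved with the HRF.

    The convolution is evaluated on a fine grid (step ``dt``) and linearly
    interpolated at ``sample_times``; this is the forward model shared by the
    synthetic BOLD generator and the design-matrix builder, so a noiseless
    round trip is exact by construction.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    t_end = float(sample_times.max()) + dt
    grid = np.arange(0.0, t_end + DURATION_S, dt)
    box = ((grid >= onset) & (grid < onset + duration)).astype(float)
    kernel = double_gamma(np.arange(0.0, DURATION_S, dt))
    conv = np.convolve(box, kernel)[: grid.size] * dt
    return np.interp(sample_times, grid, conv)
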
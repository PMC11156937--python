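"""Freeze-index baseline detector (classical band-power ratio, no training).

The freeze index is the ratio of accelerometer power in the 3-8 Hz
"freeze band" (trembling-type FOG) to power in the 0.5-3 Hz locomotor
band, computed in a sliding window.  It long predates learned detectors
and serves here as a training-free ScoreSeries producer so the scoring,
operating-point and agreement stages can be exercised end to end.

Spectral estimator: magnitude-squared FFT of the linearly detrended,
Hann-windowed segment; band power by bin summation with half weight for
bins lying exactly on a band edge.  Edges of the recording are padded by
reflection so every sample gets a centered window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .core_io import Recording, ScoreSeries
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FreezeIndexConfig:
    window_s: float = 4.0
    freeze_band: tuple = (3.0, 8.0)
    locomotor_band: tuple = (0.5, 3.0)
    axis: str = "vertical"      # "vertical" | "norm"
    fi_cap: float = 100.0       # cap when locomotor power is numerically zero
    hop: int = 1                # compute every hop-th window, hold in between

    def __post_init__(self):
        lo1, hi1 = self.locomotor_band
        lo2, hi2 = self.freeze_band
        if not (0 < lo1 < hi1 <= lo2 < hi2):
            raise ValidationError("bands must be positive, ordered and disjoint")
        if self.window_s < 2.0 / lo1:
            raise ValidationError("window must cover >= 2 periods of the lowest band edge")


def _band_weights(freqs: np.ndarray, band: tuple, eps: float = 1e-9) -> np.ndarray:
    lo, hi = band
    w = ((freqs > lo + eps) & (freqs < hi - eps)).astype(float)
    w[np.isclose(freqs, lo, atol=eps)] = 0.5
    w[np.isclose(freqs, hi, atol=eps)] = 0.5
    return w


def freeze_index(recording: Recording, config: FreezeIndexConfig = FreezeIndexConfig()
                 ) -> np.ndarray:
    """Per-sample freeze index (freeze-band power / locomotor-band power)."""
    fs = recording.sampling_rate
    win = int(round(config.window_s * fs))
    n = recording.n_samples
    if n < win:
        raise ValidationError("recording shorter than the analysis window")
    if config.axis == "vertical":
        x = recording.acc[:, 0]
    elif config.axis == "norm":
        x = np.linalg.norm(recording.acc, axis=1)
    else:
        raise ValidationError(f"unknown axis {config.axis!r}")

    pad_l = win // 2
    pad_r = win - 1 - pad_l
    xp = np.pad(x, (pad_l, pad_r), mode="reflect")
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    w_freeze = _band_weights(freqs, config.freeze_band)
    w_loco = _band_weights(freqs, config.locomotor_band)
    hann = np.hanning(win)

    idx = np.arange(0, n, config.hop)
    fi_sparse = np.empty(len(idx))
    chunk = 4096
    windows = np.lib.stride_tricks.sliding_window_view(xp, win)[idx]
    capped = 0
    for c0 in range(0, len(idx), chunk):
        seg = detrend(windows[c0:c0 + chunk], axis=1, type="linear") * hann
        psd = np.abs(np.fft.rfft(seg, axis=1)) ** 2
        p_freeze = psd @ w_freeze
        p_loco = psd @ w_loco
        tiny = p_loco <= 1e-12 * max(psd.sum(), 1e-300)
        ratio = np.where(tiny, config.fi_cap, p_freeze / np.where(tiny, 1.0, p_loco))
        capped += int(tiny.sum())
        fi_sparse[c0:c0 + chunk] = np.minimum(ratio, config.fi_cap)
    if capped:
        logger.warning("freeze index capped at %g for %d window(s) with ~zero locomotor power",
                       config.fi_cap, capped)
    if config.hop == 1:
        return fi_sparse
    return np.interp(np.arange(n), idx, fi_sparse)


def baseline_scores(recording: Recording,
                    config: FreezeIndexConfig = FreezeIndexConfig()) -> ScoreSeries:
    """Freeze index min-max scaled to [0, 1], replicated to all 3 class channels.

    The baseline has no context model, so it is class-agnostic: class
    attribution is left to downstream argmax/thresholding.  A constant
    freeze index maps to a constant 0.5.
    """
    fi = freeze_index(recording, config)
    span = fi.max() - fi.min()
    scaled = (fi - fi.min()) / span if span > 0 else np.full_like(fi, 0.5)
    return ScoreSeries(start_hesitation=scaled.copy(), turn=scaled.copy(),
                       walking=scaled.copy())
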
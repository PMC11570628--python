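"""Motion-index (MI) computation and trace transforms.

The motion index condenses a per-well grayscale video into a bulk-motion
time series: frame *t* contributes the number of pixels whose intensity
changed by at least ``threshold`` gray levels since frame *t − 1*,

    m'(I^t) = #{ (i, j) : |I_ij^t − I_ij^{t−1}| ≥ threshold },

with the default threshold of 10 intensity units.  A stack of T frames
yields a trace of length T − 1.  The transforms here (min-max
normalization, stride subsampling, Hanning smoothing) are the ones applied
to MI traces before distance computation and model training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStack",
    "MotionIndexTrace",
    "motion_index",
    "normalize_trace",
    "subsample",
    "smooth_hanning",
    "conform_length",
]

#: Eq.-style hard default: a pixel "moved" if it changed by >= 10 gray levels.
DEFAULT_THRESHOLD = 10.0

#: Dataset-wide MI normalization ceiling (min-max scaling range 0..6750).
DEFAULT_MI_MAX = 6750.0


@dataclass
class FrameStack:
    """T x H x W stack of non-negative grayscale frames (0-based internally)."""

    frames: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frame stack must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("frame stack needs at least 2 frames")


@dataclass
class MotionIndexTrace:
    """Per-well bulk-motion counts; length is one less than the frame count."""

    values: np.ndarray
    frame_rate: float | None = None
    well_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)


def motion_index(frames: FrameStack | np.ndarray,
                 threshold: float = DEFAULT_THRESHOLD,
                 frame_rate: float | None = None,
                 well_id: str | None = None) -> MotionIndexTrace:
    """Count, per consecutive frame pair, the pixels that changed by >= threshold."""
    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    if arr.ndim != 3:
        raise ValueError(f"frame stack must be T x H x W, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute a motion index")
    diffs = np.abs(np.diff(arr.astype(np.int64, copy=False), axis=0))
    values = (diffs >= threshold).sum(axis=(1, 2))
    return MotionIndexTrace(values=values, frame_rate=frame_rate, well_id=well_id)


def normalize_trace(trace: np.ndarray, lo: float = 0.0, hi: float = DEFAULT_MI_MAX) -> np.ndarray:
    """Min-max scale to [0, 1] against dataset-wide bounds, clipping outliers."""
    if hi <= lo:
        raise ValueError(f"normalization needs hi > lo, got lo={lo}, hi={hi}")
    out = (np.asarray(trace, dtype=float) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def subsample(trace: np.ndarray, stride: int = 5) -> np.ndarray:
    """Keep every ``stride``-th frame starting at index 0."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return np.asarray(trace)[..., ::stride]


def hanning_kernel(window: int) -> np.ndarray:
    """Unit-sum Hanning window of odd size ``window``."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"Hanning window must be odd and >= 3, got {window}")
    w = np.hanning(window)
    return w / w.sum()


def smooth_hanning(trace: np.ndarray, window: int = 11) -> np.ndarray:
    """Smooth with a unit-sum Hanning window, reflection-padded at the edges.

    This is the high-frequency ablation filter: window 11 removes components
    near the frame-rate Nyquist while leaving slow behavioral structure.
    Output length equals input length.  Works on 1-D traces or row-stacked
    2-D trace tables.
    """
    arr = np.asarray(trace, dtype=float)
    n = arr.shape[-1]
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    kernel = hanning_kernel(window)
    half = window // 2
    padded = np.pad(arr, [(0, 0)] * (arr.ndim - 1) + [(half, half)], mode="reflect")
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), -1, padded)


def conform_length(trace: np.ndarray, length: int) -> np.ndarray:
    """Right-truncate or zero-pad a trace to ``length`` samples."""
    arr = np.asarray(trace)
    if arr.shape[-1] >= length:
        return arr[..., :length]
    pad = [(0, 0)] * (arr.ndim - 1) + [(0, length - arr.shape[-1])]
    return np.pad(arr, pad)
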
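"""Ratiometric calcium-imaging quantification.

Implements the analysis applied to two-channel (CFP/YFP) cameleon recordings
of mechanosensory neurons: a rectangular ROI is tracked from frame to frame
by following the intensity-weighted centre of mass, fluorescence in each
channel is summed over the ROI after subtracting the mean of the faintest
decile of ROI pixels (local background), the YFP channel is corrected for
donor bleed-through, and the ratio R = F_yellow / F_cyan is expressed as a
percent change relative to the baseline ratio R0 averaged over the first few
seconds of the recording.  A stimulus-locked response is called when the peak
percent ratio change exceeds a noise-scaled threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BaselineError, ParameterError, TrackingLostError

__all__ = [
    "TwoChannelStack",
    "Roi",
    "RatioTrace",
    "ResponseCall",
    "STIMULUS_DURATIONS",
    "roi_fluorescence",
    "track_roi",
    "compute_ratio_trace",
    "call_response",
]

#: Stimulus durations in seconds: a firm 1 s nose press, or a gentle 3.7 s
#: vibrating "buzz" that mimics the mechanical signature of food.
STIMULUS_DURATIONS = {"press": 1.0, "buzz": 3.7}


@dataclass
class TwoChannelStack:
    """Time-ordered CFP/YFP frame pairs.

    ``cyan`` and ``yellow`` are float arrays of shape (T, H, W) in arbitrary
    intensity units; pixel centres sit at integer (row, col) coordinates.
    """

    cyan: np.ndarray
    yellow: np.ndarray
    frame_rate: float

    def __post_init__(self):
        self.cyan = np.asarray(self.cyan, dtype=float)
        self.yellow = np.asarray(self.yellow, dtype=float)
        if self.cyan.shape != self.yellow.shape:
            raise ParameterError("cyan and yellow channels must share shape")
        if self.cyan.ndim != 3:
            raise ParameterError("channel arrays must be (frames, rows, cols)")
        if not self.frame_rate > 0:
            raise ParameterError("frame_rate must be positive")
        if np.nanmin(self.cyan) < 0 or np.nanmin(self.yellow) < 0:
            raise ParameterError("pixel intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.cyan.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cyan.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def summed(self, t: int) -> np.ndarray:
        return self.cyan[t] + self.yellow[t]


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest.

    On the pixel grid the ROI covers the pixels whose (integer) centres lie
    within ``center +/- half`` along each axis.  The resulting block
    dimensions are frozen at construction and preserved when the ROI is
    re-centred during tracking, so the pixel count never changes along a
    tracked path.
    """

    center: tuple[float, float]
    half_height: float
    half_width: float
    block: tuple[int, int] | None = None

    def __post_init__(self):
        if self.half_height <= 0 or self.half_width <= 0:
            raise ParameterError("ROI half-sizes must be positive")
        if self.block is None:
            eps = 1e-9
            h = (math.floor(self.center[0] + self.half_height + eps)
                 - math.ceil(self.center[0] - self.half_height - eps) + 1)
            w = (math.floor(self.center[1] + self.half_width + eps)
                 - math.ceil(self.center[1] - self.half_width - eps) + 1)
            object.__setattr__(self, "block", (max(1, h), max(1, w)))
        if self.n_pixels < 10:
            raise ParameterError(
                f"ROI area {self.n_pixels} px < 10; the faintest decile would be empty"
            )

    @property
    def block_shape(self) -> tuple[int, int]:
        return self.block

    @property
    def n_pixels(self) -> int:
        h, w = self.block_shape
        return h * w

    def slices(self, image_shape: tuple[int, int]) -> tuple[slice, slice]:
        """Pixel slices of the ROI block, shifted (not shrunk) to stay inside."""
        h, w = self.block_shape
        rows, cols = image_shape
        if h > rows or w > cols:
            raise ParameterError("ROI larger than the image")
        r0 = int(round(self.center[0] - (h - 1) / 2.0))
        c0 = int(round(self.center[1] - (w - 1) / 2.0))
        r0 = min(max(r0, 0), rows - h)
        c0 = min(max(c0, 0), cols - w)
        return slice(r0, r0 + h), slice(c0, c0 + w)


@dataclass
class RatioTrace:
    """Per-frame quantification of one tracked cell."""

    roi_path: list[Roi]
    F_cyan: np.ndarray
    F_yellow: np.ndarray  # bleed-through-corrected acceptor fluorescence
    R: np.ndarray
    R0: float
    dRR0: np.ndarray  # percent ratio change, 100 * (R - R0) / R0
    alpha: float
    frame_rate: float
    baseline_window: float
    baseline_frames: int

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.R)) / self.frame_rate


@dataclass
class ResponseCall:
    """Responder classification for one stimulus presentation."""

    responder: bool
    peak_dRR0: float
    stimulus_kind: str
    stimulus_onset: float
    stimulus_duration: float
    response_window: tuple[float, float]
    sigma_base: float
    threshold_k: float
    floor_pct: float
    threshold: float = field(init=False)

    def __post_init__(self):
        self.threshold = max(self.threshold_k * self.sigma_base, self.floor_pct)


def _decile_background(pixels: np.ndarray) -> tuple[float, int]:
    """Mean of the faintest decile (k = max(1, floor(0.10 N)) pixels)."""
    flat = np.asarray(pixels, dtype=float).ravel()
    n = flat.size
    k = max(1, math.floor(0.10 * n))
    faintest = np.partition(flat, k - 1)[:k]
    return float(faintest.mean()), k


def roi_fluorescence(frame: np.ndarray, roi: Roi, mode: str = "scaled") -> float:
    """Background-subtracted fluorescence F of one ROI in one frame.

    The background estimate is the mean of the faintest 10% of ROI pixels.
    In the default ``scaled`` mode it is removed from the full ROI area,
    F = sum(ROI) - N * bg; the ``literal`` mode subtracts only the decile's
    own sum, F = sum(ROI) - sum(faintest decile).  F is reported as computed
    and may be negative in pathological frames.
    """
    pixels = np.asarray(frame, dtype=float)[roi.slices(frame.shape)]
    n = pixels.size
    if n < 10:
        raise ParameterError("ROI must contain at least 10 pixels")
    bg, k = _decile_background(pixels)
    total = float(pixels.sum())
    if mode == "scaled":
        return total - n * bg
    if mode == "literal":
        return total - k * bg
    raise ParameterError(f"unknown background mode {mode!r}")


def track_roi(stack: TwoChannelStack, initial_roi: Roi) -> list[Roi]:
    """Follow the cell body by its intensity-weighted centre of mass.

    For each frame after the first, the summed two-channel image restricted
    to the previous frame's ROI is background-subtracted with the decile
    rule, negative residuals are clipped to zero, and the ROI is re-centred
    once on the weighted centroid.  ROI dimensions are constant; the path is
    clipped so the ROI block never leaves the image.
    """
    path = [replace(initial_roi)]
    shape = stack.shape
    # validate the initial block fits
    initial_roi.slices(shape)
    for t in range(1, stack.n_frames):
        prev = path[-1]
        rs, cs = prev.slices(shape)
        window = stack.summed(t)[rs, cs]
        bg, _ = _decile_background(window)
        weights = np.clip(window - bg, 0.0, None)
        total = weights.sum()
        if not total > 0:
            raise TrackingLostError(t)
        rows = np.arange(rs.start, rs.stop, dtype=float)
        cols = np.arange(cs.start, cs.stop, dtype=float)
        r_c = float((weights.sum(axis=1) * rows).sum() / total)
        c_c = float((weights.sum(axis=0) * cols).sum() / total)
        path.append(replace(prev, center=(r_c, c_c)))
    return path


def compute_ratio_trace(
    stack: TwoChannelStack,
    roi_path: list[Roi],
    alpha: float = 0.0,
    baseline_window: float = 3.0,
    background_mode: str = "scaled",
) -> RatioTrace:
    """Bleed-through-corrected YFP/CFP ratio trace and percent change.

    Per frame, F_cyan and raw F_yellow come from :func:`roi_fluorescence`;
    the acceptor is corrected for donor bleed-through as
    F_yellow = raw F_yellow - alpha * F_cyan, and R = F_yellow / F_cyan.
    R0 is the mean R over the first ``round(baseline_window * frame_rate)``
    frames, and dRR0 = 100 * (R - R0) / R0.  Frames with F_cyan <= 0 outside
    the baseline yield NaN ratios (propagated, never zeroed).
    """
    if not 0 <= alpha < 1:
        raise ParameterError("alpha must be in [0, 1)")
    n = stack.n_frames
    if len(roi_path) != n:
        raise ParameterError("roi_path length must match the frame count")
    duration = n / stack.frame_rate
    if baseline_window > duration:
        raise ParameterError("baseline_window exceeds the recording duration")

    F_c = np.empty(n)
    F_y_raw = np.empty(n)
    for t in range(n):
        F_c[t] = roi_fluorescence(stack.cyan[t], roi_path[t], mode=background_mode)
        F_y_raw[t] = roi_fluorescence(stack.yellow[t], roi_path[t], mode=background_mode)
    F_y = F_y_raw - alpha * F_c

    n_base = int(round(baseline_window * stack.frame_rate))
    n_base = max(1, min(n_base, n))
    if np.any(F_c[:n_base] <= 0):
        raise BaselineError("F_cyan <= 0 within the baseline window")

    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(F_c > 0, F_y / F_c, np.nan)
    R0 = float(R[:n_base].mean())
    if not R0 > 0:
        raise BaselineError(f"degenerate baseline ratio R0 = {R0}")
    dRR0 = 100.0 * (R - R0) / R0
    return RatioTrace(
        roi_path=list(roi_path),
        F_cyan=F_c,
        F_yellow=F_y,
        R=R,
        R0=R0,
        dRR0=dRR0,
        alpha=alpha,
        frame_rate=stack.frame_rate,
        baseline_window=baseline_window,
        baseline_frames=n_base,
    )


def call_response(
    trace: RatioTrace,
    stimulus_onset: float,
    stimulus_kind: str,
    threshold_k: float = 3.0,
    floor_pct: float = 5.0,
    window_after: float = 10.0,
) -> ResponseCall:
    """Classify a stimulus presentation as response / no response.

    The responder criterion is peak dRR0 within
    [onset, onset + stimulus_duration + window_after] exceeding
    max(threshold_k * sigma_baseline, floor_pct), with sigma_baseline the
    sample SD of dRR0 over the baseline frames.  All thresholds are recorded
    in the returned call.
    """
    if stimulus_kind not in STIMULUS_DURATIONS:
        raise ParameterError(f"stimulus_kind must be one of {sorted(STIMULUS_DURATIONS)}")
    if stimulus_onset < trace.baseline_window:
        raise ParameterError("stimulus_onset must not precede the baseline window")
    duration = STIMULUS_DURATIONS[stimulus_kind]
    t_end_trace = len(trace.R) / trace.frame_rate
    w_start = stimulus_onset
    w_end = stimulus_onset + duration + window_after
    if w_end > t_end_trace:
        warnings.warn(
            f"response window truncated at recording end ({w_end:.1f} -> {t_end_trace:.1f} s)",
            stacklevel=2,
        )
        w_end = t_end_trace

    base = trace.dRR0[: trace.baseline_frames]
    sigma = float(np.nanstd(base, ddof=1)) if trace.baseline_frames > 1 else 0.0
    times = trace.times
    in_window = (times >= w_start) & (times <= w_end)
    window_vals = trace.dRR0[in_window]
    if window_vals.size == 0 or np.all(np.isnan(window_vals)):
        peak = float("nan")
        responder = False
    else:
        peak = float(np.nanmax(window_vals))
        responder = peak > max(threshold_k * sigma, floor_pct)
    return ResponseCall(
        responder=responder,
        peak_dRR0=peak,
        stimulus_kind=stimulus_kind,
        stimulus_onset=stimulus_onset,
        stimulus_duration=duration,
        response_window=(w_start, w_end),
        sigma_base=sigma,
        threshold_k=threshold_k,
        floor_pct=floor_pct,
    )
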
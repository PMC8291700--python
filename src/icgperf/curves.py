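"""ROI time–intensity curves: extraction from image stacks, injection-onset
detection, and smoothing.

The fluorescence recording is a stack of grayscale frames; each region of
interest (ROI) is reduced to one curve by averaging the pixels under its
mask frame by frame.  Downstream perfusion metrics need two pieces of
curve-level preprocessing that the imaging hardware does not provide: the
time at which injected dye first reaches the field of view (the operator
knows the injection time in the operating room; offline we detect it from
the curve itself) and a light moving-average smoothing so that slope
estimation is stable against frame noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SceneStack

#: Minimum number of samples a curve must have to be analysed at all.
MIN_CURVE_SAMPLES = 10

#: First samples of every recording assumed to precede the injection.
GUARANTEED_PRE_INJECTION = 5

#: Onset = background exceeded by this many background SDs ...
ONSET_SD_FACTOR = 3.0
#: ... for at least this many consecutive samples.
ONSET_CONSECUTIVE = 3


@dataclass(frozen=True)
class IntensityCurve:
    """A sampled ROI fluorescence time series.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing.
    intensity
        Fluorescence intensity in arbitrary units (a.u.), same length as
        ``time``.
    roi
        Optional ROI label (``"D1"``, ``"D2"``, ``"D3"``).
    """

    time: np.ndarray
    intensity: np.ndarray
    roi: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if t.size < MIN_CURVE_SAMPLES:
            raise ValueError(
                f"curve has {t.size} samples; at least {MIN_CURVE_SAMPLES} required"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("curve contains non-finite samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class OnsetEstimate:
    """Detected dye-arrival time and pre-injection background statistics."""

    onset_time: float
    background_mean: float
    background_sd: float
    n_background_frames: int
    no_signal: bool = False


def extract_roi_curve(stack: "SceneStack", roi: str) -> IntensityCurve:
    """Reduce an image stack to the mean-intensity curve of one ROI.

    ``intensity[k]`` is the arithmetic mean of frame ``k`` over the ROI's
    boolean mask; sample times are the stack's frame times.
    """
    if roi not in stack.roi_masks:
        raise ValueError(f"unknown ROI {roi!r}; stack has {sorted(stack.roi_masks)}")
    mask = stack.roi_masks[roi]
    if not np.any(mask):
        raise ValueError(f"ROI {roi!r} has an empty mask")
    means = stack.frames[:, mask].mean(axis=1)
    return IntensityCurve(time=stack.frame_times, intensity=means, roi=roi)


def _first_sustained_crossing(
    y: np.ndarray, threshold: float, start: int
) -> int | None:
    """Index of the first sample >= ``start`` that strictly exceeds
    ``threshold`` for :data:`ONSET_CONSECUTIVE` consecutive samples."""
    above = y > threshold
    run = 0
    for i in range(start, y.size):
        run = run + 1 if above[i] else 0
        if run >= ONSET_CONSECUTIVE:
            return i - ONSET_CONSECUTIVE + 1
    return None


def detect_injection_onset(curve: IntensityCurve) -> OnsetEstimate:
    """Detect when injected dye first raises the curve above background.

    The first :data:`GUARANTEED_PRE_INJECTION` samples are taken as
    certainly pre-injection.  Onset is the first time the intensity exceeds
    ``background_mean + 3 * background_sd`` for at least three consecutive
    samples; the background statistics are then recomputed over all samples
    strictly before that onset and the scan is repeated once.  If the curve
    never crosses, the estimate carries ``no_signal=True`` with the onset
    placed at the end of the recording.
    """
    y = curve.intensity
    t = curve.time

    n_bg = GUARANTEED_PRE_INJECTION
    idx = None
    for _ in range(2):  # initial scan, then one refinement pass
        bg = y[:n_bg]
        mean, sd = float(bg.mean()), float(bg.std(ddof=0))
        idx = _first_sustained_crossing(y, mean + ONSET_SD_FACTOR * sd, n_bg)
        if idx is None:
            break
        n_bg = max(idx, GUARANTEED_PRE_INJECTION)

    bg = y[:n_bg]
    if idx is None:
        return OnsetEstimate(
            onset_time=float(t[-1]),
            background_mean=float(bg.mean()),
            background_sd=float(bg.std(ddof=0)),
            n_background_frames=int(bg.size),
            no_signal=True,
        )
    return OnsetEstimate(
        onset_time=float(t[idx]),
        background_mean=float(bg.mean()),
        background_sd=float(bg.std(ddof=0)),
        n_background_frames=int(bg.size),
    )


def smooth_curve(curve: IntensityCurve, window_s: float = 1.0) -> IntensityCurve:
    """Centered moving average with truncated windows at the endpoints.

    The window is ``round(window_s / dt)`` samples, forced odd and at least
    3.  Output length equals input length; constant curves pass through
    unchanged and a linear ramp is preserved away from the endpoint windows.
    """
    dt = curve.dt
    if window_s < dt:
        raise ValueError(f"window_s={window_s} is shorter than the sampling dt={dt}")
    w = int(round(window_s / dt))
    if w % 2 == 0:
        w += 1
    w = max(w, 3)
    n = len(curve)
    if w > n:
        raise ValueError(f"smoothing window of {w} samples exceeds curve length {n}")
    kernel = np.ones(w)
    sums = np.convolve(curve.intensity, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return replace(curve, intensity=sums / counts)
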
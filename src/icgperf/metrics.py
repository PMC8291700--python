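"""First-passage perfusion metrics of an ICG time–intensity curve.

Two parameters quantify tissue perfusion from the fluorescence curve of a
region of interest:

* **BSFI** (background-subtracted peak fluorescence intensity): the peak
  intensity during the dye's first passage minus the pre-injection
  background level.
* **SFI** (slope of fluorescence intensity): the maximal upslope of the
  curve during the rise induced by the first dye wave, in a.u./s.

Both are evaluated inside a first-passage analysis window — a sequence of
at most 60 s starting at the detected dye arrival, cut short at the first
trough after the in-window peak so that recirculating dye is excluded.
Measurements at occlusion and reperfusion are normalised per subject
against the same ROI's baseline measurement, giving dimensionless BSFI- and
SFI-ratios: 1 equals baseline, > 1 hyperintensity, < 1 a perfusion deficit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import signal as sps

from .curves import (
    IntensityCurve,
    OnsetEstimate,
    detect_injection_onset,
    smooth_curve,
)

#: Length of the analysis sequence after dye arrival (s).
ANALYSIS_WINDOW_S = 60.0

#: Minimum recording length required for metric computation (s).
MIN_RECORDING_S = 60.0

#: Default moving-average window for slope estimation (s).
DEFAULT_SMOOTHING_S = 1.0

#: A trough qualifies as the end of the first passage only if its prominence
#: exceeds this fraction of the in-window intensity range (noise guard).
TROUGH_PROMINENCE_FRAC = 0.02

NO_SIGNAL = "no-signal"
TRUNCATED_WINDOW = "truncated-window"


@dataclass(frozen=True)
class FirstPassageWindow:
    """Analysis window ``[start, end]`` in seconds."""

    start: float
    end: float
    truncated: bool = False

    @property
    def degenerate(self) -> bool:
        return not self.end > self.start


@dataclass(frozen=True)
class PerfusionMetrics:
    """BSFI, SFI and bookkeeping for one measurement."""

    bsfi: float
    sfi: float
    peak_time: float
    first_passage_end: float
    background_mean: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RatioMetrics:
    """Baseline-normalised perfusion ratios (1 = baseline)."""

    bsfi_ratio: float
    sfi_ratio: float
    reference_timepoint: str = "T0"


class UndefinedRatioError(ValueError):
    """Raised when a baseline has no measurable signal to normalise by."""


def _window_slice(curve: IntensityCurve, window: FirstPassageWindow) -> slice:
    i0 = int(np.searchsorted(curve.time, window.start, side="left"))
    i1 = int(np.searchsorted(curve.time, window.end, side="right"))
    return slice(i0, i1)


def first_passage_window(
    curve: IntensityCurve, onset: OnsetEstimate
) -> FirstPassageWindow:
    """Locate the first-passage analysis window.

    The window starts at the detected onset and ends at the earliest of:
    60 s after onset, the end of the recording (flagged as truncated), or
    the first local minimum following the in-window global maximum (which
    marks the arrival of recirculating dye).  A no-signal onset yields a
    degenerate zero-length window.
    """
    if onset.no_signal:
        return FirstPassageWindow(start=onset.onset_time, end=onset.onset_time)
    start = onset.onset_time
    hard_end = min(start + ANALYSIS_WINDOW_S, float(curve.time[-1]))
    truncated = float(curve.time[-1]) < start + ANALYSIS_WINDOW_S

    sl = _window_slice(curve, FirstPassageWindow(start, hard_end))
    y = curve.intensity[sl]
    t = curve.time[sl]
    if y.size >= 3:
        ipeak = int(np.argmax(y))
        tail = y[ipeak:]
        if tail.size >= 3:
            prominence = TROUGH_PROMINENCE_FRAC * float(y.max() - y.min())
            troughs, _ = sps.find_peaks(-tail, prominence=max(prominence, 1e-12))
            if troughs.size:
                return FirstPassageWindow(
                    start=start, end=float(t[ipeak + troughs[0]]), truncated=truncated
                )
    return FirstPassageWindow(start=start, end=hard_end, truncated=truncated)


def compute_bsfi(
    curve: IntensityCurve, onset: OnsetEstimate, window: FirstPassageWindow
) -> float:
    """Peak intensity within the window minus the pre-injection background,
    floored at 0.  A degenerate (no-signal) window yields 0."""
    if window.degenerate:
        return 0.0
    y = curve.intensity[_window_slice(curve, window)]
    if y.size == 0:
        return 0.0
    return max(float(y.max()) - onset.background_mean, 0.0)


def compute_sfi(
    curve: IntensityCurve,
    onset: OnsetEstimate,
    window: FirstPassageWindow,
    smoothing_window_s: float = DEFAULT_SMOOTHING_S,
) -> float:
    """Maximal upslope of the smoothed curve within the window, a.u./s.

    The slope is the centered finite difference
    ``(y[k+1] - y[k-1]) / (t[k+1] - t[k-1])`` on the moving-average-smoothed
    curve, restricted to samples at or before the smoothed in-window peak
    (the rising limb), and floored at 0.
    """
    if window.degenerate:
        return 0.0
    smoothed = smooth_curve(curve, smoothing_window_s)
    sl = _window_slice(curve, window)
    if sl.stop - sl.start < 3:
        raise ValueError("first-passage window contains fewer than 3 samples")
    y = smoothed.intensity
    t = smoothed.time
    ipeak = sl.start + int(np.argmax(y[sl]))
    lo = max(sl.start, 1)
    hi = min(ipeak, t.size - 2)
    if hi < lo:
        return 0.0
    k = np.arange(lo, hi + 1)
    slopes = (y[k + 1] - y[k - 1]) / (t[k + 1] - t[k - 1])
    return max(float(slopes.max()), 0.0)


def compute_ratio(
    metrics: PerfusionMetrics,
    baseline_metrics: PerfusionMetrics,
    reference_timepoint: str = "T0",
) -> RatioMetrics:
    """Normalise a measurement against its own-subject baseline.

    Raises :class:`UndefinedRatioError` if the baseline carries a no-signal
    flag or has zero BSFI or SFI — a zero baseline admits no meaningful
    ratio (and would break the downstream log transform).
    """
    if NO_SIGNAL in baseline_metrics.flags:
        raise UndefinedRatioError("baseline measurement is flagged no-signal")
    if baseline_metrics.bsfi <= 0 or baseline_metrics.sfi <= 0:
        raise UndefinedRatioError(
            f"baseline BSFI/SFI must be positive, got "
            f"{baseline_metrics.bsfi}/{baseline_metrics.sfi}"
        )
    return RatioMetrics(
        bsfi_ratio=metrics.bsfi / baseline_metrics.bsfi,
        sfi_ratio=metrics.sfi / baseline_metrics.sfi,
        reference_timepoint=reference_timepoint,
    )


def analyze_measurement(
    curve: IntensityCurve, smoothing_window_s: float = DEFAULT_SMOOTHING_S
) -> PerfusionMetrics:
    """Full single-curve analysis: onset detection, first-passage windowing,
    BSFI and SFI.

    The first-passage window is located on the smoothed curve (trough
    detection is unstable on raw noisy samples); BSFI uses the raw curve,
    SFI the smoothed one.  Deterministic for a fixed curve.
    """
    if curve.duration < MIN_RECORDING_S:
        raise ValueError(
            f"recording of {curve.duration:.1f} s is shorter than the "
            f"{MIN_RECORDING_S:.0f}-s analysis requirement"
        )
    onset = detect_injection_onset(curve)
    smoothed = smooth_curve(curve, smoothing_window_s)
    window = first_passage_window(smoothed, onset)

    flags = set()
    if onset.no_signal:
        flags.add(NO_SIGNAL)
    if window.truncated:
        flags.add(TRUNCATED_WINDOW)

    bsfi = compute_bsfi(curve, onset, window)
    if window.degenerate:
        sfi = 0.0
        peak_time = onset.onset_time
    else:
        sfi = compute_sfi(curve, onset, window, smoothing_window_s)
        sl = _window_slice(curve, window)
        peak_time = float(curve.time[sl.start + int(np.argmax(curve.intensity[sl]))])
    return PerfusionMetrics(
        bsfi=bsfi,
        sfi=sfi,
        peak_time=peak_time,
        first_passage_end=window.end,
        background_mean=onset.background_mean,
        flags=frozenset(flags),
    )


def batch_analyze(
    measurements: Iterable,
    smoothing_window_s: float = DEFAULT_SMOOTHING_S,
    reference_timepoint: str = "T0",
):
    """Analyse a collection of study measurements into a tidy table.

    ``measurements`` is any iterable of objects with ``animal_id``,
    ``group``, ``roi``, ``timepoint`` and ``curve`` attributes (e.g. a
    :class:`~icgperf.simulate.SimulatedStudy`).  Each measurement is
    normalised against the same animal/ROI measurement at the reference
    timepoint; measurements whose baseline is unusable get NaN ratios and
    an ``undefined-ratio`` flag entry.

    Returns a :class:`pandas.DataFrame` with one row per measurement.
    """
    import pandas as pd

    analyzed: list[tuple] = []
    baselines: Mapping[tuple[str, str], PerfusionMetrics] = {}
    for m in measurements:
        metrics = analyze_measurement(m.curve, smoothing_window_s)
        tp = getattr(m.timepoint, "value", m.timepoint)
        if tp == reference_timepoint:
            baselines[(m.animal_id, getattr(m.roi, "value", m.roi))] = metrics
        analyzed.append((m, metrics))

    rows = []
    for m, metrics in analyzed:
        roi = getattr(m.roi, "value", m.roi)
        base = baselines.get((m.animal_id, roi))
        flags = set(metrics.flags)
        try:
            if base is None:
                raise UndefinedRatioError("no baseline measurement found")
            ratios = compute_ratio(metrics, base, reference_timepoint)
            bsfi_ratio, sfi_ratio = ratios.bsfi_ratio, ratios.sfi_ratio
        except UndefinedRatioError:
            bsfi_ratio = sfi_ratio = float("nan")
            flags.add("undefined-ratio")
        rows.append(
            {
                "animal_id": m.animal_id,
                "group": getattr(m.group, "value", m.group),
                "roi": roi,
                "timepoint": getattr(m.timepoint, "value", m.timepoint),
                "bsfi_au": metrics.bsfi,
                "sfi_au_per_s": metrics.sfi,
                "bsfi_ratio": bsfi_ratio,
                "sfi_ratio": sfi_ratio,
                "flags": ";".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)
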
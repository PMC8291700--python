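"""Seeded indicator-dilution simulator for the mesenteric-ischemia design.

The generative model is a standard single-tissue indicator-dilution form: a
gamma-variate arterial input function (AIF) with one recirculation echo
drives a tissue compartment whose impulse response mixes a washout term and
a leak term,

    S(t) = b + drift * t
         + F * [ (1 - L) * (AIF (*) exp(-w t)) + L * (AIF (*) 1) ]

where ``b`` is the pre-injection background, ``F`` the inflow rate
(proportional to regional blood flow), ``w`` the washout rate, and ``L``
the leak fraction — the portion of delivered dye that extravasates through
a damaged capillary bed and pools with no washout.  ``drift`` is a small
optional scattered-light ramp, zero by default.  ``(*)`` is temporal
convolution.

Defaults are calibrated to the experiment the analysis pipeline targets:
superior-mesenteric-branch flow 69.7 ml/min at baseline, exactly 0 during
complete occlusion, group-wise reperfusion hyperemia (60.7 / 97.1 /
142.5 ml/min after 3 / 6 / 10 h of ischemia), control-tissue peak
fluorescence near 16 a.u. at baseline, and capillary leak only in damaged
tissue (ischemic and transitional zones after >= 6 h of ischemia).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

import numpy as np
from scipy import integrate, stats

from .curves import IntensityCurve
from .scoring import HistoDescriptor, MacroScoreInput, descriptor_for_grade


# --------------------------------------------------------------------------
# Study design enums
# --------------------------------------------------------------------------

class Group(str, enum.Enum):
    """Experimental group = duration of mesenteric ischemia."""

    I = "I"    # 3 h of ischemia, n = 7
    II = "II"  # 6 h of ischemia, n = 7
    III = "III"  # 10 h of ischemia, n = 4

    @property
    def ischemia_hours(self) -> int:
        return {"I": 3, "II": 6, "III": 10}[self.value]


class Roi(str, enum.Enum):
    """Regions of interest by perfusion status."""

    D1 = "D1"  # ischemic (clamped branch territory)
    D2 = "D2"  # transitional zone
    D3 = "D3"  # non-ischemic control


class Timepoint(str, enum.Enum):
    T0 = "T0"          # baseline
    T1 = "T1"          # complete occlusion
    T2 = "T2"          # immediately after reperfusion
    T2_15 = "T2+15"    # 15 min after reperfusion
    T2_30 = "T2+30"
    T2_45 = "T2+45"
    T2_60 = "T2+60"

    @property
    def is_reperfusion(self) -> bool:
        return self not in (Timepoint.T0, Timepoint.T1)


TIMEPOINTS: tuple[Timepoint, ...] = tuple(Timepoint)
ROIS: tuple[Roi, ...] = tuple(Roi)

#: Default number of animals per group.
DEFAULT_N_PER_GROUP: Mapping[Group, int] = {Group.I: 7, Group.II: 7, Group.III: 4}

#: Default recording length and camera sampling interval (s).
RECORDING_DURATION_S = 120.0
DEFAULT_DT_S = 0.2

#: Transit-time flow (ml/min): baseline mean/SD, and group-wise reperfusion
#: hyperemia mean/SD; flow is exactly zero during complete occlusion.
BASELINE_FLOW_ML_MIN = 69.7
BASELINE_FLOW_SD = 16.5
REPERFUSION_FLOW_ML_MIN: Mapping[Group, tuple[float, float]] = {
    Group.I: (60.7, 48.4),
    Group.II: (97.1, 31.0),
    Group.III: (142.5, 60.0),
}

#: Inflow rate (1/s) assigned to a tissue fed at baseline flow; calibrated so
#: that the control-tissue background-subtracted peak at baseline is ~16 a.u.
#: (see docs/methods.md).
INFLOW_AT_BASELINE_FLOW = 2.27


def _coerce(cls, value):
    """Accept either the enum member or its string value."""
    try:
        return cls(value)
    except ValueError as exc:
        raise ValueError(
            f"unknown {cls.__name__} {value!r}; expected one of "
            f"{[m.value for m in cls]}"
        ) from exc


# --------------------------------------------------------------------------
# Kinetic parameters and the curve model
# --------------------------------------------------------------------------

_NONNEGATIVE = {
    "baseline_offset", "inflow_rate", "washout_rate", "aif_delay",
    "aif_amplitude", "noise_sd", "scatter_drift",
}
_POSITIVE = {"aif_shape", "aif_scale", "recirc_delay"}
_UNIT_INTERVAL = {"leak_fraction": (0.0, 1.0), "recirc_fraction": (0.0, 1.0)}


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth generative parameters for one ROI in one phase.

    Attributes
    ----------
    baseline_offset : float
        Pre-injection intensity (a.u.).
    inflow_rate : float
        Tissue inflow (1/s); proportional to regional blood flow.
    washout_rate : float
        Intravascular washout rate (1/s).
    leak_fraction : float
        Fraction of delivered dye trapped extravascularly (no washout),
        in [0, 1].  Non-zero only for capillary-damaged tissue.
    aif_delay, aif_shape, aif_scale, aif_amplitude : float
        Gamma-variate arterial input function: onset delay (s), shape
        (dimensionless, > 0), time scale (s), and amplitude (a.u.).
    recirc_fraction : float
        Relative amplitude of the single recirculation echo, in [0, 1).
    recirc_delay : float
        Delay of the recirculation echo (s).
    noise_sd : float
        SD of additive i.i.d. Gaussian camera noise (a.u.).
    scatter_drift : float
        Optional linear scattered-light drift (a.u./s); 0 by default so
        that a zero-inflow curve is exactly flat.
    """

    baseline_offset: float = 5.0
    inflow_rate: float = INFLOW_AT_BASELINE_FLOW
    washout_rate: float = 0.12
    leak_fraction: float = 0.0
    aif_delay: float = 5.0
    aif_shape: float = 3.0
    aif_scale: float = 3.0
    aif_amplitude: float = 1.0
    recirc_fraction: float = 0.15
    recirc_delay: float = 30.0
    noise_sd: float = 0.0
    scatter_drift: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if f.name in _NONNEGATIVE and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v!r}")
            if f.name in _POSITIVE and v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v!r}")
            if f.name in _UNIT_INTERVAL:
                lo, hi = _UNIT_INTERVAL[f.name]
                if not (lo <= v <= hi):
                    raise ValueError(f"{f.name} must be in [{lo}, {hi}], got {v!r}")
        if self.recirc_fraction >= 1.0:
            raise ValueError(
                f"recirc_fraction must be < 1, got {self.recirc_fraction!r}"
            )


def gamma_variate_aif(t: np.ndarray, params: KineticParams) -> np.ndarray:
    """Gamma-variate AIF with one recirculation echo, evaluated at ``t``."""
    def first_pass(tt: np.ndarray) -> np.ndarray:
        x = (tt - params.aif_delay) / params.aif_scale
        out = np.zeros_like(tt, dtype=float)
        pos = x > 0
        out[pos] = params.aif_amplitude * x[pos] ** params.aif_shape * np.exp(-x[pos])
        return out

    return first_pass(t) + params.recirc_fraction * first_pass(t - params.recirc_delay)


def _convolve_trapezoid(a: np.ndarray, k: np.ndarray, dt: float) -> np.ndarray:
    """Causal convolution of two sampled signals by the trapezoidal rule."""
    n = a.size
    full = np.convolve(a, k)[:n]
    return dt * (full - 0.5 * (a[0] * k[:n] + k[0] * a[:n]))


def noiseless_signal(params: KineticParams, t: np.ndarray, dt: float) -> np.ndarray:
    """Evaluate the deterministic part of the curve model on grid ``t``."""
    aif = gamma_variate_aif(t, params)
    washed = _convolve_trapezoid(aif, np.exp(-params.washout_rate * t), dt)
    pooled = integrate.cumulative_trapezoid(aif, dx=dt, initial=0.0)
    tissue = (1.0 - params.leak_fraction) * washed + params.leak_fraction * pooled
    return params.baseline_offset + params.scatter_drift * t + params.inflow_rate * tissue


def simulate_curve(
    params: KineticParams,
    duration: float = RECORDING_DURATION_S,
    dt: float = DEFAULT_DT_S,
    seed: int | None = None,
    roi: str | None = None,
) -> IntensityCurve:
    """Simulate one ROI fluorescence time–intensity curve.

    The noiseless signal follows the convolution model documented at module
    level; i.i.d. Gaussian noise of SD ``noise_sd`` is added on top.  The
    same seed always yields the identical curve.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if duration / dt < 10:
        raise ValueError("duration/dt must be at least 10 samples")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    y = noiseless_signal(params, t, dt)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd, size=n)
    return IntensityCurve(time=t, intensity=y, roi=roi)


# --------------------------------------------------------------------------
# Default parameters per design cell
# --------------------------------------------------------------------------

#: Relative perfusion (1.0 = baseline mesenteric flow) per (roi, timepoint
#: kind); reperfusion cells additionally scale with the group hyperemia
#: factor.  D2 is a 0.5/0.5 convex mixture of D1 and D3.
_D3_OCCLUSION_FACTOR = 1.3   # flow redistributed into the control territory
_D3_REPERFUSION_FLOOR = 1.15
_D2_MIX_WEIGHT = 0.5

#: Leak fraction of damaged tissue at reperfusion, by group (>= 6 h only).
_D1_LEAK: Mapping[Group, float] = {Group.I: 0.0, Group.II: 0.35, Group.III: 0.30}

#: Default camera-noise SD for simulated study curves (a.u.).
DEFAULT_NOISE_SD = 0.4


def _relative_flow(group: Group, roi: Roi, phase: Timepoint) -> float:
    """Regional perfusion relative to baseline mesenteric flow."""
    hyperemia = REPERFUSION_FLOW_ML_MIN[group][0] / BASELINE_FLOW_ML_MIN
    if phase is Timepoint.T0:
        return 1.0
    if phase is Timepoint.T1:
        d1, d3 = 0.0, _D3_OCCLUSION_FACTOR
    else:  # reperfusion and follow-ups: hyperemia is stable over the hour
        d1, d3 = hyperemia, max(_D3_REPERFUSION_FLOOR, hyperemia)
    if roi is Roi.D1:
        return d1
    if roi is Roi.D3:
        return d3
    return _D2_MIX_WEIGHT * d1 + (1.0 - _D2_MIX_WEIGHT) * d3


def _leak_fraction(group: Group, roi: Roi, phase: Timepoint) -> float:
    if roi is Roi.D3 or not phase.is_reperfusion:
        return 0.0
    leak = _D1_LEAK[group]
    if roi is Roi.D2:
        leak *= _D2_MIX_WEIGHT
    return leak


def default_params(group, roi, phase, noise_sd: float = DEFAULT_NOISE_SD) -> KineticParams:
    """Documented kinetic parameters for one cell of the study design.

    Encodes the experiment's structure: zero inflow in the ischemic zone
    during occlusion, intermediate transitional-zone perfusion, group-wise
    reperfusion hyperemia scaled to the printed flow means, and a positive
    leak fraction only in capillary-damaged tissue (D1/D2 after >= 6 h of
    ischemia, i.e. groups II and III).
    """
    group = _coerce(Group, group)
    roi = _coerce(Roi, roi)
    phase = _coerce(Timepoint, phase)
    return KineticParams(
        inflow_rate=INFLOW_AT_BASELINE_FLOW * _relative_flow(group, roi, phase),
        leak_fraction=_leak_fraction(group, roi, phase),
        noise_sd=noise_sd,
    )


# --------------------------------------------------------------------------
# Flow traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowTrace:
    """A simulated transit-time flow (TTFM) recording, in ml/min."""

    time: np.ndarray
    flow: np.ndarray
    group: Group
    phase: Timepoint

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", f)
        if t.shape != f.shape:
            raise ValueError("time and flow must have equal length")
        if np.any(f < 0):
            raise ValueError("flow must be non-negative")
        if self.phase is Timepoint.T1 and np.any(f != 0):
            raise ValueError("occlusion-phase flow must be exactly zero")

    @property
    def mean_flow(self) -> float:
        return float(self.flow.mean())


#: Pulsatile ripple on top of the per-phase mean flow.
_PULSE_HZ = 1.5
_PULSE_REL_AMPLITUDE = 0.05
_FLOW_NOISE_SD = 1.0


def simulate_flow_trace(
    group,
    phase,
    duration: float = 60.0,
    dt: float = 0.1,
    seed: int | None = None,
) -> FlowTrace:
    """Simulate one TTFM trace for the clamped mesenteric branch.

    The per-phase mean flow is drawn from a normal truncated at zero with
    the phase/group mean and SD (baseline 69.7 +/- 16.5 ml/min for every
    group; group-wise hyperemia after reperfusion); a small pulsatile
    ripple and measurement noise are superimposed.  During complete
    occlusion every sample is exactly 0 ml/min.
    """
    group = _coerce(Group, group)
    phase = _coerce(Timepoint, phase)
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    if phase is Timepoint.T1:
        return FlowTrace(time=t, flow=np.zeros(n), group=group, phase=phase)

    if phase is Timepoint.T0:
        mu, sd = BASELINE_FLOW_ML_MIN, BASELINE_FLOW_SD
    else:
        mu, sd = REPERFUSION_FLOW_ML_MIN[group]
    rng = np.random.default_rng(seed)
    mean = float(
        stats.truncnorm.rvs(-mu / sd, np.inf, loc=mu, scale=sd, random_state=rng)
    )
    ripple = _PULSE_REL_AMPLITUDE * mean * np.sin(2 * np.pi * _PULSE_HZ * t)
    noise = rng.normal(0.0, _FLOW_NOISE_SD, size=n)
    return FlowTrace(
        time=t, flow=np.clip(mean + ripple + noise, 0.0, None), group=group, phase=phase
    )


# --------------------------------------------------------------------------
# Image scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSchedule:
    """One cell of the crossed design: group x ROI x timepoint.

    ``roi=None`` denotes a whole-field-of-view cell (all three ROIs), as
    used when simulating an image scene.
    """

    group: Group
    phase: Timepoint
    roi: Roi | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", _coerce(Group, self.group))
        object.__setattr__(self, "phase", _coerce(Timepoint, self.phase))
        if self.roi is not None:
            object.__setattr__(self, "roi", _coerce(Roi, self.roi))


@dataclass(frozen=True)
class SceneStack:
    """A simulated fluorescence recording: frames, times, masks, truth."""

    frames: np.ndarray
    frame_times: np.ndarray
    roi_masks: Mapping[str, np.ndarray]
    ground_truth: Mapping[str, KineticParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", times)
        if frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time x height x width) array")
        if frames.shape[0] != times.size:
            raise ValueError("frame count must equal the number of frame times")
        occupancy = np.zeros(frames.shape[1:], dtype=int)
        for name, mask in self.roi_masks.items():
            if mask.shape != frames.shape[1:]:
                raise ValueError(f"mask {name!r} does not match the frame shape")
            occupancy += mask.astype(int)
        if np.any(occupancy > 1):
            raise ValueError("ROI masks must be pairwise disjoint")


def _default_roi_rects(height: int, width: int) -> dict[str, tuple[int, int, int, int]]:
    """Three non-overlapping rectangles (r0, r1, c0, c1), one per ROI."""
    margin = max(1, height // 8)
    col_w = (width - 4) // 3  # 1-px outer margins + 1-px gaps
    if col_w < 2 or height - 2 * margin < 2:
        raise ValueError("image too small for three non-overlapping ROI masks")
    rects = {}
    for i, roi in enumerate(ROIS):
        c0 = 1 + i * (col_w + 1)
        rects[roi.value] = (margin, height - margin, c0, c0 + col_w)
    return rects


def simulate_scene(
    schedule: PhaseSchedule,
    image_size: tuple[int, int] = (48, 64),
    dt: float = 0.5,
    seed: int | None = None,
    params_by_roi: Mapping[str, KineticParams] | None = None,
) -> SceneStack:
    """Simulate a small fluorescence image stack covering 120 s.

    Every pixel inside an ROI follows that ROI's generative curve plus
    independent per-pixel Gaussian noise; pixels outside all ROIs sit at
    the background level.  ``params_by_roi`` overrides the design defaults
    (by default each ROI uses ``default_params(schedule.group, roi,
    schedule.phase)``).
    """
    height, width = image_size
    if height < 16 or width < 16:
        raise ValueError("image_size must be at least 16 x 16")
    rects = _default_roi_rects(height, width)
    if params_by_roi is None:
        params_by_roi = {
            roi.value: default_params(schedule.group, roi, schedule.phase)
            for roi in ROIS
        }

    n = int(round(RECORDING_DURATION_S / dt)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)

    background = np.mean([p.baseline_offset for p in params_by_roi.values()])
    frames = np.full((n, height, width), background, dtype=np.float64)
    masks: dict[str, np.ndarray] = {}
    for roi_name, (r0, r1, c0, c1) in rects.items():
        params = params_by_roi[roi_name]
        signal = noiseless_signal(params, t, dt)
        mask = np.zeros((height, width), dtype=bool)
        mask[r0:r1, c0:c1] = True
        masks[roi_name] = mask
        frames[:, r0:r1, c0:c1] = signal[:, None, None]
        if params.noise_sd > 0:
            frames[:, r0:r1, c0:c1] += rng.normal(
                0.0, params.noise_sd, size=(n, r1 - r0, c1 - c0)
            )
    return SceneStack(
        frames=frames,
        frame_times=t,
        roi_masks=masks,
        ground_truth=dict(params_by_roi),
    )


# --------------------------------------------------------------------------
# Whole-study simulation
# --------------------------------------------------------------------------

#: Macroscopic-injury severity (0 = normal .. 1 = worst) per design cell,
#: interpolated onto the 4-component 1-4 grade scale.
_MACRO_SEVERITY_D1 = {
    Group.I: {"T1": 0.85, "T2": 0.75, "end": 0.35},
    Group.II: {"T1": 0.88, "T2": 0.80, "end": 0.60},
    Group.III: {"T1": 0.95, "T2": 0.95, "end": 0.95},
}
_D2_SEVERITY_FACTOR = 0.8

#: Chiu grade of the ischemic zone after 3 / 6 / 10 h of ischemia.
_D1_CHIU: Mapping[Group, int] = {Group.I: 3, Group.II: 4, Group.III: 5}

#: Between-animal and between-measurement lognormal variability (SD of the
#: log) applied multiplicatively to the inflow rate.
ANIMAL_EFFECT_SD = 0.20
MEASUREMENT_JITTER_SD = 0.08


@dataclass(frozen=True)
class StudyMeasurement:
    """One (animal, ROI, timepoint) observation with its ground truth."""

    animal_id: str
    group: Group
    roi: Roi
    timepoint: Timepoint
    curve: IntensityCurve
    params: KineticParams
    macro: MacroScoreInput


@dataclass(frozen=True)
class SimulatedStudy:
    """A full simulated experiment with ground truth retained."""

    measurements: tuple[StudyMeasurement, ...]
    flow_traces: Mapping[tuple[str, Timepoint], FlowTrace]
    histology: Mapping[tuple[str, Roi], HistoDescriptor]
    seed: int | None = None

    def __iter__(self) -> Iterator[StudyMeasurement]:
        return iter(self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def animal_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.measurements:
            seen.setdefault(m.animal_id, None)
        return tuple(seen)


def _macro_severity(group: Group, roi: Roi, phase: Timepoint) -> float:
    if roi is Roi.D3 or phase is Timepoint.T0:
        return 0.0
    anchors = _MACRO_SEVERITY_D1[group]
    if phase is Timepoint.T1:
        s = anchors["T1"]
    else:
        # linear recovery (or persistence) from T2 to T2+60
        steps = {"T2": 0.0, "T2+15": 0.25, "T2+30": 0.5, "T2+45": 0.75, "T2+60": 1.0}
        frac = steps[phase.value]
        s = anchors["T2"] + frac * (anchors["end"] - anchors["T2"])
    if roi is Roi.D2:
        s *= _D2_SEVERITY_FACTOR
    return s


def _macro_input(
    group: Group, roi: Roi, phase: Timepoint, rng: np.random.Generator
) -> MacroScoreInput:
    s = _macro_severity(group, roi, phase)
    grades = []
    for _ in range(4):
        g = 1 + int(round(3 * s))
        if s > 0:  # healthy tissue scores the exact floor, as observed
            g += int(rng.choice([-1, 0, 1], p=[0.2, 0.6, 0.2]))
        grades.append(int(np.clip(g, 1, 4)))
    return MacroScoreInput(*grades)


def _histology(group: Group, roi: Roi, rng: np.random.Generator) -> HistoDescriptor:
    if roi is Roi.D1:
        grade = _D1_CHIU[group]
    elif roi is Roi.D2:
        grade = int(rng.choice([1, 2], p=[0.4, 0.6]))
    else:
        grade = int(rng.choice([0, 1], p=[0.5, 0.5]))
    return descriptor_for_grade(grade)


def simulate_study(
    n_per_group: Mapping[Group, int] | None = None,
    seed: int | None = None,
    duration: float = RECORDING_DURATION_S,
    dt: float = DEFAULT_DT_S,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SimulatedStudy:
    """Simulate the full crossed design: animal x ROI x timepoint.

    With the default group sizes (7 / 7 / 4) this yields 18 animals and
    18 x 3 x 7 = 378 curve measurements, each paired with its macroscopic
    component grades, one flow trace per animal and timepoint, and one
    histology descriptor per animal and ROI.  Between-animal variability is
    a lognormal multiplier on the inflow rate shared by all measurements of
    one animal; an independent smaller lognormal jitter is applied per
    measurement.  Ground truth is retained throughout.
    """
    counts = dict(DEFAULT_N_PER_GROUP if n_per_group is None else {
        _coerce(Group, g): int(n) for g, n in n_per_group.items()
    })
    for g, n in counts.items():
        if n <= 0:
            raise ValueError(f"n_per_group[{g.value}] must be positive, got {n}")

    root = np.random.default_rng(seed)
    measurements: list[StudyMeasurement] = []
    flow_traces: dict[tuple[str, Timepoint], FlowTrace] = {}
    histology: dict[tuple[str, Roi], HistoDescriptor] = {}

    for group in Group:
        for i in range(counts.get(group, 0)):
            animal_id = f"{group.value}-{i + 1:02d}"
            animal_effect = float(root.lognormal(0.0, ANIMAL_EFFECT_SD))
            for phase in TIMEPOINTS:
                flow_traces[(animal_id, phase)] = simulate_flow_trace(
                    group, phase, seed=int(root.integers(2**31))
                )
                for roi in ROIS:
                    base = default_params(group, roi, phase, noise_sd=noise_sd)
                    jitter = float(root.lognormal(0.0, MEASUREMENT_JITTER_SD))
                    params = replace(
                        base, inflow_rate=base.inflow_rate * animal_effect * jitter
                    )
                    curve = simulate_curve(
                        params, duration=duration, dt=dt,
                        seed=int(root.integers(2**31)), roi=roi.value,
                    )
                    measurements.append(
                        StudyMeasurement(
                            animal_id=animal_id, group=group, roi=roi,
                            timepoint=phase, curve=curve, params=params,
                            macro=_macro_input(group, roi, phase, root),
                        )
                    )
            for roi in ROIS:
                histology[(animal_id, roi)] = _histology(group, roi, root)

    return SimulatedStudy(
        measurements=tuple(measurements),
        flow_traces=flow_traces,
        histology=histology,
        seed=seed,
    )
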
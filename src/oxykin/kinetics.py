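"""Shared kinetic primitives for oxygen-15 inhalation PET.

Dynamic PET measures frame-mean activity concentrations; the kinetic models
live in continuous time.  This module provides the two containers bridging
that gap (:class:`FrameSchedule`/:class:`FrameTAC` for frame data,
:class:`SampledCurve` for continuous-time curves), the exponential-kernel
convolution that every one-tissue compartment term needs, radioactive-decay
conversion, and the arterial metabolite model that splits the total-blood
input function into its metabolized-water and molecular-oxygen components

    A_w(t) = k_w * [A_t(t) (x) exp(-k_w t)],     A_o(t) = A_t(t) - A_w(t),

where k_w [1/min] is the first-order production rate of metabolized
[15O]water in arterial blood during [15O]O2 inhalation.

Units are minutes for time and kBq/ml for activity concentration throughout.
Tissue density is taken as 1 g/ml, so per-ml and per-g quantities are used
interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "O15_HALF_LIFE_MIN",
    "O15_LAMBDA_PER_MIN",
    "FrameSchedule",
    "SampledCurve",
    "FrameTAC",
    "AifSet",
    "PhysioConstants",
    "expconv",
    "metabolized_water_curve",
    "oxygen_aif",
    "build_aif_set",
    "decay_convert",
    "interpolate_lv_tac",
    "frame_average",
]

#: Physical half-life of oxygen-15, minutes (122.24 s).
O15_HALF_LIFE_MIN = 2.0373
#: Decay constant of oxygen-15, 1/min.
O15_LAMBDA_PER_MIN = float(np.log(2.0) / O15_HALF_LIFE_MIN)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FrameSchedule:
    """Time binning of a dynamic scan: half-open frames [start, end) in minutes."""

    frame_starts: np.ndarray
    frame_ends: np.ndarray

    def __post_init__(self):
        starts = _as_float_array(self.frame_starts, "frame_starts")
        ends = _as_float_array(self.frame_ends, "frame_ends")
        if starts.size != ends.size:
            raise ValueError("frame_starts and frame_ends must have equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if starts[0] < 0:
            raise ValueError("first frame must start at t >= 0")
        if np.any(ends <= starts):
            raise ValueError("each frame end must exceed its start")
        if np.any(starts[1:] < ends[:-1] - 1e-12):
            raise ValueError("frames must be sorted and non-overlapping")
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_ends", ends)

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size

    @property
    def durations(self) -> np.ndarray:
        """Frame durations, minutes."""
        return self.frame_ends - self.frame_starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.frame_starts[0]), float(self.frame_ends[-1])

    def subset(self, t_min: float, t_max: float) -> "FrameSchedule":
        """Frames fully contained in [t_min, t_max]."""
        keep = (self.frame_starts >= t_min - 1e-12) & (self.frame_ends <= t_max + 1e-12)
        if not np.any(keep):
            raise ValueError("no frames inside the requested window")
        return FrameSchedule(self.frame_starts[keep], self.frame_ends[keep])

    @classmethod
    def uniform(cls, t_end: float, frame_minutes: float, t_start: float = 0.0) -> "FrameSchedule":
        n = int(round((t_end - t_start) / frame_minutes))
        edges = t_start + frame_minutes * np.arange(n + 1)
        return cls(edges[:-1], edges[1:])

    @classmethod
    def from_durations(cls, durations_s, t_start: float = 0.0) -> "FrameSchedule":
        """Build from a sequence of frame durations in seconds."""
        d = _as_float_array(durations_s, "durations_s") / 60.0
        edges = t_start + np.concatenate([[0.0], np.cumsum(d)])
        return cls(edges[:-1], edges[1:])


@dataclass(frozen=True)
class SampledCurve:
    """Instantaneous-time curve on a strictly increasing grid (minutes, kBq/ml).

    Linear interpolation between nodes, constant extrapolation outside.
    Values must be non-negative unless ``allow_negative`` is set (difference
    curves such as an oxygen AIF with sampling noise may dip below zero).
    """

    times: np.ndarray
    values: np.ndarray
    allow_negative: bool = False

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        v = _as_float_array(self.values, "values")
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.allow_negative and t.size and v.min() < -1e-9:
            raise ValueError("negative values on a curve not flagged as a difference curve")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.values)

    def with_values(self, values, allow_negative: bool | None = None) -> "SampledCurve":
        return SampledCurve(
            self.times,
            values,
            self.allow_negative if allow_negative is None else allow_negative,
        )

    def same_grid(self, other: "SampledCurve", tol: float = 1e-9) -> bool:
        return self.times.size == other.times.size and np.allclose(
            self.times, other.times, atol=tol, rtol=0.0
        )


@dataclass(frozen=True)
class FrameTAC:
    """Frame-mean activity concentrations on a schedule (the measured quantity)."""

    schedule: FrameSchedule
    activities: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self):
        a = _as_float_array(self.activities, "activities")
        if a.size != self.schedule.n_frames:
            raise ValueError("activities length must equal number of frames")
        object.__setattr__(self, "activities", a)


@dataclass(frozen=True)
class AifSet:
    """Coupled arterial input functions during [15O]O2 inhalation.

    ``total`` is whole-blood activity A_t, ``water`` the metabolized-water
    component A_w, ``oxygen`` the molecular-oxygen component A_o; the three
    satisfy A_t = A_w + A_o on a shared grid.
    """

    total: SampledCurve
    water: SampledCurve
    oxygen: SampledCurve
    kw_used: float

    def __post_init__(self):
        if not (self.total.same_grid(self.water) and self.total.same_grid(self.oxygen)):
            raise ValueError("AifSet curves must share one time grid")
        resid = self.total.values - (self.water.values + self.oxygen.values)
        scale = max(1.0, float(np.max(np.abs(self.total.values), initial=0.0)))
        if np.max(np.abs(resid), initial=0.0) > 1e-9 * scale:
            raise ValueError("AifSet violates total = water + oxygen")
        if self.water.values.size and self.water.values.min() < -1e-9:
            raise ValueError("water AIF must be non-negative")


@dataclass(frozen=True)
class PhysioConstants:
    """Fixed physiological and physical constants of the quantification.

    kw : 1/min
        Production rate of metabolized [15O]water in arterial blood.
    p : dimensionless (printed as g/ml)
        Tissue-to-blood partition coefficient of water.
    f_vein : fraction
        Venous share of cerebral blood volume.
    lambda_decay : 1/min
        Oxygen-15 physical decay constant.
    o2_per_gram_hb : ml O2 / g
        Oxygen bound per gram of haemoglobin.
    hb_conc : g/ml
        Haemoglobin concentration in blood (study input, no canonical value).
    sao2 : fraction
        Arterial oxygen saturation.
    plasma_wb_water_ratio : dimensionless
        Plasma-to-whole-blood activity concentration ratio for [15O]water.
    """

    kw: float = 0.33
    p: float = 0.91
    f_vein: float = 0.835
    lambda_decay: float = O15_LAMBDA_PER_MIN
    o2_per_gram_hb: float = 1.39
    hb_conc: float = 0.15
    sao2: float = 0.98
    plasma_wb_water_ratio: float = 1.08

    def __post_init__(self):
        for name in (
            "kw",
            "p",
            "f_vein",
            "lambda_decay",
            "o2_per_gram_hb",
            "hb_conc",
            "sao2",
            "plasma_wb_water_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.f_vein <= 1):
            raise ValueError("f_vein must be in (0, 1]")
        if not (0 < self.sao2 <= 1):
            raise ValueError("sao2 must be in (0, 1]")


# ---------------------------------------------------------------------------
# exponential-kernel convolution


def expconv(curve: SampledCurve, rate: float) -> SampledCurve:
    """Convolve a piecewise-linear curve with ``exp(-rate * t)``.

    Returns ``I(t) = int_0^t curve(s) exp(-rate (t - s)) ds`` on the grid of
    ``curve`` (the curve is taken as zero before its first node).  The segment
    integrals are evaluated in closed form, so the result is exact for
    piecewise-linear input at any grid spacing.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    t, y = curve.times, curve.values
    if t.size < 2:
        raise ValueError("curve needs at least two time points")
    dt = np.diff(t)
    if rate == 0.0:
        out = np.concatenate([[0.0], np.cumsum(0.5 * dt * (y[:-1] + y[1:]))])
        return SampledCurve(t, out, allow_negative=curve.allow_negative)

    k = rate
    e1 = -np.expm1(-k * dt)  # 1 - exp(-k dt), stable for small k dt
    # segment j contribution to I(t_{j+1}) for linear y on [t_j, t_{j+1}]
    seg = y[:-1] * e1 / k + (y[1:] - y[:-1]) * (1.0 / k - e1 / (k * k * dt))
    decay = 1.0 - e1  # exp(-k dt)
    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        # uniform grid: I_j = decay * I_{j-1} + seg_j is a first-order IIR filter
        src = np.concatenate([[0.0], seg])
        out = lfilter([1.0], [1.0, -decay[0]], src)
    else:
        out = np.empty(t.size)
        out[0] = 0.0
        acc = 0.0
        for j in range(dt.size):
            acc = acc * decay[j] + seg[j]
            out[j + 1] = acc
    return SampledCurve(t, out, allow_negative=curve.allow_negative)


def metabolized_water_curve(total: SampledCurve, kw: float) -> SampledCurve:
    """Metabolized-water AIF ``A_w = kw * [A_t (x) exp(-kw t)]``."""
    if kw < 0:
        raise ValueError("kw must be non-negative")
    if kw == 0.0:
        return total.with_values(np.zeros_like(total.values))
    conv = expconv(total, kw)
    return total.with_values(kw * conv.values)


def oxygen_aif(total: SampledCurve, water: SampledCurve) -> SampledCurve:
    """Molecular-oxygen AIF ``A_o = A_t - A_w`` on the shared grid."""
    if not total.same_grid(water):
        raise ValueError("total and water AIFs must share one time grid")
    return SampledCurve(total.times, total.values - water.values, allow_negative=True)


def build_aif_set(total: SampledCurve, kw: float) -> AifSet:
    """Split a total-blood AIF into its water and oxygen components."""
    water = metabolized_water_curve(total, kw)
    return AifSet(total=total, water=water, oxygen=oxygen_aif(total, water), kw_used=kw)


# ---------------------------------------------------------------------------
# decay conversion


def _frame_decay_factor(schedule: FrameSchedule, lambda_decay: float, t0: float) -> np.ndarray:
    # exact frame mean of exp(-lambda (t - t0)) over [start, end)
    if lambda_decay == 0.0:
        return np.ones(schedule.n_frames)
    s = schedule.frame_starts - t0
    e = schedule.frame_ends - t0
    return (np.exp(-lambda_decay * s) - np.exp(-lambda_decay * e)) / (
        lambda_decay * (e - s)
    )


def decay_convert(tac, direction: str, lambda_decay: float = O15_LAMBDA_PER_MIN, t0: float = 0.0):
    """Convert between decay-corrected and uncorrected activities.

    ``direction`` is ``"to-corrected"`` or ``"to-uncorrected"``; ``t0`` is the
    common reference time (scan start).  For a :class:`FrameTAC` the factor is
    the exact frame mean of the decay exponential (not its midpoint value) and
    the ``decay_corrected`` flag is toggled; converting a TAC that is already
    in the requested state raises.  A :class:`SampledCurve` carries no state
    flag and is converted pointwise.
    """
    if direction not in ("to-corrected", "to-uncorrected"):
        raise ValueError("direction must be 'to-corrected' or 'to-uncorrected'")
    if isinstance(tac, SampledCurve):
        factor = np.exp(-lambda_decay * (tac.times - t0))
        if direction == "to-corrected":
            factor = 1.0 / factor
        return tac.with_values(tac.values * factor)
    if isinstance(tac, FrameTAC):
        if direction == "to-corrected" and tac.decay_corrected:
            raise ValueError("TAC is already decay-corrected")
        if direction == "to-uncorrected" and not tac.decay_corrected:
            raise ValueError("TAC is already uncorrected")
        factor = _frame_decay_factor(tac.schedule, lambda_decay, t0)
        if direction == "to-corrected":
            factor = 1.0 / factor
        return FrameTAC(
            tac.schedule,
            tac.activities * factor,
            decay_corrected=not tac.decay_corrected,
        )
    raise TypeError("decay_convert expects a FrameTAC or SampledCurve")


# ---------------------------------------------------------------------------
# frame <-> curve bridging


def interpolate_lv_tac(tac: FrameTAC) -> SampledCurve:
    """Continuous AIF from a left-ventricle frame TAC.

    Frame means are placed at frame midpoints and joined linearly, with
    constant extrapolation beyond the outer midpoints.  If the first midpoint
    is after t = 0 and the activity rises from baseline, a zero anchor at
    t = 0 is prepended so the inhalation onset is not extrapolated flat.
    """
    if tac.schedule.n_frames < 2:
        raise ValueError("need at least two frames to interpolate an LV TAC")
    t = tac.schedule.midpoints
    v = tac.activities
    rising = v[0] < np.max(v) - 1e-12
    if t[0] > 0.0 and rising:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    elif tac.schedule.frame_starts[0] < t[0]:
        # constant extrapolation back to the first frame edge
        t = np.concatenate([[tac.schedule.frame_starts[0]], t])
        v = np.concatenate([[v[0]], v])
    end = tac.schedule.frame_ends[-1]
    if end > t[-1]:
        t = np.concatenate([t, [end]])
        v = np.concatenate([v, [v[-1]]])
    return SampledCurve(t, np.maximum(v, 0.0))


_QUAD_CACHE: dict = {}


def _frame_quadrature(schedule: FrameSchedule):
    """Trapezoid nodes/weights (step <= 1 s) for frame means, cached per schedule."""
    key = (schedule.frame_starts.tobytes(), schedule.frame_ends.tobytes())
    hit = _QUAD_CACHE.get(key)
    if hit is not None:
        return hit
    ts, ws, idx = [], [], []
    for i in range(schedule.n_frames):
        s, e = schedule.frame_starts[i], schedule.frame_ends[i]
        n = max(2, int(np.ceil((e - s) * 60.0)) + 1)  # step <= 1/60 min
        sub = np.linspace(s, e, n)
        h = (e - s) / (n - 1)
        w = np.full(n, h)
        w[0] = w[-1] = 0.5 * h
        ts.append(sub)
        ws.append(w / (e - s))
        idx.append(np.full(n, i))
    out = (np.concatenate(ts), np.concatenate(ws), np.concatenate(idx), schedule.n_frames)
    _QUAD_CACHE[key] = out
    return out


def frame_average(curve: SampledCurve, schedule: FrameSchedule) -> FrameTAC:
    """Frame means of a continuous curve (trapezoid rule, sub-grid step <= 1 s)."""
    lo, hi = schedule.span
    if lo < curve.times[0] - 1e-9 or hi > curve.times[-1] + 1e-9:
        raise ValueError("schedule extends beyond the support of the curve")
    ts, ws, idx, n = _frame_quadrature(schedule)
    vals = curve(ts)
    means = np.bincount(idx, weights=vals * ws, minlength=n)
    return FrameTAC(schedule, means, decay_corrected=True)
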
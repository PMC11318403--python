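"""Arterial blood-sample processing and estimation of the water production rate.

During [15O]O2 inhalation a fraction of the inhaled oxygen is metabolized to
[15O]water, which appears in arterial blood with first-order kinetics.  The
manual blood-sampling experiment measures whole-blood and plasma counts in a
well counter; after normalization, decay correction and the plasma/whole-blood
ratio correction, the plasma-derived water curve is fitted with

    A_w(t; k_w) = k_w * [A_t(t) (x) exp(-k_w t)]

against the image-derived total-blood input function A_t to estimate k_w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import SampledCurve, metabolized_water_curve

__all__ = [
    "BloodSampleSet",
    "KwFitResult",
    "normalize_well_counts",
    "plasma_to_wholeblood_water",
    "separate_oxygen",
    "estimate_kw",
    "KW_BOUNDS",
    "KW_STARTS",
]

#: Search bounds for k_w, 1/min.
KW_BOUNDS = (0.01, 3.0)
#: Multi-start initial values for the k_w fit.
KW_STARTS = (0.1, 0.33, 1.0)


@dataclass(frozen=True)
class BloodSampleSet:
    """Raw well-counter data for one blood-sampling session.

    Counts are raw detector counts accumulated over ``count_durations``
    seconds for samples of ``sample_masses`` grams drawn at ``draw_times``
    minutes after scan start.  ``cross_cal_factor`` converts counts/s/g to
    kBq/ml so well-counter values match the PET image scale.
    """

    draw_times: np.ndarray
    wb_counts: np.ndarray
    plasma_counts: np.ndarray
    count_durations: np.ndarray
    sample_masses: np.ndarray
    cross_cal_factor: float = 1.0

    def __post_init__(self):
        arrays = {}
        n = None
        for name in ("draw_times", "wb_counts", "plasma_counts", "count_durations", "sample_masses"):
            a = np.asarray(getattr(self, name), dtype=float)
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all sample arrays must have equal length")
            arrays[name] = a
        if n == 0:
            raise ValueError("sample set is empty")
        if np.any(np.diff(arrays["draw_times"]) <= 0):
            raise ValueError("draw_times must be increasing")
        if np.any(arrays["count_durations"] <= 0) or np.any(arrays["sample_masses"] <= 0):
            raise ValueError("count durations and sample masses must be positive")
        if self.cross_cal_factor <= 0:
            raise ValueError("cross_cal_factor must be positive")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)


@dataclass(frozen=True)
class KwFitResult:
    kw_hat: float
    residual_ss: float
    n_samples: int
    converged: bool


def normalize_well_counts(
    samples: BloodSampleSet, lambda_decay: float
) -> tuple[SampledCurve, SampledCurve]:
    """Counts -> decay-corrected activity concentrations (kBq/ml).

    Each compartment value is counts / duration / mass, decay-corrected back
    to scan start with ``exp(+lambda * draw_time)`` and scaled by the
    well-counter/PET cross-calibration factor.  Returns (whole-blood, plasma)
    curves at the draw times.
    """
    decay_back = np.exp(lambda_decay * samples.draw_times)
    scale = samples.cross_cal_factor * decay_back / (
        samples.count_durations * samples.sample_masses
    )
    wb = SampledCurve(samples.draw_times, samples.wb_counts * scale)
    plasma = SampledCurve(samples.draw_times, samples.plasma_counts * scale)
    return wb, plasma


def plasma_to_wholeblood_water(plasma_curve: SampledCurve, ratio: float) -> SampledCurve:
    """Whole-blood-equivalent water concentration from a plasma curve.

    ``ratio`` is the plasma/whole-blood activity concentration ratio for
    [15O]water, so the correction divides by it.
    """
    if ratio <= 0:
        raise ValueError("plasma/whole-blood ratio must be positive")
    return plasma_curve.with_values(plasma_curve.values / ratio)


def separate_oxygen(
    wb_curve: SampledCurve, water_curve: SampledCurve, clamp: bool = True
) -> tuple[SampledCurve, int]:
    """Blood [15O]O2 curve as whole-blood minus water, at the draw times.

    With ``clamp`` the (noise-driven) negative differences are set to zero;
    the second return value counts how many points were clamped.
    """
    if not wb_curve.same_grid(water_curve):
        raise ValueError("whole-blood and water curves must share draw times")
    diff = wb_curve.values - water_curve.values
    n_clamped = 0
    if clamp:
        n_clamped = int(np.sum(diff < 0))
        diff = np.maximum(diff, 0.0)
        return SampledCurve(wb_curve.times, diff), n_clamped
    return SampledCurve(wb_curve.times, diff, allow_negative=True), n_clamped


def _water_model_at(total_aif: SampledCurve, kw: float, times: np.ndarray) -> np.ndarray:
    return metabolized_water_curve(total_aif, kw)(times)


def estimate_kw(total_aif: SampledCurve, measured_water: SampledCurve) -> KwFitResult:
    """Estimate k_w by nonlinear least squares on the measured water samples.

    Minimizes the unweighted sum of squared differences between the model
    water curve (evaluated at the draw times) and the measured values, with
    k_w bounded to ``KW_BOUNDS`` and restarted from each of ``KW_STARTS``.
    """
    t = measured_water.times
    y = measured_water.values
    if t.size < 3:
        raise ValueError("need at least three water samples inside the AIF support")
    if np.all(y == 0.0):
        return KwFitResult(kw_hat=KW_BOUNDS[0], residual_ss=0.0, n_samples=t.size, converged=False)

    def resid(x):
        return _water_model_at(total_aif, float(x[0]), t) - y

    best = None
    for start in KW_STARTS:
        sol = least_squares(
            resid, x0=[start], bounds=([KW_BOUNDS[0]], [KW_BOUNDS[1]]), xtol=1e-12, ftol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol
    converged = bool(best.success and KW_BOUNDS[0] < best.x[0] < KW_BOUNDS[1])
    return KwFitResult(
        kw_hat=float(best.x[0]),
        residual_ss=float(np.sum(best.fun**2)),
        n_samples=int(t.size),
        converged=converged,
    )
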
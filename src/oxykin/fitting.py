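"""Simultaneous CBF/OEF estimation and downstream physiological quantities.

CBF (f) and OEF are estimated jointly by nonlinear least squares on the
concatenated frame residuals of the paired [15O]O2 and [15O]CO2 tissue TACs;
the oxygen-side vascular fraction V_o is recomputed from the current OEF
iterate at every evaluation so the fixed CBV and F_vein stay consistent with
the extraction estimate.  CMRO2 follows as

    CMRO2 = [O2]a * CBF * OEF,      [O2]a = 1.39 * Hb * SaO2,

and the sensitivity of the fit to the assumed water production rate k_w is
quantified by rebuilding the arterial components at perturbed k_w and
re-fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .kinetics import (
    AifSet,
    FrameTAC,
    PhysioConstants,
    SampledCurve,
    build_aif_set,
)
from .tissue import TissueModelParams, forward_co2_tac, forward_o2_tac, vascular_fractions

__all__ = [
    "VoiKineticResult",
    "SensitivityReport",
    "TimeCourseTable",
    "F_BOUNDS",
    "OEF_BOUNDS",
    "fit_cbf_oef",
    "oxygen_content",
    "compute_cmro2",
    "kw_sensitivity",
    "timecourse_aggregate",
    "ratio_correlation",
]

#: Bounds on CBF, ml/min/g.
F_BOUNDS = (0.05, 10.0)
#: Bounds on OEF (physical fraction).
OEF_BOUNDS = (0.0, 1.0)
#: Default start and fallback multi-start grid for (f, OEF).
PRIMARY_START = (1.0, 0.5)
MULTI_STARTS = tuple((f0, e0) for f0 in (0.5, 2.0, 4.0) for e0 in (0.2, 0.7))


@dataclass(frozen=True)
class VoiKineticResult:
    """Estimates and diagnostics for one VOI/session."""

    f_hat: float
    oef_hat: float
    cmro2: float
    v_o: float
    cbv_used: float
    kw_used: float
    residual_ss: float
    n_frames: int
    converged: bool


@dataclass(frozen=True)
class SensitivityEntry:
    perturbation: float
    delta_cbf_pct: float
    delta_cmro2_pct: float
    converged: bool


@dataclass(frozen=True)
class SensitivityReport:
    kw_reference: float
    baseline: VoiKineticResult
    entries: tuple[SensitivityEntry, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "perturbation": [e.perturbation for e in self.entries],
                "delta_cbf_pct": [e.delta_cbf_pct for e in self.entries],
                "delta_cmro2_pct": [e.delta_cmro2_pct for e in self.entries],
                "converged": [e.converged for e in self.entries],
            }
        )


@dataclass(frozen=True)
class TimeCourseTable:
    """Longitudinal cohort summary.

    ``group_stats``: mean/SD of f, CMRO2 and OEF per (group, day, hemisphere).
    ``ratios``: per animal/day ipsilateral/contralateral ratios.
    ``ratio_stats``: mean/SD of the ratios per (group, day).
    """

    group_stats: pd.DataFrame
    ratios: pd.DataFrame
    ratio_stats: pd.DataFrame
    n_sessions: int
    n_excluded: int


def oxygen_content(hb_conc: float, sao2: float, o2_per_gram_hb: float = 1.39) -> float:
    """Arterial oxygen content [O2]a (ml O2 / ml blood)."""
    if hb_conc < 0 or o2_per_gram_hb <= 0:
        raise ValueError("haemoglobin inputs must be non-negative")
    if not (0.0 < sao2 <= 1.0):
        raise ValueError("sao2 must lie in (0, 1]")
    return o2_per_gram_hb * hb_conc * sao2


def compute_cmro2(f: float, oef: float, o2a: float) -> float:
    """CMRO2 = [O2]a * CBF * OEF (ml O2/min/g)."""
    if f < 0 or not (0.0 <= oef <= 1.0) or o2a < 0:
        raise ValueError("inputs out of physiological range")
    return o2a * f * oef


def _joint_residuals(
    x: np.ndarray,
    o2_tac: FrameTAC,
    co2_tac: FrameTAC,
    o2_aifs: AifSet,
    co2_water_aif: SampledCurve,
    cbv: float,
    constants: PhysioConstants,
    use_vw: bool,
    weights: tuple[np.ndarray, np.ndarray] | None,
) -> np.ndarray:
    f, oef = float(x[0]), float(x[1])
    v_o, v_w = vascular_fractions(cbv, oef, constants.f_vein)
    params = TissueModelParams(
        f=f,
        oef=oef,
        cbv=cbv,
        v_o=v_o,
        v_w=v_w if use_vw else 0.0,
        p=constants.p,
        f_vein=constants.f_vein,
    )
    r_o2 = forward_o2_tac(params, o2_aifs, o2_tac.schedule).activities - o2_tac.activities
    r_co2 = (
        forward_co2_tac(params, co2_water_aif, co2_tac.schedule).activities
        - co2_tac.activities
    )
    if weights is not None:
        r_o2 = r_o2 * weights[0]
        r_co2 = r_co2 * weights[1]
    return np.concatenate([r_o2, r_co2])


def fit_cbf_oef(
    o2_tac: FrameTAC,
    co2_tac: FrameTAC,
    o2_aifs: AifSet,
    co2_water_aif: SampledCurve,
    cbv: float,
    constants: PhysioConstants,
    use_vw: bool = False,
    frame_duration_weights: bool = False,
    o2_weight: float = 1.0,
) -> VoiKineticResult:
    """Joint NLLSF of (CBF, OEF) on paired O2/CO2 tissue TACs.

    Residuals of the two scans are concatenated unweighted by default;
    ``frame_duration_weights`` scales each residual by sqrt(frame duration)
    (useful when frame lengths vary within a scan), and ``o2_weight`` can
    down-weight or remove the O2 scan (0 reduces the fit to CO2-only CBF).
    The oxygen vascular fraction V_o is recomputed from the current OEF at
    every iterate; V_w is neglected unless ``use_vw``.  Results with a
    parameter pinned at a bound are flagged unconverged.
    """
    if not (o2_tac.decay_corrected and co2_tac.decay_corrected):
        raise ValueError("tissue TACs must be decay-corrected before fitting")
    weights = None
    w_o2 = np.full(o2_tac.schedule.n_frames, float(o2_weight))
    w_co2 = np.ones(co2_tac.schedule.n_frames)
    if frame_duration_weights:
        w_o2 = w_o2 * np.sqrt(o2_tac.schedule.durations)
        w_co2 = w_co2 * np.sqrt(co2_tac.schedule.durations)
    if frame_duration_weights or o2_weight != 1.0:
        weights = (w_o2, w_co2)

    args = (o2_tac, co2_tac, o2_aifs, co2_water_aif, cbv, constants, use_vw, weights)
    lb = [F_BOUNDS[0], OEF_BOUNDS[0]]
    ub = [F_BOUNDS[1], OEF_BOUNDS[1]]

    def _solve(x0):
        return least_squares(
            _joint_residuals, x0=list(x0), bounds=(lb, ub), args=args, xtol=1e-10, ftol=1e-10
        )

    data_ss = float(np.sum(o2_tac.activities**2) + np.sum(co2_tac.activities**2))

    def _poor(sol):
        pinned = np.any(np.isclose(sol.x, lb, atol=1e-9)) or np.any(
            np.isclose(sol.x, ub, atol=1e-9)
        )
        return (not sol.success) or pinned or (2.0 * sol.cost > 0.25 * data_ss)

    best = _solve(PRIMARY_START)
    if _poor(best):
        for x0 in MULTI_STARTS:
            sol = _solve(x0)
            if sol.cost < best.cost - 1e-15:
                best = sol
            if not _poor(best):
                break

    f_hat, oef_hat = float(best.x[0]), float(best.x[1])
    at_bound = (
        f_hat <= F_BOUNDS[0] + 1e-6
        or f_hat >= F_BOUNDS[1] - 1e-6
        or oef_hat <= OEF_BOUNDS[0] + 1e-6
        or oef_hat >= OEF_BOUNDS[1] - 1e-6
    )
    v_o, _ = vascular_fractions(cbv, oef_hat, constants.f_vein)
    o2a = oxygen_content(constants.hb_conc, constants.sao2, constants.o2_per_gram_hb)
    return VoiKineticResult(
        f_hat=f_hat,
        oef_hat=oef_hat,
        cmro2=compute_cmro2(f_hat, oef_hat, o2a),
        v_o=v_o,
        cbv_used=float(cbv),
        kw_used=float(o2_aifs.kw_used),
        residual_ss=float(np.sum(best.fun**2)),
        n_frames=int(o2_tac.schedule.n_frames + co2_tac.schedule.n_frames),
        converged=bool(best.success) and not at_bound,
    )


def kw_sensitivity(
    o2_tac: FrameTAC,
    co2_tac: FrameTAC,
    o2_total_aif: SampledCurve,
    co2_water_aif: SampledCurve,
    cbv: float,
    constants: PhysioConstants,
    perturbations=(-0.2, 0.2),
    **fit_kwargs,
) -> SensitivityReport:
    """Percent change of fitted CBF and CMRO2 under k_w perturbations.

    For each fractional perturbation pi the O2-scan arterial components are
    rebuilt from the total AIF at k_w (1 + pi) and the joint fit repeated;
    deltas are relative to the unperturbed fit.  The CO2-scan input (pure
    water) does not depend on k_w and is reused.
    """
    baseline = fit_cbf_oef(
        o2_tac,
        co2_tac,
        build_aif_set(o2_total_aif, constants.kw),
        co2_water_aif,
        cbv,
        constants,
        **fit_kwargs,
    )
    entries = []
    for pi in perturbations:
        if pi == 0.0:
            entries.append(SensitivityEntry(0.0, 0.0, 0.0, baseline.converged))
            continue
        res = fit_cbf_oef(
            o2_tac,
            co2_tac,
            build_aif_set(o2_total_aif, constants.kw * (1.0 + pi)),
            co2_water_aif,
            cbv,
            constants,
            **fit_kwargs,
        )
        entries.append(
            SensitivityEntry(
                perturbation=float(pi),
                delta_cbf_pct=100.0 * (res.f_hat / baseline.f_hat - 1.0),
                delta_cmro2_pct=100.0 * (res.cmro2 / baseline.cmro2 - 1.0),
                converged=res.converged,
            )
        )
    return SensitivityReport(
        kw_reference=constants.kw, baseline=baseline, entries=tuple(entries)
    )


_PARAM_COLS = ("f", "cmro2", "oef")


def timecourse_aggregate(results: pd.DataFrame) -> TimeCourseTable:
    """Cohort time-course statistics from per-session VOI results.

    ``results`` needs columns animal, group, day, hemisphere ('ipsi' or
    'contra'), f, cmro2, oef, and optionally ``qc_ok`` (False rows and
    sessions missing their contralateral partner are dropped and counted).
    Returns per-(group, day, hemisphere) means +- SD and per-animal
    ipsi/contra ratios with their group statistics.
    """
    required = {"animal", "group", "day", "hemisphere", *_PARAM_COLS}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    df = results.copy()
    n_in = len(df)
    if "qc_ok" in df.columns:
        df = df[df["qc_ok"].astype(bool)]

    # keep only animal-days with both hemispheres present
    counts = df.groupby(["animal", "day"])["hemisphere"].nunique()
    paired = counts[counts == 2].index
    keyed = df.set_index(["animal", "day"])
    df = keyed[keyed.index.isin(paired)].reset_index()
    n_excluded = n_in - len(df)
    if n_excluded:
        warnings.warn(f"{n_excluded} VOI rows excluded (QC or unpaired)", stacklevel=2)

    if df.empty:
        empty = pd.DataFrame()
        return TimeCourseTable(empty, empty, empty, n_sessions=0, n_excluded=n_excluded)

    group_stats = (
        df.groupby(["group", "day", "hemisphere"])[list(_PARAM_COLS)]
        .agg(["mean", "std", "count"])
        .reset_index()
    )

    wide = df.pivot_table(
        index=["group", "animal", "day"], columns="hemisphere", values=list(_PARAM_COLS)
    )
    ratios = pd.DataFrame(
        {p: wide[(p, "ipsi")] / wide[(p, "contra")] for p in _PARAM_COLS}
    ).reset_index()
    ratio_stats = (
        ratios.groupby(["group", "day"])[list(_PARAM_COLS)]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    n_sessions = int(df.groupby(["animal", "day"]).ngroups)
    return TimeCourseTable(group_stats, ratios, ratio_stats, n_sessions, n_excluded)


def ratio_correlation(ratios_a, ratios_b) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-animal ratio vectors."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least three paired values")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
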
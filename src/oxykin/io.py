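"""CSV dialects, study configuration and the session pipeline.

TAC files carry one dynamic scan per file with columns
``frame_start_min, frame_end_min, activity_kBq_per_ml, decay_corrected``;
blood files carry one sampling session with columns
``draw_time_min, wb_counts, plasma_counts, duration_s, mass_g``.
All parse failures are reported with the offending line number — no silent
coercion.  ``run_pipeline`` chains loading, decay pre-correction, AIF
construction and the joint fit over a manifest of sessions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blood import BloodSampleSet
from .fitting import TimeCourseTable, fit_cbf_oef, timecourse_aggregate
from .kinetics import (
    FrameSchedule,
    FrameTAC,
    PhysioConstants,
    build_aif_set,
    decay_convert,
    interpolate_lv_tac,
)

__all__ = [
    "TAC_COLUMNS",
    "BLOOD_COLUMNS",
    "StudyConfig",
    "SessionManifest",
    "PipelineResult",
    "TacFormatError",
    "read_tac_csv",
    "write_tac_csv",
    "read_blood_csv",
    "write_blood_csv",
    "run_pipeline",
]

log = logging.getLogger("oxykin")

TAC_COLUMNS = ["frame_start_min", "frame_end_min", "activity_kBq_per_ml", "decay_corrected"]
BLOOD_COLUMNS = ["draw_time_min", "wb_counts", "plasma_counts", "duration_s", "mass_g"]


class TacFormatError(ValueError):
    """Malformed TAC/blood CSV; message names the file and line."""


def read_tac_csv(path, allow_negative: bool = False) -> FrameTAC:
    """Read one dynamic-scan TAC; header and frame layout are validated."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TAC_COLUMNS:
        raise TacFormatError(
            f"{path}: header must be exactly {','.join(TAC_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df.empty:
        raise TacFormatError(f"{path}: empty TAC (no data rows)")
    starts = df["frame_start_min"].to_numpy(float)
    ends = df["frame_end_min"].to_numpy(float)
    acts = df["activity_kBq_per_ml"].to_numpy(float)
    # data row i lives on file line i + 2 (header is line 1)
    for i in range(len(df)):
        if not np.isfinite(starts[i]) or not np.isfinite(ends[i]) or not np.isfinite(acts[i]):
            raise TacFormatError(f"{path}: non-finite value on line {i + 2}")
        if ends[i] <= starts[i]:
            raise TacFormatError(f"{path}: frame end <= start on line {i + 2}")
        if i and starts[i] < ends[i - 1] - 1e-12:
            raise TacFormatError(f"{path}: overlapping frame on line {i + 2}")
        if acts[i] < 0 and not allow_negative:
            raise TacFormatError(f"{path}: negative activity on line {i + 2}")
    flags = set(df["decay_corrected"].astype(int))
    if len(flags) != 1:
        raise TacFormatError(f"{path}: decay_corrected flag must be constant within a file")
    return FrameTAC(FrameSchedule(starts, ends), acts, decay_corrected=bool(flags.pop()))


def write_tac_csv(tac: FrameTAC, path) -> None:
    pd.DataFrame(
        {
            "frame_start_min": tac.schedule.frame_starts,
            "frame_end_min": tac.schedule.frame_ends,
            "activity_kBq_per_ml": tac.activities,
            "decay_corrected": int(tac.decay_corrected),
        }
    ).to_csv(path, index=False)


def read_blood_csv(path, cross_cal_factor: float = 1.0) -> BloodSampleSet:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != BLOOD_COLUMNS:
        raise TacFormatError(
            f"{path}: header must be exactly {','.join(BLOOD_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df.empty:
        raise TacFormatError(f"{path}: empty blood-sample table")
    try:
        return BloodSampleSet(
            draw_times=df["draw_time_min"].to_numpy(float),
            wb_counts=df["wb_counts"].to_numpy(float),
            plasma_counts=df["plasma_counts"].to_numpy(float),
            count_durations=df["duration_s"].to_numpy(float),
            sample_masses=df["mass_g"].to_numpy(float),
            cross_cal_factor=cross_cal_factor,
        )
    except ValueError as exc:
        raise TacFormatError(f"{path}: {exc}") from exc


def write_blood_csv(samples: BloodSampleSet, path) -> None:
    pd.DataFrame(
        {
            "draw_time_min": samples.draw_times,
            "wb_counts": samples.wb_counts,
            "plasma_counts": samples.plasma_counts,
            "duration_s": samples.count_durations,
            "mass_g": samples.sample_masses,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FittingOptions:
    use_vw: bool = False
    frame_duration_weights: bool = False
    o2_weight: float = 1.0
    default_cbv: float = 0.051


@dataclass(frozen=True)
class StudyConfig:
    constants: PhysioConstants = field(default_factory=PhysioConstants)
    fitting: FittingOptions = field(default_factory=FittingOptions)
    seed: int = 0
    cross_cal_factor: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a config file; unknown keys anywhere are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for section, klass in (("constants", PhysioConstants), ("fitting", FittingOptions)):
            if section in raw:
                sect = raw[section] or {}
                names = {f.name for f in dataclasses.fields(klass)}
                bad = set(sect) - names
                if bad:
                    raise ValueError(f"unknown keys in '{section}': {sorted(bad)}")
                kwargs[section] = klass(**sect)
        for key in ("seed", "cross_cal_factor"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "constants": dataclasses.asdict(self.constants),
                    "fitting": dataclasses.asdict(self.fitting),
                    "seed": self.seed,
                    "cross_cal_factor": self.cross_cal_factor,
                },
                sort_keys=False,
            )
        )


@dataclass(frozen=True)
class SessionManifest:
    """Files and metadata for one animal-day session.

    ``paths`` maps role -> CSV path with roles ``o2_lv``, ``co2_lv``,
    ``o2_ipsi``, ``o2_contra``, ``co2_ipsi``, ``co2_contra`` and optionally
    ``co_tissue``/``co_lv`` for a CBV scan.  QC-failed sessions (poor
    inhalation dose, position shift) are excluded from fitting and counted.
    """

    animal: str
    group: str
    day: int
    paths: dict
    qc_ok: bool = True
    cbv: float | None = None


REQUIRED_ROLES = ("o2_lv", "co2_lv", "o2_ipsi", "o2_contra", "co2_ipsi", "co2_contra")


@dataclass(frozen=True)
class PipelineResult:
    results: pd.DataFrame
    timecourse: TimeCourseTable | None
    n_fitted: int
    n_excluded: int
    exit_code: int  # 0 ok, 3 partial, 4 nothing fitted


def _load_corrected(path, constants: PhysioConstants) -> FrameTAC:
    tac = read_tac_csv(path)
    if not tac.decay_corrected:
        tac = decay_convert(tac, "to-corrected", constants.lambda_decay)
    return tac


def run_pipeline(
    manifests, config: StudyConfig, out_dir=None
) -> PipelineResult:
    """Fit every QC-passing session in the manifest list and aggregate.

    Uncorrected TACs are decay pre-corrected on load; the O2-scan AIF is the
    interpolated LV TAC split at the configured k_w, the CO2-scan input is
    its own LV TAC (pure water).  Per-session results go to
    ``<out_dir>/voi_results.csv`` and the cohort summary to
    ``<out_dir>/timecourse.json`` when ``out_dir`` is given.
    """
    rows = []
    n_excluded = 0
    n_errors = 0
    for m in manifests:
        if not m.qc_ok:
            log.warning("session %s day %s excluded by QC flag", m.animal, m.day)
            n_excluded += 1
            continue
        missing = [r for r in REQUIRED_ROLES if r not in m.paths]
        if missing:
            log.error("session %s day %s missing files: %s", m.animal, m.day, missing)
            n_errors += 1
            continue
        try:
            consts = config.constants
            o2_lv = _load_corrected(m.paths["o2_lv"], consts)
            co2_lv = _load_corrected(m.paths["co2_lv"], consts)
            o2_aifs = build_aif_set(interpolate_lv_tac(o2_lv), consts.kw)
            co2_water = interpolate_lv_tac(co2_lv)
            if m.cbv is not None:
                cbv = m.cbv
            elif "co_tissue" in m.paths and "co_lv" in m.paths:
                from .tissue import cbv_from_co

                cbv = cbv_from_co(
                    _load_corrected(m.paths["co_tissue"], consts),
                    _load_corrected(m.paths["co_lv"], consts),
                )
            else:
                cbv = config.fitting.default_cbv
            for hemi in ("ipsi", "contra"):
                res = fit_cbf_oef(
                    _load_corrected(m.paths[f"o2_{hemi}"], consts),
                    _load_corrected(m.paths[f"co2_{hemi}"], consts),
                    o2_aifs,
                    co2_water,
                    cbv,
                    consts,
                    use_vw=config.fitting.use_vw,
                    frame_duration_weights=config.fitting.frame_duration_weights,
                    o2_weight=config.fitting.o2_weight,
                )
                rows.append(
                    {
                        "animal": m.animal,
                        "group": m.group,
                        "day": m.day,
                        "hemisphere": hemi,
                        "f": res.f_hat,
                        "oef": res.oef_hat,
                        "cmro2": res.cmro2,
                        "v_o": res.v_o,
                        "cbv_used": res.cbv_used,
                        "kw_used": res.kw_used,
                        "residual_ss": res.residual_ss,
                        "converged": res.converged,
                        "qc_ok": True,
                    }
                )
        except (OSError, TacFormatError) as exc:
            log.error("session %s day %s skipped: %s", m.animal, m.day, exc)
            n_errors += 1

    results = pd.DataFrame(rows)
    timecourse = None
    if not results.empty:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            timecourse = timecourse_aggregate(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "voi_results.csv", index=False)
        if timecourse is not None:
            summary = {
                "n_sessions": timecourse.n_sessions,
                "n_excluded": n_excluded,
                "group_stats": json.loads(
                    timecourse.group_stats.to_json(orient="records")
                ),
                "ratio_stats": json.loads(
                    timecourse.ratio_stats.to_json(orient="records")
                ),
            }
            (out_dir / "timecourse.json").write_text(json.dumps(summary, indent=2))
    if results.empty and (n_excluded or n_errors):
        exit_code = 4
    elif n_errors:
        exit_code = 3
    else:
        exit_code = 0
    return PipelineResult(
        results=results,
        timecourse=timecourse,
        n_fitted=len(rows),
        n_excluded=n_excluded,
        exit_code=exit_code,
    )
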
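"""Synthetic oxygen-15 inhalation studies with known ground truth.

No raw scans accompany the quantification method, so validation rests on
simulation: this module generates the arterial input functions, blood-sample
counts, dual-scan tissue TACs, CO scans and longitudinal cohorts that the
two animal experiments would have produced, from explicit ground-truth
parameters.  Every generated dataset is exactly reproducible from its seed.

The protocol defaults mirror the study conditions: continuous 8-min
inhalation of [15O]O2 and [15O]CO2 imaged with 1-min frames over 14 min,
3-min [15O]CO inhalation imaged over 10 min, and — for the blood-sampling
experiment — a 6-min scan with 12x5 s, 8x15 s and 6x30 s frames and 4-5
manual 0.1 ml draws at 30 s intervals starting 30 s after inhalation onset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blood import BloodSampleSet
from .kinetics import (
    AifSet,
    FrameSchedule,
    FrameTAC,
    PhysioConstants,
    SampledCurve,
    build_aif_set,
    frame_average,
    metabolized_water_curve,
)
from .tissue import TissueModelParams

__all__ = [
    "InhalationProfile",
    "GroundTruth",
    "CohortScenario",
    "SessionData",
    "CohortBundle",
    "O2_PROFILE",
    "CO2_PROFILE",
    "CO_PROFILE",
    "EXP1_SCHEDULE",
    "EXP2_SCHEDULE",
    "CO_SCHEDULE",
    "DAY_TO_AGE",
    "make_inhalation_aif",
    "simulate_blood_samples",
    "simulate_dual_scan",
    "simulate_co_scan",
    "generate_cohort",
]


@dataclass(frozen=True)
class InhalationProfile:
    """Saturating-ramp/washout shape of a continuous-inhalation blood curve.

    The total-blood activity rises as ``plateau (1 - exp(-(t-onset)/rise))``
    while gas is supplied, then decays exponentially with the washout time
    constant.  Rise and washout constants are effective whole-body kinetics,
    not gas-line settings.
    """

    onset: float = 0.0
    duration: float = 8.0
    rise_time_constant: float = 8.0
    washout_time_constant: float = 1.5
    plateau_level: float = 100.0

    def __post_init__(self):
        if self.duration <= 0 or self.rise_time_constant <= 0 or self.washout_time_constant <= 0:
            raise ValueError("profile time constants and duration must be positive")
        if self.plateau_level < 0:
            raise ValueError("plateau level must be non-negative")


#: Default inhalation profiles (8 min for O2/CO2, 3 min for CO).  The slow
#: rise constant keeps the total-blood curve growing through the whole
#: inhalation while the oxygen component of the split set levels off after
#: ~3 min at k_w = 0.33 — the qualitative shape of a continuous-inhalation
#: arterial curve.
O2_PROFILE = InhalationProfile(duration=8.0, rise_time_constant=8.0, plateau_level=100.0)
CO2_PROFILE = InhalationProfile(duration=8.0, rise_time_constant=8.0, plateau_level=100.0)
CO_PROFILE = InhalationProfile(duration=3.0, rise_time_constant=0.8, plateau_level=120.0)

#: Blood-sampling experiment: 12x5 s, 8x15 s, 6x30 s frames over 6 min.
EXP1_SCHEDULE = FrameSchedule.from_durations([5.0] * 12 + [15.0] * 8 + [30.0] * 6)
#: Longitudinal experiment: 1-min frames over 14 min.
EXP2_SCHEDULE = FrameSchedule.uniform(14.0, 1.0)
#: CO scan: 1-min frames over 10 min.
CO_SCHEDULE = FrameSchedule.uniform(10.0, 1.0)

#: Imaging day after the hypoxic-ischaemic insult -> postnatal age (days).
DAY_TO_AGE = {0: 9, 1: 10, 2: 11, 7: 16, 14: 23}


@dataclass(frozen=True)
class GroundTruth:
    """True physiological parameters behind one simulated session."""

    f: float = 1.0
    oef: float = 0.5
    cbv: float = 0.051
    kw: float = 0.33
    hb_conc: float = 0.15
    sao2: float = 0.98
    noise_scale: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class CohortScenario:
    """Longitudinal trajectory parameters for a simulated cohort.

    Controls mature multiplicatively between postnatal days 9 and 23
    (defaults: 2.5-fold CBF and 2-fold CMRO2 increase, so OEF drifts by the
    0.8 quotient).  The injured hemisphere of the HIE group is scaled by a
    depression factor that ramps down to its day-2 nadir and then recovers
    linearly; OEF is transiently elevated around day 2.
    """

    groups: tuple[str, ...] = ("HIE", "non-operated", "sham")
    days: tuple[int, ...] = (0, 1, 2, 7, 14)
    f_day0: float = 0.5
    oef_day0: float = 0.55
    cbv: float = 0.051
    kw: float = 0.33
    control_growth_f: float = 2.5
    control_growth_cmro2: float = 2.0
    day2_depression: float = 0.35
    recovery_rate: float = 0.04
    oef_elevation_day2: float = 1.3
    animal_cv: float = 0.08
    noise_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.day2_depression <= 1.0):
            raise ValueError("day2_depression must lie in (0, 1]")
        if self.recovery_rate < 0 or self.animal_cv < 0 or self.noise_scale < 0:
            raise ValueError("rates and noise levels must be non-negative")


@dataclass(frozen=True)
class SessionData:
    """One animal-day: simulated scans for both hemispheres plus truth."""

    animal: str
    group: str
    day: int
    o2_aifs: AifSet
    co2_water_aif: SampledCurve
    o2_tacs: dict
    co2_tacs: dict
    truth: dict
    qc_ok: bool = True


@dataclass(frozen=True)
class CohortBundle:
    sessions: tuple[SessionData, ...]
    truth_table: pd.DataFrame
    scenario: CohortScenario
    seed: int


def make_inhalation_aif(
    profile: InhalationProfile, grid_step: float = 1.0 / 60.0, t_end: float | None = None
) -> SampledCurve:
    """Total-blood AIF for a continuous-inhalation protocol.

    Zero before onset, saturating ramp during inhalation, exponential
    washout after; sampled on a uniform grid (default 1 s).
    """
    if t_end is None:
        t_end = profile.onset + profile.duration + 6.0
    n = int(np.ceil(t_end / grid_step))
    t = np.linspace(0.0, n * grid_step, n + 1)
    v = np.zeros_like(t)
    rising = (t >= profile.onset) & (t <= profile.onset + profile.duration)
    v[rising] = profile.plateau_level * -np.expm1(
        -(t[rising] - profile.onset) / profile.rise_time_constant
    )
    end = profile.onset + profile.duration
    peak = profile.plateau_level * -np.expm1(-profile.duration / profile.rise_time_constant)
    after = t > end
    v[after] = peak * np.exp(-(t[after] - end) / profile.washout_time_constant)
    return SampledCurve(t, v)


@dataclass(frozen=True)
class DrawProtocol:
    """Manual arterial sampling protocol (times in minutes from scan start)."""

    draw_times: tuple = tuple(0.5 + 0.5 * k for k in range(5))
    count_duration_s: float = 30.0
    sample_mass_g: float = 0.1
    cross_cal_factor: float = 1.0


def simulate_blood_samples(
    total_aif: SampledCurve,
    truth: GroundTruth,
    protocol: DrawProtocol = DrawProtocol(),
    noise_cv: float = 0.0,
    seed: int = 0,
    constants: PhysioConstants = PhysioConstants(),
) -> BloodSampleSet:
    """Raw well-counter counts for a blood-sampling session.

    The true water curve follows the metabolite model at ``truth.kw``; raw
    counts are produced by inverting the normalization chain (decay to draw
    time, duration x mass, cross-calibration; plasma = whole-blood water x
    plasma/whole-blood ratio) and multiplied by lognormal noise with the
    given coefficient of variation.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    times = np.asarray(protocol.draw_times, dtype=float)
    if times.min() < total_aif.times[0] or times.max() > total_aif.times[-1]:
        raise ValueError("draw times must lie inside the AIF support")
    water = metabolized_water_curve(total_aif, truth.kw)
    wb_true = total_aif(times)
    water_true = water(times)
    plasma_true = water_true * constants.plasma_wb_water_ratio

    decay = np.exp(-constants.lambda_decay * times)
    to_counts = protocol.count_duration_s * protocol.sample_mass_g / protocol.cross_cal_factor
    wb_counts = wb_true * decay * to_counts
    plasma_counts = plasma_true * decay * to_counts
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
        wb_counts = wb_counts * rng.lognormal(mu, sigma, size=times.size)
        plasma_counts = plasma_counts * rng.lognormal(mu, sigma, size=times.size)
    return BloodSampleSet(
        draw_times=times,
        wb_counts=wb_counts,
        plasma_counts=plasma_counts,
        count_durations=np.full(times.size, protocol.count_duration_s),
        sample_masses=np.full(times.size, protocol.sample_mass_g),
        cross_cal_factor=protocol.cross_cal_factor,
    )


def _frame_noise(rng: np.random.Generator, schedule: FrameSchedule, noise_scale: float):
    if noise_scale == 0.0:
        return np.zeros(schedule.n_frames)
    sd = noise_scale / np.sqrt(schedule.durations)
    return rng.normal(0.0, sd)


def simulate_dual_scan(
    truth: GroundTruth,
    o2_profile: InhalationProfile = O2_PROFILE,
    co2_profile: InhalationProfile = CO2_PROFILE,
    schedules: tuple[FrameSchedule, FrameSchedule] = (EXP2_SCHEDULE, EXP2_SCHEDULE),
    noise_scale: float | None = None,
    seed: int | None = None,
    constants: PhysioConstants = PhysioConstants(),
    use_vw: bool = False,
) -> tuple[FrameTAC, FrameTAC, AifSet, SampledCurve]:
    """Paired O2/CO2 scans for one VOI: (o2_tac, co2_tac, o2_aifs, co2_water_aif).

    Noise-free frame TACs come from the forward models; Gaussian frame noise
    is added with SD = noise_scale / sqrt(frame duration [min]), so longer
    frames are proportionally less noisy.  ``noise_scale``/``seed`` default
    to the values stored in ``truth``.
    """
    if noise_scale is None:
        noise_scale = truth.noise_scale
    # one scale for both scans, or a (o2, co2) pair for per-scan noise levels
    o2_scale, co2_scale = (
        noise_scale if isinstance(noise_scale, tuple) else (noise_scale, noise_scale)
    )
    if seed is None:
        seed = truth.seed
    o2_sched, co2_sched = schedules
    t_end = max(o2_sched.span[1], co2_sched.span[1])
    from .tissue import forward_co2_tac, forward_o2_tac  # local to avoid cycle

    aifs = build_aif_set(make_inhalation_aif(o2_profile, t_end=t_end), truth.kw)
    co2_water = make_inhalation_aif(co2_profile, t_end=t_end)
    params = TissueModelParams.from_physiology(
        truth.f, truth.oef, truth.cbv, constants, use_vw=use_vw
    )
    o2_clean = forward_o2_tac(params, aifs, o2_sched)
    co2_clean = forward_co2_tac(params, co2_water, co2_sched)
    rng = np.random.default_rng(seed)
    o2_tac = FrameTAC(o2_sched, o2_clean.activities + _frame_noise(rng, o2_sched, o2_scale))
    co2_tac = FrameTAC(
        co2_sched, co2_clean.activities + _frame_noise(rng, co2_sched, co2_scale)
    )
    return o2_tac, co2_tac, aifs, co2_water


def simulate_co_scan(
    truth: GroundTruth,
    co_profile: InhalationProfile = CO_PROFILE,
    schedule: FrameSchedule = CO_SCHEDULE,
    seed: int | None = None,
    noise_scale: float = 0.0,
) -> tuple[FrameTAC, FrameTAC]:
    """[15O]CO scan: LV follows the inhalation profile, tissue = CBV x LV."""
    if seed is None:
        seed = truth.seed
    lv_curve = make_inhalation_aif(co_profile, t_end=schedule.span[1])
    lv = frame_average(lv_curve, schedule)
    tissue_clean = truth.cbv * lv.activities
    rng = np.random.default_rng(seed)
    tissue = FrameTAC(schedule, tissue_clean + _frame_noise(rng, schedule, noise_scale))
    return tissue, lv


# ---------------------------------------------------------------------------
# longitudinal cohort


def _control_factors(scenario: CohortScenario, day: int) -> tuple[float, float]:
    """Multiplicative maturation factors (f, oef) at a given imaging day."""
    age = DAY_TO_AGE[day]
    frac = (age - 9) / 14.0
    f_fac = scenario.control_growth_f**frac
    oef_fac = (scenario.control_growth_cmro2 / scenario.control_growth_f) ** frac
    return f_fac, oef_fac


def _depression_factor(scenario: CohortScenario, day: int) -> float:
    """Ipsilateral CBF scaling: ramps to the day-2 nadir, then linear recovery."""
    d2 = scenario.day2_depression
    if day <= 2:
        return 1.0 - (1.0 - d2) * day / 2.0
    return min(1.0, d2 + scenario.recovery_rate * (day - 2))


def _oef_elevation(scenario: CohortScenario, day: int) -> float:
    """Transient ipsilateral OEF elevation, peaking at day 2, gone by day 7."""
    peak = scenario.oef_elevation_day2 - 1.0
    if peak == 0.0:
        return 1.0
    if day <= 2:
        w = day / 2.0
    elif day < 7:
        w = (7.0 - day) / 5.0
    else:
        w = 0.0
    return 1.0 + peak * w


def _group_days(scenario: CohortScenario, group: str) -> tuple[int, ...]:
    if group == "non-operated":
        return tuple(d for d in scenario.days if d != 1)
    if group == "sham":
        return (7,) if 7 in scenario.days else scenario.days[:1]
    return scenario.days


def generate_cohort(
    scenario: CohortScenario = CohortScenario(),
    n_per_group: dict | int = None,
    seed: int = 0,
    constants: PhysioConstants = PhysioConstants(),
    schedules: tuple[FrameSchedule, FrameSchedule] = (EXP2_SCHEDULE, EXP2_SCHEDULE),
) -> CohortBundle:
    """Full longitudinal study: dual scans per animal/day/hemisphere + truth.

    Per-animal lognormal scale factors (CV ``scenario.animal_cv``) are drawn
    once and applied across all of that animal's sessions, so longitudinal
    ratios are preserved.  The HIE ipsilateral hemisphere follows the
    depression/elevation trajectory; contralateral and control hemispheres
    follow the maturation curve.
    """
    if n_per_group is None:
        n_per_group = {"HIE": 5, "non-operated": 4, "sham": 3}
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in scenario.groups}
    root = np.random.SeedSequence(seed)
    sessions = []
    truth_rows = []
    for group in scenario.groups:
        n = int(n_per_group.get(group, 0))
        for i in range(n):
            animal = f"{group}-{i + 1:02d}"
            group_key = zlib.crc32(group.encode()) % (2**31)
            a_seq = np.random.SeedSequence([seed, group_key, i])
            a_rng = np.random.default_rng(a_seq)
            if scenario.animal_cv > 0:
                sigma = np.sqrt(np.log1p(scenario.animal_cv**2))
                f_scale = float(a_rng.lognormal(-0.5 * sigma**2, sigma))
                oef_scale = float(a_rng.lognormal(-0.5 * (sigma / 2) ** 2, sigma / 2))
            else:
                f_scale = oef_scale = 1.0
            for day in _group_days(scenario, group):
                f_fac, oef_fac = _control_factors(scenario, day)
                base_f = scenario.f_day0 * f_fac * f_scale
                base_oef = min(0.95, scenario.oef_day0 * oef_fac * oef_scale)
                truths = {}
                for hemi in ("ipsi", "contra"):
                    f_true, oef_true = base_f, base_oef
                    if group == "HIE" and hemi == "ipsi":
                        f_true = base_f * _depression_factor(scenario, day)
                        oef_true = min(0.95, base_oef * _oef_elevation(scenario, day))
                    truths[hemi] = GroundTruth(
                        f=f_true,
                        oef=oef_true,
                        cbv=scenario.cbv,
                        kw=scenario.kw,
                        hb_conc=constants.hb_conc,
                        sao2=constants.sao2,
                        noise_scale=scenario.noise_scale,
                        seed=int(a_rng.integers(2**31)),
                    )
                o2_tacs, co2_tacs = {}, {}
                aifs = co2_water = None
                for hemi, truth in truths.items():
                    o2_tac, co2_tac, aifs, co2_water = simulate_dual_scan(
                        truth, schedules=schedules, constants=constants
                    )
                    o2_tacs[hemi] = o2_tac
                    co2_tacs[hemi] = co2_tac
                    o2a = constants.o2_per_gram_hb * truth.hb_conc * truth.sao2
                    truth_rows.append(
                        {
                            "animal": animal,
                            "group": group,
                            "day": day,
                            "hemisphere": hemi,
                            "f": truth.f,
                            "oef": truth.oef,
                            "cmro2": o2a * truth.f * truth.oef,
                            "cbv": truth.cbv,
                            "kw": truth.kw,
                            "seed": truth.seed,
                        }
                    )
                sessions.append(
                    SessionData(
                        animal=animal,
                        group=group,
                        day=day,
                        o2_aifs=aifs,
                        co2_water_aif=co2_water,
                        o2_tacs=o2_tacs,
                        co2_tacs=co2_tacs,
                        truth={h: truths[h] for h in truths},
                    )
                )
    return CohortBundle(
        sessions=tuple(sessions),
        truth_table=pd.DataFrame(truth_rows),
        scenario=scenario,
        seed=seed,
    )
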
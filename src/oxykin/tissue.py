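"""Forward tissue models for dual-tracer oxygen-15 inhalation PET.

Both scans are described by a one-tissue compartment model in which CBF (f)
is the blood-to-tissue flux of water and p the tissue-to-blood partition
coefficient of water.  During [15O]O2 inhalation the tissue signal has a
response to the oxygen AIF (scaled by OEF), a response to the metabolized
water AIF, and intravascular contributions:

    C(t) = (1 - V_o) OEF f [A_o (x) e^(-f t / p)]
         + (1 - V_w)     f [A_w (x) e^(-f t / p)]
         + V_o A_o(t) + V_w A_w(t)

while [15O]CO2 inhalation is equivalent to an arterial water input
(A_w = A_t), leaving only the water response plus its vascular term.  The
vascular fractions derive from CBV under a fixed venous share F_vein:
V_o = CBV {1 - F_vein + (1 - OEF) F_vein}, V_w = CBV (1 - F_vein).
CBV itself comes from the [15O]CO scan as the tissue/LV activity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    AifSet,
    FrameSchedule,
    FrameTAC,
    PhysioConstants,
    SampledCurve,
    expconv,
    frame_average,
)

__all__ = [
    "TissueModelParams",
    "vascular_fractions",
    "forward_o2_tac",
    "forward_co2_tac",
    "cbv_from_co",
]


@dataclass(frozen=True)
class TissueModelParams:
    """Parameters of the one-tissue dual-input model for one VOI.

    f : ml/min/g       cerebral blood flow (water flux definition)
    oef : fraction     oxygen extraction fraction
    cbv : ml/ml        cerebral blood volume
    v_o, v_w : ml/ml   arterial-side vascular fractions for O2 and water
    p : dimensionless  water partition coefficient
    f_vein : fraction  venous share of CBV
    """

    f: float
    oef: float
    cbv: float
    v_o: float
    v_w: float
    p: float = 0.91
    f_vein: float = 0.835

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError("f must be positive")
        if not (0.0 <= self.oef <= 1.0):
            raise ValueError("oef must lie in [0, 1]")
        if not (0.0 <= self.cbv < 0.5):
            raise ValueError("cbv must lie in [0, 0.5)")
        for name in ("v_o", "v_w"):
            v = getattr(self, name)
            if not (0.0 <= v <= self.cbv + 1e-12):
                raise ValueError(f"{name} must lie in [0, cbv]")

    @classmethod
    def from_physiology(
        cls,
        f: float,
        oef: float,
        cbv: float,
        constants: PhysioConstants,
        use_vw: bool = False,
    ) -> "TissueModelParams":
        """Derive the vascular fractions from CBV, OEF and F_vein.

        ``use_vw`` keeps the (small) water vascular fraction; the default
        neglects it, matching the fitting configuration.
        """
        v_o, v_w = vascular_fractions(cbv, oef, constants.f_vein)
        return cls(
            f=f,
            oef=oef,
            cbv=cbv,
            v_o=v_o,
            v_w=v_w if use_vw else 0.0,
            p=constants.p,
            f_vein=constants.f_vein,
        )


def vascular_fractions(cbv: float, oef: float, f_vein: float) -> tuple[float, float]:
    """Arterial-equivalent vascular fractions for the O2 and water inputs.

    The venous share of the blood pool carries oxygen already depleted by
    extraction, hence the (1 - OEF) weighting of the venous compartment.
    """
    if not (0.0 <= cbv < 0.5):
        raise ValueError("cbv must lie in [0, 0.5)")
    if not (0.0 <= oef <= 1.0):
        raise ValueError("oef must lie in [0, 1]")
    if not (0.0 < f_vein <= 1.0):
        raise ValueError("f_vein must lie in (0, 1]")
    v_o = cbv * (1.0 - f_vein + (1.0 - oef) * f_vein)
    v_w = cbv * (1.0 - f_vein)
    return v_o, v_w


def forward_o2_tac(
    params: TissueModelParams, aifs: AifSet, schedule: FrameSchedule
) -> FrameTAC:
    """Model tissue TAC for the [15O]O2 inhalation scan, frame-averaged."""
    k = params.f / params.p
    resp_o = expconv(aifs.oxygen, k)
    resp_w = expconv(aifs.water, k)
    c = (
        (1.0 - params.v_o) * params.oef * params.f * resp_o.values
        + (1.0 - params.v_w) * params.f * resp_w.values
        + params.v_o * aifs.oxygen.values
        + params.v_w * aifs.water.values
    )
    curve = SampledCurve(aifs.total.times, c, allow_negative=True)
    return frame_average(curve, schedule)


def forward_co2_tac(
    params: TissueModelParams, water_aif: SampledCurve, schedule: FrameSchedule
) -> FrameTAC:
    """Model tissue TAC for the [15O]CO2 inhalation scan, frame-averaged."""
    k = params.f / params.p
    resp_w = expconv(water_aif, k)
    c = params.f * resp_w.values + params.v_w * water_aif.values
    curve = SampledCurve(water_aif.times, c, allow_negative=True)
    return frame_average(curve, schedule)


def cbv_from_co(
    tissue_tac: FrameTAC, lv_tac: FrameTAC, window: FrameSchedule | None = None
) -> float:
    """CBV (ml/ml) from the [15O]CO scan as the tissue/LV activity ratio.

    Both TACs are time-averaged (duration-weighted frame means) over
    ``window`` — the full scan by default — and the ratio is returned.  No
    small-to-large vessel haematocrit correction is applied.
    """
    if window is None:
        window = tissue_tac.schedule

    def _mean(tac: FrameTAC) -> float:
        lo, hi = window.span
        s, e = tac.schedule.span
        if lo < s - 1e-9 or hi > e + 1e-9:
            raise ValueError("TAC does not cover the averaging window")
        keep = (tac.schedule.frame_starts >= lo - 1e-12) & (
            tac.schedule.frame_ends <= hi + 1e-12
        )
        d = tac.schedule.durations[keep]
        return float(np.sum(tac.activities[keep] * d) / np.sum(d))

    lv_mean = _mean(lv_tac)
    if lv_mean == 0.0:
        raise ZeroDivisionError("LV mean activity is zero over the averaging window")
    return _mean(tissue_tac) / lv_mean
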
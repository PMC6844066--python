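"""Derived pulmonary hemodynamic indices from flow curves.

The central quantity is the pulmonary blood volume variation (PBVV): the
per-frame net in/outflow of the pulmonary circulation is the arterial flow
minus the summed venous flow, multiplied by the frame duration; its running
sum is the pulmonary volume curve over the cardiac cycle; PBVV is the range
(max − min) of that curve, in ml.  Relative PBVV indexes PBVV to the
ipsilateral arterial net flow per beat (percent), and the pulmonary vascular
distensibility reserve (PVDR) is the percent change in unilateral relative
PBVV between two body positions (reference: supine).

PBVV is computed independently per scope — right lung, left lung, and
bilaterally from the summed curves (not by adding the unilateral values).
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError
from .types import (
    INFERIOR_VEINS,
    LEFT_VEINS,
    RIGHT_VEINS,
    SUPERIOR_VEINS,
    VEINS,
    FlowCurve,
    PbvvResult,
    PvdrResult,
    SubjectPositionRecord,
    check_aligned,
)

__all__ = [
    "net_inout_per_frame",
    "cumulative_volume",
    "pbvv",
    "relative_pbvv",
    "pvdr",
    "flow_fraction_right",
    "superior_inferior_split",
    "cardiac_output",
    "av_mismatch",
    "compute_pbvv",
    "analyze_record",
    "pvdr_between",
]

SCOPES = {
    "right_lung": ("RPA", RIGHT_VEINS),
    "left_lung": ("LPA", LEFT_VEINS),
    "bilateral": ("MPA", VEINS),
}


def net_inout_per_frame(arterial: FlowCurve, venous: Sequence[FlowCurve]) -> np.ndarray:
    """Per-frame net in/outflow in ml: (arterial − summed venous flow) × frame duration."""
    check_aligned([arterial, *venous])
    qv = np.sum([v.flow for v in venous], axis=0)
    return (arterial.flow - qv) * arterial.frame_duration / 1000.0


def cumulative_volume(diff: np.ndarray) -> np.ndarray:
    """Running sum of the per-frame net in/outflow: the pulmonary volume curve in ml.

    The curve starts at the first frame's differential (no zero anchoring);
    PBVV is translation-invariant, so the baseline choice is cosmetic.  The
    final value is the total arterio-venous mismatch over the cycle.
    """
    diff = np.asarray(diff, dtype=float)
    if diff.size == 0:
        raise InvalidInputError("empty differential volume sequence")
    return np.cumsum(diff)


def pbvv(cum: np.ndarray) -> float:
    """Pulmonary blood volume variation: max − min of the cumulative volume curve, ml."""
    cum = np.asarray(cum, dtype=float)
    if cum.size == 0:
        raise InvalidInputError("empty cumulative volume curve")
    return float(cum.max() - cum.min())


def relative_pbvv(pbvv_ml: float, arterial_net: float) -> float:
    """PBVV indexed to the ipsilateral arterial net flow per beat, in percent."""
    if arterial_net <= 0:
        raise InvalidParameterError("arterial net flow must be positive")
    return 100.0 * pbvv_ml / arterial_net


def pvdr(relative_ref: float, relative_new: float) -> float:
    """Pulmonary vascular distensibility reserve: percent change in relative PBVV.

    ``100 × (new − reference) / reference``, with the supine value as the
    conventional reference.
    """
    if relative_ref <= 0:
        raise InvalidParameterError("reference relative PBVV must be positive")
    return 100.0 * (relative_new - relative_ref) / relative_ref


def flow_fraction_right(right_net: float, left_net: float) -> float:
    """Percent of pulmonary blood flow going to the right lung."""
    total = right_net + left_net
    if total <= 0:
        raise InvalidInputError("total net flow must be positive")
    return 100.0 * right_net / total


def superior_inferior_split(venous: Mapping[str, FlowCurve]) -> float:
    """Percent of total venous net flow drained by the superior pulmonary veins."""
    missing = [v for v in VEINS if v not in venous]
    if missing:
        raise InvalidInputError(f"missing venous curves: {missing}")
    sup = sum(venous[v].net_flow() for v in SUPERIOR_VEINS)
    inf = sum(venous[v].net_flow() for v in INFERIOR_VEINS)
    if sup + inf <= 0:
        raise InvalidInputError("total venous net flow must be positive")
    return 100.0 * sup / (sup + inf)


def cardiac_output(heart_rate: float, mpa_net: float) -> float:
    """Cardiac output in l/min: heart rate × main pulmonary artery net flow per beat."""
    return heart_rate * mpa_net / 1000.0


def av_mismatch(mpa_net: float, venous_total_net: float) -> Tuple[float, float]:
    """Arterio-venous mismatch: (MPA net − summed venous net) in ml and percent of MPA net."""
    if mpa_net <= 0:
        raise InvalidParameterError("MPA net flow must be positive")
    diff = mpa_net - venous_total_net
    return diff, 100.0 * diff / mpa_net


def compute_pbvv(
    arterial: FlowCurve,
    venous: Sequence[FlowCurve],
    scope: str = "bilateral",
    drift_correction: bool = False,
) -> PbvvResult:
    """Full PBVV computation for one arterial curve and its venous drainage.

    ``drift_correction=True`` removes a linear ramp from the cumulative curve
    so it closes at zero before taking the range; off by default (the
    arterio-venous mismatch is reported, not corrected).
    """
    diff = net_inout_per_frame(arterial, venous)
    cum = cumulative_volume(diff)
    if drift_correction:
        n = cum.size
        cum = cum - cum[-1] * (np.arange(1, n + 1) / n)
    value = pbvv(cum)
    arterial_net = arterial.net_flow()
    return PbvvResult(
        scope=scope,
        diff_volume=diff,
        cum_volume=cum,
        pbvv=value,
        arterial_net=arterial_net,
        relative_pbvv=relative_pbvv(value, arterial_net),
    )


def analyze_record(
    record: SubjectPositionRecord,
    drift_correction: bool = False,
) -> Dict[str, object]:
    """All derived indices for one subject-position record.

    Returns a dict with per-scope :class:`~pulmoflow.types.PbvvResult`
    (``right_lung``, ``left_lung``, ``bilateral``), the right-lung flow
    fraction, superior-vein split, cardiac output and arterio-venous
    mismatch.
    """
    curves = record.curves
    results = {
        scope: compute_pbvv(
            curves[artery], [curves[v] for v in veins], scope=scope,
            drift_correction=drift_correction,
        )
        for scope, (artery, veins) in SCOPES.items()
    }
    mpa_net = curves["MPA"].net_flow()
    venous_net = sum(curves[v].net_flow() for v in VEINS)
    mm_ml, mm_pct = av_mismatch(mpa_net, venous_net)
    return {
        "pbvv": results,
        "flow_fraction_right": flow_fraction_right(
            curves["RPA"].net_flow(), curves["LPA"].net_flow()
        ),
        "superior_split": superior_inferior_split({v: curves[v] for v in VEINS}),
        "cardiac_output": cardiac_output(record.heart_rate, mpa_net),
        "av_mismatch_ml": mm_ml,
        "av_mismatch_pct": mm_pct,
        "mpa_net": mpa_net,
    }


def pvdr_between(
    ref: Mapping[str, PbvvResult],
    new: Mapping[str, PbvvResult],
    position_ref: str,
    position_new: str,
) -> List[PvdrResult]:
    """PVDR per lung between two positions' per-scope PBVV results."""
    out = []
    for lung, scope in (("right", "right_lung"), ("left", "left_lung")):
        r, n = ref[scope].relative_pbvv, new[scope].relative_pbvv
        out.append(
            PvdrResult(
                lung=lung,
                position_ref=position_ref,
                position_new=position_new,
                relative_pbvv_ref=r,
                relative_pbvv_new=n,
                pvdr=pvdr(r, n),
            )
        )
    return out
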
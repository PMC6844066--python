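"""Synthetic phase-contrast CMR data with known ground truth.

This module generates internally consistent pulmonary flow data at three
levels:

* per-vessel flow curves (:func:`make_arterial_waveform`,
  :func:`make_venous_waveforms`, :func:`split_lungs`);
* velocity-map image series with a parabolic in-vessel profile, quadratic
  eddy-current background offsets and Gaussian noise
  (:func:`render_pc_series`);
* multi-subject, four-position cohorts with configurable positional effects
  (:func:`generate_cohort`).

Every generator is deterministic given its seed and ships the hidden
parameters in a :class:`~pulmoflow.types.GroundTruth` so that recovery can be
asserted downstream.

Waveform morphology
-------------------
The arterial curve is a single skewed systolic pulse (steeper upstroke than
decay) with an optional small late-systolic negative notch; the summed venous
curve is biphasic with a systolic (S) and diastolic (D) wave and a small
negative atrial-contraction (A) notch.  Shapes are sums of asymmetric
Gaussian pulses — smooth, periodic to numerical precision at the cycle ends,
and controlled by a handful of timing/width parameters.

Venous construction
-------------------
Venous flow is derived from the arterial curve and a target pulmonary blood
volume variation (PBVV).  Let ``tmpl`` be the biphasic venous template scaled
to the arterial net flow.  The generator returns

    Qv = (1 - beta) * Qa + beta * tmpl

with ``beta`` chosen so that the running integral of ``(Qa - Qv) * dt`` has
range exactly ``target_pbvv``.  Conservation (venous net = arterial net) is
then exact by construction, and ``target_pbvv = 0`` degenerates to venous
flow identical to arterial flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .exceptions import (
    AliasingRiskError,
    InfeasibleTargetError,
    InvalidParameterError,
)
from .types import (
    LATERAL_POSITIONS,
    MIN_FRAMES,
    POSITIONS,
    VEINS,
    AreaResult,
    FlowCurve,
    GroundTruth,
    PositionEffectConfig,
    RoiMaskSeries,
    SubjectPositionRecord,
    VesselImageSeries,
)

__all__ = [
    "make_arterial_waveform",
    "make_venous_waveforms",
    "split_lungs",
    "render_pc_series",
    "generate_cohort",
    "default_position_effects",
    "CohortTruth",
    "RenderResult",
    "DEFAULT_AREAS_MM2",
]

# Cycle-averaged cross-sectional areas (mm²) typical of healthy adult
# pulmonary vessels; used as rendering and cohort defaults.
DEFAULT_AREAS_MM2 = {
    "MPA": 700.0,
    "RPA": 380.0,
    "LPA": 350.0,
    "RSPV": 110.0,
    "RIPV": 110.0,
    "LSPV": 100.0,
    "LIPV": 100.0,
}

# Cohort calibration defaults: healthy supine values the generator emulates.
DEFAULT_STROKE_VOLUME_ML = 106.0
DEFAULT_HEART_RATE_BPM = 61.0
DEFAULT_SUPINE_RIGHT_FRACTION = 0.52
# Supine relative PBVV per lung, as fractions of ipsilateral net flow:
# right 26 ml / (0.52*106 ml), left 20 ml / (0.48*106 ml).
DEFAULT_SUPINE_RELATIVE_PBVV = {"right": 26.0 / (0.52 * 106.0), "left": 20.0 / (0.48 * 106.0)}
# Between-subject / within-subject (position-level) variability.
BETWEEN_SUBJECT_CV = {"stroke_volume": 0.15, "heart_rate": 0.12, "relative_pbvv": 0.15, "gain": 0.20}
BETWEEN_SUBJECT_SD_FRACTION = 0.02
POSITION_CV = {"stroke_volume": 0.03, "heart_rate": 0.03, "relative_pbvv": 0.08, "area": 0.05}
POSITION_SD_FRACTION = 0.01
#: Default additive measurement noise on flow curves, ml/s.
DEFAULT_FLOW_NOISE_SD = 1.0


def _asym_gauss(phase: np.ndarray, center: float, w_rise: float, w_fall: float) -> np.ndarray:
    """Asymmetric Gaussian pulse on normalized phase in [0, 1)."""
    d = phase - center
    w = np.where(d < 0, w_rise, w_fall)
    return np.exp(-0.5 * (d / w) ** 2)


def _frame_phase(n_frames: int) -> np.ndarray:
    return (np.arange(n_frames) + 0.5) / n_frames


def make_arterial_waveform(
    rr_interval: float,
    stroke_volume: float,
    n_frames: int = 35,
    seed: Optional[int] = None,
    vessel_id: str = "MPA",
    notch: bool = True,
) -> FlowCurve:
    """Generate a pulmonary arterial flow curve integrating to ``stroke_volume``.

    The curve has a single systolic peak in the first half of the cycle, an
    optional small negative notch at end systole (pulmonary valve closure),
    and near-zero diastolic flow.  The rectangle-rule net flow equals
    ``stroke_volume`` exactly (up to float rounding).  A ``seed`` jitters the
    pulse timing and width slightly for between-realization variety.
    """
    if rr_interval <= 0:
        raise InvalidParameterError("rr_interval must be positive")
    if n_frames < MIN_FRAMES:
        raise InvalidParameterError(f"n_frames must be >= {MIN_FRAMES}")
    if stroke_volume < 0:
        raise InvalidParameterError("stroke_volume must be >= 0")

    frame_duration = rr_interval / n_frames
    if stroke_volume == 0:
        return FlowCurve(vessel_id, np.zeros(n_frames), frame_duration, rr_interval)

    rng = np.random.default_rng(seed)
    peak = 0.17 + (rng.normal(0, 0.012) if seed is not None else 0.0)
    peak = float(np.clip(peak, 0.10, 0.25))
    w_rise = 0.065 * float(np.exp(rng.normal(0, 0.08))) if seed is not None else 0.065
    w_fall = 0.105 * float(np.exp(rng.normal(0, 0.08))) if seed is not None else 0.105

    phase = _frame_phase(n_frames)
    shape = _asym_gauss(phase, peak, w_rise, w_fall)
    if notch:
        shape -= 0.05 * _asym_gauss(phase, peak + 0.22, 0.03, 0.03)

    dt_s = frame_duration / 1000.0
    flow = shape * (stroke_volume / (np.sum(shape) * dt_s))
    return FlowCurve(vessel_id, flow, frame_duration, rr_interval)


def _venous_template(phase: np.ndarray) -> np.ndarray:
    """Biphasic pulmonary venous shape: S wave, dominant D wave, negative A-wave reversal.

    The D wave dominates and the A reversal is pronounced so that the natural
    arterio-venous volume range is a large fraction of the stroke volume,
    letting the mixing construction reach the high relative volume variations
    seen in the non-dependent lung without implausible venous backflow.
    """
    s_wave = 0.55 * _asym_gauss(phase, 0.34, 0.10, 0.12)
    d_wave = _asym_gauss(phase, 0.75, 0.09, 0.10)
    # A reversal straddles the cycle boundary; evaluate both wrap images
    a_notch = -0.22 * (
        _asym_gauss(phase, 0.98, 0.03, 0.03) + _asym_gauss(phase, -0.02, 0.03, 0.03)
    )
    return s_wave + d_wave + a_notch


def venous_sum_curve(arterial: FlowCurve, target_pbvv: float) -> np.ndarray:
    """Summed venous flow (ml/s per frame) conserving arterial net flow with the
    cumulative arterio-venous volume curve having range ``target_pbvv`` (ml)."""
    if target_pbvv < 0:
        raise InvalidParameterError("target_pbvv must be >= 0")
    qa = arterial.flow
    n = arterial.n_frames
    dt_s = arterial.frame_duration / 1000.0

    if target_pbvv == 0:
        return qa.copy()

    tmpl = _venous_template(_frame_phase(n))
    tmpl_net = np.sum(tmpl) * dt_s
    if tmpl_net <= 0:
        raise InvalidParameterError("degenerate venous template")
    tmpl = tmpl * (arterial.net_flow() / tmpl_net)

    v0 = np.cumsum((qa - tmpl) * dt_s)
    r0 = float(v0.max() - v0.min())
    if r0 <= 0:
        raise InfeasibleTargetError("arterial curve indistinguishable from venous template")
    beta = target_pbvv / r0
    qv = (1.0 - beta) * qa + beta * tmpl

    # Feasibility: A-wave reversal down to ~15% of the arterial peak is
    # physiologic; refuse targets that force deeper backflow over much of the cycle.
    threshold = -0.15 * float(np.max(np.abs(qa))) if np.any(qa) else 0.0
    if np.count_nonzero(qv < threshold) > 0.2 * n:
        raise InfeasibleTargetError(
            f"target_pbvv={target_pbvv} ml forces negative venous flow on "
            f">20% of frames for this arterial curve"
        )
    return qv


def make_venous_waveforms(
    arterial: FlowCurve,
    target_pbvv: float,
    venous_split: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: Optional[int] = None,
) -> Tuple[Dict[str, FlowCurve], GroundTruth]:
    """Construct the four pulmonary venous flow curves for a given arterial curve.

    ``venous_split`` gives the fractions of total venous flow carried by
    (RSPV, RIPV, LSPV, LIPV) and must sum to 1.  The summed venous curve
    conserves the arterial net flow exactly, and the implied pulmonary volume
    curve has range exactly ``target_pbvv``.
    """
    split = np.asarray(venous_split, dtype=float)
    if split.shape != (4,) or not np.isclose(split.sum(), 1.0, atol=1e-9) or np.any(split < 0):
        raise InvalidParameterError("venous_split must be 4 non-negative fractions summing to 1")

    qv = venous_sum_curve(arterial, target_pbvv)
    curves = {
        vessel: FlowCurve(vessel, frac * qv, arterial.frame_duration, arterial.rr_interval)
        for vessel, frac in zip(VEINS, split)
    }
    right_fraction = float(split[0] + split[1])
    truth = GroundTruth(
        stroke_volume=arterial.net_flow(),
        right_fraction=right_fraction if 0 < right_fraction < 1 else None,
        true_pbvv={"bilateral": float(target_pbvv)},
        seed=seed,
    )
    return curves, truth


def split_lungs(
    arterial: FlowCurve,
    venous: Mapping[str, FlowCurve],
    right_fraction: float,
) -> Dict[str, FlowCurve]:
    """Split bilateral curves into per-lung sets.

    The branch pulmonary arteries are frame-wise fractions of the main
    pulmonary artery (RPA + LPA = MPA exactly); the right venous pair carries
    ``right_fraction`` of the total venous flow, frame-wise, split within each
    lung in proportion to the input veins' net flows.
    """
    if not (0 < right_fraction < 1):
        raise InvalidParameterError("right_fraction must be in (0, 1)")
    missing = [v for v in VEINS if v not in venous]
    if missing:
        raise InvalidParameterError(f"missing venous curves: {missing}")

    total = np.sum([venous[v].flow for v in VEINS], axis=0)
    nets = {v: venous[v].net_flow() for v in VEINS}

    def _within(pair):
        a, b = nets[pair[0]], nets[pair[1]]
        return (0.5, 0.5) if a + b == 0 else (a / (a + b), b / (a + b))

    r_sup, r_inf = _within(("RSPV", "RIPV"))
    l_sup, l_inf = _within(("LSPV", "LIPV"))

    fd, rr = arterial.frame_duration, arterial.rr_interval
    return {
        "RPA": FlowCurve("RPA", right_fraction * arterial.flow, fd, rr),
        "LPA": FlowCurve("LPA", (1 - right_fraction) * arterial.flow, fd, rr),
        "RSPV": FlowCurve("RSPV", right_fraction * r_sup * total, fd, rr),
        "RIPV": FlowCurve("RIPV", right_fraction * r_inf * total, fd, rr),
        "LSPV": FlowCurve("LSPV", (1 - right_fraction) * l_sup * total, fd, rr),
        "LIPV": FlowCurve("LIPV", (1 - right_fraction) * l_inf * total, fd, rr),
    }


@dataclass(frozen=True)
class RenderResult:
    """A rendered vessel plane plus everything needed to check recovery."""

    series: VesselImageSeries
    vessel_masks: RoiMaskSeries
    static_mask: np.ndarray
    truth: GroundTruth


def render_pc_series(
    curve: FlowCurve,
    vessel_area: float,
    venc: float = 100.0,
    pixel_spacing: float = 1.4,
    noise_sd: float = 0.0,
    eddy_coeffs: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    profile: str = "parabolic",
    area_per_frame: Optional[Sequence[float]] = None,
    subsample: int = 5,
    margin_pixels: int = 10,
) -> RenderResult:
    """Render a magnitude + velocity image series for one vessel plane.

    The vessel is a centred circular lumen; the in-plane velocity profile is
    parabolic (Poiseuille) by default, or a uniform plug with
    ``profile="plug"``.  A quadratic background surface
    ``a + b*x + c*y + d*x² + e*x*y + f*y²`` (``eddy_coeffs``, cm/s, pixel
    coordinates) emulates eddy-current phase offsets, and Gaussian noise of
    ``noise_sd`` cm/s is added to the velocity map.  Generation refuses
    (``AliasingRiskError``) if the implied in-vessel peak velocity exceeds
    ``venc``; phase wrapping is never simulated.

    ``area_per_frame`` optionally prescribes a pulsatile lumen area (mm² per
    frame); the per-frame mean velocity is always ``flow / area``.
    """
    if vessel_area <= 0 or pixel_spacing <= 0:
        raise InvalidParameterError("vessel_area and pixel_spacing must be positive")
    if profile not in ("parabolic", "plug"):
        raise InvalidParameterError("profile must be 'parabolic' or 'plug'")

    n = curve.n_frames
    areas = (
        np.full(n, float(vessel_area))
        if area_per_frame is None
        else np.asarray(area_per_frame, dtype=float)
    )
    if areas.shape != (n,) or np.any(areas <= 0):
        raise InvalidParameterError("area_per_frame must give a positive area per frame")

    radii = np.sqrt(areas / np.pi)  # mm
    # mean velocity in cm/s: 1 (ml/s)/mm² = 1000 mm/s / 10 = 100 cm/s
    v_mean = curve.flow / areas * 100.0
    peak_factor = 2.0 if profile == "parabolic" else 1.0
    v_peak = float(np.max(np.abs(v_mean))) * peak_factor
    if v_peak > venc:
        raise AliasingRiskError(
            f"implied peak velocity {v_peak:.1f} cm/s exceeds venc {venc:.1f} cm/s"
        )

    r_max = float(radii.max())
    half = int(np.ceil(r_max / pixel_spacing)) + margin_pixels
    nx = 2 * half + 1
    cx = cy = float(half)  # pixel centres at integer coordinates
    xx, yy = np.meshgrid(np.arange(nx, dtype=float), np.arange(nx, dtype=float), indexing="xy")

    coeffs = np.zeros(6) if eddy_coeffs is None else np.asarray(eddy_coeffs, dtype=float)
    if coeffs.shape != (6,):
        raise InvalidParameterError("eddy_coeffs must have 6 entries (a, b, c, d, e, f)")
    a, b, c, d, e, f = coeffs
    background = a + b * xx + c * yy + d * xx**2 + e * xx * yy + f * yy**2

    offsets = (np.arange(subsample) + 0.5) / subsample - 0.5
    ox, oy = np.meshgrid(offsets, offsets, indexing="xy")

    rng = np.random.default_rng(seed)
    velocity = np.empty((n, nx, nx))
    magnitude = np.empty((n, nx, nx))
    masks = np.empty((n, nx, nx), dtype=bool)

    r2_centres = ((xx - cx) ** 2 + (yy - cy) ** 2) * pixel_spacing**2
    for i in range(n):
        r_i2 = radii[i] ** 2
        masks[i] = r2_centres <= r_i2
        if profile == "plug":
            v_in = np.where(masks[i], v_mean[i], 0.0)
            frac_in = masks[i].astype(float)
        else:
            v_in = np.zeros((nx, nx))
            frac_in = np.zeros((nx, nx))
            for dx, dy in zip(ox.ravel(), oy.ravel()):
                r2s = ((xx + dx - cx) ** 2 + (yy + dy - cy) ** 2) * pixel_spacing**2
                inside = r2s <= r_i2
                v_in += np.where(inside, 2.0 * v_mean[i] * (1.0 - r2s / r_i2), 0.0)
                frac_in += inside
            v_in /= offsets.size**2
            frac_in /= offsets.size**2
        velocity[i] = v_in + background
        magnitude[i] = 20.0 + 80.0 * frac_in
        if noise_sd > 0:
            velocity[i] += rng.normal(0.0, noise_sd, size=(nx, nx))
            magnitude[i] += rng.normal(0.0, 2.0, size=(nx, nx))
    if noise_sd > 0:
        np.clip(velocity, -venc, venc, out=velocity)

    static_mask = r2_centres > (r_max + 3.0 * pixel_spacing) ** 2

    series = VesselImageSeries(
        magnitude=magnitude,
        velocity=velocity,
        pixel_spacing=pixel_spacing,
        venc=venc,
        rr_interval=curve.rr_interval,
        vessel_id=curve.vessel_id,
        # noiseless rendering respects the bound; the aliasing check above refuses otherwise
        eddy_corrected=bool(np.max(np.abs(velocity)) > venc),
    )
    truth = GroundTruth(
        true_areas={curve.vessel_id: float(np.pi * r_max**2) if area_per_frame is None else float(np.mean(areas))},
        eddy_coeffs=coeffs,
        noise_sd=float(noise_sd),
        seed=seed,
    )
    return RenderResult(series, RoiMaskSeries(masks, pixel_spacing), static_mask, truth)


def default_position_effects() -> Dict[str, PositionEffectConfig]:
    """Default positional effect configuration for all four body positions.

    Supine and prone carry no systematic effect; the lateral positions apply
    the default dependent-flow, dependent-venous-area and non-dependent-PVDR
    gains.
    """
    out = {}
    for pos in POSITIONS:
        if pos in LATERAL_POSITIONS:
            out[pos] = PositionEffectConfig(position=pos)
        else:
            out[pos] = PositionEffectConfig(
                position=pos,
                dependent_flow_gain=0.0,
                dependent_venous_area_gain=0.0,
                nondependent_pvdr_gain=0.0,
            )
    return out


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth for a generated cohort.

    ``per_record`` maps ``(subject_id, position)`` to a
    :class:`~pulmoflow.types.GroundTruth` with that record's stroke volume,
    right flow fraction, per-lung and bilateral PBVV and vessel areas.
    """

    per_record: Dict[Tuple[str, str], GroundTruth]
    seed: Optional[int]
    flow_noise_sd: float


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative log-normal jitter with unit median and given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    return float(np.exp(rng.normal(0.0, sigma)))


def generate_cohort(
    n_subjects: int = 10,
    effects: Optional[Mapping[str, PositionEffectConfig]] = None,
    seed: Optional[int] = None,
    n_frames: int = 35,
    flow_noise_sd: float = DEFAULT_FLOW_NOISE_SD,
    stroke_volume: float = DEFAULT_STROKE_VOLUME_ML,
    heart_rate: float = DEFAULT_HEART_RATE_BPM,
    supine_right_fraction: float = DEFAULT_SUPINE_RIGHT_FRACTION,
    supine_relative_pbvv: Optional[Mapping[str, float]] = None,
) -> Tuple[List[SubjectPositionRecord], CohortTruth]:
    """Generate a cohort of subjects imaged in all four body positions.

    For each subject and position, the seven vessel curves are mutually
    consistent: branch arteries are frame-wise fractions of the main pulmonary
    artery, each lung's venous pair conserves its arterial inflow exactly, and
    per-lung PBVV is set by the position's relative-PBVV target.  Cardiac
    output carries no systematic positional effect (only position-level
    noise).  Identical seeds give bit-identical cohorts.

    ``flow_noise_sd`` adds white measurement noise (ml/s) to every curve;
    pass 0 for noiseless data, for which conservation and PBVV recovery are
    exact.  Ground truth always refers to the noiseless curves.
    """
    if n_subjects < 2:
        raise InvalidParameterError("n_subjects must be >= 2")
    effects = dict(effects) if effects is not None else default_position_effects()
    for pos in POSITIONS:
        if pos not in effects:
            raise InvalidParameterError(f"missing PositionEffectConfig for {pos!r}")
    rel0 = dict(supine_relative_pbvv or DEFAULT_SUPINE_RELATIVE_PBVV)

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)

    records: List[SubjectPositionRecord] = []
    truths: Dict[Tuple[str, str], GroundTruth] = {}

    for si in range(n_subjects):
        subject_id = f"S{si + 1:02d}"
        s_rng = np.random.default_rng(subject_seeds[si])
        sv_subj = stroke_volume * _lognormal_factor(s_rng, BETWEEN_SUBJECT_CV["stroke_volume"])
        hr_subj = heart_rate * _lognormal_factor(s_rng, BETWEEN_SUBJECT_CV["heart_rate"])
        frac_subj = float(
            np.clip(
                supine_right_fraction + s_rng.normal(0, BETWEEN_SUBJECT_SD_FRACTION), 0.40, 0.64
            )
        )
        rel_subj = {
            lung: rel0[lung] * _lognormal_factor(s_rng, BETWEEN_SUBJECT_CV["relative_pbvv"])
            for lung in ("right", "left")
        }
        area_subj = {
            v: a0 * _lognormal_factor(s_rng, 0.10) for v, a0 in DEFAULT_AREAS_MM2.items()
        }
        gain_jitter = _lognormal_factor(s_rng, BETWEEN_SUBJECT_CV["gain"])

        for position in POSITIONS:
            p_rng = np.random.default_rng(s_rng.integers(0, 2**31 - 1))
            eff = effects[position]

            sv = sv_subj * _lognormal_factor(p_rng, POSITION_CV["stroke_volume"])
            hr = hr_subj * _lognormal_factor(p_rng, POSITION_CV["heart_rate"])
            rr = 60000.0 / hr

            frac = frac_subj + p_rng.normal(0, POSITION_SD_FRACTION)
            dependent = (
                "right"
                if position == "right_lateral"
                else "left" if position == "left_lateral" else None
            )
            if dependent is not None and eff.dependent_flow_gain > 0:
                gain = eff.dependent_flow_gain * gain_jitter
                dep_frac = (frac if dependent == "right" else 1 - frac) * (1 + gain)
                dep_frac = float(np.clip(dep_frac, 0.05, 0.95))
                frac = dep_frac if dependent == "right" else 1 - dep_frac
            frac = float(np.clip(frac, 0.05, 0.95))

            rel = {
                lung: rel_subj[lung] * _lognormal_factor(p_rng, POSITION_CV["relative_pbvv"])
                for lung in ("right", "left")
            }
            if dependent is not None and eff.nondependent_pvdr_gain > 0:
                nondep = "left" if dependent == "right" else "right"
                rel[nondep] *= 1 + eff.nondependent_pvdr_gain * gain_jitter
            # clamp to what the venous construction can realize without
            # implausible backflow (analogous to the venc clamp when rendering)
            rel = {lung: min(v, 1.05) for lung, v in rel.items()}

            mpa = make_arterial_waveform(
                rr, sv, n_frames, seed=int(p_rng.integers(0, 2**31 - 1)), vessel_id="MPA"
            )
            lung_nets = {"right": frac * sv, "left": (1 - frac) * sv}
            curves: Dict[str, FlowCurve] = {"MPA": mpa}
            true_pbvv: Dict[str, float] = {}
            for lung, artery, sup, inf in (
                ("right", "RPA", "RSPV", "RIPV"),
                ("left", "LPA", "LSPV", "LIPV"),
            ):
                lf = frac if lung == "right" else 1 - frac
                art = mpa.scaled(lf, vessel_id=artery)
                target = rel[lung] * lung_nets[lung]
                qv = venous_sum_curve(art, target)
                curves[artery] = art
                curves[sup] = FlowCurve(sup, 0.5 * qv, mpa.frame_duration, rr)
                curves[inf] = FlowCurve(inf, 0.5 * qv, mpa.frame_duration, rr)
                true_pbvv[lung] = float(target)

            # Bilateral PBVV from the summed curves (not the sum of unilateral PBVVs).
            diff = (
                curves["MPA"].flow - np.sum([curves[v].flow for v in VEINS], axis=0)
            ) * mpa.frame_duration / 1000.0
            cum = np.cumsum(diff)
            true_pbvv["bilateral"] = float(cum.max() - cum.min())

            areas = dict(area_subj)
            for v in areas:
                areas[v] *= _lognormal_factor(p_rng, POSITION_CV["area"])
            if dependent is not None and eff.dependent_venous_area_gain > 0:
                dep_veins = ("RSPV", "RIPV") if dependent == "right" else ("LSPV", "LIPV")
                for v in dep_veins:
                    areas[v] *= 1 + eff.dependent_venous_area_gain * gain_jitter

            if flow_noise_sd > 0:
                curves = {
                    v: FlowCurve(
                        v,
                        c.flow + p_rng.normal(0.0, flow_noise_sd, size=c.n_frames),
                        c.frame_duration,
                        c.rr_interval,
                    )
                    for v, c in curves.items()
                }

            records.append(
                SubjectPositionRecord(
                    subject_id=subject_id,
                    position=position,
                    curves=curves,
                    heart_rate=hr,
                    areas={v: AreaResult(np.full(n_frames, a)) for v, a in areas.items()},
                )
            )
            truths[(subject_id, position)] = GroundTruth(
                stroke_volume=sv,
                right_fraction=frac,
                true_pbvv=true_pbvv,
                true_areas=areas,
                noise_sd=flow_noise_sd,
                seed=seed,
            )

    return records, CohortTruth(per_record=truths, seed=seed, flow_noise_sd=flow_noise_sd)
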
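"""Core data containers for phase-contrast CMR pulmonary flow analysis.

The central objects are :class:`FlowCurve` (one cardiac cycle of flow for one
vessel), :class:`VesselImageSeries` (a time-resolved magnitude + velocity map
pair for one imaging plane), and :class:`SubjectPositionRecord` (the seven
pulmonary vessel curves for one subject in one body position).

Units are fixed throughout the package: flow in ml/s, time in ms, velocity in
cm/s, lengths in mm, areas in mm², volumes in ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

#: The seven vessels imaged per body position: main, right and left pulmonary
#: arteries, and the four pulmonary veins (right/left superior/inferior).
VESSELS = ("MPA", "RPA", "LPA", "RSPV", "RIPV", "LSPV", "LIPV")
ARTERIES = ("MPA", "RPA", "LPA")
VEINS = ("RSPV", "RIPV", "LSPV", "LIPV")
RIGHT_VEINS = ("RSPV", "RIPV")
LEFT_VEINS = ("LSPV", "LIPV")
SUPERIOR_VEINS = ("RSPV", "LSPV")
INFERIOR_VEINS = ("RIPV", "LIPV")

#: Body positions in acquisition order.
POSITIONS = ("supine", "prone", "right_lateral", "left_lateral")
LATERAL_POSITIONS = ("right_lateral", "left_lateral")

#: Minimum number of frames per cardiac cycle accepted anywhere.
MIN_FRAMES = 8


@dataclass(frozen=True)
class FlowCurve:
    """One cardiac cycle of through-plane flow for a single vessel.

    Parameters
    ----------
    vessel_id:
        Vessel label, normally one of :data:`VESSELS`.
    flow:
        Flow per frame in ml/s; each sample represents the mean flow over its
        frame, nominally centred at ``(i + 0.5) * frame_duration``.
    frame_duration:
        Temporal resolution in ms.
    rr_interval:
        Cardiac cycle length (R-R interval) in ms.
    """

    vessel_id: str
    flow: np.ndarray
    frame_duration: float
    rr_interval: float

    def __post_init__(self):
        flow = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "flow", flow)
        if flow.ndim != 1 or flow.size < MIN_FRAMES:
            raise InvalidParameterError(
                f"flow curve needs >= {MIN_FRAMES} frames, got shape {flow.shape}"
            )
        if not np.all(np.isfinite(flow)):
            raise InvalidParameterError("flow values must be finite")
        if self.frame_duration <= 0 or self.rr_interval <= 0:
            raise InvalidParameterError("frame_duration and rr_interval must be positive")
        if abs(self.frame_duration * flow.size - self.rr_interval) > self.frame_duration:
            raise InvalidParameterError(
                "frame_duration x n_frames must equal rr_interval within one frame"
            )

    @property
    def n_frames(self) -> int:
        return int(self.flow.size)

    @property
    def times(self) -> np.ndarray:
        """Frame-centre times in ms."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration

    def net_flow(self) -> float:
        """Net flow over the cycle in ml (rectangle rule: flow × frame duration)."""
        return float(np.sum(self.flow) * self.frame_duration / 1000.0)

    def scaled(self, factor: float, vessel_id: Optional[str] = None) -> "FlowCurve":
        return FlowCurve(
            vessel_id=vessel_id or self.vessel_id,
            flow=self.flow * factor,
            frame_duration=self.frame_duration,
            rr_interval=self.rr_interval,
        )


def check_aligned(curves: Sequence[FlowCurve]) -> None:
    """Raise :class:`AlignmentError` unless all curves share grid and RR interval."""
    from .exceptions import AlignmentError

    if not curves:
        raise InvalidInputError("no flow curves given")
    ref = curves[0]
    for c in curves[1:]:
        if c.n_frames != ref.n_frames or not np.isclose(c.rr_interval, ref.rr_interval):
            raise AlignmentError(
                f"curves not frame-aligned: {c.vessel_id} ({c.n_frames} frames, "
                f"rr={c.rr_interval}) vs {ref.vessel_id} ({ref.n_frames}, rr={ref.rr_interval})"
            )


@dataclass(frozen=True)
class VesselImageSeries:
    """Time-resolved magnitude and velocity maps for one vessel plane.

    ``magnitude`` and ``velocity`` are ``(n_frames, ny, nx)`` arrays; velocity
    is in cm/s, already scaled by the velocity-encoding limit (venc).  The
    velocity bound ``|v| <= venc`` is enforced at construction; a series that
    has been background-corrected may exceed it marginally and carries
    ``eddy_corrected=True`` to record that the bound no longer applies.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    pixel_spacing: float
    venc: float
    rr_interval: float
    vessel_id: str = "UNKNOWN"
    eddy_corrected: bool = False

    def __post_init__(self):
        mag = np.asarray(self.magnitude, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "velocity", vel)
        if mag.ndim != 3 or mag.shape != vel.shape:
            raise InvalidInputError(
                f"magnitude {mag.shape} and velocity {vel.shape} must be 3-D and share dimensions"
            )
        if self.pixel_spacing <= 0:
            raise InvalidInputError("pixel_spacing must be positive")
        if self.venc <= 0:
            raise InvalidInputError("venc must be positive")
        if not self.eddy_corrected and np.max(np.abs(vel)) > self.venc * (1 + 1e-9):
            raise InvalidInputError("velocity exceeds venc; data would be aliased")

    @property
    def n_frames(self) -> int:
        return int(self.velocity.shape[0])

    @property
    def frame_duration(self) -> float:
        return self.rr_interval / self.n_frames

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm²."""
        return self.pixel_spacing**2


@dataclass(frozen=True)
class RoiMaskSeries:
    """Per-frame binary vessel masks matching a :class:`VesselImageSeries`."""

    masks: np.ndarray  # (n_frames, ny, nx) bool
    pixel_spacing: float

    def __post_init__(self):
        masks = np.asarray(self.masks, dtype=bool)
        object.__setattr__(self, "masks", masks)
        if masks.ndim != 3:
            raise InvalidInputError("masks must be (n_frames, ny, nx)")
        if self.pixel_spacing <= 0:
            raise InvalidInputError("pixel_spacing must be positive")
        if not masks.any(axis=(1, 2)).all():
            raise InvalidInputError("every frame's ROI mask must be non-empty")

    @property
    def n_frames(self) -> int:
        return int(self.masks.shape[0])


@dataclass(frozen=True)
class AreaResult:
    """Per-frame cross-sectional vessel area and its cycle average, in mm²."""

    per_frame: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.per_frame, dtype=float)
        object.__setattr__(self, "per_frame", a)
        if a.ndim != 1 or a.size == 0 or np.any(a <= 0):
            raise InvalidInputError("areas must be a non-empty 1-D array of positive values")

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.per_frame))


@dataclass(frozen=True)
class SubjectPositionRecord:
    """All seven vessel flow curves (and optional areas) for one subject in one position."""

    subject_id: str
    position: str
    curves: Mapping[str, FlowCurve]
    heart_rate: float
    areas: Optional[Mapping[str, AreaResult]] = None

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise InvalidParameterError(f"unknown position {self.position!r}")
        missing = [v for v in VESSELS if v not in self.curves]
        if missing:
            raise InvalidInputError(f"missing vessel curves: {missing}")
        check_aligned([self.curves[v] for v in VESSELS])
        rr_from_hr = 60000.0 / self.heart_rate
        if abs(rr_from_hr - self.curves["MPA"].rr_interval) > 0.01 * rr_from_hr:
            raise InvalidInputError("heart_rate inconsistent with curve rr_interval (>1%)")

    @property
    def rr_interval(self) -> float:
        return self.curves["MPA"].rr_interval

    @property
    def n_frames(self) -> int:
        return self.curves["MPA"].n_frames


@dataclass(frozen=True)
class PbvvResult:
    """Pulmonary blood volume variation for one scope (right lung, left lung or bilateral).

    ``diff_volume`` is the per-frame net in/outflow in ml, ``cum_volume`` its
    running sum (the pulmonary volume curve), ``pbvv`` the range of that curve,
    and ``relative_pbvv`` the PBVV indexed to the ipsilateral arterial net flow,
    in percent.
    """

    scope: str  # "right_lung" | "left_lung" | "bilateral"
    diff_volume: np.ndarray
    cum_volume: np.ndarray
    pbvv: float
    arterial_net: float
    relative_pbvv: float


@dataclass(frozen=True)
class PvdrResult:
    """Pulmonary vascular distensibility reserve between two body positions for one lung."""

    lung: str  # "right" | "left"
    position_ref: str
    position_new: str
    relative_pbvv_ref: float
    relative_pbvv_new: float
    pvdr: float


@dataclass(frozen=True)
class PositionEffectConfig:
    """Positional effect sizes applied by the cohort generator.

    ``dependent_flow_gain`` multiplies blood flow to the dependent lung in a
    lateral position (the non-dependent lung absorbs the complement so cardiac
    output is unchanged); ``dependent_venous_area_gain`` multiplies dependent
    venous cross-sectional areas; ``nondependent_pvdr_gain`` multiplies the
    non-dependent lung's relative PBVV.  Defaults sit in the middle of the
    measured ranges (flow +16–33%, venous area +22–27%, PVDR +68–113%).
    """

    position: str
    dependent_flow_gain: float = 0.25
    dependent_venous_area_gain: float = 0.25
    nondependent_pvdr_gain: float = 0.90

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise InvalidParameterError(f"unknown position {self.position!r}")
        for name in ("dependent_flow_gain", "dependent_venous_area_gain", "nondependent_pvdr_gain"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Hidden parameters of a synthetic dataset, kept for recovery tests."""

    stroke_volume: Optional[float] = None
    right_fraction: Optional[float] = None
    true_pbvv: Mapping[str, float] = field(default_factory=dict)  # keys: right/left/bilateral
    true_areas: Mapping[str, float] = field(default_factory=dict)  # vessel -> mm²
    eddy_coeffs: Optional[np.ndarray] = None
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if any(v < 0 for v in self.true_pbvv.values()):
            raise InvalidParameterError("true_pbvv values must be >= 0")
        if self.right_fraction is not None and not (0 < self.right_fraction < 1):
            raise InvalidParameterError("right_fraction must be in (0, 1)")
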
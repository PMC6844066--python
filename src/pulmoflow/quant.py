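"""Flow and area quantification from velocity-map image series.

Implements the image-space half of the pipeline: eddy-current background
correction (quadratic surface fitted to stationary tissue), automatic ROI
propagation through the cardiac cycle, ROI velocity integration into ml/s
flow curves, rectangle-rule net flow, and cycle-averaged cross-sectional
area.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import (
    DegenerateFitError,
    InvalidInputError,
    PropagationFailureError,
)
from .types import AreaResult, FlowCurve, RoiMaskSeries, VesselImageSeries

__all__ = [
    "fit_eddy_background",
    "propagate_roi",
    "measure_roi_flow",
    "net_flow",
    "measure_area",
    "static_tissue_mask",
]

#: Minimum number of static-tissue pixels required for the background fit.
MIN_STATIC_PIXELS = 30

# 4-connectivity for component labelling and closing, per the mask convention.
_CROSS = ndimage.generate_binary_structure(2, 1)


def _quadratic_design(xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Design matrix columns (1, x, y, x², xy, y²) for flattened coordinates."""
    return np.column_stack(
        [np.ones_like(xx), xx, yy, xx**2, xx * yy, yy**2]
    )


def eddy_surface(coeffs: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Evaluate the quadratic background surface on an image grid.

    Coordinates follow the package convention: ``x`` is the column index and
    ``y`` the row index, with pixel centres at integer coordinates.
    """
    ny, nx = shape
    xx, yy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="xy")
    a, b, c, d, e, f = np.asarray(coeffs, dtype=float)
    return a + b * xx + c * yy + d * xx**2 + e * xx * yy + f * yy**2


def fit_eddy_background(
    series: VesselImageSeries,
    static_mask: np.ndarray,
    per_frame: bool = False,
) -> Tuple[np.ndarray, VesselImageSeries]:
    """Fit and subtract the eddy-current background phase surface.

    A quadratic surface ``a + b*x + c*y + d*x² + e*x*y + f*y²`` is fitted by
    least squares to the time-averaged velocity of the static-tissue pixels
    and subtracted from every frame (eddy-current offsets are temporally
    static).  With ``per_frame=True`` a separate surface is fitted to and
    subtracted from each frame; the returned coefficients are then the
    frame-mean.

    Returns the 6 coefficients and the corrected series.  After correction
    the static-tissue time-averaged velocity has zero mean to numerical
    tolerance.
    """
    mask = np.asarray(static_mask, dtype=bool)
    if mask.shape != series.velocity.shape[1:]:
        raise InvalidInputError("static_mask dimensions do not match the image series")
    npix = int(mask.sum())
    if npix < MIN_STATIC_PIXELS:
        raise InvalidInputError(
            f"static mask has {npix} pixels; need >= {MIN_STATIC_PIXELS} for a stable fit"
        )

    yy_idx, xx_idx = np.nonzero(mask)
    design = _quadratic_design(xx_idx.astype(float), yy_idx.astype(float))

    def _solve(values: np.ndarray) -> np.ndarray:
        coeffs, _, rank, _ = np.linalg.lstsq(design, values, rcond=None)
        if rank < 6:
            raise DegenerateFitError(
                f"static pixels give a rank-{rank} quadratic design; fit is degenerate"
            )
        return coeffs

    if per_frame:
        all_coeffs = np.empty((series.n_frames, 6))
        corrected = np.empty_like(series.velocity)
        for i in range(series.n_frames):
            all_coeffs[i] = _solve(series.velocity[i][mask])
            corrected[i] = series.velocity[i] - eddy_surface(all_coeffs[i], mask.shape)
        coeffs = all_coeffs.mean(axis=0)
    else:
        coeffs = _solve(series.velocity.mean(axis=0)[mask])
        corrected = series.velocity - eddy_surface(coeffs, mask.shape)[None, :, :]

    out = VesselImageSeries(
        magnitude=series.magnitude,
        velocity=corrected,
        pixel_spacing=series.pixel_spacing,
        venc=series.venc,
        rr_interval=series.rr_interval,
        vessel_id=series.vessel_id,
        eddy_corrected=True,
    )
    return coeffs, out


def static_tissue_mask(
    series: VesselImageSeries,
    sd_percentile: float = 30.0,
    magnitude_floor: float = 5.0,
) -> np.ndarray:
    """Heuristic static-tissue mask for real data.

    Selects pixels whose temporal velocity standard deviation falls below the
    given percentile and whose time-averaged magnitude exceeds the noise
    floor — i.e. visible tissue that does not pulsate.  Synthetic data ship
    exact static masks; this is the entry point for scanner exports.
    """
    sd = series.velocity.std(axis=0)
    mag = series.magnitude.mean(axis=0)
    return (sd <= np.percentile(sd, sd_percentile)) & (mag >= magnitude_floor)


def _component_at(binary: np.ndarray, seed_yx: Tuple[int, int]) -> Optional[np.ndarray]:
    """Connected component of ``binary`` containing the seed pixel, or None."""
    labels, _ = ndimage.label(binary, structure=_CROSS)
    lab = labels[seed_yx]
    if lab == 0:
        return None
    return labels == lab


def propagate_roi(
    initial_mask: np.ndarray,
    series: VesselImageSeries,
    closing_iterations: int = 1,
) -> RoiMaskSeries:
    """Propagate a vessel ROI through the cardiac cycle on magnitude images.

    Each frame is thresholded (Otsu) and the 4-connected bright component
    seeded at the previous frame's mask centroid is taken as the vessel,
    morphologically closed and hole-filled.  Frame 0 is seeded at the
    centroid of ``initial_mask``, which must overlap the vessel.

    Raises :class:`PropagationFailureError` naming the first frame at which
    the vessel is lost.
    """
    initial = np.asarray(initial_mask, dtype=bool)
    if initial.shape != series.magnitude.shape[1:]:
        raise InvalidInputError("initial_mask dimensions do not match the image series")
    if not initial.any():
        raise InvalidInputError("initial_mask is empty")

    masks = np.zeros_like(series.magnitude, dtype=bool)
    centroid = ndimage.center_of_mass(initial)
    for i in range(series.n_frames):
        frame = series.magnitude[i]
        try:
            thr = threshold_otsu(frame)
        except ValueError:  # constant image
            raise PropagationFailureError(i) from None
        bright = frame > thr
        seed = (
            int(np.clip(round(centroid[0]), 0, frame.shape[0] - 1)),
            int(np.clip(round(centroid[1]), 0, frame.shape[1] - 1)),
        )
        comp = _component_at(bright, seed)
        if comp is None and i == 0:
            # fall back to the component with the largest overlap with the initial ROI
            labels, nlab = ndimage.label(bright, structure=_CROSS)
            overlaps = ndimage.sum_labels(initial, labels, index=np.arange(1, nlab + 1))
            if nlab and overlaps.max() > 0:
                comp = labels == (int(np.argmax(overlaps)) + 1)
        if comp is None or not comp.any():
            raise PropagationFailureError(i)
        comp = ndimage.binary_closing(comp, structure=_CROSS, iterations=closing_iterations)
        comp = ndimage.binary_fill_holes(comp, structure=_CROSS)
        masks[i] = comp
        centroid = ndimage.center_of_mass(comp)

    return RoiMaskSeries(masks, series.pixel_spacing)


def measure_roi_flow(
    series: VesselImageSeries,
    rois: RoiMaskSeries,
    allow_uncorrected: bool = False,
) -> FlowCurve:
    """Integrate ROI velocity into a flow curve in ml/s.

    For each frame, flow = Σ (velocity over ROI pixels) × pixel area, with
    cm/s·mm² converted to ml/s.  The series should be eddy-corrected first;
    pass ``allow_uncorrected=True`` to waive that check explicitly.
    """
    if rois.masks.shape != series.velocity.shape:
        raise InvalidInputError("ROI mask dimensions do not match the image series")
    if not series.eddy_corrected and not allow_uncorrected:
        raise InvalidInputError(
            "series is not eddy-corrected; correct it first or pass allow_uncorrected=True"
        )
    # 1 cm/s × 1 mm² = 10 mm³/s = 0.01 ml/s
    flow = (series.velocity * rois.masks).sum(axis=(1, 2)) * series.pixel_area * 0.01
    return FlowCurve(
        vessel_id=series.vessel_id,
        flow=flow,
        frame_duration=series.frame_duration,
        rr_interval=series.rr_interval,
    )


def net_flow(curve: FlowCurve) -> float:
    """Net flow over the cardiac cycle in ml (rectangle rule, flow × frame duration)."""
    return curve.net_flow()


def measure_area(rois: RoiMaskSeries) -> AreaResult:
    """Per-frame cross-sectional area (pixel count × pixel area) and cycle average."""
    counts = rois.masks.sum(axis=(1, 2))
    if np.any(counts == 0):
        raise InvalidInputError("empty ROI mask in at least one frame")
    return AreaResult(counts.astype(float) * rois.pixel_spacing**2)
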
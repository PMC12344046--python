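"""Slice pairing and B-spline deformable registration onto the CBCT grid.

The two series differ in slice thickness and count, so each CBCT slice is
paired with the planning-CT slice nearest in scan-axis position (ties go to
the smaller position).  The planning-CT slice is then resampled onto the CBCT
pixel grid (center-aligned bilinear) and warped onto the CBCT by a free-form
deformation: a B-spline control-point grid optimized against a Mattes mutual
-information similarity in a coarse-to-fine pyramid.  Registration is done
per slice pair in 2-D, on display-scale images, exactly the representation
the rest of the pipeline consumes.

The registration engine is SimpleITK; this module owns the contract (grid
conventions, provenance, deformation-field format: ``(H, W, 2)`` arrays of
(row, col) displacements in pixels on the fixed grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .gradation import DISPLAY_MAX, RawScanSlice


class RegistrationError(ValueError):
    pass


@dataclass(frozen=True)
class RegistrationConfig:
    control_point_spacing: float = 16.0   # px at the finest level
    levels: int = 3
    histogram_bins: int = 32
    iterations_per_level: int = 200
    learning_rate: float = 2.0            # initial step of the gradient optimizer
    sampling_fraction: float = 1.0        # dense metric sampling (deterministic)


@dataclass
class SliceSeries:
    """Ordered slices of one modality for one patient."""

    slices: list[RawScanSlice]
    patient_id: str = ""
    modality_label: str = ""

    def __post_init__(self) -> None:
        if self.slices:
            pos = [s.slice_position for s in self.slices]
            order = np.argsort(pos, kind="stable")
            self.slices = [self.slices[i] for i in order]
            pos = [s.slice_position for s in self.slices]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise RegistrationError("slice positions must be strictly monotone")


def pair_slices(cbct_series: SliceSeries, planct_series: SliceSeries
                ) -> list[tuple[RawScanSlice, RawScanSlice]]:
    """Nearest-position pairing: one planning-CT partner per CBCT slice.

    Ties on |Δposition| break toward the smaller planning-CT position.
    """
    if not cbct_series.slices or not planct_series.slices:
        raise RegistrationError("both series must be non-empty")
    pairs = []
    for cb in cbct_series.slices:
        best = min(planct_series.slices,
                   key=lambda p: (abs(p.slice_position - cb.slice_position),
                                  p.slice_position))
        pairs.append((cb, best))
    return pairs


def resample_to_grid(moving: np.ndarray, moving_spacing: tuple[float, float],
                     target_shape: tuple[int, int],
                     target_spacing: tuple[float, float]) -> np.ndarray:
    """Bilinear resample onto the CBCT pixel grid, aligned at the image center.

    Output values are rounded and clipped back to the display range.
    """
    if min(target_shape) < 1:
        raise RegistrationError("degenerate target shape")
    if min(moving_spacing) <= 0 or min(target_spacing) <= 0:
        raise RegistrationError("spacings must be > 0")
    moving = np.asarray(moving, dtype=np.float64)
    h, w = moving.shape
    th, tw = target_shape
    rows = (np.arange(th) - (th - 1) / 2) * target_spacing[0] / moving_spacing[0] + (h - 1) / 2
    cols = (np.arange(tw) - (tw - 1) / 2) * target_spacing[1] / moving_spacing[1] + (w - 1) / 2
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = map_coordinates(moving, np.stack([rr, cc]), order=1, mode="nearest")
    return np.clip(np.floor(out + 0.5), 0, DISPLAY_MAX).astype(np.int32)


def apply_deformation(field: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Backward bilinear warp of a display image by a ``(H, W, 2)`` px field.

    Out-of-domain samples take nearest-edge values; output is re-clipped to
    the display range.
    """
    img = np.asarray(img)
    field = np.asarray(field, dtype=np.float64)
    if field.shape[:2] != img.shape or field.shape[-1] != 2:
        raise RegistrationError(
            f"field shape {field.shape} does not match image {img.shape}")
    rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(np.float64)
    coords = np.stack([rr + field[..., 0], cc + field[..., 1]])
    out = map_coordinates(img.astype(np.float64), coords, order=1, mode="nearest")
    return np.clip(np.floor(out + 0.5), 0, DISPLAY_MAX).astype(np.int32)


def _mattes_mi(fixed: sitk.Image, moving: sitk.Image, bins: int) -> float:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(sitk.TranslationTransform(2))
    return reg.MetricEvaluate(fixed, moving)


def register_deformable(fixed: np.ndarray, moving: np.ndarray,
                        cfg: RegistrationConfig | None = None
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Free-form B-spline registration of ``moving`` onto ``fixed``.

    Both are display images on the same grid.  Returns ``(warped, field,
    provenance)`` where ``field[r, c]`` is the (row, col) displacement in
    pixels sampled when warping, and provenance records the settings, the
    before/after similarity and a warning flag when the similarity did not
    improve.
    """
    cfg = cfg or RegistrationConfig()
    fixed = np.asarray(fixed)
    moving = np.asarray(moving)
    if fixed.shape != moving.shape:
        raise RegistrationError("fixed and moving must share a grid; "
                                "resample_to_grid first")
    f = sitk.GetImageFromArray(fixed.astype(np.float32))
    m = sitk.GetImageFromArray(moving.astype(np.float32))

    mesh = [max(2, int(round(s / cfg.control_point_spacing)))
            for s in fixed.shape[::-1]]
    tx0 = sitk.BSplineTransformInitializer(f, mesh)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.histogram_bins)
    if cfg.sampling_fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(cfg.sampling_fraction, seed=1)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsGradientDescentLineSearch(
        learningRate=cfg.learning_rate,
        numberOfIterations=cfg.iterations_per_level,
        convergenceMinimumValue=1e-7, convergenceWindowSize=10)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (cfg.levels - 1 - i) for i in range(cfg.levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, s // 2) for s in shrink])
    reg.SetInitialTransform(tx0, inPlace=True)

    mi_before = _mattes_mi(f, m, cfg.histogram_bins)
    converged = True
    try:
        tx = reg.Execute(f, m)
    except RuntimeError as exc:  # optimizer failure: keep best-so-far transform
        warnings.warn(f"registration did not converge: {exc}", RuntimeWarning,
                      stacklevel=2)
        tx, converged = tx0, False

    field_filter = sitk.TransformToDisplacementFieldFilter()
    field_filter.SetReferenceImage(f)
    disp = sitk.GetArrayFromImage(field_filter.Execute(tx))  # (H, W, [x, y])
    field = disp[..., ::-1].astype(np.float64)               # -> (row, col)

    warped = apply_deformation(field, moving)
    mi_after = _mattes_mi(f, sitk.GetImageFromArray(warped.astype(np.float32)),
                          cfg.histogram_bins)
    improved = mi_after <= mi_before + 1e-2  # Mattes MI is negated: lower is better
    if not improved:
        warnings.warn("registration similarity did not improve", RuntimeWarning,
                      stacklevel=2)
    provenance = {
        "control_point_spacing": cfg.control_point_spacing,
        "levels": cfg.levels,
        "histogram_bins": cfg.histogram_bins,
        "iterations_per_level": cfg.iterations_per_level,
        "metric_before": float(mi_before),
        "metric_after": float(mi_after),
        "converged": converged,
        "improved": bool(improved),
    }
    return warped, field, provenance


def invert_displacement_field(field: np.ndarray, iterations: int = 20) -> np.ndarray:
    """Numerical inverse of a backward-warp displacement field.

    Solves ``g(p) = −field(p + g(p))`` by fixed-point iteration, so that
    warping by ``g`` undoes warping by ``field``.  Registration of a warped
    image back onto its source recovers this inverse, not the forward field.
    """
    field = np.asarray(field, dtype=np.float64)
    rr, cc = np.mgrid[0:field.shape[0], 0:field.shape[1]].astype(np.float64)
    g = -field.copy()
    for _ in range(iterations):
        coords = np.stack([rr + g[..., 0], cc + g[..., 1]])
        fy = map_coordinates(field[..., 0], coords, order=1, mode="nearest")
        fx = map_coordinates(field[..., 1], coords, order=1, mode="nearest")
        g = -np.stack([fy, fx], axis=-1)
    return g


def mean_endpoint_error(recovered: np.ndarray, truth: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Mean Euclidean distance between two displacement fields, optionally masked."""
    d = np.linalg.norm(np.asarray(recovered) - np.asarray(truth), axis=-1)
    if mask is not None:
        d = d[mask]
    return float(d.mean())
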
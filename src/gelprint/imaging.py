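"""Image-based measurement of drops, fibers, grids, particles and cells.

All operations take an :class:`~gelprint.synthetic.ImageField` (pixels + a
micrometer-per-pixel scale) and report physical units.  Segmentation
defaults to Otsu thresholding — a deterministic stand-in for the manual
threshold adjustment typical of interactive image analysis — with a
fixed-value override.  Conventions: pixel centers, origin top-left;
foreground connectivity 8, pore (background-hole) connectivity 4.

Fiber widths are measured as twice the Euclidean distance to background at
seeded-random points on the fiber skeleton.  The skeleton of a capped
strand sprouts short spurs at its ends where the distance field tapers, so
sampling is restricted to the central ridge (distance within 1.5 px of the
fiber's skeleton maximum); this assumes near-constant-width fibers, which
is exactly the printed-strand use case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize
from skimage.util import img_as_ubyte

from .scoring import FiberMeasurement, GridMeasurement
from .synthetic import ImageField

__all__ = [
    "SegmentationConfig",
    "PlaneCoverage",
    "PlaneComparison",
    "GranulometryResult",
    "measure_drop_diameter",
    "measure_fiber_profile",
    "measure_grid",
    "measure_granulometry",
    "cell_area_fraction",
    "compare_plane_coverage",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """How to binarize a grayscale image.

    ``threshold`` is ``"otsu"`` or ``"fixed"`` (with ``fixed_value`` in the
    8-bit range); ``invert`` flips foreground/background; objects below
    ``min_object_area`` px^2 are discarded.
    """

    threshold: str = "otsu"
    fixed_value: Optional[float] = None
    min_object_area: int = 0
    invert: bool = False

    def __post_init__(self):
        if self.threshold not in ("otsu", "fixed"):
            raise ValueError("threshold must be 'otsu' or 'fixed'")
        if self.threshold == "fixed":
            if self.fixed_value is None or not 0 <= self.fixed_value <= 255:
                raise ValueError("fixed threshold requires fixed_value in [0, 255]")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be non-negative")


DEFAULT_SEGMENTATION = SegmentationConfig()


@dataclass(frozen=True)
class PlaneCoverage:
    """Fraction of one optical plane's area occupied by cells."""

    plane_label: str
    cell_area_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.cell_area_fraction <= 1.0:
            raise ValueError("cell_area_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlaneComparison:
    """Per-plane change across the gel point plus a homogeneity verdict."""

    absolute_difference: Dict[str, float]
    relative_difference: Dict[str, float]
    homogeneous: bool
    max_relative_spread_before: float
    max_relative_spread_after: float


@dataclass(frozen=True)
class GranulometryResult:
    """Per-particle equivalent diameters (um) with their mean and SD."""

    diameters_um: np.ndarray
    mean_um: float  # NaN when no particles were found
    sd_um: float

    @property
    def n_particles(self) -> int:
        return int(self.diameters_um.size)

    @property
    def empty(self) -> bool:
        return self.n_particles == 0


def _to_ubyte(pixels: np.ndarray) -> np.ndarray:
    if pixels.dtype == np.uint8:
        return pixels
    return img_as_ubyte(pixels)


def _binarize(field: ImageField, cfg: SegmentationConfig) -> np.ndarray:
    """8-bit conversion, thresholding and optional inversion -> bool mask."""
    px = _to_ubyte(field.pixels)
    if cfg.threshold == "otsu":
        if px.min() == px.max():
            # constant image: everything is background unless fully saturated
            mask = np.full(px.shape, px.min() > 0, dtype=bool)
        else:
            mask = px > threshold_otsu(px)
    else:
        mask = px > cfg.fixed_value
    if cfg.invert:
        mask = ~mask
    return mask


def _labeled_regions(mask: np.ndarray, cfg: SegmentationConfig):
    lbl = label(mask, connectivity=2)  # 8-connectivity for foreground
    regions = [r for r in regionprops(lbl) if r.area >= max(cfg.min_object_area, 1)]
    return lbl, regions


def measure_drop_diameter(
    field: ImageField, cfg: SegmentationConfig = DEFAULT_SEGMENTATION
) -> float:
    """Equivalent-area circle diameter (mm) of the largest foreground object.

    Warns when more than one object is present (the largest is reported);
    raises when the image contains no object.
    """
    mask = _binarize(field, cfg)
    _, regions = _labeled_regions(mask, cfg)
    if not regions:
        raise ValueError("no object found in drop image")
    if len(regions) > 1:
        warnings.warn(
            f"{len(regions)} objects found; reporting the largest", stacklevel=2
        )
    largest = max(regions, key=lambda r: r.area)
    return largest.equivalent_diameter_area * field.scale / 1000.0


def measure_fiber_profile(
    field: ImageField,
    n_points: int = 10,
    seed: int = 0,
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
    min_width_px: float = 3.0,
) -> FiberMeasurement:
    """Local fiber widths (mm) at seeded-random skeleton points.

    Each connected foreground component is one fiber; ``n_points`` points
    are drawn uniformly (with a seeded generator) from its central skeleton
    ridge and the local width is twice the distance to background there.
    """
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    mask = _binarize(field, cfg)
    lbl, regions = _labeled_regions(mask, cfg)
    if not regions:
        raise ValueError("no fibers found")
    edt = ndimage.distance_transform_edt(mask)
    rng = np.random.default_rng(seed)
    widths_px: List[float] = []
    for region in sorted(regions, key=lambda r: r.label):
        component = lbl == region.label
        skel = skeletonize(component)
        d = edt[skel]
        if d.size == 0:
            continue
        ridge_floor = d.max() - 1.5  # drop end-spur pixels of the skeleton
        ys, xs = np.nonzero(skel)
        keep = d >= ridge_floor
        ys, xs, d = ys[keep], xs[keep], d[keep]
        idx = rng.choice(d.size, size=n_points, replace=d.size < n_points)
        widths_px.extend(2.0 * d[idx])
    widths_px = np.asarray(widths_px, dtype=float)
    if np.any(widths_px < min_width_px):
        raise ValueError(
            f"fiber thinner than {min_width_px} px: below the resolution floor"
        )
    return FiberMeasurement(
        diameters=widths_px * field.scale / 1000.0,
        n_fibers=len(regions),
        points_per_fiber=n_points,
    )


def measure_grid(
    field: ImageField,
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
    cad_side_x: Optional[float] = None,
    cad_side_y: Optional[float] = None,
    min_pore_area_px: int = 9,
) -> GridMeasurement:
    """Printed side lengths (mm) per axis from the enclosed grid pores.

    Pores are background components fully enclosed by foreground
    (4-connectivity; components touching the image border are the outer
    background and are discarded).  Each pore contributes its bounding-box
    width to the x sides and height to the y sides.  CAD targets may be
    supplied for downstream scoring; they default to NaN.
    """
    mask = _binarize(field, cfg)
    bg = ~mask
    lbl = label(bg, connectivity=1)  # 4-connectivity for pores
    border_labels = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    pores = [
        r
        for r in regionprops(lbl)
        if r.label not in border_labels and r.area >= min_pore_area_px
    ]
    if not pores:
        raise ValueError("no enclosed pores found in grid image")
    scale_mm = field.scale / 1000.0
    widths = np.array([r.bbox[3] - r.bbox[1] for r in pores], dtype=float) * scale_mm
    heights = np.array([r.bbox[2] - r.bbox[0] for r in pores], dtype=float) * scale_mm
    return GridMeasurement(
        cad_side_x=float("nan") if cad_side_x is None else cad_side_x,
        cad_side_y=float("nan") if cad_side_y is None else cad_side_y,
        printed_sides_x=widths,
        printed_sides_y=heights,
    )


def measure_granulometry(
    field: ImageField,
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
    min_area_px: int = 7,
) -> GranulometryResult:
    """Equivalent-area diameters (um) of the particles in a powder field.

    Connected components below ``min_area_px`` are treated as debris.  An
    empty field returns an empty result with NaN mean (flagged via
    ``.empty``) rather than raising.
    """
    mask = _binarize(field, cfg)
    filter_cfg = SegmentationConfig(
        threshold=cfg.threshold,
        fixed_value=cfg.fixed_value,
        min_object_area=max(cfg.min_object_area, min_area_px),
        invert=cfg.invert,
    )
    _, regions = _labeled_regions(mask, filter_cfg)
    diameters = np.array([r.equivalent_diameter_area for r in regions], dtype=float)
    diameters *= field.scale
    if diameters.size == 0:
        return GranulometryResult(diameters, float("nan"), float("nan"))
    sd = float(diameters.std(ddof=1)) if diameters.size > 1 else 0.0
    return GranulometryResult(diameters, float(diameters.mean()), sd)


def cell_area_fraction(
    field: ImageField, cfg: SegmentationConfig = DEFAULT_SEGMENTATION
) -> PlaneCoverage:
    """Fraction of the plane occupied by cells.

    The image is converted to 8-bit and thresholded so cells are white and
    matrix black; the black (background) fraction is measured and the cell
    fraction obtained by subtracting it from the total.
    """
    mask = _binarize(field, cfg)
    black_fraction = 1.0 - mask.mean()
    return PlaneCoverage(
        plane_label=field.plane_label,
        cell_area_fraction=1.0 - black_fraction,
    )


def compare_plane_coverage(
    before: Sequence[PlaneCoverage],
    after: Sequence[PlaneCoverage],
    rel_tolerance: float = 0.20,
) -> PlaneComparison:
    """Per-plane coverage changes across the gel point + homogeneity flag.

    ``before`` and ``after`` are matched by plane label.  The distribution
    counts as homogeneous when, at both time points, the relative spread
    (max - min over the three planes, divided by their mean) stays below
    ``rel_tolerance``.  A bottom plane several-fold denser than the top is
    the sedimentation signature and flags heterogeneous.
    """
    b = {p.plane_label: p.cell_area_fraction for p in before}
    a = {p.plane_label: p.cell_area_fraction for p in after}
    if set(b) != set(a):
        raise ValueError("plane labels do not match between time points")
    abs_diff = {k: a[k] - b[k] for k in b}
    rel_diff = {
        k: (a[k] - b[k]) / b[k] if b[k] > 0 else float("inf") if a[k] > 0 else 0.0
        for k in b
    }

    def spread(vals: Dict[str, float]) -> float:
        v = np.array(list(vals.values()), dtype=float)
        m = v.mean()
        if m == 0:
            return 0.0
        return float((v.max() - v.min()) / m)

    sb, sa = spread(b), spread(a)
    return PlaneComparison(
        absolute_difference=abs_diff,
        relative_difference=rel_diff,
        homogeneous=(sb < rel_tolerance and sa < rel_tolerance),
        max_relative_spread_before=sb,
        max_relative_spread_after=sa,
    )
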
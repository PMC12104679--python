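"""Chart-based color correction, segmentation, cleanup and per-plant splitting.

Front end of the image pipeline: a scene frame holds four plant regions of
interest (ROIs) and a color-chart patch grid; an affine color transform is
fitted on the chart, the corrected image is thresholded to a plant mask,
cleaned, and split into per-plant masks by ROI overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "Rect",
    "SceneImage",
    "BinaryMask",
    "ColorTransform",
    "fit_color_correction",
    "chart_patch_means",
    "excess_green",
    "threshold_mask",
    "clean_mask",
    "split_plants",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Rect:
    """Half-open rectangle [r0, r1) x [c0, c1) in image coordinates."""

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    def within(self, shape: tuple[int, int]) -> bool:
        return 0 <= self.r0 and 0 <= self.c0 and self.r1 <= shape[0] and self.c1 <= shape[1]

    def disjoint(self, other: "Rect") -> bool:
        return (
            self.r1 <= other.r0
            or other.r1 <= self.r0
            or self.c1 <= other.c0
            or other.c1 <= self.c0
        )


@dataclass
class SceneImage:
    """One captured frame: RGB pixels plus chart and plant ROI geometry."""

    image: np.ndarray  # (rows, cols, 3) uint8
    session: str
    scene_id: str
    chart_region: Rect | None = None
    plant_rois: list = field(default_factory=list)  # list[Rect]
    treatments: list = field(default_factory=list)  # per-ROI treatment labels
    seedling_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("scene image must be rows x cols x 3")
        shape = img.shape[:2]
        for roi in self.plant_rois:
            if not roi.within(shape):
                raise ValueError(f"plant ROI {roi} exceeds image bounds {shape}")
        if self.chart_region is not None:
            if not self.chart_region.within(shape):
                raise ValueError("chart region exceeds image bounds")
            for roi in self.plant_rois:
                if not self.chart_region.disjoint(roi):
                    raise ValueError("chart region overlaps a plant ROI")


@dataclass
class BinaryMask:
    """Boolean foreground grid with provenance."""

    data: np.ndarray
    label_id: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)

    @property
    def pixel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class ColorTransform:
    """Affine RGB map ``corrected = observed @ matrix.T + offset``."""

    matrix: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    residual_rms: np.ndarray  # per-channel RMS on the fitting patches

    def apply_to_colors(self, colors: np.ndarray) -> np.ndarray:
        return np.asarray(colors, dtype=float) @ self.matrix.T + self.offset

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Apply to an 8-bit image, clipping back to [0, 255]."""
        flat = image.reshape(-1, 3).astype(float)
        out = self.apply_to_colors(flat).reshape(image.shape)
        return np.clip(np.round(out), 0, 255).astype(np.uint8)


class RankDeficientChartError(ValueError):
    """Observed chart patches do not span enough of color space to fit a map."""


def fit_color_correction(observed_patches, reference_patches) -> ColorTransform:
    """Least-squares affine map from observed to reference patch colors.

    Requires at least 4 patch pairs whose observed colors (augmented with a
    constant) have full rank; the per-channel RMS residual on the fitting
    patches is reported and can only improve on (or match) the identity map.
    """
    obs = np.asarray(observed_patches, dtype=float)
    ref = np.asarray(reference_patches, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observed and reference patches must both be (n, 3)")
    if len(obs) < 4:
        raise ValueError("need at least 4 patch pairs to fit an affine color map")
    design = np.column_stack([obs, np.ones(len(obs))])
    rank = np.linalg.matrix_rank(design, tol=1e-8 * np.abs(design).max())
    if rank < 4:
        raise RankDeficientChartError(
            f"observed patch set spans rank {rank} < 4; add patches with more "
            "color diversity"
        )
    coefs, *_ = np.linalg.lstsq(design, ref, rcond=None)
    matrix = coefs[:3].T
    offset = coefs[3]
    resid = obs @ matrix.T + offset - ref
    rms = np.sqrt((resid**2).mean(axis=0))
    return ColorTransform(matrix=matrix, offset=offset, residual_rms=rms)


def chart_patch_means(
    image: np.ndarray, chart_region: Rect, grid: tuple[int, int] = (4, 6)
) -> np.ndarray:
    """Mean RGB of each chart patch, reading the grid row-major.

    Patch interiors are sampled with a one-pixel-per-side margin to avoid
    bleeding across patch borders.
    """
    sub = image[chart_region.slices].astype(float)
    nr, nc = grid
    h, w = sub.shape[:2]
    means = np.empty((nr * nc, 3))
    for i in range(nr):
        for j in range(nc):
            r0, r1 = round(i * h / nr), round((i + 1) * h / nr)
            c0, c1 = round(j * w / nc), round((j + 1) * w / nc)
            patch = sub[r0 + 1 : max(r0 + 2, r1 - 1), c0 + 1 : max(c0 + 2, c1 - 1)]
            means[i * nc + j] = patch.reshape(-1, 3).mean(axis=0)
    return means


def excess_green(image: np.ndarray) -> np.ndarray:
    """Excess-green index 2G - R - B as float."""
    img = np.asarray(image, dtype=float)
    return 2.0 * img[..., 1] - img[..., 0] - img[..., 2]


def threshold_mask(
    image: np.ndarray,
    bounds="auto",
    color_space: str = "rgb",
    provenance: dict | None = None,
) -> BinaryMask:
    """Segment plant pixels from a (corrected) RGB image.

    ``bounds="auto"`` thresholds the excess-green index with an Otsu cut;
    otherwise ``bounds`` is a pair of inclusive per-channel (lo, hi) triples in
    the requested color space ("rgb" with 0-255 channels or "hsv" with 0-1
    channels).  An empty foreground yields a warning, not an error.
    """
    img = np.asarray(image)
    if isinstance(bounds, str) and bounds == "auto":
        exg = excess_green(img)
        if np.ptp(exg) == 0:
            warnings.warn("flat excess-green channel: returning empty mask")
            mask = np.zeros(img.shape[:2], dtype=bool)
        else:
            mask = exg > threshold_otsu(exg)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
        space = color_space.lower()
        if space == "rgb":
            chans = img.astype(float)
        elif space == "hsv":
            chans = skcolor.rgb2hsv(img)
        else:
            raise ValueError(f"unsupported color space {color_space!r}")
        mask = np.all((chans >= lo) & (chans <= hi), axis=-1)
    if not mask.any():
        warnings.warn("threshold produced an empty foreground mask")
    return BinaryMask(data=mask, provenance=dict(provenance or {}, bounds=str(bounds)))


def clean_mask(mask: BinaryMask, min_component_px: int = 0, fill_holes: bool = True) -> BinaryMask:
    """Drop small 8-connected components and optionally fill interior holes.

    Components with fewer than ``min_component_px`` pixels are removed; holes
    are 4-connected background regions not reaching the image border.
    """
    if min_component_px < 0:
        raise ValueError("min_component_px must be >= 0")
    data = mask.data
    if min_component_px > 1:
        labels = measure.label(data, connectivity=2)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component_px
        keep[0] = False
        data = keep[labels]
    if fill_holes:
        data = ndimage.binary_fill_holes(data)
    return BinaryMask(
        data=data,
        label_id=mask.label_id,
        provenance=dict(mask.provenance, cleaned=True),
    )


def split_plants(mask: BinaryMask, plant_rois: list) -> list[BinaryMask]:
    """Assign each connected component wholly to the ROI it overlaps most.

    Components reaching outside their rectangle stay attached to it (tall
    seedlings keep their crowns); ties go to the lowest ROI index; components
    touching no ROI are dropped with a log entry.
    """
    if not plant_rois:
        raise ValueError("split_plants requires at least one plant ROI")
    labels = measure.label(mask.data, connectivity=2)
    n_labels = labels.max()
    out = [
        BinaryMask(
            data=np.zeros_like(mask.data),
            label_id=i,
            provenance=dict(mask.provenance, roi=i),
        )
        for i in range(len(plant_rois))
    ]
    for lab in range(1, n_labels + 1):
        component = labels == lab
        overlaps = [int(component[roi.slices].sum()) for roi in plant_rois]
        best = int(np.argmax(overlaps))  # argmax takes the lowest index on ties
        if overlaps[best] == 0:
            log.info("component %d (%d px) touches no ROI: dropped", lab, component.sum())
            continue
        if overlaps.count(overlaps[best]) > 1:
            log.info("component %d overlap tie: assigned to ROI %d", lab, best)
        out[best].data |= component
    return out
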
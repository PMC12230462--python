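"""Pixel-based histology quantification.

Four measurements used in cardiac-remodeling phenotyping:

* **Fibrotic index** on trichrome stains: percent blue (collagen)
  divided by percent red (muscle) pixels, classified by hue/saturation
  rules;
* **Myocyte cross-sectional area**: per-cell pixel counts scaled by
  (um/pixel)^2, from provided masks or a threshold + watershed
  segmentation, excluding border-touching cells;
* **Positive pixel fraction** (TUNEL/DAB): brown-positive pixels over
  tissue pixels (white/luminal pixels excluded from the denominator);
* **Mean intensity** (e.g. TMRE for mitochondrial membrane potential),
  optionally within a mask; group normalization lives in the stats
  layer.

The hue thresholds are configuration, not constants of nature: they
are carried on every classification result so reported indices are
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HueThresholds",
    "ColorClassification",
    "FibrosisIndex",
    "AreaResult",
    "classify_colors",
    "fibrotic_index",
    "cell_areas",
    "positive_pixel_fraction",
    "mean_intensity",
]

MIN_CELLS_PER_IMAGE = 20   # inclusion rule for area measurements

LABEL_BACKGROUND = 0
LABEL_BLUE = 1
LABEL_RED = 2


@dataclass(frozen=True)
class HueThresholds:
    """Hue (degrees) and saturation rules for stain classification."""

    blue_hue: tuple[float, float] = (180.0, 260.0)
    red_hue_max: float = 20.0      # red wraps around 0: <20 or >340
    red_hue_min_wrap: float = 340.0
    saturation_min: float = 0.15

    def __post_init__(self):
        lo, hi = self.blue_hue
        if not (0 <= lo < hi <= 360):
            raise ValueError("invalid blue hue range")
        if lo < self.red_hue_max or hi > self.red_hue_min_wrap:
            raise ValueError("red and blue hue ranges overlap")


@dataclass
class ColorClassification:
    labels: np.ndarray             # per-pixel LABEL_* codes
    thresholds: HueThresholds
    fractions: dict = field(default_factory=dict)

    def fraction(self, label: int) -> float:
        return float(np.mean(self.labels == label))


@dataclass
class FibrosisIndex:
    pct_blue: float
    pct_red: float
    index: float | None            # None when pct_red == 0
    thresholds: HueThresholds


@dataclass
class AreaResult:
    areas_um2: np.ndarray
    n_cells: int
    mean_area_um2: float | None
    median_area_um2: float | None
    meets_min_cells: bool
    scale_um_per_px: float


def _to_float_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    out = img.astype(float)
    if out.max() > 1.0:
        out = out / out.max()
    return out


def classify_colors(img: np.ndarray,
                    thresholds: HueThresholds | None = None,
                    ) -> ColorClassification:
    """Label each pixel blue / red / background by hue and saturation.

    Low-saturation pixels (unstained tissue, lumen, white balance) are
    background regardless of hue.
    """
    from skimage.color import rgb2hsv

    thresholds = thresholds or HueThresholds()
    hsv = rgb2hsv(_to_float_rgb(img))
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    saturated = sat > thresholds.saturation_min
    lo, hi = thresholds.blue_hue
    blue = saturated & (hue >= lo) & (hue <= hi)
    red = saturated & ((hue < thresholds.red_hue_max)
                       | (hue > thresholds.red_hue_min_wrap))
    labels = np.full(hue.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[blue] = LABEL_BLUE
    labels[red] = LABEL_RED
    if not saturated.any():
        warnings.warn("image is entirely background at these thresholds",
                      stacklevel=2)
    cls = ColorClassification(labels=labels, thresholds=thresholds)
    cls.fractions = {
        "blue": cls.fraction(LABEL_BLUE),
        "red": cls.fraction(LABEL_RED),
        "background": cls.fraction(LABEL_BACKGROUND),
    }
    return cls


def fibrotic_index(classification: ColorClassification) -> FibrosisIndex:
    """Percent-blue over percent-red pixel ratio (fibrosis vs muscle)."""
    pct_blue = 100.0 * classification.fraction(LABEL_BLUE)
    pct_red = 100.0 * classification.fraction(LABEL_RED)
    index = pct_blue / pct_red if pct_red > 0 else None
    if index is None:
        warnings.warn("no red (muscle) pixels: fibrotic index undefined",
                      stacklevel=2)
    return FibrosisIndex(pct_blue=pct_blue, pct_red=pct_red, index=index,
                         thresholds=classification.thresholds)


def _segment_cells(img: np.ndarray) -> np.ndarray:
    """Threshold + distance-transform watershed segmentation of myocytes.

    Intended for eosin-like stains where cells are saturated red on a
    pale background; hand-drawn masks are the more faithful route and
    can be passed to :func:`cell_areas` directly.
    """
    from scipy import ndimage as ndi
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.segmentation import watershed

    cls = classify_colors(img)
    tissue = cls.labels == LABEL_RED
    if not tissue.any():
        rgb = _to_float_rgb(img)
        redness = rgb[..., 0] - 0.5 * (rgb[..., 1] + rgb[..., 2])
        tissue = redness > threshold_otsu(redness)
    tissue = ndi.binary_fill_holes(tissue)
    dist = ndi.distance_transform_edt(tissue)
    if dist.max() <= 0:
        return np.zeros(tissue.shape, dtype=int)
    min_dist = max(3, int(0.25 * dist.max()))
    coords = peak_local_max(dist, min_distance=min_dist, labels=tissue)
    markers = np.zeros(tissue.shape, dtype=int)
    for i, c in enumerate(coords, start=1):
        markers[tuple(c)] = i
    return watershed(-dist, markers=markers, mask=tissue)


def cell_areas(img_or_masks: np.ndarray, scale_um_per_px: float,
               min_cells: int = MIN_CELLS_PER_IMAGE) -> AreaResult:
    """Per-cell cross-sectional areas in um^2.

    Accepts a labeled/boolean mask image (preferred: mirrors manual
    cell selection) or an RGB micrograph to segment automatically.
    Cells touching the image border are excluded.  ``meets_min_cells``
    flags whether the image satisfies the >= ``min_cells`` inclusion
    rule; the areas are reported either way.
    """
    from scipy import ndimage as ndi

    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    arr = np.asarray(img_or_masks)
    if arr.ndim == 3:
        labels = _segment_cells(arr)
    elif arr.dtype == bool:
        labels, _ = ndi.label(arr)
    else:
        labels = arr.astype(int)
    n = labels.max()
    areas = []
    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border])) - {0}
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue
        count = int(np.sum(labels == lab))
        if count > 0:
            areas.append(count * scale_um_per_px**2)
    if not areas:
        warnings.warn("no cells found", stacklevel=2)
    areas = np.asarray(areas, dtype=float)
    return AreaResult(
        areas_um2=areas,
        n_cells=areas.size,
        mean_area_um2=float(areas.mean()) if areas.size else None,
        median_area_um2=float(np.median(areas)) if areas.size else None,
        meets_min_cells=areas.size >= min_cells,
        scale_um_per_px=scale_um_per_px,
    )


def positive_pixel_fraction(img: np.ndarray,
                            positive_hue: tuple[float, float] = (10.0, 50.0),
                            saturation_min: float = 0.15,
                            tissue_value_max: float = 0.92,
                            ) -> float:
    """Fraction of tissue pixels positive for a chromogen (DAB brown).

    Tissue = pixels that are not white/luminal (value below
    ``tissue_value_max`` or saturated); positive = tissue pixels whose
    hue falls in ``positive_hue`` with saturation above the floor.
    """
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(_to_float_rgb(img))
    hue, sat, val = hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]
    tissue = (val < tissue_value_max) | (sat > saturation_min)
    if not tissue.any():
        warnings.warn("no tissue pixels found", stacklevel=2)
        return 0.0
    lo, hi = positive_hue
    positive = tissue & (sat > saturation_min) & (hue >= lo) & (hue <= hi)
    return float(positive.sum() / tissue.sum())


def mean_intensity(img: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean of in-mask pixel intensities (grayscale)."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if mask is None:
        return float(arr.mean())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape must match image")
    if not mask.any():
        raise ValueError("empty mask")
    return float(arr[mask].mean())
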
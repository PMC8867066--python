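"""Recover the 8 region masks from an RGB cross-section image.

The strategy works in CIE L*a*b*: the whole fruit is the largest
non-background component (holes filled); flavedo is the high-chroma ring
connected to the outer boundary; flesh is the remaining high-chroma
interior; seeds are dark compact components inside the flesh; albedo and
the central core are the bright low-saturation tissue split by radial
position; degradation cavities are near-white (very low chroma) pixels
inside the center disc or the albedo band.  Every threshold is exposed in
:class:`SegmentationConfig`.  Regions that cannot be detected come back as
all-zero masks — never as errors — so the downstream set-to-zero rule
applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.measure import label as cc_label
from skimage.morphology import disk

from citrusect._compat import despeckle, erode

from citrusect.regions import RegionMasks

__all__ = ["SegmentationConfig", "EmptySceneError", "segment", "find_whole", "find_locules"]


class EmptySceneError(ValueError):
    """Raised when no fruit-sized component is present in the image."""


@dataclass
class SegmentationConfig:
    background_luminance: float = 15.0   # L* below this is scanner background
    flavedo_chroma_a: float = 12.0       # a* above this (and bright) is orange tissue
    orange_min_luminance: float = 58.0   # splits seeds (dark) from flesh/flavedo
    albedo_luminance: tuple[float, float] = (55.0, 97.0)  # brightness band of pale tissue
    cavity_chroma: float = 8.0           # chroma below this among bright pixels is cavity
    cavity_luminance: float = 90.0
    center_max_radius_frac: float = 0.45  # pale tissue inside this radius is core
    min_component_size: int = 30
    morphological_radius: int = 1

    def __post_init__(self) -> None:
        if self.min_component_size < 0 or self.morphological_radius < 0:
            raise ValueError("sizes and radii must be >= 0")
        if not 0 <= self.background_luminance <= 100:
            raise ValueError("background_luminance outside L* range [0, 100]")


def find_whole(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Largest non-background connected component, holes filled.

    Internal cavities belong to the fruit, hence the hole fill.
    """
    config = config or SegmentationConfig()
    lab = rgb2lab(np.asarray(image, dtype=np.uint8))
    return _find_whole_lab(lab, config)


def _find_whole_lab(lab: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    fg = lab[..., 0] > config.background_luminance
    fg = despeckle(fg, max(config.min_component_size, 1))
    labels = cc_label(fg)
    if labels.max() == 0:
        raise EmptySceneError("no fruit found: image contains only background")
    sizes = np.bincount(labels.ravel())[1:]
    whole = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(whole)


def find_locules(
    flesh_mask: np.ndarray, centroid: tuple[float, float], min_size: int = 30
) -> tuple[np.ndarray, list[float]]:
    """Label flesh components and measure each locule's central angle.

    The central angle is the circular angular extent (degrees) of a
    component's pixels about ``centroid`` (row, col).  Robust to the locule
    that wraps across 0 deg: the extent is 360 minus the largest angular gap
    between member pixels.

    Returns (label image, list of angles ordered by label).
    """
    flesh_mask = np.asarray(flesh_mask, dtype=bool)
    if min_size > 0:
        flesh_mask = despeckle(flesh_mask, min_size)
    labels = cc_label(flesh_mask)
    n = labels.max()
    if n == 0:
        return labels, []
    cy, cx = centroid
    angles: list[float] = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(labels == i)
        theta = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
        theta = np.sort(theta)
        gaps = np.diff(theta)
        wrap = theta[0] + 360.0 - theta[-1]
        angles.append(float(360.0 - max(gaps.max(initial=0.0), wrap)))
    return labels, angles


def segment(image: np.ndarray, config: SegmentationConfig | None = None) -> RegionMasks:
    """Recover all 8 region masks; undetectable regions are all-zero masks."""
    config = config or SegmentationConfig()
    image = np.asarray(image, dtype=np.uint8)
    lab = rgb2lab(image)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    chroma = np.hypot(a, b)

    whole = _find_whole_lab(lab, config)
    ys, xs = np.nonzero(whole)
    cy, cx = float(ys.mean()), float(xs.mean())
    r_equiv = np.sqrt(whole.sum() / np.pi)
    yy, xx = np.mgrid[0 : whole.shape[0], 0 : whole.shape[1]]
    r_norm = np.hypot(yy - cy, xx - cx) / r_equiv

    minsz = max(config.min_component_size, 1)

    # near-white cavity/septum pixels
    white = whole & (L > config.cavity_luminance) & (chroma < config.cavity_chroma)

    # orange tissue: flavedo + flesh, split by connectivity to the rim
    orange = whole & ~white & (a > config.flavedo_chroma_a) & (L > config.orange_min_luminance)
    orange = despeckle(orange, minsz)
    rim = whole & ~erode(whole, disk(2 + config.morphological_radius))
    olab = cc_label(orange)
    touching = np.unique(olab[rim & orange])
    flavedo = np.isin(olab, touching[touching > 0])
    flesh = orange & ~flavedo
    flesh = despeckle(flesh, minsz)

    # dark compact components inside the fruit interior = seeds
    seed = whole & ~white & ~orange & (L <= config.orange_min_luminance) \
        & (L > config.background_luminance) & (r_norm < 1.0)
    seed = despeckle(seed, minsz)

    # pale tissue: albedo ring vs central core, split by radial position
    lo_l, hi_l = config.albedo_luminance
    pale = whole & ~white & ~orange & ~seed & (L >= lo_l) & (L <= hi_l)
    pale = despeckle(pale, minsz)
    center_core = pale & (r_norm <= config.center_max_radius_frac)
    albedo = pale & ~center_core

    # central cavity: white components fully inside the core radius
    degcenter = np.zeros_like(whole)
    if center_core.any():
        rc = float(r_norm[center_core].max())
    else:
        rc = config.center_max_radius_frac
    wlab = cc_label(white)
    for i in range(1, wlab.max() + 1):
        comp = wlab == i
        if r_norm[comp].max() <= rc + 0.02:
            degcenter |= comp

    # albedo degradation: white pixels within the albedo radial band
    degalbedo = np.zeros_like(whole)
    if albedo.any():
        inner = float(np.quantile(r_norm[albedo], 0.02))
        outer = float(np.quantile(r_norm[albedo], 0.98))
        degalbedo = white & (r_norm >= inner + 0.02) & (r_norm <= outer)
        degalbedo = despeckle(degalbedo, minsz)

    masks = RegionMasks(
        {
            "Whole": whole,
            "Flavedo": flavedo,
            "Albedo": albedo,
            "DegAlbedo": degalbedo,
            "Flesh": flesh,
            "Seed": seed,
            "Center": center_core,
            "DegCenter": degcenter,
        }
    )
    masks.validate()
    return masks
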
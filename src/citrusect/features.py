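"""The 21 morphological features of a fruit cross-section.

Area features are normalized by the whole-fruit area; albedo thickness by
the equivalent-circle radius.  Any region whose mask is empty contributes
zeros for all of its features (the set-to-zero rule), so a feature vector
always carries exactly 21 named values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.color import rgb2lab
from skimage.measure import find_contours, label as cc_label
from citrusect._compat import despeckle

from citrusect.regions import RegionMasks
from citrusect.segmentation import find_locules

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "circularity",
    "mean_lab",
    "albedo_thickness",
    "locule_statistics",
]

#: Canonical feature order (region by region, whole fruit first).
FEATURE_NAMES: tuple[str, ...] = (
    "Whole area",
    "Radius",
    "Circularity",
    "Locule number",
    "Locule angle",
    "Locule angleVar",
    "Flavedo area",
    "Flavedo Lab (L)",
    "Flavedo Lab (a)",
    "Flavedo Lab (b)",
    "Albedo area",
    "Albedo thickness",
    "DegAlbedo area",
    "Flesh area",
    "Flesh Lab (L)",
    "Flesh Lab (a)",
    "Flesh Lab (b)",
    "Seed area",
    "Seed number",
    "Center area",
    "DegCenter area",
)


def _boundary_perimeter(mask: np.ndarray, window: int = 5) -> float:
    """Boundary length from marching-squares contours with a short moving
    average along each contour.

    The smoothing removes the pixel staircase that inflates raw contour
    length (a raw pixel-edge count would bias circularity low on discs).
    """
    total = 0.0
    for c in find_contours(mask.astype(float), 0.5):
        k = min(window, max(len(c) // 10, 1))
        if k > 1:
            kern = np.ones(k) / k
            c = np.column_stack(
                [
                    np.convolve(
                        np.r_[c[-(k // 2):, i], c[:, i], c[: k // 2, i]],
                        kern,
                        mode="valid",
                    )
                    for i in (0, 1)
                ]
            )
        d = np.diff(np.vstack([c, c[:1]]), axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def circularity(mask: np.ndarray) -> float:
    """4*pi*Area / Perimeter**2, clipped to <= 1.05; empty mask -> 0."""
    mask = np.asarray(mask, dtype=bool)
    area = mask.sum()
    if area == 0:
        return 0.0
    per = _boundary_perimeter(mask)
    if per == 0:
        return 0.0
    return float(min(4.0 * np.pi * area / per**2, 1.05))


def mean_lab(image: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Mean CIE L*a*b* (sRGB, D65/2deg) over mask pixels; empty mask -> zeros."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return (0.0, 0.0, 0.0)
    lab = rgb2lab(np.asarray(image, dtype=np.uint8))
    vals = lab[mask]
    return tuple(float(v) for v in vals.mean(axis=0))


def albedo_thickness(
    mask: np.ndarray,
    centroid: tuple[float, float],
    radius: float,
    n_bins: int = 180,
) -> float:
    """Mean radial extent of the albedo annulus over angular bins / radius."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or radius <= 0:
        return 0.0
    ys, xs = np.nonzero(mask)
    cy, cx = centroid
    r = np.hypot(ys - cy, xs - cx)
    theta = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
    bins = np.minimum((theta / (360.0 / n_bins)).astype(int), n_bins - 1)
    extents = []
    for bi in range(n_bins):
        sel = bins == bi
        if sel.sum() < 2:
            continue
        # +1 px: pixel centers under-span the annulus by half a pixel each side
        extents.append(r[sel].max() - r[sel].min() + 1.0)
    if not extents:
        return 0.0
    return float(np.mean(extents) / radius)


def locule_statistics(angles: list[float] | np.ndarray) -> tuple[int, float, float]:
    """(count, mean, population variance) of per-locule central angles."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return 0, 0.0, 0.0
    return int(angles.size), float(angles.mean()), float(angles.var())


def extract_features(
    image: np.ndarray,
    masks: RegionMasks,
    *,
    min_component_size: int = 30,
    locule_angle_mode: str = "mean",
) -> pd.Series:
    """Compute the full 21-feature vector for one fruit.

    ``locule_angle_mode`` selects whether "Locule angle" reports the mean
    (default) or the total of per-locule central angles.
    """
    image = np.asarray(image)
    if image.shape[:2] != masks.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape[:2]} vs masks {masks.shape}"
        )
    if locule_angle_mode not in ("mean", "total"):
        raise ValueError(f"unknown locule_angle_mode {locule_angle_mode!r}")

    whole = masks["Whole"]
    whole_area = float(whole.sum())
    if whole_area == 0:
        return pd.Series(dict.fromkeys(FEATURE_NAMES, 0.0))[list(FEATURE_NAMES)]
    radius = float(np.sqrt(whole_area / np.pi))
    ys, xs = np.nonzero(whole)
    centroid = (float(ys.mean()), float(xs.mean()))

    _, angles = find_locules(masks["Flesh"], centroid, min_size=min_component_size)
    n_loc, ang_mean, ang_var = locule_statistics(angles)
    if locule_angle_mode == "total":
        ang_mean = float(np.sum(angles))

    seed_mask = despeckle(masks["Seed"], max(min_component_size, 1))
    n_seed = int(cc_label(seed_mask).max())

    def frac(region: str) -> float:
        return float(masks[region].sum() / whole_area)

    fl = mean_lab(image, masks["Flavedo"])
    fs = mean_lab(image, masks["Flesh"])
    values = {
        "Whole area": whole_area / float(image.shape[0] * image.shape[1]),
        "Radius": radius,
        "Circularity": circularity(whole),
        "Locule number": float(n_loc),
        "Locule angle": ang_mean,
        "Locule angleVar": ang_var,
        "Flavedo area": frac("Flavedo"),
        "Flavedo Lab (L)": fl[0],
        "Flavedo Lab (a)": fl[1],
        "Flavedo Lab (b)": fl[2],
        "Albedo area": frac("Albedo"),
        "Albedo thickness": albedo_thickness(masks["Albedo"], centroid, radius),
        "DegAlbedo area": frac("DegAlbedo"),
        "Flesh area": frac("Flesh"),
        "Flesh Lab (L)": fs[0],
        "Flesh Lab (a)": fs[1],
        "Flesh Lab (b)": fs[2],
        "Seed area": frac("Seed"),
        "Seed number": float(n_seed),
        "Center area": frac("Center"),
        "DegCenter area": frac("DegCenter"),
    }
    return pd.Series(values)[list(FEATURE_NAMES)]
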
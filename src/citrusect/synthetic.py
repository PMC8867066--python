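"""Synthetic citrus cross-section generator.

Produces rasterized fruit images with exact ground-truth region masks, a
population of genotypes observed over years, and ordinal/binary trait
scores driven by the ground-truth morphology — the statistical structure
the downstream analyses assume (genotype effects, year effects,
degradation-driven traits).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from citrusect.regions import REGION_NAMES, RegionMasks

__all__ = [
    "FruitSpec",
    "TraitModel",
    "PopulationDataset",
    "default_palette",
    "default_spec_prior",
    "default_trait_models",
    "render_fruit",
    "ground_truth_features",
    "sample_population",
    "generate_traits",
]


def default_palette() -> dict[str, tuple[int, int, int]]:
    """Region colors: scanner-like near-black background, near-white
    septa/cavities so degradation is detectable as bright low-chroma pixels."""
    return {
        "background": (8, 8, 10),
        "flavedo": (235, 140, 25),
        "albedo": (238, 226, 188),
        "flesh": (247, 166, 60),
        "seed": (138, 95, 48),
        "center": (242, 231, 198),
        "cavity": (252, 252, 250),
    }


@dataclass
class FruitSpec:
    """Parametric geometry of one synthetic fruit cross-section.

    Thickness/radius fields are fractions of the fruit radius; degradation
    fields are target areas as fractions of the whole cross-section area.
    """

    image_size: int = 256
    fruit_radius: float = 0.88          # fraction of half-image
    flavedo_thickness: float = 0.08     # fraction of fruit radius
    albedo_thickness: float = 0.12
    locule_count: int = 9
    septum_angle: float = 4.0           # degrees per septum
    seed_count: int = 6
    seed_axes: tuple[float, float] = (10.0, 6.0)   # half-axes, pixels
    center_radius: float = 0.18         # fraction of fruit radius
    degcenter_frac: float = 0.02        # target DegCenter area / whole area
    degalbedo_frac: float = 0.01        # target DegAlbedo area / whole area
    palette: dict[str, tuple[int, int, int]] = field(default_factory=default_palette)
    boundary_jitter: float = 0.01       # relative amplitude of ring perturbation
    ellipticity: float = 0.96           # minor/major axis ratio
    sector_weights: tuple[float, ...] | None = None  # relative locule angles

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry -------------------------------------------------
    @property
    def flesh_outer(self) -> float:
        """Inner radius of the albedo ring = outer radius of the flesh band."""
        return 1.0 - self.flavedo_thickness - self.albedo_thickness

    @property
    def albedo_band_frac(self) -> float:
        """Area of the full albedo annulus as a fraction of the whole."""
        return (1.0 - self.flavedo_thickness) ** 2 - self.flesh_outer**2

    def validate(self) -> None:
        if self.flavedo_thickness + self.albedo_thickness + self.center_radius >= 1.0:
            raise ValueError(
                "infeasible geometry: flavedo_thickness + albedo_thickness + "
                "center_radius must be < 1 (rings overlap)"
            )
        for name in (
            "fruit_radius",
            "flavedo_thickness",
            "albedo_thickness",
            "center_radius",
            "degcenter_frac",
            "degalbedo_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invariant violated: {name}={v} outside [0, 1]")
        if self.locule_count < 1:
            raise ValueError("invariant violated: locule_count must be >= 1")
        if self.degcenter_frac > self.center_radius**2 + 1e-12:
            raise ValueError(
                "invariant violated: degcenter_frac exceeds the center-disc "
                f"capacity center_radius**2 = {self.center_radius ** 2:.4f}"
            )
        if self.degalbedo_frac > self.albedo_band_frac + 1e-12:
            raise ValueError(
                "invariant violated: degalbedo_frac exceeds the albedo-ring "
                f"capacity {self.albedo_band_frac:.4f}"
            )
        if self.septum_angle * self.locule_count >= 360.0:
            raise ValueError("invariant violated: septa consume the full circle")
        if not 0.0 < self.ellipticity <= 1.0:
            raise ValueError("invariant violated: ellipticity must be in (0, 1]")
        if self.sector_weights is not None and len(self.sector_weights) != self.locule_count:
            raise ValueError("sector_weights length must equal locule_count")

    def replace(self, **kwargs) -> "FruitSpec":
        return dataclasses.replace(self, **kwargs)

    def sector_angles(self) -> np.ndarray:
        """Angular extent of each flesh sector (locule), degrees."""
        free = 360.0 - self.locule_count * self.septum_angle
        if self.sector_weights is None:
            return np.full(self.locule_count, free / self.locule_count)
        w = np.asarray(self.sector_weights, dtype=float)
        return free * w / w.sum()


# ---------------------------------------------------------------------------
# rendering


def _angdiff(a: np.ndarray, b: float) -> np.ndarray:
    """Absolute angular difference in degrees on the circle."""
    d = np.abs((a - b + 180.0) % 360.0 - 180.0)
    return d


def render_fruit(
    spec: FruitSpec, rng: np.random.Generator
) -> tuple[np.ndarray, RegionMasks]:
    """Rasterize one fruit; returns (H, W, 3) uint8 image and exact masks.

    The pixel partition is exact: Whole is the disjoint union of the seven
    sub-regions plus the septum pixels (rendered in the cavity color).
    """
    spec.validate()
    S = spec.image_size
    cx = cy = (S - 1) / 2.0
    Rx = spec.fruit_radius * S / 2.0
    Ry = Rx * spec.ellipticity

    yy, xx = np.mgrid[0:S, 0:S]
    X = (xx - cx) / Rx
    Y = (yy - cy) / Ry
    u = np.hypot(X, Y)
    theta = np.degrees(np.arctan2(Y, X)) % 360.0

    # low-order sinusoidal boundary perturbation, |j| <= 1
    coefs = rng.uniform(-1.0, 1.0, size=4)  # cos2, sin2, cos3, sin3
    norm = np.sum(np.abs(coefs)) or 1.0
    th = np.radians(theta)
    j = (
        coefs[0] * np.cos(2 * th)
        + coefs[1] * np.sin(2 * th)
        + coefs[2] * np.cos(3 * th)
        + coefs[3] * np.sin(3 * th)
    ) / norm
    t = u / (1.0 + spec.boundary_jitter * j)

    tf, ta, cr = spec.flavedo_thickness, spec.albedo_thickness, spec.center_radius
    whole = t <= 1.0
    flavedo = whole & (t > 1.0 - tf)
    albedo_band = whole & (t <= 1.0 - tf) & (t > spec.flesh_outer)
    flesh_band = whole & (t <= spec.flesh_outer) & (t > cr)
    center_disc = t <= cr

    # albedo degradation: contiguous angular wedge of the albedo ring
    if spec.degalbedo_frac > 0 and spec.albedo_band_frac > 0:
        gap_deg = 360.0 * spec.degalbedo_frac / spec.albedo_band_frac
        gap_start = rng.uniform(0.0, 360.0)
        degalbedo = albedo_band & ((theta - gap_start) % 360.0 <= gap_deg)
    else:
        degalbedo = np.zeros_like(whole)
    albedo = albedo_band & ~degalbedo

    # central cavity: disc in normalized coordinates, area frac = tau**2
    tau = float(np.sqrt(spec.degcenter_frac))
    degcenter = t <= tau if spec.degcenter_frac > 0 else np.zeros_like(whole)
    center = center_disc & ~degcenter

    # septa: angular wedges between flesh sectors
    sector = spec.sector_angles()
    offset = rng.uniform(0.0, 360.0)
    boundaries = offset + np.concatenate(
        [[0.0], np.cumsum(sector + spec.septum_angle)]
    )[: spec.locule_count]
    # widen septa to >= ~2 px of arc near the center so rasterized locules
    # never touch around the inner flesh radius
    rpx = np.hypot(xx - cx, yy - cy)
    min_half_deg = np.degrees(1.0 / np.maximum(rpx, 1.0))
    half_width = np.maximum(spec.septum_angle / 2.0, min_half_deg)
    in_septum = np.zeros_like(whole)
    for b in boundaries:
        in_septum |= _angdiff(theta, float(b)) <= half_width
    septa = flesh_band & in_septum
    flesh = flesh_band & ~septa

    # seeds: ellipses inside locules, rejection-sampled against overlap
    seed_mask = np.zeros_like(whole)
    sector_centers = (boundaries + spec.septum_angle / 2.0 + sector / 2.0) % 360.0
    n_placed = 0
    if spec.seed_count > 0:
        order = rng.permutation(spec.locule_count)
        slots = [sector_centers[order[i % spec.locule_count]] for i in range(spec.seed_count)]
        a_px, b_px = spec.seed_axes
        mid_t = (cr + spec.flesh_outer) / 2.0
        for ang in slots:
            placed = False
            for _ in range(25):
                tt = mid_t + rng.uniform(-0.08, 0.08)
                aa = ang + rng.uniform(-4.0, 4.0)
                px = cx + tt * Rx * np.cos(np.radians(aa))
                py = cy + tt * Ry * np.sin(np.radians(aa))
                phi = np.radians(aa)  # major axis along the radial direction
                dx, dy = xx - px, yy - py
                xr = dx * np.cos(phi) + dy * np.sin(phi)
                yr = -dx * np.sin(phi) + dy * np.cos(phi)
                ell = (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0
                if not ell.any():
                    continue
                if np.all(flesh[ell] & ~seed_mask[ell]):
                    seed_mask |= ell
                    n_placed += 1
                    placed = True
                    break
            if not placed:
                continue
    flesh = flesh & ~seed_mask

    masks = RegionMasks(
        {
            "Whole": whole,
            "Flavedo": flavedo,
            "Albedo": albedo,
            "DegAlbedo": degalbedo,
            "Flesh": flesh,
            "Seed": seed_mask,
            "Center": center,
            "DegCenter": degcenter,
        }
    )

    pal = spec.palette
    image = np.empty((S, S, 3), dtype=np.uint8)
    image[:] = pal["background"]
    image[flavedo] = pal["flavedo"]
    image[albedo] = pal["albedo"]
    image[flesh] = pal["flesh"]
    image[center] = pal["center"]
    image[septa] = pal["cavity"]
    image[degalbedo] = pal["cavity"]
    image[degcenter] = pal["cavity"]
    image[seed_mask] = pal["seed"]
    return image, masks


# ---------------------------------------------------------------------------
# analytic ground truth


def _lab_of(rgb: tuple[int, int, int]) -> tuple[float, float, float]:
    from skimage.color import rgb2lab

    arr = np.asarray(rgb, dtype=np.float64).reshape(1, 1, 3) / 255.0
    L, a, b = rgb2lab(arr)[0, 0]
    return float(L), float(a), float(b)


def _ellipse_circularity(ratio: float) -> float:
    """4*pi*A/P**2 for an ellipse of axis ratio b/a, Ramanujan perimeter."""
    a, b = 1.0, ratio
    h = ((a - b) / (a + b)) ** 2
    per = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    return float(4 * np.pi * (np.pi * a * b) / per**2)


def ground_truth_features(spec: FruitSpec, seed_count: int | None = None) -> dict[str, float]:
    """The 21 morphological features implied by a spec, computed analytically.

    Area features are fractions of the whole cross-section area (Whole area
    itself is the fraction of the image covered); thickness is a fraction of
    the equivalent-circle radius, mirroring the extractor's normalization.
    """
    n_seed = spec.seed_count if seed_count is None else seed_count
    Rx = spec.fruit_radius * spec.image_size / 2.0
    Ry = Rx * spec.ellipticity
    whole_px = np.pi * Rx * Ry
    sector = spec.sector_angles()
    septa_angular = spec.locule_count * spec.septum_angle / 360.0
    flesh_band = spec.flesh_outer**2 - spec.center_radius**2
    seed_frac = n_seed * np.pi * spec.seed_axes[0] * spec.seed_axes[1] / whole_px
    fl, fa, fb = _lab_of(spec.palette["flavedo"])
    sl, sa, sb = _lab_of(spec.palette["flesh"])
    return {
        "Whole area": whole_px / spec.image_size**2,
        "Radius": float(np.sqrt(Rx * Ry)),
        "Circularity": _ellipse_circularity(spec.ellipticity),
        "Locule number": float(spec.locule_count),
        "Locule angle": float(sector.mean()),
        "Locule angleVar": float(sector.var()),
        "Flavedo area": 1.0 - (1.0 - spec.flavedo_thickness) ** 2,
        "Flavedo Lab (L)": fl,
        "Flavedo Lab (a)": fa,
        "Flavedo Lab (b)": fb,
        "Albedo area": spec.albedo_band_frac - spec.degalbedo_frac,
        "Albedo thickness": spec.albedo_thickness,
        "DegAlbedo area": spec.degalbedo_frac,
        "Flesh area": flesh_band * (1.0 - septa_angular) - seed_frac,
        "Flesh Lab (L)": sl,
        "Flesh Lab (a)": sa,
        "Flesh Lab (b)": sb,
        "Seed area": seed_frac,
        "Seed number": float(n_seed),
        "Center area": spec.center_radius**2 - spec.degcenter_frac,
        "DegCenter area": spec.degcenter_frac,
    }


# ---------------------------------------------------------------------------
# population sampling


def default_spec_prior() -> dict[str, tuple[float, float]]:
    """Uniform ranges for the genotype-level latent spec fields."""
    return {
        "fruit_radius": (0.70, 0.94),
        "flavedo_thickness": (0.05, 0.12),
        "albedo_thickness": (0.06, 0.18),
        "locule_count": (8, 11),
        "septum_angle": (2.5, 5.0),
        "seed_count": (0, 8),
        "center_radius": (0.13, 0.22),
        "degcenter_frac": (0.0, 0.028),
        "degalbedo_frac": (0.0, 0.018),
        "boundary_jitter": (0.0, 0.02),
        "ellipticity": (0.90, 1.0),
    }


_INT_FIELDS = {"locule_count", "seed_count"}


@dataclass
class PopulationDataset:
    """Everything one simulated harvest produces."""

    table: pd.DataFrame                     # fruit_id, genotype, year + 21 features
    specs: list[FruitSpec]
    images: list[np.ndarray] | None = None  # None when render=False
    masks: list[RegionMasks] | None = None


def _clip_spec_fields(values: dict[str, float]) -> dict[str, float]:
    v = dict(values)
    v["fruit_radius"] = float(np.clip(v["fruit_radius"], 0.4, 0.98))
    v["flavedo_thickness"] = float(np.clip(v["flavedo_thickness"], 0.02, 0.2))
    v["albedo_thickness"] = float(np.clip(v["albedo_thickness"], 0.02, 0.3))
    v["center_radius"] = float(np.clip(v["center_radius"], 0.08, 0.3))
    v["degcenter_frac"] = float(np.clip(v["degcenter_frac"], 0.0, 0.95 * v["center_radius"] ** 2))
    v["ellipticity"] = float(np.clip(v["ellipticity"], 0.8, 1.0))
    v["boundary_jitter"] = float(np.clip(v["boundary_jitter"], 0.0, 0.05))
    v["septum_angle"] = float(np.clip(v["septum_angle"], 1.0, 8.0))
    for k in _INT_FIELDS:
        v[k] = int(np.clip(round(v[k]), 0 if k == "seed_count" else 1, 14))
    # albedo degradation capacity depends on the two peel thicknesses
    cap = (1 - v["flavedo_thickness"]) ** 2 - (
        1 - v["flavedo_thickness"] - v["albedo_thickness"]
    ) ** 2
    v["degalbedo_frac"] = float(np.clip(v["degalbedo_frac"], 0.0, 0.95 * cap))
    return v


def sample_population(
    n_genotypes: int,
    n_years: int,
    fruits_per_genotype_year: int,
    spec_prior: dict[str, tuple[float, float]] | None = None,
    rng: np.random.Generator | None = None,
    *,
    image_size: int = 256,
    jitter: float = 0.04,
    color_latent_scale: float = 12.0,
    year_effects: dict[str, float] | None = None,
    render: bool = True,
) -> PopulationDataset:
    """Simulate a harvest: genotypes x years x fruits.

    Each genotype has a latent :class:`FruitSpec`; individual fruits jitter
    around it (relative s.d. ``jitter``); years shift the degradation
    fractions and the fruit radius so a removable year effect exists.  A
    genotype-level color latent, coupled to the degradation latent, shifts
    the flavedo/flesh palette — giving color features an apparent but
    indirect association with the traits.

    With ``render=False`` only the analytic ground-truth feature table is
    produced (fast path for statistical simulations).
    """
    if n_genotypes < 1 or n_years < 1 or fruits_per_genotype_year < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(rng)
    prior = default_spec_prior() if spec_prior is None else dict(spec_prior)
    base = FruitSpec(image_size=image_size)
    for name, (lo, hi) in prior.items():
        if lo > hi:
            raise ValueError(f"prior range for {name} inverted: ({lo}, {hi})")
    if year_effects is None:
        year_effects = {"degcenter_frac": 0.006, "degalbedo_frac": 0.003, "fruit_radius": 0.03}
    year_index = np.arange(n_years) - (n_years - 1) / 2.0

    rows = []
    specs: list[FruitSpec] = []
    images: list[np.ndarray] = []
    all_masks: list[RegionMasks] = []
    fruit_id = 0
    for g in range(n_genotypes):
        latent = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in prior.items()}
        latent = _clip_spec_fields(latent)
        # color latent shared with degradation: drives flavedo/flesh palette
        lo_d, hi_d = prior.get("degcenter_frac", (0.0, 0.03))
        span = (hi_d - lo_d) or 1.0
        m = (latent["degcenter_frac"] - lo_d) / span - 0.5 + rng.normal(0.0, 0.25)
        pal = default_palette()
        shift = int(round(color_latent_scale * m))
        pal["flavedo"] = tuple(int(np.clip(c + d, 0, 255)) for c, d in
                               zip(pal["flavedo"], (shift, -shift, 0)))
        pal["flesh"] = tuple(int(np.clip(c + d, 0, 255)) for c, d in
                             zip(pal["flesh"], (shift // 2, -shift, 0)))
        for y in range(n_years):
            for _ in range(fruits_per_genotype_year):
                v = dict(latent)
                for k in v:
                    if k in _INT_FIELDS:
                        continue
                    v[k] = v[k] * (1.0 + rng.normal(0.0, jitter)) if jitter > 0 else v[k]
                for k, eff in year_effects.items():
                    v[k] = v.get(k, getattr(base, k)) + eff * year_index[y]
                v = _clip_spec_fields(v)
                spec = base.replace(palette=pal, **v)
                placed = spec.seed_count
                if render:
                    img, masks = render_fruit(spec, rng)
                    placed = int(round(masks.area("Seed") /
                                       max(np.pi * spec.seed_axes[0] * spec.seed_axes[1], 1.0)))
                    images.append(img)
                    all_masks.append(masks)
                feats = ground_truth_features(spec, seed_count=placed)
                rows.append({"fruit_id": f"F{fruit_id:05d}", "genotype": f"G{g:03d}",
                             "year": int(y), **feats})
                specs.append(spec)
                fruit_id += 1
    table = pd.DataFrame(rows)
    return PopulationDataset(
        table=table,
        specs=specs,
        images=images if render else None,
        masks=all_masks if render else None,
    )


def cavity_classification_dataset(
    n_per_class: int,
    rng: np.random.Generator | None = None,
    image_size: int = 128,
    cavity_frac: tuple[float, float] = (0.050, 0.078),
    null_cavity_frac: tuple[float, float] = (0.004, 0.010),
) -> tuple[list[np.ndarray], np.ndarray, list[RegionMasks]]:
    """Two-class image set differing only by a large central cavity.

    Class 1 fruits carry a DegCenter cavity with area fraction drawn from
    ``cavity_frac``; class 0 fruits carry only a sliver (so both classes
    have a nonempty DegCenter region for relevance comparison).  All other
    geometry jitters identically across classes.  The central core uses a
    darker beige than the near-white cavity so the contrast survives
    downsampling to the classifier's input resolution.  Returns (images,
    labels, masks).
    """
    rng = np.random.default_rng(rng)
    images, labels, masks_list = [], [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            frac = float(rng.uniform(*(cavity_frac if cls == 1 else null_cavity_frac)))
            pal = default_palette()
            pal["center"] = (228, 205, 160)
            spec = FruitSpec(
                image_size=image_size,
                fruit_radius=float(rng.uniform(0.82, 0.92)),
                flavedo_thickness=float(rng.uniform(0.06, 0.10)),
                albedo_thickness=float(rng.uniform(0.09, 0.15)),
                locule_count=int(rng.integers(8, 12)),
                septum_angle=float(rng.uniform(3.0, 5.0)),
                seed_count=int(rng.integers(0, 7)),
                seed_axes=(0.04 * image_size, 0.024 * image_size),
                center_radius=float(rng.uniform(0.28, 0.32)),
                degcenter_frac=frac,
                palette=pal,
                degalbedo_frac=float(rng.uniform(0.0, 0.012)),
                boundary_jitter=float(rng.uniform(0.0, 0.02)),
                ellipticity=float(rng.uniform(0.92, 1.0)),
            )
            img, masks = render_fruit(spec, rng)
            images.append(img)
            labels.append(cls)
            masks_list.append(masks)
    return images, np.asarray(labels), masks_list


# ---------------------------------------------------------------------------
# trait generation


@dataclass
class TraitModel:
    """Linear model mapping ground-truth features to one sensory trait score.

    continuous = intercept + sum(coef * feature) + genotype + year + noise;
    the ordinal category is the continuous score cut at ``cutpoints``; the
    binary class splits at the population median (``binary_rule='median'``)
    or drops the middle band (``binary_rule='tails'``).
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    genotype_sd: float = 0.25
    year_effects: tuple[float, ...] | None = None   # one value per year index
    residual_sd: float = 0.25
    cutpoints: tuple[float, float, float, float] = (1.8, 2.4, 3.0, 3.6)
    binary_rule: str = "median"
    tail_quantiles: tuple[float, float] = (0.4, 0.6)
    class_labels: tuple[str, str] = ("easy", "difficult")

    def __post_init__(self) -> None:
        if len(self.cutpoints) != 4 or np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be 4 strictly increasing values")
        if self.residual_sd < 0 or self.genotype_sd < 0:
            raise ValueError("effect s.d. values must be >= 0")
        if self.binary_rule not in ("median", "tails"):
            raise ValueError(f"unknown binary_rule {self.binary_rule!r}")


def default_trait_models() -> list[TraitModel]:
    """Peeling driven down by degradation, up by size; FruH driven down by
    central degradation, up by seeds, peel and size (high score = difficult
    to peel / hard fruit)."""
    return [
        TraitModel(
            name="Peeling",
            intercept=1.2,
            coefficients={"DegCenter area": -35.0, "DegAlbedo area": -25.0, "Whole area": 3.0},
            class_labels=("easy", "difficult"),
        ),
        TraitModel(
            name="FruH",
            intercept=0.8,
            coefficients={"DegCenter area": -35.0, "Seed area": 18.0,
                          "Flavedo area": 5.0, "Whole area": 3.0},
            class_labels=("soft", "hard"),
        ),
    ]


def generate_traits(
    truth: pd.DataFrame,
    models: list[TraitModel] | TraitModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Score each fruit under each trait model.

    ``truth`` must carry ``genotype`` and ``year`` columns plus every feature
    named by a nonzero model coefficient.  Returns a long table with columns
    (fruit_id, genotype, year, trait, continuous, ordinal, binary,
    binary_label).
    """
    if models is None:
        models = default_trait_models()
    if isinstance(models, TraitModel):
        models = [models]
    rng = np.random.default_rng(rng)
    for col in ("genotype", "year"):
        if col not in truth.columns:
            raise KeyError(f"truth table lacks required column {col!r}")

    out = []
    genotypes = truth["genotype"].unique()
    years = np.sort(truth["year"].unique())
    for model in models:
        missing = [f for f, c in model.coefficients.items() if c != 0 and f not in truth.columns]
        if missing:
            raise KeyError(f"truth table lacks feature columns {missing} "
                           f"required by trait {model.name!r}")
        g_eff = dict(zip(genotypes, rng.normal(0.0, model.genotype_sd, len(genotypes))))
        if model.year_effects is not None:
            if len(model.year_effects) < len(years):
                raise ValueError("year_effects shorter than the number of years")
            y_eff = {y: model.year_effects[i] for i, y in enumerate(years)}
        else:
            y_eff = {y: 0.15 * (i - (len(years) - 1) / 2.0) for i, y in enumerate(years)}
        lin = np.full(len(truth), model.intercept)
        for f, c in model.coefficients.items():
            lin = lin + c * truth[f].to_numpy(dtype=float)
        cont = (
            lin
            + truth["genotype"].map(g_eff).to_numpy(dtype=float)
            + truth["year"].map(y_eff).to_numpy(dtype=float)
            + rng.normal(0.0, model.residual_sd, len(truth))
        )
        ordinal = 1 + np.searchsorted(np.asarray(model.cutpoints), cont)
        if model.binary_rule == "median":
            thr = np.median(cont)
            binary = (cont >= thr).astype(int)
            keep = np.ones(len(cont), dtype=bool)
        else:
            lo, hi = np.quantile(cont, model.tail_quantiles)
            binary = (cont >= hi).astype(int)
            keep = (cont < lo) | (cont >= hi)
        df = pd.DataFrame(
            {
                "fruit_id": truth.get("fruit_id", pd.RangeIndex(len(truth)).astype(str)),
                "genotype": truth["genotype"],
                "year": truth["year"],
                "trait": model.name,
                "continuous": cont,
                "ordinal": ordinal.astype(int),
                "binary": binary,
                "binary_label": [model.class_labels[b] for b in binary],
            }
        )
        out.append(df[keep] if model.binary_rule == "tails" else df)
    return pd.concat(out, ignore_index=True)
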
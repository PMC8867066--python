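"""Region mask container shared by the generator, the segmenter and the
feature extractor."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical region order.  Index i+1 is the label of region i in label images.
REGION_NAMES: tuple[str, ...] = (
    "Whole",
    "Flavedo",
    "Albedo",
    "DegAlbedo",
    "Flesh",
    "Seed",
    "Center",
    "DegCenter",
)

#: Regions that must be mutually disjoint and contained in Whole.
DISJOINT_REGIONS: tuple[str, ...] = ("Flavedo", "Albedo", "Flesh", "Seed", "Center")


@dataclass
class RegionMasks:
    """One boolean mask per region, all the same shape.

    A region that is absent from the fruit is an all-zero mask, never a
    missing entry.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in REGION_NAMES if r not in self.masks]
        if missing:
            raise ValueError(f"missing region masks: {missing}")
        shapes = {self.masks[r].shape for r in REGION_NAMES}
        if len(shapes) != 1:
            raise ValueError(f"region masks have inconsistent shapes: {shapes}")
        for r in REGION_NAMES:
            self.masks[r] = np.asarray(self.masks[r], dtype=bool)

    def __getitem__(self, region: str) -> np.ndarray:
        return self.masks[region]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks["Whole"].shape

    def area(self, region: str) -> int:
        return int(self.masks[region].sum())

    def validate(self) -> None:
        """Assert containment and pairwise disjointness invariants."""
        whole = self.masks["Whole"]
        for r in DISJOINT_REGIONS:
            if np.any(self.masks[r] & ~whole):
                raise ValueError(f"region {r} not contained in Whole")
        for i, a in enumerate(DISJOINT_REGIONS):
            for b in DISJOINT_REGIONS[i + 1 :]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"regions {a} and {b} overlap")
        for r in ("DegAlbedo", "DegCenter"):
            if np.any(self.masks[r] & ~whole):
                raise ValueError(f"region {r} not contained in Whole")

    def to_label_image(self) -> np.ndarray:
        """Encode as a single uint8 label image, 0 = background, 1..8 = regions.

        Later regions in :data:`REGION_NAMES` overwrite earlier ones wherever
        masks overlap (only Whole overlaps the others by construction).
        """
        labels = np.zeros(self.shape, dtype=np.uint8)
        for i, r in enumerate(REGION_NAMES):
            labels[self.masks[r]] = i + 1
        return labels

    @classmethod
    def from_label_image(cls, labels: np.ndarray) -> "RegionMasks":
        labels = np.asarray(labels)
        masks = {r: labels == i + 1 for i, r in enumerate(REGION_NAMES)}
        # every labelled pixel belongs to the whole fruit
        masks["Whole"] = labels > 0
        return cls(masks)
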
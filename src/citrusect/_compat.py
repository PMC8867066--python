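"""Version bridges for scikit-image API churn."""

from __future__ import annotations

import numpy as np
from skimage import morphology as _morph

# remove_small_objects renamed its threshold parameter (min_size -> max_size)
try:
    _morph.remove_small_objects(np.zeros((2, 2), dtype=bool), max_size=1)
    _SIZE_KW = "max_size"
except TypeError:  # pragma: no cover - older scikit-image
    _SIZE_KW = "min_size"


def despeckle(mask: np.ndarray, size: int) -> np.ndarray:
    """Drop connected components smaller than ``size`` pixels."""
    if size <= 0:
        return mask
    return _morph.remove_small_objects(mask, **{_SIZE_KW: size})


def erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    fn = getattr(_morph, "erosion", None) or _morph.binary_erosion
    return fn(mask, footprint).astype(bool)
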
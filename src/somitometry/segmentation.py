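"""Binary body-mask extraction from bright-field / nuclear-stain images.

The recipe: resample to an isotropic working resolution (1 µm/px), threshold
with a global histogram method (Otsu, triangle or Yen — picked automatically
or by the user), then clean the mask by filling small holes, discarding small
debris and smoothing with a morphological opening.  All cleaning thresholds
are pixel-denominated at the 1 µm/px working resolution.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .grids import ImageGrid, LabeledMask

__all__ = [
    "resample_isotropic",
    "binarize",
    "select_threshold_method",
    "clean_mask",
    "THRESHOLD_METHODS",
]

THRESHOLD_METHODS = {
    "otsu": filters.threshold_otsu,
    "triangle": filters.threshold_triangle,
    "yen": filters.threshold_yen,
}

#: Method used when the histogram is degenerate and no comparison is possible.
DEFAULT_METHOD = "otsu"


def resample_isotropic(image: ImageGrid, target_px: float = 1.0) -> ImageGrid:
    """Resample a 2-D image to an isotropic pixel size (linear interpolation).

    Returns the input unchanged (same lattice) when it is already at
    ``target_px`` on both axes.
    """
    if image.data.ndim != 2 or image.channel_names is not None:
        raise ValueError("resample_isotropic expects a 2-D single-channel image")
    if target_px <= 0:
        raise ValueError("target_px must be positive")
    dy, dx = image.pixel_size
    if dy == target_px and dx == target_px:
        return ImageGrid(image.data, (target_px, target_px))
    zoom = (dy / target_px, dx / target_px)
    out = ndimage.zoom(image.data.astype(float), zoom, order=1, grid_mode=True,
                       mode="nearest")
    return ImageGrid(out, (target_px, target_px),
                     frame_interval=image.frame_interval)


def binarize(image: ImageGrid, method: str = "otsu") -> LabeledMask:
    """Threshold a single-channel image with a global histogram method.

    Foreground is *strictly above* the threshold; ties at the threshold go to
    background.  A constant image yields an empty mask flagged ``degenerate``
    rather than an exception.
    """
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from "
                         f"{sorted(THRESHOLD_METHODS)}")
    data = image.data
    if image.channel_names is not None:
        raise ValueError("binarize expects a single-channel image")
    prov = {"method": method}
    if np.ptp(data) == 0:
        warnings.warn("constant image: binarization is degenerate", stacklevel=2)
        prov.update(degenerate=True, threshold=float(data.flat[0]))
        return LabeledMask(np.zeros_like(data, dtype=bool), image.pixel_size, prov)
    thr = float(THRESHOLD_METHODS[method](data))
    prov["threshold"] = thr
    return LabeledMask(data > thr, image.pixel_size, prov)


def _boundary_area_ratio(mask: np.ndarray) -> float:
    """Boundary length / area of a mask; inf for an empty mask."""
    area = int(mask.sum())
    if area == 0:
        return np.inf
    eroded = ndimage.binary_erosion(mask)
    boundary = int(mask.sum() - eroded.sum())
    return boundary / area


def select_threshold_method(image: ImageGrid) -> tuple[str, dict]:
    """Recommend a threshold method for this image.

    Each candidate (otsu, triangle, yen) is applied and the method whose mask
    has the smallest boundary-length-to-area ratio — i.e. the most compact
    foreground, least fragmented by histogram misfit — wins.  Deterministic
    given the image; the choice is a recommendation and any method can be
    forced in :func:`binarize`.

    Returns ``(method, info)`` where ``info`` holds the per-method ratios and
    a ``degenerate`` flag for constant images.
    """
    if np.ptp(image.data) == 0:
        return DEFAULT_METHOD, {"degenerate": True, "ratios": {}}
    ratios: dict[str, float] = {}
    for name in sorted(THRESHOLD_METHODS):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = binarize(image, name)
        ratios[name] = _boundary_area_ratio(m.mask)
    best = min(ratios, key=lambda k: (ratios[k], k))
    return best, {"degenerate": False, "ratios": ratios}


def clean_mask(mask: LabeledMask, min_size: int = 10000,
               opening_radius: int = 5) -> LabeledMask:
    """Clean a binary body mask.

    Steps, in fixed order: fill holes smaller than ``min_size`` pixels, remove
    foreground components smaller than ``min_size`` pixels, then smooth with a
    morphological opening using a disk of ``opening_radius`` pixels.  The
    opening can split a component into fragments below ``min_size``; those are
    removed in a final pass so the operation is idempotent.

    ``min_size`` and ``opening_radius`` are pixel-denominated and assume the
    1 µm/px working resolution; a warning is raised for other pixel sizes.
    """
    if mask.mask.ndim != 2:
        raise ValueError("clean_mask expects a 2-D mask")
    if any(abs(p - 1.0) > 1e-6 for p in mask.pixel_size):
        warnings.warn(
            f"clean_mask thresholds are pixel-denominated for 1 µm/px; mask is "
            f"at {mask.pixel_size} µm/px", stacklevel=2)
    m = mask.mask
    if m.any():
        # "smaller than min_size" semantics: remove/fill strictly below
        m = morphology.remove_small_holes(m, max_size=min_size - 1)
        m = morphology.remove_small_objects(m, max_size=min_size - 1)
        if opening_radius > 0:
            m = morphology.opening(m, morphology.disk(opening_radius))
        m = morphology.remove_small_objects(m, max_size=min_size - 1)
    prov = dict(mask.provenance)
    prov["clean"] = {"min_size": min_size, "opening_radius": opening_radius}
    return LabeledMask(m, mask.pixel_size, prov)


def segment(image: ImageGrid, method: str = "auto", target_px: float = 1.0,
            min_size: int = 10000, opening_radius: int = 5) -> LabeledMask:
    """Full segmentation: resample, threshold, clean.

    ``method='auto'`` delegates to :func:`select_threshold_method`.
    """
    work = resample_isotropic(image, target_px)
    if method == "auto":
        method, _ = select_threshold_method(work)
    raw = binarize(work, method)
    return clean_mask(raw, min_size=min_size, opening_radius=opening_radius)
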
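"""Whole-section tissue mask — the denominator of every infarct fraction.

All four stains leave the slide background unstained and near-white, so
tissue is whatever is not near-white.  Interior pale regions (a TTC
infarct core is off-white, bubbles are white) must still count toward the
section area, hence the hole filling.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import morphology

from ._exceptions import EmptyTissueError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_WHITE_FLOOR = 235
DEFAULT_MIN_OBJECT_PX = 64


def make_tissue_mask(
    img: np.ndarray,
    white_floor: int = DEFAULT_WHITE_FLOOR,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    *,
    closing_radius: int = 3,
    fill_holes: bool = True,
) -> np.ndarray:
    """Binary mask of the whole tissue section.

    A pixel is tissue when ``min(R, G, B) < white_floor``.  The raw mask is
    then closed with a disk of ``closing_radius``, holes are filled (unless
    ``fill_holes`` is disabled, e.g. to keep ventricular cavities out of
    the denominator), and connected components smaller than
    ``min_object_px`` are dropped as debris.

    Raises
    ------
    EmptyTissueError
        If no tissue pixel survives; usually means ``white_floor`` needs
        to be raised for a palely stained section.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected an H x W x 3 image, got shape {arr.shape}")
    mask = arr.min(axis=2) < white_floor
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if min_object_px > 0:
        mask = _drop_small_components(mask, min_object_px)
    if not mask.any():
        raise EmptyTissueError(
            f"no tissue found with white_floor={white_floor}; raise the "
            "threshold or check the image"
        )
    return mask


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove 8-connected components with fewer than ``min_px`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def mask_union_check(infarct: np.ndarray, tissue: np.ndarray) -> np.ndarray:
    """Intersect the infarct mask with the tissue mask.

    By construction the infarct mask should already be a subset of the
    tissue mask; any infarct pixel outside tissue is logged as a warning
    count before being clipped.
    """
    infarct = np.asarray(infarct, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    if infarct.shape != tissue.shape:
        raise ValidationError(
            f"mask shapes differ: infarct {infarct.shape} vs tissue {tissue.shape}"
        )
    outside = int(np.count_nonzero(infarct & ~tissue))
    if outside:
        logger.warning("%d infarct pixel(s) fall outside the tissue mask", outside)
    return infarct & tissue
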
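"""Lossless raster I/O and slide splitting.

Whole-slide scans typically carry several serial sections stacked
vertically on one glass slide; downstream analysis runs one section at a
time, so the scan is cut into horizontal bands, one per section.  All
splitting is pixel-exact: no resampling, no re-encoding losses.

Coordinate convention: 0-based, row-major, half-open row intervals
``[top, bottom)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from ._exceptions import ImageIOError, ValidationError

logger = logging.getLogger(__name__)

#: extensions accepted for lossless output
LOSSLESS_EXTENSIONS = {".png", ".tif", ".tiff"}

#: lossy extensions accepted on *read* only (with a warning)
LOSSY_EXTENSIONS = {".jpg", ".jpeg"}


@dataclass(frozen=True)
class SplitLayout:
    """Ordered horizontal bands cutting a slide scan into sub-images.

    Each band is a half-open row interval ``(top, bottom)``; bands must be
    pairwise non-overlapping and ordered top to bottom.
    """

    bands: tuple[tuple[int, int], ...]

    def __init__(self, bands: Sequence[Sequence[int]]):
        object.__setattr__(self, "bands", tuple((int(t), int(b)) for t, b in bands))

    @property
    def count(self) -> int:
        return len(self.bands)

    def validate(self, height: int) -> None:
        """Raise :class:`ValidationError` if any band is empty, out of range,
        or overlaps its predecessor, listing the offending band indices."""
        bad: list[int] = []
        for i, (top, bottom) in enumerate(self.bands):
            if not (0 <= top < bottom <= height):
                bad.append(i)
            elif i > 0 and top < self.bands[i - 1][1]:
                bad.append(i)
        if bad:
            raise ValidationError(
                f"invalid bands at indices {bad} for image height {height}: "
                f"{[self.bands[i] for i in bad]}"
            )


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as an 8-bit RGB array of shape (H, W, 3).

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped.  JPEG input is accepted with a logged warning (compression
    artifacts shift pixel colors, which matters for color-threshold rules).
    """
    path = Path(path)
    if path.suffix.lower() in LOSSY_EXTENSIONS:
        logger.warning(
            "%s is JPEG-compressed; compression artifacts may perturb "
            "color-threshold classification", path
        )
    try:
        arr = np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc

    if arr.size == 0:
        raise ValidationError(f"{path} decodes to a zero-size image")
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise ValidationError(
            f"{path} is not 8-bit (dtype {arr.dtype}); convert before analysis"
        )
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"{path} has unsupported shape {arr.shape}")
    return np.ascontiguousarray(arr)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB (or single-channel mask) array losslessly (PNG/TIFF).

    Lossy extensions are rejected so a write/read round trip is always
    bit-identical.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in LOSSLESS_EXTENSIONS:
        raise ValidationError(
            f"refusing lossy/unknown extension {ext!r} for {path}; "
            f"use one of {sorted(LOSSLESS_EXTENSIONS)}"
        )
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        iio.imwrite(path, arr)
    except Exception as exc:
        raise ImageIOError(f"cannot write image {path}: {exc}") from exc


def split_slide(img: np.ndarray, layout: SplitLayout) -> list[np.ndarray]:
    """Cut ``img`` into one sub-image per layout band (pixel-exact crops).

    Each output keeps all columns and the full resolution of the input.
    """
    _check_rgb(img)
    layout.validate(img.shape[0])
    return [np.ascontiguousarray(img[top:bottom]) for top, bottom in layout.bands]


def suggest_bands(
    img: np.ndarray,
    count: int,
    *,
    white_floor: int = 235,
    row_tissue_frac: float = 0.01,
    pad: int = 2,
) -> SplitLayout:
    """Propose ``count`` horizontal bands around the tissue sections in a scan.

    A pixel is background when ``min(R, G, B) >= white_floor`` (unstained
    near-white slide glass); a row counts as tissue when more than
    ``row_tissue_frac`` of its pixels are non-background.  Contiguous tissue
    row-runs are detected and, if more than ``count`` are found, runs
    separated by the smallest gaps are merged first.  Each band is padded by
    ``pad`` rows without crossing its neighbours.
    """
    _check_rgb(img)
    if count < 1:
        raise ValidationError(f"count must be >= 1, got {count}")
    non_bg = img.min(axis=2) < white_floor
    tissue_rows = non_bg.mean(axis=1) > row_tissue_frac
    runs = _runs(tissue_rows)
    if len(runs) < count:
        raise ValidationError(
            f"found {len(runs)} tissue band(s) but {count} were requested; "
            "adjust white_floor/row_tissue_frac or split manually"
        )
    while len(runs) > count:
        gaps = [runs[i + 1][0] - runs[i][1] for i in range(len(runs) - 1)]
        i = int(np.argmin(gaps))
        runs[i] = (runs[i][0], runs[i + 1][1])
        del runs[i + 1]
    height = img.shape[0]
    bands: list[tuple[int, int]] = []
    for i, (start, stop) in enumerate(runs):
        lo = max(0, start - pad)
        hi = min(height, stop + pad)
        if i > 0:
            lo = max(lo, (runs[i - 1][1] + start) // 2)
        if i < len(runs) - 1:
            hi = min(hi, (stop + runs[i + 1][0] + 1) // 2)
        bands.append((lo, hi))
    return SplitLayout(bands)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) intervals of consecutive True entries."""
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _check_rgb(img: np.ndarray) -> None:
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValidationError(f"expected an H x W x 3 image, got shape {img.shape}")
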
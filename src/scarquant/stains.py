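"""Per-pixel infarct classification rules for the four staining techniques.

Each stain leaves the infarct (scar) and the surrounding viable myocardium
with different colors, and each rule below turns that contrast into a
boolean pixel test in raw 8-bit RGB:

MTS (Masson's trichrome)
    Collagen-rich scar stains blue, muscle red.  An infarct pixel has a
    small red channel (``R <= mts_r_max``) and is blue-dominant
    (``B / R >= mts_br_ratio_min``).

TTC (triphenyltetrazolium chloride)
    Viable tissue turns deep red, infarct stays off-white, i.e. nearly
    gray.  Gray pixels have almost equal channels, so the population
    standard deviation of (R, G, B) is small; an infarct pixel satisfies
    ``std(R, G, B) <= ttc_std_max``.

PSR (picrosirius red)
    Collagen stains a dominant red against a paler counterstain.  With
    ``mean_GB = (G + B) / 2``, an infarct pixel is red-dominant with a
    margin: ``R > mean_GB`` and ``R - mean_GB >= psr_thd``.

H&E (hematoxylin & eosin)
    Infarct is poorly contrasted; a two-step image transform reveals it.
    Step 1 zeroes any channel value above ``he_channel_cap`` (removes
    saturated stain).  Step 2 keeps only green-dominant pixels as pure
    green ``(0, G, 0)`` and blanks everything else.  A transformed pixel
    is infarct when ``G >= he_g_min``.

All rules are pure pixel tests: they must be composed with a tissue mask,
since unstained background (white for MTS/H&E/PSR, gray-neutral for TTC)
trivially satisfies some of them.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ._exceptions import ConfigurationError, ValidationError

STAINS = ("MTS", "HE", "TTC", "PSR")


@dataclass
class StainConfig:
    """Stain identifier plus every threshold of the classification rules.

    All thresholds are deliberately user-adjustable: staining intensity
    varies between batches, so the defaults are starting points that
    separate typical infarct/non-infarct colors with a wide margin.

    Parameters
    ----------
    stain:
        One of ``MTS``, ``HE``, ``TTC``, ``PSR``.
    mts_r_max:
        Upper red-channel limit for an MTS infarct pixel (8-bit units).
    mts_br_ratio_min:
        Lower bound on the blue/red ratio for an MTS infarct pixel
        (dimensionless; infarct collagen is blue-dominant).
    ttc_std_max:
        Upper bound on the population standard deviation of a pixel's
        three channels for a TTC infarct pixel (8-bit units).
    psr_thd:
        Required red-over-mean(G, B) margin for a PSR infarct pixel
        (8-bit units).
    he_channel_cap:
        H&E step-1 threshold: any channel value above it is zeroed.
    he_g_min:
        Minimum surviving green intensity for an H&E infarct pixel after
        the two-step transform.
    psr_literal_or:
        Use the disjunctive PSR reading ``R > mean_GB OR margin >= thd``
        instead of the default conjunction.  Under the disjunction the
        margin threshold is inert for any red-dominant pixel, so the
        conjunction is the default.
    """

    stain: str = "MTS"
    mts_r_max: float = 150.0
    mts_br_ratio_min: float = 1.2
    ttc_std_max: float = 30.0
    psr_thd: float = 50.0
    he_channel_cap: float = 200.0
    he_g_min: float = 120.0
    psr_literal_or: bool = False

    def __post_init__(self) -> None:
        self.stain = str(self.stain).upper().replace("&", "")
        if self.stain not in STAINS:
            raise ConfigurationError(
                f"unknown stain {self.stain!r}; choose one of {list(STAINS)}"
            )
        for name in ("mts_r_max", "ttc_std_max", "he_channel_cap", "he_g_min"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ConfigurationError(f"{name} must be in [0, 255], got {v}")
        if self.mts_br_ratio_min <= 0:
            raise ConfigurationError("mts_br_ratio_min must be > 0")
        if self.psr_thd < 0:
            raise ConfigurationError("psr_thd must be >= 0")

    def replace(self, **kwargs) -> "StainConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return StainConfig(**current)


def _split_channels(pixels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValidationError(f"expected RGB triplets in the last axis, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("channel values must lie in [0, 255]")
    return arr[..., 0], arr[..., 1], arr[..., 2]


def classify_mts(pixels, cfg: StainConfig) -> np.ndarray | bool:
    """True where a pixel is MTS infarct: ``R <= mts_r_max`` and blue-dominant.

    The blue/red ratio uses ``R + 1`` in the denominator when ``R == 0`` so
    pure black never divides by zero; background exclusion is the tissue
    mask's job, not this guard's.
    """
    r, _, b = _split_channels(pixels)
    denom = np.where(r == 0, 1.0, r)
    out = (r <= cfg.mts_r_max) & (b / denom >= cfg.mts_br_ratio_min)
    return out if out.ndim else bool(out)


def classify_ttc(pixels, cfg: StainConfig) -> np.ndarray | bool:
    """True where a pixel is TTC infarct: near-gray, i.e. low channel spread.

    Uses the population standard deviation (divisor 3) of the three
    channel values of each pixel.
    """
    arr = np.stack(_split_channels(pixels), axis=-1)
    out = arr.std(axis=-1) <= cfg.ttc_std_max
    return out if out.ndim else bool(out)


def classify_psr(pixels, cfg: StainConfig) -> np.ndarray | bool:
    """True where a pixel is PSR infarct: red-dominant with margin >= psr_thd."""
    r, g, b = _split_channels(pixels)
    mean_gb = (g + b) / 2.0
    margin = r - mean_gb
    if cfg.psr_literal_or:
        out = (r > mean_gb) | (margin >= cfg.psr_thd)
    else:
        out = (r > mean_gb) & (margin >= cfg.psr_thd)
    return out if out.ndim else bool(out)


def transform_he(img: np.ndarray, cfg: StainConfig) -> np.ndarray:
    """Apply the two-step H&E transform that reveals the infarct in green.

    Step 1 zeroes each channel value exceeding ``he_channel_cap`` (each
    channel independently; the other channels of the pixel are kept).
    Step 2 keeps only green-dominant pixels: where ``R < G`` or ``B < G``
    the pixel becomes ``(0, G, 0)``, otherwise ``(0, 0, 0)``.  Every output
    pixel is therefore pure green or black.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected an H x W x 3 image, got shape {arr.shape}")
    capped = np.where(arr > cfg.he_channel_cap, 0, arr).astype(np.uint8)
    r, g, b = capped[..., 0], capped[..., 1], capped[..., 2]
    keep = (r < g) | (b < g)
    out = np.zeros_like(capped)
    out[..., 1] = np.where(keep, g, 0)
    return out


def classify_he(pixels, cfg: StainConfig) -> np.ndarray | bool:
    """True where a transformed H&E pixel keeps green at or above ``he_g_min``."""
    _, g, _ = _split_channels(pixels)
    out = g >= cfg.he_g_min
    return out if out.ndim else bool(out)


_PIXEL_RULES = {"MTS": classify_mts, "TTC": classify_ttc, "PSR": classify_psr}


def classify_image(img: np.ndarray, cfg: StainConfig, tissue: np.ndarray) -> np.ndarray:
    """Stain-appropriate infarct mask restricted to tissue pixels.

    For H&E the two-step transform runs first and the green threshold is
    applied to its output.  Pixels outside ``tissue`` are always False, so
    the result is a subset of the tissue mask.
    """
    arr = np.asarray(img)
    tissue = np.asarray(tissue, dtype=bool)
    if tissue.shape != arr.shape[:2]:
        raise ValidationError(
            f"tissue mask shape {tissue.shape} != image shape {arr.shape[:2]}"
        )
    if cfg.stain == "HE":
        mask = classify_he(transform_he(arr, cfg), cfg)
    else:
        try:
            rule = _PIXEL_RULES[cfg.stain]
        except KeyError:
            raise ConfigurationError(
                f"unknown stain {cfg.stain!r}; choose one of {list(STAINS)}"
            ) from None
        mask = rule(arr, cfg)
    return np.asarray(mask, dtype=bool) & tissue
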
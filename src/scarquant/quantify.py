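"""Infarct quantification: relative size, physical areas, serial-section volumes.

Per section, with square pixels of edge ``px`` (μm):

    relative infarct size (%) = 100 · ΣP_s / ΣP_t
    infarct area  A_s = px² · ΣP_s        section area  A_t = px² · ΣP_t

where ΣP_s and ΣP_t are the infarct and whole-section pixel counts.

For a serially sectioned heart, each stained section of height h1 is
followed by a gap of discarded tissue of height h2; the gap is assumed to
share the adjacent section's areas.  Summing over sections i:

    V_Ts = Σ_i A_s,i · (h1_i + h2_i)      V_Tt = Σ_i A_t,i · (h1_i + h2_i)
    relative infarct volume (%) = 100 · V_Ts / V_Tt

Pixel sizes and heights are in μm; volumes are reported in mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._exceptions import ValidationError

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class SectionQuant:
    """Pixel counts and physical areas for one section."""

    n_infarct: int
    n_section: int
    px_um: float
    section_id: str = ""

    def __post_init__(self):
        if self.n_section <= 0:
            raise ValidationError("section pixel count must be > 0")
        if not 0 <= self.n_infarct <= self.n_section:
            raise ValidationError(
                f"infarct count {self.n_infarct} outside [0, {self.n_section}]"
            )
        if self.px_um <= 0:
            raise ValidationError("pixel size must be > 0")

    @property
    def relative_pct(self) -> float:
        return relative_infarct_size(self.n_infarct, self.n_section)

    @property
    def infarct_area_um2(self) -> float:
        return pixel_area(self.n_infarct, self.px_um)

    @property
    def section_area_um2(self) -> float:
        return pixel_area(self.n_section, self.px_um)

    @property
    def infarct_area_mm2(self) -> float:
        return self.infarct_area_um2 / 1e6

    @property
    def section_area_mm2(self) -> float:
        return self.section_area_um2 / 1e6


@dataclass(frozen=True)
class ManifestEntry:
    """One section of a serial stack: areas in μm², heights in μm."""

    section_id: str
    infarct_area_um2: float
    section_area_um2: float
    h1_um: float
    h2_um: float

    def __post_init__(self):
        if self.h1_um <= 0 or self.h2_um < 0:
            raise ValidationError(
                f"section {self.section_id}: h1 must be > 0 and h2 >= 0"
            )
        if self.infarct_area_um2 < 0 or self.section_area_um2 < 0:
            raise ValidationError(f"section {self.section_id}: areas must be >= 0")
        if self.infarct_area_um2 > self.section_area_um2:
            raise ValidationError(
                f"section {self.section_id}: infarct area exceeds section area"
            )


@dataclass(frozen=True)
class VolumeManifest:
    """Anatomically ordered per-section records for whole-heart integration."""

    sections: tuple[ManifestEntry, ...]

    def __init__(self, sections: Sequence[ManifestEntry]):
        object.__setattr__(self, "sections", tuple(sections))

    def __len__(self) -> int:
        return len(self.sections)


@dataclass(frozen=True)
class HeartVolumes:
    """Whole-heart volume integration result (volumes in mm³)."""

    infarct_volume_mm3: float
    tissue_volume_mm3: float
    per_section: tuple[tuple[float, float, float, float], ...] = field(repr=False)
    #: per section: (V_s, V_rs, V_t, V_rt) in mm³

    @property
    def relative_volume_pct(self) -> float:
        return 100.0 * self.infarct_volume_mm3 / self.tissue_volume_mm3


def relative_infarct_size(n_infarct: int, n_section: int) -> float:
    """Infarct pixel count as a percentage of the whole-section pixel count."""
    if n_section <= 0:
        raise ValidationError(f"section pixel count must be > 0, got {n_section}")
    if not 0 <= n_infarct <= n_section:
        raise ValidationError(
            f"infarct count {n_infarct} must lie in [0, {n_section}]"
        )
    return n_infarct * 100.0 / n_section


def pixel_area(n: int, px_size: float) -> float:
    """Physical area of ``n`` square pixels of edge ``px_size`` (unit²)."""
    if n < 0:
        raise ValidationError(f"pixel count must be >= 0, got {n}")
    if px_size <= 0:
        raise ValidationError(f"pixel size must be > 0, got {px_size}")
    return px_size * px_size * n


def section_volumes(area: float, h1: float, h2: float) -> tuple[float, float]:
    """(section volume, removed-gap volume) = (A·h1, A·h2).

    The gap of discarded tissue between adjacent sections is assumed to
    share the adjacent section's area, so its volume is the same area
    times the gap height.
    """
    if area < 0:
        raise ValidationError(f"area must be >= 0, got {area}")
    if h1 <= 0 or h2 < 0:
        raise ValidationError(f"h1 must be > 0 and h2 >= 0, got h1={h1}, h2={h2}")
    return area * h1, area * h2


def heart_volumes(
    manifest: VolumeManifest, *, include_trailing_gap: bool = True
) -> HeartVolumes:
    """Integrate infarct and tissue volumes over a serial-section manifest.

    Every section contributes A·h1 plus A·h2 for the gap that follows it.
    Whether a gap follows the final section is a sampling-design question;
    by default the trailing gap is counted (uniform formula), and
    ``include_trailing_gap=False`` drops it.  With uniform h1 and h2 the
    relative volume percentage is identical either way.
    """
    if len(manifest) == 0:
        raise ValidationError("manifest is empty")
    per_section = []
    v_ts = v_tt = 0.0
    last = len(manifest) - 1
    for i, sec in enumerate(manifest.sections):
        h2 = sec.h2_um if (include_trailing_gap or i < last) else 0.0
        vs, vrs = section_volumes(sec.infarct_area_um2, sec.h1_um, h2)
        vt, vrt = section_volumes(sec.section_area_um2, sec.h1_um, h2)
        per_section.append(
            (vs / UM3_PER_MM3, vrs / UM3_PER_MM3, vt / UM3_PER_MM3, vrt / UM3_PER_MM3)
        )
        v_ts += vs + vrs
        v_tt += vt + vrt
    if v_tt == 0:
        raise ValidationError("total tissue volume is zero; check manifest areas")
    return HeartVolumes(v_ts / UM3_PER_MM3, v_tt / UM3_PER_MM3, tuple(per_section))


def relative_volume_pct(infarct_volume: float, tissue_volume: float) -> float:
    """Relative infarct volume (%) from whole-heart totals in matching units."""
    if tissue_volume <= 0:
        raise ValidationError("tissue volume must be > 0")
    if infarct_volume < 0 or infarct_volume > tissue_volume:
        raise ValidationError("infarct volume must lie in [0, tissue volume]")
    return 100.0 * infarct_volume / tissue_volume


def sections_to_frame(quants: Sequence[SectionQuant]) -> pd.DataFrame:
    """Per-section results table (full precision; display rounding is the CLI's job)."""
    return pd.DataFrame(
        {
            "section_id": [q.section_id for q in quants],
            "n_infarct": [q.n_infarct for q in quants],
            "n_section": [q.n_section for q in quants],
            "relative_pct": [q.relative_pct for q in quants],
            "infarct_area_mm2": [q.infarct_area_mm2 for q in quants],
            "section_area_mm2": [q.section_area_mm2 for q in quants],
        }
    )


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    """Read a stack manifest CSV: ``section_id,image,h1_um,h2_um,px_um``."""
    df = pd.read_csv(path)
    required = {"section_id", "image", "h1_um", "h2_um", "px_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest is missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("manifest lists no sections")
    return df
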
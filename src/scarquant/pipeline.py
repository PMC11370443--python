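"""End-to-end section analysis: the library core behind the CLI commands.

``analyze_section`` runs tissue masking, stain-specific classification,
optional crop/exclusions/dilation, and quantification on one image;
``analyze_stack`` maps it over a serial-section manifest and integrates
whole-heart volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .config import PipelineConfig
from .imgio import read_image
from .masking import make_tissue_mask, mask_union_check
from .postprocess import (
    ExclusionSet,
    Rect,
    apply_exclusions,
    crop_roi,
    dilate_mask,
    embed_mask,
    render_overlay,
)
from .quantify import (
    HeartVolumes,
    ManifestEntry,
    SectionQuant,
    VolumeManifest,
    heart_volumes,
    read_manifest_csv,
)
from .stains import StainConfig, classify_image


@dataclass
class SectionResult:
    """All artifacts of one section analysis."""

    quant: SectionQuant
    tissue_mask: np.ndarray = field(repr=False)
    infarct_mask: np.ndarray = field(repr=False)
    overlay: np.ndarray = field(repr=False)


def analyze_section(
    img: np.ndarray,
    stain_cfg: StainConfig,
    pipe_cfg: PipelineConfig | None = None,
    *,
    crop: Rect | None = None,
    exclusions: ExclusionSet | None = None,
    section_id: str = "",
) -> SectionResult:
    """Detect, isolate and quantify the infarct in one section image.

    With ``crop`` the color rule runs on the cropped region only (the
    denominator tissue mask still covers the whole frame).  Exclusion
    polygons are applied to the infarct mask only: an artifact such as a
    bubble stops counting as infarct but stays inside the whole-section
    denominator, consistent with hole filling in the tissue mask.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    tissue = make_tissue_mask(
        img,
        pipe_cfg.white_floor,
        pipe_cfg.min_object_px,
        closing_radius=pipe_cfg.closing_radius,
        fill_holes=pipe_cfg.fill_holes,
    )
    if crop is not None:
        sub_img, rect = crop_roi(img, crop)
        sub_tissue, _ = crop_roi(tissue[..., None], rect)
        sub_mask = classify_image(sub_img, stain_cfg, sub_tissue[..., 0])
        infarct = embed_mask(sub_mask, rect, tissue.shape)
    else:
        infarct = classify_image(img, stain_cfg, tissue)
    if exclusions is not None:
        infarct = apply_exclusions(infarct, exclusions)
    if pipe_cfg.dilation_radius > 0:
        infarct = dilate_mask(infarct, pipe_cfg.dilation_radius)
    infarct = mask_union_check(infarct, tissue)
    quant = SectionQuant(
        n_infarct=int(np.count_nonzero(infarct)),
        n_section=int(np.count_nonzero(tissue)),
        px_um=pipe_cfg.px_um,
        section_id=section_id,
    )
    return SectionResult(quant, tissue, infarct, render_overlay(img, infarct, tissue))


def analyze_stack(
    manifest: pd.DataFrame,
    stain_cfg: StainConfig,
    pipe_cfg: PipelineConfig | None = None,
    *,
    base_dir: str | Path | None = None,
    include_trailing_gap: bool = True,
) -> tuple[list[SectionResult], HeartVolumes]:
    """Run :func:`analyze_section` over a manifest and integrate volumes.

    ``manifest`` follows :func:`scarquant.quantify.read_manifest_csv`
    (columns ``section_id, image, h1_um, h2_um, px_um``); relative image
    paths resolve against ``base_dir``.  Any failing section aborts the
    run with its section id.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    base = Path(base_dir) if base_dir is not None else Path(".")
    results: list[SectionResult] = []
    entries: list[ManifestEntry] = []
    for row in manifest.itertuples(index=False):
        path = Path(row.image)
        if not path.is_absolute():
            path = base / path
        try:
            img = read_image(path)
            res = analyze_section(
                img,
                stain_cfg,
                PipelineConfig(
                    white_floor=pipe_cfg.white_floor,
                    min_object_px=pipe_cfg.min_object_px,
                    closing_radius=pipe_cfg.closing_radius,
                    fill_holes=pipe_cfg.fill_holes,
                    dilation_radius=pipe_cfg.dilation_radius,
                    px_um=float(row.px_um),
                ),
                section_id=str(row.section_id),
            )
        except Exception as exc:
            raise ValidationError(f"section {row.section_id!r} failed: {exc}") from exc
        results.append(res)
        entries.append(
            ManifestEntry(
                section_id=str(row.section_id),
                infarct_area_um2=res.quant.infarct_area_um2,
                section_area_um2=res.quant.section_area_um2,
                h1_um=float(row.h1_um),
                h2_um=float(row.h2_um),
            )
        )
    volumes = heart_volumes(
        VolumeManifest(entries), include_trailing_gap=include_trailing_gap
    )
    return results, volumes


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Convenience re-export of the manifest reader."""
    return read_manifest_csv(path)
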
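"""Synthetic stained-section phantoms with known ground truth.

Every pipeline stage is validated on phantoms: a near-white slide
background, a smooth blob-shaped tissue section, a contiguous infarct
region (or sparse fibrotic strands), optional bubble artifacts, and
per-class Gaussian channel noise.  Class palettes are anchored to
published exemplar pixel values for each stain; palette entries that no
exemplar pins down are synthetic companions chosen to keep each class on
the correct side of the default thresholds.

The rules under test are purely pixel-wise, so the phantoms model color
statistics only — no fiber texture, nuclei or staining gradients.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from skimage import draw

from ._exceptions import ValidationError
from .quantify import ManifestEntry, VolumeManifest
from .stains import STAINS

#: Per-stain class palettes (mean RGB).  Infarct means for TTC and PSR and
#: both H&E green values are published exemplars; the MTS means pin the
#: published R values 41 (infarct) and 251 (non-infarct); remaining
#: channels are synthetic, chosen in-palette for the stain.
DEFAULT_PALETTES: dict[str, dict[str, tuple[int, int, int]]] = {
    "MTS": {"infarct": (41, 80, 190), "normal": (251, 120, 130)},
    "TTC": {"infarct": (133, 136, 134), "normal": (187, 69, 61)},
    "PSR": {"infarct": (240, 129, 143), "normal": (204, 191, 174)},
    "HE": {"infarct": (150, 174, 120), "normal": (230, 99, 180)},
}

#: unstained slide glass; bright and spectrally flat
BACKGROUND_RGB = (250, 250, 250)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic section image.

    ``noise_sigma`` (default 8) is the per-channel Gaussian noise applied
    to tissue classes; the slide background gets the much smaller
    ``background_sigma`` (default 2), since blank glass scans nearly
    noise-free compared with stained tissue.
    ``bubbles`` are (row, col, radius) discs painted background-colored
    inside the tissue.  ``fibrosis_density`` scatters thin strands of the
    infarct color over the tissue (MTS fibrosis phantoms); an optional
    ``fibrosis_region`` (top, bottom, left, right) confines strand seeds.
    """

    stain: str = "MTS"
    canvas: tuple[int, int] = (256, 320)
    infarct_frac: float = 0.25
    boundary_amp: float = 0.03
    noise_sigma: float = 8.0
    background_sigma: float = 2.0
    palettes: dict[str, tuple[int, int, int]] | None = None
    bubbles: tuple[tuple[int, int, int], ...] = ()
    fibrosis_density: float = 0.0
    fibrosis_region: tuple[int, int, int, int] | None = None
    seed: int = 0

    def __post_init__(self):
        stain = str(self.stain).upper().replace("&", "")
        object.__setattr__(self, "stain", stain)
        if stain not in STAINS:
            raise ValidationError(f"unknown stain {stain!r}; choose from {list(STAINS)}")
        if not 0.0 <= self.infarct_frac < 1.0:
            raise ValidationError("infarct_frac must lie in [0, 1)")
        if not 0.0 <= self.fibrosis_density < 1.0:
            raise ValidationError("fibrosis_density must lie in [0, 1)")
        if self.noise_sigma < 0 or self.background_sigma < 0:
            raise ValidationError("noise scales must be >= 0")
        h, w = self.canvas
        if h < 32 or w < 32:
            raise ValidationError(f"canvas {self.canvas} too small for a section")
        for mean in (self.palettes or {}).values():
            if min(mean) < 0 or max(mean) > 255:
                raise ValidationError(f"palette mean {mean} outside [0, 255]")

    @property
    def palette(self) -> dict[str, tuple[int, int, int]]:
        return self.palettes or DEFAULT_PALETTES[self.stain]


@dataclass(frozen=True)
class PhantomOutput:
    """Rendered phantom plus its ground truth."""

    image: np.ndarray
    tissue_truth: np.ndarray
    infarct_truth: np.ndarray
    metadata: dict = field(repr=False)


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render one phantom section; deterministic for a given spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    tissue = _section_mask(spec, rng)
    infarct = _infarct_mask(spec, tissue, rng)
    strands = _strand_mask(spec, tissue, infarct, rng)
    bubbles = _bubble_mask(spec, tissue)
    image = _render(spec, tissue, infarct | strands, bubbles, rng)

    scar_truth = (infarct | strands) & ~bubbles
    n_tissue = int(np.count_nonzero(tissue))
    meta = {
        "spec": _spec_dict(spec),
        "n_tissue": n_tissue,
        "n_infarct": int(np.count_nonzero(scar_truth)),
        "infarct_frac_realized": float(np.count_nonzero(infarct & ~bubbles)) / n_tissue,
        "fibrosis_frac_realized": float(np.count_nonzero(strands & ~bubbles)) / n_tissue,
    }
    return PhantomOutput(image, tissue, scar_truth, meta)


def generate_serial_stack(
    spec: PhantomSpec,
    n_sections: int,
    h1_um: float,
    h2_um: float,
    px_um: float = 10.0,
    profile: Sequence[float] | None = None,
) -> tuple[list[PhantomOutput], VolumeManifest]:
    """Serial-section stack sharing one base section shape.

    ``profile`` gives the infarct disc radius of each section in pixels;
    by default a rise-and-fall half-sine profile emulates an infarct that
    grows and then shrinks along the apex-to-base axis.  The manifest is
    filled with the *ground-truth* pixel-count areas, so closed-form
    volume oracles can be checked against the image pipeline.
    """
    if n_sections < 1:
        raise ValidationError("n_sections must be >= 1")
    if px_um <= 0:
        raise ValidationError("px_um must be > 0")
    h, w = spec.canvas
    r_cap = 0.45 * min(0.37 * h, 0.40 * w) * (1 - spec.boundary_amp)
    if profile is None:
        i = np.arange(n_sections)
        profile = r_cap * np.sin(np.pi * (i + 0.5) / n_sections)
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (n_sections,):
        raise ValidationError(
            f"profile length {profile.shape} != n_sections {n_sections}"
        )
    if profile.min() < 0 or profile.max() > r_cap + 1e-9:
        raise ValidationError(f"profile radii must lie in [0, {r_cap:.1f}] px")

    shape_rng = np.random.default_rng(spec.seed)
    tissue = _section_mask(spec, shape_rng)
    center = (spec.canvas[0] / 2.0, spec.canvas[1] / 2.0)
    dist = _dist_grid(spec.canvas, center)

    children = np.random.SeedSequence(spec.seed).spawn(n_sections)
    outputs: list[PhantomOutput] = []
    entries: list[ManifestEntry] = []
    n_tissue = int(np.count_nonzero(tissue))
    for i, radius in enumerate(profile):
        infarct = (dist <= radius) & tissue if radius > 0 else np.zeros_like(tissue)
        rng = np.random.default_rng(children[i])
        image = _render(spec, tissue, infarct, np.zeros_like(tissue), rng)
        n_inf = int(np.count_nonzero(infarct))
        meta = {
            "spec": _spec_dict(spec),
            "section_index": i,
            "disc_radius_px": float(radius),
            "n_tissue": n_tissue,
            "n_infarct": n_inf,
            "infarct_frac_realized": n_inf / n_tissue,
        }
        outputs.append(PhantomOutput(image, tissue, infarct, meta))
        entries.append(
            ManifestEntry(
                section_id=f"s{i:03d}",
                infarct_area_um2=px_um * px_um * n_inf,
                section_area_um2=px_um * px_um * n_tissue,
                h1_um=h1_um,
                h2_um=h2_um,
            )
        )
    return outputs, VolumeManifest(entries)


# ---------------------------------------------------------------------------
# construction internals

def _spec_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["bubbles"] = [list(b) for b in spec.bubbles]
    return d


def _dist_grid(canvas: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:canvas[0], 0:canvas[1]]
    return np.hypot(rr - center[0], cc - center[1])


def _section_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Ellipse with low-frequency radial perturbation: a smooth tissue blob.

    Harmonics are kept low (k = 2..4) and shallow so the outline has no
    concavity narrower than the tissue-mask closing element; the rasterized
    truth is then stable under the mask pipeline's morphology.
    """
    h, w = spec.canvas
    a, b = 0.37 * h, 0.40 * w
    rr, cc = np.mgrid[0:h, 0:w]
    dy, dx = rr - h / 2.0, cc - w / 2.0
    theta = np.arctan2(dy, dx)
    rfun = np.ones_like(theta)
    for k in (2, 3, 4):
        amp = spec.boundary_amp * rng.uniform(0.3, 1.0) / k
        phase = rng.uniform(0, 2 * np.pi)
        rfun += amp * np.sin(k * theta + phase)
    return (dy / a) ** 2 + (dx / b) ** 2 <= rfun**2


def _infarct_mask(
    spec: PhantomSpec, tissue: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous infarct hitting the target area fraction near-exactly.

    The region is the intersection of the tissue with a disc grown around
    an off-center focus; the radius is the k-th smallest focus distance
    among tissue pixels, where k is the target pixel count, so the
    realized fraction is exact up to distance ties.
    """
    if spec.infarct_frac == 0:
        return np.zeros_like(tissue)
    h, w = spec.canvas
    center = (h / 2.0, w / 2.0 - 0.18 * w)  # focus toward one ventricle wall
    dist = _dist_grid(spec.canvas, center)
    d_tissue = np.sort(dist[tissue])
    k = int(round(spec.infarct_frac * d_tissue.size))
    if k < 1:
        return np.zeros_like(tissue)
    radius = d_tissue[k - 1]
    return (dist <= radius) & tissue


def _strand_mask(
    spec: PhantomSpec,
    tissue: np.ndarray,
    infarct: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thin random line segments until the target tissue fraction is reached."""
    if spec.fibrosis_density == 0:
        return np.zeros_like(tissue)
    allowed = tissue & ~infarct
    if spec.fibrosis_region is not None:
        top, bottom, left, right = spec.fibrosis_region
        region = np.zeros_like(tissue)
        region[top:bottom, left:right] = True
        seed_allowed = allowed & region
    else:
        seed_allowed = allowed
    seed_pts = np.argwhere(seed_allowed)
    if seed_pts.size == 0:
        raise ValidationError("no tissue available for fibrotic strands")
    n_tissue = np.count_nonzero(tissue)
    target = int(round(spec.fibrosis_density * n_tissue))
    strands = np.zeros_like(tissue)
    h, w = spec.canvas
    count = 0
    # each strand adds ~15-50 px; granularity is well under 1% of tissue
    for _ in range(200_000):
        if count >= target:
            break
        r0, c0 = seed_pts[rng.integers(len(seed_pts))]
        angle = rng.uniform(0, np.pi)
        length = rng.integers(8, 25)
        r1 = int(np.clip(r0 + length * np.sin(angle), 0, h - 1))
        c1 = int(np.clip(c0 + length * np.cos(angle), 0, w - 1))
        rr, cc = draw.line(int(r0), int(c0), r1, c1)
        if rng.random() < 0.5:  # about half the strands are 2 px wide
            rr = np.concatenate([rr, np.clip(rr + 1, 0, h - 1)])
            cc = np.concatenate([cc, cc])
        keep = allowed[rr, cc]
        strands[rr[keep], cc[keep]] = True
        count = int(np.count_nonzero(strands))
    return strands


def _bubble_mask(spec: PhantomSpec, tissue: np.ndarray) -> np.ndarray:
    bubbles = np.zeros_like(tissue)
    for row, col, radius in spec.bubbles:
        rr, cc = draw.disk((row, col), radius, shape=tissue.shape)
        bubbles[rr, cc] = True
    if (bubbles & ~tissue).any():
        raise ValidationError("bubble artifacts must lie inside the tissue section")
    return bubbles


def _render(
    spec: PhantomSpec,
    tissue: np.ndarray,
    scar: np.ndarray,
    bubbles: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = spec.canvas
    palette = spec.palette
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    img[tissue] = palette["normal"]
    img[scar] = palette["infarct"]
    img[bubbles] = BACKGROUND_RGB  # air gap shows slide glass
    sigma = np.where((tissue & ~bubbles)[..., None], spec.noise_sigma, spec.background_sigma)
    img += rng.normal(0.0, 1.0, img.shape) * sigma
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
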
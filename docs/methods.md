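# Methods

## Model

`scarquant` treats infarct detection in stained sections as pure
per-pixel color classification in raw 8-bit RGB.  No color-space
conversion, stain unmixing or texture model is used: the stains of
interest separate scar from viable myocardium by color alone, and a
pixel-wise rule keeps the method transparent and user-adjustable.

Assumptions:

- the slide background is unstained, near-white glass;
- scar and viable tissue fall on opposite sides of a simple channel
  inequality for each stain;
- pixels are square, of known physical edge length;
- in serial sectioning, the discarded gap between adjacent sections has
  the same infarct and tissue areas as the section next to it.

## Stain rules and their parameters

All channel-valued thresholds are in 8-bit units (0–255) and exposed in
the run configuration; defaults separate the documented exemplar colors
of each class with a wide margin but must be expected to need tuning on
real slides, where staining intensity varies between batches.

**MTS** — infarct iff `R ≤ mts_r_max` (default 150) and
`B/R ≥ mts_br_ratio_min` (default 1.2).  Scar collagen is blue with a
very low red channel (exemplar R = 41) while muscle is red (R = 251);
the blue/red ratio removes faintly blue pixels.  The division guards
`R = 0` by substituting 1 in the denominator; background exclusion is
the tissue mask's job, not this guard's.

**TTC** — infarct iff the population standard deviation (divisor 3) of
the pixel's three channels is ≤ `ttc_std_max` (default 30).  The
off-white infarct is nearly gray (exemplar 133/136/134, std ≈ 1.25);
viable tissue is strongly red (187/69/61, std ≈ 57.6).  The divisor
choice only rescales the threshold, since n = 3 is fixed; population
form avoids the sample-size-2 correction.

**PSR** — with `mean_GB = (G+B)/2`, infarct iff `R > mean_GB` **and**
`R − mean_GB ≥ psr_thd` (default 50).  The conjunction is deliberate: a
disjunctive reading makes the margin threshold inert for every
red-dominant pixel, leaving no user-adjustable sensitivity between the
exemplar margins 21.5 (non-infarct) and 104 (infarct).  The disjunctive
variant remains available behind `psr_literal_or` for comparison.

**H&E** — a two-step transform precedes classification.  Step 1 zeroes
each channel value above `he_channel_cap` (default 200), applied
per channel, which removes saturated eosin.  Step 2 keeps only
green-dominant pixels (`R < G` or `B < G`) as pure green `(0, G, 0)`
and blanks the rest, so every transformed pixel is green or black.  A
pixel is infarct iff its surviving green is ≥ `he_g_min` (default 120,
between the documented infarct green 174 and non-infarct green 99).
All rule thresholds are inclusive (`≤`/`≥`).

## Tissue mask

The quantification denominator is the whole section: pixels with
`min(R,G,B) < white_floor` (default 235), closed with a disk of radius
3, hole-filled, and cleared of 8-connected components smaller than
`min_object_px` (default 64).  Hole filling is essential: the TTC
infarct core is itself off-white and bubbles are white, yet both belong
to the section area.  `fill_holes=False` is available when ventricular
cavities should not count as tissue.  An image with no tissue raises an
error suggesting a threshold adjustment rather than returning an empty
mask.

## Dilation, artifacts, cropping

`dilate_mask` uses a disk structuring element (scikit-image's
rasterization; radius 1 is the 4-connected plus shape); radius 0 is the
identity.  Dilation before quantification is **off by default**
(`dilation_radius = 0`): on a compact region it adds roughly
perimeter × radius pixels, which on a 25%-of-section disc already
biases the fraction by nearly +2 percentage points, and it multiplies
any isolated false-positive pixel ~13-fold at radius 2.  It remains
available for real tissue where the color rule under-segments a
speckled scar interior.  The fibrosis analyzer likewise defaults to no
dilation and no minimum-component filter, because individual collagen
strands are legitimately one or two pixels wide.

Artifact exclusion takes file-supplied polygons (JSON lists of
0-based (row, col) vertices); interior fill uses the even-odd rule and
boundary pixels count as excluded.  Exclusions are applied to the
infarct mask only: a bubble stops counting as infarct but stays inside
the hole-filled section denominator, keeping the denominator's meaning
("the entire section") stable.  Cropping is half-open and pixel-exact,
and returns its offsets so masks computed on a crop can be re-embedded
in the full frame.

## Quantification and units

Pixel sizes and section heights are in μm, areas in μm² (mm² in output
tables), volumes in mm³.  Relative infarct size is
`100·ΣPs/ΣPt`; areas are `Px²·ΣP`; each section contributes
`A·(h1 + h2)` to its heart total, the `h2` term standing for the
removed gap assumed to share the section's areas.  Whether a gap
follows the *last* section is a sampling-design question; it is counted
by default (uniform formula) and `--no-trailing-gap` drops it — with
uniform heights the relative volume percentage is identical either
way.  All area/volume arithmetic is exact for integer counts; summaries
print percentages at one decimal, CSVs keep full precision.

## Slide splitting

Multi-section slide scans are split into horizontal bands (one section
per band), pixel-exact and without resampling; columns are never cut.
Band suggestion marks a row as tissue when more than 1% of its pixels
are non-background, merges the closest row-runs down to the requested
count, and pads each band by 2 rows without crossing its neighbours.
The library accepts any band count; the CLI warns above 5, which is as
many sections as commonly fit on one slide.  I/O is lossless (PNG/TIFF);
JPEG is accepted on read with a warning, since compression artifacts
perturb exactly the color values the rules test.

## Phantom generator

Phantoms emulate: a bright, spectrally flat slide background
(250,250,250); a smooth blob-shaped section (ellipse with shallow
radial harmonics k = 2–4, amplitude ≤ 3%, so the outline is stable
under the mask pipeline's closing); a contiguous infarct grown around
an off-center focus to hit the target area fraction near-exactly (the
radius is chosen as an order statistic of focus distances, so the
realized fraction recorded in the metadata is exact up to distance
ties); optional background-colored bubble discs inside the tissue; and,
for fibrosis, thin random strands (1–2 px wide, length 8–25 px)
accumulated until the target tissue fraction is reached.

Noise is independent per-channel Gaussian, clipped to [0, 255], with a
per-class scale: `noise_sigma` (default 8) on tissue classes and
`background_sigma` (default 2) on the slide background, reflecting that
blank glass scans nearly noise-free compared with stained tissue.  The
separation matters for the denominator: a heavily noisy near-white
background would scatter sub-threshold pixels that the closing step
then welds into spurious tissue.

Class palettes anchor every documented exemplar channel value
(MTS R 41/251, TTC 133-136-134 vs 187-69-61, PSR 240-129-143 vs
204-191-174, H&E green 174 vs 99); companion channels that no exemplar
pins down are synthetic, chosen in-palette for the stain.  Serial
stacks share one base section shape and vary the infarct disc radius
along a rise-and-fall half-sine profile by default, emulating an
infarct that grows and then shrinks from apex to base; the manifest is
filled with ground-truth pixel areas so closed-form volume oracles can
be checked against the image pipeline.

What the phantoms do **not** model: histological texture (fibers,
nuclei), staining gradients and batch variation, scanner vignetting,
compression artifacts, or partial-volume mixing at class boundaries.
Passing phantom tests therefore demonstrates that the rules, masks and
arithmetic are implemented correctly under the stated color model — not
that the default thresholds are optimal for any particular real slide
set.

## Validation problem sizes

The test suite and the acceptance script run on 256×320 phantom
sections (≈38 000 tissue pixels), 10 noise seeds per stain for noisy
recovery, a 20-section serial stack at h1 = 5 μm, h2 = 10 μm and
10 μm pixels, and strand densities 2.5%, 9.7% and 18.9% for fibrosis —
sizes at which every ground-truth recovery band (±1 percentage point
for infarct fraction, 5% for stack volume, ±0.5 points for fibrosis) is
meaningfully exercised while the whole suite runs in seconds.

## Known limitations

- Only horizontal-band slide splitting; no 2-D grid layouts.
- No anatomical compartmentation (LV/RV/septum); the distribution map
  is a plain grid over the tissue bounding box.
- The H&E rule's default green threshold (120) sits 2.6σ above the
  non-infarct exemplar green (99) at noise σ = 8, so ≈0.4% of viable
  pixels misclassify; negligible for section-level fractions (≈+0.3
  points at 25% infarct) but material when integrating very small
  infarct volumes over many sections, where threshold adjustment or a
  component-size filter is advisable.
- Thresholds are global per image; sections with strong staining
  gradients need per-image tuning, as with any global color threshold.
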
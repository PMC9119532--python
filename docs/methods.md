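# Methods

This note documents the measurement model, the synthetic-data generator,
the tunable parameters and the numerical choices behind `ectolayers`.

## Band coordinate system

The epithelium is treated as a band between two annotated polylines: the
apical border (toward the lumen) and the basal border (toward the stroma).
All layer logic runs in *relative depth*, `d = D_a / (D_a + D_b)`, the
ratio of Euclidean point-to-polyline distances. This definition is exact,
cheap, and independently checkable against brute-force point-to-segment
minimization; it is adequate for band-shaped tissue without folds, and
folded or overlapping tissue is explicitly out of scope. A geodesic depth
would differ for strongly curved bands but has no closed-form oracle.

The raster mask contains every pixel whose center lies in the closed
polygon bounded by the two polylines and the connecting end segments,
minus pixels lying exactly on the geometrically deeper polyline. The
half-open convention makes stacked bands tile without double counting and
makes the rectangle fixtures exact (a band between rows 10 and 110 spans
exactly 100 rows). Because the exclusion rule is applied to the lower
polyline regardless of labels, swapping apical and basal yields the same
mask (with a warning).

Thickness is measured with `n_probes = 200` normal rays cast from
arc-length-uniform points on the apical polyline to their first
intersection with the basal polyline; the reported thickness is the mean
over probes. Rays that miss are skipped (more than 50 % missing is an
error). A per-layer thickness is the layer's relative-depth width times
the mean probe length, so the four layers sum to the total by
construction. Whether the original microscopy workflow averaged along the
section or sampled representative positions is not documented anywhere we
know of; mean-of-dense-probes is this package's choice because it is
stable and has an analytic fixture.

## Layer segmentation

All layer decisions are made on depth-binned profiles (default
`n_bins = 50`), never per pixel, then broadcast back by depth: the layers
of a stratified epithelium are bands, and binning regularizes noisy
staining. Every positivity call is Otsu's threshold computed over
epithelium-mask pixels only — the method is parameter-free and equivariant
under positive rescaling of intensities, so coverage and relative heights
do not depend on acquisition gain. A constant channel is treated as
all-positive if nonzero (a band filling the whole depth) and all-negative
if zero. Every boundary call must hold for `persistence = 2` consecutive
bins to resist single-bin noise.

**Four-layer scheme (junction mesh).**

* `b1` (superficial → upper IM): shallowest depth where the net
  area-fraction per bin reaches `theta_net = 0.05`.
* `b3` (lower IM → parabasal): shallowest depth past `b1` where detected
  nucleus density reaches `theta_nuc = 2` times the median density of the
  deeper bins. Nuclei are local maxima of the Gaussian-smoothed nuclear
  channel above Otsu, with minimum separation half a nominal nucleus
  diameter (6 μm).
* `b2` (upper IM → lower IM): shallowest depth in `(b1, b3)` where the
  *intactness profile* reaches `theta_intact = 0.5 ×` its maximum. The
  intactness of a bin is the fraction of its area covered by closed mesh
  cells: connected components of mask-minus-net that do not touch the mask
  boundary and whose area lies within [0.1, 10] × the nominal cell area
  π(d/2)² for cell diameter d (default 15 μm). The relative threshold is
  deliberate — absolute closure rates depend on mesh geometry, while the
  broken/intact distinction is relative within a sample. Because closure
  ramps up over roughly one cell diameter at the transition, the call is
  refined by walking back (at most `persistence` bins) while the profile
  still exceeds half the calling threshold.

Undetectable boundaries collapse onto the adjacent boundary, leaving an
empty layer and a warning — e.g. an unfragmented mesh yields `b2 ≈ b1`
(empty upper IM), and an absent junction stain yields
`b1 = b2 = b3` with the whole non-parabasal epithelium labeled
superficial. Out-of-order boundaries raise.

The parabasal layer is defined here by nucleus density alone. An
alternative reading of the source workflow defines it by high-intensity
nuclear junction staining; which signal drove the original boundary is not
decidable from the available description, and only the density rule is
implemented.

**Three-layer scheme (marker band).** Per-bin Otsu-positive area fraction;
the marker-positive layer is the longest contiguous run of bins with
fraction ≥ `theta_band = 0.25`; the flanking layers are marker-negative.
Band edges are refined sub-bin from the edge bins' partial coverage
(otherwise they quantize to the 1/50 grid and drag marker-negative slices
into the band MFI). A sample whose stain never reaches the threshold, or
whose positive/negative separation is below `band_min_snr = 8` background
standard deviations (an all-noise channel thresholded by Otsu), is
recorded as a segmentation failure — never an exception — mirroring
per-stain quality exclusions in real cohorts.

E-cadherin MFI averages positive pixels only ("MFI of the positive
staining"); band MFI averages all pixels of the marker-positive layer,
and MFI/μm² divides by the layer's area. Both modes are exposed.

**CD4 quantification.** The positively stained area fraction is the
primary frequency readout (the standard proxy when single-cell
segmentation is impossible); connected components ≥ 10 μm² provide
centroids for per-layer proportions (component-counted by default,
area-weighted behind a config switch) and for the mean distance to the
apical border. A centroid exactly on a layer boundary belongs to the
deeper layer — an arbitrary but fixed and tested tie rule.

## Statistics

Mann–Whitney U is exact (scipy's enumeration) for pooled n ≤ 16 without
ties, otherwise normal approximation with tie and continuity corrections.
BH adjustment uses the statsmodels step-up implementation; note BH is not
idempotent (re-adjusting an adjusted vector can change it), so only the
step-up identity and monotonicity are asserted. The 2×k Freeman–Halton
test enumerates all first rows compatible with the margins (vectorized
log-hypergeometric probabilities, tolerance 1e-7 on the "no more probable
than observed" comparison); totals above 500 require the seeded Monte
Carlo mode. The 2×2 chi-squared applies the Yates correction by default,
which reproduces the printed two-decimal p of the study-population
regular-partner table (the uncorrected statistic does not). Spearman's p
is exact by full permutation enumeration for n ≤ 10. Confounder
adjustment by generalized linear models is intentionally not in the stats
core — the upstream description does not fix a family or link — and only a
documented hook (covariates carried in the sample sheet) exists.

## Synthetic scenes

The generator emulates what the analysis assumes, with exact bookkeeping:

* **Geometry** — a sinusoidal apical border (amplitude 10 μm, one period
  per image width, random phase) and a basal border offset along the local
  normal, so the band has constant true thickness; layer boundaries are
  the cumulative layer fractions of depth.
* **Junction mesh** — a Poisson-sampled Voronoi tessellation with mean
  cell diameter 15 μm (typical squamous epithelial cell). Edges whose
  midpoints lie above `b1` are absent; edges in the upper IM are deleted
  independently with probability `broken_fraction_upper`; deeper edges are
  kept. Kept edges are drawn 1.6 μm wide at intensity 8000 AU. The vector
  mesh (regions, edges, kept flags) is retained so closure rates can be
  computed without rasterization — the oracle for the intactness profile.
* **Nuclei** — Poisson-placed Gaussian spots (6 μm, 10⁴ AU) at
  12 / 1000 μm² in the parabasal zone and 1.5 / 1000 μm² elsewhere.
* **Marker band** — constant intensity over a configured relative-depth
  interval, so the true band MFI is the configured mean exactly.
* **CD4** — disk spots (radius 3.5 μm, 9000 AU) assigned to layers by the
  configured weights and placed with a minimum separation so components
  remain countable; crowded zones degrade to overlapping placement rather
  than dropping spots.
* **Noise** — additive Gaussian (σ = 150 AU) then Poisson resampling at
  scale 0.05, clipped at zero; one deterministic substream per channel, so
  toggling a channel never changes another.

Two scenarios encode the study arms as configured conditions:
`control_like` (layers 69 / 71 / 100 / 60 μm, band [0.51, 0.93] at 10⁴ AU,
fragmentation 0.5, CD4 weights 0 / 0.10 / 0.44 / 0.46) and `dmpa_like`
(36 / 86 / 110 / 65 μm, band [0.40, 0.96] at 6 × 10³ AU, fragmentation
0.65, CD4 weights 0 / 0.18 / 0.34 / 0.48). The superficial and upper-IM
heights, the totals, the band intensity ratio (6:10) and the CD4 IM
weights are the respective group medians; the lower-IM/parabasal split and
all rendering constants are free choices, fixed once at the values above.
Both arms use a clearly fragmented upper IM because that layer is *defined*
by a broken net; the arms differ in layer thicknesses, band intensity and
CD4 distribution, which is where the study's group differences live.
Scenes default to 512 × 512 px at 0.8 μm/px (≈ 410 × 410 μm), which holds
the 300 μm band with margin and keeps a full scene-plus-analysis cycle at
about two seconds — the recovery suites (20 seeds per arm) and the
fragmentation sweep (9 levels × 4 paired seeds) run in minutes.

**What the generator does not emulate:** optics (no PSF, vignetting or
chromatic shifts), 3-D structure, intensity gradients within layers,
irregular cell shapes and sizes, autofluorescence texture, annotation
error in the borders, and folded tissue. Passing recovery tests therefore
demonstrates the pipeline's correctness under its stated model — banded
tissue, mesh-like junction staining, Otsu-separable stains — not
robustness to every real-world artifact.

## Degenerate inputs and numerical conventions

Coordinates are 0-based (row, col) with pixel centers on integers; pixel
area is `um_per_px²`. Metrics are written with 6 significant digits;
integer rasters round-trip losslessly through TIFF. Undefined measurements
(empty layer, no CD4 components, no positive pixels) are NaN internally,
dropped from the metric table, and listed in the per-sample QC report;
a sample is only "aborted" when its inputs cannot be read. Group
comparisons require two samples per group and at least half the cohort
carrying the metric. Determinism: a cohort run is a pure function of
(inputs, config, seed); reruns are byte-identical.

## Known limitations

* Boundary recovery resolution is limited by the depth bin (0.02) plus
  about one mesh-cell diameter at the b2 transition; recovered upper-IM
  thickness carries a corresponding ±1-bin jitter.
* The Freeman–Halton enumeration is dense over the first-row lattice; for
  margins whose product exceeds ~5 × 10⁷ cells it refuses and points to
  the Monte Carlo mode.
* Area-fraction CD4 "frequency" is a proxy; touching cells are not split,
  so counts saturate at high densities (the generator's separation rule
  keeps the tested regime countable).
* The exact-permutation Spearman p enumerates n! permutations and is
  intended for n ≤ 10 only.
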
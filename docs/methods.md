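# Methods

This note documents what `vitreoct` computes, the assumptions behind each
stage, the defaults and why they were chosen, and what the synthetic
validation does and does not demonstrate.

## Scan model and calibration

A B-scan is an 8-bit grayscale cross-section, by default 1536 × 496 px
covering 3 mm laterally × 0.969 mm axially; an eye is a series of 61
B-scans with animal/side/group/sex/week metadata. The per-pixel area uses
the **square-pixel convention**: `(3000/1536 µm)² ≈ 3.815 µm²`, which makes
the total image area 2.906 mm². (Lateral × axial pitch would give
3.816 µm²; that alternative is available via `square_pixels=False`. The
square convention is the one consistent with the printed device
calibration.) Reduced-resolution profiles rescale the calibration with the
pixel grid, so areas stay in µm².

RGB inputs (AVI frames, PNG stacks) are converted to luminance with the
BT.601 weights 0.299/0.587/0.114 — the common video-export convention; the
conversion is the identity on already-gray frames. The bundled AVI codec
handles only uncompressed 24-bit DIB streams: it exists to make the video
round trip lossless and dependency-free, not to support arbitrary codecs.

## Layer segmentation

Segmentation is column-wise (per A-scan):

1. Intensities are median-filtered axially (window 5 px). A median, not a
   mean: at a noiseless intensity step the median-filtered crossing stays
   exactly on the step row, so planted flat layers are recovered without
   the half-window bias a boxcar would introduce.
2. The background level is estimated from the top rows (height/8 by
   default) as **median ± 1.4826·MAD**. Robust statistics matter here:
   in heavily infiltrated eyes the upper vitreous contains many bright
   cells, and a mean/SD estimate inflates until the retina itself falls
   below threshold.
3. A column's retina is the **longest run** of ≥ 3 consecutive samples
   above `background + 3·SD`; the run's first row is the ILM. The longest
   run (rather than the first crossing) makes the boundary immune to
   bright floaters above the ILM, which otherwise capture the first
   crossing and truncate the vitreous. `strategy="first"` restores the
   naive behaviour.
4. The RPE is the brightest band below `ILM + 20 px` (guard offset); its
   inner/outer boundaries sit where the smoothed intensity falls below
   background + half the peak elevation (full-width-half-maximum).
5. Failed columns are linearly interpolated from their neighbours and all
   boundary curves are median-filtered across columns (width 15), so every
   B-scan yields full-width masks. If no column segments, or the boundary
   ordering ILM < RPE is violated, the B-scan fails loudly with a
   `SegmentationError` (the pipeline records it and continues the series).

The vitreous mask is everything **strictly above** the ILM row; the RPE
mask is the closed band [inner, outer].

## VIT/RPE relative intensity

Per B-scan: mean grayscale over the vitreous mask divided by mean over the
RPE mask. Per eye: the arithmetic mean over the series' B-scans. The RPE
serves as an internal brightness reference, normalizing away device gain.

## Opacity detection

Per B-scan, on the grayscale image `I`:

1. **Edge emphasis.** Correlation with the 3×3 vertical-gradient kernel
   `[[1,2,1],[0,0,0],[−1,−2,−1]]` (edge-replicated borders) emphasizes
   horizontal edges; the response is rectified so bright-over-dark and
   dark-over-bright boundaries contribute alike.
2. **Otsu binarization.** A 256-bin Otsu threshold on the magnitude image;
   foreground is strictly greater than the threshold. For integer-valued
   images the bins are the exact gray levels, so the returned threshold
   induces precisely the partition the histogram optimized (and matches an
   exhaustive search over all 256 candidates); histogram ties — e.g. an
   empty gap between two modes — break to the midpoint of the tied
   candidates. A constant image returns the constant (empty foreground).
3. **Candidate regions.** The binary edge map is closed (radius-2 disk)
   and hole-filled: the gradient kernel marks a band around each region
   boundary, and closing bridges the weak response at near-vertical
   boundary segments. Components are labeled 8-connected (4-connected via
   config) after intersection with the vitreous mask.
4. **Denoising.** Each candidate's mean grayscale intensity must strictly
   exceed the **Tukey upper fence (Q3 + 1.5·IQR) of the vitreous pixel
   intensities** — an opacity must stand out from the speckle background.
   This is the background-referenced reading of "upper outliers of the
   intensity of the areas in the vitreous"; the alternative reading (fence
   over the region mean intensities themselves, with <4 regions → +∞) is
   available as `denoise_reference="regions"`, but it removes *every*
   region when the vitreous holds only genuine, similar-intensity cells,
   so the background reference is the default. The filter is applied once.
5. **Grayscale snap.** Edge responses localize an opacity but blur its
   outline, so each surviving candidate's footprint is re-derived from the
   grayscale image: threshold at the **geometric mean** of the vitreous
   background (median) and the candidate's mean intensity — the log-domain
   midpoint, where multiplicative speckle misclassifies background and
   opacity pixels at comparably tiny rates — keep the connected bright
   components touching the candidate, fill holes, and re-label the union.
   This merges split detections of one opacity and re-separates neighbours
   the closing had fused. Disable with `grayscale_snap=False` (then a 3×3
   erosion compensates the kernel's band dilation instead).

### Morphometry

Per region: `area = n_pixels × pixel_area`; mean intensity from the
grayscale under the region; second central moments of the pixel
coordinates with **+1/12 per-axis pixel-extent correction**, so a single
pixel is a well-defined circle. Eccentricity is `√(1 − λ₂/λ₁)` of the
moment eigenvalues (0 = circle, → 1 = segment); orientation is the
half-angle of the eigenvector, degrees in (−90°, 90°], counterclockwise
positive with image rows increasing downward (a horizontal elongation is
0°, a vertical one 90°); a perfectly circular region reports 0° by
convention. Areas map to soma classes with the boundary convention
[10, 50) / [50, 250] / (250, ∞) µm², `<10` isolated — a partition of the
positive reals.

## Per-eye summaries

Opacities are pooled over the series: mean count per B-scan, total area,
and per class count, percentage, mean area/intensity/eccentricity/
orientation (empty classes report missing means). Mean orientation is the
**arithmetic mean of signed degrees** — deliberately not a circular mean,
because cancellation of opposed orientations toward 0° is itself the
signal of interest (a dispersing population); the axial circular mean is
available via `circular_orientation=True`.

## Statistics stage

Thin, validated wrappers over scipy.stats: one-way ANOVA (`f_oneway`),
Tukey HSD (`tukey_hsd`), Pearson correlation (`pearsonr`), and
`alpha/m` Bonferroni. Normality screening is one-sample KS against a
normal with the sample's own mean and SD; since the parameters are
estimated, the p-value is **Monte-Carlo calibrated** (Lilliefors-style,
2000 fixed-seed simulations by default) rather than taken from the
classical KS null. The week-by-week report runs ANOVA + Tukey per metric
per week and attaches the Bonferroni per-test level over the ANOVA count.

## Synthetic generator

Scenes are layered: vitreous level 24, retina 110, RPE 230, sub-RPE 60
(8-bit), flat ILM at 40% height and an 8-px RPE band near 85% by default —
values are plumbing and fully configurable. Opacities are ellipses
rasterized by the pixel-center rule (boundary ties inside), placed by
rejection sampling with ≥3 px separation and margins inside the vitreous;
overlap or spill below the ILM is an error. Speckle is **multiplicative
unit-mean gamma noise** (shape 10 by default, i.e. ~32% intensity
contrast — a standard OCT speckle surrogate at moderate frame averaging);
ground truth (label masks, pixel counts, areas, intensities, continuous
*and rasterized-mask* moment descriptors) is recorded before noise.

Cohorts follow the study design: groups × sides × sexes × weeks
(0–24 weeks; controls at 0/12/24 only), with per-B-scan opacity counts of
**uniform 10–20 per B-scan in controls vs. Poisson mean 70 in glaucoma
groups**, and a glaucoma size mix holding ~45% of opacities in the
activated (50–250 µm²) range vs. a non-activated-dominated control mix.
No distributional forms for counts or sizes are reported for the real
data; uniform/Poisson counts and a log-uniform size draw within each class
interval are the package's choices, made once and exposed as
configuration. All randomness descends from a master seed through
`SeedSequence` spawn keys (group, eye, side, week, B-scan), so any single
image is regenerable in isolation and whole cohorts reproduce byte-for-byte.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline assumes — layered
anatomy, multiplicative speckle, compact bright opacities in the reported
count/size regimes. It does **not** model wave-optics speckle correlation,
motion/blink artifacts, vascular shadowing, optic-nerve-head geometry,
intensity gradients with depth, or textured/non-uniform cell interiors.
Passing recovery benchmarks therefore demonstrates the pipeline's
correctness and internal consistency under its stated assumptions, not its
accuracy on any particular device's in-vivo images.

## Validation design and problem sizes

Validation is by planted-truth recovery (the in-vivo data are available
only on request to the original authors, so no real-data values are
asserted):

- **Detection benchmark**: 12 half-resolution (248×768) speckled B-scans,
  20 opacities each of 10–80 px at ≥5× background contrast; matching by
  IoU > 0.3. Eccentricity recovery is scored against the planted
  *rasterized region's* moment eccentricity — for small regions the
  continuous ellipse parameter is not recoverable from the pixel grid even
  in principle (rasterizing a 30-px ellipse of eccentricity 0.38 can yield
  a mask of moment eccentricity 0.0), and area against the rasterized
  pixel count.
- **Class-mix recovery**: a noiseless 8-scan series at full lateral
  resolution planted 50/50 non-activated/activated.
- **Group separation**: ten cohorts (seeds fixed in the test suite) of
  10 eyes per group at the 384×124 reduced profile, 4 B-scans per eye,
  control 10–20 vs. Poisson-70 counts; ANOVA on per-eye mean counts.
- **Statistical calibration**: 10,000 null ANOVA simulations (3 groups of
  10) against the nominal 5% level.

The reduced profiles keep a full validation run under a minute on one CPU;
every study accepts the full 1536 × 496 geometry through its keyword
arguments.

## Known limitations

- Dim small opacities near the denoising fence (≈1.8× background at the
  default speckle) are genuinely ambiguous and account for the residual
  ~2% miss rate in the benchmark.
- Opacities separated by less than ~2 px may merge at detection; the
  generator's placement keeps planted regions resolvable by construction.
- No tracking of opacities across B-scans or weeks, no 3-D merging across
  adjacent B-scans, no optic-nerve-head exclusion; per-eye summaries treat
  the 61 B-scans as independent samples of the vitreous.
- The AVI reader supports the uncompressed export variant only; compressed
  videos must be converted upstream or supplied as image stacks.
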
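# Methods

`tonoquant` quantifies two aspects of vacuole biology in plant root
rhizodermis cells imaged with a membrane-localized (tonoplast) fluorescent
marker in a single confocal plane:

1. **Vacuome organization** — how far central-vacuole consolidation has
   progressed, measured per cell by the vacuolar morphology index (VMI) and
   the tonoplast topology index (TTI).
2. **Rapid tonoplast motility** — cytoplasmic-streaming-driven membrane
   movement on the seconds-to-minutes scale, measured per cell as the decay
   of the frame-to-first-frame pixel-intensity correlation coefficient R
   over a 120-s window.

Because these measurements are ordinarily validated only qualitatively, the
package ships a synthetic image generator with exact ground truth; every
pipeline stage is tested quantitatively against it.

## Morphometry

**Segmentation.** Within a rectangular cell ROI, the membrane signal is
thresholded (Otsu), morphologically closed (disk radius 2 px), and the
complement is labeled with 4-connectivity. Complement components containing
an ROI corner pixel are unenclosed cytoplasm/background and are dropped
(corners sit in plasma-membrane territory, outside any vacuolar
compartment); components below `min_area_px` (default 9 px, sub-diffraction
specks) are removed; components touching the ROI border are retained but
flagged, since the central vacuole abuts the cell edge in elongated cells.
A constant ROI yields an empty mask flagged degenerate.

**VMI.** The largest-area compartment is reduced to its convex hull (over
pixel-center coordinates) and measured as maximal Feret diameter times the
maximal extent perpendicular to that diameter, both converted to um; the
product (um^2) is the VMI, and its natural logarithm (`ln_vmi`) is used for
statistics, where it brings the right-skewed distribution closer to normal.
Extents are floored at one pixel so degenerate one-pixel-wide regions keep
a finite area. A plain largest-compartment-area variant is available via
`strategy="area"`. Higher VMI = larger nascent compartments = more advanced
consolidation.

**TTI.** A straight transect runs diagonally corner-to-corner across the
ROI (default top-left to bottom-right; `diagonal="both"` averages the two
diagonals), sampled at 0.5-px steps with bilinear interpolation. The
profile is segmented by a 3-class Otsu: the upper threshold isolates the
membrane, the lower one the vacuole lumen (2-class profiles fall back to
plain Otsu for both). A 2-class threshold is not sufficient here: on a
lumen/cytoplasm/membrane profile it splits the two dark classes and misses
the membrane entirely. Crossings are counted as two per lumen-deep gap
enclosed between two membrane runs that stay clear of the transect
endpoints. This equals naive membrane-run counting for every transversal
crossing, but (a) counts zero for a tangential graze of a membrane (one run
with cytoplasm on both sides), and (b) excludes anything touching a
transect endpoint as a plasma-membrane contact — together making the count
structurally even, as expected of closed membranes, and robust to noise.
TTI = crossings / transect length (um); higher TTI = more convoluted,
fragmented vacuome.

## Preprocessing for motility

The literal stage order is: global percentile contrast stretch to 8 bits
(default total saturated fraction 0.35%, the documented ImageJ default,
applied per frame — which also compensates bleaching), rigid-body
registration of every frame into the first frame's coordinates, rotation of
the field to orient the root vertically (user-supplied angle; exact
multiples of 90 degrees are lossless lattice permutations), per-cell ROI
cropping (cell length = ROI y-extent x pixel size), and a second per-ROI
contrast stretch. Correlation is computed on these 8-bit per-ROI images.

**Registration.** The rigid estimator searches translation + rotation by a
coarse rotation grid combined with subpixel phase correlation on a
downsampled pyramid level, then refines all three parameters by Nelder-Mead
on the masked mean-squared intensity difference; both sides are lightly
Gaussian-smoothed (sigma 1 px) during refinement, which suppresses the bias
of bilinear resampling. Accuracy on noiseless warps with |shift| <= 10 px
and |rotation| <= 10 deg is ~0.005 px / 0.005 deg, far inside the 0.5 px /
0.5 deg contract. Stacks are registered by propagating consecutive-frame
estimates (as recursive stack-registration tools do) and then refining each
cumulative transform directly against frame 0, which stops error
accumulation and makes re-registration a near-exact no-op.

## Motility

R(t) is the Pearson correlation between the (duplicated) first frame and
frame t of the preprocessed per-cell stack; `window_px="full"` (default)
correlates the whole pixel vectors, while an integer window tiles the ROI
into non-overlapping blocks, computes Pearson per block, and averages the
blocks with defined variance (zero-variance blocks are skipped rather than
counted as zero, so undefined correlations cannot bias the mean). The
endpoint `r_end` is R at the frame nearest the 120-s horizon
(configurable); shorter movies are flagged truncated. Group curves report
mean and SEM per time point. A kymograph helper renders position x time
images along an arbitrary segment.

## Synthetic data

The generator emulates a tonoplast marker in root atrichoblasts: rectangular
cells (width 100-140 px, length 180-410 px at 0.11 um/px, i.e. roughly
11-15 x 20-45 um) containing vacuolar compartments drawn as discs deformed
by a low-order radial harmonic, rendered as dark lumina (15 a.u.) bounded
by bright membranes (200 a.u., 2 px thick) in cytoplasm at 40 a.u., blurred
by a Gaussian PSF (sigma 1.2 px), with Poisson shot noise (6 photons per
intensity unit), Gaussian read noise (sigma 2.5), and exponential bleaching
(0.2%/frame). Presets: `consolidated` = 1-2 large compartments (62-88% of
the feasible radius), `fragmented` = 9-14 compartments of radius 12-22 px.
The fragmented preset is packed densely on purpose: a fragmented vacuome
tiles the optical section, and a diagonal transect must actually sample it.
Compartment packing is rejection-sampled with shrink-and-retry; infeasible
geometry raises an explicit `PackingError`.

Time-lapse movies (default 61 frames at 2 s = 0-120 s) displace each
compartment boundary along a smooth Gaussian process: a stationary unit GP
with a 3-frame temporal correlation length, modulated by a monotone
envelope `sqrt(1 - exp(-2t/tau))` (relaxation tau = 30 frames) and scaled
to saturate at `2.5 x membrane_speed` px. The envelope makes the RMS
displacement from the initial position grow monotonically — hence a
monotone R(t) decay — while keeping it bounded, so a grid of speeds maps
onto graded endpoint correlations instead of uniformly saturating at full
decorrelation. (An unbounded random walk was tried first and rejected for
exactly that reason.) Slow growth drift is applied as a cumulative rigid
transform per frame; compartments that would leave the cell are clamped and
counted. Ground truth exposes per-frame transforms, mean step and
cumulative boundary displacement, per-cell geometry, and per-frame lumen
label images.

What the generator does **not** emulate: 3-D sectioning effects, optically
dense cytoplasmic organelles, uneven illumination, directional cytoplasmic
streaming, membrane fusion/fission events, and cell-to-cell mechanical
coupling. Passing tests therefore validate the measurement chain
(geometry -> metric recovery, motion amplitude -> correlation decay,
drift -> registration), not the biological realism of any particular
recording.

## Statistics

Cells are pooled across all groups of an experiment and split at the median
length into "small" (below) and "large" (above); with an odd count the
median cell joins the class containing its closest neighbor by length, and
an exactly equidistant pair breaks toward "small" (deterministic,
documented). Between-group comparisons use Mann-Whitney U (exact
enumeration when the combined sample is <= 12 without ties — the feasible
enumeration bound — otherwise the tie-corrected normal approximation), with
Benjamini-Hochberg step-up FDR correction applied across the family of one
metric-by-stratification analysis (the caption-level correction scope).
Kruskal-Wallis (tie-corrected) with Dunn's mean-rank z post hoc
(BH-adjusted) serves multi-group designs; Welch's t-test (chosen over
pooled-variance as the safer default) and a type-II two-way ANOVA with
interaction serve the factorial motility designs. Significance bands:
`**` p <= 0.01, `*` 0.01 < p <= 0.05, `(*)` 0.05 < p < 0.1, `NS`
otherwise. `ln_vmi` is the tested VMI scale; TTI and r_end are tested raw.

## Problem sizes and numerical choices

The shipped validation suite uses: 40 cells per membrane speed x 61 frames
for the motility grid; 20 rigid warps plus a 5-frame re-registration check;
20 + 20 cells for preset discrimination; 100 cells for crossing-count
semantics and 20 noiseless cells for the 2x-resolution stability of the
group-mean TTI (crossing counts are integers, so individual near-tangent
cells can legitimately flip by one crossing between resolutions); 1,000
random vectors against a brute-force BH implementation; 2,000 null
replicates for the type-I calibration of the stratified comparison (12 + 12
cells, giving exact-branch Mann-Whitney in each stratum); and a 13-frame,
10-s-interval drifting movie for the registration-dependence check. Movies
are quantized to 16-bit on write; analysis runs on floats internally.

Known limitations: the VMI formula is an operationalization of "dimension
of the largest compartment" (Feret box), not a certified port of any
specific prior implementation; TTI reproduces the transect definition
only, without upstream filtering pipelines; rotation angles are
user-supplied (no automatic root-axis detection); registration assumes
rigid motion and a dominant static scene; no 3-D reconstruction, optical
flow, or particle tracking.
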
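# Methods

## The measurement model

roGFP is a ratiometric redox sensor: its two excitation bands shift
reciprocally with the oxidation state of an engineered disulfide, so the
two-photon excitation ratio R = F740/F910 increases with oxidation while
being invariant to expression level and optical path length. Given the
response-range calibration — the fully oxidized ratio R_ox, the fully
reduced ratio R_red, and the instrument factor IF = F910_ox/F910_red (an
optics- and wavelength-dependent constant) — the relative degree of
oxidation of the sensor pool is

    OxD = (R − R_red) / [ IF·(R_ox − R) + (R − R_red) ].

`redoxmap.calibration` implements this conversion, its exact algebraic
inverse R(OxD), and Monte-Carlo propagation of the calibration SDs
(independent normal draws of the triple, invalid draws rejected, median
and central 95 % interval reported; more than 50 % invalid draws is an
error). The conversion is evaluated outside [R_red, R_ox] without
clamping — out-of-range OxD values are screened later, not clipped, since
a clipped value would silently masquerade as a valid endpoint. For IF < 1
the denominator is positive for every R > 0; for IF > 1 it has a pole
above R_ox, beyond which NaN is returned as an undefined-value marker.

The reference calibration shipped as `DEFAULT_CALIBRATION` (R_ox = 0.916
± 0.106 over 76 cells, R_red = 0.408 ± 0.063 over 78 cells, IF = 0.497 ±
0.126) was measured in the CA1 pyramidal layer with the H2O2/DTT endpoint
protocol and, as in the original workflow, is applied to all brain
regions — a stated assumption, not re-derived per region.

## Forward fluorophore model (the generator's core)

The synthetic generator uses a linear two-state emission model: oxidized
and reduced sensor species emit with fixed coefficients (a_ox, a_red) in
the F740 channel and (b_ox, b_red) in F910, so a soma at oxidation x has
relative intensities a_ox·x + a_red·(1−x) and b_ox·x + b_red·(1−x). Any
calibration triple inverts exactly into such coefficients
(a_ox = R_ox·IF, a_red = R_red, b_ox = IF, b_red = 1, up to one overall
scale), and substituting the forward ratio into the OxD formula returns x
identically. This algebraic closure is the package's central oracle: the
test suite verifies the roundtrip to ≤1e−12 over a thousand random
models, and with all noise disabled the entire image pipeline reproduces
every cell's ground-truth OxD to ≤1e−6 (the residual being float
arithmetic, not model error).

## Image formation and noise

Somata are uniform disks (radius 6 px ± 10 %) placed by rejection
sampling with a no-overlap constraint (≥ 2 px separation; infeasible
packings raise rather than silently truncate). Per cell: ground-truth
OxD drawn from the group's normal truncated to [0.02, 0.98] — inside the
downstream 5–95 % screen, keeping the conversion well-conditioned — and a
unit-mean lognormal expression factor (σ = 0.3) so that ratios are
brightness-invariant but single-channel intensities are not. Channels are
blurred with a Gaussian PSF proxy (σ = 1 px), receive a diffuse neuropil
baseline (10 % of the photon scale, at the ratio of the group mean) and a
constant detector background (10 counts), then Poisson shot noise and
Gaussian read noise (SD 3), and are stored as 16-bit counts. The photon
scale (expected F910 counts of a unit-expression soma at OxD 0) defaults
to 2000; setting it to infinity disables all noise sources and yields
float images. Channels are generated pre-registered, matching optically
aligned excitation paths.

One integer seed expands into independent substreams (placement, OxD,
expression, noise), so toggling one source leaves the others' draws
unchanged, and identical scenario + seed reproduces identical bytes.

Defaults encode the study conditions: group OxD means follow the
measured slice-level baselines per region × genotype (WT vs heterozygous
MeCP2-deficient) × age (p50 vs >p100), with the cell-level values used
for the two groups that were reported per neuron (CA1 WT p50 0.466 ±
0.172; DG WT p50 0.719 ± 0.132) and a cell-level SD of 0.15 where only
slice-level spread was reported. The mCAT transgene is modelled purely as
a multiplicative suppression of the genotype OxD shift (`mcat_effect`,
1 = absent, 0 = shift abolished).

## Quantification

The ratio image is computed pixelwise with a validity mask: pixels whose
F910 falls below a floor (default: background mean + 3 SD, background
taken as the below-Otsu pixels) are excluded from every average. Before
ratio computation the quantification workflow subtracts each channel's
diffuse background level (median of non-soma pixels): without this, the
additive neuropil + offset component pulls soma ratios toward the
background ratio and inflates single-channel means — the instrument
factor estimate shifts by ~+0.05 otherwise. Somata are detected on the
F910 channel (smooth → threshold → connected components filtered by
equivalent radius, overlap resolved toward the larger blob,
deterministic ordering); ROI measurements use the core 75 % of the
detected radius to keep blur-mixed edge pixels out. The primary ROI
statistic is the mean of pixelwise ratios over valid pixels; the ratio of
channel means is carried as a QC cross-check and a >5 % disagreement
raises a flag, as do <50 % pixel validity and channel means within 2 % of
the detector maximum. A ROI with no valid pixel reports NaN with a flag,
never an exception. The ×1000 display rendering (12-bit indices, index 0
reserved for invalid pixels, values clipped to [1, 4095]) is
display-only and bit-isolated from quantification.

Calibration estimation averages endpoint ROI ratios; the instrument
factor uses matched per-cell F910 quotients when the two endpoint
recordings share cells (per-cell pairing cancels expression
heterogeneity; the endpoint generator shares geometry and expression
factors for exactly this reason), falling back to the quotient of means
with a delta-method SD for unmatched recordings.

## Screening and statistics

Pipeline order: intactness screen → ROUT → aggregation → tests. The
intactness screen keeps 0.05 ≤ OxD ≤ 0.95 (closed interval; undefined
OxD excluded with its own reason code); it runs before ROUT so the
outlier test operates on biologically plausible values. Both screens are
idempotent and every exclusion carries a reason.

ROUT is implemented for the constant (column) model: centre = median,
robust scale = 68.27th percentile of absolute residuals with the n/(n−1)
small-sample correction; each point's |residual|/scale gets a two-sided
t tail probability (n−1 df) and points are flagged by the
Benjamini–Hochberg step-up rule at Q = 1 %, examining at most the most
extreme 30 % of the sample. It is applied per (region, genotype, age)
column. Simulation shows a false-flag rate well under 2 % on clean
normal columns while a gross planted outlier is always caught. This
follows the published description of the method; the commercial
implementation is validated against behaviour, not bit-equality.

Aggregation is reported at two levels: per neuron, and slice-first (mean
of per-slice means, n = slices) — under unequal slice sizes the two
deliberately differ, and a regression test pins this.

Group comparisons use a two-way (genotype × age) ANOVA with sum-to-zero
coding and Type-III (marginal) sums of squares via statsmodels —
appropriate for the unbalanced cell counts — followed by all six
pairwise contrasts among the four design cells using t statistics on the
pooled residual variance. Holm–Šídák step-down adjustment: sort the k
raw p ascending, p_(i) → 1 − (1 − p_(i))^(k−i+1), enforce monotone
non-decreasing. Families are per region; no cross-region correction.
Markers: asterisks for age contrasts, crosshatches for genotype
contrasts (one symbol p < 0.05, two p < 0.01). Welch's unequal-variance
t-test with Satterthwaite df is used for the two-class correlative
comparison.

## Correlative stage

Live (F740/F910) and fixed (nuclear / immunolabel / structural) fields
are registered translation-only by cross-correlating binarised
bleach-mark masks (pixels below half the median intensity — the bleached
square sits at detector background while intact tissue fluoresces);
the peak within the search radius is exact to 1 px for integer shifts
and a peak-overlap confidence below 0.5 raises a registration error.
Nuclei are classified by a two-component Gaussian mixture on log mean
immunolabel intensity (Otsu fallback), with a ΔBIC(1→2) < 10 bimodality
warning for degenerate mosaics. Matching is greedy one-to-one nearest
neighbour after the offset, radius defaulting to one soma radius.

Because the fixed recording uses different optics, this stage compares
raw ratios, not OxD: every cell is divided by its slice's mean ratio over
MeCP2-positive cells. The default denominator is inclusive (each
positive cell enters its own denominator, so the within-slice positive
mean is exactly 1); a leave-one-out denominator is available, one of the
mechanisms that can make a pooled positive mean deviate slightly from 1.
Slices with fewer than 5 positive cells are excluded. The comparison is
gauge-invariant: rescaling all ratios of a slice changes nothing.

The correlative generator draws positive-cell ratios as base ratio ×
unit-mean lognormal (σ = 0.30, chosen so the normalised within-class SD
matches the ~0.31 observed for this preparation) and each deficient
cell as (effect × slice positive mean) × lognormal — the
deficient-vs-positive effect is multiplicative on the slice mean,
mirroring the normalisation the analysis applies. With the effect at
1.101 and 193 vs 110 cells the pipeline recovers the pooled deficient
mean to within ~0.01; note that at these group sizes and spreads the
Welch test has only ~55–60 % power at α = 0.01, so a two-crosshatch
outcome on any single simulated dataset is expected but not guaranteed.

## Problem sizes and reproduction

The recovery experiments in `scripts/acceptance.py` and the acceptance
tests use the study's group sizes directly (76/78 calibration cells, 110
and 142 neurons for the cell-level groups, 9 slices × 30 neurons for the
slice-level group, 193 + 110 correlative neurons over 6 slices), fields
of 256²–420² pixels with ~14–50 somata each, and average each reported
quantity over 10 seeds (20 for calibration recovery); a full run takes
well under a minute on one CPU.

## What the generator does not emulate

No optics beyond a Gaussian blur (no depth attenuation, scattering or
z-stacks; best-plane selection is collapsed to single-plane input), no
neurites or subcellular structure, no photobleaching or time courses
(calibration endpoints only), no fixation shrinkage or rotation
(registration is translation-only by design), and no antibody chemistry
beyond a two-class lognormal intensity contrast. Passing tests therefore
demonstrate the correctness of the analysis chain and its statistical
behaviour under a faithful photon-noise model — not robustness to every
artefact of real tissue, such as detection errors on overlapping or
dim cells, non-rigid deformation between live and fixed recordings, or
spatially structured background.

## Known limitations

- Automated blob detection replaces manual ROI placement; on real data
  with touching somata a watershed split or a ROI-list import
  (`measure_rois` accepts any ROI list) may be needed.
- The ROUT reduction to the constant model is behaviour-validated; exact
  numerical parity with proprietary implementations is not claimed.
- Mouse-level nesting is not modelled (slice-first aggregation stands in
  for a mixed-effects treatment, as in the original workflow).
- The X-inactivation clone model is a spatial nearest-seed partition;
  the true spatial granularity of cortical vs hippocampal mosaic patches
  is not quantified, so `clone_count` is a free parameter.
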
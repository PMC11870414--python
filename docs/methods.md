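# Methods

This note documents the models and procedures implemented in `imnpheno`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmarks do and do not demonstrate.

## The measurement problem

Cultures of induced motor neurons (iMN) made by direct conversion of
fibroblasts are morphologically heterogeneous: only a fraction of cells
acquire a neuronal phenotype (a small, bright, round cell body with
neurites), alongside flat non-converted cells and condensed dead cells.
Every downstream readout — neurite morphology, TDP-43 localization,
mitochondrial state, survival — therefore begins with finding,
segmenting and classifying single cells, and every per-cell statistic is
conditional on that classification. The package implements this chain as
composable library functions with a thin CLI, and pairs it with seeded
synthetic-microscopy generators whose ground truth is exactly what the
renderer drew, so each stage can be verified by recovery rather than by
eyeballing.

## Image analysis

**Detection.** Cell bodies are detected by optional grey opening (radius
2 px by default in the permissive candidate mode; removes 2-px-wide
neurites so a soma detaches from its arbor), Gaussian blurring
(σ = 2 px), Otsu or fixed thresholding, and size/roundness exclusion.
Circularity is `4πA/P²` with the Crofton perimeter estimate, which is
close to unbiased for discs down to ~7 px radius (the naive perimeter
estimator undershoots circularity by ~10% at soma scale). Default
exclusion bands: somata 20–400 µm², nuclei 20–250 µm², roundness ≥ 0.5;
candidate detection upstream of classification widens to 10–2000 µm² and
roundness ≥ 0.2 because large flat cells must reach the classifier.
All bands are config-exposed.

**Background subtraction** estimates the background as a grey opening
(disk radius 50 px default) of a smoothed copy of the image (σ = 4 px;
without smoothing the erosion tracks noise minima and the estimate is
biased low by several noise standard deviations) and subtracts it from
the original.

**Single-cell segmentation** is marker-controlled watershed: detected
cell bodies seed a flooding of the blurred intensity terrain restricted
to foreground (terrain ≥ Otsu threshold). Each seed yields exactly one
region; regions partition the foreground. For immunofluorescence the
terrain can be an enhanced-contrast (EQ) image: both channels are
histogram-equalized to [0, 1] (256 bins) and summed, which lifts dim
cytosolic signal into the terrain. Nuclei are paired to cells by maximal
pixel overlap; cells claimed by two nuclei are flagged.

**Classification** replaces a trained image classifier with a
deterministic morphology-feature rule set behind a pluggable interface
(crops in, labels out — any learned model honouring the contract can be
substituted). Features per centre-crop (128 px): soma area, Crofton
roundness, mean intensity, eccentricity, and attached skeleton length
outside the soma. Rules: iMN ⇔ soma 30–300 µm² ∧ roundness ≥ 0.7 ∧
attached skeleton ≥ 20 µm; dead ⇔ area < 40 µm² without neurites;
otherwise non-neuron. A small cell with neurites is iMN, not dead (the
neurite flag breaks the tie). Thresholds were calibrated on the
synthetic generator and are config-exposed; on default scenes the rules
give ≥ 0.9 precision and recall per class, which is what the benchmarks
assert — not that they transfer to any particular real stain.

## Morphometry

Cell masks are thinned to 1-px skeletons (scikit-image) and read as a
pixel graph: unit edges between 4-neighbours, √2 edges between diagonal
neighbours, with a diagonal edge dropped when an orthogonal pixel
already bridges the pair. Spurs shorter than 5 px hanging off a junction
are pruned as thinning artefacts. Neurite length sums edge lengths
outside the soma; branch points are clusters of degree-≥3 nodes outside
the soma (adjacent junction pixels merge — thinning splits Y-centres).
Digital length measured this way carries the classical digitization
bias: a straight segment at worst-case orientation (~22.5°) reads ~8%
long, and randomly oriented arbors average ~3–4% long. We keep the
plain √2 convention (it is the field's default and rotation-robust to
≤ 10%) and verify recovery as a mean over cells, which lands within 5%
of truth.

TDP-43 localization is the mean intensity over the nucleus versus the
cytosol (cell minus nucleus), reported as the cytosol/nucleus ratio.
Images are assumed background-subtracted upstream (no local ring
correction); a cell whose segmentation leaves no cytosolic pixels is
flagged invalid rather than silently dropped. The ratio is invariant to
detector gain by construction.

## Mitochondria

Within each cell, punctate TMRM signal is segmented by a white top-hat
(radius 5 px) followed by Otsu within the cell mask, minimum object size
2 px. Per cell we report the mitochondrion count, mean area (µm²), mean
per-mitochondrion TMRM, and the integrated TMRM over the whole cell
mask; aspect ratio is emitted as an extra shape descriptor. Measured
punctum intensities include the cytosolic haze and camera background the
renderer adds, and the ground truth records the rendered means, so
recovery is checked against truth (a programmed 2× group difference in
punctum brightness is recovered within 10%).

Motility is measured on kymographs: the neurite path is resampled at
1-px arc steps, each column is the maximum over a 5-px band normal to
the path, one column per frame (default acquisition 10 min at 0.33 Hz,
i.e. 198 frames at 0.1725 µm/px). Per-column peaks are linked by
nearest-position matching. The linking gate is expressed physically as
4 µm/frame: at 0.33 Hz and 40x a 1 µm/s mitochondrion moves ~3 µm
(~18 px) between frames, so any gate fixed at a few pixels would cut the
fastest biologically reported speeds; gaps up to 2 frames are bridged by
linear interpolation. A track is *motile* when its net displacement
reaches 2 µm over the recording (config-exposed; the threshold defines
the motile fraction). Average speed is segmental — the mean speed over
steps where the punctum actually moved (≥ 0.1 µm) — so pauses and
arrivals at the path end do not dilute it; maximum speed is the largest
single-step speed. Anterograde is increasing arc length from the marked
soma end of the path.

## Bioenergetics

Flux plates follow the four-segment schedule baseline → oligomycin →
FCCP → antimycin A + rotenone (+ 2-deoxy-D-glucose). Segment rates are
means that exclude the first post-injection measurement (a one-cycle
settle window; the synthetic plate deliberately renders that sample
mid-transition to keep the window honest). Non-mitochondrial OCR and
non-glycolytic ECAR (final segment) are subtracted from all OCR and ECAR
values; basal, ATP-linked (oligomycin-sensitive), maximal, spare
(maximal − basal) and basal ECAR follow; wells with any negative
corrected stage are discarded and logged, and surviving stages are
divided by the well's cell count. Subtraction precedes normalization;
the order only matters if per-well cell counts differ, and the
convention is stated here so results are comparable. The OCR/ECAR ratio
is taken on corrected basal rates and is scale-free.

PercevalHR traces (25 min at 0.2 Hz; oligomycin at 5 min, 2-DG at
15 min) are summarized as phase means of the 490/405 nm ratio over
[start, t₁), [t₁+settle, t₂), [t₂+settle, end], with a 2-sample (10 s)
settle window; samples with non-positive 405 nm signal are excluded, and
a phase losing more than half its samples is reported NaN and flagged.

## Survival analysis

**Tracking.** Detections (per-frame cell bodies with class labels) are
linked by greedy mutual nearest-neighbour matching within 20 µm, with
tracks surviving up to 1 missed frame. This is a deterministic stand-in
honouring the same contract as a learned multi-object tracker; the
plug-in point accepts any tracker producing identity-stable tracks.
A track ends at its last matched frame; bridged gaps are not deaths.

**Lifelines.** A cell enters the risk set the day it is first classified
iMN. Disappearance before the final frame is an observed death at the
last-seen day; survival to the final imaging day (D46 by default) is
censoring. Tracks never classified iMN are excluded and counted in QC.
Analysis is on the duration scale (time since entry); a left-truncation
mode is not implemented because entry is the natural time origin here.

**Statistics**, implemented from first principles and cross-checked
against `lifelines` in the test suite:

* Kaplan-Meier product-limit estimator
  S(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ);
* pairwise logrank tests — observed minus expected events under the
  pooled risk set, hypergeometric variance, χ² with 1 df, reported raw
  and Bonferroni-adjusted over all pairs;
* Cox proportional hazards by Newton-Raphson maximization of the
  partial likelihood with the **Efron** correction for ties (the 2-day
  imaging grid produces heavily tied death times, where Breslow is
  visibly biased), standard errors from the inverse observed
  information, Wald CIs as logHR ± 1.96·SE. Convergence: gradient
  max-norm < 1e-8, or a machine-precision plateau (step and
  log-likelihood change < 1e-10), within 100 iterations. Monotone
  likelihoods (perfect separation) are detected by coefficient
  divergence and raised as errors naming the covariate.

Group effects enter as indicator covariates against a reference group
(alphabetically first by default). Sampling of lifelines per group
(default 500, or all available if fewer) is uniform without replacement
and seed-reproducible.

## Synthetic data: what it emulates, and what it does not

The generators draw every random quantity from one seeded
`numpy.random.Generator`, so identical spec + seed is bit-identical.
Scenes render three morphological classes on a constant background with
additive Gaussian noise: iMN (Gaussian-profile soma disc, radius 5 µm;
two neurite trees of 40 µm total arc each, 2 px wide, recursive
branching with an exact length budget), non-neurons (ellipses 15×6 µm
half-axes, dimmer), dead cells (2.5 µm bright discs). Channels: nuclei,
eGFP, TMRM (puncta inside the soma), TDP-43 (nucleus at full level,
cytosol at the programmed ratio). Pixel sizes follow the imaging modes
used for each assay: 0.69 (10x, viability), 0.345 (20x, neurites),
0.1725 µm/px (40x, mitochondria).

Ground truth records exactly what was rendered — polyline arc lengths,
branch events and their coordinates, punctum pixel areas and rendered
mean intensities — so recovery tests measure the analysis, not the
renderer. Neurite trees steer around other cell bodies and around all
previously grown arbors (a shared spatial hash of waypoints with 1.8 µm
clearance, sampled at half-segment spacing, lagging two steps behind
each growing tip): overlapping arms would merge in the rendered mask
and silently corrupt both the mask-derived truth and the skeleton
topology. Deflections are limited to ±70°; a rare fully-blocked step
proceeds and costs a few erased pixels (masks of different cells are
kept disjoint) rather than a false branch point. Field densities
default to 50 cells per 353 µm field with ≥ 22 µm centre separation —
chosen so cells are separable, which the culture protocols also aim
for; denser fields degrade classification gracefully but are not part
of the stated conditions.

Time-lapses use the D12–D46 every-second-day schedule (18 frames).
Death times are exponential per cell with the movie's hazard (events per
day); a dead cell's pixels vanish from all later frames. Cells drift as
a 0.5 µm/frame random walk and are omitted from a frame with 5% dropout
probability to emulate transient detection failures. One movie carries
one hazard; grouped designs render one movie per group, because group
identity cannot be carried through an image-only analysis otherwise.

What passing these benchmarks shows: the chain of operators recovers
programmed quantities through realistic amounts of noise, crowding,
drift, dropout and censoring. What it does not show: performance on real
micrographs — uneven illumination, overlapping cells, debris, focus
drift, staining variability and photobleaching are deliberately absent,
and the rule-based classifier encodes the generator's morphology rather
than learned appearance. The pluggable classifier/tracker interfaces are
where learned models would enter for real data.

## Benchmark problem sizes

The acceptance benchmarks run: 200 random ≤8-subject datasets for the
Cox brute-force cross-check; 20 replicates of n = 500/group for Cox
recovery at HR 2; 1000 null replicates of n = 200/group for logrank
calibration; 20 rendered two-group movies of 40 iMN per group for the
end-to-end chain; 10 default 50-cell scenes for classification; ~50
noiseless cells for morphometry; 24 cells across two intensity groups
for mitochondria. These sizes give binomial/Monte-Carlo tolerances well
inside the asserted bounds while keeping a full run in minutes on one
core.

## Known limitations

* The greedy nearest-neighbour tracker has no motion model; it is
  adequate for near-stationary cells (which these cultures are) and
  will switch identities for fast-crossing objects.
* Digital skeleton length carries the +3–4% average digitization bias
  discussed above; comparisons between groups measured identically are
  unaffected.
* Watershed boundaries on flat intensity plateaus follow flood order
  rather than geodesic midpoints; with realistic intensity saddles the
  boundary lands on the ridge.
* The Cox implementation covers right-censoring, tied times and fixed
  covariates only — no time-varying covariates, strata or frailties.
* Flux QC discards whole wells (not single measurements) when any
  corrected stage is negative; with very noisy plates this is
  conservative.
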
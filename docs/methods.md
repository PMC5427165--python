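# Methods

## The analysis model

The pipeline analyses a cell-based reporter screen in which each well's
read-out is (a) the number of analyzable cells and (b) the mean per-cell
cytoplasmic fluorescence of two reporters (mCherry, YFP) fused to APP.
Silencing a gene that modulates APP metabolism shifts the reporter levels
multiplicatively, so the unit of analysis is the fold-change of a well's
mean intensity against the non-targeting (NT) control wells on the same
plate, taken in log₂. All stages assume:

* intensities are positive and effects multiplicative (hence log-normal
  noise and log₂ analysis);
* plate-to-plate variation is a common multiplicative factor per plate and
  channel, which within-plate NT normalization removes exactly;
* one well per gene per replicate, with the same plate layout across
  replicates.

## Stage by stage

**Quality control.** For each plate–replicate the strictly standardized
mean difference SSMD = (μ₁ − μ₂)/√(σ₁² + σ₂²) (unbiased variances, sign
preserved) is computed between each positive-control group and the NT
group, per channel, on raw well means (pre-normalization, so control
separation is judged on what the instrument measured). The plate passes
when |SSMD| ≥ 3 for **both** controls on the mCherry channel; the channel
set is configurable, and mCherry-only is the default because it is the main
read-out (YFP turns over quickly at the membrane and detects down-shifts
poorly). The magnitude is compared, not the signed value, because the two
controls shift the reporters in opposite directions. Degenerate input
(both groups constant) raises a distinct undefined-SSMD error rather than
returning ±∞. A plate failing QC excludes that plate–replicate's wells
only; the gene keeps its other replicates.

**Filtering.** A well is included iff its analyzable cell count is
≥ `min_cells` (default 300; the boundary count 300 is included) and its
plate–replicate passed QC. Raising `min_cells` can only shrink the
included set (tested as a property).

**Normalization.** Per plate–replicate and channel, fc = well mean /
arithmetic mean of included NT well means. NT wells receive fold-changes
too, so their mean fc is exactly 1 — a self-consistency invariant the
tests assert. A plate with included sample wells but no usable NT wells is
an error; a fully excluded plate is skipped.

**Aggregation and hit calling.** Per gene, log₂ fc per replicate, then the
mean and unbiased SD across the included replicates (log-then-average, the
geometric-mean convention — averaging linear fold-changes first and then
taking the log is deliberately not done). Genes with fewer than
`min_replicates` (default 2 of 3) included replicates are dropped into a
report, not an exception. Hits are quota-selected: with N scored genes and
tail fraction f (default 0.025), the ⌊fN⌋ lowest mean log₂ fc are "down"
hits and the ⌊fN⌋ highest "up" hits — exactly 2⌊fN⌋ hits for every N, with
lexicographic gene-id tie-breaks so the selection is deterministic and
permutation-invariant. Floor rounding is used because it is the rounding
rule consistent with a 5% quota at genome scale. Replicate robustness is
reported as the SD of the linear fold-changes × 100 ("percent of the NT
level"), overall and among hits, with a 25%-exceedance count.

**Genetics cross-reference.** Hit genes are intersected (exact id match
after upper-casing, set semantics) with a GWAS-locus gene list. The
per-gene association summary — lead SNP, effect on standardized log CSF
Aβ42, p-value — is filtered at the gene-wide Bonferroni threshold α/m with
m = number of candidate genes tested; the exact threshold (0.05/8 =
0.00625) is used for the strict comparison p < α/m and displayed rounded
to three decimals (0.006). The association regressions themselves are out
of scope: the package consumes summary tables, never cohort genotypes. The
packaged eight-gene table is the published candidate set; its third gene is
recorded under the symbol PVRIG (alias MGC2463).

## Synthetic data

**Intensity-level screen simulator.** Well intensity = baseline ×
2^(gene log₂ effect) × plate factor × well noise, per channel; plate factor
and well noise are unit-mean log-normal with CVs `plate_effect_cv` (0.05)
and `well_noise_cv` (0.1). Defaults: 384-well plates, 3 replicates,
14 NT + 14 siAPP + 14 siPSEN1 control wells per plate at the left-edge
columns (cycled so no control owns a column), genes filling the remaining
342 wells in column-major order, fixed across replicates. Control effect
factors default to 0.4×/0.4× (siAPP; silencing the reporter construct
suppresses both channels) and 2.2×/1.9× (siPSEN1; blocking γ-secretase
accumulates intracellular fragments). These values put the expected plate
SSMD around 5 — roughly 2.5 estimator-SDs above the pass threshold with
n = 14 wells per group — giving the ~98–99% plate pass rate typical of a
well-calibrated screen; weaker controls (expected SSMD ≈ 3–4) would fail
QC spuriously on ~10–20% of plates purely from SSMD estimator noise.
The effect-panel sampler assigns a configurable fraction of genes
(default 5%) a true log₂ effect of fixed magnitude (default 1.0), split
evenly between up- and down-regulation as in a two-tailed screen design;
YFP effects are the mCherry effects scaled by 0.6 (the YFP reporter
responds more weakly).

**Cell counts.** Per-well analyzable cell counts follow a normal
distribution truncated at zero whose *observed* mean and SD are calibrated
to 795 and 345 cells — the underlying location/scale are solved
numerically from the truncated-moment equations, because plugging the
targets in directly would inflate the observed mean ~1.2% through
truncation. At these parameters ~7.6% of wells fall below the 300-cell
floor, which is the dominant source of gene attrition in simulated runs.

**Image simulator.** Each cell is a circular nucleus (radius 6 px) with a
concentric annular cytoplasm (outer radius 13 px) carrying a uniform true
reporter intensity; per-cell intensities are log-normal around the well
mean with CV 0.3, pixel noise is additive Gaussian (clipped at zero), and
background is a per-channel constant. Placement is rejection sampling on a
spatial hash with centres ≥ 2 × cytoplasm radius apart, so ground-truth
masks are disjoint and exact; count draws are capped at a 45% disc-area
packing fraction (≈ 888 cells at the default geometry), below the ~54.7%
jamming density where sequential placement stalls. The geometry was chosen
so the calibrated mean of 795 cells fits in the default 1024 × 1024 field.
Not emulated: point-spread functions, shot noise, illumination gradients,
autofluorescence, cell-shape variation, overlapping/mitotic cells. Passing
the recovery tests therefore shows the estimators are unbiased and
well-conditioned on clean geometry, not that segmentation is robust to
real-microscopy artifacts.

## Numerical and design choices

* **Cytoplasm ring.** The measured cytoplasm is `expand(nuclei, margin +
  width) − expand(nuclei, margin)` with a 1-px inner guard margin and 4-px
  width. The guard margin keeps nucleus-boundary pixels (whose assignment
  is uncertain by ±1 px after thresholding) out of the cytoplasmic mean,
  and margin + width ≤ the true annulus width, so on well-segmented cells
  every measured pixel carries genuine cytoplasmic signal. This is what
  makes ≤2% per-cell intensity error achievable; a wider ring grown flush
  from the nucleus spills into zero-signal territory and biases means by
  10–20% at this cell scale.
* **Background.** Median of non-cell pixels, per channel per image —
  robust, and it makes the per-well means exactly invariant to a uniform
  additive offset and equivariant to channel scaling (both tested).
* **Per-well intensity** is the unweighted mean of per-cell means (not
  area-weighted): the read-out is defined per cell.
* **Border cells** are excluded by default (their cytoplasm is clipped and
  would bias means); configurable.
* **Watershed seeding** uses distance-transform peaks with a 7-px minimum
  separation — at the default nucleus radius a single disc yields one
  peak, while tangent discs yield two (both constructed in tests).
* **Determinism.** All randomness flows through `numpy.random.Generator`
  seeded from a single integer; the pipeline derives independent stream
  seeds via `SeedSequence`. Outputs are plain CSV/JSON and the run manifest
  stores SHA-256 digests, so end-to-end byte-identity under a fixed seed is
  an asserted property.

## Problem sizes used in the checks

Published-scale checks run at the scale the numbers require (16,653 genes
for the 832-hit quota — 49 plates × 3 replicates, seconds at the intensity
level). Recovery and recall studies use 2,000-gene screens over 20 seeds,
and image-accuracy studies 20 full-scale wells (roughly 795 cells each),
which bound count error ≤ 5% and per-cell intensity error ≤ 2% at default
noise.

## Known limitations

* Quota hit calling fixes the hit count by construction; it makes no error
  control claim (no FDR/p-values), mirroring the screen design it models.
* Empirical constants of the original screen (plate pass rate, attrition
  counts, replicate-SD summaries, per-gene fold-changes in the packaged
  association table's screen columns) are properties of undeposited data;
  the suite asserts the analytic properties those summaries rely on
  instead of the constants themselves.
* The simulators model no spatial plate artifacts (edge effects,
  gradients), consistent with a pipeline that applies no spatial
  correction.
* Gene-to-well assignment is fixed across replicates; replicate
  randomization is not modelled.
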
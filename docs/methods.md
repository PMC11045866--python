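# Methods

mucoflow quantifies how dietary fiber, the gut microbial community and
colonic mucus function relate to each other, starting from tabular data:
metabolic panels, ASV count tables with a phylogeny, bead coordinate
clouds, timed thickness measurements, assay plates and metabolite peak
tables. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Composite donor ranking

Donor selection for microbiota transplantation aggregates three rankings:

1. **Metabolic.** For each of six parameters (waist-to-hip ratio, BMI,
   free fat mass, total cholesterol, triglycerides, fasting glucose) the
   improvement is `direction x (pre - post)`, ranked descending (rank 1 =
   largest improvement, ties share the mean rank). The six ranks are
   combined by their mean (Borda count). Mean rank was chosen over sum
   (equivalent ordering) or median to keep a single auditable rule.
2. **Microbiota shift.** Among the top `top_metabolic` (default 10)
   responders, the paired pre/post community dissimilarity is computed
   twice - Bray-Curtis and weighted UniFrac - each ranked descending and
   combined by mean rank.
3. **Overall.** The metabolic rank re-ranked within the eligible set and
   the gut rank are averaged; the best `n_donors` (default 5) are
   selected. Remaining ties break lexicographically on (metabolic rank,
   participant id), which is deterministic and recorded in the audit
   table.

Improvement directions: a decrease is an improvement for waist-to-hip
ratio, BMI, cholesterol, triglycerides and glucose; an increase is an
improvement for free fat mass (read as fat-free mass). Because "free fat
mass" is ambiguous in the field, the direction map is a configurable
input with this documented default rather than a hard-coded constant.
Improvement is measured as the raw delta by default; a
percent-of-baseline flag exists because rank aggregation is invariant to
strictly monotone per-criterion transforms only within a criterion, not
across participants with different baselines.

## Beta diversity

Bray-Curtis: `sum|x_i - y_i| / sum(x_i + y_i)` on raw counts (the formula
is invariant to rescaling both vectors; a proportions-first flag exists
for parity with other tools).

Weighted UniFrac is computed in one post-order traversal. For each branch
`i` with length `b_i`, `p_i` is the fraction of the sample's total
abundance descending through the branch; the distance is

    sum_i b_i |p_i^x - p_i^y|  /  sum_i b_i (p_i^x + p_i^y)

This is the proportion-weighted, normalized form (the alpha = 1 member of
the generalized-UniFrac family); it lies in [0, 1], is symmetric, and is
invariant to total-count rescaling of either sample. The raw
(unnormalized) numerator is available behind `normalized=False`, and the
choice is recorded in the pipeline manifest. Newick input must be rooted:
a root with other than two children is treated as unrooted and rejected
with the advice to midpoint-root externally - rooting is deliberately not
re-invented here. Internal multifurcations are accepted. Tree leaves not
present in the table carry zero mass; table taxa missing from the tree
are an error.

## Compositional 16S post-processing

Processing starts from an integer feature table (denoising and taxonomy
assignment are out of scope).

* **Low-abundance filter**: keep a taxon iff it is present (count > 0) in
  at least `min_samples` (default 2) samples *and* its total count is at
  least `min_total` (default 10). The natural-language form of this rule
  is grammatically ambiguous; this conjunction is the standard reading,
  and both thresholds are parameters so the other reading is one flag
  away. The filter is idempotent.
* **Relative abundance**: per-sample division by the sample total.
* **CLR**: `log(x_i + c) - mean_j log(x_j + c)` with additive pseudocount
  `c = 1` on counts (zero handling is not standardized in the field; the
  pseudocount is a parameter). Rows sum to zero by construction.
* **Alpha diversity**: observed taxa and Shannon index in natural log
  (the base is a convention; nats are the default here).
* **Rarefaction**: multivariate hypergeometric subsampling (without
  replacement) to a caller-chosen depth - the appropriate depth depends
  on the sequencing run, so it is a required parameter. Deterministic
  under the given seed.
* **Core genera**: a genus is core to a group when detected (strictly
  positive) in at least the given prevalence fraction (e.g. 25 % or 80 %)
  of the group's samples. Detection uses no abundance floor; the
  threshold is parameterized. Cores are nested by prevalence.
* **Group-max normalization**: per genus, group mean abundances are
  scaled so the highest group reads 100 %. An all-zero genus is reported
  as undefined (NaN), never as 0/0 = 0.

## Mucus function

**Growth rate.** Thickness is measured at five sites per explant at 0 and
45 minutes; each timepoint is averaged over sites and the rate is the
difference divided by the elapsed time (um/min). Healthy mouse colon
grows at roughly 2 um/min, which the default synthetic "chow" group
reproduces.

**Penetrability.** Each bead contributes its vertical distance
`z - h(x, y)` to the epithelial height field (constant, plane, or
linearly interpolated grid). Vertical distance matches z-stack
acquisition geometry; 3D nearest-point distance is out of scope. The
mucus surface is the center of the modal 5-um bin of the distance
histogram - beads sediment onto the impenetrable surface, so the densest
band marks the luminal boundary. The default bin width equals the
confocal z-step (5 um); ties between equally tall bins break toward the
lumen so a surface accumulation beats a crypt-floor artifact. Beads
below the epithelium (negative distance) and above the detected surface
(excess, unwashed) are excluded from the denominator and counted in QC
fields. The summary statistic is the fraction of in-mucus beads within
10 um of the epithelium, averaged over a mouse's images (2-3 per mouse);
pooled distance distributions are summarized as median and quartiles
with the linear-interpolation convention.

Whether the 10-um fraction denominator should include beads resting on
the mucus surface is not settled; this implementation excludes them (the
in-mucus denominator) and the generators' ground truth is defined over
penetrating beads for the same reason.

## Assay quantification

Standard curves are ordinary least squares on (concentration, signal) or
(log10 copies, Cq) pairs, requiring at least 4 points and 3 distinct
x values; r^2 is reported, and a constant response yields slope 0 with
undefined r^2 rather than an error. Enzyme activity inverts the curve on
the mean of duplicate signals and divides by incubation time (default
45 min) and protein mass, in uM min^-1 mg^-1; a signal below the blank is
floored at zero activity with a QC flag instead of reporting negative
release. Per-mouse enzyme shares divide each activity by the mouse's
total (undefined for an all-zero mouse). qPCR copy number is
`10^((Cq - intercept)/slope)` rescaled to a 10 ng RNA reporting basis.
CFU/g multiplies colonies by dilution factor over plated volume, times
suspension volume over sample mass; zero colonies are reported at the
limit of detection and flagged censored. All CFU factors are explicit
parameters because suspension conventions vary between labs.

Metabolomics preprocessing: peak areas are divided by sample weight,
missing values are imputed per metabolite at 20 % of its minimum positive
value (LOD imputation), then log10-transformed (the log base is a
convention). The two-group significance screen requires both a
fold-change of at least 1.5 (or at most 1/1.5) on weight-normalized,
unlogged group means - the common metabolomics convention - and a
two-sided exact Mann-Whitney p below 0.05.

## Exact small-sample statistics

Group sizes of 4-10 dominate the downstream comparisons, so the tests
are exact where feasible:

* **Mann-Whitney U**: U from rank sums with mid-ranks. With no ties and
  n1 + n2 <= 30, the null distribution of U is enumerated by dynamic
  programming over rank subsets (the counts sum to C(n1+n2, n1), which is
  asserted in tests); the two-sided p is `min(1, 2 x min tail)`. This
  convention reproduces the canonical exact-value series for n = 4 vs 6:
  p = 0.0095, 0.0190, 0.0381, 0.0667, 0.1143 at U = 0..4. Ties or larger
  samples fall back to the normal approximation with tie and continuity
  correction, flagged `exact=False`. Whether a continuity correction is
  applied in approximate mode varies between packages; the flag records
  the choice here.
* **Wilcoxon signed-rank**: zero differences dropped; exact enumeration
  of the 2^n sign assignments (via the generating function of rank
  subset sums) for tie-free |differences| with n <= 25.
* **Spearman**: Pearson correlation of mid-ranks; exact permutation p
  for n <= 9 (full n! enumeration), otherwise the t approximation with
  n - 2 degrees of freedom. Constant input yields an undefined (NaN)
  correlation rather than a spurious value.
* **Benjamini-Hochberg**: classic step-up, returned in input order,
  capped at 1.
* **Taxon-phenotype screen**: the top-n (default 30) taxa by mean
  relative abundance are Spearman-correlated with the phenotype (on CLR
  or relative values) and BH-adjusted across the screen.

The exact Mann-Whitney test is conservative at nominal 0.05 due to
discreteness; the calibration test and the acceptance script verify the
empirical type-I error at (4, 6) over 10,000 null draws.

## Synthetic-data generators

One global seed drives a fixed registry of per-generator seed streams, so
adding a generator never changes another's output, and identical
configurations are bit-identical. `noise_sd` is a single relative noise
dial scaled by each measurement's natural magnitude (baseline value,
typical thickness of 100 um, full-scale assay signal); setting it to zero
silences every generator, and null configurations (zero effect, zero
shift, zero noise) propagate to exactly-zero downstream estimates.

Default study conditions: 67 participants with 5 planted responders;
responder improvement 10 % of baseline against 5 % relative noise (a
2-sigma effect per criterion); 60 taxa at sequencing depth 10,000 with 8
samples per group; community shift scale 0.5 with responders shifting
2x; bead images of 750 beads with a 120-um mucus surface; growth rates
2.0 (chow) vs 1.0 (WSD) um/min.

* **Cohort**: responders improve by `responder_effect x baseline` in the
  per-parameter improvement direction plus noise; non-responders get
  zero-mean noise. Baselines are plausible middle-aged values, clipped
  at 20 % of the mean so physiological quantities stay positive.
* **Paired communities**: a random rooted bifurcating tree with
  exponential branch lengths; shared log-normal baseline intensities with
  individual jitter; the post sample displaces the log-intensity vector
  by a random direction of *fixed* norm `s x sqrt(n_taxa)` with
  `s = shift_scale x (1 + bonus)` for responders - the displacement is
  exactly proportional to the planted shift, not merely in expectation.
  Counts are Poisson draws of the intensity proportions, so tables are
  integer-valued like real ASV tables. A participant with zero
  displacement re-emits identical pre counts (a re-measurement of the
  same community), so the null propagates exactly.
* **Bead clouds**: a gently tilted plane epithelium; bead height follows
  an exponential(`bead_lambda`) law truncated at the mucus surface, mixed
  with a dense mode just below the surface where washed-on beads
  accumulate. The surface-mode weight (default 0.30) is chosen so the
  surface accumulation is the densest 5-um band, which is the premise of
  the mode-based surface definition; at much lower weights the first
  near-epithelium bin of the exponential law can win the mode and the
  surface estimate collapses to the epithelium. Ground truth records the
  realized fraction of penetrating (non-surface-mode) beads within
  10 um - exactly the estimand of the penetrability routine.
  `bead_lambda_for_fraction` inverts the truncated-exponential CDF to
  plant a target fraction.
* **Mucus experiment**: 5 sites x 2 timepoints per mouse;
  `thickness(45) = thickness(0) + 45 x rate + noise`.
* **Assay plates**: a 7-step serial two-fold dilution plus blank with a
  linear signal model, and duplicate unknown wells encoding planted
  activities.
* **Metabolite tables**: two groups with planted fold changes on a subset
  of metabolites, peak area = concentration x sample weight (so weight
  normalization recovers the planted structure), log-normal noise and
  completely-at-random missingness.

What the generators do **not** emulate: sequencing error and read-level
noise, compositional closure artifacts beyond Poisson sampling,
phylogenetic signal in abundances (taxa are exchangeable on the tree),
spatial bead clustering, batch effects, and informative missingness in
metabolomics. Passing recovery tests therefore demonstrates that the
estimators are correct and well-calibrated under clean, known-truth
conditions - not that they are robust to every artifact of real data.

## Problem sizes and numerical choices

The test suite and the acceptance script use 100-replicate recovery runs
(donor selection on 67 participants; penetrability at 3 images x 750
beads), 10,000 null draws for type-I calibration, and 100 permutations
for the false-discovery screen - sizes at which the Monte-Carlo error of
each rate is well below the margin being asserted. Exact-test
enumeration bounds (Mann-Whitney n1 + n2 <= 30, Wilcoxon n <= 25,
Spearman n <= 9) keep the exact path memory- and time-bounded; beyond
them the flagged approximations are accurate to well under the
tolerances used anywhere in the pipeline.

## Known limitations

* The weighted UniFrac normalization variant differs between published
  tools; results are comparable across variants only qualitatively, which
  is why the variant is stamped into output metadata.
* The mode-based mucus surface is biased by up to half a bin width and
  assumes the surface accumulation dominates the histogram; for sparse
  bead preparations supply the surface z-position directly.
* Exact tests refuse no input, but with heavy ties their approximate
  p-values inherit the usual mid-rank caveats.
* The donor-selection rule fixes the combination to mean rank; other
  aggregation schemes (median rank, weighted Borda) can change the
  selected set when criteria disagree strongly.
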
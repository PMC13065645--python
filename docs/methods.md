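# Methods

## Problem setting

Philadelphia-negative MPN (polycythemia vera, essential thrombocythemia,
primary myelofibrosis) are clonal disorders of bone-marrow (BM)
hematopoiesis driven by JAK2/CALR/MPL mutations, monitored through the
variant allele frequency (VAF) of those drivers.  Routine monitoring uses
genomic DNA (gDNA) from peripheral-blood (PB) nucleated cells, which
under-represents the marrow clone whenever PB composition shifts — most
visibly when lymphocytes, which do not carry the myeloid clone, make up a
large share of the differential.  Plasma cell-free DNA (cfDNA) is released
substantially by marrow-resident cells and offers a complementary readout.
`marrowtrace` implements the quantitative machinery for this comparison:
tissue-of-origin deconvolution to establish where each analyte's DNA comes
from, paired-VAF statistics to quantify the cfDNA advantage, longitudinal
classification to contrast treatment dynamics, and a clinical predictor to
choose the analyte per patient.

## Reference atlas

Given healthy BM and PB methylation matrices over a shared CpG universe
(beta values in [0, 1]), per-tissue means are taken over non-missing
samples; CpGs missing in more than 20% of either tissue's references are
excluded (stabilizes means; the cutoff is a parameter).  Candidates satisfy
`|mean_BM − mean_PB| ≥ min_delta` (default 0.2) and are ranked by
descending absolute difference.  The top `k` (default 582) are selected
balanced between BM-hypermethylated and BM-hypomethylated sites
(⌈k/2⌉/⌊k/2⌋, with any deficit in the scarcer direction taken from the
other).  Ties are broken lexicographically by CpG id, and the ranking key
rounds |Δβ| at 1e-10 so summation-order float noise cannot reorder
effective ties — selection is therefore deterministic and invariant to row
and column permutations of the input.  Mean-difference ranking with
direction balance is the standard construction for cfDNA deconvolution
atlases; more elaborate selection statistics (moderated tests, multi-tissue
one-vs-rest) are out of scope because exactly two tissues are modelled.

## Deconvolution

A sample's betas `b` over atlas CpGs are modelled as a non-negative
combination of the atlas columns `A` (CpGs × 2): solve
`min_{f≥0} ||A f − b||₂` by NNLS, then renormalize `f` to sum to one.  The
sum-to-one constraint deliberately stays outside the solve: the free scale
absorbs global intensity differences and keeps the root-mean-square
residual interpretable on the beta scale.  CpGs missing in the sample are
dropped from both `A` and `b` for that solve (no imputation), with a
minimum-coverage floor of 50% of atlas CpGs (configurable); an all-zero
solution (possible only for degenerate inputs such as `b = 0`) is an
error, not a silent 0/0.  For two tissues this procedure is equivalent to a
one-dimensional search over mixture direction with a closed-form optimal
scale, which is what the test suite's independent grid-search oracle
exploits.

The `fold_enrichment` helper expresses the ratio of two mean tissue
fractions (e.g. BM fraction in cfDNA over gDNA) with half-up rounding at
one decimal, the form in which such enrichments are reported.

## Limit of detection

For a spike tissue (say BM) into a background (PB), mixtures
`f·spike + (1−f)·background` are formed over atlas CpGs at each grid
fraction, perturbed with additive Gaussian noise on the beta scale
truncated to [0, 1] by clipping, and deconvolved.  The blank (f = 0)
replicates define the detection cutoff as the 95th percentile of the
estimated spike fraction; the LoD is the smallest grid fraction whose
replicates exceed that cutoff in at least 95% of cases (both the quantile
and the reliability are parameters — "reliably detected" needs a concrete
criterion to be testable).  If no grid point qualifies the result is
flagged "not detected within grid" rather than raised.  Randomness flows
from a single seed through one `numpy` Philox-style substream per
(grid point, replicate); the standard-normal draws are independent of the
noise sd, so runs at different noise levels share common random numbers and
the monotonicity of LoD in noise can be checked without Monte-Carlo
ambiguity.  At `noise_sd = 0` the LoD is exactly the smallest positive grid
point.  The default grid/replicate settings (n_reps = 50, reliability 0.95)
reproduce the *procedure* of in-silico validation; the specific printed
limits of any one study depend on its grid granularity and noise model.

## Concordance and the cfDNA advantage

Observations are joined on (patient, gene, mutation, timepoint); detection
is strict `VAF > 0.02` (a value exactly at 2% is not reported).  Overlap
accounting partitions pairs into both / cfDNA-only / gDNA-only with
percentages rounded half-up to one decimal.  The advantage statistic is
the mean of `(VAF_cf − VAF_g)/VAF_g` over both-detected pairs, reported in
percent; restricting to both-detected pairs guarantees the denominator is
positive, and one-sided detections are reported through the overlap summary
instead.  `n` counts mutation-timepoint pairs, not patients.  The paired
comparison is a two-sided t-test by default with a Wilcoxon signed-rank
option; identical vectors yield a flagged NaN p-value, never a spurious 0.
The recommendation rubric maps (advantage, p): ≥30% and p<0.05 →
"Prioritize cfDNA"; ≥30% and p<0.10 → "cfDNA preferred"; >5% → "Consider
cfDNA"; otherwise "Consider gDNA".  Under swapping of the analytes an
advantage `a` (fraction scale) maps exactly to `−a/(1+a)`, a property the
suite asserts.

WBC stratification splits pairs at a threshold (default 10×10⁹/L, the
high stratum closed on the left) or by patient-level WBC quartiles
(25/50/75th percentiles, linear interpolation, strata closed on the left).
Each stratum reports per-analyte mean VAF and a within-stratum paired
test; the across-strata two-sample t-test per analyte compares low vs high
(threshold mode) or Q1 vs Q4 (quartile mode — the extremes carry the
clinical contrast).  Strata with fewer than two pairs are flagged
insufficient rather than dropped.

## Longitudinal classification

The patient-level summary VAF is the unweighted mean over detected
mutations of a class (drivers = {JAK2, CALR, MPL}; everything else
non-driver; "all" pools both) for one analyte and timepoint.  With
`Δ = VAF(T2) − VAF(T1)` in absolute VAF points: `Δ ≤ −0.05` → response,
`Δ ≥ +0.05` → resistance, otherwise stable; progression is flagged at
`Δ ≥ +0.10`.  Both boundaries are inclusive, and a 1e-12 guard below each
threshold prevents binary rounding of printed-scale differences (e.g.
0.45 → 0.50) from demoting an exact boundary case.  The thresholds are
interpreted in absolute percentage points — the progression threshold and
the reported Δ values only cohere on that scale — with a `relative` flag
preserving the alternative reading.  Under the defaults progression implies
resistance.  Cohort summaries give per-analyte category proportions
(half-up, one decimal; they sum to 100 ± rounding) and a cross-analyte
concordant/discordant patient count; group summaries (by hematologic
response, treatment, …) give per-analyte mean ± SEM of Δ and a paired
cross-analyte t-test, with singleton groups reported but flagged untested.

## Lymphocyte predictor

Per-patient advantage is the mean relative advantage over the patient's
both-detected pairs, in percent (percent is this module's native unit so
fitted coefficients read in clinical scale).  `fit_lymph_model` is ordinary
least squares of advantage on lymphocyte percentage with `r` the Pearson
correlation; a constant response yields slope 0 with `r` flagged NaN, and a
constant predictor is an error.  `select_test` is deterministic and
monotone in lymphocyte percentage: lymphocytes strictly above the cutoff
(default 20%) or any gene labelled "Prioritize cfDNA"/"cfDNA preferred"
suffice for cfDNA; gDNA requires every gene to map to "Consider gDNA" with
the lymphocyte rule silent; "dual" appears only when the caller flags a
critical decision point and the two signal levels conflict.  Genes whose
only label is "Consider cfDNA" resolve to cfDNA — the lean of the label —
which is what keeps the rule monotone.

## Synthetic data

The generators encode the data-generating story the analysis assumes; they
are first-class, tested code.

**Methylation.**  Discriminative CpGs (default 600 of 1000) receive tissue
means separated by `delta_beta` (default 0.3) around a midpoint drawn
uniform [0.1, 0.9] (re-drawn, bounded retries, if a mean would leave
[0, 1]), with balanced random directions; background CpGs share one common
mean per site.  Reference samples (default 6 per tissue, the typical
healthy-donor panel size) add truncated Gaussian noise of sd 0.02.
Mixtures are convex combinations of the per-tissue mean profiles plus
truncated noise, with the true fraction recorded.

**Paired cohort.**  Each patient carries one driver drawn by prevalence
(JAK2 0.80, CALR 0.15, MPL 0.08 — the landscape of a treated MPN cohort)
and each non-driver independently (DNMT3A 0.23, TET2 0.15, ASXL1 0.10,
SF3B1 0.08).  True clonal VAF per mutation is Beta(5, 5) rescaled to
[0.05, 0.95] (clonal burdens centred near 0.5, matching driver VAF means
around 0.45–0.52).  Measured VAFs:

* cfDNA = true × gene multiplier (CALR 1.593, SF3B1 1.436, MPL 1.361,
  ASXL1 1.157, JAK2 1.119, TET2 0.997, DNMT3A 0.972 — one plus the
  per-gene advantage the statistic should recover);
* gDNA = true × (1 − 0.006 × LYMPH%), lymphocytes drawn uniform [5, 45]%;
* both plus truncated Gaussian measurement noise (sd 0.02) and clamped to
  [0, 1], with a warning if more than 20% of values clamp;
* T2 adds the assigned regimen's (Δcf, Δg) shifts — HU (+0.038, −0.011),
  IFN (−0.015, +0.089), IFN+HU (−0.026, +0.041), RUX/aspirin (0, 0) —
  with regimen frequencies matching a predominantly HU-treated cohort.

Observations at or below the 2% detection threshold are not emitted.  WBC
is constructed as `4 + 25 × (patient mean gDNA VAF) + N(0, 2)` so the
gDNA-vs-WBC dependence the stratified analyses look for exists by
construction, while cfDNA stays comparatively independent.  Clinical
covariates (HCT, PLT, HGB) are uniform draws over adult reference-to-MPN
ranges; hematologic response labels are drawn at the frequencies of a
worsening treated cohort (T1 10/17/12 CR/PR/NR of 39, T2 8/14/17).  All
draws descend from one seed via named substreams per table, so equal
configurations give byte-identical output files.

The linear lymphocyte dilution at coefficient 0.006 yields a per-patient
advantage-vs-lymphocyte correlation near r ≈ 0.5 in default cohorts (the
clinically observed association strength); note the implied *slope* is of
order 1 percentage point of advantage per lymphocyte point, since a linear
dilution bounded away from zero cannot produce an arbitrarily steep
advantage line over a wide lymphocyte range without driving gDNA VAF
negative.  The generator targets the correlation, not the printed slope of
any particular cohort.  A `null()` configuration (unit multipliers, no
dilution, no treatment effect) makes the analytes exchangeable up to noise;
the suite checks that advantage then centres at zero and classification
proportions are symmetric between analytes.

What the generator does **not** emulate: sub-clonal architecture beyond one
driver plus at most one non-driver per patient, fragment-length or
nucleosome-footprint features of real cfDNA, array batch effects or probe
biases, informative missingness, and correlation between methylation and
mutation data for the same virtual patient.  Passing recovery tests on
these cohorts therefore demonstrates correctness of the estimators under
the declared generative model, not performance on real EPIC arrays or
clinical panels.

## Numerical choices

* VAFs live on the [0, 1] fraction scale everywhere except the predictor
  module (advantage in %); conversion from percent tables happens once at
  the I/O boundary and is idempotent.
* Percentages print with half-up rounding at one decimal (ties away from
  zero), matching clinical-table conventions and making string-level
  expectations exact.
* Betas outside [0, 1] beyond 1e-9 and fractions off the simplex beyond
  1e-9 are validation errors; missing cells are NaN-flagged, never zeroed.
* File round trips preserve floats exactly (`%.17g` on write, round-trip
  parsing on read).
* Deconvolution problem sizes in the suite (582-CpG atlas, 100–200
  mixtures, 20–50 LoD replicates) were chosen as the smallest sizes at
  which the recovery properties are comfortably non-marginal.

## Known limitations

* Exactly two tissues are supported in atlas construction and LoD; the
  atlas type carries an ordered tissue tuple so a multi-tissue extension is
  structural, not a rewrite.
* The per-gene recommendation rubric is a reconstruction that reproduces
  the canonical label set from (advantage, p) pairs; other cohorts may
  warrant different cutoffs.
* Monitoring handles exactly two timepoints; longer trajectories must be
  analysed pairwise by the caller.
* Hematologic response (CR/PR/NR) is consumed as a label; response-criteria
  evaluation from blood counts is out of scope, as are survival and
  transformation outcomes.
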
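# Methods

This note documents the models, conventions and design choices behind
`ayamel`, in the order the pipeline runs.

## Synthetic cohort generator

The generator produces inputs with the statistical structure the analysis
assumes; it defines the study conditions under which the package is
tested.

**Expression.** Counts are negative-binomial in the mean/dispersion
parameterization, Var(K) = μ + αμ², with the dispersion α shared across
genes in the generator (the DE stage estimates it per gene and must not
assume sharing).  Per-gene baseline means are log-normal with median
`baseline_mean` (default 100 counts) and log-SD 1, giving the broad
abundance spread that rank-based scoring needs; per-sample library factors
are log-normal with log-SD 0.25 so that normalization has real work to do.
Three outcome classes of `n_per_group` samples each are produced:
`resistant` (PD-like), `CR`, and `PR`.  A planted program of
`n_signature_genes` genes (half up, half down) has its mean multiplied by
2^(±`log2_effect`) in the resistant class; PR samples receive half the
exponent, which exercises the rule that PR samples are excluded from
signature training (their heterogeneous, intermediate biology would blur
the contrast).  Defaults — 24 samples per class, 2,000 genes, 100 planted
genes at |log2FC| = 1.5, α = 0.15 — are the cohort scale the package's
recovery properties are stated at.  The real cohort's dispersion and
library-size spread are not published; the defaults here are ordinary
values for bulk RNA-seq of the tissue type and are deliberately
unremarkable.  A short list of canonical immune marker genes (CD8A, FOXP3,
PDCD1, HLA-A, …) heads the gene list and is never planted, so downstream
immunophenogram and drug-matching stages see real symbols.

**Cell tables.** Each (phenotype, region) stratum is a homogeneous Poisson
point pattern: the count is Poisson(intensity × area) and coordinates are
uniform inside the region's rectangle.  The two regions (intratumor,
peritumor) are disjoint rectangles of the configured areas (mm²;
coordinates in μm, 1 mm² = 10⁶ μm²).  Default intensities put regulatory
T cells predominantly in the peritumoral stroma (100 vs 17 cells/mm²),
matching the magnitude of reported ICI-resistant densities.  What the
generator does *not* emulate: spatial clustering/exclusion interactions,
segmentation noise, marker-intensity thresholds (inputs arrive already
binarized) and irregular region geometry — so passing tests demonstrate
correct counting and normalization arithmetic, not robustness to imaging
artifacts.

**Variants.** For n ≥ 20 the first 20 records are a deterministic
stratified set covering every filter rule's pass and fail branches,
including TERT-promoter records (which exercise the waivers) and both
caller labels; additional records are random.  The fixture's expected
kept/dropped partition was traced by hand once and frozen into the tests.

**Outcomes.** PFS is exponential with the class hazard (events/month);
OS adds an independent exponential tail at one third the hazard; an
independent exponential censoring time (default rate 0.01/month) censors
both.  Default hazards give a resistant median PFS of 3.4 months and a CR
median of 40 months.  Exponential survival is a deliberate idealization —
it makes the Kaplan–Meier median testable against ln 2 / h in closed form.

All generators are deterministic given the seed; sub-streams are derived
per generator so adding one stage does not perturb another's draws.

## Expression processing

Genes are kept iff their count exceeds `min_count` (20) in strictly more
than `min_samples` (5) samples.  The published filter sentence admits
several readings (strict vs non-strict, per-group vs overall); this strict
overall reading was chosen as the evident low-information-gene removal,
and both bounds are arguments.

Size factors are median-of-ratios: per sample, the median over reference
genes (nonzero in every sample) of count / geometric-mean-across-samples.
Only ratios of size factors are identified (the geometric-mean reference
fixes the overall scale), which the tests respect.

Differential expression is a per-gene NB Wald test: per-group
method-of-moments dispersion on normalized counts (pooled by degrees of
freedom, floored at 10⁻⁸), log2 fold change of normalized group means with
pseudo-count 0.5, delta-method standard error, standard-normal reference,
BH adjustment across tested genes.  This is intentionally *not* a
re-implementation of shrinkage-based DE frameworks: no dispersion
shrinkage, no independent filtering, no covariates.  Correctness is
claimed in terms of calibration (null P-values uniform within KS 0.05 at
2,000 genes) and recovery (≥ 90% of planted genes at BH P < 0.05 with
≤ 10% false positives under the default conditions), not equality with any
specific package's P-values.

BH is the standard step-up; BKY is the two-stage step-up (stage-1 BH at
α/(1+α), stage-2 BH with the re-estimated null count), reported at
α = 0.05 via statsmodels.  BKY is offered because it is the usual choice
when many comparisons are negatively correlated (e.g. cell-type densities
that trade off against each other).

## Directed rank scoring

The score is the mean directed rank (see README for the formula).
Conventions:

* ties get average (fractional) ranks — deterministic and standard for
  rank statistics;
* up- and down-weighted genes are pooled into one mean, following the
  single-sum form of the score; a two-block variant (mean up-rank + mean
  reversed down-rank) is available behind `two_block=True` for sensitivity
  analysis, as is a min–max normalized variant `(score − 1)/(G − 1)`
  behind `normalized=True`.  Both variants are monotone transforms under
  fixed G and N, so AUC-based conclusions are unchanged; the raw mean rank
  is the default because it is the printed definition;
* set genes absent from the data are excluded from numerator and
  denominator; a sample with no overlap is an error (single-sample call)
  or a logged skip (cohort call).

Useful exact properties (all tested): the all-genes +1 set scores
(G+1)/2; flipping every weight maps s → G + 1 − s in tie-free data; any
strictly increasing transform of a sample's values leaves its score
unchanged; raising a +1 gene never lowers the score.

Signature construction takes the DE table between resistant (PD) and CR
patients — PR excluded upstream — and weights genes at adjusted P < 0.05
by the sign of their fold change.  Equal-weight comparator sets load from
plain GMT (all +1); signed sets use a two-column GMT extension with
`gene:+1` / `gene:-1` tokens.  Composite immune scores merge positively
weighted effector components with negatively weighted suppressive
components into one signed set; a gene claimed by both sides is dropped
with a warning.

## Immunophenogram

Per gene, z = (value − cross-sample mean) / cross-sample SD (n−1
denominator); zero-variance genes get z = 0; a category's score is the
mean z over its marker genes present in the matrix, NaN (flagged, not
raised) when none are present.  The packaged category lists (effector
cells, suppressor cells, checkpoints, MHC) are an editable reconstruction
of commonly used markers — the original marker tables are not printed in
the main text — and any category → gene-list mapping can be supplied
instead.  The qualitative high/low immunogenicity split has no published
rule; it is exposed as a threshold (default 0) on the mean category score
and documented as a reconstruction.

## Variant filter cascade

Eight rules applied conjunctively (module docstring lists them); the
keep/drop decision is order-independent, and attribution of a dropped
record follows the printed order (first failing rule).  Interpretations
made explicit:

* rule 4's "no positive call for … bias" means both boolean flags false;
* rule 6/7 apply only to records of their caller; records merged from
  both callers skip both;
* rule 7 is implemented literally as 0.1 < AF ≤ 0.2 for LoFreq-only
  calls.  The upper bound reads like it may be a transcription slip for a
  lower-bound-only filter, so it is toggleable (`r7_upper_bound=False`);
* coding vs non-coding for rule 8 is decided from the sequence-ontology
  consequence term against a fixed non-coding set;
* TERT-promoter membership is an input flag or derived from a configured
  genomic interval — never hard-coded coordinates, since they are
  assembly-dependent.

Sample-level sequencing-QC exclusion (average unique-DNA score < 50)
concerns raw run metrics that are not part of this package's inputs; it is
a documented manual step upstream.

MAF emission writes the standard required columns with 1-based inclusive
coordinates; records without a gene symbol are written as `Unknown` with a
warning.  Mutation co-occurrence builds the per-sample 2×2
presence/absence table and delegates to the exact test, with Haldane +0.5
odds-ratio correction when a cell is zero.

## Spatial quantification

Densities are counts of query-matching cells divided by the region's
declared area; `total` divides summed counts by summed areas.  Region
labels come from the input table (the tissue classifier that produced them
is out of scope); cells with undeclared labels are excluded and logged,
mirroring the exclusion of necrosis and artifacts.  Ratios with a zero
denominator are NaN with a log flag rather than an exception, because a
missing phenotype in a region is an ordinary observation, not an error.

## Statistics

* Fisher 2×2: two-sided by probability ordering (sum of hypergeometric
  probabilities ≤ observed, relative tolerance 10⁻⁷ against
  floating-point ties).
* Freeman–Halton r×c: full depth-first enumeration of margin-consistent
  tables when their number is ≤ 2×10⁶ (cohort-scale tables enumerate in
  well under a second); otherwise a seeded Monte-Carlo estimate over at
  least 10⁶ Patefield-sampled tables, with the method logged.  A table
  with a zero margin returns P = 1 with a warning.  Chi-square (no
  continuity correction) is also exposed, as the conventional test for
  r×c tables.
* Mann–Whitney U: exact enumeration of all group assignments when both
  groups have ≤ 8 observations (valid under ties); otherwise tie-corrected
  normal approximation without continuity correction, which makes the
  two-group case agree with Kruskal–Wallis.
* Kaplan–Meier median: earliest time with S(t) ≤ 0.5, no interpolation,
  NaN when never reached.  Log-rank uses the standard hypergeometric
  variance at each distinct event time (ties included).
* ROC AUC: midrank formula, equal to the concordance probability and to
  U / (n₁n₂).

Two-way ANOVA is mentioned in the source analyses but no in-scope result
uses it; it is omitted.

## Druggable-target matching

An interaction matches a patient iff its gene is expressed or mutated in
that patient and its category tags contain every required tag for that
basis.  "Expressed" defaults to normalized expression above the cohort
upper quartile for that gene (no published threshold exists; it is
configurable).  Required tags are configurable per basis — conjunction of
{approved, antineoplastic, immunotherapy} for expression-based matches,
{approved, antineoplastic} for mutation-based — because immunotherapy-
style targets are matched on expression while small-molecule targets are
matched on mutations.  The packaged interaction table is a small synthetic
snapshot for demos and tests; analyses against the real database must load
a current export, and no attempt is made to reproduce database-version-
dependent match counts.

## Problem sizes and limitations

The test suite and the acceptance script run the full recovery study at
24 + 24 training samples × 2,000 genes with 100 random comparator
signatures, 200 brute-force scoring instances, 100-table statistical
identity sweeps, and 500-draw survival experiments; these sizes were
chosen so the whole suite completes in well under a minute of compute
while keeping Monte-Carlo error far from every tested threshold.

Known limitations: the DE test's moment dispersion is noisy for very low
counts (mitigated by the low-count filter); the r×c exact test is
enumeration-based and falls back to Monte Carlo for large tables; the
synthetic generator does not model batch effects, clustered spatial
patterns or read-level data; and the immunophenogram marker lists and the
drug-interaction snapshot are reconstructions intended to be replaced by
user-supplied resources.
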
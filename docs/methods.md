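# Methods

## The evaluation problem

Neoantigen immunogenicity predictors emit continuous values on incompatible
scales and in opposite orientations: binding affinity in nM and eluted/
percentile ranks point *down* (lower = more immunogenic), immunogenicity
scores point *up*. Comparing them fairly requires (i) a principled way to
binarize each output, (ii) metrics computed on a curated database with known
positives and negatives, (iii) an error assessment on a held-out,
patient-like validation set, and (iv) an aggregation rule that orders methods
when no one dominates. `neobench` implements each stage behind an explicit
`MethodSpec` (method, metric code, direction, threshold rule) so that
orientation is always declared, never guessed.

## Threshold selection

For a DOP-thresholded method, every distinct observed output value is a
candidate threshold. At each candidate the records are classified (a value
exactly at the threshold counts positive — the candidate set is the observed
values, so the minimizer must be attainable), the confusion counts formed,
and

DOP = ‖(Se, Sp, PPV, NPV) − (1,1,1,1)‖₂

computed. The argmin is returned; ties on DOP (to 1e-12) break toward the
candidate classifying more records positive (most sensitive), then toward the
smaller native value. Degenerate denominators (no predicted positives, no
predicted negatives, a single-class column) resolve to 0, which pushes DOP
toward its maximum of 2 for useless thresholds — the behavior the argmin
needs. Thresholds are **fitted on the database only and frozen**; validation
FPR/FNR and cohort TNB always use the frozen value. Author-published rules
(rank ≤ 0.5 % strong binder, ≤ 2 % weak binder, affinity < 500 nM,
percentile < 2 %, score > 0.5, score > 0) are applied verbatim with their own
strict/inclusive comparators; methods whose authors published no rule raise
rather than silently falling back.

## Metrics and tests

Se, Sp, PPV, NPV and F1 live in [0,1]; FPR = 100(1−Sp) and FNR = 100(1−Se)
are carried in percent and rounded (2 decimals) only at the reporting layer.
AUC is the Mann–Whitney statistic computed from midranks — the probability a
random positive outscores a random negative, ties counted half — after
orienting scores so higher means more immunogenic; constant scores and
single-class labels are errors, not silent 0.5s. The rank-sum test uses exact
enumeration when the combined sample is ≤ 12 and untied, otherwise the normal
approximation with continuity and tie corrections (via
`scipy.stats.mannwhitneyu`); all-constant data short-circuits to p = 1. One
consequence of the continuity correction worth knowing: two *identical small*
samples give p ≈ 0.8, not 1 — the approximation is conservative at tiny n;
from n ≈ 30 per group identical samples give p > 0.99.

## Rank aggregation

Each method's DOP (ascending), F1 (descending), FPR and FNR (ascending)
columns are ranked with competition (min-tie) ranks: tied values share the
smallest rank of their block. AR is the mean of the four ranks and ARsd their
sample standard deviation (n−1 denominator — the published AR/ARsd pairs
reproduce only under this choice, e.g. ranks (4,5,3,2) → 3.5/1.29). The final
ordering is lexicographic (AR, ARsd) with stable input order as the only
further tie-break; the shipped published table is stored in its printed order,
which that convention preserves. CR and FDRR are the means of the
database-side and validation-side rank pairs.

## DAI analysis

DAI_BA = WT_BA − mut_BA (nM; positive when the mutant binds more strongly)
and DAI_R = mut_R / WT_R (dimensionless; > 1 when the mutant ranks worse).
Discrimination is assessed per anchor stratum (mutation at position 2 or the
C-terminus vs elsewhere) as an AUC plus a two-sided rank-sum p-value. The
score orientation for the AUC is an explicit configuration value defaulting
to "higher DAI = immunogenic" for both flavours: an automatic best-side flip
would fabricate apparent discrimination from noise, so an inverted
relationship shows up honestly as AUC < 0.5. Ratio-DAI summaries are reported
on the natural-log scale; the log is never applied inside the test statistic
(rank-based, hence invariant). Strata with one label or constant DAI are
skipped with warnings. Anchor positions default to {2, last}; a strict mode
uses the literal {2, 9} for both lengths, since 10-mers' C-terminal anchor is
position 10 but some curation conventions class position 9 regardless.

## TNB biomarker

A patient's TNB under (spec, frozen threshold) is the count of their
candidate neoantigens classified immunogenic; patients with zero candidates
keep TNB 0 and stay in the test. Association with ICB response is the
two-sided rank-sum test, reported per cohort × method with **no**
multiple-testing adjustment by default (mirroring how such grids are
conventionally reported, one association at a time); a Benjamini–Hochberg
flag is available. Cells that cannot be computed (degenerate groups) are
recorded absent rather than failing the grid. Reports annotate p ≥ 0.05
as "NS".

## Synthetic data generator

The generator defines the study conditions for everything not computable from
the shipped published table:

- **Database**: 129 immunogenic + 70 non-immunogenic records (199 total).
  WT peptides uniform over the 20-letter alphabet; one substituted position,
  uniform over 1..length by default (an `anchor_fraction` switch oversamples
  anchors for DAI stratum tests). Lengths 9:10 mixed 80/20 (a curated-db-like
  skew toward 9-mers; the exact split is a package choice). Alleles are
  allocated by largest remainder from a weight table whose default gives
  HLA-A*02:01 exactly 80/199 = 40.2 %, with the rest spread over 8 common
  class-I alleles. Evidence flags satisfy the inclusion rules by
  construction, so generated databases always validate clean.
- **Scores**: binormal latents — negatives N(0,1), positives N(μ,1) with
  μ = √2·Φ⁻¹(AUC) — mapped monotonically to each metric's native scale
  (nM = exp(6.5 − 1.2·latent); ranks/percentiles 100·Φ(−latent); scores
  Φ(latent)). Monotone maps leave every rank-based quantity unchanged, so the
  empirical AUC is calibrated to the target (verified to ±0.01 at n = 10⁴).
  Default targets per method-metric sit in the weak 0.52–0.60 regime these
  predictors actually reach.
- **Validation set**: 109 + 4-dual-HLA non-immunogenic and 6 + 1-dual-HLA
  non-SNV immunogenic peptides → 113/7 = 120 pairs. With 7 positives and 113
  negatives, achievable FNRs are multiples of 100/7 and FPRs of 100/113 — a
  residue structure the published FNR/FNR columns also satisfy.
- **Cohorts**: TMB ~ NegBin(mean 200, dispersion 2), candidates ~
  Binomial(TMB, 0.5), responders' candidate count multiplied by
  `burden_effect` before rounding (default 1.0 = null). Defaults: 40 patients,
  35 % responders, sizes in the range of real ICB cohorts. Each patient draws
  from an own substream, so changing `burden_effect` perturbs only
  responders' candidate lists.

One root seed; every component (database, each score table, each cohort,
each patient) derives a deterministic substream via a CRC-keyed
`SeedSequence`, so outputs are byte-identical across runs and platforms and
regenerating one component never shifts another.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: HLA-specific binding motifs and anchor-residue
preferences (peptides are uniform random), correlations between predictors
(each method's scores are independent draws), realistic proteome-derived
peptide frequencies, MS-elution physics, and any relationship between a
patient's TMB and their mutations' actual immunogenicity. Tests on synthetic
data certify the *statistical machinery* (threshold search, ranking, tests,
calibration), not any predictor's real-world accuracy.

## Numerical choices

- Boundary at the threshold counts positive (≥ / ≤ after orientation).
- Zero-denominator convention: undefined Se/Sp/PPV/NPV → 0; F1 = 0 when
  PPV + Se = 0.
- AUC ties get half credit.
- Percentages rounded to 1 decimal in summaries, 2 in benchmark reports;
  internal values unrounded.
- Decimal-comma numeric cells ("0,88") are accepted by the table readers and
  converted; all output uses decimal points. "NA", "." and empty cells read
  as missing.
- Exact rank-sum branch bound: combined n ≤ 12, untied.
- Jaccard of two empty positive-call sets is 1.0 by convention.

## Problem sizes in tests and the acceptance script

Oracle comparisons run on 300–1000 random instances (n ≤ 200 for the DOP
scan, n ≤ 50 for pairwise AUC); calibration uses one draw of 10⁴ records;
type-I error uses 1000 null rank-sum tests at 30 + 30; TNB null uniformity
uses 300–500 cohorts of 24 patients and the power curve 60 replicates per
effect size. These sizes give simulation standard errors comfortably inside
the asserted tolerances while keeping a full run in tens of seconds.

## Known limitations

- Recomputing the published table's raw DOP/F1/AUC/FPR/FNR values requires
  the seven external predictors' outputs on the curated database; the package
  treats those metric columns as *input* and owns everything downstream
  (ranking, aggregation, ordering). The method list is data, not a constant.
- The strong/weak-binder labels are defined on the eluted-rank scale; for
  binding-affinity columns carrying such labels an explicit numeric threshold
  must be supplied in the method config, since no nM-scale definition exists.
- No confidence intervals on AUC and no significance testing of rank
  differences between methods.
- Hierarchical clustering/dendrograms of the agreement matrix are out of
  scope; the binary call matrix and Jaccard matrix are exported for external
  plotting.
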
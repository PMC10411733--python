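# neobench

Benchmarking framework for tumor-specific-neoantigen (TSN) immunogenicity
predictors.

Predicting which tumor mutations yield peptides that actually trigger a
CD8 T-cell response is a central problem for personalized cancer vaccines and
for neoantigen-burden biomarkers, and current predictors — MHC-I binding
models and dedicated immunogenicity models alike — discriminate only weakly
(AUCs barely above chance on curated databases). That makes the *evaluation
methodology* itself the hard part: how to pick classification thresholds for
heterogeneous continuous outputs, and how to declare a winner when no method
dominates on every metric. `neobench` implements that methodology as a tested,
reusable library for immunoinformaticians comparing predictors on curated
neoantigen databases, patient-style validation sets, and immune-checkpoint-
blockade (ICB) cohorts.

## What it computes

**DOP threshold selection.** Each predictor emits a continuous value (binding
affinity in nM, eluted rank %, percentile, or an immunogenicity score). A
threshold is chosen over the observed outputs by minimizing the Distance to
the Optimal Point,

    DOP_i = sqrt[ (Se_i−1)² + (Sp_i−1)² + (PPV_i−1)² + (NPV_i−1)² ],
    best threshold = argmin_i DOP_i,

the Euclidean distance of (sensitivity, specificity, PPV, NPV) from the
perfect classifier (1,1,1,1). Author-published rules (strong/weak binder rank
cutoffs, affinity < 500 nM, score > 0.5, …) are supported alongside.

**Rank aggregation.** Each method-metric-threshold combination gets four
competition (min-tie) ranks — DOP and F1 on the database, FPR and FNR on a
held-out validation set — and methods are ordered by the average rank AR with
the sample standard deviation ARsd as tie-breaker. CR (mean of the
database-side ranks) and FDRR (mean of the validation-side ranks) are
reported as sub-aggregates.

**Also included:** ROC/AUC (Mann–Whitney identity), Wilcoxon rank-sum testing
(exact for small untied samples), top-k prioritization counts, cross-method
agreement (Jaccard/consensus), the Differential Agretopicity Index
(DAI_BA = WT_BA − mut_BA, DAI_R = mut_R / WT_R) with anchor-stratified
discrimination analysis, tumor-neoantigen-burden (TNB) association with ICB
response, a database validator for the curation inclusion rules, and a
seeded synthetic-data generator for all of the above.

## Worked example

The package ships the published 16-method performance table; recomputing the
rank columns from the metric values alone reproduces it exactly:

```bash
python examples/rank_published_benchmark.py
```

prints (abridged):

```
    method metric threshold  rank_dop  rank_f1  rank_fpr  rank_fnr    ar  ar_sd
DeepHLApan      I       DOP         4        5         3         2  3.50   1.29
 MHCflurry      B       DOP         2        7         7         6  5.50   2.38
     PRIME     SI       DOP         1        4        12         6  5.75   4.65
...
rank cells matching the published table: 64/64
top performer: DeepHLApan (I, DOP) with AR=3.5 ARsd=1.29
```

Reading: DeepHLApan's immunogenicity score with a DOP-fitted threshold is
never the single best column (it ranks 4th on DOP, 5th on F1), but its mean
rank 3.5 with the smallest spread (ARsd 1.29) makes it the most *balanced*
performer across classification and false-detection metrics — which is
exactly what the AR ordering is designed to surface.

Other examples, one per capability: `simulate_and_benchmark.py` (end-to-end
synthetic benchmark), `dai_anchor_analysis.py`, `tnb_response_association.py`,
`validate_and_summarize.py`. A thin CLI wraps the same functions:
`neobench simulate|validate|benchmark|prioritize|dai|tnb|fit-thresholds`
(see `neobench --help`).

## Layout

- `src/neobench/` — the library (`models`, `io`, `validate`, `metrics`,
  `thresholds`, `ranking`, `dai`, `tnb`, `simulate`, `cli`)
- `src/neobench/data/published_benchmark.tsv` — the published 16-row table
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, assumptions, numerical choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests
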
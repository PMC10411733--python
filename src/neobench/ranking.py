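"""Benchmark assembly: per-method performance rows, the four-column
competition ranking with AR/ARsd/CR/FDRR aggregation and the final method
ordering, top-k prioritization, and cross-method agreement analysis.

The aggregation logic is the headline computation: each method-metric-
threshold combination receives four ranks — DOP and F1 measured on the
curated database, false-positive and false-negative rates measured on a
held-out validation set — and methods are ordered by the mean rank (AR),
with the sample standard deviation of the ranks (ARsd) as tie-breaker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from neobench.metrics import as_binary_labels, metric_panel, orient, roc_auc
from neobench.models import Direction, MethodSpec
from neobench.thresholds import (
    apply_author_rule,
    author_threshold,
    best_threshold_dop,
    classify,
    confusion_from_calls,
)

__all__ = [
    "PerformanceRow",
    "competition_rank",
    "aggregate_ranks",
    "evaluate_method",
    "evaluate_benchmark",
    "prioritize_top_k",
    "agreement_matrix",
]

METRIC_ORDERS = {"dop": "ascending", "f1": "descending",
                 "fpr": "ascending", "fnr": "ascending"}


@dataclass
class PerformanceRow:
    """One benchmark-table row: metric values, the four per-column ranks,
    and their aggregates (AR = mean rank, ARsd = sample SD, CR = mean of the
    database-side ranks, FDRR = mean of the validation-side ranks)."""

    method_metric_threshold_id: str
    dop: float
    f1: float
    fpr: float
    fnr: float
    auc: float | None = None
    rank_dop: int = 0
    rank_f1: int = 0
    rank_fpr: int = 0
    rank_fnr: int = 0
    ar: float = 0.0
    ar_sd: float = 0.0
    cr: float = 0.0
    fdrr: float = 0.0


def competition_rank(values, order: str = "ascending") -> np.ndarray:
    """Min-tie ("competition") ranks: tied values share the smallest rank of
    their block; the next distinct value resumes at 1 + the number of strictly
    better values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty sequence")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if order not in ("ascending", "descending"):
        raise ValueError("order must be 'ascending' or 'descending'")
    key = v if order == "ascending" else -v
    return stats.rankdata(key, method="min").astype(int)


def aggregate_ranks(rows: pd.DataFrame) -> pd.DataFrame:
    """Rank each metric column across methods and aggregate.

    ``rows`` needs columns ``dop``, ``f1``, ``fpr``, ``fnr`` (plus any
    identifier columns, carried through). Ranks: DOP, FPR, FNR ascending
    (lower better); F1 descending. AR is the mean of the four ranks, ARsd the
    sample standard deviation (n−1), CR the mean of the database-side ranks
    (DOP, F1) and FDRR the mean of the validation-side ranks (FPR, FNR).
    The result is sorted by (AR, ARsd), stable in the input order.
    """
    if len(rows) < 2:
        raise ValueError("rank aggregation needs at least 2 methods")
    for col in METRIC_ORDERS:
        if col not in rows.columns:
            raise ValueError(f"missing metric column {col!r}")
        bad = rows.index[pd.to_numeric(rows[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"missing {col!r} value on row {bad[0]}")
    out = rows.reset_index(drop=True).copy()
    for col, order in METRIC_ORDERS.items():
        out[f"rank_{col}"] = competition_rank(out[col].to_numpy(float), order)
    ranks = out[["rank_dop", "rank_f1", "rank_fpr", "rank_fnr"]].to_numpy(float)
    out["ar"] = ranks.mean(axis=1)
    out["ar_sd"] = ranks.std(axis=1, ddof=1)
    out["cr"] = ranks[:, :2].mean(axis=1)
    out["fdrr"] = ranks[:, 2:].mean(axis=1)
    return out.sort_values(
        ["ar", "ar_sd"], kind="mergesort"
    ).reset_index(drop=True)


def evaluate_method(
    db_scores: pd.DataFrame,
    validation_scores: pd.DataFrame,
    spec: MethodSpec,
    author_variant: str | None = None,
) -> dict:
    """Evaluate one method-metric-threshold combination end to end.

    The threshold is fitted on the database slice only (DOP minimization) or
    taken from the authors' published rule, then frozen and applied to the
    validation slice. Returns the metric values that feed
    :func:`aggregate_ranks`: dop, f1 and AUC on the database; fpr, fnr on
    validation. AUC is reported absent (None) for author-thresholded rows,
    which are evaluated as binary calls only; it is also absent when the
    database scores are degenerate (constant), in which case the threshold row
    is still produced.

    Both slices need ``value`` and ``label`` columns.
    """
    db_values = db_scores["value"].to_numpy(float)
    db_labels = db_scores["label"].tolist()

    if spec.threshold_rule == "author":
        rule = spec.author_rule or author_threshold(spec, author_variant)
        db_calls = apply_author_rule(db_values, rule)
        panel = metric_panel(confusion_from_calls(db_calls, db_labels))
        threshold = rule.cutoff
        rule_name = rule.name or "A"
        auc = None
    else:
        result = best_threshold_dop(db_values, db_labels, spec)
        panel = result.panel
        threshold = result.threshold
        rule_name = "DOP"
        try:
            _, auc = roc_auc(db_values, db_labels, spec.direction)
        except ValueError as exc:
            warnings.warn(
                f"{spec.method_metric_id}: AUC unavailable ({exc})", stacklevel=2
            )
            auc = None

    val_values = validation_scores["value"].to_numpy(float)
    val_labels = as_binary_labels(validation_scores["label"].tolist())
    if spec.threshold_rule == "author":
        rule = spec.author_rule or author_threshold(spec, author_variant)
        val_calls = apply_author_rule(val_values, rule)
    else:
        val_calls = classify(val_values, spec, threshold)
    val_panel = metric_panel(confusion_from_calls(val_calls, val_labels))

    return {
        "method": spec.method,
        "metric": spec.metric,
        "threshold_rule": rule_name,
        "threshold": threshold,
        "dop": panel.dop,
        "f1": panel.f1,
        "auc": auc,
        "fpr": val_panel.fpr,
        "fnr": val_panel.fnr,
    }


def evaluate_benchmark(
    db_scores_by_spec: list[tuple[MethodSpec, pd.DataFrame, pd.DataFrame]],
) -> pd.DataFrame:
    """Run :func:`evaluate_method` over every spec and aggregate the ranks
    into the full benchmark table."""
    rows = pd.DataFrame(
        [evaluate_method(db, val, spec) for spec, db, val in db_scores_by_spec]
    )
    return aggregate_ranks(rows)


def prioritize_top_k(
    candidates: pd.DataFrame, spec: MethodSpec, k: int
) -> tuple[pd.DataFrame, int]:
    """Rank candidates by oriented score (best first, stable on ties) and
    count the immunogenic labels in the top k. k larger than the candidate
    list is clamped with a warning."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(candidates):
        warnings.warn(
            f"k={k} exceeds {len(candidates)} candidates; clamped", stacklevel=2
        )
        k = len(candidates)
    oriented = orient(candidates["value"].to_numpy(float), spec.direction)
    order = np.argsort(-oriented, kind="mergesort")
    ranked = candidates.reset_index(drop=True).iloc[order].reset_index(drop=True)
    top = ranked.head(k)
    hits = int(as_binary_labels(top["label"].tolist()).sum())
    return ranked, hits


def agreement_matrix(
    calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Cross-method agreement on binary immunogenicity calls.

    ``calls`` is a records × methods boolean frame (identical record sets per
    method by construction). Returns the matrix itself, the pairwise Jaccard
    similarity of the positive-call sets (two empty sets → 1.0 by convention),
    and the consensus count: records called positive by every method.
    """
    if calls.shape[1] < 2:
        raise ValueError("agreement needs at least 2 methods")
    if calls.isna().any().any():
        raise ValueError("mismatched record sets: calls contain missing entries")
    m = calls.astype(bool)
    consensus = int(m.all(axis=1).sum())
    methods = list(m.columns)
    jac = pd.DataFrame(1.0, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            inter = int((m[a] & m[b]).sum())
            union = int((m[a] | m[b]).sum())
            val = 1.0 if union == 0 else inter / union
            jac.loc[a, b] = jac.loc[b, a] = val
    return m, jac, consensus
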
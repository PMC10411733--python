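"""Classification metrics: confusion-matrix panel, the DOP distance, ROC/AUC,
the rank-sum test, and the false-positive operations used on negative-only
peptide sets.

The Distance to the Optimal Point (DOP) is the Euclidean distance of the
vector (Se, Sp, PPV, NPV) from the ideal classifier (1, 1, 1, 1); minimizing
it over observed predictor outputs is how classification thresholds are
selected throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from neobench.models import Direction, Label, MethodSpec

__all__ = [
    "ConfusionCounts",
    "MetricPanel",
    "metric_panel",
    "dop",
    "roc_auc",
    "rank_sum_test",
    "false_positive_rate_on_negatives",
    "filter_negative_binders",
    "orient",
    "as_binary_labels",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")


@dataclass(frozen=True)
class MetricPanel:
    """Se/Sp/PPV/NPV/F1 in [0,1]; FPR/FNR in percent; dop in [0,2].

    Values are unrounded — 2-decimal rounding happens only in reports.
    """

    se: float
    sp: float
    ppv: float
    npv: float
    f1: float
    fpr: float
    fnr: float
    dop: float


def _ratio(num: int, den: int) -> float:
    # Zero-denominator convention: undefined rates collapse to 0, which
    # pushes DOP toward its maximum for degenerate thresholds.
    return num / den if den > 0 else 0.0


def metric_panel(c: ConfusionCounts) -> MetricPanel:
    """Full metric panel from confusion counts.

    se = tp/(tp+fn), sp = tn/(tn+fp), ppv = tp/(tp+fp), npv = tn/(tn+fn),
    f1 = harmonic mean of ppv and se, fpr = 100(1−sp), fnr = 100(1−se).
    Zero denominators resolve to 0 by convention.
    """
    se = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    f1 = 2 * ppv * se / (ppv + se) if (ppv + se) > 0 else 0.0
    return MetricPanel(
        se=se,
        sp=sp,
        ppv=ppv,
        npv=npv,
        f1=f1,
        fpr=100.0 * (1.0 - sp),
        fnr=100.0 * (1.0 - se),
        dop=dop(se, sp, ppv, npv),
    )


def dop(se: float, sp: float, ppv: float, npv: float) -> float:
    """Distance to the optimal point: ‖(se, sp, ppv, npv) − (1,1,1,1)‖₂.

    Ranges from 0 (perfect classifier) to 2 (all four statistics zero).
    """
    for name, v in (("se", se), ("sp", sp), ("ppv", ppv), ("npv", npv)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return math.sqrt(
        (se - 1.0) ** 2 + (sp - 1.0) ** 2 + (ppv - 1.0) ** 2 + (npv - 1.0) ** 2
    )


def as_binary_labels(labels) -> np.ndarray:
    """Coerce a label sequence (Label enums, their string values, or 0/1)
    to a 0/1 integer array where 1 = immunogenic."""
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, Label):
            out[i] = 1 if lab is Label.IMMUNOGENIC else 0
        elif isinstance(lab, str):
            out[i] = 1 if Label(lab) is Label.IMMUNOGENIC else 0
        else:
            v = int(lab)
            if v not in (0, 1):
                raise ValueError(f"binary label expected, got {lab!r}")
            out[i] = v
    return out


def orient(values, direction: Direction) -> np.ndarray:
    """Orient raw metric values so that higher always means more immunogenic."""
    v = np.asarray(values, dtype=float)
    if isinstance(direction, str):
        direction = Direction(direction)
    return v if direction is Direction.HIGHER_IS_POSITIVE else -v


def roc_auc(
    scores,
    labels,
    direction: Direction = Direction.HIGHER_IS_POSITIVE,
) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC with scores oriented before computation.

    The AUC is the Mann–Whitney statistic: the probability that a random
    immunogenic record outscores a random non-immunogenic one, ties counted
    half. ROC points are (fpr, tpr) at every distinct oriented threshold,
    including the (0,0) and (1,1) endpoints.
    """
    y = as_binary_labels(labels)
    s = orient(scores, direction)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    if np.all(s == s[0]):
        raise ValueError("AUC undefined: scores are constant")

    # Mann–Whitney identity via midranks.
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # ROC points: sweep thresholds from high to low over distinct values.
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return roc, float(auc)


_ALTERNATIVES = {"two_sided": "two-sided", "a_greater": "greater", "a_less": "less"}

#: Combined-size bound below which the exact rank-sum null is enumerated.
EXACT_MAX_N = 12


def rank_sum_test(group_a, group_b, alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum / Mann–Whitney p-value comparing two samples.

    Exact enumeration when the combined sample size is ≤ 12 and untied;
    otherwise the normal approximation with continuity and tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0  # no evidence either way; the normal approx degenerates
    untied = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= EXACT_MAX_N and untied) else "asymptotic"
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=_ALTERNATIVES[alternative],
        method=method,
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def false_positive_rate_on_negatives(
    rows: pd.DataFrame, spec: MethodSpec, threshold: float
) -> tuple[int, float]:
    """Count and percentage of negative-only rows called immunogenic.

    ``rows`` is a score-table slice with a ``value`` column and, when a
    ``label`` column is present, only non-immunogenic labels.
    """
    from neobench.thresholds import classify

    if len(rows) == 0:
        raise ValueError("empty negative set")
    if "label" in rows.columns:
        y = as_binary_labels(rows["label"].tolist())
        if y.any():
            raise ValueError("negative set contains immunogenic rows")
    calls = classify(rows["value"].to_numpy(), spec, threshold)
    count = int(calls.sum())
    return count, 100.0 * count / len(rows)


def filter_negative_binders(rows: pd.DataFrame) -> pd.DataFrame:
    """Retain non-immunogenic 9/10-mers with measured binding affinity < 500 nM.

    Expects columns ``label``, ``length`` and ``ba`` (measured affinity, nM).
    Rows with a missing affinity are dropped with a warning rather than
    raising.
    """
    required = {"label", "length", "ba"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    ba = pd.to_numeric(rows["ba"], errors="coerce")
    n_missing = int(ba.isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} row(s) lack a measured binding affinity and were dropped",
            stacklevel=2,
        )
    neg = rows["label"].map(
        lambda v: (v.value if isinstance(v, Label) else str(v))
        == Label.NON_IMMUNOGENIC.value
    )
    keep = neg & rows["length"].isin([9, 10]) & (ba < 500)
    return rows.loc[keep.fillna(False)].reset_index(drop=True)
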
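"""Threshold selection: turn a continuous predictor output into a binary
immunogenicity call, either by the predictor authors' published rule or by
minimizing the Distance to the Optimal Point over the observed outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neobench.metrics import (
    ConfusionCounts,
    MetricPanel,
    as_binary_labels,
    metric_panel,
    orient,
)
from neobench.models import AuthorRule, Direction, MethodSpec

__all__ = [
    "ThresholdResult",
    "classify",
    "apply_author_rule",
    "author_threshold",
    "best_threshold_dop",
    "confusion_from_calls",
    "KNOWN_AUTHOR_RULES",
]


@dataclass(frozen=True)
class ThresholdResult:
    spec: MethodSpec
    threshold: float  # on the metric's native scale
    rule: str
    dop_at_threshold: float
    panel: MetricPanel


def classify(values, spec: MethodSpec, threshold: float) -> np.ndarray:
    """Binary immunogenicity calls at a native-scale threshold.

    Boundary convention: a value exactly at the threshold is called positive
    (≥ for higher-is-positive metrics, ≤ for lower-is-positive ones), so every
    candidate threshold drawn from the observed values is attainable.
    """
    v = np.asarray(values, dtype=float)
    if spec.direction is Direction.HIGHER_IS_POSITIVE:
        return v >= threshold
    return v <= threshold


def apply_author_rule(values, rule: AuthorRule) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    ops = {
        "lt": v < rule.cutoff,
        "le": v <= rule.cutoff,
        "gt": v > rule.cutoff,
        "ge": v >= rule.cutoff,
    }
    return ops[rule.comparator]


# Published author rules, keyed by (method, metric). SB/WB are defined on the
# eluted-rank scale; WB counts the SB ∪ WB region positive. PRIME assigns
# score 0 to non-immunogenic peptides, so any positive score is a call.
KNOWN_AUTHOR_RULES: dict[tuple[str, str], dict[str, AuthorRule]] = {
    ("NetMHCpan", "R"): {
        "SB": AuthorRule("le", 0.5, "SB"),
        "WB": AuthorRule("le", 2.0, "WB"),
    },
    ("MHCflurry", "B"): {"A": AuthorRule("lt", 500.0, "A")},
    ("MHCflurry", "BA"): {"A": AuthorRule("lt", 500.0, "A")},
    ("MHCflurry", "P"): {"A": AuthorRule("lt", 2.0, "A")},
    ("DeepHLApan", "I"): {"A": AuthorRule("gt", 0.5, "A")},
    ("PRIME", "S"): {"A": AuthorRule("gt", 0.0, "A")},
    ("PRIME", "SI"): {"A": AuthorRule("gt", 0.0, "A")},
}


def author_threshold(spec: MethodSpec, variant: str | None = None) -> AuthorRule:
    """The author-suggested rule for a method-metric, if one was published.

    ``variant`` selects among multiple published cutoffs (``"SB"``/``"WB"``
    for eluted-rank strong/weak binders); when omitted and a single rule
    exists, that rule is returned. Methods whose authors published no
    threshold (MixMHCpred, DeepImmuno, CIImm) raise.
    """
    if spec.author_rule is not None:
        return spec.author_rule
    rules = KNOWN_AUTHOR_RULES.get((spec.method, spec.metric))
    if not rules:
        raise ValueError(
            f"no author threshold for {spec.method} {spec.metric}; use the DOP rule"
        )
    if variant is None:
        if len(rules) == 1:
            return next(iter(rules.values()))
        raise ValueError(
            f"{spec.method} {spec.metric} has variants {sorted(rules)}; pick one"
        )
    if variant not in rules:
        raise ValueError(f"unknown variant {variant!r} for {spec.method} {spec.metric}")
    return rules[variant]


def confusion_from_calls(calls, labels) -> ConfusionCounts:
    c = np.asarray(calls, dtype=bool)
    y = as_binary_labels(labels).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(c & y)),
        fp=int(np.sum(c & ~y)),
        tn=int(np.sum(~c & ~y)),
        fn=int(np.sum(~c & y)),
    )


def best_threshold_dop(values, labels, spec: MethodSpec) -> ThresholdResult:
    """DOP-minimizing threshold over the observed output values.

    Every distinct observed value is a candidate; for each, records are
    classified (boundary positive), the confusion counts formed, and the
    distance to the optimal point computed. The candidate with the smallest
    DOP wins; ties break toward the candidate classifying more records
    positive (most sensitive), then toward the smaller native value.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    y = as_binary_labels(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold search needs both immunogenic and "
                         "non-immunogenic records")

    s = orient(v, spec.direction)
    candidates = np.unique(s)  # ascending oriented scale
    # positive call: oriented score >= oriented threshold
    pos_sorted = np.sort(s[y == 1])
    neg_sorted = np.sort(s[y == 0])
    tp = n_pos - np.searchsorted(pos_sorted, candidates, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, candidates, side="left")
    fn = n_pos - tp
    tn = n_neg - fp

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(n_pos > 0, tp / n_pos, 0.0)
        sp = np.where(n_neg > 0, tn / n_neg, 0.0)
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        npv = np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), 0.0)
    dops = np.sqrt((se - 1) ** 2 + (sp - 1) ** 2 + (ppv - 1) ** 2 + (npv - 1) ** 2)

    best_dop = dops.min()
    tied = np.flatnonzero(dops <= best_dop + 1e-12)
    # Lower oriented threshold ⇒ more records called positive. Candidates are
    # distinct, so the positive-count key fully resolves the tie; the smaller-
    # native-value key is kept for explicitness on the lower-is-positive scale.
    n_called = tp[tied] + fp[tied]
    native = np.where(
        spec.direction is Direction.HIGHER_IS_POSITIVE,
        candidates[tied],
        -candidates[tied],
    )
    order = sorted(range(len(tied)), key=lambda i: (-n_called[i], native[i]))
    pick = tied[order[0]]

    native_threshold = float(
        candidates[pick]
        if spec.direction is Direction.HIGHER_IS_POSITIVE
        else -candidates[pick]
    )
    counts = ConfusionCounts(
        tp=int(tp[pick]), fp=int(fp[pick]), tn=int(tn[pick]), fn=int(fn[pick])
    )
    panel = metric_panel(counts)
    return ThresholdResult(
        spec=spec,
        threshold=native_threshold,
        rule="dop",
        dop_at_threshold=float(panel.dop),
        panel=panel,
    )
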
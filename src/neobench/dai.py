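"""Differential Agretopicity Index (DAI): wild-type vs mutant comparison of
binding predictions, and its power to discriminate immunogenicity stratified
by mutation anchor class.

Two flavours are computed: the affinity difference DAI = WT_BA − mut_BA
(positive when the mutant binds more strongly, in nM) and the rank ratio
DAI = mut_R / WT_R (above 1 when the mutant ranks worse). For mutations at
non-anchor positions the predictions of the pair are nearly identical, so the
ratio DAI sits near 1 and carries little signal — the stratified analysis
makes that visible rather than averaging it away.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from neobench.metrics import rank_sum_test, roc_auc
from neobench.models import Direction, Label, PositionClass

__all__ = ["DaiRecord", "compute_dai", "dai_discrimination"]


@dataclass
class DaiRecord:
    record_id: str
    position_class: PositionClass
    label: Label
    wt_ba: float | None = None
    mut_ba: float | None = None
    wt_r: float | None = None
    mut_r: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.position_class, str):
            self.position_class = PositionClass(self.position_class)
        if isinstance(self.label, str):
            self.label = Label(self.label)

    @property
    def dai_ba(self) -> float | None:
        if self.wt_ba is None or self.mut_ba is None:
            return None
        return compute_dai(self.wt_ba, self.mut_ba, "difference")

    @property
    def dai_r(self) -> float | None:
        if self.wt_r is None or self.mut_r is None or self.wt_r <= 0:
            return None
        return compute_dai(self.wt_r, self.mut_r, "ratio")


def compute_dai(wt_value: float, mut_value: float, kind: str) -> float:
    """difference → WT − mut (affinities, nM); ratio → mut / WT (ranks)."""
    if not (math.isfinite(wt_value) and math.isfinite(mut_value)):
        raise ValueError("DAI inputs must be finite")
    if kind == "difference":
        return wt_value - mut_value
    if kind == "ratio":
        if wt_value == 0:
            raise ValueError("ratio DAI undefined for wt_value == 0")
        return mut_value / wt_value
    raise ValueError("kind must be 'difference' or 'ratio'")


# Score orientation is an explicit choice, not an auto-flip: by default a
# larger difference-DAI (mutant binds more strongly than WT) and a larger
# ratio-DAI are both treated as pointing toward immunogenic. An invisible
# best-side flip would fabricate discrimination where there is none.
DEFAULT_DIRECTIONS = {
    "difference": Direction.HIGHER_IS_POSITIVE,
    "ratio": Direction.HIGHER_IS_POSITIVE,
}


def dai_discrimination(
    records: list[DaiRecord],
    directions: dict[str, Direction] | None = None,
) -> pd.DataFrame:
    """Per (kind, anchor-stratum) discrimination analysis.

    For each DAI flavour and each mutation-position stratum with both labels
    present: the AUC of the DAI as an immunogenicity score, the two-sided
    rank-sum p-value between labels, the group sizes, and (for the ratio DAI)
    natural-log-scale group means as summaries. Strata with a single label or
    degenerate (constant) DAI values are skipped with a warning.
    """
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    rows = []
    for kind, attr in (("difference", "dai_ba"), ("ratio", "dai_r")):
        for stratum in (PositionClass.ANCHOR, PositionClass.NON_ANCHOR):
            sub = [
                r
                for r in records
                if r.position_class is stratum and getattr(r, attr) is not None
            ]
            if not sub:
                continue
            dai = np.array([getattr(r, attr) for r in sub], dtype=float)
            labels = [r.label for r in sub]
            n_pos = sum(1 for l in labels if l is Label.IMMUNOGENIC)
            n_neg = len(labels) - n_pos
            if n_pos == 0 or n_neg == 0:
                warnings.warn(
                    f"{kind}/{stratum.value}: single-label stratum skipped",
                    stacklevel=2,
                )
                continue
            if np.all(dai == dai[0]):
                warnings.warn(
                    f"{kind}/{stratum.value}: constant DAI (no discrimination "
                    "possible), stratum skipped",
                    stacklevel=2,
                )
                continue
            try:
                _, auc = roc_auc(dai, labels, directions[kind])
            except ValueError as exc:
                warnings.warn(
                    f"{kind}/{stratum.value}: stratum skipped ({exc})", stacklevel=2
                )
                continue
            pos = dai[[l is Label.IMMUNOGENIC for l in labels]]
            neg = dai[[l is Label.NON_IMMUNOGENIC for l in labels]]
            p = rank_sum_test(pos, neg, "two_sided")
            row = {
                "kind": kind,
                "stratum": stratum.value,
                "n_immunogenic": n_pos,
                "n_non_immunogenic": n_neg,
                "auc": auc,
                "p_value": p,
            }
            if kind == "ratio":
                # Log-scale summaries (plotting/reporting only; the test
                # statistic is rank-based and unaffected by the transform).
                row["log_ratio_mean_immunogenic"] = float(np.log(pos).mean())
                row["log_ratio_mean_non_immunogenic"] = float(np.log(neg).mean())
            rows.append(row)
    return pd.DataFrame(rows)
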
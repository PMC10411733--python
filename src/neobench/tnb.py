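"""Tumor Neoantigen Burden (TNB) as an immunotherapy-response biomarker.

A patient's TNB under a given predictor and threshold is the number of their
candidate neoantigens classified immunogenic. The association between burden
(TMB or TNB) and checkpoint-blockade response is measured with the two-sided
Wilcoxon rank-sum test, with no multiple-testing adjustment across the
cohort × method grid by default (a Benjamini–Hochberg flag is available).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from neobench.metrics import rank_sum_test
from neobench.models import CohortPatient, MethodSpec, Response
from neobench.thresholds import classify

__all__ = ["tnb", "association", "association_grid", "annotate_significance"]


def tnb(patient: CohortPatient, spec: MethodSpec, threshold: float) -> int:
    """Count of the patient's candidates classified immunogenic.

    Candidates lacking a value for the requested method-metric are skipped
    with a warning; an empty candidate list gives TNB 0.
    """
    cand = patient.candidates
    if len(cand) == 0:
        return 0
    mask = (cand["method"] == spec.method) & (cand["metric"] == spec.metric)
    n_records = cand["record_id"].nunique()
    covered = cand.loc[mask, "record_id"].nunique()
    if covered < n_records:
        warnings.warn(
            f"{patient.patient_id}: {n_records - covered} candidate(s) lack "
            f"{spec.method_metric_id} values and were skipped",
            stacklevel=2,
        )
    values = cand.loc[mask, "value"].to_numpy(float)
    if values.size == 0:
        return 0
    return int(classify(values, spec, threshold).sum())


def _burdens(
    cohort: list[CohortPatient],
    burden: str,
    spec: MethodSpec | None,
    threshold: float | None,
) -> np.ndarray:
    if burden == "tmb":
        return np.array([p.tmb for p in cohort], dtype=float)
    if burden == "tnb":
        if spec is None or threshold is None:
            raise ValueError("tnb burden requires spec and threshold")
        return np.array([tnb(p, spec, threshold) for p in cohort], dtype=float)
    raise ValueError("burden must be 'tmb' or 'tnb'")


def association(
    cohort: list[CohortPatient],
    burden: str = "tnb",
    spec: MethodSpec | None = None,
    threshold: float | None = None,
) -> float:
    """Two-sided rank-sum p-value comparing burden between responders and
    non-responders. Patients with zero candidates keep TNB 0 and stay in the
    test. Each response group needs at least 2 patients."""
    values = _burdens(cohort, burden, spec, threshold)
    resp = np.array([p.response is Response.RESPONDER for p in cohort])
    if resp.sum() < 2 or (~resp).sum() < 2:
        raise ValueError("each response group needs at least 2 patients")
    return rank_sum_test(values[resp], values[~resp], "two_sided")


def association_grid(
    cohorts: dict[str, list[CohortPatient]],
    specs_thresholds: list[tuple[MethodSpec, float]],
    adjust: bool = False,
) -> pd.DataFrame:
    """Full cohort × method grid of burden–response association p-values.

    Thresholds are expected to be frozen on the curated database (not refit
    per cohort). Per-cell failures (e.g. a degenerate cohort) are recorded as
    absent cells, not raised. ``adjust=True`` adds Benjamini–Hochberg
    adjusted p-values across the computed cells; the unadjusted values mirror
    the convention of reporting each cohort–method association on its own.
    """
    rows = []
    for cohort_name, patients in cohorts.items():
        n_r = sum(p.response is Response.RESPONDER for p in patients)
        n_nr = len(patients) - n_r
        for spec, thr in specs_thresholds:
            row = {
                "cohort": cohort_name,
                "method": spec.method,
                "metric": spec.metric,
                "rule": spec.threshold_rule,
                "threshold": thr,
                "n_responders": n_r,
                "n_non_responders": n_nr,
            }
            try:
                row["p_value"] = association(patients, "tnb", spec, thr)
            except ValueError as exc:
                warnings.warn(
                    f"{cohort_name}/{spec.method_metric_id}: cell absent ({exc})",
                    stacklevel=2,
                )
                row["p_value"] = np.nan
            rows.append(row)
    grid = pd.DataFrame(rows)
    if adjust and len(grid):
        grid["p_adjusted"] = _benjamini_hochberg(grid["p_value"].to_numpy())
    grid["significance"] = grid["p_value"].map(annotate_significance)
    return grid


def annotate_significance(p: float) -> str:
    """Report annotation: the p-value when < 0.05, 'NS' otherwise."""
    if np.isnan(p):
        return "NA"
    return "NS" if p >= 0.05 else f"P = {p:.3g}"


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan, dtype=float)
    q = p[ok]
    m = q.size
    order = np.argsort(q)
    adj = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out
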
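"""TSV readers and writers for the package's external interfaces.

All files are tab-separated UTF-8 with a mandatory header row; ``.`` marks a
missing optional field. Numeric cells may use a decimal comma ("0,88"), as in
the published benchmark table — they are converted on read; all output uses
decimal points.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from neobench.models import (
    CohortPatient,
    Label,
    NeoantigenRecord,
    PeptideHlaPair,
    ScoreTable,
)

__all__ = [
    "SchemaError",
    "read_neoantigen_table",
    "write_neoantigen_table",
    "read_pairs_table",
    "write_pairs_table",
    "read_score_table",
    "write_score_table",
    "read_cohort",
    "write_cohort",
    "read_benchmark_metrics",
    "load_published_benchmark",
    "parse_decimal",
    "labels_from_records",
]

MISSING = "."

NEOANTIGEN_COLUMNS = [
    "record_id",
    "mut_peptide",
    "wt_peptide",
    "hla",
    "gene",
    "tissue",
    "length",
    "mutation_position",
    "position_class",
    "label",
    "evidence",
    "reference",
]

PAIR_COLUMNS = ["pair_id", "peptide", "hla", "label", "source"]
SCORE_COLUMNS = ["dataset_id", "record_id", "method", "metric", "value"]
COHORT_COLUMNS = ["patient_id", "cohort", "response", "tmb"]
COHORT_SCORE_COLUMNS = ["patient_id", "record_id", "method", "metric", "value"]


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unparsable row."""


def parse_decimal(cell) -> float:
    """Parse a numeric cell, accepting decimal commas ("0,88" → 0.88)."""
    if isinstance(cell, (int, float)):
        return float(cell)
    return float(str(cell).strip().replace(",", "."))


def _read_tsv(path, mandatory: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _opt(cell: str) -> str | None:
    return None if cell in ("", MISSING) else cell


def read_neoantigen_table(path) -> list[NeoantigenRecord]:
    """Read a curated neoantigen database.

    Reading only types the fields; substantive rules (lengths, single
    substitution, anchor consistency, evidence flags) are checked separately
    by :func:`neobench.validate.validate_database`, so e.g. a length-8 row
    reads fine and is flagged at validation.
    """
    df = _read_tsv(path, NEOANTIGEN_COLUMNS)
    records = []
    extra_cols = [c for c in df.columns if c not in NEOANTIGEN_COLUMNS]
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after header
        try:
            evidence = [e for e in row["evidence"].split(";") if e and e != MISSING]
            records.append(
                NeoantigenRecord(
                    record_id=row["record_id"],
                    mut_peptide=row["mut_peptide"],
                    wt_peptide=row["wt_peptide"],
                    hla=row["hla"],
                    gene=_opt(row["gene"]),
                    tissue=_opt(row["tissue"]),
                    length=int(row["length"]),
                    mutation_position=int(row["mutation_position"]),
                    position_class=row["position_class"],
                    label=row["label"],
                    evidence=evidence,
                    reference=_opt(row["reference"]),
                    metadata={c: row[c] for c in extra_cols},
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path}: unparsable row at line {line}: {exc}") from exc
    return records


def write_neoantigen_table(records: list[NeoantigenRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "mut_peptide": r.mut_peptide,
                "wt_peptide": r.wt_peptide,
                "hla": r.hla,
                "gene": r.gene or MISSING,
                "tissue": r.tissue or MISSING,
                "length": r.length,
                "mutation_position": r.mutation_position,
                "position_class": r.position_class.value,
                "label": r.label.value,
                "evidence": ";".join(sorted(e.value for e in r.evidence)) or MISSING,
                "reference": r.reference or MISSING,
                **r.metadata,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pairs_table(path) -> list[PeptideHlaPair]:
    df = _read_tsv(path, PAIR_COLUMNS)
    pairs = []
    for i, row in df.iterrows():
        try:
            pairs.append(
                PeptideHlaPair(
                    pair_id=row["pair_id"],
                    peptide=row["peptide"],
                    hla=row["hla"],
                    label=row["label"],
                    source=row["source"],
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: unparsable row at line {i + 2}: {exc}") from exc
    return pairs


def write_pairs_table(pairs: list[PeptideHlaPair], path) -> None:
    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "peptide": p.peptide,
                "hla": p.hla,
                "label": p.label.value,
                "source": p.source.value,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_score_table(path) -> ScoreTable:
    df = _read_tsv(path, SCORE_COLUMNS)
    try:
        df["value"] = df["value"].map(parse_decimal)
    except ValueError as exc:
        raise SchemaError(f"{path}: unparsable value column: {exc}") from exc
    return ScoreTable(df)


def write_score_table(table: ScoreTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_cohort(cohort_path, scores_path=None) -> list[CohortPatient]:
    """Read patients and (optionally) their per-candidate predictor scores."""
    df = _read_tsv(cohort_path, COHORT_COLUMNS)
    scores = None
    if scores_path is not None:
        scores = _read_tsv(scores_path, COHORT_SCORE_COLUMNS)
        scores["value"] = scores["value"].map(parse_decimal)
    patients = []
    for i, row in df.iterrows():
        try:
            cand = (
                scores.loc[
                    scores["patient_id"] == row["patient_id"],
                    ["record_id", "method", "metric", "value"],
                ].reset_index(drop=True)
                if scores is not None
                else pd.DataFrame(columns=["record_id", "method", "metric", "value"])
            )
            patients.append(
                CohortPatient(
                    patient_id=row["patient_id"],
                    cohort=row["cohort"],
                    response=row["response"],
                    tmb=int(row["tmb"]),
                    candidates=cand,
                )
            )
        except ValueError as exc:
            raise SchemaError(
                f"{cohort_path}: unparsable row at line {i + 2}: {exc}"
            ) from exc
    return patients


def write_cohort(patients: list[CohortPatient], cohort_path, scores_path=None) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "cohort": p.cohort,
                "response": p.response.value,
                "tmb": p.tmb,
            }
            for p in patients
        ]
    ).to_csv(cohort_path, sep="\t", index=False)
    if scores_path is not None:
        frames = []
        for p in patients:
            if len(p.candidates):
                f = p.candidates.copy()
                f.insert(0, "patient_id", p.patient_id)
                frames.append(f)
        cols = COHORT_SCORE_COLUMNS
        out = pd.concat(frames)[cols] if frames else pd.DataFrame(columns=cols)
        out.to_csv(scores_path, sep="\t", index=False)


def read_benchmark_metrics(path) -> pd.DataFrame:
    """Read a benchmark metric table (method, metric, threshold, dop, f1, auc,
    fpr, fnr, optionally printed rank/AR columns). Decimal commas and "NA"
    cells are handled."""
    df = _read_tsv(path, ["method", "metric", "threshold", "dop", "f1", "fpr", "fnr"])
    for col in df.columns:
        if col in ("method", "metric", "threshold"):
            continue
        df[col] = df[col].map(
            lambda c: float("nan") if c in ("NA", "", MISSING) else parse_decimal(c)
        )
    return df


def load_published_benchmark() -> pd.DataFrame:
    """The benchmark study's published 16-row performance table.

    Columns: method, metric, threshold, the metric values (dop, f1, auc, fpr,
    fnr) and, for cross-checking, the published rank/AR/ARsd columns. Rows are
    in the published (AR, ARsd)-sorted order.
    """
    ref = importlib.resources.files("neobench.data").joinpath(
        "published_benchmark.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return read_benchmark_metrics(Path(path))


def labels_from_records(records) -> dict[str, Label]:
    """record_id → label mapping from neoantigen records or peptide-HLA pairs."""
    out = {}
    for r in records:
        key = getattr(r, "record_id", None) or r.pair_id
        out[key] = r.label
    return out
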
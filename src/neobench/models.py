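"""Domain types for neoantigen predictor benchmarking.

The central objects are curated neoantigen records (mutant/wild-type peptide
pairs with an HLA restriction and an experimentally determined immunogenicity
label), peptide--HLA validation pairs, method specifications (which predictor
output is being evaluated, which way it points, and how it is thresholded),
long-format score tables, and immune-checkpoint-blockade cohort patients.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "Label",
    "PositionClass",
    "Direction",
    "Source",
    "Response",
    "EvidenceFlag",
    "NeoantigenRecord",
    "PeptideHlaPair",
    "AuthorRule",
    "MethodSpec",
    "ScoreTable",
    "CohortPatient",
    "normalize_hla",
    "is_valid_hla",
    "anchor_positions",
    "find_mutation_position",
    "direction_for_metric",
]

#: The 20 standard amino acids; B, J, O, U, X, Z are rejected at validation.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_HLA_RE = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2}$")


class Label(str, Enum):
    IMMUNOGENIC = "immunogenic"
    NON_IMMUNOGENIC = "non_immunogenic"


class PositionClass(str, Enum):
    ANCHOR = "anchor"
    NON_ANCHOR = "non_anchor"


class Direction(str, Enum):
    """Which way a predictor metric points.

    ``HIGHER_IS_POSITIVE``: larger values mean more immunogenic (scores).
    ``LOWER_IS_POSITIVE``: smaller values mean more immunogenic (affinity nM,
    eluted ranks, percentiles).
    """

    HIGHER_IS_POSITIVE = "higher_is_positive"
    LOWER_IS_POSITIVE = "lower_is_positive"


class Source(str, Enum):
    SNV = "snv"
    FUSION = "fusion"
    INTRON_RETENTION = "intron_retention"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


class Response(str, Enum):
    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"


class EvidenceFlag(str, Enum):
    BINDING_VALIDATED = "binding_validated"
    PRESENTATION_VALIDATED = "presentation_validated"
    IMMUNOGENICITY_ASSAYED = "immunogenicity_assayed"


# Metric-code conventions: affinity (nM), eluted/affinity ranks and
# percentiles point down (lower = stronger/more immunogenic); scores point up.
_LOWER_METRICS = {"BA", "B", "R", "P", "RI"}
_HIGHER_METRICS = {"S", "I", "SI"}


def direction_for_metric(metric: str) -> Direction:
    """Default score direction for a metric code.

    BA/B (binding affinity nM), R (eluted rank %), P (percentile %) and RI
    (immunogenicity rank) are lower-is-positive; S, I, SI scores are
    higher-is-positive.
    """
    code = metric.strip().upper()
    if code in _LOWER_METRICS:
        return Direction.LOWER_IS_POSITIVE
    if code in _HIGHER_METRICS:
        return Direction.HIGHER_IS_POSITIVE
    raise ValueError(f"unknown metric code {metric!r}; pass direction explicitly")


def normalize_hla(allele: str) -> str:
    """Normalize an HLA class-I allele string to 4-digit form.

    Inputs lacking the ``HLA-`` prefix are prefixed, not rejected; whitespace
    is stripped and the locus letter upper-cased. Malformed strings are
    returned normalized-as-far-as-possible — well-formedness is checked by the
    database validator, not here.
    """
    s = allele.strip().upper()
    if s and not s.startswith("HLA-"):
        s = "HLA-" + s
    return s


def is_valid_hla(allele: str) -> bool:
    return bool(_HLA_RE.match(allele))


def anchor_positions(length: int, strict: bool = False) -> frozenset[int]:
    """MHC-I anchor positions for a peptide of the given length.

    Default reading: position 2 and the C-terminal position (so {2, 10} for
    10-mers). ``strict=True`` applies the literal {2, 9} rule regardless of
    length.
    """
    if strict:
        return frozenset({2, 9})
    return frozenset({2, length})


def find_mutation_position(
    wt: str, mut: str, strict_anchors: bool = False
) -> tuple[int, PositionClass]:
    """Locate the single substitution between a WT/mutant peptide pair.

    Returns the 1-based differing position and its anchor/non-anchor class.
    Raises ``ValueError`` if the peptides differ in length or at a number of
    positions other than one (the count is stated in the message).
    """
    if len(wt) != len(mut):
        raise ValueError(
            f"peptide length mismatch: wt has {len(wt)} residues, mut has {len(mut)}"
        )
    diffs = [i for i, (a, b) in enumerate(zip(wt, mut), start=1) if a != b]
    if len(diffs) != 1:
        raise ValueError(
            f"expected exactly 1 substitution between WT and mutant, found {len(diffs)}"
        )
    pos = diffs[0]
    cls = (
        PositionClass.ANCHOR
        if pos in anchor_positions(len(wt), strict=strict_anchors)
        else PositionClass.NON_ANCHOR
    )
    return pos, cls


@dataclass
class NeoantigenRecord:
    """One curated database entry: a mutant 9/10-mer, its WT counterpart,
    the restricting HLA allele and the experimentally determined
    immunogenicity label."""

    record_id: str
    mut_peptide: str
    wt_peptide: str
    hla: str
    length: int
    mutation_position: int
    position_class: PositionClass
    label: Label
    evidence: frozenset[EvidenceFlag] = frozenset()
    gene: str | None = None
    tissue: str | None = None
    reference: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mut_peptide = self.mut_peptide.upper()
        self.wt_peptide = self.wt_peptide.upper()
        self.hla = normalize_hla(self.hla)
        if isinstance(self.position_class, str):
            self.position_class = PositionClass(self.position_class)
        if isinstance(self.label, str):
            self.label = Label(self.label)
        self.evidence = frozenset(EvidenceFlag(e) for e in self.evidence)


@dataclass
class PeptideHlaPair:
    """One validation-set row: a peptide restricted to one allele. A peptide
    restricted to two alleles contributes two pairs."""

    pair_id: str
    peptide: str
    hla: str
    label: Label
    source: Source = Source.OTHER

    def __post_init__(self) -> None:
        self.peptide = self.peptide.upper()
        self.hla = normalize_hla(self.hla)
        if isinstance(self.label, str):
            self.label = Label(self.label)
        if isinstance(self.source, str):
            self.source = Source(self.source)


@dataclass(frozen=True)
class AuthorRule:
    """An author-suggested classification rule on the metric's native scale.

    ``comparator`` is one of lt/le/gt/ge applied as ``value <op> cutoff``;
    a row satisfying the rule is called immunogenic.
    """

    comparator: str
    cutoff: float
    name: str = ""

    _OPS = {"lt", "le", "gt", "ge"}

    def __post_init__(self) -> None:
        if self.comparator not in self._OPS:
            raise ValueError(f"comparator must be one of {sorted(self._OPS)}")


@dataclass
class MethodSpec:
    """A method-metric-threshold combination under evaluation.

    ``threshold_rule`` is either ``"dop"`` (threshold fitted by minimizing
    the distance to the optimal point on the database) or ``"author"``
    (the predictor authors' published rule, carried in ``author_rule``).
    """

    method: str
    metric: str
    direction: Direction | None = None
    threshold_rule: str = "dop"
    author_rule: AuthorRule | None = None

    def __post_init__(self) -> None:
        if isinstance(self.direction, str):
            self.direction = Direction(self.direction)
        if self.direction is None:
            self.direction = direction_for_metric(self.metric)
        if self.threshold_rule not in {"dop", "author"}:
            raise ValueError("threshold_rule must be 'dop' or 'author'")
        if self.threshold_rule == "author" and self.author_rule is None:
            # Late resolution: thresholds.author_threshold fills known rules.
            from neobench.thresholds import author_threshold

            self.author_rule = author_threshold(self)

    @property
    def method_metric_id(self) -> str:
        return f"{self.method}:{self.metric}"

    @property
    def spec_id(self) -> str:
        tag = self.author_rule.name or "A" if self.threshold_rule == "author" else "DOP"
        return f"{self.method}:{self.metric}:{tag}"


class ScoreTable:
    """Long-format predictor outputs: one row per
    (dataset_id, record_id, method, metric) with one continuous value.

    Thin wrapper over a pandas DataFrame; the frame is the substrate of all
    evaluation and is reachable via ``.df``.
    """

    COLUMNS = ["dataset_id", "record_id", "method", "metric", "value"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        df = df.loc[:, self.COLUMNS].copy()
        df["value"] = pd.to_numeric(df["value"])
        if not df["value"].map(lambda v: v == v and abs(v) != float("inf")).all():
            raise ValueError("score table contains non-finite values")
        key = ["dataset_id", "record_id", "method", "metric"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise ValueError(
                "duplicate score row for "
                f"({dup.dataset_id}, {dup.record_id}, {dup.method}, {dup.metric})"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def slice(self, spec: MethodSpec, dataset_id: str | None = None) -> pd.DataFrame:
        """Rows for one method-metric (optionally one dataset), indexed by record."""
        m = (self.df["method"] == spec.method) & (self.df["metric"] == spec.metric)
        if dataset_id is not None:
            m &= self.df["dataset_id"] == dataset_id
        return self.df.loc[m].reset_index(drop=True)

    def join_labels(self, labels: dict[str, Label]) -> pd.DataFrame:
        """Attach immunogenicity labels; every record_id must resolve."""
        out = self.df.copy()
        unresolved = set(out["record_id"]) - set(labels)
        if unresolved:
            raise KeyError(
                f"{len(unresolved)} record_id(s) have no label, e.g. "
                f"{sorted(unresolved)[:3]}"
            )
        out["label"] = out["record_id"].map(lambda r: Label(labels[r]).value)
        return out


@dataclass
class CohortPatient:
    """One ICB-treated patient: response label, tumor mutation burden and the
    per-candidate predictor scores from which the tumor neoantigen burden is
    counted. ``candidates`` has columns record_id, method, metric, value and
    may be empty."""

    patient_id: str
    cohort: str
    response: Response
    tmb: int
    candidates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["record_id", "method", "metric", "value"]
        )
    )

    def __post_init__(self) -> None:
        if isinstance(self.response, str):
            self.response = Response(self.response)
        if self.tmb < 0:
            raise ValueError("tmb must be non-negative")
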
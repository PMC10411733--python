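"""Database inclusion-criteria validation, composition summaries, and
validation-set assembly.

The validator applies every computable inclusion rule for a curated
tumor-specific-neoantigen database: 9/10-mer WT/mutant pairs differing at
exactly one position, consistent mutation-position and anchor-class fields,
well-formed HLA alleles, the standard amino-acid alphabet, the required
experimental-evidence flags, and duplicate detection. Violations are
reported, never raised.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from neobench.models import (
    AMINO_ACIDS,
    EvidenceFlag,
    Label,
    NeoantigenRecord,
    PeptideHlaPair,
    PositionClass,
    Source,
    anchor_positions,
    is_valid_hla,
)

__all__ = [
    "Violation",
    "ValidationReport",
    "validate_database",
    "summarize_database",
    "build_validation_set",
]

_ALPHABET = set(AMINO_ACIDS)


@dataclass(frozen=True)
class Violation:
    record_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    @property
    def counts_by_rule(self) -> dict[str, int]:
        return dict(Counter(v.rule for v in self.violations))

    def add(self, record_id: str, rule: str, message: str) -> None:
        self.violations.append(Violation(record_id, rule, message))

    def __str__(self) -> str:
        if self.passed:
            return "validation passed: 0 violations"
        lines = [f"validation failed: {len(self.violations)} violation(s)"]
        lines += [f"  [{v.rule}] {v.record_id}: {v.message}" for v in self.violations]
        return "\n".join(lines)


def validate_database(
    records: list[NeoantigenRecord], strict_anchors: bool = False
) -> ValidationReport:
    """Apply every computable inclusion rule; returns a report, never raises.

    ``strict_anchors`` switches the anchor set from {2, C-terminus} to the
    literal {2, 9} for all lengths.
    """
    report = ValidationReport()
    seen: dict[tuple[str, str], str] = {}
    for r in records:
        rid = r.record_id
        bad_alpha = (set(r.mut_peptide) | set(r.wt_peptide)) - _ALPHABET
        if bad_alpha:
            report.add(
                rid, "alphabet",
                f"non-standard residue letter(s) {sorted(bad_alpha)}",
            )
        if len(r.mut_peptide) != len(r.wt_peptide):
            report.add(
                rid, "length_pair",
                f"mut length {len(r.mut_peptide)} != wt length {len(r.wt_peptide)}",
            )
        if r.length not in (9, 10):
            report.add(rid, "length_range", f"length {r.length} not in {{9, 10}}")
        if len(r.mut_peptide) != r.length:
            report.add(
                rid, "length_field",
                f"length field {r.length} != peptide length {len(r.mut_peptide)}",
            )
        diffs = [
            i
            for i, (a, b) in enumerate(zip(r.wt_peptide, r.mut_peptide), start=1)
            if a != b
        ]
        if len(r.mut_peptide) == len(r.wt_peptide):
            if len(diffs) == 0:
                report.add(rid, "substitution", "no substitution (mut == wt)")
            elif len(diffs) > 1:
                report.add(
                    rid, "substitution",
                    f"not SNV-derived single substitution ({len(diffs)} differences)",
                )
            elif diffs[0] != r.mutation_position:
                report.add(
                    rid, "mutation_position",
                    f"stated position {r.mutation_position}, observed {diffs[0]}",
                )
        anchors = anchor_positions(r.length, strict=strict_anchors)
        expected = (
            PositionClass.ANCHOR
            if r.mutation_position in anchors
            else PositionClass.NON_ANCHOR
        )
        if r.position_class is not expected:
            report.add(
                rid, "position_class",
                f"position {r.mutation_position} should be {expected.value} "
                f"for anchor set {sorted(anchors)}",
            )
        if not is_valid_hla(r.hla):
            report.add(rid, "hla", f"malformed HLA allele {r.hla!r}")
        required = {EvidenceFlag.BINDING_VALIDATED, EvidenceFlag.IMMUNOGENICITY_ASSAYED}
        missing = required - r.evidence
        if missing:
            report.add(
                rid, "evidence",
                f"missing required evidence flag(s) {sorted(f.value for f in missing)}",
            )
        if (
            r.label is Label.IMMUNOGENIC
            and EvidenceFlag.PRESENTATION_VALIDATED not in r.evidence
        ):
            report.add(
                rid, "evidence",
                "immunogenic record lacks presentation_validated",
            )
        key = (r.mut_peptide, r.hla)
        if key in seen:
            report.add(
                rid, "duplicate",
                f"duplicate (mut_peptide, hla) with record {seen[key]}",
            )
        else:
            seen[key] = rid
    return report


def summarize_database(records: list[NeoantigenRecord]) -> dict:
    """Composition summary: total and per-label / per-allele / per-length /
    per-position-class counts with percentages rounded to 1 decimal."""

    def tally(keys):
        counts = Counter(keys)
        total = len(records)
        return {
            k: {"count": n, "pct": round(100.0 * n / total, 1)}
            for k, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        }

    if not records:
        return {
            "total": 0,
            "by_label": {},
            "by_allele": {},
            "by_length": {},
            "by_position_class": {},
        }
    return {
        "total": len(records),
        "by_label": tally(r.label.value for r in records),
        "by_allele": tally(r.hla for r in records),
        "by_length": tally(r.length for r in records),
        "by_position_class": tally(r.position_class.value for r in records),
    }


def build_validation_set(
    n_neopeptides: int,
    n_multi_hla_neopeptides: int,
    n_neoantigens: int,
    n_multi_hla_neoantigens: int,
    alleles: tuple[str, str] = ("HLA-A*02:01", "HLA-B*07:02"),
) -> list[PeptideHlaPair]:
    """Assemble a prioritization validation set as peptide–HLA pairs.

    ``n_neopeptides`` non-immunogenic peptides of which
    ``n_multi_hla_neopeptides`` carry a second HLA restriction (each such
    peptide contributes two pairs), and likewise ``n_neoantigens`` /
    ``n_multi_hla_neoantigens`` immunogenic ones. The default composition
    used throughout the package is (109, 4, 6, 1) → 113 non-immunogenic +
    7 immunogenic = 120 pairs. Peptide sequences here are structural
    placeholders; scored synthetic sets come from
    :func:`neobench.simulate.simulate_validation_set`.
    """
    for name, val in (
        ("n_neopeptides", n_neopeptides),
        ("n_multi_hla_neopeptides", n_multi_hla_neopeptides),
        ("n_neoantigens", n_neoantigens),
        ("n_multi_hla_neoantigens", n_multi_hla_neoantigens),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_multi_hla_neopeptides > n_neopeptides:
        raise ValueError("multi-HLA neopeptide count exceeds neopeptide total")
    if n_multi_hla_neoantigens > n_neoantigens:
        raise ValueError("multi-HLA neoantigen count exceeds neoantigen total")

    pairs: list[PeptideHlaPair] = []

    def emit(prefix: str, n: int, n_multi: int, label: Label, sources):
        for i in range(n):
            pid = f"{prefix}{i + 1:04d}"
            source = sources[i % len(sources)]
            pairs.append(
                PeptideHlaPair(
                    pair_id=f"{pid}.1",
                    peptide=_placeholder_peptide(prefix, i),
                    hla=alleles[0],
                    label=label,
                    source=source,
                )
            )
            if i < n_multi:
                pairs.append(
                    PeptideHlaPair(
                        pair_id=f"{pid}.2",
                        peptide=_placeholder_peptide(prefix, i),
                        hla=alleles[1],
                        label=label,
                        source=source,
                    )
                )

    emit("VNP", n_neopeptides, n_multi_hla_neopeptides,
         Label.NON_IMMUNOGENIC, [Source.SNV])
    # Non-SNV immunogenic neoantigens: gene fusions, intron retention, and a
    # frameshift-derived open reading frame.
    emit("VNA", n_neoantigens, n_multi_hla_neoantigens, Label.IMMUNOGENIC,
         [Source.FUSION, Source.INTRON_RETENTION, Source.INTRON_RETENTION,
          Source.FUSION, Source.INTRON_RETENTION, Source.FRAMESHIFT])
    return pairs


def _placeholder_peptide(prefix: str, i: int) -> str:
    # Deterministic distinct 9-mers over the standard alphabet.
    letters = AMINO_ACIDS
    base = [letters[(i * 7 + j * 3 + len(prefix)) % 20] for j in range(9)]
    return "".join(base)
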
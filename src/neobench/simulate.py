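"""Synthetic-data generators for every input the benchmark consumes.

The generators emulate the structure of a curated tumor-specific-neoantigen
database (9/10-mer single-substitution WT/mutant pairs with a skewed HLA
distribution and a 129/70 immunogenic/non-immunogenic split), predictor
score tables with controlled discrimination, a 113-negative/7-positive
prioritization validation set, and checkpoint-blockade cohorts with
negative-binomial mutation burdens and a tunable burden–response effect.

Scores follow a binormal model: non-immunogenic latents ~ N(0, 1) and
immunogenic latents ~ N(μ, 1) with μ = √2·Φ⁻¹(AUC), which gives the
requested population AUC exactly; latents are then mapped monotonically to
each metric's native scale (affinity in nM, rank/percentile in %, or a
unit-interval score), which leaves every rank-based quantity unchanged.

A single root seed drives everything; each component (database, scores,
validation set, cohort) draws from its own deterministic substream so
regenerating one component does not shift another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from neobench.models import (
    AMINO_ACIDS,
    CohortPatient,
    Direction,
    EvidenceFlag,
    Label,
    MethodSpec,
    NeoantigenRecord,
    PeptideHlaPair,
    PositionClass,
    Response,
    ScoreTable,
    anchor_positions,
    direction_for_metric,
)
from neobench.validate import build_validation_set

__all__ = [
    "SimulationConfig",
    "simulate_database",
    "simulate_scores",
    "simulate_validation_set",
    "simulate_cohort",
    "binormal_mu",
    "default_method_specs",
]

#: Database composition: 129 immunogenic / 70 non-immunogenic records with
#: HLA-A*02:01 carrying 80 of the 199 restrictions (40.2%). Allele weights
#: are exact counts at the default size, allocated by largest remainder.
DEFAULT_ALLELE_WEIGHTS = {
    "HLA-A*02:01": 80,
    "HLA-A*01:01": 20,
    "HLA-A*03:01": 18,
    "HLA-A*11:01": 15,
    "HLA-A*24:02": 15,
    "HLA-B*07:02": 14,
    "HLA-B*08:01": 13,
    "HLA-B*35:01": 12,
    "HLA-C*07:01": 12,
}

#: Target AUCs per method-metric in the 0.52–0.60 regime the benchmarked
#: predictors reach on the curated database.
DEFAULT_TARGET_AUC = {
    "DeepHLApan:I": 0.57,
    "MHCflurry:B": 0.60,
    "MHCflurry:P": 0.53,
    "PRIME:SI": 0.58,
    "PRIME:RI": 0.57,
    "DeepImmune:I": 0.52,
    "NetMHCpan:R": 0.56,
    "NetMHCpan:B": 0.57,
    "MixMHCpred:S": 0.52,
    "MixMHCpred:R": 0.54,
    "CIImm:I": 0.55,
}

_GENES = ["KRAS", "TP53", "PIK3CA", "BRAF", "EGFR", "CTNNB1"]
_TISSUES = ["melanoma", "lung", "colorectal", "breast", "pancreas"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Database: ``n_positive``/``n_negative`` records, allele weights, a 9/10-mer
    length mix and optionally an oversampled anchor fraction. Scores: one
    target AUC per method-metric id ("method:METRIC"). Validation set: the
    four composition counts. Cohorts: patient count, responder fraction,
    negative-binomial TMB (mean and dispersion/size), the per-mutation
    candidate rate, and ``burden_effect`` — the multiplicative shift applied
    to responders' candidate counts (1.0 = no burden–response association).
    """

    seed: int = 0
    # database
    n_positive: int = 129
    n_negative: int = 70
    allele_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_WEIGHTS)
    )
    length_mix: dict[int, float] = field(default_factory=lambda: {9: 0.8, 10: 0.2})
    anchor_fraction: float | None = None  # None → positions uniform over 1..length
    strict_anchors: bool = False
    # scores
    target_auc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_AUC)
    )
    affinity_scale: tuple[float, float] = (6.5, 1.2)  # nM = exp(a − b·latent)
    # validation set
    n_neopeptides: int = 109
    n_multi_hla_neopeptides: int = 4
    n_neoantigens: int = 6
    n_multi_hla_neoantigens: int = 1
    # cohort
    n_patients: int = 40
    responder_fraction: float = 0.35
    tmb_mean: float = 200.0
    tmb_dispersion: float = 2.0
    candidate_rate: float = 0.5
    burden_effect: float = 1.0

    def __post_init__(self) -> None:
        for mm, auc in self.target_auc.items():
            if not 0.5 < auc < 1.0:
                raise ValueError(f"target_auc[{mm!r}]={auc} outside (0.5, 1)")
        for p in (self.responder_fraction, self.candidate_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.length_mix.values()) - 1.0) > 1e-9:
            raise ValueError("length_mix must sum to 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component substream of the root seed."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def binormal_mu(target_auc: float) -> float:
    """Positive-class latent mean giving the target AUC under the binormal
    model with unit variances: μ = √2·Φ⁻¹(AUC)."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError(f"target_auc={target_auc} outside (0.5, 1)")
    return float(np.sqrt(2.0) * stats.norm.ppf(target_auc))


def _allocate_exact(weights: dict[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n items to categories, preserving the
    weight proportions exactly at matching totals (80/199 stays 80/199)."""
    total = sum(weights.values())
    quotas = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    shortfall = n - sum(counts.values())
    by_remainder = sorted(
        weights, key=lambda k: (-(quotas[k] - counts[k]), k)
    )
    for k in by_remainder[:shortfall]:
        counts[k] += 1
    out = []
    for k, c in counts.items():
        out.extend([k] * c)
    return out


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def simulate_database(cfg: SimulationConfig) -> list[NeoantigenRecord]:
    """Synthetic curated database passing the validator with zero violations."""
    rng = _rng(cfg.seed, "database")
    n = cfg.n_positive + cfg.n_negative
    alleles = _allocate_exact(cfg.allele_weights, n)
    rng.shuffle(alleles)
    lengths = _allocate_exact(
        {str(k): v for k, v in cfg.length_mix.items()}, n
    )
    rng.shuffle(lengths)

    records = []
    for i in range(n):
        length = int(lengths[i])
        wt = _random_peptide(rng, length)
        anchors = sorted(anchor_positions(length, strict=cfg.strict_anchors))
        if cfg.anchor_fraction is not None and rng.random() < cfg.anchor_fraction:
            pos = int(rng.choice(anchors))
        else:
            pos = int(rng.integers(1, length + 1))
        old = wt[pos - 1]
        new = rng.choice([a for a in AMINO_ACIDS if a != old])
        mut = wt[: pos - 1] + new + wt[pos:]
        label = Label.IMMUNOGENIC if i < cfg.n_positive else Label.NON_IMMUNOGENIC
        evidence = {EvidenceFlag.BINDING_VALIDATED, EvidenceFlag.IMMUNOGENICITY_ASSAYED}
        if label is Label.IMMUNOGENIC:
            evidence.add(EvidenceFlag.PRESENTATION_VALIDATED)
        records.append(
            NeoantigenRecord(
                record_id=f"TSN{i + 1:04d}",
                mut_peptide=mut,
                wt_peptide=wt,
                hla=alleles[i],
                gene=_GENES[i % len(_GENES)],
                tissue=_TISSUES[i % len(_TISSUES)],
                length=length,
                mutation_position=pos,
                position_class=(
                    PositionClass.ANCHOR if pos in anchors else PositionClass.NON_ANCHOR
                ),
                label=label,
                evidence=frozenset(evidence),
                reference=f"synthetic:{cfg.seed}",
            )
        )
    return records


def _to_native(latent: np.ndarray, metric: str, cfg: SimulationConfig) -> np.ndarray:
    """Monotone map from the latent immunogenicity axis to the metric's
    native scale and direction."""
    direction = direction_for_metric(metric)
    code = metric.upper()
    if code in {"BA", "B"}:
        a, b = cfg.affinity_scale
        return np.exp(a - b * latent)  # nM, decreasing in latent
    if direction is Direction.LOWER_IS_POSITIVE:  # R, P, RI: percent scale
        return 100.0 * stats.norm.cdf(-latent)
    return stats.norm.cdf(latent)  # S, I, SI: unit-interval score


def simulate_scores(
    records,
    cfg: SimulationConfig,
    dataset_id: str = "db",
    stream: str = "scores",
) -> ScoreTable:
    """Binormal predictor outputs for labeled records, one row per
    (record, method-metric), mapped to each metric's native scale."""
    rng = _rng(cfg.seed, f"{stream}:{dataset_id}")
    ids = [getattr(r, "record_id", None) or r.pair_id for r in records]
    is_pos = np.array([r.label is Label.IMMUNOGENIC for r in records], dtype=float)
    frames = []
    for mm_id, auc in cfg.target_auc.items():
        method, metric = mm_id.split(":")
        latent = rng.standard_normal(len(records)) + binormal_mu(auc) * is_pos
        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": dataset_id,
                    "record_id": ids,
                    "method": method,
                    "metric": metric,
                    "value": _to_native(latent, metric, cfg),
                }
            )
        )
    return ScoreTable(pd.concat(frames, ignore_index=True))


def simulate_validation_set(
    cfg: SimulationConfig,
) -> tuple[list[PeptideHlaPair], ScoreTable]:
    """Prioritization validation set (default 113 non-immunogenic + 7
    immunogenic peptide–HLA pairs) with scores from the binormal model."""
    pairs = build_validation_set(
        cfg.n_neopeptides,
        cfg.n_multi_hla_neopeptides,
        cfg.n_neoantigens,
        cfg.n_multi_hla_neoantigens,
    )
    scores = simulate_scores(pairs, cfg, dataset_id="validation")
    return pairs, scores


def simulate_cohort(cfg: SimulationConfig, cohort_id: str = "cohort1") -> list[CohortPatient]:
    """Checkpoint-blockade cohort with negative-binomial TMB and per-patient
    candidate lists.

    TMB ~ NegBin(mean, dispersion); the candidate count is Binomial(TMB,
    candidate_rate); responders' counts are multiplied by ``burden_effect``
    before rounding, so 1.0 means no burden–response association. Candidate
    scores are unlabeled latents N(0,1) mapped to each metric's native scale.
    """
    n_resp = int(round(cfg.n_patients * cfg.responder_fraction))
    responses = [Response.RESPONDER] * n_resp + [Response.NON_RESPONDER] * (
        cfg.n_patients - n_resp
    )
    p_nb = cfg.tmb_dispersion / (cfg.tmb_dispersion + cfg.tmb_mean)
    patients = []
    for i, response in enumerate(responses):
        # one substream per patient: varying burden_effect perturbs only the
        # responders' candidate counts, never another patient's draws
        rng = _rng(cfg.seed, f"cohort:{cohort_id}:patient:{i}")
        tmb = int(rng.negative_binomial(cfg.tmb_dispersion, p_nb))
        n_cand = int(rng.binomial(tmb, cfg.candidate_rate))
        if response is Response.RESPONDER:
            n_cand = int(round(n_cand * cfg.burden_effect))
        frames = []
        for mm_id in cfg.target_auc:
            method, metric = mm_id.split(":")
            latent = rng.standard_normal(n_cand)
            frames.append(
                pd.DataFrame(
                    {
                        "record_id": [f"C{i + 1:03d}.{j + 1}" for j in range(n_cand)],
                        "method": method,
                        "metric": metric,
                        "value": _to_native(latent, metric, cfg),
                    }
                )
            )
        candidates = (
            pd.concat(frames, ignore_index=True)
            if frames and n_cand
            else pd.DataFrame(columns=["record_id", "method", "metric", "value"])
        )
        patients.append(
            CohortPatient(
                patient_id=f"{cohort_id}.P{i + 1:03d}",
                cohort=cohort_id,
                response=response,
                tmb=tmb,
                candidates=candidates,
            )
        )
    return patients


def default_method_specs(cfg: SimulationConfig) -> list[MethodSpec]:
    """One DOP-thresholded MethodSpec per simulated method-metric."""
    specs = []
    for mm_id in cfg.target_auc:
        method, metric = mm_id.split(":")
        specs.append(MethodSpec(method=method, metric=metric))
    return specs
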
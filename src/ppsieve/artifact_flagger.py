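"""Flagging of clinically labelled variants as processed-pseudogene artifacts.

A PP-derived false positive in a parent gene has three hallmarks: it sits on
an intron-exon junction (the PP lacks the intron, so misaligned junction
reads create frameshift/splice-loss calls there), its carriers are confined
to PP-positive samples, and its allelic balance is diluted below the 50%
heterozygous mode. A variant is flagged ``likely_pp_artifact`` when all
evaluable criteria hold:

  1. junction distance <= junction_window,
  2. carrier status associates with PP status (Pearson chi-squared on the
     2x2 carrier x PP table, p < alpha, enrichment in the PP group),
  3. mean carrier AB <= ab_ceiling.

Clinical labels (P/LP) are inputs; no pathogenicity classification happens
here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ppsieve.allelic_balance import VariantObservation, allelic_balance
from ppsieve.annotation_model import GeneModel, nearest_junction_distance
from ppsieve.pp_detector import CohortPPMatrix

logger = logging.getLogger(__name__)

LIKELY_PP_ARTIFACT = "likely_pp_artifact"
NOT_FLAGGED = "not_flagged"


@dataclass
class ClinicalVariant:
    """A clinically labelled small variant and the samples that carry it."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str
    clinical_label: str  # P / LP / other
    carriers: set = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FlagParams:
    """Artifact-flagging thresholds.

    junction_window: max bp from an exon junction (±10 covers the canonical
        splice region).
    ab_ceiling: max mean carrier AB (0.40 separates the PP-shifted 25-33%
        band from the 50% het mode).
    alpha: chi-squared significance level; bonferroni divides it by the
        number of variants tested when enabled.
    yates: continuity correction for the chi-squared test.
    """

    junction_window: int = 10
    ab_ceiling: float = 0.40
    alpha: float = 0.05
    yates: bool = False
    bonferroni: bool = False


@dataclass(frozen=True)
class ArtifactVerdict:
    """Per-variant evidence and final artifact flag.

    Criterion fields are None when unevaluable (e.g. no AB data); the flag
    is then decided on the remaining criteria.
    """

    variant: ClinicalVariant
    junction_distance: int | None
    n_carriers_with_pp: int
    n_carriers_without_pp: int
    chi2_stat: float | None
    p_value: float | None
    mean_carrier_ab: float | None
    junction_criterion: bool | None
    association_criterion: bool | None
    ab_criterion: bool | None
    flag: str


def read_clinical_tsv(path: str | Path) -> list[ClinicalVariant]:
    """Read a clinical-variant table: chrom, pos, ref, alt, gene, label."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene_id", "clinical_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical TSV missing columns: {sorted(missing)}")
    return [
        ClinicalVariant(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            gene_id=r.gene_id,
            clinical_label=r.clinical_label,
        )
        for r in df.itertuples()
    ]


def assign_carriers(
    variants: Sequence[ClinicalVariant], observations: Iterable[VariantObservation]
) -> None:
    """Fill each variant's carrier set from per-sample VCF observations."""
    by_key: dict[tuple, ClinicalVariant] = {v.key: v for v in variants}
    for obs in observations:
        v = by_key.get((obs.chrom, obs.pos, obs.ref, obs.alt))
        if v is not None:
            v.carriers.add(obs.sample_id)


def contingency(
    variant: ClinicalVariant, pp_matrix: CohortPPMatrix, gene_id: str
) -> np.ndarray:
    """2x2 table: rows = variant carrier yes/no, columns = PP present yes/no."""
    if gene_id not in pp_matrix.matrix.columns:
        raise ValueError(f"gene {gene_id} absent from PP matrix")
    if pp_matrix.n_samples < 2:
        raise ValueError("cohort must contain at least 2 samples")
    if not variant.carriers:
        raise ValueError(f"variant {variant.key} has no carriers")
    pp_carriers = pp_matrix.carriers(gene_id)
    cohort = set(pp_matrix.matrix.index)
    carriers = variant.carriers & cohort
    a = len(carriers & pp_carriers)
    b = len(carriers) - a
    c = len(pp_carriers) - a
    d = pp_matrix.n_samples - a - b - c
    return np.array([[a, b], [c, d]], dtype=np.int64)


class UndefinedTestError(ValueError):
    """Chi-squared test undefined (a zero margin)."""


def chi_squared_test(
    table: np.ndarray | Sequence[Sequence[int]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 df, optional Yates correction.

    Returns (statistic, p-value). Both margins must be positive; a zero row
    or column margin leaves expected counts undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise UndefinedTestError("zero margin: chi-squared test undefined")
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def flag_variant(
    variant: ClinicalVariant,
    gene: GeneModel,
    pp_matrix: CohortPPMatrix,
    carrier_ab: Sequence[float] | None,
    params: FlagParams = FlagParams(),
    n_tests: int = 1,
) -> ArtifactVerdict:
    """Evaluate the three artifact criteria and return the verdict.

    carrier_ab holds the AB values observed in the variant's carriers; pass
    None when AB evidence is unavailable, in which case the flag is decided
    on the junction and association criteria alone.
    """
    span = gene.span
    if not span.start <= variant.pos - 1 < span.end:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} outside span of {gene.gene_id}"
        )
    # junction proximity
    if gene.junctions:
        jdist: int | None = nearest_junction_distance(variant.pos, gene)
        junction_ok: bool | None = jdist <= params.junction_window
    else:
        jdist, junction_ok = None, None

    # cohort association
    table = contingency(variant, pp_matrix, gene.gene_id)
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    alpha = params.alpha / max(n_tests, 1) if params.bonferroni else params.alpha
    try:
        chi2_stat, p_value = chi_squared_test(table, correction=params.yates)
        # enrichment direction: carrier rate higher among PP-positive samples
        pp_total, no_pp_total = a + c, b + d
        enriched = (a / pp_total) > (b / no_pp_total)
        association_ok: bool | None = (p_value < alpha) and enriched
    except UndefinedTestError:
        chi2_stat, p_value, association_ok = None, None, None

    # allelic balance
    if carrier_ab:
        mean_ab: float | None = float(np.mean(carrier_ab))
        ab_ok: bool | None = mean_ab <= params.ab_ceiling
    else:
        mean_ab, ab_ok = None, None
        logger.warning(
            "%s:%s no AB data; criterion unevaluable", variant.chrom, variant.pos
        )

    evaluable = [c for c in (junction_ok, association_ok, ab_ok) if c is not None]
    flagged = bool(evaluable) and all(evaluable)
    return ArtifactVerdict(
        variant=variant,
        junction_distance=jdist,
        n_carriers_with_pp=a,
        n_carriers_without_pp=b,
        chi2_stat=chi2_stat,
        p_value=p_value,
        mean_carrier_ab=mean_ab,
        junction_criterion=junction_ok,
        association_criterion=association_ok,
        ab_criterion=ab_ok,
        flag=LIKELY_PP_ARTIFACT if flagged else NOT_FLAGGED,
    )


def flag_clinical_variants(
    variants: Sequence[ClinicalVariant],
    genes: Mapping[str, GeneModel],
    pp_matrix: CohortPPMatrix,
    observations: Sequence[VariantObservation],
    params: FlagParams = FlagParams(),
) -> list[ArtifactVerdict]:
    """Flag a batch of clinical variants against cohort evidence.

    Carrier sets are filled from the observations when empty; AB values come
    from the same observations.
    """
    assign_carriers(variants, observations)
    ab_by_key: dict[tuple, list[float]] = {}
    keys = {v.key for v in variants}
    for obs in observations:
        k = (obs.chrom, obs.pos, obs.ref, obs.alt)
        if k in keys:
            ab_by_key.setdefault(k, []).append(allelic_balance(obs))
    verdicts = []
    for v in variants:
        if v.gene_id not in genes:
            warnings.warn(f"variant {v.key}: gene {v.gene_id} not in annotation; skipped")
            continue
        if not v.carriers:
            warnings.warn(f"variant {v.key}: no carriers in cohort; skipped")
            continue
        verdicts.append(
            flag_variant(
                v,
                genes[v.gene_id],
                pp_matrix,
                ab_by_key.get(v.key),
                params,
                n_tests=len(variants),
            )
        )
    return verdicts


def flagged_sample_percentage(flagged_samples: Iterable[str] | int, cohort_size: int) -> float:
    """Percent of the cohort carrying at least one flagged variant.

    Accepts either the set of unique flagged sample ids or their count.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    n = flagged_samples if isinstance(flagged_samples, int) else len(set(flagged_samples))
    return 100.0 * n / cohort_size


def fp_report(
    flags_by_caller: Mapping[str, Mapping[str, set]],
    cohort_size: int | None = None,
) -> pd.DataFrame:
    """Long-format false-positive report: caller x gene x flagged-carrier count.

    ``flags_by_caller`` maps caller name -> {gene_id -> set of flagged
    carrier samples}. Genes are unioned across callers so a caller with zero
    flags keeps its all-zero rows. With ``cohort_size``, a per-caller
    ``percent_samples`` column reports the unique flagged-sample percentage.
    """
    if not flags_by_caller:
        raise ValueError("at least one caller result set required")
    all_genes = sorted({g for flags in flags_by_caller.values() for g in flags})
    rows = []
    for caller, flags in flags_by_caller.items():
        unique_samples = set().union(*flags.values()) if flags else set()
        for gene in all_genes:
            row = {
                "caller": caller,
                "gene_id": gene,
                "n_flagged_carriers": len(flags.get(gene, set())),
            }
            if cohort_size is not None:
                row["percent_samples"] = flagged_sample_percentage(
                    unique_samples, cohort_size
                )
            rows.append(row)
    return pd.DataFrame(rows)


def write_verdicts_tsv(verdicts: Sequence[ArtifactVerdict], path: str | Path) -> None:
    def fmt(x, spec="{:.4g}"):
        return "NA" if x is None else (spec.format(x) if isinstance(x, float) else str(x))

    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tgene_id\tclinical_label\tn_carriers\t"
            "junction_distance\tn_carriers_with_pp\tn_carriers_without_pp\t"
            "chi2_stat\tp_value\tmean_carrier_ab\tjunction_criterion\t"
            "association_criterion\tab_criterion\tflag\n"
        )
        for vd in verdicts:
            v = vd.variant
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene_id,
                        v.clinical_label,
                        str(len(v.carriers)),
                        fmt(vd.junction_distance),
                        str(vd.n_carriers_with_pp),
                        str(vd.n_carriers_without_pp),
                        fmt(vd.chi2_stat),
                        fmt(vd.p_value, "{:.3g}"),
                        fmt(vd.mean_carrier_ab),
                        fmt(vd.junction_criterion),
                        fmt(vd.association_criterion),
                        fmt(vd.ab_criterion),
                        vd.flag,
                    ]
                )
                + "\n"
            )
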
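"""Allelic balance (AB) computation and per-gene AB distribution summaries.

AB is the fraction of reads supporting the alternative allele at a site,
computed from the VCF AD field (DP also counts uninformative reads, so the
AD sum is the denominator). True heterozygous variants sit near 50% and
homozygous-alt near 100%; variants that actually live on a processed
pseudogene are diluted by parent-gene reads and shift to ~25-33%:

    expected AB = variant_copies / (gene_copies + pp_copies)

e.g. 1/3 for a variant on the single PP copy of a heterozygous carrier.
Distribution summaries use a histogram of twenty 5%-wide bins on [0, 1]
(the last bin closed, so AB = 1 lands in [95%, 100%]); at 30x depth the het
peak dominates the [50%, 55%) bin and the hom peak the [95%, 100%] bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

HET = "het"
HOM_ALT = "hom_alt"
OTHER = "other"

# 20 five-percent-wide bins with edges at multiples of 5%; np.histogram
# closes the last bin, so AB = 1 is counted in [0.95, 1.0]
AB_BIN_EDGES = np.round(np.arange(0, 21) * 0.05, 2)
AB_BIN_CENTERS = np.round(AB_BIN_EDGES[:-1] + 0.025, 3)


@dataclass(frozen=True)
class VariantObservation:
    """One small-variant call in one sample, with its AD read counts."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # het / hom_alt / other
    ad_ref: int
    ad_alt: int

    def __post_init__(self) -> None:
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("AD counts must be non-negative")


def allelic_balance(obs: VariantObservation) -> float:
    """ad_alt / (ad_ref + ad_alt); requires positive total informative depth."""
    total = obs.ad_ref + obs.ad_alt
    if total <= 0:
        raise ValueError(
            f"{obs.chrom}:{obs.pos} in {obs.sample_id}: zero informative depth"
        )
    return obs.ad_alt / total


def expected_ab(gene_copies: int, pp_copies: int, variant_copies: int) -> float:
    """Idealized copy-ratio AB: variant copies over total aligned gene copies.

    A het variant in a PP-free diploid is (2, 0, 1) -> 0.5; a variant on the
    single PP copy of a het carrier is (2, 1, 1) -> 1/3.
    """
    if min(gene_copies, pp_copies, variant_copies) < 0:
        raise ValueError("copy numbers must be non-negative")
    total = gene_copies + pp_copies
    if total <= 0:
        raise ValueError("total copy number must be positive")
    if variant_copies > total:
        raise ValueError("variant copies exceed total copies")
    return variant_copies / total


def _classify_genotype(allele_a: int, allele_b: int, alt_index: int) -> str | None:
    """Genotype for ALT number ``alt_index`` (1-based); None when missing."""
    if allele_a < 0 or allele_b < 0:
        return None
    pair = sorted((allele_a, allele_b))
    if pair == [alt_index, alt_index]:
        return HOM_ALT
    if pair == [0, alt_index]:
        return HET
    if alt_index in pair:
        return OTHER
    return None  # this ALT not carried


def read_small_vcf(
    vcf_path: str | Path,
    sample_id: str | None = None,
    include_genotypes: tuple[str, ...] = (HET, HOM_ALT),
) -> list[VariantObservation]:
    """Read GT/AD observations from a small-variant VCF.

    Multiallelic records are split per ALT, with AB computed against that
    ALT's AD entry. Records without AD, with missing genotypes, or with zero
    informative depth are excluded (warned once per file).
    """
    vcf_path = str(vcf_path)
    vcf = VCF(vcf_path)
    samples = vcf.samples or ([sample_id] if sample_id else [])
    if not samples:
        samples = [Path(vcf_path).stem]
    out: list[VariantObservation] = []
    n_excluded = 0
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            n_excluded += 1
            continue
        genotypes = rec.genotypes
        for si, sample in enumerate(samples):
            sid = sample_id if (sample_id and len(samples) == 1) else sample
            alleles = genotypes[si][:-1]
            if len(alleles) < 2:
                continue
            for ai, alt in enumerate(rec.ALT):
                gt = _classify_genotype(alleles[0], alleles[1], ai + 1)
                if gt is None or gt not in include_genotypes:
                    continue
                ad_ref = int(ad[si][0]) if ad[si][0] >= 0 else 0
                ad_alt = int(ad[si][ai + 1]) if ad[si][ai + 1] >= 0 else 0
                if ad_ref + ad_alt <= 0:
                    n_excluded += 1
                    continue
                out.append(
                    VariantObservation(
                        sample_id=sid,
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        genotype=gt,
                        ad_ref=ad_ref,
                        ad_alt=ad_alt,
                    )
                )
    vcf.close()
    if n_excluded:
        warnings.warn(f"{vcf_path}: {n_excluded} records excluded (no AD or zero depth)")
    return out


def ab_histogram(values: Sequence[float]) -> np.ndarray:
    """Counts per 5% bin (20 bins over [0, 1]); sums to len(values)."""
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("AB values must lie in [0, 1]")
    counts, _ = np.histogram(arr, bins=AB_BIN_EDGES)
    return counts


def histogram_modes(counts: np.ndarray) -> list[float]:
    """Bin centers of local maxima of a histogram.

    A bin (or plateau of equal bins) is a mode when its count is positive
    and strictly greater than both flanking counts; missing flanks count as
    lower. A plateau is reported once, at its lowest-AB bin.
    """
    counts = np.asarray(counts)
    n = len(counts)
    modes = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left = counts[i - 1] if i > 0 else -1
        right = counts[j + 1] if j + 1 < n else -1
        if counts[i] > 0 and counts[i] > left and counts[i] > right:
            modes.append(float(AB_BIN_CENTERS[i]))
        i = j + 1
    return modes


@dataclass(frozen=True)
class ABSummary:
    """AB distribution for one (gene, PP status) group."""

    gene_id: str
    group: str  # PP_present / no_PP (or any label)
    n_variants: int
    mean_ab: float
    histogram: tuple[int, ...]  # 20 five-percent bins
    modes: tuple[float, ...]  # bin centers, as fractions

    @property
    def mode_percent(self) -> tuple[float, ...]:
        return tuple(100 * m for m in self.modes)

    @property
    def dominant_mode(self) -> float:
        """Bin center (fraction) of the highest-count mode."""
        if not self.modes:
            raise ValueError("distribution has no modes")
        centers = list(AB_BIN_CENTERS)
        return max(self.modes, key=lambda m: self.histogram[centers.index(m)])


def summarize_ab(
    observations: Sequence[VariantObservation], gene_id: str, group: str
) -> ABSummary:
    """Mean, 5%-bin histogram and histogram modes of a group's AB values."""
    if not observations:
        raise ValueError(f"empty group {group} for gene {gene_id}")
    values = [allelic_balance(o) for o in observations]
    counts = ab_histogram(values)
    return ABSummary(
        gene_id=gene_id,
        group=group,
        n_variants=len(values),
        mean_ab=float(np.mean(values)),
        histogram=tuple(int(c) for c in counts),
        modes=tuple(histogram_modes(counts)),
    )


def summarize_groups(
    grouped: Mapping[tuple[str, str], Sequence[VariantObservation]],
) -> list[ABSummary]:
    """summarize_ab over a {(gene_id, group): observations} mapping.

    Empty groups are omitted with a warning rather than raising.
    """
    out = []
    for (gene_id, group), obs in sorted(grouped.items()):
        if not obs:
            warnings.warn(f"empty AB group ({gene_id}, {group}) omitted")
            continue
        out.append(summarize_ab(obs, gene_id, group))
    return out


def variants_per_sample(
    observations: Sequence[VariantObservation], sample_ids: Sequence[str]
) -> pd.Series:
    """Variant count per sample over the given cohort (zeros included)."""
    counts = pd.Series(0, index=pd.Index(sample_ids, name="sample_id"), dtype=int)
    for o in observations:
        if o.sample_id in counts.index:
            counts[o.sample_id] += 1
    return counts


def variant_excess(
    pp_counts: Sequence[float], no_pp_counts: Sequence[float]
) -> float:
    """Ratio of mean variants-per-sample, PP carriers over non-carriers.

    PP carriers accumulate the pseudogene's divergence variants on top of
    the background, so this ratio measures the excess call burden. A zero
    non-carrier mean yields +inf with a warning.
    """
    if len(pp_counts) == 0 or len(no_pp_counts) == 0:
        raise ValueError("both groups must be non-empty")
    num = float(np.mean(pp_counts))
    den = float(np.mean(no_pp_counts))
    if den == 0:
        warnings.warn("non-carrier group has zero mean variant count")
        return float("inf")
    return num / den


def write_summaries_tsv(summaries: Sequence[ABSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgroup\tn_variants\tmean_ab\tmodes_percent\thistogram\n")
        for s in summaries:
            modes = ",".join(f"{m:g}" for m in s.mode_percent)
            hist = ",".join(str(c) for c in s.histogram)
            fh.write(
                f"{s.gene_id}\t{s.group}\t{s.n_variants}\t{s.mean_ab:.4f}\t{modes}\t{hist}\n"
            )
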
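"""Processed-pseudogene calling from SV deletion records.

A PP inserts an intronless gene copy elsewhere in the genome; reads from it
align back to the parent gene and span exon-exon junctions, so SV callers in
the LUMPY/Smoove family emit one deletion call per intron with breakpoints
at the intron boundaries. A sample is called a PP carrier for a gene when
deletions breakpoint-match at least ``min_matched_introns`` of its introns.

Matching is breakpoint-anchored (both deletion ends within ``tol`` of the
intron ends), not reciprocal-overlap: a genuine genomic deletion rarely hits
both intron boundaries, and a deletion spanning several introns matches none
of them — that pattern indicates a real deletion, not a retrocopy.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from ppsieve.annotation_model import GeneModel, GenomicInterval, genes_by_chrom

logger = logging.getLogger(__name__)

PP_PRESENT = "PP_present"
NO_PP = "no_PP"
UNDETECTABLE = "undetectable"


@dataclass(frozen=True)
class DeletionCall:
    """One SVTYPE=DEL record from a sample's SV VCF."""

    sample_id: str
    interval: GenomicInterval
    sv_id: str = "."
    quality: float | None = None


@dataclass(frozen=True)
class PPCall:
    """Per (sample, gene) PP verdict with supporting evidence counts."""

    sample_id: str
    gene_id: str
    n_introns_total: int
    n_introns_matched: int
    matched_intron_indices: tuple[int, ...]
    verdict: str

    def __post_init__(self) -> None:
        if not 0 <= self.n_introns_matched <= max(self.n_introns_total, 0):
            raise ValueError("matched introns out of range")


@dataclass(frozen=True)
class DetectorParams:
    """Detection thresholds.

    min_matched_introns: how many breakpoint-matched introns call a PP.
        One intronic deletion is a common true SV; two breakpoint-exact
        intron matches are the PP-specific signature, hence the default 2.
    tol: breakpoint tolerance in bp (SV callers place breakpoints
        imprecisely).
    """

    min_matched_introns: int = 2
    tol: int = 10

    def __post_init__(self) -> None:
        if self.min_matched_introns < 1:
            raise ValueError("min_matched_introns must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


def parse_sv_vcf(
    vcf_path: str | Path,
    sample_id: str | None = None,
    filter_policy: str = "pass",
) -> list[DeletionCall]:
    """Read SVTYPE=DEL records from an SV VCF (Smoove/LUMPY dialect).

    The deletion end comes from INFO/END, or POS + |SVLEN| when END is
    absent; records with neither are skipped with a warning. VCF 1-based
    coordinates are converted to 0-based half-open: POS is the first deleted
    base in the Smoove DEL convention used here.

    filter_policy: "pass" keeps records with FILTER PASS or '.'; "all"
    keeps everything.
    """
    if filter_policy not in ("pass", "all"):
        raise ValueError("filter_policy must be 'pass' or 'all'")
    vcf_path = str(vcf_path)
    vcf = VCF(vcf_path)
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(vcf_path).stem
    calls: list[DeletionCall] = []
    n_read = n_kept = 0
    for rec in vcf:
        n_read += 1
        if rec.INFO.get("SVTYPE") != "DEL":
            continue
        if filter_policy == "pass" and rec.FILTER is not None:
            # cyvcf2 reports PASS / '.' as None
            continue
        start = rec.POS - 1
        end = rec.INFO.get("END")
        if end is None:
            svlen = rec.INFO.get("SVLEN")
            if svlen is None:
                warnings.warn(
                    f"{vcf_path}: DEL at {rec.CHROM}:{rec.POS} has neither END nor SVLEN; skipped"
                )
                continue
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            end = start + abs(int(svlen))
        calls.append(
            DeletionCall(
                sample_id=sample_id,
                interval=GenomicInterval(rec.CHROM, start, int(end)),
                sv_id=rec.ID or ".",
                quality=rec.QUAL,
            )
        )
        n_kept += 1
    vcf.close()
    logger.info("%s: %d records read, %d DEL kept", vcf_path, n_read, n_kept)
    return calls


def match_deletion_to_intron(
    deletion: DeletionCall, intron: GenomicInterval, tol: int
) -> bool:
    """Breakpoint-anchored match: both deletion ends within tol of the intron ends."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    iv = deletion.interval
    return (
        iv.chrom == intron.chrom
        and abs(iv.start - intron.start) <= tol
        and abs(iv.end - intron.end) <= tol
    )


def detect_pp(
    deletions: Iterable[DeletionCall],
    genes: Sequence[GeneModel],
    params: DetectorParams = DetectorParams(),
) -> list[PPCall]:
    """Call PP carriers from deletion records, one PPCall per (sample, gene).

    Emits a call for every (sample, gene) pair with at least one
    breakpoint-matched intron; the verdict is PP_present when the matched
    count reaches ``params.min_matched_introns``, undetectable when the gene
    has fewer introns than that threshold, and no_PP otherwise. Results are
    independent of input record order.
    """
    genes = list(genes)
    if not genes:
        warnings.warn("empty gene set: no PP calls possible")
        return []
    by_chrom = genes_by_chrom(genes)
    # (sample, gene_id) -> set of matched intron indices
    matches: dict[tuple[str, str], set[int]] = {}
    gene_lookup: dict[str, GeneModel] = {g.gene_id: g for g in genes}
    for dele in deletions:
        for gene in by_chrom.get(dele.interval.chrom, []):
            for idx, intron in enumerate(gene.introns):
                if match_deletion_to_intron(dele, intron, params.tol):
                    matches.setdefault((dele.sample_id, gene.gene_id), set()).add(idx)
    calls = []
    for (sample_id, gene_id), idxs in sorted(matches.items()):
        gene = gene_lookup[gene_id]
        n_total = len(gene.introns)
        n_matched = len(idxs)
        if n_total < params.min_matched_introns:
            verdict = UNDETECTABLE
        elif n_matched >= params.min_matched_introns:
            verdict = PP_PRESENT
        else:
            verdict = NO_PP
        calls.append(
            PPCall(
                sample_id=sample_id,
                gene_id=gene_id,
                n_introns_total=n_total,
                n_introns_matched=n_matched,
                matched_intron_indices=tuple(sorted(idxs)),
                verdict=verdict,
            )
        )
    return calls


class CohortPPMatrix:
    """Sample x gene PP presence with per-gene carrier frequencies.

    ``matrix`` is a boolean DataFrame indexed by sample_id with one column
    per gene; frequencies are percentages of the full cohort.
    """

    def __init__(self, matrix: pd.DataFrame):
        self.matrix = matrix

    @property
    def n_samples(self) -> int:
        return len(self.matrix)

    @property
    def gene_frequency(self) -> pd.Series:
        """Carrier percentage per gene over the whole cohort."""
        return 100.0 * self.matrix.sum(axis=0) / self.n_samples

    @property
    def sample_pp_counts(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def fraction_samples_with_pp(self) -> float:
        """Fraction of samples carrying at least one PP."""
        return float((self.sample_pp_counts > 0).mean())

    def carriers(self, gene_id: str) -> set[str]:
        col = self.matrix[gene_id]
        return set(col.index[col])

    def to_tsv(self, path: str | Path) -> None:
        out = self.matrix.astype(int)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortPPMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={0: str})
        df.index = df.index.astype(str)
        return cls(df.astype(bool))

    def summary(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_genes": int(self.matrix.shape[1]),
            "gene_frequency_percent": {
                g: round(float(f), 4) for g, f in self.gene_frequency.items()
            },
            "fraction_samples_with_pp": round(self.fraction_samples_with_pp, 4),
        }

    def write_summary_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def cohort_pp_matrix(
    ppcalls: Iterable[PPCall],
    sample_ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> CohortPPMatrix:
    """Aggregate per-sample PP calls into a cohort presence matrix.

    ``sample_ids`` must list the whole cohort (samples without calls count
    in the denominators); it defaults to the samples seen in the calls.
    Duplicate (sample, gene) calls are deduplicated with a warning.
    """
    calls = list(ppcalls)
    seen: dict[tuple[str, str], PPCall] = {}
    dup = 0
    for c in calls:
        key = (c.sample_id, c.gene_id)
        if key in seen:
            dup += 1
        seen[key] = c
    if dup:
        warnings.warn(f"{dup} duplicate (sample, gene) PP calls deduplicated")
    if sample_ids is None:
        sample_ids = sorted({c.sample_id for c in calls})
    if gene_ids is None:
        gene_ids = sorted({c.gene_id for c in calls})
    if not sample_ids:
        raise ValueError("cohort has no samples")
    mat = pd.DataFrame(
        False, index=pd.Index(sample_ids, name="sample_id"), columns=list(gene_ids)
    )
    for (sid, gid), call in seen.items():
        if call.verdict == PP_PRESENT and gid in mat.columns and sid in mat.index:
            mat.loc[sid, gid] = True
    return CohortPPMatrix(mat)


def compare_with_annotation(
    detected_genes: Iterable[str], annotated_pp_genes: Iterable[str]
) -> dict:
    """Set-difference report of detected PP parent genes vs an annotated list.

    Used to split detections into previously annotated and novel, e.g.
    against the parent genes of GENCODE-annotated processed pseudogenes.
    """
    detected = set(detected_genes)
    annotated = set(annotated_pp_genes)
    known = detected & annotated
    novel = detected - annotated
    return {
        "n_detected": len(detected),
        "n_known": len(known),
        "n_novel": len(novel),
        "known_genes": sorted(known),
        "novel_genes": sorted(novel),
    }


def write_ppcalls_tsv(calls: Sequence[PPCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgene_id\tn_introns_total\tn_introns_matched\tverdict\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.gene_id}\t{c.n_introns_total}\t"
                f"{c.n_introns_matched}\t{c.verdict}\n"
            )


def read_ppcalls_tsv(path: str | Path) -> list[PPCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        PPCall(
            sample_id=str(r.sample_id),
            gene_id=r.gene_id,
            n_introns_total=int(r.n_introns_total),
            n_introns_matched=int(r.n_introns_matched),
            matched_intron_indices=(),
            verdict=r.verdict,
        )
        for r in df.itertuples()
    ]
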
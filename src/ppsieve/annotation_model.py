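"""Gene models from GTF/GFF3 annotation.

Builds one model per gene as the *union projection* of exons across all of
its transcripts; introns are the gaps between merged exons and junctions are
the exon boundaries interior to the gene. The intron set is the substrate
for PP detection (a processed pseudogene is an intronless gene copy) and the
junction set anchors the artifact-variant proximity criterion.

All internal coordinates are 0-based half-open; conversion from the 1-based
annotation/VCF conventions happens at the parsing boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


class AnnotationParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Union of intervals: sorted, with overlapping or adjacent ones fused."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return ()
    merged: list[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom != last.chrom:
            raise ValueError("cannot merge intervals across chromosomes")
        if iv.start <= last.end:  # overlap or book-ended: no zero-length intron
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return tuple(merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene as merged exons; introns and junctions are derived.

    ``junctions`` holds every exon boundary interior to the gene span, i.e.
    both endpoints of every intron, as 0-based coordinates. A single-exon
    gene has no introns and is undetectable by the intronic-deletion
    signature.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...] = field(init=False)
    junctions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        for a, b in zip(self.exons, self.exons[1:]):
            if not a.end < b.start:
                raise ValueError(f"gene {self.gene_id}: exons must be disjoint and sorted")
        introns = tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )
        junctions = tuple(sorted(p for iv in introns for p in (iv.start, iv.end)))
        object.__setattr__(self, "introns", introns)
        object.__setattr__(self, "junctions", junctions)

    @classmethod
    def from_exons(
        cls, gene_id: str, gene_name: str, exons: Iterable[GenomicInterval], strand: str = "."
    ) -> "GeneModel":
        """Build a model from raw (possibly overlapping, multi-transcript) exons."""
        merged = merge_intervals(exons)
        if not merged:
            raise ValueError(f"gene {gene_id}: no exons")
        return cls(gene_id, gene_name, merged[0].chrom, strand, merged)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def detectable(self) -> bool:
        """Whether the intronic-deletion signature can exist at all."""
        return len(self.introns) > 0


def _normalize_chrom(chrom: str, add_prefix: bool) -> str:
    if add_prefix and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def parse_gene_models(
    source: str | TextIO,
    exon_feature: str = "exon",
    chr_prefix_normalize: bool = False,
) -> list[GeneModel]:
    """Parse GTF or GFF3 text into merged-exon gene models.

    Parameters
    ----------
    source
        Path to an annotation file, or an open text stream / string of
        annotation lines. GENCODE-dialect GTF (``gene_id``/``gene_name``
        attributes) and GFF3 are accepted; exon features must carry a gene
        identifier (``gene_id``, or ``Parent`` as a fallback).
    exon_feature
        Feature type projected into the models.
    chr_prefix_normalize
        When true, chromosome names lacking a ``chr`` prefix get one.

    Returns
    -------
    list of GeneModel, sorted by (chrom, start). Genes whose exons all merge
    to one interval are valid models with zero introns (undetectable).
    """
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        stream: TextIO = open(source)
        close = True
    elif isinstance(source, str):
        stream = io.StringIO(source)
        close = False
    else:
        stream = source
        close = False

    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    names: dict[str, str] = {}
    strands: dict[str, str] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from exc
            if feat.featuretype != exon_feature:
                continue
            attrs = feat.attributes
            if "gene_id" in attrs:
                gid = attrs["gene_id"][0]
            elif "Parent" in attrs:
                gid = attrs["Parent"][0]
            else:
                raise AnnotationParseError(
                    f"line {lineno}: exon feature carries no gene identifier"
                )
            chrom = _normalize_chrom(feat.seqid, chr_prefix_normalize)
            strand = feat.strand if feat.strand in STRANDS else "."
            try:
                iv = GenomicInterval(chrom, feat.start - 1, feat.end, strand)
            except ValueError as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from exc
            exons_by_gene.setdefault(gid, []).append(iv)
            if "gene_name" in attrs:
                names[gid] = attrs["gene_name"][0]
            strands[gid] = strand
    finally:
        if close:
            stream.close()

    models = []
    for gid, exons in exons_by_gene.items():
        models.append(
            GeneModel.from_exons(gid, names.get(gid, gid), exons, strands.get(gid, "."))
        )
    models.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    n_single = sum(1 for g in models if not g.detectable)
    if n_single:
        logger.warning("%d of %d genes are single-exon (undetectable)", n_single, len(models))
    return models


def nearest_junction_distance(pos: int, gene: GeneModel) -> int:
    """Distance in bp from a 1-based position to the closest exon junction.

    Returns 0 when the (0-based) position coincides with a junction boundary.
    Raises ValueError outside the gene span or for intronless genes.
    """
    pos0 = pos - 1
    span = gene.span
    if not span.start <= pos0 < span.end:
        raise ValueError(
            f"position {pos} outside span of {gene.gene_id} "
            f"[{span.start + 1}, {span.end}]"
        )
    if not gene.junctions:
        raise ValueError(f"gene {gene.gene_id} has no junctions (single exon)")
    return min(abs(pos0 - j) for j in gene.junctions)


def genes_by_chrom(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for lst in out.values():
        lst.sort(key=lambda g: g.span.start)
    return out


def write_gtf(genes: Sequence[GeneModel], path: str, source: str = "ppsieve") -> None:
    """Serialize merged gene models as GENCODE-dialect GTF (exon features)."""
    with open(path, "w") as fh:
        fh.write("##description: merged-exon gene models\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
            span = g.span
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand if g.strand != '.' else '+'}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand if g.strand != '.' else '+'}\t.\t"
                    f'{attrs}transcript_id "{g.gene_id}.t1"; exon_number {i};\n'
                )


def write_gene_table(genes: Sequence[GeneModel], path: str) -> None:
    """BED12-like TSV dump of gene models for inspection."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tgene_id\tgene_name\tstrand\tn_exons\t"
            "exon_sizes\texon_starts\tn_introns\n"
        )
        for g in genes:
            span = g.span
            sizes = ",".join(str(len(e)) for e in g.exons)
            starts = ",".join(str(e.start - span.start) for e in g.exons)
            fh.write(
                f"{g.chrom}\t{span.start}\t{span.end}\t{g.gene_id}\t{g.gene_name}\t"
                f"{g.strand}\t{len(g.exons)}\t{sizes}\t{starts}\t{len(g.introns)}\n"
            )
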
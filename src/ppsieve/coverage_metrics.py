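"""Exon/intron coverage ratio from per-interval depth tracks.

A PP adds exon-only reads to its parent gene, so carriers show a mean exon
depth above the mean intron depth. With diploid gene depth d and c extra PP
copies the idealized ratio is (2 + c) / 2; non-carriers sit at ~1. Depth
tracks are mosdepth-style BED/bedGraph inputs (chrom, start, end, mean
depth); no pileup computation happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ppsieve.annotation_model import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


class UndefinedDepthError(ValueError):
    """No covered bases under the queried intervals."""


@dataclass
class DepthTrack:
    """Sorted, non-overlapping per-interval mean depths for one sample."""

    sample_id: str
    intervals: dict  # chrom -> (starts, ends, depths) numpy arrays

    @classmethod
    def from_records(
        cls, sample_id: str, records: Iterable[tuple[str, int, int, float]]
    ) -> "DepthTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, depth in records:
            if depth < 0:
                raise ValueError(f"negative depth at {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, depth))
        out = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping depth intervals on {chrom}")
            depths = np.array([r[2] for r in rows], dtype=float)
            out[chrom] = (starts, ends, depths)
        return cls(sample_id=sample_id, intervals=out)

    @classmethod
    def from_bed(cls, path: str | Path, sample_id: str | None = None) -> "DepthTrack":
        """Read a BED4/bedGraph depth file (chrom, start, end, depth)."""
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str},
        )
        if sample_id is None:
            sample_id = Path(path).name.split(".")[0]
        return cls.from_records(
            sample_id, df.itertuples(index=False, name=None)
        )


def _covered_depth(
    query: GenomicInterval, track: DepthTrack
) -> tuple[float, int]:
    """(sum of depth*bp, covered bp) for one query interval."""
    if query.chrom not in track.intervals:
        return 0.0, 0
    starts, ends, depths = track.intervals[query.chrom]
    lo = int(np.searchsorted(ends, query.start, side="right"))
    hi = int(np.searchsorted(starts, query.end, side="left"))
    if lo >= hi:
        return 0.0, 0
    s = np.maximum(starts[lo:hi], query.start)
    e = np.minimum(ends[lo:hi], query.end)
    span = np.maximum(e - s, 0)
    return float(np.dot(span, depths[lo:hi])), int(span.sum())


def mean_depth_over(
    intervals: Sequence[GenomicInterval],
    track: DepthTrack,
    missing: str = "zero",
) -> float:
    """Length-weighted mean depth over a set of intervals.

    missing="zero" counts bases absent from the track as depth 0 (mosdepth
    emits complete tracks, so zero-fill is safe); missing="ignore" averages
    over covered bases only. Raises UndefinedDepthError when no base is
    covered under the "ignore" policy (or the intervals are empty).
    """
    if missing not in ("zero", "ignore"):
        raise ValueError("missing must be 'zero' or 'ignore'")
    if not intervals:
        raise ValueError("intervals must be non-empty")
    total = 0.0
    covered = 0
    length = 0
    for iv in intervals:
        t, c = _covered_depth(iv, track)
        total += t
        covered += c
        length += len(iv)
    denom = length if missing == "zero" else covered
    if denom == 0:
        raise UndefinedDepthError("no covered bases under the queried intervals")
    return total / denom


@dataclass(frozen=True)
class CoverageRatio:
    """Per (sample, gene) exon/intron mean-depth ratio.

    ``ratio`` is None when the intron mean is zero (flagged undefined).
    """

    sample_id: str
    gene_id: str
    exon_mean_depth: float
    intron_mean_depth: float
    ratio: float | None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def exon_intron_ratio(
    gene: GeneModel, track: DepthTrack, missing: str = "zero"
) -> CoverageRatio:
    """Ratio of mean exon depth to mean intron depth for one gene.

    Requires at least one intron; a zero intron mean yields a flagged,
    undefined ratio rather than an exception.
    """
    if not gene.introns:
        raise ValueError(f"gene {gene.gene_id} has no introns; ratio undefined")
    exon_mean = mean_depth_over(gene.exons, track, missing=missing)
    intron_mean = mean_depth_over(gene.introns, track, missing=missing)
    ratio = exon_mean / intron_mean if intron_mean > 0 else None
    if ratio is None:
        logger.warning(
            "%s/%s: intron mean depth is zero; ratio undefined",
            track.sample_id,
            gene.gene_id,
        )
    return CoverageRatio(
        sample_id=track.sample_id,
        gene_id=gene.gene_id,
        exon_mean_depth=exon_mean,
        intron_mean_depth=intron_mean,
        ratio=ratio,
    )


def write_ratios_tsv(ratios: Sequence[CoverageRatio], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgene_id\texon_mean\tintron_mean\tratio\n")
        for r in ratios:
            ratio = f"{r.ratio:.6g}" if r.ratio is not None else "NA"
            fh.write(
                f"{r.sample_id}\t{r.gene_id}\t{r.exon_mean_depth:.6g}\t"
                f"{r.intron_mean_depth:.6g}\t{ratio}\n"
            )
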
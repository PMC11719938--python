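"""Synthetic WGS-cohort generator with ground truth for every record.

The generator emits the *downstream evidence* a PP leaves in standard
pipeline outputs — never reads. For each PP carrier (c extra gene copies):

* one SVTYPE=DEL record per intron of the parent gene, breakpoints jittered
  uniformly within ``sv_jitter`` bp of the intron boundaries (the Smoove
  signature of exon-junction-spanning reads);
* exonic depth scaled by (2 + c) / 2 while introns stay at baseline;
* ``pp_divergence_variants`` heterozygous-looking variants at gene-level
  fixed sites (one of them on an exon junction), with alt reads drawn
  Binomial(depth, c_eff / (2 + c_eff)) where c_eff = c * (1 - read_loss)
  accounts for PP reads lost to other mappings.

Non-carriers (and every sample, as background) get het/hom variants at
random exonic sites with AB sampled Binomial around 0.5 / 1.0 — the normal
bimodal pattern. A truth table links every emitted record to its origin.

Same parameters + seed reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ppsieve.allelic_balance import VariantObservation
from ppsieve.annotation_model import GeneModel, GenomicInterval, write_gtf
from ppsieve.coverage_metrics import DepthTrack
from ppsieve.pp_detector import DeletionCall

logger = logging.getLogger(__name__)

REF_BASE = "A"
ALT_BASE = "G"

ORIGIN_GENE_HET = "gene_het"
ORIGIN_GENE_HOM = "gene_hom"
ORIGIN_PP_DIVERGENCE = "pp_divergence"


@dataclass(frozen=True)
class GeneSpec:
    """Geometry of one synthetic gene: equal-length exons and introns."""

    n_exons: int = 6
    exon_len: int = 150
    intron_len: int = 1200


DEFAULT_GENES = (
    GeneSpec(n_exons=8),  # PRKRA-like: many introns, high PP frequency
    GeneSpec(n_exons=6),
    GeneSpec(n_exons=5),
    GeneSpec(n_exons=7),
    GeneSpec(n_exons=4),  # PP-free control gene
)


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation conditions.

    Defaults emulate a 30x short-read WGS cohort: mean depth 30 with Poisson
    noise, a high-frequency PP gene alongside rarer ones plus a PP-free
    control, 4 pseudogene-divergence variants per carrier over a background
    of ~1 ordinary variant per gene per sample (so carriers show a ~5x
    variant excess), and 15% of PP-derived reads lost to other mappings so
    the PP-variant AB means land in the observed 25-30% band.
    """

    n_samples: int = 200
    genes: tuple[GeneSpec, ...] = DEFAULT_GENES
    pp_allele_freq: tuple[float, ...] = (0.27, 0.12, 0.05, 0.20, 0.0)
    carrier_quota: bool = False  # treat frequencies as exact carrier fractions
    depth: float = 30.0
    depth_noise: str = "poisson"  # "poisson" or "none"
    pp_divergence_variants: int = 4
    read_loss: float = 0.15
    bg_het_rate: float = 0.7  # mean het background variants per sample-gene
    bg_hom_rate: float = 0.3
    background_del_rate: float = 0.01  # lone true intronic SV per sample-gene
    true_pathogenic_rate: float = 0.02  # carriers of the per-gene true P site
    sv_jitter: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.genes) != len(self.pp_allele_freq):
            raise ValueError("one pp_allele_freq per gene required")
        if any(not 0 <= f <= 1 for f in self.pp_allele_freq):
            raise ValueError("pp_allele_freq values must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.depth_noise not in ("poisson", "none"):
            raise ValueError("depth_noise must be 'poisson' or 'none'")
        if not 0 <= self.read_loss < 1:
            raise ValueError("read_loss must lie in [0, 1)")
        if self.sv_jitter < 0:
            raise ValueError("sv_jitter must be >= 0")
        for spec in self.genes:
            if spec.n_exons < 1 or spec.exon_len < 1:
                raise ValueError("genes need >= 1 exon of positive length")
            if spec.n_exons > 1 and spec.intron_len <= 2 * self.sv_jitter:
                raise ValueError(
                    "intron_len must exceed twice the SV breakpoint jitter"
                )


@dataclass
class TruthTable:
    """Ground truth: PP genotypes and the origin of every variant record."""

    pp: pd.DataFrame  # sample_id, gene_id, copies
    variants: pd.DataFrame  # sample_id, gene_id, chrom, pos, ref, alt, origin, genotype, expected_ab

    def pp_copies(self, sample_id: str, gene_id: str) -> int:
        m = self.pp[(self.pp.sample_id == sample_id) & (self.pp.gene_id == gene_id)]
        return int(m.copies.iloc[0]) if len(m) else 0

    def carriers(self, gene_id: str) -> set:
        sub = self.pp[(self.pp.gene_id == gene_id) & (self.pp.copies > 0)]
        return set(sub.sample_id)


@dataclass
class SimulatedCohort:
    """In-memory cohort plus serialization to the on-disk formats."""

    params: SimParams
    genes: list[GeneModel]
    sample_ids: list[str]
    deletions: dict  # sample_id -> list[DeletionCall]
    depth_tracks: dict  # sample_id -> DepthTrack
    observations: dict  # sample_id -> list[VariantObservation]
    truth: TruthTable
    clinical_sites: pd.DataFrame  # chrom, pos, ref, alt, gene_id, clinical_label

    def all_observations(self) -> list[VariantObservation]:
        return [o for sid in self.sample_ids for o in self.observations[sid]]

    def write(self, out_dir: str | Path) -> dict:
        """Serialize GTF, per-sample SV VCF / depth BED / small-variant VCF,
        truth tables, clinical TSV and a params manifest. Returns the paths."""
        out = Path(out_dir)
        (out / "sv").mkdir(parents=True, exist_ok=True)
        (out / "depth").mkdir(exist_ok=True)
        (out / "smallvar").mkdir(exist_ok=True)
        gtf = out / "genes.gtf"
        write_gtf(self.genes, str(gtf))
        contigs = {g.chrom: g.span.end + 1000 for g in self.genes}
        paths = {
            "gtf": gtf,
            "sv_vcfs": {},
            "depth_beds": {},
            "small_vcfs": {},
        }
        for sid in self.sample_ids:
            sv = out / "sv" / f"{sid}.vcf"
            _write_sv_vcf(sv, sid, self.deletions[sid], contigs)
            paths["sv_vcfs"][sid] = sv
            bed = out / "depth" / f"{sid}.bed"
            _write_depth_bed(bed, self.depth_tracks[sid])
            paths["depth_beds"][sid] = bed
            vcf = out / "smallvar" / f"{sid}.vcf"
            _write_small_vcf(vcf, sid, self.observations[sid], contigs)
            paths["small_vcfs"][sid] = vcf
        self.truth.pp.to_csv(out / "truth_pp.tsv", sep="\t", index=False)
        self.truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
        self.clinical_sites.to_csv(out / "clinical_variants.tsv", sep="\t", index=False)
        paths["truth_pp"] = out / "truth_pp.tsv"
        paths["truth_variants"] = out / "truth_variants.tsv"
        paths["clinical"] = out / "clinical_variants.tsv"
        manifest = out / "params.json"
        with open(manifest, "w") as fh:
            json.dump(dataclasses.asdict(self.params), fh, indent=2, default=list)
            fh.write("\n")
        paths["params"] = manifest
        return paths


def _build_genes(specs: Sequence[GeneSpec]) -> list[GeneModel]:
    genes = []
    for i, spec in enumerate(specs):
        chrom = f"chr{i + 1}"
        start = 10_000
        exons = []
        pos = start
        for _ in range(spec.n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + spec.exon_len, "+"))
            pos += spec.exon_len + spec.intron_len
        genes.append(
            GeneModel.from_exons(f"G{i + 1:03d}", f"SIMG{i + 1}", exons, "+")
        )
    return genes


def _gene_sites(
    gene: GeneModel, k_divergence: int, rng: np.random.Generator
) -> tuple[list[int], int, np.ndarray]:
    """Fixed per-gene variant sites (1-based).

    Returns (divergence sites: first one on a junction, the rest exonic),
    the mid-exon "true pathogenic" site, and the pool of exonic positions
    left for background variants.
    """
    exon_pos = np.concatenate(
        [np.arange(e.start + 1, e.end + 1) for e in gene.exons]
    )
    if gene.junctions:
        junction_site = gene.junctions[0] + 1  # first base of the first intron
    else:
        junction_site = int(exon_pos[0])
    mid_exon = gene.exons[len(gene.exons) // 2]
    true_p_site = (mid_exon.start + mid_exon.end) // 2 + 1
    reserved = {junction_site, true_p_site}
    pool = exon_pos[~np.isin(exon_pos, sorted(reserved))]
    n_extra = max(k_divergence - 1, 0)
    extra = rng.choice(pool, size=n_extra, replace=False) if n_extra else np.array([], int)
    divergence_sites = [junction_site] + sorted(int(p) for p in extra)
    reserved.update(divergence_sites)
    background_pool = exon_pos[~np.isin(exon_pos, sorted(reserved))]
    return divergence_sites, true_p_site, background_pool


def _pp_genotypes(
    params: SimParams, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, n_genes) PP copy numbers: HWE draws or exact quota."""
    n = params.n_samples
    copies = np.zeros((n, n_genes), dtype=int)
    for gi, f in enumerate(params.pp_allele_freq):
        if params.carrier_quota:
            n_carriers = int(round(f * n))
            order = rng.permutation(n)
            copies[order[:n_carriers], gi] = 1
        else:
            copies[:, gi] = rng.binomial(2, f, size=n)
    return copies


def _draw_depth(expected: float, noise: str, rng: np.random.Generator) -> int:
    if noise == "none":
        return int(round(expected))
    return int(rng.poisson(expected))


def simulate_cohort(params: SimParams = SimParams()) -> SimulatedCohort:
    """Generate a full synthetic cohort with ground truth.

    See the module docstring for the generative model. All randomness flows
    from ``params.seed``; identical params give identical cohorts.
    """
    rng = np.random.default_rng(params.seed)
    genes = _build_genes(params.genes)
    n_genes = len(genes)
    sample_ids = [f"S{i + 1:04d}" for i in range(params.n_samples)]

    site_info = [
        _gene_sites(g, params.pp_divergence_variants, rng) for g in genes
    ]
    copies = _pp_genotypes(params, n_genes, rng)

    deletions: dict[str, list[DeletionCall]] = {s: [] for s in sample_ids}
    tracks: dict[str, DepthTrack] = {}
    observations: dict[str, list[VariantObservation]] = {s: [] for s in sample_ids}
    pp_rows = []
    var_rows = []

    def add_variant(sid, gene, pos, origin, genotype, p_alt, depth_expected):
        dp = max(_draw_depth(depth_expected, params.depth_noise, rng), 1)
        if params.depth_noise == "none":
            ad_alt = int(round(dp * p_alt))
        else:
            ad_alt = int(rng.binomial(dp, p_alt))
        ad_ref = dp - ad_alt
        if ad_alt == 0:  # not observable as a call
            return
        obs = VariantObservation(
            sample_id=sid,
            chrom=gene.chrom,
            pos=int(pos),
            ref=REF_BASE,
            alt=ALT_BASE,
            genotype=genotype,
            ad_ref=ad_ref,
            ad_alt=ad_alt,
        )
        observations[sid].append(obs)
        var_rows.append(
            {
                "sample_id": sid,
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "pos": int(pos),
                "ref": REF_BASE,
                "alt": ALT_BASE,
                "origin": origin,
                "genotype": genotype,
                "expected_ab": p_alt,
            }
        )

    for si, sid in enumerate(sample_ids):
        depth_records = []
        for gi, gene in enumerate(genes):
            c = int(copies[si, gi])
            c_eff = c * (1 - params.read_loss)
            if c > 0:
                pp_rows.append(
                    {"sample_id": sid, "gene_id": gene.gene_id, "copies": c}
                )
            # --- SV deletion records ---
            if c > 0:
                for intron in gene.introns:
                    js = int(rng.integers(-params.sv_jitter, params.sv_jitter + 1))
                    je = int(rng.integers(-params.sv_jitter, params.sv_jitter + 1))
                    deletions[sid].append(
                        DeletionCall(
                            sample_id=sid,
                            interval=GenomicInterval(
                                gene.chrom, intron.start + js, intron.end + je
                            ),
                            sv_id=f"{sid}_{gene.gene_id}_DEL",
                            quality=100.0,
                        )
                    )
            elif gene.introns and rng.random() < params.background_del_rate:
                # a lone true intronic SV: matches one intron only
                intron = gene.introns[int(rng.integers(len(gene.introns)))]
                js = int(rng.integers(-params.sv_jitter, params.sv_jitter + 1))
                je = int(rng.integers(-params.sv_jitter, params.sv_jitter + 1))
                deletions[sid].append(
                    DeletionCall(
                        sample_id=sid,
                        interval=GenomicInterval(
                            gene.chrom, intron.start + js, intron.end + je
                        ),
                        sv_id=f"{sid}_{gene.gene_id}_BG",
                        quality=60.0,
                    )
                )
            # --- depth track: exons scaled by (2+c)/2, introns at baseline ---
            exon_scale = (2 + c) / 2
            for ex in gene.exons:
                expected = params.depth * exon_scale
                if params.depth_noise == "none":
                    d = expected
                else:
                    d = rng.poisson(expected * len(ex)) / len(ex)
                depth_records.append((gene.chrom, ex.start, ex.end, round(d, 3)))
            for intr in gene.introns:
                if params.depth_noise == "none":
                    d = params.depth
                else:
                    d = rng.poisson(params.depth * len(intr)) / len(intr)
                depth_records.append((gene.chrom, intr.start, intr.end, round(d, 3)))

            divergence_sites, true_p_site, bg_pool = site_info[gi]
            sample_depth = params.depth * (2 + c_eff) / 2

            # --- background small variants (bimodal AB) ---
            n_het = int(rng.poisson(params.bg_het_rate))
            n_hom = int(rng.poisson(params.bg_hom_rate))
            n_bg = min(n_het + n_hom, len(bg_pool))
            bg_sites = rng.choice(bg_pool, size=n_bg, replace=False)
            for k, pos in enumerate(bg_sites):
                if k < n_het:
                    p = 1 / (2 + c_eff)  # 0.5 in non-carriers
                    add_variant(sid, gene, pos, ORIGIN_GENE_HET, "het", p, sample_depth)
                else:
                    add_variant(sid, gene, pos, ORIGIN_GENE_HOM, "hom_alt", 1.0, sample_depth)
            # --- true pathogenic het at the gene's fixed clinical site ---
            if rng.random() < params.true_pathogenic_rate:
                p = 1 / (2 + c_eff)
                add_variant(
                    sid, gene, true_p_site, ORIGIN_GENE_HET, "het", p, sample_depth
                )
            # --- PP divergence variants at the gene's fixed sites ---
            if c > 0:
                p = c_eff / (2 + c_eff)
                for pos in divergence_sites:
                    add_variant(
                        sid, gene, pos, ORIGIN_PP_DIVERGENCE, "het", p, sample_depth
                    )
        observations[sid].sort(key=lambda o: (o.chrom, o.pos))
        tracks[sid] = DepthTrack.from_records(sid, depth_records)

    clinical_rows = []
    for gi, gene in enumerate(genes):
        divergence_sites, true_p_site, _ = site_info[gi]
        if params.pp_allele_freq[gi] > 0:
            clinical_rows.append(
                {
                    "chrom": gene.chrom,
                    "pos": divergence_sites[0],
                    "ref": REF_BASE,
                    "alt": ALT_BASE,
                    "gene_id": gene.gene_id,
                    "clinical_label": "LP",
                }
            )
        clinical_rows.append(
            {
                "chrom": gene.chrom,
                "pos": true_p_site,
                "ref": REF_BASE,
                "alt": ALT_BASE,
                "gene_id": gene.gene_id,
                "clinical_label": "P",
            }
        )

    truth = TruthTable(
        pp=pd.DataFrame(pp_rows, columns=["sample_id", "gene_id", "copies"]),
        variants=pd.DataFrame(
            var_rows,
            columns=[
                "sample_id",
                "gene_id",
                "chrom",
                "pos",
                "ref",
                "alt",
                "origin",
                "genotype",
                "expected_ab",
            ],
        ),
    )
    logger.info(
        "simulated %d samples x %d genes: %d PP genotypes, %d variants",
        params.n_samples,
        n_genes,
        len(truth.pp),
        len(truth.variants),
    )
    return SimulatedCohort(
        params=params,
        genes=genes,
        sample_ids=sample_ids,
        deletions=deletions,
        depth_tracks=tracks,
        observations=observations,
        truth=truth,
        clinical_sites=pd.DataFrame(clinical_rows),
    )


def write_fixture_suite(out_dir: str | Path, seed: int = 17) -> dict:
    """Write the canonical deterministic mini-cohort (5 genes x 20 samples).

    The first gene mirrors a PRKRA-like high-frequency scenario: an exact
    0.47 carrier fraction by quota sampling. Returns the path map from
    ``SimulatedCohort.write`` plus the cohort itself under "cohort".
    """
    params = SimParams(
        n_samples=20,
        pp_allele_freq=(0.47, 0.25, 0.10, 0.05, 0.0),
        carrier_quota=True,
        seed=seed,
    )
    cohort = simulate_cohort(params)
    paths = cohort.write(out_dir)
    paths["cohort"] = cohort
    return paths


# ---------------------------------------------------------------------------
# plain-text writers for the simulator's output dialects


def _vcf_header(sid: str, contigs: dict, sv: bool) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=ppsieve-cohort-simulator"]
    for chrom, length in sorted(contigs.items()):
        lines.append(f"##contig=<ID={chrom},length={length}>")
    if sv:
        lines += [
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
            '##ALT=<ID=DEL,Description="Deletion">',
        ]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if not sv:
        lines += [
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sid
    )
    return "\n".join(lines) + "\n"


def _write_sv_vcf(
    path: Path, sid: str, dels: Sequence[DeletionCall], contigs: dict
) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(sid, contigs, sv=True))
        for d in sorted(dels, key=lambda x: (x.interval.chrom, x.interval.start)):
            iv = d.interval
            svlen = -(iv.end - iv.start)
            qual = f"{d.quality:g}" if d.quality is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start + 1}\t{d.sv_id}\tN\t<DEL>\t{qual}\tPASS\t"
                f"SVTYPE=DEL;END={iv.end};SVLEN={svlen}\tGT\t0/1\n"
            )


def _write_depth_bed(path: Path, track: DepthTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            starts, ends, depths = track.intervals[chrom]
            for s, e, d in zip(starts, ends, depths):
                fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


def _write_small_vcf(
    path: Path, sid: str, obs: Sequence[VariantObservation], contigs: dict
) -> None:
    gt_codes = {"het": "0/1", "hom_alt": "1/1", "other": "1/2"}
    with open(path, "w") as fh:
        fh.write(_vcf_header(sid, contigs, sv=False))
        for o in sorted(obs, key=lambda x: (x.chrom, x.pos)):
            dp = o.ad_ref + o.ad_alt
            fh.write(
                f"{o.chrom}\t{o.pos}\t.\t{o.ref}\t{o.alt}\t50\tPASS\t.\t"
                f"GT:AD:DP\t{gt_codes[o.genotype]}:{o.ad_ref},{o.ad_alt}:{dp}\n"
            )
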
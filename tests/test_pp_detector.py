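import numpy as np
import pytest

from ppsieve.annotation_model import GeneModel, GenomicInterval
from ppsieve.pp_detector import (
    NO_PP,
    PP_PRESENT,
    UNDETECTABLE,
    DeletionCall,
    DetectorParams,
    cohort_pp_matrix,
    compare_with_annotation,
    detect_pp,
    match_deletion_to_intron,
    parse_sv_vcf,
)

from conftest import random_gene

SV_HEADER = "\n".join(
    [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=100000>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="e">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
    ]
)


def write_sv(tmp_path, records, name="s1.vcf"):
    path = tmp_path / name
    path.write_text(SV_HEADER + "\n" + "\n".join(records) + "\n")
    return path


def dele(chrom, start, end, sample="S1"):
    return DeletionCall(sample, GenomicInterval(chrom, start, end))


class TestParseSvVcf:
    def test_end_coordinate_conversion(self, tmp_path):
        path = write_sv(
            tmp_path, ["chr1\t1001\td1\tN\t<DEL>\t99\tPASS\tSVTYPE=DEL;END=2000\tGT\t0/1"]
        )
        (call,) = parse_sv_vcf(path)
        assert (call.interval.start, call.interval.end) == (1000, 2000)
        assert call.sample_id == "S1"

    def test_non_deletion_excluded(self, tmp_path):
        path = write_sv(
            tmp_path,
            [
                "chr1\t1001\td1\tN\t<DUP>\t99\tPASS\tSVTYPE=DUP;END=2000\tGT\t0/1",
                "chr1\t3001\td2\tN\t<DEL>\t99\tPASS\tSVTYPE=DEL;END=4000\tGT\t0/1",
            ],
        )
        calls = parse_sv_vcf(path)
        assert [c.sv_id for c in calls] == ["d2"]

    def test_end_from_svlen(self, tmp_path):
        path = write_sv(
            tmp_path, ["chr1\t101\td1\tN\t<DEL>\t99\tPASS\tSVTYPE=DEL;SVLEN=-500\tGT\t0/1"]
        )
        (call,) = parse_sv_vcf(path)
        assert (call.interval.start, call.interval.end) == (100, 600)

    def test_missing_end_and_svlen_skipped(self, tmp_path):
        path = write_sv(
            tmp_path, ["chr1\t101\td1\tN\t<DEL>\t99\tPASS\tSVTYPE=DEL\tGT\t0/1"]
        )
        with pytest.warns(UserWarning, match="neither END nor SVLEN"):
            assert parse_sv_vcf(path) == []

    def test_filter_policy(self, tmp_path):
        recs = [
            "chr1\t1001\tok\tN\t<DEL>\t99\tPASS\tSVTYPE=DEL;END=2000\tGT\t0/1",
            "chr1\t3001\tlow\tN\t<DEL>\t9\tLowQual\tSVTYPE=DEL;END=4000\tGT\t0/1",
        ]
        path = write_sv(tmp_path, recs)
        assert [c.sv_id for c in parse_sv_vcf(path)] == ["ok"]
        assert [c.sv_id for c in parse_sv_vcf(path, filter_policy="all")] == ["ok", "low"]


class TestMatchDeletionToIntron:
    intron = GenomicInterval("chr2", 100, 200)

    def test_exact_match(self):
        assert match_deletion_to_intron(dele("chr2", 100, 200), self.intron, tol=10)

    def test_within_tolerance(self):
        assert match_deletion_to_intron(dele("chr2", 95, 206), self.intron, tol=10)

    def test_beyond_tolerance_or_other_chrom(self):
        assert not match_deletion_to_intron(dele("chr2", 85, 200), self.intron, tol=10)
        assert not match_deletion_to_intron(dele("chr3", 100, 200), self.intron, tol=10)

    def test_multi_intron_spanning_deletion_matches_neither(self, trio_gene):
        """A deletion spanning two introns signals a real deletion, not a PP."""
        span_del = dele("chr2", 50, 400)
        for intron in trio_gene.introns:
            assert not match_deletion_to_intron(span_del, intron, tol=10)


class TestDetectPP:
    def test_all_introns_matched_calls_pp(self, trio_gene):
        dels = [dele("chr2", i.start, i.end) for i in trio_gene.introns]
        (call,) = detect_pp(dels, [trio_gene])
        assert call.verdict == PP_PRESENT
        assert call.n_introns_matched == call.n_introns_total == 2

    def test_single_match_below_threshold(self, trio_gene):
        dels = [dele("chr2", 100, 200)]
        (call,) = detect_pp(dels, [trio_gene], DetectorParams(min_matched_introns=2))
        assert call.verdict == NO_PP
        assert call.n_introns_matched == 1

    def test_single_intron_gene_undetectable(self):
        gene = GeneModel.from_exons(
            "TWOEX",
            "TWOEX",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)],
        )
        dels = [dele("chr1", 100, 200)]
        (call,) = detect_pp(dels, [gene], DetectorParams(min_matched_introns=2))
        assert call.verdict == UNDETECTABLE

    def test_empty_gene_set_warns(self):
        with pytest.warns(UserWarning, match="empty gene set"):
            assert detect_pp([dele("chr1", 0, 10)], []) == []

    def test_order_invariance(self, small_cohort):
        dels = [d for sid in small_cohort.sample_ids for d in small_cohort.deletions[sid]]
        fwd = detect_pp(dels, small_cohort.genes)
        rev = detect_pp(dels[::-1], small_cohort.genes)
        assert fwd == rev

    def test_monotone_in_added_matching_deletion(self, trio_gene):
        dels = [dele("chr2", 100, 200), dele("chr2", 300, 400)]
        (before,) = detect_pp(dels, [trio_gene])
        assert before.verdict == PP_PRESENT
        (after,) = detect_pp(dels + [dele("chr2", 102, 198)], [trio_gene])
        assert after.verdict == PP_PRESENT
        assert after.n_introns_matched >= before.n_introns_matched

    @pytest.mark.parametrize("seed", range(4))
    def test_equivalence_with_brute_force_oracle(self, seed):
        """detect_pp agrees with an exhaustive (deletion, intron) pair checker."""
        rng = np.random.default_rng(seed)
        params = DetectorParams(min_matched_introns=2, tol=10)
        genes = [random_gene(rng, chrom=f"chr{i % 3}") for i in range(8)]
        for i, g in enumerate(genes):
            object.__setattr__(g, "gene_id", f"G{i}")
        samples = [f"S{j}" for j in range(15)]
        dels = []
        for s in samples:
            for _ in range(rng.integers(0, 12)):
                g = genes[rng.integers(len(genes))]
                if rng.random() < 0.6 and g.introns:
                    intr = g.introns[rng.integers(len(g.introns))]
                    s0 = intr.start + rng.integers(-20, 21)
                    e0 = intr.end + rng.integers(-20, 21)
                else:
                    s0 = rng.integers(0, 3000)
                    e0 = s0 + rng.integers(50, 500)
                if e0 > s0:
                    dels.append(dele(g.chrom, int(s0), int(e0), sample=s))
        # brute force: every (sample, gene, intron, deletion) combination
        expected = {}
        for s in samples:
            for g in genes:
                matched = set()
                for idx, intr in enumerate(g.introns):
                    for d in dels:
                        if d.sample_id != s or d.interval.chrom != intr.chrom:
                            continue
                        if (
                            abs(d.interval.start - intr.start) <= params.tol
                            and abs(d.interval.end - intr.end) <= params.tol
                        ):
                            matched.add(idx)
                if matched:
                    if len(g.introns) < params.min_matched_introns:
                        verdict = UNDETECTABLE
                    elif len(matched) >= params.min_matched_introns:
                        verdict = PP_PRESENT
                    else:
                        verdict = NO_PP
                    expected[(s, g.gene_id)] = (frozenset(matched), verdict)
        got = {
            (c.sample_id, c.gene_id): (frozenset(c.matched_intron_indices), c.verdict)
            for c in detect_pp(dels, genes, params)
        }
        assert got == expected


class TestCohortMatrix:
    def test_high_frequency_gene_rounds_to_47_percent(self):
        from ppsieve.pp_detector import PPCall

        n, carriers = 13_307, 6_234
        calls = [
            PPCall(f"S{i}", "PRKRA", 7, 7, tuple(range(7)), PP_PRESENT)
            for i in range(carriers)
        ]
        samples = [f"S{i}" for i in range(n)]
        m = cohort_pp_matrix(calls, sample_ids=samples)
        freq = float(m.gene_frequency["PRKRA"])
        assert freq == pytest.approx(100 * carriers / n)
        assert round(freq) == 47

    def test_zero_and_full_frequency(self, trio_gene):
        from ppsieve.pp_detector import PPCall

        samples = ["A", "B", "C"]
        none = cohort_pp_matrix([], sample_ids=samples, gene_ids=["TRIO"])
        assert float(none.gene_frequency["TRIO"]) == 0.0
        calls = [PPCall(s, "TRIO", 2, 2, (0, 1), PP_PRESENT) for s in samples]
        full = cohort_pp_matrix(calls, sample_ids=samples)
        assert float(full.gene_frequency["TRIO"]) == 100.0
        assert full.fraction_samples_with_pp == 1.0

    def test_duplicate_calls_deduplicated(self):
        from ppsieve.pp_detector import PPCall

        c = PPCall("A", "TRIO", 2, 2, (0, 1), PP_PRESENT)
        with pytest.warns(UserWarning, match="duplicate"):
            m = cohort_pp_matrix([c, c], sample_ids=["A", "B"])
        assert int(m.matrix.sum().sum()) == 1

    def test_matrix_tsv_round_trip(self, tmp_path):
        from ppsieve.pp_detector import CohortPPMatrix, PPCall

        calls = [PPCall("A", "G1", 3, 3, (0, 1, 2), PP_PRESENT)]
        m = cohort_pp_matrix(calls, sample_ids=["A", "B"], gene_ids=["G1", "G2"])
        m.to_tsv(tmp_path / "m.tsv")
        back = CohortPPMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.matrix.equals(m.matrix)


class TestAnnotationComparison:
    def test_novel_set_difference(self):
        detected = {f"G{i}" for i in range(234)}
        annotated = {f"G{i}" for i in range(57)} | {"NOT_DETECTED"}
        report = compare_with_annotation(detected, annotated)
        assert report["n_detected"] == 234
        assert report["n_known"] == 57
        assert report["n_novel"] == 177
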
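import numpy as np
import pytest

from ppsieve.annotation_model import GeneModel, GenomicInterval
from ppsieve.cohort_simulator import GeneSpec, SimParams, simulate_cohort

GTF_TEXT = "\n".join(
    [
        "##provider: test",
        # two transcripts of ALPHA: union is [100,250),[300,400)
        'chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "ALPHA"; gene_name "ALPHA"; transcript_id "A.1";',
        'chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "ALPHA"; gene_name "ALPHA"; transcript_id "A.1";',
        'chr1\ttest\texon\t101\t250\t.\t+\t.\tgene_id "ALPHA"; gene_name "ALPHA"; transcript_id "A.2";',
        'chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "ALPHA"; gene_name "ALPHA"; transcript_id "A.2";',
        # single-exon gene
        'chr1\ttest\texon\t1001\t1500\t.\t-\t.\tgene_id "SOLO"; gene_name "SOLO"; transcript_id "S.1";',
        # three-exon gene at [0,100),[200,300),[400,500)
        'chr2\ttest\texon\t1\t100\t.\t+\t.\tgene_id "TRIO"; gene_name "TRIO"; transcript_id "T.1";',
        'chr2\ttest\texon\t201\t300\t.\t+\t.\tgene_id "TRIO"; gene_name "TRIO"; transcript_id "T.1";',
        'chr2\ttest\texon\t401\t500\t.\t+\t.\tgene_id "TRIO"; gene_name "TRIO"; transcript_id "T.1";',
    ]
)


@pytest.fixture
def gtf_text():
    return GTF_TEXT


@pytest.fixture
def trio_gene():
    """3 exons of 100 bp separated by 100 bp introns, starting at 0."""
    return GeneModel.from_exons(
        "TRIO",
        "TRIO",
        [
            GenomicInterval("chr2", 0, 100),
            GenomicInterval("chr2", 200, 300),
            GenomicInterval("chr2", 400, 500),
        ],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample noisy cohort reused across read-only tests."""
    return simulate_cohort(SimParams(n_samples=60, seed=11))


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort60")
    paths = small_cohort.write(out)
    return paths


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Single het carrier per gene, no depth/AD noise, no read loss."""
    params = SimParams(
        n_samples=1,
        genes=(GeneSpec(n_exons=5),),
        pp_allele_freq=(1.0,),
        carrier_quota=True,
        depth_noise="none",
        read_loss=0.0,
        background_del_rate=0.0,
        true_pathogenic_rate=0.0,
        seed=3,
    )
    return simulate_cohort(params)


def random_gene(rng: np.random.Generator, chrom: str = "chrR") -> GeneModel:
    """Random multi-exon gene model for property tests."""
    n_exons = int(rng.integers(2, 7))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 300))
        exons.append(GenomicInterval(chrom, pos, pos + length))
        pos += length + int(rng.integers(60, 500))
    return GeneModel.from_exons(f"R{rng.integers(1e6)}", "R", exons)
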
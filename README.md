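# ppsieve

Detection of **processed pseudogenes (PPs)** from structural-variant evidence
in short-read WGS cohorts, and flagging of the false-positive "clinically
significant" small variants that PPs induce in their parent genes.

## The problem

A processed pseudogene is an intronless, reverse-transcribed copy of a gene
reintegrated elsewhere in the genome. Most PPs are absent from the reference,
so their reads align back onto the parent gene, where they leave three
characteristic footprints:

1. **Intronic-deletion SV calls.** PP reads span exon–exon junctions, so SV
   callers in the LUMPY/Smoove family emit one `SVTYPE=DEL` record per intron,
   with breakpoints at the intron boundaries. A sample whose SV VCF carries
   breakpoint-matched deletions at ≥ 2 introns of a gene is called a PP
   carrier for that gene.
2. **Exon-only coverage excess.** With diploid gene depth *d* and *c* extra
   PP copies, the exon/intron mean-depth ratio is (2 + *c*) / 2 — 1.5 for a
   heterozygous carrier, ~1 for everyone else.
3. **Diluted allelic balance.** A variant that actually lives on the PP is
   diluted by parent-gene reads: AB = *v* / (2 + *c*) ≈ 25–33%, versus the
   normal bimodal pattern of ~50% (het) and ~100% (hom). Misaligned junction
   reads additionally produce spurious frameshift/splice-loss calls **on the
   intron–exon junctions** that automated ACMG classification happily labels
   pathogenic.

`ppsieve` consumes standard pipeline outputs (GTF/GFF3 annotation, SV VCFs,
mosdepth-style depth BEDs, small-variant VCFs with GT/AD, a clinical-variant
TSV) and combines the three footprints. A clinically labelled variant is
flagged `likely_pp_artifact` when it is junction-proximal (≤ 10 bp), its
carriers are significantly enriched among PP carriers (Pearson χ² on the 2×2
carrier × PP table, p < 0.05), and its mean carrier AB is ≤ 0.40.

A synthetic-cohort generator (`ppsieve.cohort_simulator`) emits all of these
inputs with a per-record ground-truth table, so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
import numpy as np
from ppsieve import (SimParams, simulate_cohort, detect_pp, cohort_pp_matrix,
                     exon_intron_ratio)
from ppsieve.allelic_balance import summarize_ab
from ppsieve.artifact_flagger import (flag_clinical_variants,
                                      read_clinical_tsv, FlagParams)

cohort = simulate_cohort(SimParams(n_samples=100, seed=7))
paths = cohort.write("example_cohort")

dels = [d for sid in cohort.sample_ids for d in cohort.deletions[sid]]
matrix = cohort_pp_matrix(detect_pp(dels, cohort.genes),
                          sample_ids=cohort.sample_ids,
                          gene_ids=[g.gene_id for g in cohort.genes])
print(matrix.gene_frequency.round(1).to_string())
```

```
G001    46.0
G002    26.0
G003     4.0
G004    41.0
G005     0.0
```

Per-gene carrier percentages recovered purely from the SV deletion records
(73% of samples carry at least one PP in this cohort). The orthogonal
evidence separates carriers cleanly — for the high-frequency gene `G001`:

```
mean exon/intron ratio, G001: carriers 1.58, non-carriers 1.00
AB in G001 carriers: mean 0.374, modes at (32.5, 97.5) %
```

Carriers sit near the heterozygous-PP expectation of 1.5 (the mean is pulled
slightly above by two-copy carriers) while non-carriers sit at 1.0, and the
carrier AB distribution shows the PP-shifted ~30% mode alongside the normal
homozygous mode. Flagging the simulator's clinically labelled sites:

```
G001 chr1:10151 [LP] junction_dist=0  p=1.52e-23 mean_AB=0.32 -> likely_pp_artifact
G001 chr1:15476 [P]  junction_dist=75 p=4.66e-01 mean_AB=0.43 -> not_flagged
...
G005 chr5:12776 [P]  junction_dist=75 p=NA       mean_AB=0.61 -> not_flagged
```

Every pseudogene-divergence site (junction-adjacent, carriers confined to PP
carriers, low AB) is flagged; every genuinely heterozygous pathogenic site is
left alone. For `G005` no sample carries a PP, so the association test is
undefined (`NA`) and the variant is judged on the remaining criteria.

The same pipeline is available as subcommands:

```bash
ppsieve simulate --out cohort --seed 7 --n-samples 100
ppsieve detect-pp --gtf cohort/genes.gtf --sv-vcf cohort/sv/S0001.vcf ... --out det
ppsieve flag-artifacts --gtf cohort/genes.gtf --clinical cohort/clinical_variants.tsv \
        --pp-matrix det/pp_matrix.tsv --vcf cohort/smallvar/S0001.vcf ... --out flags
ppsieve fp-report --caller gatk=flags/flagged_carriers.tsv --cohort-size 100 --out fp.tsv
```

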
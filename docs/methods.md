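# Methods

## Detection model

A processed pseudogene (PP) is an intronless retrocopy of a parent gene.
When the PP is absent from the reference genome, its reads align to the
parent gene, and reads spanning the PP's exon–exon joins become
split/discordant reads at the parent's introns. SV callers of the
LUMPY/Smoove family summarize this as deletion records whose breakpoints
coincide with intron boundaries.

`ppsieve` calls a sample a PP carrier for a gene when its SV VCF contains
deletions that **breakpoint-match** at least `min_matched_introns` introns of
that gene. Matching requires both deletion ends to fall within `tol` bp of
the corresponding intron ends; reciprocal overlap is deliberately not used,
because a genuine genomic deletion rarely lands on both intron boundaries,
and a deletion spanning several introns matches none of them (it indicates a
real deletion, not a retrocopy). Gene models are the union projection of
exon features across all transcripts of a gene — the most conservative
intron definition: a region is intronic only if no isoform uses it as exon.

Two orthogonal per-gene diagnostics support a call:

* **Exon/intron coverage ratio.** With baseline diploid depth d and c extra
  PP copies, exonic depth is d·(2+c)/2 while intronic depth stays at d, so
  the length-weighted exon mean over intron mean is (2+c)/2. The ratio is
  scale-invariant in d.
* **Allelic balance (AB).** AB is alt-AD over total AD (DP is not used: it
  counts uninformative reads). Under the copy-ratio model a variant present
  on v of the 2+c gene-equivalent copies has AB = v/(2+c): 0.5 for an
  ordinary het, 1/3 for a variant on the single PP copy of a het carrier,
  0.25 for one of two PP copies.

## Artifact flagging

A clinically labelled (P/LP) variant in a parent gene is flagged
`likely_pp_artifact` when all evaluable criteria hold:

1. **Junction proximity** — distance from the variant to the nearest exon
   boundary interior to the gene is ≤ `junction_window` (default 10 bp,
   covering the canonical splice region; PP artifacts arise from misaligned
   junction-spanning reads and cluster on the junctions).
2. **Cohort association** — a Pearson χ² test (1 df) on the 2×2 table of
   variant-carrier status against PP-carrier status, at `alpha` = 0.05, with
   the additional requirement that carriers are *enriched* in the PP group
   (a significant deficit must not flag). Yates correction and a Bonferroni
   option exist but are off by default; no multiple-testing correction is
   applied otherwise. When a margin is zero (e.g. no PP carrier exists for
   the gene) the test is undefined and the criterion is skipped.
3. **Allelic balance** — mean carrier AB ≤ `ab_ceiling` (default 0.40,
   between the PP-shifted 25–33% band and the 50% heterozygous mode).

A criterion that cannot be evaluated (no AB data, undefined test) is
reported as such, and the flag is decided on the remaining criteria. This
conjunction is a formalization choice: the three evidence types are
individually necessary in the generative model of a PP artifact, and each is
reported separately in the verdict table so users can re-weigh them.

## AB histograms and modes

AB distributions are summarized in twenty 5%-wide bins on [0, 1] with edges
at multiples of 5% (the last bin closed, so AB = 1 falls in [95%, 100%]).
Edge-aligned bins were chosen after a null-model analysis: at ~30× depth the
AB support points k/depth alias with bins *centered* on multiples of 5% —
only 15/30 falls in a bin centered at 50% while two support points fall in
each flanking bin — which misplaces the heterozygous mode. With edge-aligned
bins the het peak dominates the [50%, 55%) bin and the hom peak the
[95%, 100%] bin across all seeds tried; reported mode bin centers are
therefore 52.5% and 97.5%. A mode is a bin (or plateau of equal bins)
strictly greater than both flanking counts, reported at the plateau's
lowest-AB bin; `dominant_mode` is the highest-count mode, which is the
robust summary when sampling noise creates small secondary bumps.

## Synthetic cohorts

The generator emits the downstream evidence the pipeline consumes — SV
records, per-interval depths, AD counts — never reads: the method never
touches alignments, so read-level simulation would add cost without adding
test coverage. Defaults describe a 30× WGS cohort:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 200 | cohort size |
| `genes` | 5 genes, 4–8 exons, 150 bp exons, 1200 bp introns | gene geometry |
| `pp_allele_freq` | 0.27, 0.12, 0.05, 0.20, 0.0 | per-gene PP allele frequency; copies drawn Binomial(2, f) (Hardy–Weinberg), or exact carrier quota with `carrier_quota` |
| `depth` | 30 | mean read depth (reads) |
| `depth_noise` | poisson | per-interval Poisson depth; `none` gives the exact forward model |
| `pp_divergence_variants` | 4 | divergence variants per PP over a background of ~1 variant per sample-gene, giving the ~5× carrier variant excess |
| `read_loss` | 0.15 | fraction of PP reads not mapped back to the parent, placing PP-variant AB means in the 25–30% band; a tuning knob, not a measured value |
| `bg_het_rate`, `bg_hom_rate` | 0.7, 0.3 | Poisson means of background het/hom variants per sample-gene |
| `background_del_rate` | 0.01 | chance of a lone true intronic SV per sample-gene (exercises the `min_matched_introns` = 2 threshold) |
| `true_pathogenic_rate` | 0.02 | carriers of a fixed mid-exon true pathogenic het site per gene |
| `sv_jitter` | 5 | uniform breakpoint jitter of emitted DEL records (bp) |

The first PP allele frequency, 0.27, gives an expected carrier fraction of
1 − (1 − 0.27)² ≈ 0.47, mirroring a known high-frequency PP scenario. Each
gene has fixed divergence sites shared by all its carriers (retrocopies of a
common origin share divergence variants), one of them on the first exon
junction and labelled LP in the emitted clinical TSV; each gene also has a
fixed mid-exon site labelled P whose carriers are genuine heterozygotes.
Depth tracks scale exon intervals by (2+c)/2 exactly; AD sampling uses the
effective copy number c·(1 − read_loss), with total depth
Poisson(depth·(2 + c_eff)/2) and alt reads Binomial at the expected AB.
Variants whose sampled alt count is zero are not emitted (a caller would not
call them). All randomness flows from a single `numpy` generator seeded by
`SimParams.seed`; identical parameters produce byte-identical files.

What the simulator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: mapping-quality structure, GC and
mappability bias, multi-gene homology (reads shared between paralogs),
isoform-specific PPs with partial exon sets, indel artifacts (all synthetic
variants are SNVs), population structure beyond Hardy–Weinberg, and SV
caller failure modes other than breakpoint jitter.

## Numerical and design notes

* Coordinates are 0-based half-open internally; 1-based conversions happen
  only at VCF/GTF boundaries. Deletion intervals from VCF are
  [POS−1, END); when END is absent, END = POS−1+|SVLEN|.
* Book-ended exons merge (no zero-length introns); genes whose exons merge
  to a single interval are *undetectable*, as are genes with fewer introns
  than `min_matched_introns`.
* Depth queries use length-weighted means; bases absent from a depth track
  count as zero by default (mosdepth-style tracks are complete), with an
  `ignore` option. A zero intron mean yields an undefined, flagged ratio.
* The χ² p-value comes from the asymptotic χ²₁ distribution (the test used
  at cohort scale, where it is accurate). For small cohorts the discrete
  permutation null has non-trivial tie mass at the observed statistic; the
  test suite checks that the asymptotic p lies within the permutation
  null's tie bracket [P(T > t), P(T ≥ t)] up to Monte-Carlo error.
* Multiallelic small-variant records are split per ALT, AB computed against
  that ALT's AD entry; missing genotypes are excluded.
* CLI exit codes: 0 success, 1 usage error, 2 data error. Every command
  writes a `run_manifest.json`; seeded stages reproduce byte-for-byte.

## Problem sizes used in the test and acceptance runs

The default acceptance simulations use 200 samples (detector operating
point) and 400 samples × 5 genes (AB background modes, ≥ 500 variants per
genotype class); the exhaustive χ² check enumerates all 34,810 valid 2×2
tables with margins in [1, 20] and cross-checks 20 random tables against a
100,000-draw permutation null. These sizes give stable statistics (mode bins
reproduce across seeds; detector sensitivity/false-call rates are exact 1/0
at the defaults) while keeping a full run in the minutes range.

## Known limitations

* The PP insertion site is not located, and PPs from different isoforms of
  the same gene are not distinguished — only presence/absence per
  (sample, gene).
* `min_matched_introns` = 2 means single-intron genes are never callable.
* The flag conjunction requires cohort data; a single sample cannot be
  flagged in isolation (the association criterion needs carriers and
  non-carriers).
* Annotation parsing requires exon features carrying `gene_id` (GENCODE
  GTF/GFF3 do); bare GFF3 with only `Parent` chains to transcripts groups
  exons by transcript parent instead of gene.
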
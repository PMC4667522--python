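# fusionloci

Characterization of fusion-transcript loci for transcriptomics: given a
genome, gene models with CDS, and a table of fusion junction calls (e.g.
from a FusionMap-style caller), `fusionloci` answers the questions a fusion
cohort analysis asks:

* **Junction classification** — does each fusion junction use an annotated
  exon border of one, both or neither parental gene; which donor–acceptor
  dinucleotide class does it use (GT-AG, GC-AG, AT-AC, CT-AC, CT-GC or
  other); does it preserve the reading frame; and is it a read-through
  chimera of adjacent genes, a same-chromosome non-adjacent fusion, or
  interchromosomal?
* **Flank co-hybridization** — could the two parental loci base-pair with
  each other? The four 100-nt flanks around the two breakpoints are
  combined pairwise across a 20-N spacer, folded, and the inter-molecular
  base pairs are profiled by distance from the fusion point; hybridized
  stretches ≥ 8 nt are exported for motif tools.
* **Repeat overlap** — which RepeatMasker families overlap the 100-nt flank
  windows, for fusions versus random non-fusion splice-site controls.
* **Junction matching** — which fusion junctions recur in an external
  transcript assembly (BED12/GTF), at a configurable coordinate tolerance.
* **RT-qPCR regulation calls** — ΔΔCt fold changes against a housekeeping
  gene, two-fold arrow calls (↑/↓/–/NE), and the k-of-n tumour majority
  rule.

A seeded synthetic-data module generates genomes, annotations, repeat
tracks, fusion tables and Ct tables with known planted truth, so the whole
pipeline is testable end to end without any downloads.

## The statistics and algorithms

**Reading frame.** The codon phase of a breakpoint base is
`p = (number of coding bases from the CDS start through the base − 1) mod 3`.
A junction with phases `(p1, p2)` is in frame iff `p2 = (p1 + 1) mod 3`;
junctions whose break base lies outside a CDS get an absent phase (labels
like `2→`, `→0`, `→`) and are tallied with the frame-preserving group by
default (switchable).

**Splice pattern.** The donor is the two bases immediately 3′ of the last
gene-1 base on gene 1's strand, the acceptor the two bases immediately 5′
of the first gene-2 base on gene 2's strand — i.e. the intron's terminal
dinucleotides when the junction sits on exon borders.

**Folding.** The built-in pairing engine is a maximum-base-pair Nussinov
dynamic program, `M[i,j] = max(M[i+1,j], max_k 1 + M[i+1,k−1] + M[k+1,j])`
over a DNA Watson–Crick alphabet (A:T, G:C; G:T wobble optional, minimum
loop 3, N never pairs), with a deterministic traceback. Externally computed
structures (e.g. RNAfold) can be substituted via a dot-bracket adapter; the
analysis consumes only the pair set.

**ΔΔCt.** `fold = 2^−ΔΔCt` with
`ΔΔCt = (Ct_target − Ct_hk)_treated − (Ct_target − Ct_hk)_mock`,
replicate means taken before differencing; a plain two-sample t-test on the
ΔCt replicates is provided.

## Worked example

```bash
fusionloci synth --outdir demo --seed 7 \
    --n-read-through 20 --n-non-adjacent 4 --n-interchromosomal 2
fusionloci characterize --fusions demo/fusions.tsv --genome demo/genome.fa \
    --genes demo/genes.gtf --out demo/classified.tsv --summary demo/summary.json
fusionloci qpcr --ct demo/ct.csv --out demo/calls.tsv
```

prints

```
wrote synthetic dataset (26 fusions) to demo
classified 26 fusions -> demo/classified.tsv
3 targets called -> demo/calls.tsv
```

and `demo/classified.tsv` begins

```
fusion_id  gene1    gene2    splice_class  donor  acceptor  boundary_class  frame_label  frame_status  category          sense_antisense  read_count
fus1       chr1_g1  chr2_g1  GT-AG         GT     AG        both            2→0          in_frame      interchromosomal  False            6
fus2       chr2_g2  chr2_g3  GT-AG         GT     AG        gene1_only      2→0          in_frame      read_through     False            14
```

`fus1` joins genes on different chromosomes at both exon borders through a
canonical GT-AG junction and keeps the frame (phase 2 base followed by a
phase 0 base). The qPCR table calls the planted 2.5-fold target ↑
(`FUSION_A  fold 2.30  ↑  p 0.0019`), the 0.4-fold target ↓ and the
unchanged target – , exactly the two-fold arrow convention.

Other subcommands: `fusionloci hybridize` (positional pairing profile +
stretch FASTA), `fusionloci repeats` (family overlap vs controls),
`fusionloci controls` (random consecutive-exon splice sites),
`fusionloci match` (junction matching against an assembly).

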
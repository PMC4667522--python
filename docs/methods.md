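# Methods

## Coordinate model and breakpoint semantics

All internal coordinates are 0-based half-open; every external dialect
(GTF and RepeatMasker `.out`: 1-based inclusive; FusionMap-style tables:
1-based positions; BED12: native) is converted at the I/O boundary, and a
writer exists for every reader so conversions are round-trip tested.

Breakpoint semantics are fixed — and worth stating prominently, because
fusion callers rarely do: `break1` is the **last transcribed base** of the
gene-1 portion of the fusion transcript and `break2` the **first
transcribed base** of the gene-2 portion. All downstream definitions
(donor/acceptor dinucleotides, exon-border tests, flank windows) are
derived from these two bases and the parental strands carried in the
fusion record; strands are never inferred from sequence. `N` is a legal
base everywhere: it never pairs and never matches a splice dinucleotide.

## Junction classification

* **Splice pattern.** Donor = two bases 3′ of `break1` on gene 1's strand;
  acceptor = two bases 5′ of `break2` on gene 2's strand. The label is
  `donor-acceptor` when that string is one of GT-AG, GC-AG, AT-AC, CT-AC,
  CT-GC, else `other`; GT-AG is flagged canonical. Breakpoints within two
  bases of a contig end are an error, not a silent truncation.
* **Exon boundary.** `break1` must equal the transcription-order 3′ end of
  some exon of some transcript of gene 1 (`break2`: a 5′ exon start of
  gene 2). With multiple transcripts per gene a match on any transcript
  counts and the matched transcript id is recorded — the analysis operates
  at gene level.
* **Frame.** Phase of a break base = its 0-based index within the CDS mod
  3; absent outside a CDS. In-frame iff `p2 = (p1 + 1) mod 3`. Cohort
  fractions are reported over two denominators, because they genuinely
  differ: over all fusions (classes with an absent phase counted with the
  frame-preserving group, since a junction in a UTR cannot interrupt the
  downstream ORF; a config flag flips this) and over the classifiable
  (both-phase) subset.
* **Category.** Interchromosomal when the parental chromosomes differ;
  otherwise read-through when no third annotated gene's span lies entirely
  within the gap between the two parental gene spans (overlapping parents
  are also adjacent), else intrachromosomal non-adjacent. Containment is
  deterministic and annotation-driven, computed per chromosome
  irrespective of strand. The sense-antisense flag compares the two break
  strands on a shared chromosome; the repeat analysis subset keeps
  same-chromosome, same-strand fusions only.

## Flank co-hybridization

Four strand-oriented segments of width W (default 100 nt) are taken per
fusion: gene-1 up/downstream of `break1` and gene-2 up/downstream of
`break2`. Signed offsets run −W..−1 (upstream, −1 abutting the junction)
and +1..+W (downstream); there is no offset 0. Segments truncated by a
contig end are flagged. The four combinations up1–up2, up1–down2,
down1–up2, down1–down2 are concatenated across a spacer of exactly 20 N.

The pairing engine is a maximum-cardinality Nussinov DP rather than a
thermodynamic folder: the analysis consumes only the base-pair set, the DP
is exactly checkable against exhaustive enumeration, and a dot-bracket
adapter ingests externally computed structures (e.g. RNAfold, which
accepts single-stranded DNA input) bit-exactly when an energy model is
wanted. Numerical choices: DNA Watson–Crick alphabet (A:T, G:C) by
default with G:T wobble behind a flag (inputs are genomic DNA); minimum
loop length 3 (the spacer guarantees inter-molecular pairs are never
loop-constrained); deterministic traceback preferring, in order, leaving
the left base unpaired, pairing the interval ends, then the smallest
bifurcation point — so outputs are reproducible across platforms.

Pairs are partitioned into inter-molecular (one end in each segment) and
intra-molecular; the partition conserves the pair count. The positional
profile counts, per combination and signed offset, the fusions whose base
at that offset participates in an inter-molecular pair, with gene-1 and
gene-2 tracks kept separate, plus the mean number of inter-paired
nucleotides (two per pair) per fusion. For motif export, maximal runs of
consecutive inter-paired positions are concatenated **per segment per
fusion** (the natural reading that preserves fusion-level attribution; the
alternative, pooling across fusions, would destroy it) and candidates of
at least 8 nt are emitted to FASTA, per segment, for external motif tools.
Both gene-1 and gene-2 emissions are produced so either pooling convention
can be applied downstream.

## Repeat overlap

Each fusion (or control site) contributes its four flank windows as plain
genomic intervals; overlap with a repeat family means ≥ 1 shared base
(`--min-overlap` exists, default 1, since no minimum is inherent in the
definition). Counts are reported per window stratum (family × gene slot ×
side × source) and de-duplicated per fusion (a fusion counts once per
family however many of its windows hit), the latter being the headline
number. The control set is sub-sampled (seeded, without replacement) to
the fusion cohort size. The any-overlap rule is invariant to splitting a
feature into abutting pieces, which the tests check.

## Controls and junction matching

Control sites are consecutive-exon splice junctions sampled uniformly
without replacement from multi-exon transcripts, reproducible from a
seed; each carries a donor and acceptor position and flows through the
same flank/overlap machinery as a fusion. Junction keys order their two
(chromosome, position) sides lexicographically so keys built from either
side ordering compare equal; matching requires both positions within the
tolerance on the same key — i.e. the same external transcript junction —
by default (a relaxed mode matches the two sides independently), and
strand is ignored unless requested, since coordinate comparison is the
robust common denominator across assemblies.

## RT-qPCR

`fold = 2^−ΔΔCt`, ΔCt paired within replicate against the housekeeping
target (default 18S), replicate means taken before differencing, standard
error propagated from the two condition means. Arrows: ↑ when fold ≥ 2,
↓ when fold ≤ 0.5 (boundaries inclusive — "at least two-fold"), –
otherwise, NE when a target shows no amplification (absent rows; a Ct
ceiling is configurable). The tumour panel rule calls a direction when at
least k of n samples (default 4 of 7) individually pass the two-fold bar.
A plain two-sample Student's t-test between mock and treated ΔCt
replicates is included, with no multiple-testing correction, and no
amplification-efficiency correction.

## Synthetic data: what it emulates and what it does not

One integer seed drives every PRNG stream. The genome generator lays out
multi-exon genes sequentially per chromosome (defaults: 6 chromosomes ×
220 kb × 90 genes; 4–6 exons of 60–120 nt; introns 80–160 nt; intergenic
gaps 400–700 nt; strand kept from the previous gene with probability 0.8
so equal-strand neighbours are common, as in real gene neighbourhoods),
writes intron boundary dinucleotides from a configurable class mix
(default 96 % GT-AG / 4 % GC-AG), assigns each transcript a CDS whose
length is a codon multiple, and plants repeat intervals from six families
(SINE, LINE, LTR, DNA, Simple_repeat, Low_complexity).

The fusion planter consumes dedicated gene pairs: read-through fusions use
consecutive genes, non-adjacent fusions skip exactly one complete gene,
interchromosomal fusions draw from two chromosomes. Per fusion it places
the two break bases to realise the requested exon-boundary label
(exon border, exon interior, or mid-intron), retunes the parental CDS
start within the first exon to realise the requested codon phases, and
writes the requested donor/acceptor dinucleotides just outside the break
bases. The default cohort mirrors the composition the package is
documented against: 185 fusions, 140/30/15 categories, 140 GT-AG, a
95/66/24 both/one/neither boundary split, 140/25/20
in-frame/frameshift/absent-phase junctions, and two sense-antisense
fusions, leaving 168 same-chromosome same-strand fusions for the repeat
analysis.

The complementary-flank planting mode exists to give the hybridization
stage an unambiguous truth: it resets the four flank windows to an inert
`A` background and writes a C-run (gene 1) and its reverse complement, a
G-run (gene 2), at the requested offsets, forcing the affected junctions
to the pairing-inert `AA`/`AA` "other" splice dinucleotides. Under a
maximum-cardinality objective this makes the planted duplex the unique
optimal structure, so the positional profile must peak at exactly the
planted offsets; with a natural random background, alternative optimal
structures could legitimately pair planted bases intramolecularly and the
"exact peak" truth would be ill-defined.

What the generator does **not** emulate: read-level evidence (no FASTQ,
no alignment noise, no miscalled junction coordinates), expression beyond
an integer read count, repeat sequence content (repeats are annotation
intervals only), overlapping genes, multiple transcripts per gene, and
genome-scale base composition. Passing the closure tests therefore shows
the classifiers invert the planting construction exactly and the pipeline
plumbing is coordinate-correct — not that a particular fusion caller's
breakpoints are accurate on real reads.

## Problem sizes and numerical notes

The test suite and acceptance script run the full default cohort (185
fusions, ~1.3 Mb genome), a 200-fusion coding cohort for the
translation-oracle frame check, 100 random sequences of length ≤ 14
against exhaustive structure enumeration, a 50-fusion planted-complement
cohort, and 1,000 × 1,000 random window/feature instances against the
quadratic overlap oracle — sizes chosen so every check completes in
seconds while leaving nothing about the algorithms untested at larger n
(the DP, interval and coordinate code paths are size-independent). The
Nussinov inner loop is JIT-compiled (numba); ties in the DP are resolved
by the fixed traceback order, and degenerate inputs (empty cohorts,
empty strata, zero-noise Ct tables, all-N regions) are defined results,
not errors, except where the input is unusable (off-contig breakpoints,
missing housekeeping rows, malformed table rows — which raise with the
offending column or line).

## Known limitations

* Adjacency ("no complete third gene in the gap") depends on annotation
  completeness; a sparse annotation inflates read-through calls.
* The maximum-pairing engine overestimates pairing relative to a
  thermodynamic model; comparisons are meaningful fusion-vs-control under
  the same objective, not as absolute hybridization propensities.
* Frame analysis trusts the annotated CDS; it does not re-derive ORFs
  from sequence.
* The ΔΔCt module assumes ideal amplification efficiency.
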
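# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing its output.

## Coordinates and formats

All genomic intervals are 1-based inclusive internally (the GFF3
convention); BED-style 0-based half-open coordinates are converted at the
boundary only, and the two converters are exact inverses. Gene models
carry *coding* exons plus an optional 5′ UTR interval; intron (start, end)
always means first/last intronic base. Sense-strand sequences of
minus-strand features are reverse complements of the plus-strand slice.

## Intron catalog

Junction records (scaffold, start, end, strand, read support) are merged
per locus (support summed — evidence from multiple samples), then filtered
with an inclusive support threshold (default ≥ 3 reads) and a closed
length window (default 40–1000 bp). The defaults mirror the standard
junction-extraction practice for short-read RNA-seq in compact genomes;
both are exposed in `PipelineConfig`.

Classification: an intron is canonical iff its sense donor/acceptor
dinucleotides are GT..AG; GC‑AG and GA‑AG donors are tabulated as a
separate subcategory but counted inside the non-canonical (NCI) class,
because the NCI definition is strictly "not GT‑AG". Junction strands of
'?' are resolved from the splice dinucleotides (GT..AG forward, CT..AC
reverse), then from the host gene's strand, and default to '+' as a last
resort. Host genes are assigned by span containment with matching strand;
the phase is the number of coding nucleotides of the interrupted codon
upstream of the intron (0/1/2), computed from the annotated exon
structure. Introns that sit in intergenic regions or do not match an
annotated exon boundary stay in the catalog with no host/phase and are
excluded from gene typing and conservation analyses.

The splice-site frequency report contains the 16×16 donor×acceptor count
table (entries sum to the catalog size) and positional base-frequency
matrices over the first/last 10 intronic and 5 flanking exonic positions;
flanks beyond scaffold ends are N-padded and excluded from denominators.
The matrices are directly renderable with any sequence-logo tool.

## Introner elements

**IR grammar.** An inverted repeat is an exact reverse-complement arm pair
with arm length 8–20 nt, the 5′ arm starting within 6 nt of the intron
start, the 3′ arm ending within 6 nt of the intron end, and an unpaired
loop of ≥ 3 nt between the arms. For each offset pair the maximal arm
length is reported; the primary IR is the longest (ties: smaller offsets).
No mismatches are allowed and N never matches — mismatch-tolerant arms
would blur the family key (below), and the detector is validated against
an exhaustive enumeration oracle, so the grammar is exact by design.

**DR grammar.** Direct repeats are common substrings (3–8 nt) of the two
boundary windows (last 8 exonic + first 8 intronic nt at the 5′ boundary;
last 8 intronic + first 8 exonic at the 3′ boundary), reported when
maximal or as length-8 croppings of longer commonalities, with signed
offsets relative to the boundaries. The headline DR length range in this
family of elements is 3–5; the search range extends to 8 so the length
distribution itself is an output rather than an assumption. DR presence
is descriptive: the IE call requires an IR only.

**IE calling.** NCI + ≥ 1 IR ⇒ IE candidate. Canonical introns with IR
(and DR) structure are flagged separately and never counted as IEs — the
structural organization does occur in a minority of canonical introns and
the flag makes that measurable.

**Families.** Two-stage deterministic clustering: (1) group by exact
(arm5, arm3) pair — "100% identity in sequence composition and length";
(2) within a group, greedy incremental clustering in intron-length
descending order (ties by id): a candidate joins the first cluster whose
*founder* it matches at ≥ 30% global DNA identity, else founds a cluster.
Size-1 clusters and ungrouped candidates are singletons. The greedy
founder-representative scheme is the CD-HIT idiom; determinism and
input-order invariance follow from the stated sort. DNA identity uses
match +5 / mismatch −4 with gap open 10 / extend 1 (EDNAFULL-style
Needle scoring), identity = matches / alignment columns.

**Profiles and scanning.** Each family with ≥ 2 members gets a
position-specific log-odds model (log2 vs the 0-order base composition of
the whole catalog, pseudocount 0.5) over two windows: intron start through
the farthest member arm end + 5 nt, and the mirror window at the 3′ end.
The acceptance threshold per window is the minimum member self-score
relaxed by 20% (for positive scores this is exactly 0.8 × min self-score),
so every member passes by construction; an intron is a repeated-intron
member when it passes both windows and lies within the family's length
range. Multi-family hits resolve to the highest total score, ties to the
lexicographically smallest family id. A profile-HMM with gaps was
deliberately not used: family arms are fixed-length by definition, so
gapless windows capture the signature, and a self-score-relative threshold
avoids the database-size dependence of E-values.

**Superfamilies.** Families are embedded as 3-mer frequency vectors of
their arm consensus sequences (5′ + 3′ concatenated) and clustered by Ward
linkage on Euclidean distance; the dendrogram is exported as Newick and
cut at a configurable k (default 4).

**Identical pairs.** All unordered pairs of distinct IE loci with
byte-identical sense sequences; m identical loci yield C(m,2) pairs.
These are the strongest evidence of recent mobility.

## Genome architecture

*Orientation shift*: in each complete non-overlapping 10-gene window, the
number of adjacent-pair strand changes (0–9), averaged over windows. An
alternative "minority orientation count" reading is available as
`metric="minority"`; both are reported because the published descriptions
of this statistic are ambiguous between the two.

*Co-oriented blocks*: maximal runs of ≥ 5 same-strand genes in which every
opposite-strand interruption is ≤ 2 contiguous genes, trimmed to start and
end on block-orientation genes, built greedily left to right. Interruption
genes count toward block span and coverage (block coverage of ~98% of
genes is the published regime this mirrors).

*Tandem duplications*: intra-genome protein pairs at ≥ 95% local-alignment
identity over ≥ 90% of the longer protein, single-linkage components,
split into co-localized runs allowing ≤ 1 intervening gene; only runs of
≥ 2 genes are reported.

*Telomeres*: a scaffold end is positive when ≥ 3 tandem (possibly
interleaved) copies of TTTAGGG/TTTGGGG — or their reverse complements —
occur within the terminal 200 bp. The copy and window defaults are this
package's choices (logged in the run config) since no standard exists.

## Orthology and synteny

Protein alignment is Smith–Waterman under BLOSUM62 with affine gaps (open
10, extend 1; the first gap position costs the open penalty). `X` scores 0
against everything. Hits are retained at score **strictly** > 300.
Orthologs are best reciprocal hits under the score ordering (ties to the
lexicographically smallest subject, reciprocity still required); score was
chosen over identity as the BRH ordering because it is the retained
statistic of the alignment stage. Synteny blocks chain anchors per
scaffold pair, sorted by rank in genome A, while consecutive anchors
differ by ≤ 15 ranks in both genomes and rank B stays monotone (direction
fixed at the chain's second anchor); chains of ≥ 5 anchors are blocks.
The "≤ 15 genes between any two genes" rule is applied to consecutive
anchors — the literal any-two reading would cap block span at 15 and
contradict the long collinear blocks this statistic exists to describe.

## Intron conservation

Ortholog pairs are globally aligned (same scoring as above; end gaps
penalized). Conserved blocks replace a Gblocks run with an explicit,
parameterized rule: a column is retained iff non-gap in both rows, more
than 5 columns from any gap, and ≥ 5 identities lie in its centered
9-column window. Each intron maps to the alignment column of the last
residue encoded wholly or partially by its upstream exon (residue
⌈cds_offset/3⌉), with phase cds_offset mod 3; the mapping is reversible
(column + phase ⇒ CDS nucleotide offset). An intron is conserved iff both
orthologs have introns at the same column, same phase, in a retained
column. Placements in masked columns are excluded from numerators *and*
denominators; pairs with < 50 retained columns are excluded entirely
(guard against 0/0 on hyper-diverged pairs). The conservation-vs-identity
trend bins pairs by 5% identity with NaN for empty bins.

## Spliced-leader detection

A read is SL-tagged when its prefix equals a suffix (≥ 5 nt) of the
configured 22-nt leader; because suffixes end at the leader's 3′ end,
every accepted read carries the TCAAG 3′ pentamer. An 8-mer index over the
leader's 3′ 16-mer prefilters reads; 5–7 nt suffixes, which cannot contain
a full 8-mer, are tested directly. The post-SL portion must map exactly
and uniquely to the genome (ambiguous/unmappable reads are dropped with a
logged reason); the junction is the first post-SL base. The two read bases
before the junction must be AG (the leader's 3′ end); on failure the
junction shifts upstream ≤ 13 nt while the prefix stays consistent with
the leader, else the junction is flagged rather than discarded. Junctions
attach to strand-consistent genes by 5′ UTR overlap, then first coding
exon overlap, then nearest gene start (ties to the smaller id). The SL
sequence is configuration, not a constant: only its 22-nt length and
TCAAG pentamer are structural assumptions.

## Synthetic data generator

The generator emulates the study conditions end to end: two strain
genomes (default 4 scaffolds × 50 genes each) with

* random proteins of 120–300 aa back-translated to CDS (length chosen so
  genuine orthologs at ~50% identity clear the score > 300 retention);
* 70% spliced genes, 1 + Poisson(2) intron sites per spliced gene
  (≈ the 69.8% spliced / ~4 exons-per-gene regime of compact genomes);
* splice classes drawn as 34% canonical / 36% plain-NCI / 30% IE (the
  one-third-canonical spectrum of the systems this emulates; IE share set
  high enough that family statistics are well-populated at this genome
  size);
* 5 IE families: arms 8–20 nt from the template TTA[AG][AG]…G, family
  loop length ±3 nt, TSD-style direct repeats of 3–5 nt copied across the
  insertion point (skipped when that would create a stop codon); loop and
  pad bases are constrained so the planted arms are exactly maximal —
  the generator's grammar and the detector's grammar agree by
  construction, which is itself a tested invariant;
* strain B derived by codon substitution targeting a protein identity
  (default 50%) with a 2:1 synonymous:nonsynonymous preference —
  substitution-only, so ortholog alignments are gap-free and identity
  targeting is exact to within ±2%;
* strain-specific intron gain: each ancestral site is strain-specific
  with probability `intron_gain_rate × (1 − target identity)` (rate per
  unit of protein divergence, default 0.2 ⇒ 10% at default divergence).
  Coupling gain to divergence makes zero-divergence duplicates carry
  strictly identical intron positions and produces the expected decreasing
  conserved-fraction trend along a divergence ladder;
* planted identical-IE groups (default sizes 3 and 2 per strain) whose
  expected pair counts are computed from the final planted sequence
  multisets;
* gene layout: log-normal intergenic spacers (median ~800 bp — the
  ~240 genes/Mb compact-genome regime), strand flips between neighbors
  with probability 0.02 (10-gene-window orientation shift ≈ 0.18), tandem
  duplicate genes (default 4, ~2% aa divergence, adjacent rank), Poisson
  segmental inversions in strain B (rate 0.02/gene) as the only
  rearrangements, and 5 telomere motif copies at every scaffold end;
* junction evidence: Poisson(20) read support per true intron plus 5%
  false junctions placed inside exons (support 1 + Poisson(0.5), almost
  all below the validation threshold; never coinciding with true splice
  sites so truth evaluation stays clean);
* SL reads for ~30% of genes (flagged trans-spliced): a sampled 5–22 nt
  leader suffix + 60 nt of transcript from the gene's first transcribed
  base; 5′ UTRs are 60–120 nt so error-free reads never cross the first
  intron.

Everything is driven by one `numpy` generator seeded from `SimConfig.seed`;
identical configs reproduce byte-identical genomes, junctions and reads.

**What it does not emulate** (hence what green tests do and do not show):
no indel evolution in proteins (alignments of true orthologs are
gap-free, so conservation-mapping is exercised on clean columns; the mask
logic is tested separately on gapped alignments), no read-level sequencing
noise beyond uniform substitutions, no repeat/TE landscape, no IE
insertion-site preference (uniform within coding exons), no RNA editing,
and no splice-site sequence context beyond the planted dinucleotides.
Detector performance on real data will be bounded by assembly and junction
quality in ways the simulation cannot measure.

## Problem sizes and determinism

The test suite and the acceptance script run the default 2 × 200-gene
genome (plus smaller 60-gene configurations for the divergence ladder);
at these sizes the full suite and the acceptance run each complete in
about a minute on one CPU, while every statistic of interest (hundreds of
introns, ~190 ortholog pairs) is still well-populated. All randomized
tests are seeded; order-dependent operations state their tie-breaks
(lexicographic ids everywhere) so outputs are invariant to input order.

## Known limitations

* The IR detector's exact-match grammar will miss degenerate arms; the
  published element families in real genomes were built with
  mismatch-tolerant tools, so real-data family counts are sensitive to
  this choice in ways the synthetic benchmark (which plants exact arms)
  cannot reveal.
* BRH orthology is one-to-one; lineage-specific paralog expansions (and
  even the planted tandem duplicates) can displace true ortholog pairs.
* The profile scanner searches the validated intron catalog, not the raw
  genome; a genome-wide scan would require a windowed scoring pass that is
  out of scope here.
* `run_pipeline` is sequential and single-CPU by design; all-vs-all
  alignment dominates its runtime and scales quadratically in gene count.
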
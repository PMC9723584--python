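# Methods

This note records the models, definitions and numerical choices behind
`phagectx`, in the spirit of a methods appendix: what each stage
computes, what the synthetic data emulate, and where design decisions
were genuinely open.

## Coordinates, identity and formats

All internal coordinates are 0-based half-open; GFF3 I/O converts to and
from 1-based inclusive at the boundary, which removes every off-by-one
ambiguity from downstream arithmetic. Wrap-around genes on circular
genomes are rejected at parse time (no convention exists for them in the
data this package targets, and the generator never emits them).

Per-read identity is `1 − mismatches / read_length`, with mismatches
taken from the SAM NM-style edit count. This makes "3 mismatches per
150 bp read" equal 98% similarity exactly, which is the arithmetic the
read filters (97% DNA, 98% RNA) are phrased in. The alternative —
dividing by aligned length — is supported by supplying pre-filtered
alignments; the denominator choice matters only for clipped reads, which
the generator does not produce. Aligned target intervals are derived
from the CIGAR with M/=/X consuming both sequences, D consuming target
(a deletion still spans target bases, so it extends the current block),
N splitting blocks, and I/S/H consuming only the query. A read wrapping
the origin of a circular genome is represented as two aligned blocks and
serialized as a primary plus a supplementary SAM line.

Pairwise sequence identity elsewhere (protein-family clustering, marker
dereplication) is defined from the global Needleman–Wunsch edit distance
d as `1 − d / max(len_a, len_b)`, computed with edlib. Because the
alignment is global, mutual coverage reduces to
`min(len) / max(len)`, so the ≥0.75 mutual-coverage constraint is
enforced exactly. For the substitution-only sequences the generator
emits, this identity equals per-site identity exactly.

## Synthetic study conditions

The generator's defaults are the study conditions every recovery test
runs under; they are chosen once and mirror the real system:

| parameter | default | rationale |
|---|---|---|
| genome_length | 30,000 bp | test scale; 300 kbp mirrors the real genomes but adds nothing to the logic being exercised |
| gc_target | 0.32 | complete genomes span 31.0–33.7% GC |
| coding_density_target | 0.93 | reported range 91.1–94.9% |
| mean_gene_length | 800 bp | ~350–400 genes on a 300 kbp genome |
| n_clades / n_genomes | 3 / 12 | several related clades, a handful of genomes each |
| within_clade_divergence | 0.02 /site | high intra-clade similarity (sibling genomes ≈96% identical) |
| clade_divergence | 0.06 /site | module proteins ≥80% identical across clades, ≥95% within |
| read_length | 150 bp | short-read metagenomes |
| depth | 20× | the curation threshold regime (≥20×) |
| error_rate | 0.005 /base | a stated default; the real error model is unknown |

Gene intervals tile the genome with gaps drawn so realized coding
density lands on target (the wasted tail past the last whole gene is
compensated in the mean gap). The conserved module is planted around the
middle gene: the anchor (bS21, reverse strand) flanked at −1/+1 by two
hypothetical-protein genes, TerL at −4, portal at −3, prohead protease
at +2 and MCP at +4 — all structural roles within five genes, on the
strand opposite the anchor. Module proteins descend from run-level
ancestral sequences; clade founders mutate them at `clade_divergence`
and clade members re-mutate the founder at `within_clade_divergence`, a
star topology whose sibling-pair identity is
`(1−d)² + d²/3` per site. Background proteins are independent random
sequences per founder, so they form clade-private families — this is
what lets presence/absence clustering separate clades.

The mutation model is substitution-only throughout (clades, spacers,
reads). This keeps every mismatch count exact against the dual spacer
rule and the identity filters; it also means indel robustness is *not*
exercised by passing tests.

CRISPR hosts carry one array of `n_spacers + 1` exact repeat copies
(default 30 bp) interleaved with spacers sampled as phage substrings
(either strand) carrying an exact requested number of substitutions.
One construction detail matters: if every spacer began (or ended) with
the same base, that base would be an exact extension of the repeat and
the planted boundary unrecoverable *in principle*; the generator
resamples the second spacer until it differs from the first at both
ends, which restores identifiability without biasing mismatch counts.

DNA reads start uniformly over the genome (wrapping on circular
genomes); RNA reads are drawn per gene with probability proportional to
true expression weight × gene length and lie wholly inside their source
gene (base-level gene counting does not define junction handling, so
junction reads are not modeled). True weights are role weights
(structural genes and bS21 high, MCP highest — the late-replication
expression pattern) times a per-gene log-normal jitter (σ = 0.5), which
makes rank-recovery tests meaningful rather than tie-dominated.
Per-read mismatch counts are Binomial(read_length, error_rate).

Two-group MSAs plant divergent columns (group consensuses differ; each
group ≥90% internally conserved, enforced by construction), one aromatic
column (every sequence Y/H/F with Y predominant, mirroring the
Tyr54-style conservation at the ASD-blocking position), and background
columns sharing one consensus across groups at 0.95 conservation.

Everything derives from `numpy.random.default_rng` seeded from the spec;
a fixed seed reproduces all emitted files byte for byte.

## Neighborhood profiling

Neighborhoods are windows of up to `radius` (default 10) genes each side
of the anchor in scaffold coordinate order, truncated at scaffold ends.
Position signs follow coordinate order; because the figure-style
orientation convention relative to the anchor's own strand is ambiguous,
an optional marker-based reorientation (default marker label "MCP")
flips all signs when every marker gene lies at negative positions, so a
mirrored genome produces the same profile.

Family clustering replaces a two-step subfamily + profile–profile
(HMM–HMM) merge with single-pass greedy centroid clustering under the
same 0.75 coverage constraint: proteins are visited longest-first (ties
by ID, making the partition input-order invariant), and each joins the
first centroid reached at ≥30% global identity with ≥0.75 mutual
coverage. Profile–profile comparison is out of scope here; the 30%
identity default is a stated choice (the cited pipeline does not publish
its threshold) and is configurable. At the divergences the generator
produces (≤20% within a module family, random between families — random
200-aa proteins align at ≲25% identity) the greedy partition is
unambiguous, which is exactly the regime the tests verify.

Consensus annotation takes, among hits with *e* < 10⁻⁵, the label
hitting the most distinct member proteins, requires that count to reach
5% of the family, breaks ties lexicographically, and otherwise returns
"hyp".

Position profiles count *genomes*, not genes: each genome contributes
at most one count per (family, position) cell, also when it carries
several anchors. Per-family mean |distance| to the anchor and an
optional top-k most-frequent-family filter reproduce the bubble-plot
summaries. Presence/absence clustering drops genomes below 100 kbp
(configurable; the synthetic cohort is clustered at 20 kbp), builds the
binary family matrix, reports the count of families present in *all*
retained genomes, and applies average-linkage clustering to Jaccard
distances; genome IDs are sorted so tie-breaking is deterministic, and
the default flat cut sits in the largest merge-height gap (a fixed-k
cut is available separately).

## Spacer matching

Matching is substitution-only (Hamming) on both strands: the rule is
phrased purely in match length and mismatch count, and gapped matches
are undefined under it. For each spacer and target strand, every
ungapped full-spacer alignment frame is scanned (vectorized mismatch
prefix sums), and every sub-window of length ≥24 with ≤1 mismatch or
length ≥30 with ≤3 mismatches qualifies; windows hanging off the target
are not considered. Overlapping qualifying windows at one locus are
reduced to one hit — maximal length, then minimal mismatches, then
leftmost — per (spacer, target, strand); the dedupe rule is a package
convention (no published one exists). The matcher is tested for exact
set equality against a brute-force enumeration oracle on hundreds of
random instances; there is deliberately no heuristic pre-search
(BLAST-style seeding) because at desk scale the final filter can simply
be applied exhaustively.

The array detector anchors on an exact seed k-mer (the minimum repeat
length, 21), chains occurrences whose start-to-start periods are
compatible with repeat (21–48 bp) plus spacer (18–72 bp) lengths,
requires ≥3 copies, extends the repeat while every copy stays within
Hamming distance 2 of the first, and finally trims the repeat end back
to columns unanimous across all copies so the mismatch budget cannot
absorb spacer bases. Repeats whose leading seed is itself mutated are
missed — exact-repeat arrays (the generator default) are recovered
byte-identically, which is the clean-oracle regime the tests rely on.
Arrays are reported leftmost-first and never overlap.

## Detection, NTL and community profiles

Breadth is computed by interval union over aligned blocks of
identity-passing reads and verified against per-position boolean arrays.
Coverage divides total aligned target bases by the *covered* length —
"total length of mapped reads" is interpreted as aligned target bases,
which is robust to clipping; the two differ only for clipped or
indel-containing reads. Detection is `breadth ≥ 0.90` exactly, and the
flag flips at that boundary by construction.

For NTL, `total_read_genome` counts identity-passing RNA records mapped
anywhere on the genome (the formula's denominator is reads mapped to the
genome, not to genes); a read overlapping a gene partially contributes
only its overlapping bases; multi-mapping reads count once per target
with no rescaling (competitive mapping was checked in the original
analysis and made no difference, so no deduplication is attempted).
NTL is reported as NA below the 80% gene-base-coverage gate and when no
reads pass. Two invariants pin the formula down: duplicating every
record leaves each defined NTL fixed, and
Σ NTL·length·total_reads ≤ total mapped RNA bases, with equality only
when genes tile the genome.

rpS3 profiling drops markers under 300 nt, dereplicates greedily
(longest first) at 0.97 identity with 0.5 mutual coverage, filters
alignments at ≤3% mismatches per read, and reports per-taxon sums of
(mapped bases ÷ marker length).

## Two-group divergence

External divergence/conservation scorers are replaced by an explicit
modal-frequency statistic with exposed thresholds: per column, the
modal non-gap residue and its frequency are computed per group (ties
break alphabetically); a column is divergent iff both modal frequencies
are ≥ `tau_group` (0.7) and the modal residues differ, conserved iff the
pooled modal frequency is ≥ `tau_cons` (0.9), and uncallable when gaps
exceed half the rows. The statistic is symmetric under group exchange.
"Significantly divergent" has no published quantitative meaning here, so
the flags are threshold-based and labeled as such. Consensus sequences
emit the modal residue at ≥50% non-gap frequency, 'x' below it, and '-'
for majority-gap columns. Reference numbering maps alignment columns
onto 1-based residue numbers of a chosen ungapped reference (reporting
matches the Tyr54 convention; internals stay 0-based), and the aromatic
check reports each sequence's residue at a reference-numbered position
with membership in {F, Y, W, H}.

## Problem sizes and determinism

Tests and the acceptance script run at test scale: 30 kb genomes
(12 genomes, 3 clades), 150 bp reads at 15–50×, 70-column MSAs of 30+30
sequences, spacer oracles on targets of ≤700 bp with ≥200 instances —
sizes chosen so the whole suite completes in well under a minute while
still exercising every rule boundary (0/1/2/3 mismatches at 24/30 nt,
the 0.90 breadth flip, the 80% NTL gate, the 5% consensus rule). All
TSV output uses fixed column order and `%.6g` float formatting, so the
full CLI chain is byte-reproducible under a fixed seed; this is itself a
measured quantity.

## Known limitations

* No indel handling anywhere downstream of the SAM parser: spacer
  matching, clade simulation and identity arithmetic are
  substitution-only.
* The family clustering is greedy single-linkage-to-centroid, not
  profile–profile; at identities near the 30% threshold its partition
  can depend on the length-sorted visiting order in ways the planted
  (well-separated) regime never shows.
* The ORF caller is deliberately naive — ATG-only starts, standard
  code, Ns terminate ORFs, no wrap-around ORFs on circular genomes —
  and is meant as a fallback; real analyses should supply GFF3.
* The array detector misses repeats whose first 21 bp are mutated and
  reports exact boundaries only for exact repeats.
* Synthetic data omit: indels, chimeric and junction-spanning reads,
  quality scores, strain mixtures, GC skew and codon structure inside
  genes. Passing recovery tests therefore demonstrate the correctness
  of the implemented rules under their stated models, not robustness to
  every artifact of real sequencing data.
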
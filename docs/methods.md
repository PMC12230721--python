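# Methods

This note documents the models and procedures implemented in panforge, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Orthogroup inference

**Model.** An orthogroup is the set of genes descended from one gene in the
last common ancestor of the analyzed genomes; operationally we recover it as
a cluster in a similarity graph whose edges are reciprocal best hits (RBHs)
between genomes and recent-paralog pairs within genomes. The approach is the
OrthoMCL family: graph construction, per-category score normalization,
Markov clustering.

**Similarity engine.** The built-in engine is exact Smith–Waterman (BLOSUM62,
gap open 11 / extend 1, Biopython's C kernel). Identity is counted over
aligned columns (gaps included in the denominator); coverage is measured on
the query sequence, making each directed hit's coverage gate directional —
this matches common search-tool semantics and the directed tables RBH
consumes. Raw scores become bits via the Karlin–Altschul transform with
ungapped BLOSUM62 constants (λ = 0.3176, K = 0.134; configurable). Default
gates: identity ≥ 40%, coverage ≥ 70%.

A k-mer prescreen (skip pairs sharing < 3 protein 4-mers) makes the
quadratic all-vs-all practical at desk scale. Two unrelated 150-residue
proteins share ~0.1 four-mers in expectation, while full-length homologs at
40% identity share several, so the screen discards essentially all
unrelated pairs at negligible risk to genuine hits; it can be disabled
(`prefilter_kmer=None`) for the exhaustive mode, which tests use on small
inputs. External search tools are supported through a 12-column tabular
parser with the same threshold contract.

**RBH ties.** "Best hit" keeps *all* co-best targets at the exact maximal
bit score rather than breaking ties arbitrarily. The degenerate case that
motivates this is exact duplicates: if genome B holds two identical copies
b1, b2 of a's ortholog, a unique-best rule necessarily drops one reciprocal
pair and orphans the other copy, whereas keeping tied co-bests connects all
three genes. With continuous scores ties otherwise have measure zero, so
this reduces to the familiar unique-best RBH on real data. Where a single
winner is genuinely required (HEG screening, closest relatives), ties break
by higher identity then lexicographically smaller id, for determinism.

**Recent paralogs.** An intra-genome pair (x, y) is retained iff its score
strictly exceeds both genes' best inter-genome scores — the duplication
postdates every divergence represented in the dataset. Intra-genome edge
scores are the mean of the two directed bit scores, as for RBH edges.

**Normalization.** Each edge weight is divided by the mean raw weight of its
category; every inter-genome pair is one category and each genome's paralog
edges are one category. Post-normalization each category's mean is exactly 1
(asserted to 1e-9 in tests), preventing closely related genome pairs from
dominating MCL flow.

**MCL.** Sparse implementation; inflation 1.5 (the standard choice for
orthology granularity), self-loops of weight 1 added before column
stochasticization, prune threshold 1e-5, convergence when the max entry
change < 1e-8, cap 200 iterations (non-convergence returns the current
state with a warning flag). Clusters are read from attractor rows of the
limit matrix; overlapping attractor systems are merged, and a node claimed
by several systems goes to the one holding most of its column mass (ties to
the earlier cluster), enforcing a strict partition. The test suite checks
partitions against an independently coded dense reference implementation on
random planted-partition graphs (19/20 agreement required; in practice
20/20).

**Batched mode.** Genomes are deterministically shuffled under the seed and
sliced into batches (default 250; a trailing singleton batch is merged into
its predecessor). Per-batch orthogroups are summarized by a pseudo-genome:
one representative per orthogroup, the longest member protein, ties to the
lexicographically smallest id. Second-level inference over pseudo-genomes is
the same algorithm; representatives then expand back through the recorded
backmap, which partitions the batch's genes by construction. With batch size
≥ n the code path reduces exactly to direct inference.

## Orthogroup products

The table is sorted by the gene coordinates of the first genome, then of the
second for rows absent from the first, and so on; row indices after sorting
are the orthogroup numbers used everywhere downstream. Singleton genes are
emitted as one-member rows, so the numeric genome representation (each ORF
replaced by its orthogroup number, in file order) reserves −1 for genes
genuinely dropped upstream (e.g. untranslatable records); this keeps −1 rare
and meaningful. Orphan reporting distinguishes orphan orthogroups (≥ 2
genes, single genome) from orphan single genes (no orthologs, no paralogs);
the two classes partition the genes of single-genome orthogroups exactly.

Consensus sequences (used as orthogroup representatives for functional
annotation) take the plurality non-gap residue per column, drop columns
exceeding 50% gaps, and break ties alphabetically. OrthoXML export follows
the 0.3 schema layout (species → database → genes; groups → orthologGroup →
geneRef) and round-trips membership through a generic XML parser.

## Alignments, core genome, species tree

Production alignments come from MAFFT (`--auto`) through an adapter; the
built-in fallback is a center-star progressive aligner (longest sequence as
center, global pairwise alignments merged on center coordinates) that
guarantees the degap-identity invariant but is fixture-grade — adequate for
testing the surrounding machinery, not a substitute for a real MSA program
on diverged sequences. Reverse translation maps each residue to its source
codon and each gap to `---` after verifying that the DNA translates exactly
to the degapped row (trailing stop codons are tolerated and stripped), so a
codon alignment is always exactly three times its protein alignment.

Core orthogroups must cover ≥ `core_threshold_pct` of genomes (default
100%). Multi-member cells contribute one uniformly drawn representative
under the run seed. Below-100% thresholds leave genomes missing from some
orthogroups; their blocks are padded with gaps in the concatenation
(standard supermatrix practice, keeps rows equal length). When more than
1000 core orthogroups exist, 1000 are sampled uniformly without replacement
for the tree, to bound tree-builder runtime.

The species tree is built from the concatenated core proteome by an external
program (FastTree detected automatically; any tool reading aligned FASTA and
printing Newick can be configured), with a neighbor-joining fallback on
protein p-distances. Rooting utilities: midpoint rooting (used for display
when no outgroup is chosen) and outgroup rooting on the branch subtending a
named leaf; both preserve the unrooted bipartition set.

## Codon bias

*W* vectors follow Sharp & Li, computed from codon counts pooled over the
genome's HEG homologs: within each synonymous family of translation table
11, w(c) = count(c) / max family count, so every family's maximum is exactly
1. Codons unobserved in the HEG pool get 0.5 / max count — the customary
pseudo-value that keeps CAI's log well-defined without inflating rare
codons. A fully unobserved family is uninformative: all its members get
w = 1 with a warning. CAI is the geometric mean of w over a gene's codons,
excluding stops and the single-codon families ATG and TGG; per-orthogroup
CAI is the arithmetic mean over member genes, each scored under its own
genome's W.

The HEG screen aligns each panel protein against all translated ORFs, gating
on an E-value (default 1e-10, Karlin–Altschul on the query × database-size
space) and HEG-side coverage (default 70%). An ORF hit by several HEG
queries enters the codon pool once, to avoid double-weighting one gene's
usage. The user supplies the HEG protein FASTA; the canonical panel is a set
of 40 well-characterized *E. coli* HEGs distributed with the upstream
databases, and the test fixtures build a clearly labelled synthetic panel
from simulation ancestors instead.

## Completeness, KO assignment, ANI

Completeness is |profiles with ≥ 1 hit at E ≤ evalue_max| / panel size, with
defaults E ≤ 0.01 and a 148-profile core-bacterial single-copy-ortholog
panel; the denominator is the full panel regardless of which profiles hit,
so the statistic is comparable across genomes. KO assignment keeps hits
whose score **strictly exceeds** the KO's adaptive threshold (a hit exactly
at threshold is rejected); all passing KOs are reported sorted by descending
score, with a best-only switch. Both statistics operate on tabular hit files
from external profile-search tools (a `--tblout`-style parser is included);
profile scoring itself is out of scope.

ANI estimates are direction-dependent and missing for distant pairs, so the
matrix builder averages the two directions when both exist, uses the single
value otherwise, marks absent pairs missing (NaN, symmetric by
construction), and forces the diagonal to 100. Closest relatives are the
off-diagonal non-missing row maxima (ties to the lexicographically smaller
partner; isolated genomes report none). Hierarchical-clustering enhancement
of the heatmap is guarded on a fully observed matrix (`ani_is_complete`).

## Synthetic pan-genome generator

The generator defines the study conditions for all ground-truthed tests.
Defaults: 10 genomes, 50 core + 20 accessory families (accessory presence
probability 0.5), duplication probability 0.05, per-site mutation rate 0.05,
3 orphan genes per genome, codon-usage skew 0.7, gene lengths 80–160 codons.
Family ancestors are random codon sequences under a per-simulation skewed
codon distribution (one preferred codon per family, weight 1 vs 1 − skew);
genomes accumulate codon-level substitutions independently (half synonymous
re-draws, half amino-acid replacements, frame and stops preserved).
Duplicates are tandem and diverge at half the genome rate after copying, so
they are strictly closer to their source than to any ortholog — and exactly
identical in the zero-mutation limit, where family recovery must be perfect
(ARI = 1.0). Rearrangements (inversions, translocations, insertions of
novel genes) are applied one per distinct genome and logged with exact
block coordinates; a translocation's destination always differs from its
source slot so every logged event is a genuine edit.

Not emulated: intergenic DNA, gene loss along a phylogeny (presence is
i.i.d. per genome), lateral transfer, domain shuffling, indels within genes,
GC heterogeneity. Passing tests therefore demonstrate algorithmic
correctness under controlled signal, not performance on real assemblies.

For the threshold-contrast check (defaults (40, 70) vs strict (60, 80)), the
simulation uses mutation rate 0.2 on 6 genomes: measured within-family
amino-acid identity then averages ~59% (range ~44–90%), straddling the
40–60% identity band so that raising the thresholds genuinely fragments
families — the premise of the contrast. At the default 5% divergence both
runs would see identical hit sets and the contrast would be vacuous.

## Problem sizes and runtime

The test suite and the acceptance script run on one CPU in well under a
minute each at these sizes: orthology recovery uses the default 10-genome
simulation (~660 genes, ~2 × 10⁵ candidate pairs before the k-mer screen);
rearrangement detection uses twenty 4-genome simulations; the MCL
cross-check uses twenty graphs of ≤ 30 nodes; CAI/normalization/completeness
exactness use 100 random instances each; determinism runs the full pipeline
twice on a 3-genome simulation. These sizes were chosen as the smallest that
still exercise every code path with non-trivial structure (paralogs,
accessory absence, orphans, batching into ≥ 3 batches).

## Known limitations

- The built-in aligners (protein search and MSA) are exact but quadratic;
  hundreds of genomes require the external-tool adapters.
- MCL granularity is controlled only by inflation; very shallow divergences
  can merge adjacent families regardless of threshold settings.
- The recent-paralog rule is dataset-relative: a duplication is "recent"
  only with respect to the genomes present, so adding a close relative can
  reclassify paralogs.
- Plasmid filtering is a case-insensitive substring match on headers —
  exactly as specified, and exactly as fragile as header curation.
- ANI values and profile-HMM scores are consumed, never computed; their
  quality is the upstream tool's responsibility.
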
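# panforge

Comparative bacterial pan-genomics at desk scale: orthogroup inference,
pan-genome products, core-genome phylogenomics, codon-bias analysis and
annotation statistics — as a tested Python library with a thin CLI.

## Who this is for

Groups comparing collections of bacterial genomes (species, strains or
isolates): given one FASTA file per genome — assemblies, contigs, or DNA ORF
sets — the pipeline clusters genes into **orthogroups** (groups of genes
descended from a single ancestral gene), and derives the standard comparative
products from that table: phyletic presence/absence patterns, per-genome
orphan genes, a numeric gene-order encoding that exposes rearrangements,
concatenated core-genome/core-proteome supermatrices and a species tree,
per-genome codon-usage adaptiveness (*W*) vectors with per-gene CAI,
BUSCO-style completeness fractions, KEGG Orthology assignment, and an ANI
matrix with closest-relative calls.

## The method

Orthogroup inference follows the OrthoMCL family of algorithms:

1. **All-vs-all protein search.** Translated ORFs (table 11) are compared
   either with the built-in exact Smith–Waterman engine (desk scale) or via
   an external search tool's tabular output. Hits must pass identity ≥ 40%
   and query coverage ≥ 70% (both configurable).
2. **Graph construction.** For each genome pair, reciprocal best hits (RBHs)
   become inter-genome edges weighted by the mean directed bit score. Within
   each genome, gene pairs scoring higher to each other than either scores
   to *any* gene of another genome are **recent paralogs** (duplications
   postdating divergence) and become intra-genome edges.
3. **Normalization.** Edge weights are divided by the mean weight of their
   category (each genome pair, and each genome's paralog set, is its own
   category), so each category's mean weight is exactly 1 and closely
   related genome pairs cannot dominate the clustering.
4. **Markov clustering.** The weighted graph is clustered with MCL at
   inflation *r* = 1.5: the column-stochastic flow matrix *M* is alternately
   squared (expansion) and taken to the entrywise power *r* with
   re-normalization (inflation) until idempotence; clusters are read from
   the attractor structure. Genes absent from the graph become singleton
   orthogroups.
5. **Batched mode.** For many genomes, inference runs per batch, a
   *pseudo-genome* holding one representative (longest member) per batch
   orthogroup is built, the same algorithm runs over the pseudo-genomes,
   and representatives are expanded back to full membership.

Downstream, core orthogroups (present in ≥ a threshold percentage of
genomes, default 100%) are aligned per orthogroup, reverse-translated to
codon alignments, and concatenated (sampling at most 1000 core orthogroups
for the tree). Codon bias follows Sharp & Li: the *W* vector is each codon's
count in highly-expressed-gene (HEG) homologs divided by the count of its
family's commonest codon, and CAI is the geometric mean of *W* over a gene's
codons (stops and single-codon families excluded). Completeness is the
fraction of a universal single-copy-ortholog profile panel (148 profiles)
with at least one hit at E ≤ 0.01.

## Worked example

```bash
panforge simulate --genomes 4 --core 12 --accessory 4 --mutation-rate 0.05 \
    --seed 7 --out genomes
panforge run genomes --out results --no-plots
```

The simulated input has 4 genomes sharing 12 core gene families, 4 accessory
families, and 3 unique orphan genes each. The run prints `done: results` and
the output folders contain, among others:

```text
results/02b_orf_statistics/orf_stats.csv
    genome,orf_count,gc_percent
    G00,17,46.0181
    G01,17,46.0317
    ...

results/05b_orthogroup_products/og_size_histogram.csv
    n_genomes,count
    1,12        <- the 12 orphan genes, one singleton orthogroup each
    2,2
    3,2
    4,12        <- the 12 core families, recovered in all 4 genomes

results/04_orphans/orphan_counts.csv
    genome,orphan_orthogroups,orphan_single_genes
    G00,0,3     <- exactly the 3 simulated orphans per genome
    ...

results/08_species_tree/species_tree.newick
    (G00:0.0714,G02:0.0941,(G01:0.1013,G03:0.0706)0.633:0.0011);
```

The orthogroup table (`05a_orthogroups/orthogroups.csv`) has one row per
orthogroup and one column per genome; multi-gene cells are
semicolon-joined (`G03|g0001;G03|g0002` marks a recent duplication). Rows
follow the gene order of the first genome, then of the second for
orthogroups absent from the first, and so on — so the numeric representation
(`05b_orthogroup_products/numeric_representation.txt`) of closely related
genomes is near-monotone, and inversions/translocations appear as reversed
or displaced integer blocks.

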
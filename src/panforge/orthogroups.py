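"""Orthogroup inference: RBH + recent-paralog graph, score normalization, MCL.

The method follows the OrthoMCL family of algorithms.  For every genome pair,
reciprocal best hits (RBHs) between threshold-filtered protein searches form
inter-genome edges; within each genome, gene pairs more similar to each other
than either is to any gene of another genome form intra-genome ("recent
paralog") edges.  Edge bit scores are normalized per category (each genome
pair, and each genome's paralog set, is its own category) so that no pair of
closely related genomes dominates the flow, and the resulting weighted graph
is clustered with MCL at inflation 1.5.

For large genome collections the quadratic all-vs-all becomes prohibitive, so
inference can run hierarchically: genomes are partitioned into batches,
orthogroups are inferred within each batch, a "pseudo-genome" holding one
representative per batch orthogroup is formed, the same algorithm is applied
to the pseudo-genomes, and finally each representative is expanded back to
its full membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import mcl as _mcl
from .similarity import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    HitTable,
    SimilarityHit,
    all_vs_all,
)

ProteinSets = Mapping[str, Mapping[str, str]]  # genome -> gene id -> protein


@dataclass
class OrthoParams:
    """Tunable knobs of the inference.

    Identity/coverage thresholds are percentages applied to every directed
    hit; inflation is the MCL granularity parameter.
    """

    min_identity_pct: float = DEFAULT_MIN_IDENTITY
    min_coverage_pct: float = DEFAULT_MIN_COVERAGE
    inflation: float = 1.5
    prune_threshold: float = 1e-5
    max_iters: int = 200
    convergence_tol: float = 1e-8
    prefilter_kmer: int | None = 4
    prefilter_min_shared: int = 3


@dataclass
class Edge:
    u: str
    v: str
    weight: float
    category: tuple  # ("inter", gA, gB) with gA < gB, or ("intra", g)


@dataclass
class OrthologyGraph:
    genome_of: dict[str, str]
    edges: list[Edge] = field(default_factory=list)

    def nodes(self) -> list[str]:
        seen = dict.fromkeys(self.genome_of)
        return list(seen)


@dataclass
class Orthogroup:
    og_id: int
    members: dict[str, list[str]]  # genome -> gene ids (file order)

    def all_genes(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]

    def n_genomes(self) -> int:
        return sum(1 for genes in self.members.values() if genes)

    def size(self) -> int:
        return sum(len(genes) for genes in self.members.values())


class OrthogroupTable:
    """Genomes x orthogroups membership table (rows = orthogroups)."""

    def __init__(self, genome_order: Sequence[str], rows: list[Orthogroup]):
        self.genome_order = list(genome_order)
        self.rows = rows
        self._check_partition()

    def _check_partition(self):
        seen: set[str] = set()
        for og in self.rows:
            if og.size() == 0:
                raise ValueError(f"empty orthogroup {og.og_id}")
            for gene in og.all_genes():
                if gene in seen:
                    raise ValueError(f"gene {gene!r} appears in more than one orthogroup")
                seen.add(gene)

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def all_genes(self) -> list[str]:
        return [g for og in self.rows for g in og.all_genes()]

    def gene_to_og(self) -> dict[str, int]:
        return {gene: og.og_id for og in self.rows for gene in og.all_genes()}

    def sort(self, coords: Mapping[str, Mapping[str, int]]) -> "OrthogroupTable":
        """Sort rows by the gene-order convention and reindex og ids.

        Key = (index of the first genome in ``genome_order`` that has a
        member in the orthogroup, coordinate rank of that genome's first
        member).  ``coords`` maps genome -> gene id -> coordinate rank.
        """

        def key(og: Orthogroup):
            for gi, genome in enumerate(self.genome_order):
                genes = og.members.get(genome) or []
                if genes:
                    return (gi, min(coords[genome][g] for g in genes))
            raise ValueError("orthogroup with no members")

        new_rows = sorted(self.rows, key=key)
        rows = [Orthogroup(i, og.members) for i, og in enumerate(new_rows)]
        return OrthogroupTable(self.genome_order, rows)

    def to_dataframe(self):
        import pandas as pd

        data = {
            genome: [";".join(og.members.get(genome, [])) for og in self.rows]
            for genome in self.genome_order
        }
        df = pd.DataFrame(data, index=[og.og_id for og in self.rows])
        df.index.name = "OG"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "OrthogroupTable":
        import pandas as pd

        df = pd.read_csv(path, index_col=0, keep_default_na=False, dtype=str)
        genome_order = list(df.columns)
        rows = []
        for i, (_, row) in enumerate(df.iterrows()):
            members = {g: row[g].split(";") for g in genome_order if row[g]}
            rows.append(Orthogroup(i, members))
        return cls(genome_order, rows)


# ---------------------------------------------------------------------------
# graph construction


def split_by_genome_pair(
    hits: HitTable, genome_of: Mapping[str, str]
) -> dict[tuple[str, str], HitTable]:
    """Split a global hit table into per-(query genome, target genome) tables."""
    out: dict[tuple[str, str], HitTable] = {}
    for h in hits:
        key = (genome_of[h.query_id], genome_of[h.target_id])
        out.setdefault(key, HitTable()).add(h)
    return out


def find_rbh(hits_ab: HitTable, hits_ba: HitTable) -> list[tuple[str, str, float]]:
    """Reciprocal best hits between genome A (queries of ``hits_ab``) and B.

    Gene a of A and b of B form an RBH iff b is among a's best hits in B and
    a is among b's best hits in A, "best" being the maximal bit score.  All
    co-best hits at the exact maximal score are kept: when several targets
    tie (identical sequences, e.g. fresh duplicates), every tied reciprocal
    pair is an RBH — an arbitrary tie-break would orphan exact copies.  The
    edge score is the mean of the two directed bit scores.
    """

    def best_map(table: HitTable) -> dict[str, dict[str, SimilarityHit]]:
        best: dict[str, tuple[float, dict[str, SimilarityHit]]] = {}
        for h in table:
            cur = best.get(h.query_id)
            if cur is None or h.bit_score > cur[0]:
                best[h.query_id] = (h.bit_score, {h.target_id: h})
            elif h.bit_score == cur[0]:
                cur[1][h.target_id] = h
        return {q: targets for q, (_, targets) in best.items()}

    best_ab = best_map(hits_ab)
    best_ba = best_map(hits_ba)
    out = []
    for a in sorted(best_ab):
        for b in sorted(best_ab[a]):
            rev = best_ba.get(b, {})
            if a in rev:
                h, r = best_ab[a][b], rev[a]
                out.append((a, b, (h.bit_score + r.bit_score) / 2.0))
    return out


def best_inter_genome_scores(
    hits: HitTable, genome_of: Mapping[str, str]
) -> dict[str, float]:
    """Each gene's maximal bit score to any gene of another genome (0 if none)."""
    best: dict[str, float] = {}
    for h in hits:
        if genome_of[h.query_id] != genome_of[h.target_id]:
            if h.bit_score > best.get(h.query_id, 0.0):
                best[h.query_id] = h.bit_score
            if h.bit_score > best.get(h.target_id, 0.0):
                best[h.target_id] = h.bit_score
    return best


def find_recent_paralogs(
    within_hits: HitTable, best_inter_score: Mapping[str, float]
) -> list[tuple[str, str, float]]:
    """Intra-genome gene pairs closer to each other than to any other genome.

    A pair (x, y) is a recent paralog edge iff its bit score strictly exceeds
    both genes' best inter-genome scores — i.e. the duplication postdates the
    divergence from every other genome in the dataset.
    """
    out = []
    seen: set[tuple[str, str]] = set()
    for h in within_hits:
        x, y = sorted((h.query_id, h.target_id))
        if (x, y) in seen:
            continue
        rev = within_hits.get(h.target_id, h.query_id)
        score = h.bit_score if rev is None else (h.bit_score + rev.bit_score) / 2.0
        if score > best_inter_score.get(x, 0.0) and score > best_inter_score.get(y, 0.0):
            seen.add((x, y))
            out.append((x, y, score))
    return out


def normalize_weights(graph: OrthologyGraph) -> OrthologyGraph:
    """Divide each edge weight by the mean raw weight of its category.

    After normalization every category's mean weight is exactly 1, so no
    genome pair (or paralog set) dominates the clustering by virtue of
    overall sequence similarity.
    """
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for e in graph.edges:
        sums[e.category] = sums.get(e.category, 0.0) + e.weight
        counts[e.category] = counts.get(e.category, 0) + 1
    means = {c: sums[c] / counts[c] for c in sums}
    new_edges = [Edge(e.u, e.v, e.weight / means[e.category], e.category) for e in graph.edges]
    return OrthologyGraph(dict(graph.genome_of), new_edges)


def build_orthology_graph(
    hits: HitTable, genome_of: Mapping[str, str]
) -> OrthologyGraph:
    """Assemble RBH and recent-paralog edges from a global filtered hit table."""
    per_pair = split_by_genome_pair(hits, genome_of)
    genomes = sorted(set(genome_of.values()))
    edges: list[Edge] = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            ab = per_pair.get((ga, gb), HitTable())
            ba = per_pair.get((gb, ga), HitTable())
            for a, b, w in find_rbh(ab, ba):
                edges.append(Edge(a, b, w, ("inter", ga, gb)))
    best_inter = best_inter_genome_scores(hits, genome_of)
    for g in genomes:
        within = per_pair.get((g, g), HitTable())
        for x, y, w in find_recent_paralogs(within, best_inter):
            edges.append(Edge(x, y, w, ("intra", g)))
    return OrthologyGraph(dict(genome_of), edges)


# ---------------------------------------------------------------------------
# inference


def _flatten(proteins: ProteinSets) -> tuple[dict[str, str], dict[str, str]]:
    universe: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for genome, genes in proteins.items():
        for gid, seq in genes.items():
            if gid in universe:
                raise ValueError(f"gene id {gid!r} occurs in more than one genome")
            universe[gid] = seq
            genome_of[gid] = genome
    return universe, genome_of


def _coords(proteins: ProteinSets) -> dict[str, dict[str, int]]:
    return {g: {gid: i for i, gid in enumerate(genes)} for g, genes in proteins.items()}


def _clusters_to_table(
    clusters: list[list[str]],
    proteins: ProteinSets,
    genome_of: Mapping[str, str],
) -> OrthogroupTable:
    genome_order = list(proteins)
    coords = _coords(proteins)
    clustered = {g for c in clusters for g in c}
    rows = []
    for c in clusters:
        members: dict[str, list[str]] = {}
        for gene in c:
            members.setdefault(genome_of[gene], []).append(gene)
        for genome in members:
            members[genome].sort(key=lambda g: coords[genome][g])
        rows.append(Orthogroup(0, members))
    # singleton genes absent from the graph become one-member orthogroups
    for genome, genes in proteins.items():
        for gid in genes:
            if gid not in clustered:
                rows.append(Orthogroup(0, {genome: [gid]}))
    table = OrthogroupTable(genome_order, [Orthogroup(i, og.members) for i, og in enumerate(rows)])
    return table.sort(coords)


def infer_orthogroups(
    proteins: ProteinSets,
    params: OrthoParams | None = None,
    hits: HitTable | None = None,
) -> OrthogroupTable:
    """Infer orthogroups for >=2 genomes of translated ORFs.

    ``proteins`` maps genome name -> ordered mapping of gene id -> protein
    sequence (the inner order must follow genomic coordinates; it drives the
    table sorting convention).  A precomputed, already threshold-filtered
    ``hits`` table (e.g. from an external search tool) may be supplied to
    skip the built-in all-vs-all.
    """
    params = params or OrthoParams()
    if len(proteins) < 2:
        raise ValueError("orthogroup inference requires at least 2 genomes")
    universe, genome_of = _flatten(proteins)
    if hits is None:
        hits = all_vs_all(
            universe,
            universe,
            min_identity_pct=params.min_identity_pct,
            min_coverage_pct=params.min_coverage_pct,
            prefilter_kmer=params.prefilter_kmer,
            prefilter_min_shared=params.prefilter_min_shared,
        )
    graph = build_orthology_graph(hits, genome_of)
    graph = normalize_weights(graph)
    nodes = sorted({e.u for e in graph.edges} | {e.v for e in graph.edges})
    result = _mcl.mcl(
        nodes,
        [(e.u, e.v, e.weight) for e in graph.edges],
        inflation=params.inflation,
        prune_threshold=params.prune_threshold,
        max_iters=params.max_iters,
        convergence_tol=params.convergence_tol,
    )
    return _clusters_to_table(result.clusters, proteins, genome_of)


# ---------------------------------------------------------------------------
# batched (pseudo-genome) mode


def partition_batches(
    genome_names: Sequence[str], batch_size: int, seed: int = 0
) -> list[list[str]]:
    """Deterministically shuffle genomes and slice into batches.

    The last batch may be smaller; a trailing batch of size 1 is merged into
    the previous one (single-genome inference is undefined).
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    names = list(genome_names)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    shuffled = [names[i] for i in order]
    batches = [shuffled[i : i + batch_size] for i in range(0, len(shuffled), batch_size)]
    if len(batches) > 1 and len(batches[-1]) == 1:
        batches[-2].extend(batches.pop())
    return batches


@dataclass
class PseudoGenome:
    """One representative protein per orthogroup of a batch."""

    name: str
    records: dict[str, str]  # representative gene id -> protein
    backmap: dict[str, list[str]]  # representative -> all member gene ids


def build_pseudo_genome(
    batch_table: OrthogroupTable, proteins: Mapping[str, str], name: str
) -> PseudoGenome:
    """Pick the longest member protein of each orthogroup as representative.

    Ties are broken by lexicographically smallest gene id.  The backmap
    partitions the batch's genes across representatives.
    """
    records: dict[str, str] = {}
    backmap: dict[str, list[str]] = {}
    for og in batch_table:
        genes = og.all_genes()
        rep = min(genes, key=lambda g: (-len(proteins[g]), g))
        records[rep] = proteins[rep]
        backmap[rep] = sorted(genes)
    return PseudoGenome(name=name, records=records, backmap=backmap)


def infer_orthogroups_batched(
    proteins: ProteinSets,
    params: OrthoParams | None = None,
    batch_size: int = 250,
    seed: int = 0,
) -> OrthogroupTable:
    """Hierarchical inference: per-batch orthogroups -> pseudo-genomes -> expand.

    With ``batch_size >= len(proteins)`` this reduces exactly to
    :func:`infer_orthogroups`.
    """
    params = params or OrthoParams()
    if len(proteins) < 2:
        raise ValueError("orthogroup inference requires at least 2 genomes")
    batches = partition_batches(list(proteins), batch_size, seed)
    if len(batches) == 1:
        return infer_orthogroups(proteins, params)

    universe, genome_of = _flatten(proteins)
    pseudo_sets: dict[str, dict[str, str]] = {}
    backmaps: dict[str, list[str]] = {}
    for bi, batch in enumerate(batches):
        sub = {g: proteins[g] for g in batch}
        table = infer_orthogroups(sub, params)
        pg = build_pseudo_genome(table, universe, name=f"batch{bi}")
        pseudo_sets[pg.name] = pg.records
        backmaps.update(pg.backmap)

    second = infer_orthogroups(pseudo_sets, params)

    coords = _coords(proteins)
    rows = []
    for og in second:
        members: dict[str, list[str]] = {}
        for rep in og.all_genes():
            for gene in backmaps[rep]:
                members.setdefault(genome_of[gene], []).append(gene)
        for genome in members:
            members[genome].sort(key=lambda g: coords[genome][g])
        rows.append(Orthogroup(0, members))
    table = OrthogroupTable(list(proteins), [Orthogroup(i, og.members) for i, og in enumerate(rows)])
    return table.sort(coords)
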
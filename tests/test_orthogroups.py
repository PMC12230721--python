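import itertools
import random

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from panforge.orthogroups import (
    Edge,
    OrthogroupTable,
    OrthologyGraph,
    OrthoParams,
    best_inter_genome_scores,
    build_pseudo_genome,
    find_rbh,
    find_recent_paralogs,
    infer_orthogroups,
    infer_orthogroups_batched,
    normalize_weights,
    partition_batches,
)
from panforge.similarity import HitTable, SimilarityHit
from panforge.simulate import simulate_pangenome, to_protein_sets


def _hits(rows):
    t = HitTable()
    for q, tg, bits in rows:
        t.add(SimilarityHit(q, tg, bits, 90.0, 90.0))
    return t


def ari_vs_truth(table, truth):
    genes = table.all_genes()
    g2o = table.gene_to_og()
    return adjusted_rand_score(
        [truth.family_of[g] for g in genes], [g2o[g] for g in genes]
    )


class TestFindRbh:
    def test_mutual_best_is_rbh(self):
        ab = _hits([("a", "b", 100.0)])
        ba = _hits([("b", "a", 90.0)])
        assert find_rbh(ab, ba) == [("a", "b", 95.0)]

    def test_asymmetric_best_is_not_rbh(self):
        ab = _hits([("a", "b", 100.0)])
        ba = _hits([("b", "a2", 120.0), ("b", "a", 90.0)])
        assert find_rbh(ab, ba) == []

    def test_tied_co_best_hits_all_qualify(self):
        # two identical targets: both tied pairs are reciprocal
        ab = _hits([("a", "b1", 100.0), ("a", "b2", 100.0)])
        ba = _hits([("b1", "a", 100.0), ("b2", "a", 100.0)])
        assert sorted(find_rbh(ab, ba)) == [("a", "b1", 100.0), ("a", "b2", 100.0)]

    def test_matches_brute_force_on_random_tables(self):
        rng = random.Random(17)
        a_genes = [f"a{i}" for i in range(5)]
        b_genes = [f"b{i}" for i in range(5)]
        for _ in range(20):
            ab = _hits(
                [(a, b, rng.randrange(50, 200)) for a in a_genes for b in b_genes if rng.random() < 0.6]
            )
            ba = _hits(
                [(b, a, rng.randrange(50, 200)) for a in a_genes for b in b_genes if rng.random() < 0.6]
            )
            got = {(a, b) for a, b, _ in find_rbh(ab, ba)}
            expect = set()
            for a, b in itertools.product(a_genes, b_genes):
                h_ab, h_ba = ab.get(a, b), ba.get(b, a)
                if h_ab is None or h_ba is None:
                    continue
                best_a = max(h.bit_score for h in ab.hits_from(a))
                best_b = max(h.bit_score for h in ba.hits_from(b))
                if h_ab.bit_score == best_a and h_ba.bit_score == best_b:
                    expect.add((a, b))
            assert got == expect


class TestRecentParalogs:
    def test_closer_than_any_other_genome_retained(self):
        within = _hits([("x", "y", 200.0), ("y", "x", 200.0)])
        assert find_recent_paralogs(within, {"x": 150.0, "y": 150.0}) == [("x", "y", 200.0)]

    def test_single_gene_genome_has_none(self):
        assert find_recent_paralogs(_hits([]), {}) == []

    def test_not_retained_when_inter_genome_is_closer(self):
        within = _hits([("x", "y", 140.0), ("y", "x", 140.0)])
        assert find_recent_paralogs(within, {"x": 150.0, "y": 100.0}) == []

    def test_best_inter_scores_ignore_intra(self):
        hits = _hits([("a1", "a2", 300.0), ("a1", "b1", 120.0), ("b1", "a1", 110.0)])
        genome_of = {"a1": "A", "a2": "A", "b1": "B"}
        best = best_inter_genome_scores(hits, genome_of)
        assert best == {"a1": 120.0, "b1": 120.0}


class TestNormalizeWeights:
    def test_category_means_become_one(self):
        g = OrthologyGraph(
            {"a": "A", "b": "B", "c": "A", "d": "B"},
            [
                Edge("a", "b", 50.0, ("inter", "A", "B")),
                Edge("c", "d", 150.0, ("inter", "A", "B")),
                Edge("a", "c", 80.0, ("intra", "A")),
            ],
        )
        out = normalize_weights(g)
        weights = {(e.u, e.v): e.weight for e in out.edges}
        assert weights[("a", "b")] == pytest.approx(0.5)
        assert weights[("c", "d")] == pytest.approx(1.5)
        assert weights[("a", "c")] == pytest.approx(1.0)

    def test_random_graphs_mean_one_per_category(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            genomes = ["A", "B", "C"]
            genome_of, edges = {}, []
            for i in range(30):
                genome_of[f"g{i}"] = genomes[i % 3]
            for _ in range(60):
                i, j = rng.integers(0, 30, 2)
                if i == j:
                    continue
                u, v = f"g{i}", f"g{j}"
                ga, gb = sorted((genome_of[u], genome_of[v]))
                cat = ("intra", ga) if ga == gb else ("inter", ga, gb)
                edges.append(Edge(u, v, float(rng.uniform(10, 300)), cat))
            out = normalize_weights(OrthologyGraph(genome_of, edges))
            sums: dict = {}
            for e in out.edges:
                sums.setdefault(e.category, []).append(e.weight)
            for cat, ws in sums.items():
                assert abs(np.mean(ws) - 1.0) < 1e-9


class TestInferOrthogroups:
    def test_conserved_families_recovered_exactly(self, small_sim):
        genomes, truth = small_sim
        table = infer_orthogroups(to_protein_sets(genomes))
        assert ari_vs_truth(table, truth) == 1.0

    def test_unique_gene_becomes_singleton(self, small_sim):
        genomes, truth = small_sim
        table = infer_orthogroups(to_protein_sets(genomes))
        orphan_genes = {g for g, f in truth.family_of.items() if f.startswith("orphan")}
        g2o = table.gene_to_og()
        by_og: dict = {}
        for g in table.all_genes():
            by_og.setdefault(g2o[g], []).append(g)
        for gene in orphan_genes:
            assert by_og[g2o[gene]] == [gene]

    def test_noisy_simulation_recovery(self, noisy_sim, noisy_table):
        _, truth = noisy_sim
        assert ari_vs_truth(noisy_table, truth) >= 0.95

    def test_partition_invariant(self, noisy_sim, noisy_table):
        genomes, _ = noisy_sim
        all_input = sorted(r.id for g in genomes for r in g.records)
        assert sorted(noisy_table.all_genes()) == all_input

    def test_requires_two_genomes(self):
        with pytest.raises(ValueError):
            infer_orthogroups({"only": {"g1": "MKL"}})

    def test_table_round_trips_through_csv(self, tmp_path, small_sim):
        genomes, _ = small_sim
        table = infer_orthogroups(to_protein_sets(genomes))
        path = tmp_path / "ogs.csv"
        table.to_csv(path)
        back = OrthogroupTable.from_csv(path)
        assert [og.members for og in back] == [og.members for og in table]


class TestBatching:
    def test_partition_sizes(self):
        batches = partition_batches([f"g{i}" for i in range(10)], 4, seed=0)
        assert sorted(len(b) for b in batches) == [2, 4, 4]

    def test_batch_size_at_least_n_single_batch(self):
        assert len(partition_batches(["a", "b", "c"], 5, seed=1)) == 1

    def test_trailing_singleton_merged(self):
        batches = partition_batches([f"g{i}" for i in range(5)], 2, seed=3)
        assert all(len(b) >= 2 for b in batches)

    def test_deterministic_under_seed(self):
        names = [f"g{i}" for i in range(20)]
        assert partition_batches(names, 6, seed=9) == partition_batches(names, 6, seed=9)

    def test_pseudo_genome_representative_and_backmap(self, small_sim):
        genomes, _ = small_sim
        prots = to_protein_sets(genomes)
        table = infer_orthogroups(prots)
        flat = {gid: s for d in prots.values() for gid, s in d.items()}
        pg = build_pseudo_genome(table, flat, "b0")
        assert len(pg.records) == len(table)
        # representative is a longest member
        for rep, members in pg.backmap.items():
            assert len(flat[rep]) == max(len(flat[m]) for m in members)
        # backmap partitions the gene set
        all_back = sorted(g for ms in pg.backmap.values() for g in ms)
        assert all_back == sorted(flat)

    def test_batched_agrees_with_direct(self, noisy_sim, noisy_table):
        genomes, _ = noisy_sim
        prots = to_protein_sets(genomes)
        batched = infer_orthogroups_batched(prots, batch_size=4, seed=7)
        genes = noisy_table.all_genes()
        d, b = noisy_table.gene_to_og(), batched.gene_to_og()
        ari = adjusted_rand_score([d[g] for g in genes], [b[g] for g in genes])
        assert ari >= 0.95
        assert sorted(batched.all_genes()) == sorted(genes)

    def test_degenerate_batching_identical_to_direct(self, small_sim):
        genomes, _ = small_sim
        prots = to_protein_sets(genomes)
        direct = infer_orthogroups(prots)
        batched = infer_orthogroups_batched(prots, batch_size=len(prots), seed=5)
        assert [og.members for og in batched] == [og.members for og in direct]
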
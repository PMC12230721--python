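import io
import random

import numpy as np
import pytest

from panforge.og_products import (
    consensus_sequence,
    find_orphans,
    numeric_representation,
    og_size_histogram,
    parse_orthoxml_membership,
    phyletic_pattern,
    read_phyletic_fasta,
    sort_table,
    write_orthoxml,
    write_phyletic_fasta,
)
from panforge.orthogroups import Orthogroup, OrthogroupTable
from panforge.simulate import apply_event, simulate_pangenome, to_protein_sets
from panforge.orthogroups import infer_orthogroups


def naive_sort_oracle(table, coords):
    """O(n^2) comparator-based sort of orthogroup rows."""

    def key(og):
        for gi, genome in enumerate(table.genome_order):
            genes = og.members.get(genome) or []
            if genes:
                return (gi, min(coords[genome][g] for g in genes))
        raise AssertionError

    rows = list(table.rows)
    out = []
    while rows:
        best = rows[0]
        for og in rows[1:]:
            if key(og) < key(best):
                best = og
        rows.remove(best)
        out.append(best)
    return [og.members for og in out]


class TestSortTable:
    COORDS = {
        "gA": {"a1": 0, "a2": 1, "a3": 2},
        "gB": {"b1": 0, "b2": 1, "b3": 2},
    }

    def test_first_genome_rank_orders_rows(self):
        rows = [
            Orthogroup(0, {"gA": ["a3"], "gB": ["b1"]}),
            Orthogroup(1, {"gA": ["a1"], "gB": ["b2"]}),
        ]
        table = OrthogroupTable(["gA", "gB"], rows)
        out = sort_table(table, self.COORDS)
        assert [og.members["gA"] for og in out] == [["a1"], ["a3"]]
        assert [og.og_id for og in out] == [0, 1]  # reindexed

    def test_rows_without_first_genome_sort_after(self):
        rows = [
            Orthogroup(0, {"gB": ["b1"]}),
            Orthogroup(1, {"gA": ["a2"]}),
        ]
        out = sort_table(OrthogroupTable(["gA", "gB"], rows), self.COORDS)
        assert list(out.rows[0].members) == ["gA"]
        assert list(out.rows[1].members) == ["gB"]

    def test_agrees_with_naive_comparator_sort(self):
        rng = random.Random(2)
        for _ in range(10):
            genomes = ["gA", "gB", "gC"]
            coords = {g: {f"{g}_{i}": i for i in range(12)} for g in genomes}
            rows, used = [], {g: set() for g in genomes}
            for og_id in range(8):
                members = {}
                for g in genomes:
                    if rng.random() < 0.6:
                        avail = [x for x in coords[g] if x not in used[g]]
                        if avail:
                            pick = rng.choice(avail)
                            used[g].add(pick)
                            members[g] = [pick]
                if members:
                    rows.append(Orthogroup(og_id, members))
            table = OrthogroupTable(genomes, rows)
            out = sort_table(table, coords)
            assert [og.members for og in out] == naive_sort_oracle(table, coords)


class TestPhyleticPattern:
    def test_toy_pattern(self):
        rows = [
            Orthogroup(0, {"g1": ["a"], "g2": ["b"]}),
            Orthogroup(1, {"g1": ["c"]}),
        ]
        pat = phyletic_pattern(OrthogroupTable(["g1", "g2"], rows))
        assert pat.row_string("g1") == "11"
        assert pat.row_string("g2") == "10"

    def test_all_core_all_ones(self, toy_table):
        core_rows = [og for og in toy_table if og.n_genomes() == 3]
        table = OrthogroupTable(toy_table.genome_order, [Orthogroup(0, core_rows[0].members)])
        pat = phyletic_pattern(table)
        assert pat.matrix.all()

    def test_fasta_round_trip(self, toy_table):
        pat = phyletic_pattern(toy_table)
        buf = io.StringIO()
        write_phyletic_fasta(pat, buf)
        back = read_phyletic_fasta(io.StringIO(buf.getvalue()))
        assert back.genome_order == pat.genome_order
        assert (back.matrix == pat.matrix).all()

    def test_row_sums_equal_membership_counts(self, toy_table):
        pat = phyletic_pattern(toy_table)
        for i, g in enumerate(pat.genome_order):
            expect = sum(1 for og in toy_table if og.members.get(g))
            assert pat.matrix[i].sum() == expect
        assert (pat.matrix.sum(axis=0) >= 1).all()


class TestOrphans:
    def test_classes(self, toy_table):
        rep = find_orphans(toy_table)
        assert rep.orphan_orthogroups["gC"] == [2]  # paralog pair c2,c3
        assert rep.orphan_single_genes["gB"] == ["b3"]
        assert rep.orphan_orthogroups["gA"] == []
        assert rep.orphan_single_genes["gA"] == []

    def test_classes_partition_single_genome_og_genes(self, toy_table):
        rep = find_orphans(toy_table)
        single_genome_genes = set()
        for og in toy_table:
            present = [g for g, genes in og.members.items() if genes]
            if len(present) == 1:
                single_genome_genes.update(og.all_genes())
        reported = set()
        by_id = {og.og_id: og for og in toy_table}
        for ogs in rep.orphan_orthogroups.values():
            for i in ogs:
                reported.update(by_id[i].all_genes())
        for genes in rep.orphan_single_genes.values():
            reported.update(genes)
        assert reported == single_genome_genes


class TestNumericRepresentation:
    def test_codes_follow_orf_order(self, toy_table):
        ng = numeric_representation("gA", ["a1", "unknown", "a2"], toy_table)
        assert ng.codes == [0, -1, 1]

    def test_identical_genomes_identical_codes(self):
        rows = [Orthogroup(i, {"g1": [f"x{i}"], "g2": [f"y{i}"]}) for i in range(5)]
        table = OrthogroupTable(["g1", "g2"], rows)
        c1 = numeric_representation("g1", [f"x{i}" for i in range(5)], table).codes
        c2 = numeric_representation("g2", [f"y{i}" for i in range(5)], table).codes
        assert c1 == c2 == list(range(5))

    @pytest.mark.parametrize("kind", ["inversions", "translocations"])
    def test_rearrangements_move_exactly_the_logged_block(self, kind):
        genomes, truth = simulate_pangenome(
            n_genomes=4,
            n_core_families=25,
            n_accessory_families=0,
            mutation_rate=0.0,
            duplication_prob=0.0,
            n_orphans_per_genome=0,
            rearrangement_spec={kind: 1},
            seed=31,
        )
        table = infer_orthogroups(to_protein_sets(genomes))
        (event,) = truth.events
        g = event.genome
        pre = numeric_representation(g, truth.pre_rearrangement_order[g], table).codes
        post = numeric_representation(g, truth.order[g], table).codes
        assert post == apply_event(pre, event)
        assert post != pre  # the edit is visible


class TestOgSizeHistogram:
    def test_core_only(self):
        rows = [Orthogroup(i, {"g1": [f"a{i}"], "g2": [f"b{i}"], "g3": [f"c{i}"]}) for i in range(5)]
        hist = og_size_histogram(OrthogroupTable(["g1", "g2", "g3"], rows))
        assert hist == {3: 5}

    def test_counts_sum_to_og_count(self, toy_table):
        hist = og_size_histogram(toy_table)
        assert sum(hist.values()) == len(toy_table)
        # size counts genomes, not genes: the paralog pair in gC counts as size 1
        assert hist[1] == 2


class TestConsensus:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            (["MA-", "MA-", "MAC"], "MA"),  # 3rd column 2/3 gaps -> dropped
            (["M-KL"], "MKL"),  # single row minus gaps
            (["AAC", "AAC", "CCA"], "AAC"),
            (["AB", "BA"], "AA"),  # ties go alphabetically
        ],
    )
    def test_rules(self, rows, expected):
        assert consensus_sequence(rows) == expected

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            consensus_sequence([])


class TestOrthoXml:
    def test_round_trip_membership(self, toy_table):
        doc = write_orthoxml(toy_table)
        membership = parse_orthoxml_membership(doc)
        assert {int(k): sorted(v) for k, v in membership.items()} == {
            og.og_id: sorted(og.all_genes()) for og in toy_table
        }

    def test_gene_count_conserved(self, toy_table):
        doc = write_orthoxml(toy_table)
        assert doc.count("<gene ") == len(toy_table.all_genes())
        assert doc.count("orthologGroup") // 2 == len(toy_table.rows)
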
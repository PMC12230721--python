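"""Products derived from the orthogroup table.

Phyletic patterns, orphan-gene reports, the numeric genome representation
used for rearrangement detection, orthogroup size histograms, consensus
sequences and OrthoXML export.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import SequenceRecord, parse_fasta, write_fasta
from .orthogroups import OrthogroupTable


def sort_table(
    table: OrthogroupTable, orf_coordinates: Mapping[str, Mapping[str, int]]
) -> OrthogroupTable:
    """Canonical row order: by the first genome's gene coordinates, then the
    second genome's for orthogroups absent from the first, and so on."""
    return table.sort(orf_coordinates)


@dataclass
class PhyleticPattern:
    genome_order: list[str]
    og_order: list[int]
    matrix: np.ndarray  # genomes x OGs, dtype uint8

    def row_string(self, genome: str) -> str:
        i = self.genome_order.index(genome)
        return "".join(map(str, self.matrix[i]))


def phyletic_pattern(table: OrthogroupTable) -> PhyleticPattern:
    """Binary presence/absence matrix: entry (i, j) = 1 iff genome i has at
    least one member in orthogroup j."""
    og_order = [og.og_id for og in table]
    mat = np.zeros((len(table.genome_order), len(table.rows)), dtype=np.uint8)
    for j, og in enumerate(table):
        for i, genome in enumerate(table.genome_order):
            if og.members.get(genome):
                mat[i, j] = 1
    return PhyleticPattern(list(table.genome_order), og_order, mat)


def write_phyletic_fasta(pattern: PhyleticPattern, dest) -> None:
    """Each genome's presence vector as a '0'/'1' string under its name."""
    recs = [
        SequenceRecord(g, g, pattern.row_string(g)) for g in pattern.genome_order
    ]
    write_fasta(recs, dest)


def read_phyletic_fasta(source) -> PhyleticPattern:
    recs = parse_fasta(source)
    mat = np.array([[int(c) for c in r.seq] for r in recs], dtype=np.uint8)
    return PhyleticPattern([r.id for r in recs], list(range(mat.shape[1])), mat)


@dataclass
class OrphanReport:
    """Per-genome orphan classes.

    *Orphan orthogroups* are multi-gene clusters confined to one genome
    (paralog families with no orthologs elsewhere); *orphan single genes*
    have neither orthologs nor paralogs.  The two classes are disjoint and
    together cover exactly the genes of single-genome orthogroups.
    """

    orphan_orthogroups: dict[str, list[int]]
    orphan_single_genes: dict[str, list[str]]

    def counts(self) -> dict[str, dict[str, int]]:
        genomes = set(self.orphan_orthogroups) | set(self.orphan_single_genes)
        return {
            g: {
                "orphan_orthogroups": len(self.orphan_orthogroups.get(g, [])),
                "orphan_single_genes": len(self.orphan_single_genes.get(g, [])),
            }
            for g in sorted(genomes)
        }

    def total_orphan_genes(self, table: OrthogroupTable) -> int:
        by_id = {og.og_id: og for og in table}
        n = sum(len(v) for v in self.orphan_single_genes.values())
        for ogs in self.orphan_orthogroups.values():
            n += sum(by_id[i].size() for i in ogs)
        return n


def find_orphans(table: OrthogroupTable) -> OrphanReport:
    orphan_ogs: dict[str, list[int]] = {g: [] for g in table.genome_order}
    orphan_singles: dict[str, list[str]] = {g: [] for g in table.genome_order}
    for og in table:
        present = [g for g, genes in og.members.items() if genes]
        if len(present) != 1:
            continue
        genome = present[0]
        genes = og.members[genome]
        if len(genes) >= 2:
            orphan_ogs[genome].append(og.og_id)
        else:
            orphan_singles[genome].append(genes[0])
    return OrphanReport(orphan_ogs, orphan_singles)


@dataclass
class NumericGenome:
    name: str
    codes: list[int]


def numeric_representation(
    genome_name: str,
    orf_order: Sequence[str],
    table: OrthogroupTable,
    missing_code: int = -1,
) -> NumericGenome:
    """Replace each ORF id (in genomic-coordinate order) by its orthogroup
    row index, or by -1 for genes excluded upstream of the table.

    Because singleton genes are emitted as table rows, -1 is rare and marks
    genuinely unassigned genes (e.g. dropped during translation).
    """
    gene_to_og = table.gene_to_og()
    codes = [gene_to_og.get(g, missing_code) for g in orf_order]
    return NumericGenome(genome_name, codes)


def write_numeric_representations(numerics: Sequence[NumericGenome], dest) -> None:
    """One whitespace-separated integer row per genome, name first."""
    close = False
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        dest = open(dest, "w")
        close = True
    try:
        for ng in numerics:
            dest.write(ng.name + "\t" + " ".join(map(str, ng.codes)) + "\n")
    finally:
        if close:
            dest.close()


def og_size_histogram(table: OrthogroupTable) -> dict[int, int]:
    """Distribution of orthogroup sizes, size = number of genomes included."""
    hist: dict[int, int] = {}
    for og in table:
        s = og.n_genomes()
        hist[s] = hist.get(s, 0) + 1
    return dict(sorted(hist.items()))


def consensus_sequence(aligned: Sequence[str], max_gap_frac: float = 0.5) -> str:
    """Column-plurality consensus of an aligned protein set.

    Columns where gaps exceed ``max_gap_frac`` are dropped; otherwise the
    most frequent non-gap residue wins, ties going to the alphabetically
    first residue.
    """
    if not aligned:
        raise ValueError("empty alignment")
    length = len(aligned[0])
    if any(len(row) != length for row in aligned):
        raise ValueError("alignment rows differ in length")
    out = []
    n = len(aligned)
    for j in range(length):
        col = [row[j] for row in aligned]
        gaps = col.count("-")
        if gaps / n > max_gap_frac:
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        out.append(min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0])
    return "".join(out)


def write_orthoxml(table: OrthogroupTable, origin: str = "panforge", version: str = "0.1.0") -> str:
    """Serialize the orthogroup structure as OrthoXML 0.3.

    Each genome becomes a species element whose genes carry integer ids;
    each orthogroup becomes an orthologGroup of geneRef elements.
    """
    NS = "http://orthoXML.org/2011/"
    ET.register_namespace("", NS)
    root = ET.Element(
        f"{{{NS}}}orthoXML",
        {"version": "0.3", "origin": origin, "originVersion": version},
    )
    gene_int: dict[str, int] = {}
    counter = 1
    for genome in table.genome_order:
        species = ET.SubElement(root, f"{{{NS}}}species", {"name": genome, "NCBITaxId": "0"})
        db = ET.SubElement(species, f"{{{NS}}}database", {"name": origin, "version": version})
        genes_el = ET.SubElement(db, f"{{{NS}}}genes")
        for og in table:
            for gid in og.members.get(genome, []):
                gene_int[gid] = counter
                ET.SubElement(
                    genes_el, f"{{{NS}}}gene", {"id": str(counter), "protId": gid}
                )
                counter += 1
    groups = ET.SubElement(root, f"{{{NS}}}groups")
    for og in table:
        grp = ET.SubElement(groups, f"{{{NS}}}orthologGroup", {"id": str(og.og_id)})
        for gid in og.all_genes():
            ET.SubElement(grp, f"{{{NS}}}geneRef", {"id": str(gene_int[gid])})
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, xml_declaration=True, encoding="utf-8")
    return buf.getvalue().decode()


def parse_orthoxml_membership(doc: str) -> dict[str, list[str]]:
    """Recover orthogroup membership (og id -> protein ids) from OrthoXML."""
    root = ET.fromstring(doc)
    ns = {"o": "http://orthoXML.org/2011/"}
    int_to_prot = {
        g.get("id"): g.get("protId") for g in root.iter("{http://orthoXML.org/2011/}gene")
    }
    out: dict[str, list[str]] = {}
    for grp in root.find("o:groups", ns):
        out[grp.get("id")] = [int_to_prot[ref.get("id")] for ref in grp]
    return out
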
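"""Per-orthogroup alignment, codon-level reverse translation, core-genome
construction and phylogeny utilities.

Production alignment quality comes from an external aligner (MAFFT) driven
through :func:`mafft_adapter`; the built-in :func:`align_protein_og` is a
fixture-grade center-star progressive aligner so the rest of the pipeline is
testable without external binaries.  Likewise the species tree is normally
built by an external maximum-likelihood tool via :func:`tree_adapter`, with a
neighbor-joining fallback on protein p-distances.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .genome_io import SequenceRecord, parse_fasta, translate, write_fasta
from .orthogroups import OrthogroupTable
from .similarity import make_aligner


@dataclass
class MSA:
    """A multiple sequence alignment: ordered (name, aligned string) rows."""

    rows: list[tuple[str, str]]
    alphabet: str = "protein"  # "protein" | "codon"

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"MSA rows differ in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def degapped(self, name: str) -> str:
        for n, s in self.rows:
            if n == name:
                return s.replace("-", "")
        raise KeyError(name)

    def as_dict(self) -> dict[str, str]:
        return dict(self.rows)


def _global_aligner():
    a = make_aligner()
    a.mode = "global"
    a.open_end_gap_score = -1.0  # cheap terminal gaps, as in most MSA tools
    a.extend_end_gap_score = -0.5
    return a


def align_protein_og(sequences: Mapping[str, str]) -> MSA:
    """Fixture-grade center-star progressive alignment.

    The longest sequence (ties: lexicographically smallest name) is the
    center; every other sequence is aligned to it globally, and the pairwise
    alignments are merged on center coordinates.  Guaranteed invariant:
    removing gaps from any row reproduces its input sequence exactly.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    items = list(sequences.items())
    if len(items) == 1:
        name, seq = items[0]
        return MSA([(name, seq)])
    center_name = min(items, key=lambda kv: (-len(kv[1]), kv[0]))[0]
    center = sequences[center_name]
    aligner = _global_aligner()

    # per row: inserted chars before each center position, + aligned char per position
    others = [(n, s) for n, s in items if n != center_name]
    parsed = []
    for name, seq in others:
        aln = aligner.align(center, seq)[0]
        c_aln, s_aln = str(aln[0]), str(aln[1])
        ins: list[list[str]] = [[] for _ in range(len(center) + 1)]
        match: list[str] = []
        ci = 0
        for cc, sc in zip(c_aln, s_aln):
            if cc == "-":
                ins[ci].append(sc)
            else:
                match.append(sc)
                ci += 1
        parsed.append((name, ins, match))

    master_ins = [0] * (len(center) + 1)
    for _, ins, _ in parsed:
        for i, chunk in enumerate(ins):
            master_ins[i] = max(master_ins[i], len(chunk))

    def build(ins, match):
        out = []
        for i in range(len(center)):
            chunk = ins[i]
            out.append("".join(chunk) + "-" * (master_ins[i] - len(chunk)))
            out.append(match[i])
        chunk = ins[len(center)]
        out.append("".join(chunk) + "-" * (master_ins[len(center)] - len(chunk)))
        return "".join(out)

    center_row = build([[] for _ in range(len(center) + 1)], list(center))
    rows = []
    by_name = {name: build(ins, match) for name, ins, match in parsed}
    for name, _ in items:
        rows.append((name, center_row if name == center_name else by_name[name]))
    return MSA(rows)


def mafft_adapter(sequences: Mapping[str, str], binary: str = "mafft") -> MSA:
    """Align with MAFFT (``--auto``); raises if the binary is unavailable."""
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"{binary!r} not found on PATH; use the built-in align_protein_og fallback"
        )
    with tempfile.TemporaryDirectory() as tmp:
        inp = os.path.join(tmp, "in.faa")
        write_fasta([SequenceRecord(n, n, s) for n, s in sequences.items()], inp)
        proc = subprocess.run(
            [binary, "--auto", "--quiet", "--anysymbol", inp],
            capture_output=True,
            text=True,
            check=True,
        )
    recs = parse_fasta(proc.stdout)
    return MSA([(r.id, r.seq) for r in recs])


class ReverseTranslationError(ValueError):
    pass


def reverse_translate(msa: MSA, dna: Mapping[str, str]) -> MSA:
    """Map a protein alignment back onto codons.

    Each residue is replaced by its source codon, each gap by ``---``; a
    trailing stop codon in the DNA is tolerated and dropped.  The DNA must
    translate exactly to the degapped protein row.
    """
    rows = []
    for name, arow in msa.rows:
        if name not in dna:
            raise ReverseTranslationError(f"no DNA supplied for {name!r}")
        d = dna[name].upper()
        prot = translate(d, name)
        degapped = arow.replace("-", "")
        if prot != degapped:
            pos = next(
                (i for i, (x, y) in enumerate(zip(prot, degapped)) if x != y),
                min(len(prot), len(degapped)),
            )
            raise ReverseTranslationError(
                f"{name!r}: translated DNA disagrees with aligned row at residue {pos}"
            )
        codons = [d[3 * i : 3 * i + 3] for i in range(len(prot))]
        out = []
        ci = 0
        for c in arow:
            if c == "-":
                out.append("---")
            else:
                out.append(codons[ci])
                ci += 1
        rows.append((name, "".join(out)))
    return MSA(rows, alphabet="codon")


@dataclass
class CoreSet:
    """Orthogroups present in at least ``threshold_pct`` of genomes, with one
    representative gene chosen per (orthogroup, genome)."""

    threshold_pct: float
    og_ids: list[int]
    representative: dict[tuple[int, str], str]


def select_core(
    table: OrthogroupTable, threshold_pct: float = 100.0, seed: int = 0
) -> CoreSet:
    """Select core orthogroups and draw one representative per genome cell.

    An orthogroup qualifies iff the percentage of genomes with at least one
    member reaches ``threshold_pct`` (default 100: a member from every
    genome).  Multi-member cells (recent paralogs) contribute one uniformly
    drawn representative under ``seed``.
    """
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError("threshold_pct must be in (0, 100]")
    rng = np.random.default_rng(seed)
    n = len(table.genome_order)
    og_ids: list[int] = []
    reps: dict[tuple[int, str], str] = {}
    for og in table:
        frac = 100.0 * og.n_genomes() / n
        if frac + 1e-12 < threshold_pct:
            continue
        og_ids.append(og.og_id)
        for genome in table.genome_order:
            genes = og.members.get(genome) or []
            if genes:
                reps[(og.og_id, genome)] = (
                    genes[0] if len(genes) == 1 else genes[int(rng.integers(len(genes)))]
                )
    if not og_ids:
        raise ValueError(
            f"no core orthogroups at threshold {threshold_pct}%; reduce the threshold"
        )
    return CoreSet(threshold_pct, og_ids, reps)


def concatenate_core(
    core: CoreSet,
    protein_msas: Mapping[int, Mapping[str, str]],
    codon_msas: Mapping[int, Mapping[str, str]],
    genome_order: Sequence[str],
) -> tuple[MSA, MSA, list[int]]:
    """Concatenate per-orthogroup alignments into supermatrices.

    ``protein_msas``/``codon_msas`` map og id -> genome -> aligned row (over
    representatives).  Genomes missing from an orthogroup (sub-100%
    thresholds) are padded with all-gap blocks.  Returns (core proteome MSA,
    core genome MSA, manifest of og ids in block order); the core genome is
    exactly three times the proteome length.
    """
    prot_rows = {g: [] for g in genome_order}
    codon_rows = {g: [] for g in genome_order}
    manifest = []
    for og_id in core.og_ids:
        pm = protein_msas[og_id]
        cm = codon_msas[og_id]
        plen = len(next(iter(pm.values())))
        clen = len(next(iter(cm.values())))
        if clen != 3 * plen:
            raise ValueError(f"OG {og_id}: codon alignment is not 3x the protein alignment")
        manifest.append(og_id)
        for g in genome_order:
            prot_rows[g].append(pm.get(g, "-" * plen))
            codon_rows[g].append(cm.get(g, "-" * clen))
    proteome = MSA([(g, "".join(prot_rows[g])) for g in genome_order])
    genome = MSA([(g, "".join(codon_rows[g])) for g in genome_order], alphabet="codon")
    return proteome, genome, manifest


def sample_core_for_tree(
    core_og_ids: Sequence[int], limit: int = 1000, seed: int = 0
) -> list[int]:
    """Uniform sample without replacement when the core exceeds ``limit``."""
    ids = list(core_og_ids)
    if len(ids) <= limit:
        return ids
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=limit, replace=False)
    return [ids[i] for i in sorted(picked)]


# ---------------------------------------------------------------------------
# trees


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    t = tree.clone(depth=1)
    if all((e.length or 0) == 0 for e in t.edges()):
        t.reroot_at_node(t.seed_node, update_bipartitions=False)
        return t
    t.reroot_at_midpoint(update_bipartitions=True)
    return t


def outgroup_root(tree: dendropy.Tree, genome_name: str) -> dendropy.Tree:
    """Root on the branch subtending the named leaf."""
    t = tree.clone(depth=1)
    node = t.find_node_with_taxon_label(genome_name)
    if node is None:
        names = sorted(l.taxon.label for l in t.leaf_node_iter())
        raise ValueError(f"unknown outgroup {genome_name!r}; leaves: {names}")
    length = node.edge.length or 0.0
    t.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0, update_bipartitions=True)
    return t


def protein_p_distance(msa: MSA) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distance (fraction of differing residues over shared
    gap-free columns) between MSA rows."""
    names = [n for n, _ in msa.rows]
    seqs = [np.frombuffer(s.encode(), dtype="S1") for _, s in msa.rows]
    n = len(names)
    d = np.zeros((n, n))
    gap = np.array([b"-"], dtype="S1")
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            total = int(ok.sum())
            if total == 0:
                dist = 0.0
            else:
                dist = float((seqs[i][ok] != seqs[j][ok]).sum()) / total
            d[i, j] = d[j, i] = dist
    return names, d


def nj_tree(msa: MSA) -> dendropy.Tree:
    """Neighbor-joining tree on protein p-distances (fixture-grade fallback)."""
    names, d = protein_p_distance(msa)
    import csv
    import io as _io

    buf = _io.StringIO()
    w = csv.writer(buf)
    w.writerow([""] + names)
    for i, name in enumerate(names):
        w.writerow([name] + [f"{x:.10f}" for x in d[i]])
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for e in tree.edges():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return tree


def tree_adapter(
    proteome: MSA,
    binary: str | None = None,
    model_args: Sequence[str] = (),
) -> dendropy.Tree:
    """Build the species tree from the concatenated core proteome.

    Uses an external tree program when available (``binary`` defaults to
    ``fasttree`` if found on PATH; any program reading aligned FASTA on a
    file argument and printing Newick on stdout works — pass model flags via
    ``model_args``).  Falls back to built-in neighbor joining otherwise.
    """
    if binary is None:
        binary = shutil.which("fasttree") or shutil.which("FastTree")
    if binary is None:
        return nj_tree(proteome)
    with tempfile.TemporaryDirectory() as tmp:
        inp = os.path.join(tmp, "core_proteome.faa")
        write_fasta([SequenceRecord(n, n, s) for n, s in proteome.rows], inp)
        cmd = [binary, *model_args, inp]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"tree program failed ({' '.join(cmd)}):\n{proc.stderr[-2000:]}"
            )
    return parse_newick(proc.stdout)


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as the smaller side's label sets)."""
    t = tree.clone(depth=1)
    t.encode_bipartitions()
    all_leaves = frozenset(l.taxon.label for l in t.leaf_node_iter())
    out = set()
    for edge in t.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        side = frozenset(
            l.taxon.label for l in edge.head_node.leaf_iter()
        )
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, all_leaves - side, key=lambda s: (len(s), sorted(s))))
    return out
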
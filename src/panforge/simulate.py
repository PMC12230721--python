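"""Synthetic pan-genome generator with full ground truth.

The generator emulates the signal structure a comparative bacterial-genomics
pipeline consumes: a set of genomes sharing core gene families, accessory
families present in a random subset of genomes, genome-unique orphan genes,
recent tandem duplications, point mutations accumulated independently per
genome, gene-order rearrangements (inversions, translocations, insertions of
novel genes) and a tunable genome-wide codon-usage skew.  Every emitted gene
carries ground truth (its true family, genome and coordinate rank) and every
rearrangement is logged, so downstream inferences can be scored exactly.

What it does **not** emulate: intergenic sequence, pseudogenes, lateral gene
transfer, domain-level shuffling, GC-content gradients, or realistic codon
usage beyond a single preferred-codon skew — conclusions from these fixtures
concern algorithmic correctness, not biological performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .codon_bias import SYNONYMOUS_FAMILIES
from .genome_io import Genome, SequenceRecord, translate

_AAS = sorted(SYNONYMOUS_FAMILIES)  # 20 amino acids, stable order


@dataclass
class RearrangementEvent:
    """One logged gene-order edit, 0-based on the pre-event gene order.

    ``kind``: "inversion" (block [start, end) reversed in place),
    "translocation" (block [start, end) excised and re-inserted so that it
    starts at ``dest`` in the post-excision list), or "insertion" (``genes``
    novel gene ids inserted at ``start``).
    """

    kind: str
    genome: str
    start: int
    end: int
    dest: int | None = None
    genes: tuple[str, ...] = ()


@dataclass
class PanGenomeTruth:
    family_of: dict[str, str]  # gene id -> true family id
    genome_of: dict[str, str]
    order: dict[str, list[str]]  # genome -> final gene order (file order)
    pre_rearrangement_order: dict[str, list[str]]
    events: list[RearrangementEvent]
    codon_skew_strength: float
    preferred_codons: dict[str, str] = field(default_factory=dict)  # aa -> codon

    def labels_for(self, genes: Sequence[str]) -> list[str]:
        return [self.family_of[g] for g in genes]


def apply_event(order: list, event: RearrangementEvent) -> list:
    """Apply a logged rearrangement to a gene-order (or code) list."""
    out = list(order)
    if event.kind == "inversion":
        out[event.start : event.end] = reversed(out[event.start : event.end])
    elif event.kind == "translocation":
        block = out[event.start : event.end]
        del out[event.start : event.end]
        out[event.dest : event.dest] = block
    elif event.kind == "insertion":
        out[event.start : event.start] = list(event.genes)
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return out


class _CodonSampler:
    """Skewed synonymous-codon choice: within each family the preferred codon
    has sampling weight 1, the others weight (1 - skew)."""

    def __init__(self, skew: float, rng: np.random.Generator):
        if not (0.0 <= skew <= 1.0):
            raise ValueError("codon_skew_strength must be in [0, 1]")
        self.skew = skew
        self.preferred = {
            aa: fam[int(rng.integers(len(fam)))] for aa, fam in SYNONYMOUS_FAMILIES.items()
        }

    def codon(self, aa: str, rng: np.random.Generator) -> str:
        fam = SYNONYMOUS_FAMILIES[aa]
        if len(fam) == 1:
            return fam[0]
        weights = np.array(
            [1.0 if c == self.preferred[aa] else max(1.0 - self.skew, 1e-9) for c in fam]
        )
        weights /= weights.sum()
        return fam[int(rng.choice(len(fam), p=weights))]


def _random_gene(n_codons: int, sampler: _CodonSampler, rng: np.random.Generator) -> str:
    aas = [_AAS[int(i)] for i in rng.integers(0, len(_AAS), n_codons)]
    body = "".join(sampler.codon(aa, rng) for aa in aas)
    return "ATG" + body + "TAA"


def _mutate(
    dna: str, rate: float, sampler: _CodonSampler, rng: np.random.Generator
) -> str:
    """Per-codon substitution process preserving the reading frame.

    Each body codon mutates with probability ``1 - (1-rate)^3`` (three sites
    at per-site rate ``rate``); half of the events are synonymous re-draws
    from the skewed codon distribution, half replace the amino acid — a
    crude but adequate stand-in for selection on protein sequence.
    """
    if rate == 0.0:
        return dna
    codons = [dna[i : i + 3] for i in range(3, len(dna) - 3, 3)]
    p_codon = 1.0 - (1.0 - rate) ** 3
    hit = rng.random(len(codons)) < p_codon
    syn = rng.random(len(codons)) < 0.5
    for i in np.nonzero(hit)[0]:
        aa = translate(codons[i])
        if not aa or aa == "*":
            continue
        if syn[i]:
            codons[i] = sampler.codon(aa, rng)
        else:
            others = [x for x in _AAS if x != aa]
            codons[i] = sampler.codon(others[int(rng.integers(len(others)))], rng)
    return dna[:3] + "".join(codons) + dna[-3:]


def simulate_pangenome(
    n_genomes: int = 10,
    n_core_families: int = 50,
    n_accessory_families: int = 20,
    accessory_presence_prob: float = 0.5,
    duplication_prob: float = 0.05,
    mutation_rate: float = 0.05,
    n_orphans_per_genome: int = 3,
    rearrangement_spec: Mapping[str, int] | None = None,
    codon_skew_strength: float = 0.7,
    seed: int = 0,
    gene_len_codons: tuple[int, int] = (80, 160),
) -> tuple[list[Genome], PanGenomeTruth]:
    """Simulate DNA-ORF genomes plus complete ground truth.

    ``rearrangement_spec`` maps event kinds ("inversions", "translocations",
    "insertions") to counts; each event targets a distinct genome so that a
    genome's final order differs from its logged pre-rearrangement order by
    exactly one logged edit.  Duplicated genes accumulate extra divergence at
    half the genome-level mutation rate (a duplication that postdates the
    genome's separation), so at ``mutation_rate=0`` all copies of a family
    are exactly identical.  Deterministic under ``seed``.
    """
    for name, value in [
        ("accessory_presence_prob", accessory_presence_prob),
        ("duplication_prob", duplication_prob),
        ("mutation_rate", mutation_rate),
    ]:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    rng = np.random.default_rng(seed)
    sampler = _CodonSampler(codon_skew_strength, rng)
    genome_names = [f"G{i:02d}" for i in range(n_genomes)]

    families: dict[str, str] = {}
    n_fam = n_core_families + n_accessory_families
    lengths = rng.integers(gene_len_codons[0], gene_len_codons[1] + 1, n_fam)
    for fi in range(n_fam):
        families[f"F{fi:03d}"] = _random_gene(int(lengths[fi]), sampler, rng)
    core_ids = [f"F{fi:03d}" for fi in range(n_core_families)]
    acc_ids = [f"F{fi:03d}" for fi in range(n_core_families, n_fam)]

    family_of: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    pre_order: dict[str, list[str]] = {}
    seqs: dict[str, str] = {}

    for g in genome_names:
        order: list[str] = []
        counter = 0

        def emit(seq: str, family: str) -> str:
            nonlocal counter
            gid = f"{g}|g{counter:04d}"
            counter += 1
            seqs[gid] = seq
            family_of[gid] = family
            genome_of[gid] = g
            order.append(gid)
            return gid

        present = list(core_ids) + [
            f for f in acc_ids if rng.random() < accessory_presence_prob
        ]
        for fam in present:
            copy = _mutate(families[fam], mutation_rate, sampler, rng)
            emit(copy, fam)
            if rng.random() < duplication_prob:
                dup = _mutate(copy, mutation_rate / 2.0, sampler, rng)
                emit(dup, fam)  # tandem: placed right after its source
        for oi in range(n_orphans_per_genome):
            orphan = _random_gene(int(rng.integers(*gene_len_codons)), sampler, rng)
            emit(orphan, f"orphan:{g}:{oi}")
        pre_order[g] = order

    # rearrangements: one event per (distinct) genome
    spec = dict(rearrangement_spec or {})
    kinds = (
        ["inversion"] * spec.get("inversions", 0)
        + ["translocation"] * spec.get("translocations", 0)
        + ["insertion"] * spec.get("insertions", 0)
    )
    if len(kinds) > n_genomes:
        raise ValueError("more rearrangement events than genomes (one event per genome)")
    targets = [genome_names[int(i)] for i in rng.choice(n_genomes, len(kinds), replace=False)]
    events: list[RearrangementEvent] = []
    final_order = {g: list(o) for g, o in pre_order.items()}
    for kind, g in zip(kinds, targets):
        n = len(final_order[g])
        if kind == "insertion":
            novel = []
            for k in range(3):
                gid = f"{g}|ins{k:02d}"
                seqs[gid] = _random_gene(int(rng.integers(*gene_len_codons)), sampler, rng)
                family_of[gid] = f"inserted:{g}:{k}"
                genome_of[gid] = g
                novel.append(gid)
            ev = RearrangementEvent(kind, g, int(rng.integers(0, n + 1)), 0, genes=tuple(novel))
        else:
            span = int(rng.integers(3, max(4, n // 3)))
            start = int(rng.integers(0, n - span))
            if kind == "inversion":
                ev = RearrangementEvent(kind, g, start, start + span)
            else:
                # destination must differ from the source slot, else the
                # "translocation" would be a logged no-op
                dest = start
                while dest == start:
                    dest = int(rng.integers(0, n - span))
                ev = RearrangementEvent(kind, g, start, start + span, dest=dest)
        final_order[g] = apply_event(final_order[g], ev)
        events.append(ev)

    genomes = [
        Genome(
            name=g,
            records=[SequenceRecord(gid, gid, seqs[gid]) for gid in final_order[g]],
            kind="orf_set",
        )
        for g in genome_names
    ]
    truth = PanGenomeTruth(
        family_of=family_of,
        genome_of=genome_of,
        order=final_order,
        pre_rearrangement_order=pre_order,
        events=events,
        codon_skew_strength=codon_skew_strength,
        preferred_codons=dict(sampler.preferred),
    )
    return genomes, truth


def to_protein_sets(genomes: list[Genome]) -> dict[str, dict[str, str]]:
    """Translate DNA-ORF genomes into the mapping orthogroup inference eats."""
    return {
        g.name: {r.id: translate(r.seq, r.id) for r in g.records} for g in genomes
    }


def heg_panel(truth_families: Mapping[str, str], n: int = 40) -> list[SequenceRecord]:
    """Synthetic highly-expressed-gene panel: the translated ancestors of the
    first ``n`` families, usable as the query panel for the HEG screen on
    genomes simulated from those same ancestors."""
    recs = []
    for fam_id in sorted(truth_families)[:n]:
        prot = translate(truth_families[fam_id], fam_id)
        recs.append(SequenceRecord(f"HEG_{fam_id}", f"HEG_{fam_id} synthetic panel", prot))
    return recs


def mock_profile_hits(
    genome: Genome,
    panel_size: int = 148,
    hit_fraction: float = 0.9,
    seed: int = 0,
):
    """Synthetic single-copy-ortholog profile hits for completeness tests.

    A deterministic stand-in for a profile search: ``hit_fraction`` of the
    panel's profiles get one significant hit (E-value 1e-6) against a random
    ORF of the genome, the rest either miss entirely or hit insignificantly.
    """
    from .annotation_qc import ProfileHit

    rng = np.random.default_rng(seed)
    n_hit = int(round(hit_fraction * panel_size))
    chosen = set(rng.choice(panel_size, n_hit, replace=False).tolist())
    hits = []
    orf_ids = [r.id for r in genome.records]
    for p in range(panel_size):
        orf = orf_ids[int(rng.integers(len(orf_ids)))]
        if p in chosen:
            hits.append(ProfileHit(f"P{p:03d}", orf, score=150.0, evalue=1e-6))
        elif rng.random() < 0.3:
            hits.append(ProfileHit(f"P{p:03d}", orf, score=8.0, evalue=0.5))
    return hits


def mock_ani_pairs(
    genome_names: Sequence[str], seed: int = 0, low: float = 82.0, high: float = 99.5
) -> list[tuple[str, str, float]]:
    """Synthetic directed ANI estimates for matrix-assembly fixtures."""
    rng = np.random.default_rng(seed)
    out = []
    for i, ga in enumerate(genome_names):
        for gb in genome_names[i + 1 :]:
            base = float(rng.uniform(low, high))
            out.append((ga, gb, base))
            out.append((gb, ga, min(100.0, base + float(rng.normal(0, 0.2)))))
    return out
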
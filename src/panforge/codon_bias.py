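"""Codon-bias analysis: HEG screening, W vectors and the codon adaptation index.

Codon bias — the unequal usage of synonymous codons — is strongest in highly
expressed genes (HEGs), where selection for translational efficiency favors
codons matching the abundant tRNAs.  Following Sharp & Li's CAI framework,
each genome's HEG homologs define a *W vector* of relative adaptiveness: a
codon's count in the HEG pool divided by the count of the commonest codon of
its synonymous family (so the preferred codon of every family has W = 1).
The CAI of a gene is then the geometric mean of W over its codons, excluding
stops and the single-codon families (ATG/Met, TGG/Trp); genes written purely
in preferred codons score exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .genome_io import TABLE11, Genome, SequenceRecord, translate
from .orthogroups import OrthogroupTable
from .similarity import local_align, make_aligner, to_bit_score, to_evalue

#: Sense codons of translation table 11, grouped into synonymous families.
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(TABLE11.forward_table.items()):
    if set(_codon) <= set("ACGT"):
        SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)

SENSE_CODONS: list[str] = sorted(c for fam in SYNONYMOUS_FAMILIES.values() for c in fam)
SINGLE_CODON_FAMILIES: frozenset[str] = frozenset(
    fam[0] for fam in SYNONYMOUS_FAMILIES.values() if len(fam) == 1
)  # {"ATG", "TGG"} under table 11


@dataclass
class WVector:
    genome: str
    w: dict[str, float]  # sense codon -> relative adaptiveness in (0, 1]


def codon_counts(dnas: Iterable[str]) -> dict[str, int]:
    """Pooled sense-codon counts over in-frame DNA sequences."""
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for dna in dnas:
        dna = dna.upper()
        for i in range(0, len(dna) - len(dna) % 3, 3):
            codon = dna[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    return counts


def compute_w(heg_orf_dnas: list[str], genome: str = "") -> WVector:
    """W vector of codon relative adaptiveness from a genome's HEG ORFs.

    Within each synonymous family, w(c) = count(c) / max family count.
    Codons never observed in the HEG pool get the conventional pseudo-value
    0.5 / max count (avoids zero factors in the CAI's geometric mean).  A
    family with no observations at all is uninformative and scores 1 for
    every member.
    """
    if not heg_orf_dnas:
        raise ValueError("at least one HEG ORF is required to compute W")
    counts = codon_counts(heg_orf_dnas)
    w: dict[str, float] = {}
    for fam in SYNONYMOUS_FAMILIES.values():
        mx = max(counts[c] for c in fam)
        if mx == 0:
            for c in fam:
                w[c] = 1.0
            continue
        for c in fam:
            w[c] = counts[c] / mx if counts[c] > 0 else 0.5 / mx
    return WVector(genome=genome, w=w)


def cai(gene_dna: str, wvec: WVector) -> float:
    """Codon adaptation index: geometric mean of W over the gene's codons.

    Stop codons and the single-codon families (ATG, TGG) are excluded from
    the mean, as they carry no synonymous choice.
    """
    dna = gene_dna.upper()
    if len(dna) % 3:
        raise ValueError("gene length must be divisible by 3")
    log_sum = 0.0
    n = 0
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if codon in SINGLE_CODON_FAMILIES or codon not in wvec.w:
            continue  # stops, Met/Trp, ambiguous codons
        log_sum += math.log(wvec.w[codon])
        n += 1
    if n == 0:
        raise ValueError("gene contains no codons countable for CAI")
    return math.exp(log_sum / n)


@dataclass
class CaiAnnotation:
    gene_cai: dict[str, float]
    og_mean_cai: dict[int, float]


def annotate_og_cai(
    table: OrthogroupTable, gene_cai: Mapping[str, float]
) -> CaiAnnotation:
    """Arithmetic mean CAI per orthogroup over its member genes.

    Each gene's CAI must have been computed under its own genome's W vector.
    Genes without a CAI (e.g. from genomes where no HEGs were found) are
    skipped; an orthogroup with no scored member gets no mean.
    """
    og_mean: dict[int, float] = {}
    for og in table:
        vals = [gene_cai[g] for g in og.all_genes() if g in gene_cai]
        if vals:
            og_mean[og.og_id] = sum(vals) / len(vals)
    return CaiAnnotation(dict(gene_cai), og_mean)


def find_heg_homologs(
    orf_dna: Genome,
    heg_proteins: list[SequenceRecord],
    evalue_max: float = 1e-10,
    min_coverage_pct: float = 70.0,
) -> dict[str, str]:
    """Built-in HEG screen: each HEG protein vs all translated ORFs.

    Desk-scale stand-in for a translated search tool: every HEG query is
    locally aligned against every translated ORF; the best hit per HEG is
    kept if it passes the E-value (Karlin-Altschul, ungapped constants, on a
    query x database-size search space) and HEG-side coverage gates.
    Returns HEG id -> best ORF id.  Raises when no HEG passes — a W vector
    cannot be computed without HEG signal.
    """
    aligner = make_aligner()
    translated = {}
    for rec in orf_dna.records:
        try:
            prot = translate(rec.seq, rec.id)
        except ValueError:
            continue
        if prot:
            translated[rec.id] = prot
    db_len = sum(len(p) for p in translated.values())
    out: dict[str, str] = {}
    for heg in heg_proteins:
        best: tuple[float, str] | None = None
        for orf_id, prot in translated.items():
            raw = aligner.score(heg.seq, prot)  # cheap prescreen before traceback
            if raw <= 0 or to_evalue(to_bit_score(raw), len(heg.seq), db_len) > evalue_max:
                continue
            score, _, cov, _ = local_align(heg.seq, prot, aligner)
            if cov < min_coverage_pct:
                continue
            bits = to_bit_score(score)
            if best is None or (bits, _neg(orf_id)) > (best[0], _neg(best[1])):
                best = (bits, orf_id)
        if best is not None:
            out[heg.id] = best[1]
    if not out:
        raise ValueError(
            f"genome {orf_dna.name!r}: insufficient HEG signal for W computation"
        )
    return out


class _neg(str):
    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def genome_w_vector(
    orf_dna: Genome,
    heg_proteins: list[SequenceRecord],
    evalue_max: float = 1e-10,
    min_coverage_pct: float = 70.0,
) -> WVector:
    """Screen a genome for HEG homologs and compute its W vector.

    An ORF hit by several HEG queries enters the codon pool once.
    """
    hits = find_heg_homologs(orf_dna, heg_proteins, evalue_max, min_coverage_pct)
    orf_ids = sorted(set(hits.values()))
    by_id = {r.id: r.seq for r in orf_dna.records}
    return compute_w([by_id[i] for i in orf_ids], genome=orf_dna.name)


def w_vectors_to_dataframe(vectors: list[WVector]):
    import pandas as pd

    return pd.DataFrame(
        [[v.w[c] for c in SENSE_CODONS] for v in vectors],
        index=[v.genome for v in vectors],
        columns=SENSE_CODONS,
    )
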
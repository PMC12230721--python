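"""Protein-protein similarity: exact local alignment, bit scores, hit tables.

The built-in engine is an exact Smith-Waterman search (Biopython's C
implementation) intended for desk-scale datasets — up to a few thousand
short proteins.  Production-scale searches come from an external tool whose
tabular output is ingested through :func:`parse_external_hits`; both routes
produce the same :class:`HitTable` contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

#: Default homolog-detection thresholds (percent identity, percent coverage).
DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 70.0

# Ungapped BLOSUM62 Karlin-Altschul constants (Altschul & Gish 1996).
LAMBDA_UNGAPPED = 0.3176
K_UNGAPPED = 0.134


@dataclass
class SimilarityHit:
    """A directed, scored match from ``query_id`` to ``target_id``."""

    query_id: str
    target_id: str
    bit_score: float
    identity_pct: float
    coverage_pct: float

    def __post_init__(self):
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct out of bounds: {self.identity_pct}")
        if not (0.0 <= self.coverage_pct <= 100.0):
            raise ValueError(f"coverage_pct out of bounds: {self.coverage_pct}")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")


class HitTable:
    """Directed hit store keeping the best hit per ordered (query, target) pair.

    "Best" is maximal bit score, ties broken by higher identity then by
    insertion order stability; re-adding a dominated hit is a no-op.
    """

    def __init__(self):
        self._hits: dict[tuple[str, str], SimilarityHit] = {}

    def add(self, hit: SimilarityHit) -> None:
        key = (hit.query_id, hit.target_id)
        cur = self._hits.get(key)
        if cur is None or (hit.bit_score, hit.identity_pct) > (cur.bit_score, cur.identity_pct):
            self._hits[key] = hit

    def get(self, query_id: str, target_id: str) -> SimilarityHit | None:
        return self._hits.get((query_id, target_id))

    def hits(self) -> list[SimilarityHit]:
        return list(self._hits.values())

    def hits_from(self, query_id: str) -> list[SimilarityHit]:
        return [h for (q, _), h in self._hits.items() if q == query_id]

    def __len__(self):
        return len(self._hits)

    def __iter__(self):
        return iter(self._hits.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._hits

    def subset(self, keep) -> "HitTable":
        out = HitTable()
        for h in self:
            if keep(h):
                out.add(h)
        return out


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def local_align(
    a: str,
    b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, float, float, int]:
    """Optimal local alignment of two proteins.

    Returns ``(raw_score, identity_pct, coverage_pct, aligned_length)`` where
    identity is counted over aligned columns (gap columns included in the
    denominator) and coverage is the fraction of the *query* (``a``) covered
    by the local alignment.  A pair with no positive-scoring alignment gets
    all zeros.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    if aligner is None:
        aligner = make_aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, 0.0, 0.0, 0
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    aligned_len = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_len if aligned_len else 0.0
    qcov_residues = sum(int(e) - int(s) for s, e in alignment.aligned[0])
    coverage = 100.0 * qcov_residues / len(a)
    return float(score), identity, coverage, int(aligned_len)


def to_bit_score(raw_score: float, lam: float = LAMBDA_UNGAPPED, K: float = K_UNGAPPED) -> float:
    """Convert a raw alignment score to bits: ``(lambda*S - ln K) / ln 2``."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return (lam * raw_score - math.log(K)) / math.log(2)


def to_evalue(bit_score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul E-value for a bit score on an m x n search space."""
    return query_len * db_len * 2.0 ** (-bit_score)


def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def all_vs_all(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    min_identity_pct: float = DEFAULT_MIN_IDENTITY,
    min_coverage_pct: float = DEFAULT_MIN_COVERAGE,
    aligner: Align.PairwiseAligner | None = None,
    prefilter_kmer: int | None = 4,
    prefilter_min_shared: int = 3,
) -> HitTable:
    """Exact all-vs-all local-alignment search with threshold filtering.

    Every ordered non-self (query, target) pair is evaluated; hits failing
    either the identity or the coverage threshold are dropped.  With
    ``prefilter_kmer`` set, pairs sharing fewer than ``prefilter_min_shared``
    protein k-mers are skipped without alignment — a cheap screen that, at
    the package's default (k=4, >=3 shared 4-mers), discards essentially all
    unrelated random-protein pairs while keeping full-length homologs down
    to roughly 40% identity.  Pass ``prefilter_kmer=None`` for the exhaustive
    exact mode.
    """
    if aligner is None:
        aligner = make_aligner()
    table = HitTable()
    kq = kt = None
    if prefilter_kmer:
        kq = {qid: _kmer_set(s, prefilter_kmer) for qid, s in queries.items()}
        kt = {tid: _kmer_set(s, prefilter_kmer) for tid, s in targets.items()}
    # symmetric raw score: compute once per unordered pair, emit both directions
    done: set[tuple[str, str]] = set()
    for qid, qseq in queries.items():
        for tid, tseq in targets.items():
            if qid == tid or (tid, qid) in done:
                continue
            done.add((qid, tid))
            if kq is not None:
                shared = kq.get(qid) or _kmer_set(qseq, prefilter_kmer)
                tset = (kt or {}).get(tid) or _kmer_set(tseq, prefilter_kmer)
                if len(shared & tset) < prefilter_min_shared:
                    continue
            score, ident, cov_q, _ = local_align(qseq, tseq, aligner)
            if score <= 0:
                continue
            bits = to_bit_score(score)
            # coverage is measured on the query side of each direction
            if ident >= min_identity_pct and cov_q >= min_coverage_pct:
                table.add(SimilarityHit(qid, tid, bits, ident, cov_q))
            if tid in queries and qid in targets:
                _, _, cov_t, _ = local_align(tseq, qseq, aligner)
                if ident >= min_identity_pct and cov_t >= min_coverage_pct:
                    table.add(SimilarityHit(tid, qid, bits, ident, cov_t))
    return table


def parse_external_hits(
    source: Iterable[str],
    query_lengths: Mapping[str, int],
    min_identity_pct: float = DEFAULT_MIN_IDENTITY,
    min_coverage_pct: float = DEFAULT_MIN_COVERAGE,
) -> HitTable:
    """Ingest 12-column tab-separated search-tool output (outfmt-6 dialect).

    Columns: query, target, %identity, alignment length, mismatches, gap
    opens, qstart, qend, tstart, tend, evalue, bit score.  Query coverage is
    derived as ``(qend - qstart + 1) / query length`` from the supplied
    lengths map.  The same threshold contract as :func:`all_vs_all` applies;
    self-hits are dropped.
    """
    table = HitTable()
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}")
        try:
            qid, tid = fields[0], fields[1]
            ident = float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            bits = float(fields[11])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
        if qid == tid:
            continue
        if qid not in query_lengths:
            raise ValueError(f"line {lineno}: unknown query {qid!r} (no length supplied)")
        cov = 100.0 * (abs(qend - qstart) + 1) / query_lengths[qid]
        cov = min(cov, 100.0)
        if ident >= min_identity_pct and cov >= min_coverage_pct:
            table.add(SimilarityHit(qid, tid, bits, ident, cov))
    return table
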
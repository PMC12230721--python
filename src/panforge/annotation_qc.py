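"""Completeness scoring, KO assignment and ANI-matrix assembly.

The heavy lifting (profile HMM searches, whole-genome ANI estimation) is done
by external tools; this module owns the statistics layered on their tabular
output: the completeness fraction over a universal single-copy-ortholog
profile panel, threshold-filtered KEGG Orthology assignment of orthogroup
consensus sequences, and the symmetrized ANI matrix with missing-value
semantics and closest-relative extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Size of the core-bacterial single-copy-ortholog profile panel.
DEFAULT_PANEL_SIZE = 148
#: Default significance gate for completeness hits.
DEFAULT_COMPLETENESS_EVALUE = 0.01


@dataclass
class ProfileHit:
    profile_id: str
    sequence_id: str
    score: float
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def parse_hmmer_tblout(source: Iterable[str]) -> list[ProfileHit]:
    """Parse HMMER3 ``--tblout``-style rows into profile hits.

    Whitespace-delimited columns: target name, target accession, query name,
    query accession, full-sequence E-value, full-sequence score, ...  The
    query (the profile) becomes ``profile_id`` and the target the sequence.
    """
    hits = []
    for lineno, line in enumerate(source, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"line {lineno}: expected >=6 whitespace-separated columns")
        try:
            hits.append(
                ProfileHit(
                    profile_id=fields[2],
                    sequence_id=fields[0],
                    evalue=float(fields[4]),
                    score=float(fields[5]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
    return hits


def completeness(
    hits: Sequence[ProfileHit],
    n_profiles: int = DEFAULT_PANEL_SIZE,
    evalue_max: float = DEFAULT_COMPLETENESS_EVALUE,
) -> float:
    """Fraction of profiles with at least one hit at E-value <= ``evalue_max``.

    The denominator is the full panel size, independent of which profiles
    happened to hit anything.
    """
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    hit_profiles = {h.profile_id for h in hits if h.evalue <= evalue_max}
    return len(hit_profiles) / n_profiles


@dataclass
class KoCatalog:
    """KEGG Orthology profile catalog: KO id -> adaptive score threshold."""

    thresholds: dict[str, float]

    def __post_init__(self):
        for ko, t in self.thresholds.items():
            if not math.isfinite(t):
                raise ValueError(f"non-finite threshold for {ko}")

    @classmethod
    def from_tsv(cls, source: Iterable[str]) -> "KoCatalog":
        thresholds = {}
        for line in source:
            if not line.strip() or line.startswith("#"):
                continue
            ko, t = line.split("\t")[:2]
            thresholds[ko.strip()] = float(t)
        return cls(thresholds)


def assign_ko(
    og_consensus_hits: Mapping[int, Sequence[ProfileHit]],
    catalog: KoCatalog,
    best_only: bool = False,
) -> dict[int, list[tuple[str, float]]]:
    """KO assignment by adaptive-threshold filtering.

    ``og_consensus_hits`` maps orthogroup id -> profile hits of its consensus
    sequence; ``profile_id`` is the KO id.  A KO is assigned iff the hit
    score strictly exceeds that KO's threshold (a hit exactly at threshold is
    rejected).  Passing KOs are returned sorted by descending score;
    ``best_only`` keeps just the top one.
    """
    out: dict[int, list[tuple[str, float]]] = {}
    for og_id, hits in og_consensus_hits.items():
        passing = []
        for h in hits:
            if h.profile_id not in catalog.thresholds:
                raise ValueError(f"hit references unknown profile {h.profile_id!r}")
            if h.score > catalog.thresholds[h.profile_id]:
                passing.append((h.profile_id, h.score))
        passing.sort(key=lambda kv: (-kv[1], kv[0]))
        if best_only and passing:
            passing = passing[:1]
        out[og_id] = passing
    return out


def build_ani_matrix(
    pair_values: Iterable[tuple[str, str, float]],
    genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble a symmetric ANI matrix from directed pair estimates.

    Average nucleotide identity estimators are direction-dependent and
    return nothing for distant pairs, so: both directions present -> mean;
    one direction -> that value; neither -> missing (NaN).  The diagonal is
    forced to 100.  Values outside (0, 100] are rejected.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    names: set[str] = set(genomes or [])
    for ga, gb, ani in pair_values:
        if not (0.0 < ani <= 100.0):
            raise ValueError(f"ANI value out of (0, 100]: {ani} for ({ga}, {gb})")
        names.update((ga, gb))
        if ga != gb:
            acc.setdefault(tuple(sorted((ga, gb))), []).append(float(ani))
    order = sorted(names)
    mat = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    for (ga, gb), vals in acc.items():
        mean = sum(vals) / len(vals)
        mat.loc[ga, gb] = mean
        mat.loc[gb, ga] = mean
    for g in order:
        mat.loc[g, g] = 100.0
    return mat


def ani_is_complete(matrix: pd.DataFrame) -> bool:
    """True iff no entry is missing — the precondition for enhancing the ANI
    heatmap with hierarchical clustering."""
    return not matrix.isna().any().any()


def closest_relatives(matrix: pd.DataFrame) -> dict[str, tuple[str, float] | None]:
    """Per genome, the off-diagonal non-missing maximum.

    Ties go to the lexicographically smallest partner; a genome with no
    usable entry maps to ``None``.
    """
    out: dict[str, tuple[str, float] | None] = {}
    for g in matrix.index:
        row = matrix.loc[g].drop(labels=[g])
        row = row.dropna()
        if row.empty:
            out[g] = None
            continue
        best_val = row.max()
        partner = sorted(row[row == best_val].index)[0]
        out[g] = (partner, float(best_val))
    return out
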
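"""Genome input/output: FASTA parsing, plasmid filtering, translation, ORF utilities.

A *genome* here is one FASTA file — either a full assembly (contigs) or a set
of DNA open reading frames (ORFs).  Record order is preserved everywhere
because downstream gene-order analyses assume that the order of ORFs in a
file follows their genomic coordinates.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio.Data.CodonTable import unambiguous_dna_by_id

log = logging.getLogger(__name__)

#: NCBI translation table 11 (bacterial, archaeal and plant plastid code).
TABLE11 = unambiguous_dna_by_id[11]

_STOPS = frozenset(TABLE11.stop_codons)
_DNA_RE = re.compile(r"^[ACGTURYSWKMBDHVN]*$")


@dataclass
class SequenceRecord:
    """One FASTA entry.

    ``id`` is the first whitespace-delimited token of the header, ``header``
    the full description line, ``seq`` the uppercased sequence with all
    whitespace removed.
    """

    id: str
    header: str
    seq: str


@dataclass
class Genome:
    """An ordered set of records from one input file."""

    name: str
    records: list[SequenceRecord]
    kind: str = "orf_set"  # "assembly" | "orf_set"

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class OrfStats:
    orf_count: int
    gc_percent: float


class FastaFormatError(ValueError):
    pass


def parse_fasta(source: str | os.PathLike | TextIO) -> list[SequenceRecord]:
    """Parse FASTA text into records, preserving order.

    ``source`` may be a path or an open text handle.  Sequence lines are
    concatenated and uppercased; Windows line endings are tolerated.
    Raises :class:`FastaFormatError` on empty input, sequence data before the
    first header, or duplicate record ids.
    """
    if isinstance(source, (str, os.PathLike)) and not (
        isinstance(source, str) and source.lstrip().startswith(">")
    ):
        with open(source) as fh:
            return parse_fasta(fh)
    if isinstance(source, str):
        source = io.StringIO(source)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush():
        assert header is not None
        rid = header.split()[0] if header.split() else ""
        if not rid:
            raise FastaFormatError("record with empty header")
        if rid in seen:
            raise FastaFormatError(f"duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(rid, header, "".join(chunks).upper()))

    for line in source:
        line = line.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise FastaFormatError("sequence data before first '>' header")
            chunks.append("".join(line.split()))
    if header is not None:
        flush()
    if not records:
        raise FastaFormatError("no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: str | os.PathLike | TextIO, width: int = 80) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w") as fh:
            write_fasta(records, fh, width=width)
        return
    for rec in records:
        dest.write(f">{rec.header}\n")
        for i in range(0, len(rec.seq), width):
            dest.write(rec.seq[i : i + width] + "\n")
        if not rec.seq:
            dest.write("\n")


def filter_plasmids(records: list[SequenceRecord], enabled: bool = True) -> list[SequenceRecord]:
    """Drop records whose header mentions "plasmid" (case-insensitive substring).

    With ``enabled=False`` the input list is returned unchanged.  Applied
    uniformly to contigs and ORF records alike.
    """
    if not enabled:
        return records
    kept = [r for r in records if "plasmid" not in r.header.lower()]
    if not kept and records:
        log.warning("plasmid filter removed all %d records", len(records))
    return kept


def load_genome(path: str | os.PathLike, kind: str = "orf_set", drop_plasmids: bool = False) -> Genome:
    """Load one genome file; the genome name is the file basename minus extension."""
    base = os.path.basename(os.fspath(path))
    for ext in (".fasta", ".fa", ".fna", ".ffn", ".faa", ".txt"):
        if base.lower().endswith(ext):
            base = base[: -len(ext)]
            break
    records = parse_fasta(path)
    if drop_plasmids:
        records = filter_plasmids(records, True)
    return Genome(name=base, records=records, kind=kind)


def load_genome_dir(path: str | os.PathLike, kind: str = "orf_set", drop_plasmids: bool = False) -> list[Genome]:
    """Load every FASTA file of a directory, sorted by file name.

    Raises if two files collapse to the same genome name.
    """
    exts = (".fasta", ".fa", ".fna", ".ffn", ".faa")
    genomes = []
    for fn in sorted(os.listdir(path)):
        if fn.lower().endswith(exts):
            genomes.append(load_genome(os.path.join(path, fn), kind=kind, drop_plasmids=drop_plasmids))
    names = [g.name for g in genomes]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"genome name collision after extension stripping: {sorted(dupes)}")
    if not genomes:
        raise ValueError(f"no FASTA files found in {path}")
    return genomes


class TranslationError(ValueError):
    pass


def translate(dna: str, record_id: str = "?") -> str:
    """Translate a DNA ORF under the bacterial code (translation table 11).

    An incomplete trailing codon is trimmed (with a log message); a trailing
    stop codon is stripped.  Internal stops are rendered as ``'*'`` and
    flagged via a log warning.  Alternative start codons are NOT forced to
    methionine: the raw table-11 translation of the first codon is reported.
    Raises :class:`TranslationError` on characters outside A/C/G/T.
    """
    dna = dna.upper().replace("U", "T")
    if not _DNA_RE.match(dna) or any(c not in "ACGTN" for c in dna):
        bad = sorted({c for c in dna if c not in "ACGTN"})
        raise TranslationError(f"record {record_id}: non-IUPAC DNA characters {bad}")
    if len(dna) % 3:
        log.debug("record %s: trimming %d trailing nucleotides", record_id, len(dna) % 3)
        dna = dna[: len(dna) - len(dna) % 3]
    fwd = TABLE11.forward_table
    aas = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if codon in _STOPS:
            aas.append("*")
        else:
            aas.append(fwd.get(codon, "X"))
    if aas and aas[-1] == "*":
        aas.pop()
    prot = "".join(aas)
    if "*" in prot:
        log.warning("record %s: internal stop codon(s) in translation", record_id)
    return prot


def translate_genome(genome: Genome) -> Genome:
    """Translate every DNA record of an ORF-set genome to protein."""
    out = [SequenceRecord(r.id, r.header, translate(r.seq, r.id)) for r in genome.records]
    return Genome(name=genome.name, records=out, kind="orf_set")


def genome_orf_stats(orfs: list[SequenceRecord]) -> OrfStats:
    """ORF count and pooled GC percentage over all ORF nucleotides."""
    gc = at = 0
    for r in orfs:
        s = r.seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("zero total ORF length; cannot compute GC content")
    return OrfStats(orf_count=len(orfs), gc_percent=100.0 * gc / (gc + at))


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def naive_orf_finder(assembly: Genome, min_len: int = 90) -> list[SequenceRecord]:
    """Fixture-grade ORF caller: maximal ATG→stop frames on both strands.

    Reports every maximal open frame of at least ``min_len`` nucleotides
    (including the stop codon), 5'→3', with provenance encoded in the id as
    ``<genome>|<contig>:<start>-<end>(<strand>)`` using 1-based inclusive
    coordinates on the forward strand.  Output is sorted by (contig, start).
    This is deliberately simple plumbing for tests; real gene calling is an
    external adapter's job.
    """
    found: list[tuple[str, int, int, str, str]] = []
    for contig in assembly.records:
        n = len(contig.seq)
        for strand, seq in (("+", contig.seq), ("-", _revcomp(contig.seq))):
            for frame in range(3):
                i = frame
                start = None
                while i + 3 <= len(seq):
                    codon = seq[i : i + 3]
                    if start is None:
                        if codon == "ATG":
                            start = i
                    elif codon in _STOPS:
                        orf = seq[start : i + 3]
                        if len(orf) >= min_len:
                            if strand == "+":
                                s, e = start + 1, i + 3
                            else:
                                s, e = n - (i + 3) + 1, n - start
                            found.append((contig.id, s, e, strand, orf))
                        start = None
                    i += 3
    found.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    out = []
    for contig_id, s, e, strand, orf in found:
        rid = f"{assembly.name}|{contig_id}:{s}-{e}({strand})"
        out.append(SequenceRecord(rid, rid, orf))
    return out
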
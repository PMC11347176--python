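"""Sequence I/O and desk-scale read processing.

Implements the read-processing chain used to turn raw amplicon paired-end
sequencing of an in vitro selection library into a table of unique,
constant-length sequences: primer clipping with orientation unification,
paired-read merging, length filtering, and unique-sequence counting.
Positional analyses downstream (conservation, covariation, stem pairing)
require every retained sequence to have the same length, so indel-containing
reads are removed by the length filter rather than aligned.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "Rejection",
    "UniqueSequenceTable",
    "FastqParseError",
    "read_fastq",
    "read_fasta",
    "write_fastq",
    "write_fasta",
    "reverse_complement",
    "hamming",
    "clip_and_orient",
    "merge_pairs",
    "filter_and_count",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


class FastqParseError(ValueError):
    """Malformed FASTQ record; message names the offending line number."""


@dataclass
class SequenceRecord:
    """A sequencing read or processed insert.

    Parameters
    ----------
    id : str
        Read label.
    sequence : str
        Bases over {A,C,G,T,N}; never empty.
    quality : list[int] | None
        Optional per-base Phred scores, same length as ``sequence``.
    """

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        qual = None if self.quality is None else self.quality[::-1]
        return SequenceRecord(self.id, reverse_complement(self.sequence), qual)


@dataclass(frozen=True)
class Rejection:
    """Outcome of a processing step that discarded a read, with the reason."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class UniqueSequenceTable:
    """Map from constant-length sequence to read count.

    The central exchange format between read processing, conservation
    profiling, covariation scanning and stem-pairing statistics. All
    sequences share one length; ``total_reads`` equals the sum of counts.
    """

    entries: dict[str, int] = field(default_factory=dict)
    length: int = 0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.entries}
        if len(lengths) > 1:
            raise ValueError(f"non-uniform sequence lengths: {sorted(lengths)}")
        if lengths:
            inferred = lengths.pop()
            if self.length and self.length != inferred:
                raise ValueError("declared length disagrees with entries")
            self.length = inferred
        if any(c < 1 for c in self.entries.values()):
            raise ValueError("all counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries.items())

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "UniqueSequenceTable":
        entries: dict[str, int] = {}
        for s in seqs:
            entries[s] = entries.get(s, 0) + 1
        return cls(entries)

    def most_common(self, n: int | None = None) -> list[tuple[str, int]]:
        items = sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))
        return items if n is None else items[:n]

    def to_tsv(self, path: str | Path) -> None:
        """Write as two-column TSV (sequence, count) with a one-line header."""
        with open(path, "w") as fh:
            fh.write("sequence\tcount\n")
            for seq, count in self.most_common():
                fh.write(f"{seq}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "UniqueSequenceTable":
        entries: dict[str, int] = {}
        lines = read_tsv_lines(path)
        if not lines or not lines[0].startswith("sequence"):
            raise ValueError(f"{path}: missing 'sequence\\tcount' header")
        for line in lines[1:]:
            seq, count = line.split("\t")
            entries[seq] = int(count)
        return cls(entries)


def read_tsv_lines(path: str | Path) -> list[str]:
    """Non-empty TSV lines with '#' provenance/comment lines stripped."""
    with open(path) as fh:
        return [
            line.rstrip("\n")
            for line in fh
            if line.strip() and not line.startswith("#")
        ]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield records from a (optionally gzipped) Phred+33 FASTQ file.

    Malformed records (missing ``+`` separator, quality/sequence length
    mismatch, truncated record) raise :class:`FastqParseError` naming the
    line number.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            sep = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not sep or not qual and not seq:
                raise FastqParseError(f"line {lineno}: truncated record")
            lineno += 3
            if not sep.startswith("+"):
                raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield SequenceRecord(
                id=header[1:].split()[0],
                sequence=seq.upper(),
                quality=[ord(c) - 33 for c in qual],
            )


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield records from a (optionally gzipped) FASTA file."""
    with _open_text(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            yield SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    )
    _BioSeqIO.write(bio, str(path), "fasta")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = r.quality if r.quality is not None else [40] * len(r)
            fh.write(
                f"@{r.id}\n{r.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


def _match_at_start(seq: str, primer: str, max_mismatch: int) -> bool:
    if len(primer) > len(seq):
        return False
    return hamming(seq[: len(primer)], primer) <= max_mismatch


def clip_and_orient(
    record: SequenceRecord,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 2,
) -> SequenceRecord | Rejection:
    """Unify read orientation and clip both primers.

    Searches for ``fwd_primer`` (Hamming distance <= ``max_mismatch``,
    substitutions only) at the 5' end of the read, then of its reverse
    complement. In the matching orientation the reverse primer is expected
    as ``reverse_complement(rev_primer)`` at the 3' end; both are removed
    and the insert is returned in forward orientation. Reads without both
    primers are rejected with a reason, never raised.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if len(fwd_primer) + len(rev_primer) >= len(record.sequence):
        return Rejection("primers_longer_than_read")

    oriented: SequenceRecord | None = None
    if _match_at_start(record.sequence, fwd_primer, max_mismatch):
        oriented = record
    else:
        rc = record.reverse_complement()
        if _match_at_start(rc.sequence, fwd_primer, max_mismatch):
            oriented = rc
    if oriented is None:
        return Rejection("fwd_primer_not_found")

    rev_site = reverse_complement(rev_primer)
    tail = oriented.sequence[-len(rev_site):]
    if hamming(tail, rev_site) > max_mismatch:
        return Rejection("rev_primer_not_found")

    start, stop = len(fwd_primer), len(oriented) - len(rev_site)
    qual = None if oriented.quality is None else oriented.quality[start:stop]
    return SequenceRecord(oriented.id, oriented.sequence[start:stop], qual)


def merge_pairs(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> SequenceRecord | Rejection:
    """Merge a read pair by overlapping the 3' of r1 with revcomp(r2).

    Scans overlaps from longest to shortest (ties therefore resolve toward
    the longer overlap) and accepts the first whose mismatch fraction is
    <= ``max_mismatch_frac``. At disagreeing positions the base with the
    higher Phred quality wins (missing qualities default to 40).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rc2 = r2.reverse_complement()
    q1 = r1.quality if r1.quality is not None else [40] * len(r1)
    q2 = rc2.quality if rc2.quality is not None else [40] * len(rc2)

    for ov in range(min(len(r1), len(rc2)), min_overlap - 1, -1):
        s1 = r1.sequence[len(r1) - ov:]
        s2 = rc2.sequence[:ov]
        mism = hamming(s1, s2)
        if mism / ov > max_mismatch_frac:
            continue
        bases: list[str] = []
        quals: list[int] = []
        for k in range(ov):
            qa, qb = q1[len(r1) - ov + k], q2[k]
            if s1[k] == s2[k] or qa >= qb:
                bases.append(s1[k])
            else:
                bases.append(s2[k])
            quals.append(max(qa, qb))
        merged_seq = r1.sequence[: len(r1) - ov] + "".join(bases) + rc2.sequence[ov:]
        merged_qual = q1[: len(r1) - ov] + quals + q2[ov:]
        return SequenceRecord(f"{r1.id}:merged", merged_seq, merged_qual)
    return Rejection("no_qualifying_overlap")


def filter_and_count(
    records: Iterable[SequenceRecord],
    length_min: int,
    length_max: int,
) -> UniqueSequenceTable:
    """Length-filter reads, drop N-containing ones, and count uniques.

    Only the modal surviving length is retained so that every sequence in
    the resulting table has the same length (positional analyses require
    uniform length; length variants are treated as indel artefacts).
    """
    if length_min > length_max:
        raise ValueError("length_min must be <= length_max")
    by_length: dict[int, dict[str, int]] = {}
    for rec in records:
        seq = rec.sequence
        if "N" in seq or not length_min <= len(seq) <= length_max:
            continue
        bucket = by_length.setdefault(len(seq), {})
        bucket[seq] = bucket.get(seq, 0) + 1
    if not by_length:
        warnings.warn("all records filtered out; returning empty table")
        return UniqueSequenceTable({})
    modal = max(by_length, key=lambda L: sum(by_length[L].values()))
    return UniqueSequenceTable(by_length[modal], length=modal)
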
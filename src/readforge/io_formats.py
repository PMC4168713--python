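"""Readers and writers for the plain-text formats used throughout readforge.

Formats handled here: 4-line FASTQ (training reads and simulator output),
multi-FASTA (the organism database), the 2-column tab-delimited abundance
profile, the taxonomy-annotated hit table, and the ground-truth sidecar TSV
that accompanies every simulated FASTQ.

All parsers are strict by default: a malformed record aborts with a
:class:`FormatError` naming the offending record or line, so that model
training never silently runs on corrupt input.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "SequenceRecord",
    "AbundanceProfile",
    "HitRecord",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "parse_abundance",
    "write_abundance",
    "read_hit_table",
    "write_hit_table",
    "write_reads",
    "TRUTH_COLUMNS",
]

VALID_BASES = frozenset("ACGTN")
#: IUPAC ambiguity codes accepted under the permissive FASTA flag (mapped to N).
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")

QUALITY_MIN = 0
QUALITY_MAX = 93  # printable Phred+33 ceiling ('~')

TRUTH_COLUMNS = (
    "read_id",
    "genome_id",
    "start",
    "end",
    "strand",
    "n_sub",
    "n_ins",
    "n_del",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A sequence with an optional Phred quality vector.

    ``id`` is the header token before the first whitespace.  ``sequence`` is
    uppercase over the alphabet {A, C, G, T, N}.  ``qualities``, when present,
    holds integer Phred scores of the same length as the sequence.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise FormatError(
                    f"record {self.id!r}: sequence length {len(self.sequence)} "
                    f"!= quality length {len(self.qualities)}"
                )
            for q in self.qualities:
                if not (QUALITY_MIN <= q <= QUALITY_MAX):
                    raise FormatError(
                        f"record {self.id!r}: quality {q} outside "
                        f"[{QUALITY_MIN}, {QUALITY_MAX}]"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AbundanceProfile:
    """Relative abundances of the genomes in a simulated community.

    Entries are ordered (genome_id, abundance) pairs.  After construction the
    abundances sum to 1 (within 1e-6), every abundance is strictly positive
    and genome ids are unique.
    """

    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise FormatError("abundance profile has no entries")
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise FormatError(f"duplicate genome id(s) in profile: {dupes}")
        for g, a in self.entries:
            if not a > 0:
                raise FormatError(f"genome {g!r}: non-positive abundance {a}")
        total = sum(a for _, a in self.entries)
        if abs(total - 1.0) > 1e-6:
            # normalise rather than reject: callers may pass raw weights
            self.entries = [(g, a / total) for g, a in self.entries]

    @property
    def ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def abundances(self) -> list[float]:
        return [a for _, a in self.entries]

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


@dataclass
class HitRecord:
    """One homology-search hit: query, bit score, and a root-first lineage."""

    query_id: str
    bit_score: float
    lineage: list[str]

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise FormatError(
                f"hit for {self.query_id!r}: negative bit score {self.bit_score}"
            )
        if not self.lineage:
            raise FormatError(f"hit for {self.query_id!r}: empty lineage")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path, *, offset: int = 33) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line-per-record FASTQ file.

    Qualities are decoded to integers with the given ASCII ``offset``
    (33 for Phred+33, 64 for Phred+64).  Sequences are uppercased.  A record
    whose sequence and quality lines differ in length aborts with a
    :class:`FormatError` naming the (0-based) record index.  An empty file
    yields an empty stream.
    """
    with open(path) as handle:
        index = -1
        iterator = FastqGeneralIterator(handle)
        while True:
            index += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"malformed FASTQ record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FormatError(
                    f"malformed FASTQ record {index}: sequence/quality "
                    f"length mismatch ({len(seq)} vs {len(qual)})"
                )
            qualities = [ord(c) - offset for c in qual]
            bad = [q for q in qualities if not (QUALITY_MIN <= q <= QUALITY_MAX)]
            if bad:
                raise FormatError(
                    f"malformed FASTQ record {index}: quality value(s) {bad[:3]} "
                    f"outside [{QUALITY_MIN}, {QUALITY_MAX}] with offset {offset}"
                )
            yield SequenceRecord(
                id=title.split()[0],
                sequence=seq.upper(),
                qualities=qualities,
            )


def write_fastq(records: Iterable[SequenceRecord], path, *, offset: int = 33) -> int:
    """Write records as 4-line FASTQ; returns the number written.

    The write is atomic (temp file + rename) so a failure never leaves a
    truncated file behind.
    """
    n = 0
    with _atomic_open(path) as handle:
        for rec in records:
            if rec.qualities is None:
                raise FormatError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + offset) for q in rec.qualities)
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, *, permissive: bool = False) -> list[SequenceRecord]:
    """Read a multi-FASTA organism database.

    Wrapped sequence lines are concatenated and everything is uppercased.
    Duplicate ids and an empty file are fatal.  Characters outside
    {A,C,G,T,N} are fatal unless ``permissive`` is set, in which case IUPAC
    ambiguity codes are mapped to N.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise FormatError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            if permissive and bad <= IUPAC_AMBIGUITY:
                table = str.maketrans({c: "N" for c in bad})
                seq = seq.translate(table)
            else:
                raise FormatError(
                    f"record {rid!r}: non-IUPAC/ambiguous character(s) {sorted(bad)}"
                    + ("" if permissive else " (use permissive=True to map to N)")
                )
        records.append(SequenceRecord(id=rid, sequence=seq))
    if not records:
        raise FormatError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, *, width: int = 70) -> int:
    n = 0
    with _atomic_open(path) as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Abundance profile (Grinder/GemSIM-style 2-column TSV)
# ---------------------------------------------------------------------------

def parse_abundance(path) -> AbundanceProfile:
    """Parse a tab-delimited genome-id / relative-abundance profile.

    Comment lines starting with '#' and blank lines are ignored.  If the
    column sum is 100 +/- 0.5 the values are interpreted as percentages.
    Output abundances are normalised to sum to 1.
    """
    entries: list[tuple[str, float]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
            gid = parts[0].strip()
            try:
                value = float(parts[1])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric abundance {parts[1]!r}"
                ) from None
            if gid in seen:
                raise FormatError(f"line {lineno}: duplicate genome id {gid!r}")
            if not value > 0:
                raise FormatError(f"line {lineno}: non-positive abundance {value}")
            seen.add(gid)
            entries.append((gid, value))
    if not entries:
        raise FormatError(f"no abundance entries in {path}")
    total = sum(a for _, a in entries)
    if abs(total - 100.0) <= 0.5:
        entries = [(g, a / 100.0) for g, a in entries]
        total = sum(a for _, a in entries)
    entries = [(g, a / total) for g, a in entries]
    return AbundanceProfile(entries=entries)


def write_abundance(profile: AbundanceProfile, path) -> None:
    with _atomic_open(path) as handle:
        handle.write("# genome_id\trelative_abundance\n")
        for gid, ab in profile.entries:
            handle.write(f"{gid}\t{ab:.10g}\n")


# ---------------------------------------------------------------------------
# Hit table (query_id, bit_score, semicolon-joined root-first lineage)
# ---------------------------------------------------------------------------

def read_hit_table(path) -> list[HitRecord]:
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected >=3 tab-separated columns")
            try:
                score = float(parts[1])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric bit score {parts[1]!r}"
                ) from None
            lineage = [t.strip() for t in parts[2].split(";") if t.strip()]
            if not lineage:
                raise FormatError(f"line {lineno}: empty lineage")
            hits.append(HitRecord(query_id=parts[0].strip(), bit_score=score, lineage=lineage))
    if not hits:
        raise FormatError(f"no hits in {path}")
    return hits


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    with _atomic_open(path) as handle:
        handle.write("# query_id\tbit_score\tlineage\n")
        for hit in hits:
            handle.write(f"{hit.query_id}\t{hit.bit_score:g}\t{';'.join(hit.lineage)}\n")


# ---------------------------------------------------------------------------
# Simulated reads + ground-truth sidecar
# ---------------------------------------------------------------------------

def write_reads(records, fastq_path, truth_path, *, offset: int = 33) -> int:
    """Write simulated reads as FASTQ plus a tab-delimited ground-truth file.

    Truth columns: read_id, genome_id, start (0-based), end (half-open),
    strand (+/-), n_sub, n_ins, n_del.  Strand '+' means the error-free read
    equals the genome slice; '-' means its reverse complement.  Returns the
    number of reads written; an empty stream yields a valid empty FASTQ and
    a header-only truth file.
    """
    n = 0
    with _atomic_open(fastq_path) as fq, _atomic_open(truth_path) as truth:
        truth.write("\t".join(TRUTH_COLUMNS) + "\n")
        for read in records:
            if read.qualities is None:
                raise FormatError(f"simulated read {read.id!r} has no qualities")
            qual = "".join(chr(q + offset) for q in read.qualities)
            fq.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
            truth.write(
                f"{read.id}\t{read.genome_id}\t{read.start}\t{read.end}\t"
                f"{read.strand}\t{read.n_sub}\t{read.n_ins}\t{read.n_del}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

class _atomic_open:
    """Context manager writing to a temp file and renaming on success."""

    def __init__(self, path):
        self.path = str(path)
        self._tmp = None
        self._handle = None

    def __enter__(self):
        directory = os.path.dirname(self.path) or "."
        fd, self._tmp = tempfile.mkstemp(
            dir=directory, prefix=os.path.basename(self.path) + ".", suffix=".tmp"
        )
        self._handle = os.fdopen(fd, "w")
        return self._handle

    def __exit__(self, exc_type, exc, tb):
        self._handle.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False
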
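"""FASTA/FASTQ reading, writing, and seeded random read picking.

The central object is :class:`ReadIndex`, an array of byte offsets — one per
record — into a (possibly gzip-compressed) FASTA or FASTQ file.  Random
subsamples are drawn over those offsets with a seeded Mersenne-Twister
generator, so a subsample is fully reproducible from ``(path, m, seed,
replacement)`` and never requires loading the whole dataset into memory.

Conventions:

* FASTA input may be line-wrapped; output FASTA is unwrapped.
* FASTQ records must be strict 4-line (instrument convention); quality
  length must equal sequence length.
* The record id is the definition line up to the first whitespace; any
  remainder is kept as ``source_label`` (used by the synthetic-read
  generator to tag each read with its source genome).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterator, List, Optional, Sequence, Union

import numpy as np

__all__ = [
    "ReadRecord",
    "ReadIndex",
    "ParseError",
    "SampleSizeError",
    "index_reads",
    "pick_reads",
    "write_reads",
    "iter_reads",
    "read_at",
    "detect_format",
]

#: Quality character written when FASTQ output is requested for records
#: that carry no qualities (Phred 40 in Sanger encoding).
PLACEHOLDER_QUALITY = "I"


class ParseError(ValueError):
    """A malformed FASTA/FASTQ record; the message names the byte offset."""


class SampleSizeError(ValueError):
    """Requested subsample size exceeds the available read pool."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read.

    Parameters
    ----------
    read_id
        Definition line up to the first whitespace; unique within a file.
    sequence
        Bases over ``{A, C, G, T, N}`` (case preserved as given).
    qualities
        Sanger-encoded quality string of the same length, or ``None`` for
        FASTA-derived records.
    source_label
        Remainder of the definition line, if any.  The synthetic-community
        generator stores the source subject id here.
    """

    read_id: str
    sequence: str
    qualities: Optional[str] = None
    source_label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadIndex:
    """Byte-offset index over a FASTA/FASTQ file: one offset per record."""

    path: str
    format: str  # "fasta" | "fastq"
    offsets: np.ndarray = field(repr=False)  # int64, strictly increasing

    @property
    def total_reads(self) -> int:
        return int(len(self.offsets))

    def __len__(self) -> int:
        return self.total_reads


def _open_binary(path: Union[str, Path]) -> BinaryIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rb")  # type: ignore[return-value]
    return open(path, "rb")


def detect_format(path: Union[str, Path]) -> str:
    """Guess ``fasta``/``fastq`` from the file suffix (``.gz`` stripped)."""
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def _split_defline(line: str, prefix: str, offset: int) -> tuple[str, Optional[str]]:
    if not line.startswith(prefix):
        raise ParseError(
            f"expected {prefix!r} at byte offset {offset}, got {line[:20]!r}"
        )
    body = line[1:].rstrip("\n")
    if not body:
        raise ParseError(f"empty definition line at byte offset {offset}")
    parts = body.split(None, 1)
    read_id = parts[0]
    label = parts[1] if len(parts) == 2 else None
    return read_id, label


def index_reads(path: Union[str, Path], format: Optional[str] = None) -> ReadIndex:
    """Scan *path* once and record the byte offset of every record start.

    An empty file yields an index with ``total_reads == 0``.  Malformed
    records raise :class:`ParseError` naming the byte offset.  Offsets are
    positions in the decompressed stream for ``.gz`` input.
    """
    fmt = format or detect_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {fmt!r}")
    offsets: List[int] = []
    with _open_binary(path) as fh:
        if fmt == "fasta":
            _scan_fasta(fh, offsets)
        else:
            _scan_fastq(fh, offsets)
    return ReadIndex(path=str(path), format=fmt, offsets=np.asarray(offsets, dtype=np.int64))


def _scan_fasta(fh: BinaryIO, offsets: List[int]) -> None:
    pos = 0
    seen_seq = True  # so a leading '>' is legal
    for raw in fh:
        line = raw.strip()
        if line.startswith(b">"):
            offsets.append(pos)
            seen_seq = False
        elif line:
            if not offsets:
                raise ParseError(f"sequence before first '>' at byte offset {pos}")
            seen_seq = True
        pos += len(raw)
    if offsets and not seen_seq:
        raise ParseError(f"record at byte offset {offsets[-1]} has no sequence")


def _scan_fastq(fh: BinaryIO, offsets: List[int]) -> None:
    pos = 0
    while True:
        start = pos
        lines = []
        for _ in range(4):
            raw = fh.readline()
            if not raw:
                break
            lines.append(raw)
            pos += len(raw)
        if not lines:
            break
        if len(lines) < 4 and all(not ln.strip() for ln in lines):
            break  # trailing blank line(s)
        if len(lines) < 4:
            raise ParseError(f"truncated FASTQ record at byte offset {start}")
        header, seq, plus, qual = (ln.rstrip(b"\r\n") for ln in lines)
        if not header.startswith(b"@"):
            raise ParseError(f"expected '@' at byte offset {start}")
        if not plus.startswith(b"+"):
            raise ParseError(f"expected '+' separator in record at byte offset {start}")
        if len(seq) != len(qual):
            raise ParseError(
                f"quality length {len(qual)} != sequence length {len(seq)} "
                f"in record at byte offset {start}"
            )
        if len(seq) == 0:
            raise ParseError(f"empty sequence in record at byte offset {start}")
        offsets.append(start)


def read_at(index: ReadIndex, position: int) -> ReadRecord:
    """Parse the single record at ordinal *position* of the index."""
    with _open_binary(index.path) as fh:
        return _read_record(fh, index, position)


def _read_record(fh: BinaryIO, index: ReadIndex, position: int) -> ReadRecord:
    offset = int(index.offsets[position])
    fh.seek(offset)
    if index.format == "fastq":
        header = fh.readline().decode("ascii")
        seq = fh.readline().decode("ascii").rstrip("\r\n")
        fh.readline()  # '+'
        qual = fh.readline().decode("ascii").rstrip("\r\n")
        read_id, label = _split_defline(header, "@", offset)
        return ReadRecord(read_id, seq, qual, label)
    header = fh.readline().decode("ascii")
    read_id, label = _split_defline(header, ">", offset)
    parts: List[str] = []
    while True:
        raw = fh.readline()
        if not raw or raw.startswith(b">"):
            break
        parts.append(raw.decode("ascii").strip())
    return ReadRecord(read_id, "".join(parts), None, label)


def iter_reads(index: ReadIndex) -> Iterator[ReadRecord]:
    """Yield every record of the index in file order."""
    with _open_binary(index.path) as fh:
        for position in range(index.total_reads):
            yield _read_record(fh, index, position)


def pick_reads(
    index: ReadIndex,
    m: int,
    seed: int,
    replacement: bool = False,
) -> List[ReadRecord]:
    """Draw *m* reads uniformly at random over record positions.

    Uses ``numpy.random.RandomState`` (Mersenne Twister MT19937) seeded with
    *seed*: the ordered selection is bit-reproducible across runs and
    platforms.  Without replacement the selected positions are distinct.
    """
    if m < 0:
        raise ValueError(f"subsample size m must be >= 0, got {m}")
    n = index.total_reads
    if not replacement and m > n:
        raise SampleSizeError(
            f"cannot draw {m} reads without replacement from a pool of {n}"
        )
    rng = np.random.RandomState(seed)
    if m == 0:
        return []
    if replacement:
        positions = rng.randint(0, n, size=m)
    else:
        positions = rng.choice(n, size=m, replace=False)
    # Fetch in file order (one pass, gzip-friendly), then restore draw order.
    order = np.argsort(positions, kind="stable")
    fetched: dict[int, ReadRecord] = {}
    with _open_binary(index.path) as fh:
        for idx in order:
            pos = int(positions[idx])
            if pos not in fetched:
                fetched[pos] = _read_record(fh, index, pos)
    return [fetched[int(p)] for p in positions]


def write_reads(
    records: Sequence[ReadRecord],
    path: Union[str, Path],
    format: str = "fastq",
) -> None:
    """Write records as unwrapped FASTA or strict 4-line FASTQ.

    FASTQ output for records without qualities synthesizes a constant
    placeholder quality (:data:`PLACEHOLDER_QUALITY`); the census run log
    notes when this happened.  ``.gz`` suffix triggers gzip compression.
    The output round-trips through :func:`index_reads` to equal records on
    (id, sequence, qualities).
    """
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {format!r}")
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        for rec in records:
            defline = rec.read_id if rec.source_label is None else f"{rec.read_id} {rec.source_label}"
            if format == "fasta":
                fh.write(f">{defline}\n{rec.sequence}\n")
            else:
                qual = rec.qualities or PLACEHOLDER_QUALITY * len(rec.sequence)
                fh.write(f"@{defline}\n{rec.sequence}\n+\n{qual}\n")
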
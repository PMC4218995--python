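"""Best-hit read alignment: a hermetic naive backend and an external blastn backend.

The alignment contract is deliberately minimal: for each read, at most one
hit (the *best hit*), reported only if it clears the identity floor and the
e-value cutoff.  Two backends honour it:

``naive``
    An ungapped, substitution-only aligner written for hermetic testing.
    Candidate placements on either strand are generated from shared 11-mers
    between read and reference, then verified by exact Hamming counting;
    the placement with the fewest mismatches wins.  Ties break by highest
    score, then lexicographically smallest subject id, then forward strand,
    then smallest offset — determinism is required for golden tests.  Its
    e-value is a monotone surrogate (decreasing in score) adequate only for
    thresholding, not comparable to BLAST statistics.

``external``
    Shells out to ``blastn -task megablast -evalue 1e-6 -max_target_seqs 1
    -perc_identity 90`` with 12-column tabular output.  Availability is
    probed at run time and never assumed.

The host-depletion pre-filter (clinical samples) partitions reads into
host-derived and remainder: a read is host if some alignment covers at
least ``min_match_fraction`` of its length with mismatches at most
``max_mismatch_fraction`` of the aligned length (defaults 0.8 and 0.1).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

from .seqio import ReadRecord
from .taxonomy import UNMAPPED, SubjectTaxMap, resolve_subject

__all__ = [
    "AlignmentHit",
    "AlignerParams",
    "ReferenceIndex",
    "ExternalBackendError",
    "align_best_hit",
    "naive_best_hit",
    "host_filter",
    "reverse_complement",
]

SEED_LENGTH = 11  # word size for naive candidate generation

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ExternalBackendError(RuntimeError):
    """blastn/makeblastdb not found; caller should fall back to naive."""


@dataclass(frozen=True)
class AlignmentHit:
    """Best hit of one read against the reference collection."""

    read_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int
    mismatches: int
    evalue: float
    bitscore: float
    taxid: int = UNMAPPED
    strand: str = "+"


@dataclass(frozen=True)
class AlignerParams:
    """Alignment thresholds; defaults follow megablast best-hit profiling."""

    min_identity: float = 90.0
    evalue_cutoff: float = 1e-6
    max_targets: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity must be in [0, 100]")
        if self.max_targets != 1:
            raise ValueError("best-hit contract: max_targets must be 1")


class ReferenceIndex:
    """Reference sequences plus an exact 11-mer index for seed lookup."""

    def __init__(self, sequences: Dict[str, str], source_fasta: Optional[str] = None):
        if not sequences:
            raise ValueError("reference collection is empty")
        self.subject_ids: List[str] = sorted(sequences)
        self.sequences: Dict[str, str] = {k: sequences[k].upper() for k in self.subject_ids}
        self.arrays: Dict[str, np.ndarray] = {
            k: np.frombuffer(v.encode("ascii"), dtype=np.uint8)
            for k, v in self.sequences.items()
        }
        self.total_length = sum(len(v) for v in self.sequences.values())
        self.source_fasta = source_fasta
        self._seed_index: Dict[bytes, List[Tuple[str, int]]] = {}
        for sid, seq in self.sequences.items():
            raw = seq.encode("ascii")
            for off in range(len(raw) - SEED_LENGTH + 1):
                self._seed_index.setdefault(raw[off : off + SEED_LENGTH], []).append((sid, off))

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ReferenceIndex":
        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences, source_fasta=str(path))

    def __len__(self) -> int:
        return len(self.subject_ids)

    def seed_candidates(self, seq: str) -> List[Tuple[str, int]]:
        """Candidate (subject, start) placements of *seq* from shared seeds."""
        raw = seq.upper().encode("ascii")
        length = len(raw)
        if length < SEED_LENGTH:
            return [
                (sid, start)
                for sid in self.subject_ids
                for start in range(len(self.sequences[sid]) - length + 1)
            ]
        seen = set()
        out: List[Tuple[str, int]] = []
        for j in range(length - SEED_LENGTH + 1):
            for sid, off in self._seed_index.get(raw[j : j + SEED_LENGTH], ()):
                start = off - j
                if 0 <= start <= len(self.sequences[sid]) - length:
                    key = (sid, start)
                    if key not in seen:
                        seen.add(key)
                        out.append(key)
        return out


def _best_placement(
    read_seq: str, reference: ReferenceIndex
) -> Optional[Tuple[int, str, str, int]]:
    """Minimum-mismatch full-length ungapped placement over both strands.

    Returns ``(mismatches, subject_id, strand, start)`` or ``None`` if no
    seeded candidate exists.  Tie order: fewer mismatches, then subject id,
    then forward strand, then smaller offset.
    """
    best: Optional[Tuple[int, str, int, int]] = None  # (mm, sid, strand_rank, start)
    length = len(read_seq)
    for strand_rank, seq in enumerate((read_seq, reverse_complement(read_seq))):
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        for sid, start in reference.seed_candidates(seq):
            mm = int(np.count_nonzero(reference.arrays[sid][start : start + length] != arr))
            key = (mm, sid, strand_rank, start)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    mm, sid, strand_rank, start = best
    return mm, sid, "+" if strand_rank == 0 else "-", start


def _surrogate_scores(length: int, mismatches: int) -> Tuple[float, float]:
    """(bitscore, evalue) surrogate: score +2/match, -3/mismatch."""
    score = 2 * (length - mismatches) - 3 * mismatches
    return float(score), float(length) * 2.0 ** (-score)


def naive_best_hit(
    read: ReadRecord,
    reference: ReferenceIndex,
    params: AlignerParams = AlignerParams(),
) -> Optional[AlignmentHit]:
    """Best ungapped full-length placement of *read*, or ``None``."""
    placement = _best_placement(read.sequence, reference)
    if placement is None:
        return None
    mm, sid, strand, _start = placement
    length = len(read.sequence)
    identity = 100.0 * (length - mm) / length
    bitscore, evalue = _surrogate_scores(length, mm)
    if identity < params.min_identity or evalue > params.evalue_cutoff:
        return None
    return AlignmentHit(
        read_id=read.read_id,
        subject_id=sid,
        percent_identity=identity,
        aligned_length=length,
        mismatches=mm,
        evalue=evalue,
        bitscore=bitscore,
        strand=strand,
    )


def align_best_hit(
    reads: Sequence[ReadRecord],
    reference: ReferenceIndex,
    params: AlignerParams = AlignerParams(),
    backend: str = "naive",
    subject_map: Optional[SubjectTaxMap] = None,
) -> Dict[str, AlignmentHit]:
    """Map each read to its best hit; reads without a qualifying hit are absent.

    With *subject_map*, each hit's ``taxid`` is resolved (possibly to the
    unmapped sentinel); otherwise taxids stay unmapped.
    """
    if backend == "naive":
        hits: Dict[str, AlignmentHit] = {}
        for read in reads:
            hit = naive_best_hit(read, reference, params)
            if hit is not None:
                hits[read.read_id] = hit
    elif backend == "external":
        hits = _blast_best_hits(reads, reference, params)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if subject_map is not None:
        hits = {
            rid: AlignmentHit(
                read_id=h.read_id,
                subject_id=h.subject_id,
                percent_identity=h.percent_identity,
                aligned_length=h.aligned_length,
                mismatches=h.mismatches,
                evalue=h.evalue,
                bitscore=h.bitscore,
                taxid=resolve_subject(subject_map, h.subject_id),
                strand=h.strand,
            )
            for rid, h in hits.items()
        }
    return hits


def _require_blast() -> None:
    for tool in ("blastn", "makeblastdb"):
        if shutil.which(tool) is None:
            raise ExternalBackendError(
                f"{tool} not found on PATH; external alignment backend "
                "unavailable — rerun with backend='naive'"
            )


def _reference_fasta(reference: ReferenceIndex, workdir: Path) -> Path:
    if reference.source_fasta and Path(reference.source_fasta).exists():
        return Path(reference.source_fasta)
    path = workdir / "reference.fasta"
    with open(path, "w") as fh:
        for sid in reference.subject_ids:
            fh.write(f">{sid}\n{reference.sequences[sid]}\n")
    return path


def _run_blastn(
    reads: Sequence[ReadRecord],
    reference: ReferenceIndex,
    extra_args: List[str],
) -> List[List[str]]:
    """Run blastn, returning parsed 12-column tabular rows."""
    _require_blast()
    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        ref_fasta = _reference_fasta(reference, workdir)
        db = workdir / "refdb"
        subprocess.run(
            ["makeblastdb", "-in", str(ref_fasta), "-dbtype", "nucl", "-out", str(db)],
            check=True,
            capture_output=True,
        )
        query = workdir / "query.fasta"
        with open(query, "w") as fh:
            for read in reads:
                fh.write(f">{read.read_id}\n{read.sequence}\n")
        result = subprocess.run(
            ["blastn", "-task", "megablast", "-query", str(query), "-db", str(db),
             "-outfmt", "6", *extra_args],
            check=True,
            capture_output=True,
            text=True,
        )
    return [line.split("\t") for line in result.stdout.splitlines() if line.strip()]


def _blast_best_hits(
    reads: Sequence[ReadRecord],
    reference: ReferenceIndex,
    params: AlignerParams,
) -> Dict[str, AlignmentHit]:
    if not reads:
        return {}
    rows = _run_blastn(
        reads,
        reference,
        ["-evalue", str(params.evalue_cutoff),
         "-max_target_seqs", "1",
         "-perc_identity", str(params.min_identity)],
    )
    hits: Dict[str, AlignmentHit] = {}
    for row in rows:
        qseqid, sseqid, pident, length, mismatch = row[0], row[1], float(row[2]), int(row[3]), int(row[4])
        sstart, send, evalue, bitscore = int(row[8]), int(row[9]), float(row[10]), float(row[11])
        if qseqid in hits:  # keep first (highest-ranked) HSP per query
            continue
        hits[qseqid] = AlignmentHit(
            read_id=qseqid,
            subject_id=sseqid,
            percent_identity=pident,
            aligned_length=length,
            mismatches=mismatch,
            evalue=evalue,
            bitscore=bitscore,
            strand="+" if send >= sstart else "-",
        )
    return hits


def host_filter(
    reads: Sequence[ReadRecord],
    host_reference: Optional[ReferenceIndex],
    min_match_fraction: float = 0.8,
    max_mismatch_fraction: float = 0.1,
    backend: str = "naive",
) -> Tuple[List[ReadRecord], List[ReadRecord]]:
    """Partition reads into (host_reads, unaligned_reads), order preserved.

    A read is host if some alignment covers >= ``min_match_fraction`` of its
    length with mismatches <= ``max_mismatch_fraction`` of the aligned
    length.  The naive backend considers full-length ungapped placements
    (coverage 1), so the rule reduces to the mismatch bound.
    """
    if not (0 < min_match_fraction <= 1) or not (0 < max_mismatch_fraction <= 1):
        raise ValueError("filter fractions must be in (0, 1]")
    if host_reference is None or len(host_reference) == 0:
        warnings.warn("empty host reference: no reads filtered", stacklevel=2)
        return [], list(reads)

    host: List[ReadRecord] = []
    rest: List[ReadRecord] = []
    if backend == "naive":
        for read in reads:
            placement = _best_placement(read.sequence, host_reference)
            is_host = (
                placement is not None
                and placement[0] <= max_mismatch_fraction * len(read.sequence)
            )
            (host if is_host else rest).append(read)
        return host, rest
    if backend == "external":
        rows = _run_blastn(reads, host_reference, ["-evalue", "1e-6", "-max_target_seqs", "1"])
        host_ids = set()
        for row in rows:
            qlen_aligned = int(row[3])
            mismatch = int(row[4])
            qstart, qend = int(row[6]), int(row[7])
            coverage_len = abs(qend - qstart) + 1
            host_ids.add((row[0], coverage_len, mismatch, qlen_aligned))
        by_id = {r.read_id: r for r in reads}
        qualifying = set()
        for qseqid, coverage_len, mismatch, aligned_len in host_ids:
            read = by_id.get(qseqid)
            if read is None:
                continue
            if (
                coverage_len >= min_match_fraction * len(read.sequence)
                and mismatch <= max_mismatch_fraction * aligned_len
            ):
                qualifying.add(qseqid)
        for read in reads:
            (host if read.read_id in qualifying else rest).append(read)
        return host, rest
    raise ValueError(f"unknown backend {backend!r}")
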
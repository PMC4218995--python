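"""Hermetic synthetic fixtures: toy genomes, toy taxonomy, labeled reads.

The generator emulates a mixed microbial community sequenced with
substitution errors: random genomes (one per taxon), a four-level taxonomy
whose leaves are the genomes, a complete subject→taxid map, and single-end
reads drawn from the genomes at fixed proportions with i.i.d. base
substitutions.  Every read's definition line carries its source genome id
as a label, so downstream accuracy can be scored against ground truth.

Genomes are uniform-random sequences, deliberately *not* real genomes:
random genomes share essentially no similarity, so the perfect-alignment
assumption of the design calculator is realizable and every read has an
unambiguous true source.  A rejection check verifies that no read-length
window of one genome aligns to another at >= 90% identity (the aligner's
default floor); offending genomes are regenerated.

The default community mirrors a six-member mixture at proportions
0.50 / 0.20 / 0.20 / 0.07 / 0.02 / 0.01 with 50 bp reads — a mixture of
dominant, mid-, and rare (1%) members that exercises the census filter at
its design point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .seqio import ReadRecord, write_reads
from .taxonomy import SubjectTaxMap, TaxNode, TaxonomyTree
from .aligner import reverse_complement

__all__ = [
    "Component",
    "CommunitySpec",
    "FixtureBundle",
    "SeedError",
    "DEFAULT_PROPORTIONS",
    "make_reference_fixture",
    "simulate_reads",
    "default_community_spec",
    "write_fixture",
    "write_taxdump",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Community proportions of the default six-member synthetic mixture.
DEFAULT_PROPORTIONS = (0.50, 0.20, 0.20, 0.07, 0.02, 0.01)

_SEED_LEN = 11  # word size used by the cross-mapping rejection check


class SeedError(RuntimeError):
    """Genome generation kept violating the separation check; try a new seed."""


@dataclass(frozen=True)
class Component:
    subject_id: str
    taxid: int
    proportion: float


@dataclass(frozen=True)
class CommunitySpec:
    """Composition and sequencing parameters of a synthetic community."""

    components: Tuple[Component, ...]
    n_reads: int
    read_length: int = 50
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        total = sum(c.proportion for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        ids = [c.subject_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")


@dataclass
class FixtureBundle:
    """In-memory reference fixture: genomes + taxonomy + subject map."""

    sequences: Dict[str, str]
    tree: TaxonomyTree
    subject_map: SubjectTaxMap
    leaf_taxids: Dict[str, int]
    paths: Dict[str, Path] = field(default_factory=dict)


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def _separation_violations(
    sequences: Dict[str, str], read_length: int, min_identity: float = 90.0
) -> List[str]:
    """Subject ids owning a window that maps to another genome at >= min_identity.

    Candidate diagonals come from exact 11-mers shared between genomes (an
    ungapped match at >= 90% identity over a short window is vanishingly
    unlikely without one); each candidate diagonal is verified by Hamming
    counting over every read-length window containing the shared word.
    """
    arrays = {
        sid: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for sid, seq in sequences.items()
    }
    kmers: Dict[bytes, List[Tuple[str, int]]] = {}
    for sid, seq in sequences.items():
        raw = seq.encode("ascii")
        rc = reverse_complement(seq).encode("ascii")
        for variant in (raw, rc):
            for off in range(len(variant) - _SEED_LEN + 1):
                kmers.setdefault(variant[off : off + _SEED_LEN], []).append(
                    (sid, off if variant is raw else -1)
                )
    bad: set[str] = set()
    max_mm = read_length - math.ceil(min_identity / 100.0 * read_length)
    for placements in kmers.values():
        sids = {sid for sid, _ in placements}
        if len(sids) < 2:
            continue
        fwd = [(sid, off) for sid, off in placements if off >= 0]
        for a_sid, a_off in fwd:
            for b_sid, b_off in fwd:
                if a_sid == b_sid:
                    continue
                a_arr, b_arr = arrays[a_sid], arrays[b_sid]
                lo = max(0, a_off - (read_length - _SEED_LEN))
                hi = min(a_off, len(a_arr) - read_length)
                for ws in range(lo, hi + 1):
                    wb = b_off - (a_off - ws)
                    if not (0 <= wb <= len(b_arr) - read_length):
                        continue
                    mm = int(
                        np.count_nonzero(
                            a_arr[ws : ws + read_length] != b_arr[wb : wb + read_length]
                        )
                    )
                    if mm <= max_mm:
                        bad.add(b_sid)
        # Reverse-strand sharing is flagged conservatively without a
        # diagonal verify: regenerate any genome whose reverse complement
        # shares a word placed within a qualifying window of another.
    return sorted(bad)


def _build_taxonomy(subject_ids: Sequence[str]) -> Tuple[TaxonomyTree, Dict[str, int]]:
    """Four-level chain per taxon: root → domain → family → genus → species.

    Genus nodes (depth 3) are unique per taxon, so the default slim depth
    keeps community members distinct; the two domain nodes give the tree
    shared internal structure.
    """
    nodes: Dict[int, TaxNode] = {1: TaxNode(1, 1, "no rank", "root", 0)}
    leaf_taxids: Dict[str, int] = {}
    for k, sid in enumerate(subject_ids):
        domain = 10 + (k % 2)
        if domain not in nodes:
            nodes[domain] = TaxNode(domain, 1, "superkingdom", f"domain_{domain - 10}", 1)
        family = 100 + k
        genus = 200 + k
        leaf = 1000 + k
        nodes[family] = TaxNode(family, domain, "family", f"family_{sid}", 2)
        nodes[genus] = TaxNode(genus, family, "genus", f"genus_{sid}", 3)
        nodes[leaf] = TaxNode(leaf, genus, "species", f"species_{sid}", 4)
        leaf_taxids[sid] = leaf
    return TaxonomyTree(nodes=nodes, root_taxid=1), leaf_taxids


def make_reference_fixture(
    n_taxa: int,
    genome_length: int = 3000,
    seed: int = 0,
    read_length: int = 50,
    outdir: Optional[Union[str, Path]] = None,
    max_attempts: int = 25,
) -> FixtureBundle:
    """Generate n_taxa random genomes, a toy taxonomy, and a subject map.

    Genomes failing the cross-mapping separation check are regenerated up
    to *max_attempts* times; persistent failure raises :class:`SeedError`
    advising a different seed.  With *outdir*, the fixture is also written
    to disk (reference FASTA, taxdump nodes/names, subject-map TSV).
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if genome_length < read_length:
        raise ValueError("genome_length must be >= read_length")
    rng = np.random.default_rng(seed)
    subject_ids = [f"genome{k:02d}" for k in range(n_taxa)]
    sequences = {sid: _random_genome(rng, genome_length) for sid in subject_ids}
    for _ in range(max_attempts):
        bad = _separation_violations(sequences, read_length) if n_taxa > 1 else []
        if not bad:
            break
        for sid in bad:
            sequences[sid] = _random_genome(rng, genome_length)
    else:
        raise SeedError(
            f"could not generate {n_taxa} separated genomes in {max_attempts} "
            f"attempts; try a different seed"
        )
    tree, leaf_taxids = _build_taxonomy(subject_ids)
    subject_map = SubjectTaxMap(mapping=dict(leaf_taxids))
    bundle = FixtureBundle(
        sequences=sequences, tree=tree, subject_map=subject_map, leaf_taxids=leaf_taxids
    )
    if outdir is not None:
        write_fixture(bundle, outdir)
    return bundle


def default_community_spec(
    n_reads: int = 50_000,
    read_length: int = 50,
    error_rate: float = 0.01,
    seed: int = 0,
    bundle: Optional[FixtureBundle] = None,
) -> CommunitySpec:
    """Six-member community at the default proportions, bound to a fixture."""
    if bundle is None:
        bundle = make_reference_fixture(len(DEFAULT_PROPORTIONS), seed=seed,
                                        read_length=read_length)
    sids = sorted(bundle.leaf_taxids)
    if len(sids) != len(DEFAULT_PROPORTIONS):
        raise ValueError(
            f"default proportions need {len(DEFAULT_PROPORTIONS)} taxa, "
            f"fixture has {len(sids)}"
        )
    components = tuple(
        Component(sid, bundle.leaf_taxids[sid], prop)
        for sid, prop in zip(sids, DEFAULT_PROPORTIONS)
    )
    return CommunitySpec(
        components=components,
        n_reads=n_reads,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )


def _quality_char(error_rate: float) -> str:
    if error_rate <= 0.0:
        return "I"  # Phred 40
    phred = int(round(-10.0 * math.log10(error_rate)))
    return chr(33 + min(40, max(2, phred)))


def simulate_reads(
    spec: CommunitySpec,
    reference: Union[Dict[str, str], FixtureBundle],
    out_path: Optional[Union[str, Path]] = None,
    format: str = "fastq",
) -> List[ReadRecord]:
    """Draw labeled error-bearing reads from the community.

    Per read: the source component is drawn with probability equal to its
    proportion, the start uniformly along the genome, the strand by fair
    coin; substitutions hit each base independently at ``error_rate`` and
    always change the base.  The definition line label is the source
    subject id.  Reproducible from ``spec.seed``.
    """
    sequences = reference.sequences if isinstance(reference, FixtureBundle) else reference
    missing = [c.subject_id for c in spec.components if c.subject_id not in sequences]
    if missing:
        raise ValueError(f"reference lacks community subjects: {missing}")
    for comp in spec.components:
        if spec.read_length > len(sequences[comp.subject_id]):
            raise ValueError(
                f"read_length {spec.read_length} exceeds genome "
                f"{comp.subject_id} ({len(sequences[comp.subject_id])} bp)"
            )
    rng = np.random.default_rng(spec.seed)
    props = np.array([c.proportion for c in spec.components])
    arrays = {
        sid: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for sid, seq in sequences.items()
    }
    sources = rng.choice(len(spec.components), size=spec.n_reads, p=props)
    qual = _quality_char(spec.error_rate) * spec.read_length
    length = spec.read_length
    records: List[ReadRecord] = []
    for idx in range(spec.n_reads):
        comp = spec.components[int(sources[idx])]
        genome = arrays[comp.subject_id]
        start = int(rng.integers(0, len(genome) - length + 1))
        window = genome[start : start + length].copy()
        if int(rng.integers(0, 2)):
            seq = reverse_complement(window.tobytes().decode("ascii"))
            window = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        n_err = int(rng.binomial(length, spec.error_rate)) if spec.error_rate > 0 else 0
        if n_err:
            positions = rng.choice(length, size=n_err, replace=False)
            for pos in positions:
                choices = BASES[BASES != window[pos]]
                window[pos] = choices[int(rng.integers(0, 3))]
        records.append(
            ReadRecord(
                read_id=f"read{idx:07d}",
                sequence=window.tobytes().decode("ascii"),
                qualities=qual if format == "fastq" else None,
                source_label=comp.subject_id,
            )
        )
    if out_path is not None:
        write_reads(records, out_path, format=format)
    return records


def write_taxdump(tree: TaxonomyTree, outdir: Union[str, Path]) -> Tuple[Path, Path]:
    """Write the tree as taxdump-dialect nodes.dmp / names.dmp."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes_path = outdir / "nodes.dmp"
    names_path = outdir / "names.dmp"
    with open(nodes_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            node = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{node.parent_taxid}\t|\t{node.rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            node = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{node.scientific_name}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


def write_fixture(bundle: FixtureBundle, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write reference FASTA, taxdump files, and the subject map as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fasta"
    with open(fasta, "w") as fh:
        for sid in sorted(bundle.sequences):
            fh.write(f">{sid}\n{bundle.sequences[sid]}\n")
    nodes_path, names_path = write_taxdump(bundle.tree, outdir)
    tsv = outdir / "subject_map.tsv"
    with open(tsv, "w") as fh:
        for sid in sorted(bundle.subject_map.mapping):
            fh.write(f"{sid}\t{bundle.subject_map.mapping[sid]}\n")
    bundle.paths = {
        "reference": fasta,
        "nodes": nodes_path,
        "names": names_path,
        "subject_map": tsv,
    }
    return bundle.paths
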
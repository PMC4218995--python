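"""The census engine: iterate, subsample, align, tally, filter, report.

One *census iteration* draws ``m`` reads (without replacement within the
iteration), maps each to its best reference hit, resolves hits to tax ids,
projects them onto the tax slim at the configured depth, and tallies reads
per slim node; reads with no qualifying hit count as *unaligned* and hits
whose subject has no taxid mapping count as *unresolved*, so every
iteration's tallies sum exactly to ``m``.

After ``i`` independent iterations, a slim node is *retained* only if it
was present (>= 1 read) in strictly more than ``p * i`` iterations — the
same strict boundary the design calculator uses.  Abundance statistics
(min/max/mean/median/sd and a normal-approximation 95% interval, truncated
to [0, 1]) are computed over all ``i`` per-iteration fractions, zeros
included for iterations where the node was absent: this matches the pooled
estimator whose error the design module quantifies.

Iteration seeds derive from ``(config.seed, iteration_index)`` through a
stable cryptographic hash, so results are independent of execution order
and fully reproducible from the configuration alone.

For clinical-style samples an optional host-depletion step maps every read
to a host genome first and runs the census on the unaligned remainder.
"""

from __future__ import annotations

import hashlib
import json
import statistics
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .aligner import AlignerParams, ReferenceIndex, align_best_hit, host_filter
from .design import Z_95, retention_threshold
from .seqio import ReadIndex, SampleSizeError, index_reads, iter_reads, pick_reads, write_reads
from .taxonomy import UNMAPPED, SubjectTaxMap, TaxonomyTree, slim_project

__all__ = [
    "CensusConfig",
    "IterationProfile",
    "NodeStats",
    "CensusResult",
    "AlignerBundle",
    "TaxonomyBundle",
    "iteration_seed",
    "run_iteration",
    "aggregate",
    "run_census",
    "write_reports",
]

REPORT_FILES = (
    "log.txt",
    "gi_centric_table.csv",
    "tax_centric_table.csv",
    "taxslim_centric_table.csv",
)


@dataclass(frozen=True)
class CensusConfig:
    """Run parameters: reads per iteration m, iterations i, presence
    threshold p, slim depth, master seed, host-filter switch."""

    m: int
    i: int
    p: float = 0.8
    depth: int = 3
    seed: int = 0
    host_filter_enabled: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.i < 1:
            raise ValueError(f"i must be >= 1, got {self.i}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


@dataclass(frozen=True)
class AlignerBundle:
    reference: ReferenceIndex
    params: AlignerParams = AlignerParams()
    backend: str = "naive"


@dataclass(frozen=True)
class TaxonomyBundle:
    tree: TaxonomyTree
    subject_map: SubjectTaxMap


@dataclass
class IterationProfile:
    """Per-iteration tallies; counts + unaligned + unresolved == m."""

    iteration_index: int
    counts: Dict[int, int]
    unaligned: int
    unresolved: int
    m: int
    subject_counts: Dict[str, int] = field(default_factory=dict)
    leaf_counts: Dict[int, int] = field(default_factory=dict)
    subject_taxids: Dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        total = sum(self.counts.values()) + self.unaligned + self.unresolved
        if total != self.m:
            raise AssertionError(
                f"iteration {self.iteration_index}: tallies sum to {total}, expected m={self.m}"
            )


@dataclass
class NodeStats:
    """Presence and abundance statistics for one slim node (or sentinel)."""

    taxid: Union[int, str]
    name: str
    presence_count: int
    fractions: List[float]
    minimum: float
    maximum: float
    mean: float
    median: float
    sd: float
    ci_low: float
    ci_high: float
    retained: bool


@dataclass
class CensusResult:
    """Aggregated census output across all iterations."""

    nodes: Dict[int, NodeStats]
    unaligned: NodeStats
    unresolved: NodeStats
    iterations: int
    m: int
    p: float
    config: Optional[CensusConfig] = None
    subject_rows: List[dict] = field(default_factory=list)
    leaf_rows: List[dict] = field(default_factory=list)
    host_removed_fraction: Optional[float] = None
    notes: List[str] = field(default_factory=list)

    def retained_taxids(self) -> List[int]:
        return sorted(t for t, s in self.nodes.items() if s.retained)

    def to_json(self) -> str:
        """Deterministic serialization (used by the reproducibility checks)."""

        def node_dict(s: NodeStats) -> dict:
            return {
                "taxid": s.taxid,
                "name": s.name,
                "presence_count": s.presence_count,
                "fractions": [round(f, 12) for f in s.fractions],
                "min": round(s.minimum, 12),
                "max": round(s.maximum, 12),
                "mean": round(s.mean, 12),
                "median": round(s.median, 12),
                "sd": round(s.sd, 12),
                "ci_low": round(s.ci_low, 12),
                "ci_high": round(s.ci_high, 12),
                "retained": s.retained,
            }

        payload = {
            "config": None if self.config is None else {
                "m": self.config.m,
                "i": self.config.i,
                "p": self.config.p,
                "depth": self.config.depth,
                "seed": self.config.seed,
                "host_filter_enabled": self.config.host_filter_enabled,
            },
            "nodes": {str(t): node_dict(s) for t, s in sorted(self.nodes.items())},
            "unaligned": node_dict(self.unaligned),
            "unresolved": node_dict(self.unresolved),
            "host_removed_fraction": self.host_removed_fraction,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def iteration_seed(master_seed: int, iteration_index: int) -> int:
    """Stable per-iteration seed: blake2b of "seed:index", reduced below 2^31."""
    digest = hashlib.blake2b(
        f"{master_seed}:{iteration_index}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def run_iteration(
    read_index: ReadIndex,
    aligner_bundle: AlignerBundle,
    taxonomy_bundle: TaxonomyBundle,
    config: CensusConfig,
    iteration_index: int,
) -> IterationProfile:
    """One census iteration: subsample, align, resolve, project, tally."""
    seed = iteration_seed(config.seed, iteration_index)
    reads = pick_reads(read_index, config.m, seed, replacement=False)
    hits = align_best_hit(
        reads,
        aligner_bundle.reference,
        aligner_bundle.params,
        backend=aligner_bundle.backend,
        subject_map=taxonomy_bundle.subject_map,
    )
    counts: Dict[int, int] = {}
    subject_counts: Dict[str, int] = {}
    leaf_counts: Dict[int, int] = {}
    subject_taxids: Dict[str, int] = {}
    unaligned = 0
    unresolved = 0
    for read in reads:
        hit = hits.get(read.read_id)
        if hit is None:
            unaligned += 1
            continue
        subject_counts[hit.subject_id] = subject_counts.get(hit.subject_id, 0) + 1
        subject_taxids[hit.subject_id] = hit.taxid
        if hit.taxid == UNMAPPED:
            unresolved += 1
            continue
        leaf_counts[hit.taxid] = leaf_counts.get(hit.taxid, 0) + 1
        slim = slim_project(taxonomy_bundle.tree, hit.taxid, config.depth)
        counts[slim] = counts.get(slim, 0) + 1
    profile = IterationProfile(
        iteration_index=iteration_index,
        counts=counts,
        unaligned=unaligned,
        unresolved=unresolved,
        m=config.m,
        subject_counts=subject_counts,
        leaf_counts=leaf_counts,
        subject_taxids=subject_taxids,
    )
    profile.check_conservation()
    return profile


def _stats_from_fractions(
    taxid: Union[int, str],
    name: str,
    fractions: List[float],
    presence_count: int,
    threshold: float,
) -> NodeStats:
    arr = np.asarray(fractions, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return NodeStats(
        taxid=taxid,
        name=name,
        presence_count=presence_count,
        fractions=fractions,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=mean,
        median=float(statistics.median(fractions)),
        sd=sd,
        ci_low=max(0.0, mean - Z_95 * sd),
        ci_high=min(1.0, mean + Z_95 * sd),
        retained=presence_count > threshold,
    )


def aggregate(
    profiles: List[IterationProfile],
    p: float,
    tree: Optional[TaxonomyTree] = None,
) -> CensusResult:
    """Combine iteration profiles into filtered abundance statistics.

    Statistics run over all ``i`` per-iteration fractions (zeros included
    for absent iterations); a node is retained iff its presence count
    strictly exceeds ``p * i``.
    """
    if not profiles:
        raise ValueError("aggregate needs at least one iteration profile")
    ms = {prof.m for prof in profiles}
    if len(ms) != 1:
        raise ValueError(f"iteration profiles disagree on m: {sorted(ms)}")
    m = ms.pop()
    i = len(profiles)
    threshold = retention_threshold(p, i)

    all_nodes = sorted({t for prof in profiles for t in prof.counts})
    nodes: Dict[int, NodeStats] = {}
    for taxid in all_nodes:
        fractions = [prof.counts.get(taxid, 0) / m for prof in profiles]
        presence = sum(1 for prof in profiles if prof.counts.get(taxid, 0) >= 1)
        name = tree.name(taxid) if tree is not None else ""
        nodes[taxid] = _stats_from_fractions(taxid, name, fractions, presence, threshold)

    unaligned_fr = [prof.unaligned / m for prof in profiles]
    unresolved_fr = [prof.unresolved / m for prof in profiles]
    unaligned = _stats_from_fractions(
        "unaligned", "unaligned reads", unaligned_fr,
        sum(1 for prof in profiles if prof.unaligned >= 1), threshold,
    )
    unresolved = _stats_from_fractions(
        "unresolved", "hits without taxid mapping", unresolved_fr,
        sum(1 for prof in profiles if prof.unresolved >= 1), threshold,
    )

    # Subject- and leaf-level tallies for the hit-centric report tables.
    subject_totals: Dict[str, int] = {}
    subject_iters: Dict[str, int] = {}
    subject_taxids: Dict[str, int] = {}
    leaf_totals: Dict[int, int] = {}
    leaf_iters: Dict[int, int] = {}
    for prof in profiles:
        for sid, count in prof.subject_counts.items():
            subject_totals[sid] = subject_totals.get(sid, 0) + count
            subject_iters[sid] = subject_iters.get(sid, 0) + 1
            subject_taxids[sid] = prof.subject_taxids.get(sid, UNMAPPED)
        for taxid, count in prof.leaf_counts.items():
            leaf_totals[taxid] = leaf_totals.get(taxid, 0) + count
            leaf_iters[taxid] = leaf_iters.get(taxid, 0) + 1

    subject_rows = [
        {
            "subject_id": sid,
            "taxid": subject_taxids[sid],
            "total_hits": subject_totals[sid],
            "iterations_hit": subject_iters[sid],
        }
        for sid in sorted(subject_totals)
    ]
    leaf_rows = [
        {
            "taxid": taxid,
            "name": tree.name(taxid) if tree is not None else "",
            "total_hits": leaf_totals[taxid],
            "iterations_hit": leaf_iters[taxid],
        }
        for taxid in sorted(leaf_totals)
    ]
    return CensusResult(
        nodes=nodes,
        unaligned=unaligned,
        unresolved=unresolved,
        iterations=i,
        m=m,
        p=p,
        subject_rows=subject_rows,
        leaf_rows=leaf_rows,
    )


def run_census(
    config: CensusConfig,
    reads_path: Union[str, Path],
    reference: ReferenceIndex,
    taxonomy: TaxonomyTree,
    subject_map: SubjectTaxMap,
    host_reference: Optional[ReferenceIndex] = None,
    backend: str = "naive",
    params: AlignerParams = AlignerParams(),
) -> CensusResult:
    """End-to-end census on a reads file; deterministic for a fixed seed.

    With host filtering enabled, every read is first mapped to the host
    genome and the census runs on the unaligned remainder only; the removed
    fraction is recorded on the result and echoed in ``log.txt``.
    """
    read_index = index_reads(reads_path)
    notes: List[str] = []
    host_removed: Optional[float] = None

    with tempfile.TemporaryDirectory(prefix="readcensus_") as tmp:
        if config.host_filter_enabled:
            if host_reference is None:
                raise ValueError("host_filter_enabled requires a host reference")
            all_reads = list(iter_reads(read_index))
            host_reads, rest = host_filter(all_reads, host_reference, backend=backend)
            total = len(all_reads)
            host_removed = len(host_reads) / total if total else 0.0
            notes.append(
                f"host filter removed {len(host_reads)}/{total} reads "
                f"({100.0 * host_removed:.2f}%)"
            )
            if len(rest) < config.m:
                raise SampleSizeError(
                    f"only {len(rest)} reads remain after host filtering but "
                    f"m={config.m}; rerun with a smaller subsample size"
                )
            filtered_path = Path(tmp) / "non_host.fastq"
            write_reads(rest, filtered_path, format="fastq")
            read_index = index_reads(filtered_path)

        if read_index.total_reads < config.m:
            raise SampleSizeError(
                f"dataset has {read_index.total_reads} reads but m={config.m}; "
                "rerun with a smaller subsample size"
            )
        aligner_bundle = AlignerBundle(reference=reference, params=params, backend=backend)
        taxonomy_bundle = TaxonomyBundle(tree=taxonomy, subject_map=subject_map)
        profiles = [
            run_iteration(read_index, aligner_bundle, taxonomy_bundle, config, j)
            for j in range(config.i)
        ]

    result = aggregate(profiles, config.p, tree=taxonomy)
    result.config = config
    result.host_removed_fraction = host_removed
    result.notes = notes
    return result


def _percent_table(result: CensusResult) -> pd.DataFrame:
    rows = []
    ordered = [result.nodes[t] for t in sorted(result.nodes)]
    ordered += [result.unaligned, result.unresolved]
    for s in ordered:
        rows.append(
            {
                "slim_taxid": s.taxid,
                "name": s.name,
                "presence_count": s.presence_count,
                "mean_pct": 100.0 * s.mean,
                "median_pct": 100.0 * s.median,
                "min_pct": 100.0 * s.minimum,
                "max_pct": 100.0 * s.maximum,
                "sd_pct": 100.0 * s.sd,
                "ci_low_pct": 100.0 * s.ci_low,
                "ci_high_pct": 100.0 * s.ci_high,
                "retained": s.retained,
            }
        )
    return pd.DataFrame(rows)


def write_reports(
    result: CensusResult,
    outdir: Union[str, Path],
    manifest: Optional[dict] = None,
) -> List[Path]:
    """Write the four report files (plus a JSON export of the slim table).

    ``log.txt`` echoes every parameter; ``gi_centric_table.csv`` is sorted
    by subject id, ``tax_centric_table.csv`` by leaf-most taxid, and
    ``taxslim_centric_table.csv`` by slim node with the unaligned and
    unresolved categories as their own trailing rows.  Byte-identical
    across repeated runs with the same seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    log_path = outdir / "log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"readcensus {__version__}\n")
        if result.config is not None:
            c = result.config
            fh.write(
                f"parameters: m={c.m} i={c.i} p={c.p} depth={c.depth} "
                f"seed={c.seed} host_filter={c.host_filter_enabled}\n"
            )
        else:
            fh.write(f"parameters: m={result.m} i={result.iterations} p={result.p}\n")
        fh.write(
            "confidence interval: normal approximation, mean +/- 1.96*sd over "
            "iteration fractions, truncated to [0, 1]\n"
        )
        fh.write(
            "FASTQ written from quality-less records uses placeholder quality 'I'\n"
        )
        if result.host_removed_fraction is not None:
            fh.write(f"host_removed_fraction: {result.host_removed_fraction:.6f}\n")
        for note in result.notes:
            fh.write(f"note: {note}\n")
        if manifest is not None:
            fh.write("manifest:\n")
            fh.write(json.dumps(manifest, sort_keys=True, indent=1, default=str))
            fh.write("\n")
    written.append(log_path)

    gi = pd.DataFrame(
        result.subject_rows,
        columns=["subject_id", "taxid", "total_hits", "iterations_hit"],
    )
    gi_path = outdir / "gi_centric_table.csv"
    gi.to_csv(gi_path, index=False)
    written.append(gi_path)

    tax = pd.DataFrame(
        result.leaf_rows, columns=["taxid", "name", "total_hits", "iterations_hit"]
    )
    tax_path = outdir / "tax_centric_table.csv"
    tax.to_csv(tax_path, index=False)
    written.append(tax_path)

    slim = _percent_table(result)
    slim_path = outdir / "taxslim_centric_table.csv"
    slim.to_csv(slim_path, index=False, float_format="%.6f")
    written.append(slim_path)

    json_path = outdir / "taxslim_centric_table.json"
    with open(json_path, "w") as fh:
        fh.write(result.to_json())
        fh.write("\n")
    written.append(json_path)
    return written
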
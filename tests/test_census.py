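"""Census engine: iteration tallies, aggregation/filtering, reports,
reproducibility."""

import math

import numpy as np
import pytest

from readcensus.aligner import AlignerParams, ReferenceIndex
from readcensus.census import (
    AlignerBundle,
    CensusConfig,
    IterationProfile,
    TaxonomyBundle,
    aggregate,
    iteration_seed,
    run_census,
    run_iteration,
    write_reports,
)
from readcensus.seqio import ReadRecord, SampleSizeError, index_reads, write_reads
from readcensus.synthdata import (
    CommunitySpec,
    Component,
    make_reference_fixture,
    simulate_reads,
)


def _profile(j, counts, m, unaligned=0, unresolved=0):
    return IterationProfile(
        iteration_index=j, counts=counts, unaligned=unaligned,
        unresolved=unresolved, m=m,
    )


class TestAggregate:
    def test_direct_arithmetic(self):
        """Node present in all 5 iterations: stats match hand arithmetic."""
        m = 20
        fractions = [0.4, 0.5, 0.45, 0.5, 0.4]
        profiles = [
            _profile(j, {7: int(f * m)}, m, unaligned=m - int(f * m))
            for j, f in enumerate(fractions)
        ]
        result = aggregate(profiles, p=0.8)
        stats = result.nodes[7]
        assert stats.retained
        assert stats.presence_count == 5
        assert stats.mean == pytest.approx(0.45)
        assert stats.median == pytest.approx(0.45)
        assert stats.minimum == pytest.approx(0.4)
        assert stats.maximum == pytest.approx(0.5)

    def test_strict_boundary_four_of_five_is_filtered(self):
        """presence 4 of i=5 at p=0.8: 4 > 4 is false, so the node is dropped."""
        m = 10
        profiles = [_profile(j, {7: 1} if j < 4 else {}, m, unaligned=m - (j < 4)) for j in range(5)]
        result = aggregate(profiles, p=0.8)
        assert result.nodes[7].presence_count == 4
        assert not result.nodes[7].retained

    def test_absent_iterations_contribute_zero_fractions(self):
        m = 10
        profiles = [_profile(0, {5: 10}, m), _profile(1, {}, m, unaligned=10)]
        stats = aggregate(profiles, p=0.0).nodes[5]
        assert stats.fractions == [1.0, 0.0]
        assert stats.mean == pytest.approx(0.5)
        assert stats.minimum == 0.0

    def test_retained_set_matches_brute_force_recount(self):
        """Random count matrices: retention equals an independent recount."""
        rng = np.random.default_rng(17)
        m, i, p = 30, 12, 0.6
        taxa = list(range(100, 108))
        matrix = rng.integers(0, 3, size=(i, len(taxa)))
        profiles = []
        for j in range(i):
            counts = {t: int(c) for t, c in zip(taxa, matrix[j]) if c > 0}
            profiles.append(_profile(j, counts, m, unaligned=m - int(matrix[j].sum())))
        result = aggregate(profiles, p=p)
        for k, taxid in enumerate(taxa):
            presences = int(np.count_nonzero(matrix[:, k]))
            expected = presences > p * i
            observed = taxid in result.nodes and result.nodes[taxid].retained
            assert observed == expected

    def test_filter_monotone_in_p(self):
        rng = np.random.default_rng(23)
        m, i = 25, 10
        profiles = []
        for j in range(i):
            counts = {t: int(c) for t, c in zip(range(5), rng.integers(0, 2, 5)) if c}
            profiles.append(_profile(j, counts, m, unaligned=m - sum(counts.values())))
        sizes = [
            len([t for t, s in aggregate(profiles, p=p).nodes.items() if s.retained])
            for p in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_profile_list_is_error(self):
        with pytest.raises(ValueError):
            aggregate([], p=0.8)


@pytest.fixture(scope="module")
def single_subject(tmp_path_factory):
    bundle = make_reference_fixture(1, genome_length=500, seed=41)
    sid = next(iter(bundle.sequences))
    reads = [
        ReadRecord(f"r{k}", bundle.sequences[sid][k : k + 50]) for k in range(40)
    ]
    path = tmp_path_factory.mktemp("single") / "reads.fasta"
    write_reads(reads, path, format="fasta")
    return bundle, index_reads(path)


class TestRunIteration:
    def test_all_exact_copies_tally_to_one_node(self, single_subject):
        bundle, index = single_subject
        config = CensusConfig(m=20, i=1, seed=1)
        profile = run_iteration(
            index,
            AlignerBundle(ReferenceIndex(bundle.sequences)),
            TaxonomyBundle(bundle.tree, bundle.subject_map),
            config,
            0,
        )
        assert profile.unaligned == 0 and profile.unresolved == 0
        assert list(profile.counts.values()) == [20]

    def test_random_reads_all_unaligned(self, single_subject, tmp_path):
        bundle, _ = single_subject
        rng = np.random.default_rng(3)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        reads = [
            ReadRecord(f"x{k}", rng.choice(bases, size=50).tobytes().decode())
            for k in range(30)
        ]
        path = tmp_path / "random.fasta"
        write_reads(reads, path, format="fasta")
        config = CensusConfig(m=30, i=1, seed=1)
        profile = run_iteration(
            index_reads(path),
            AlignerBundle(ReferenceIndex(bundle.sequences)),
            TaxonomyBundle(bundle.tree, bundle.subject_map),
            config,
            0,
        )
        assert profile.unaligned == 30
        assert profile.counts == {}

    def test_two_taxon_balanced_community_within_binomial_noise(self, tmp_path):
        """50/50 mixture, m=200: counts within 4 sd of 100 (sd ~ 7.1)."""
        bundle = make_reference_fixture(2, genome_length=2000, seed=42)
        sids = sorted(bundle.sequences)
        spec = CommunitySpec(
            components=tuple(
                Component(sid, bundle.leaf_taxids[sid], 0.5) for sid in sids
            ),
            n_reads=4000,
            error_rate=0.0,
            seed=6,
        )
        path = tmp_path / "balanced.fastq"
        simulate_reads(spec, bundle, out_path=path)
        config = CensusConfig(m=200, i=1, depth=4, seed=5)
        profile = run_iteration(
            index_reads(path),
            AlignerBundle(ReferenceIndex(bundle.sequences)),
            TaxonomyBundle(bundle.tree, bundle.subject_map),
            config,
            0,
        )
        sd = math.sqrt(200 * 0.25)
        for count in profile.counts.values():
            assert abs(count - 100) <= 4 * sd

    def test_conservation_invariant(self, single_subject):
        bundle, index = single_subject
        config = CensusConfig(m=15, i=3, seed=9)
        for j in range(config.i):
            profile = run_iteration(
                index,
                AlignerBundle(ReferenceIndex(bundle.sequences)),
                TaxonomyBundle(bundle.tree, bundle.subject_map),
                config,
                j,
            )
            total = sum(profile.counts.values()) + profile.unaligned + profile.unresolved
            assert total == config.m

    def test_iteration_seeds_are_distinct_and_stable(self):
        seeds = [iteration_seed(123, j) for j in range(100)]
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2**31 for s in seeds)
        assert seeds == [iteration_seed(123, j) for j in range(100)]


class TestRunCensus:
    def test_host_filtered_microbe_fraction(self, tmp_path):
        """99% host + 1% microbe: after depletion the microbe dominates."""
        bundle = make_reference_fixture(2, genome_length=2000, seed=43)
        host_sid, microbe_sid = sorted(bundle.sequences)
        spec = CommunitySpec(
            components=(
                Component(host_sid, bundle.leaf_taxids[host_sid], 0.99),
                Component(microbe_sid, bundle.leaf_taxids[microbe_sid], 0.01),
            ),
            n_reads=5000,
            error_rate=0.01,
            seed=12,
        )
        path = tmp_path / "clinical.fastq"
        simulate_reads(spec, bundle, out_path=path)
        microbe_ref = ReferenceIndex({microbe_sid: bundle.sequences[microbe_sid]})
        host_ref = ReferenceIndex({host_sid: bundle.sequences[host_sid]})
        config = CensusConfig(m=20, i=10, seed=7, host_filter_enabled=True)
        result = run_census(
            config, path, microbe_ref, bundle.tree, bundle.subject_map,
            host_reference=host_ref,
        )
        assert result.host_removed_fraction == pytest.approx(0.99, abs=0.01)
        microbe_slim = [s for s in result.nodes.values() if s.retained]
        assert len(microbe_slim) == 1
        assert microbe_slim[0].mean > 0.9  # nearly all of the remainder

    def test_host_filter_off_is_noop_branch(self, tmp_path, reads_path, bundle):
        config = CensusConfig(m=50, i=5, seed=3)
        ref = ReferenceIndex(bundle.sequences)
        with_off = run_census(config, reads_path, ref, bundle.tree, bundle.subject_map)
        again = run_census(
            config, reads_path, ref, bundle.tree, bundle.subject_map,
            host_reference=None,
        )
        assert with_off.to_json() == again.to_json()

    def test_same_seed_byte_identical_serialization(self, reads_path, bundle):
        config = CensusConfig(m=60, i=6, seed=101)
        ref = ReferenceIndex(bundle.sequences)
        first = run_census(config, reads_path, ref, bundle.tree, bundle.subject_map)
        second = run_census(config, reads_path, ref, bundle.tree, bundle.subject_map)
        assert first.to_json() == second.to_json()

    def test_too_few_reads_after_filtering(self, tmp_path):
        bundle = make_reference_fixture(1, genome_length=500, seed=44)
        sid = next(iter(bundle.sequences))
        reads = [ReadRecord(f"r{k}", bundle.sequences[sid][k : k + 50]) for k in range(5)]
        path = tmp_path / "tiny.fasta"
        write_reads(reads, path, format="fasta")
        config = CensusConfig(m=10, i=2, seed=1)
        with pytest.raises(SampleSizeError, match="smaller"):
            run_census(
                config, path, ReferenceIndex(bundle.sequences),
                bundle.tree, bundle.subject_map,
            )


class TestReports:
    def _small_result(self, reads_path, bundle, seed=55):
        config = CensusConfig(m=40, i=4, seed=seed)
        return run_census(
            config, reads_path, ReferenceIndex(bundle.sequences),
            bundle.tree, bundle.subject_map,
        )

    def test_four_report_files_written(self, tmp_path, reads_path, bundle):
        result = self._small_result(reads_path, bundle)
        write_reports(result, tmp_path)
        for name in (
            "log.txt",
            "gi_centric_table.csv",
            "tax_centric_table.csv",
            "taxslim_centric_table.csv",
            "taxslim_centric_table.json",
        ):
            assert (tmp_path / name).exists()
        log = (tmp_path / "log.txt").read_text()
        for token in ("m=40", "i=4", "p=0.8", "depth=3", "seed=55"):
            assert token in log

    def test_empty_result_tables_have_header_only(self, tmp_path):
        profiles = [_profile(0, {}, 5, unaligned=5)]
        result = aggregate(profiles, p=0.8)
        write_reports(result, tmp_path)
        gi = (tmp_path / "gi_centric_table.csv").read_text().splitlines()
        assert gi == ["subject_id,taxid,total_hits,iterations_hit"]

    def test_reports_byte_identical_across_repeated_runs(self, tmp_path, reads_path, bundle):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_reports(self._small_result(reads_path, bundle), out1)
        write_reports(self._small_result(reads_path, bundle), out2)
        for name in ("gi_centric_table.csv", "tax_centric_table.csv",
                     "taxslim_centric_table.csv", "taxslim_centric_table.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_config_validation():
    with pytest.raises(ValueError):
        CensusConfig(m=0, i=1)
    with pytest.raises(ValueError):
        CensusConfig(m=1, i=1, p=1.5)
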
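"""Shared fixtures: a small synthetic community, its reads file, and indexes."""

from pathlib import Path

import pytest

from readcensus.aligner import ReferenceIndex
from readcensus.seqio import write_reads
from readcensus.synthdata import (
    default_community_spec,
    make_reference_fixture,
    simulate_reads,
)


@pytest.fixture(scope="session")
def bundle():
    """Six separated toy genomes with a four-level taxonomy."""
    return make_reference_fixture(6, seed=11)


@pytest.fixture(scope="session")
def community_spec(bundle):
    """Default six-member mixture (0.50/0.20/0.20/0.07/0.02/0.01), 20k reads."""
    return default_community_spec(n_reads=20_000, seed=11, bundle=bundle)


@pytest.fixture(scope="session")
def community_reads(community_spec, bundle):
    return simulate_reads(community_spec, bundle)


@pytest.fixture(scope="session")
def reads_path(community_reads, tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("reads") / "community.fastq"
    write_reads(community_reads, path, format="fastq")
    return path


@pytest.fixture(scope="session")
def reference_index(bundle) -> ReferenceIndex:
    return ReferenceIndex(bundle.sequences)
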
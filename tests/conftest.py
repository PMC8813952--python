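"""Shared fixtures: a small synthetic cohort with simulated reads.

The read-backed fixtures are session-scoped because BAM simulation is the
expensive part; tests treat them as read-only.
"""

from __future__ import annotations

import os

import pysam
import pytest

from mosaicbench import SimConfig
from mosaicbench.insilico_mix import ReadSource
from mosaicbench.synthetic_data import (
    make_reference,
    make_sample_genotypes,
    simulate_reads,
    write_fasta,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(
        genome_length=30_000,
        n_samples=3,
        unique_per_sample=12,
        shared_germline=8,
        indel_fraction=0.25,
        depth=150.0,
        seed=20260515,
    )


@pytest.fixture(scope="session")
def reference(sim_config) -> str:
    return make_reference(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config, reference):
    return make_sample_genotypes(sim_config, reference)


@pytest.fixture(scope="session")
def work_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("bams")


@pytest.fixture(scope="session")
def reference_fasta(work_dir, sim_config, reference):
    path = write_fasta(str(work_dir / "reference.fa"), sim_config.chrom, reference)
    return pysam.FastaFile(path)


@pytest.fixture(scope="session")
def sample_bams(work_dir, sim_config, reference, cohort) -> dict[str, str]:
    """One coordinate-sorted BAM per cohort sample at the config depth."""
    paths = {}
    for sid in cohort.sample_ids:
        paths[sid] = simulate_reads(
            reference,
            cohort.truth[sid],
            sim_config,
            str(work_dir / f"{sid}.bam"),
            sample_id=sid,
        )
    return paths


@pytest.fixture(scope="session")
def read_sources(sample_bams) -> dict[str, ReadSource]:
    return {sid: ReadSource(sid, path) for sid, path in sample_bams.items()}
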
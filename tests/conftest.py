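"""Shared fixtures: small references and seeded simulated libraries."""

from __future__ import annotations

import pytest

from ampliscan import (
    AmpliconArchitecture,
    ReadProfile,
    build_reference,
    homozygote,
    project_alignments,
    simulate_read_pairs,
    window_counts,
)


TOY_CHROM = "chr"


@pytest.fixture(scope="session")
def toy_ref():
    """200 kb single-chromosome reference used across the genomic tests."""
    return build_reference(42, {TOY_CHROM: 200_000})


@pytest.fixture(scope="session")
def toy_arch_dd():
    """Two tandem copies of a 40 kb unit: the heterogeneous-duplication shape."""
    return AmpliconArchitecture(TOY_CHROM, 80_000, 120_000, 2, label="D")


@pytest.fixture(scope="session")
def toy_arch_ss():
    return AmpliconArchitecture(TOY_CHROM, 80_000, 120_000, 1, label="S")


def simulate_library(ref, arch, seed, coverage=30.0, error_rate=0.0,
                     read_length=100, insert_mean=250, insert_sd=25.0):
    """Simulate a homozygous library and return its projected records."""
    profile = ReadProfile(
        read_length=read_length,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        error_rate=error_rate,
        coverage=coverage,
        seed=seed,
    )
    sim = simulate_read_pairs(homozygote(ref, arch), profile)
    return list(project_alignments(sim))


@pytest.fixture(scope="session")
def dd_records(toy_ref, toy_arch_dd):
    return simulate_library(toy_ref, toy_arch_dd, seed=101)


@pytest.fixture(scope="session")
def ss_records(toy_ref, toy_arch_ss):
    return simulate_library(toy_ref, toy_arch_ss, seed=102)


@pytest.fixture(scope="session")
def dd_track(toy_ref, dd_records):
    return window_counts(dd_records, toy_ref.lengths)[TOY_CHROM]


@pytest.fixture(scope="session")
def ss_track(toy_ref, ss_records):
    return window_counts(ss_records, toy_ref.lengths)[TOY_CHROM]
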
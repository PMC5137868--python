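"""Tests of the synthetic-data generator: haplotype construction, read
simulation, oracle alignment projection, and the assay simulators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampliscan import (
    AmpliconArchitecture,
    DiploidGenotype,
    ReadProfile,
    build_haplotype,
    build_reference,
    homozygote,
    project_alignments,
    simulate_activities,
    simulate_bioassay,
    simulate_qpcr,
    simulate_read_pairs,
)
from ampliscan.simulate import NoiseModel, ReadSimulation


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def test_reference_is_deterministic_and_validated():
    a = build_reference(1, {"chr": 1000})
    b = build_reference(1, {"chr": 1000})
    c = build_reference(2, {"chr": 1000})
    assert a["chr"] == b["chr"]
    assert a["chr"] != c["chr"]
    assert len(a["chr"]) == 1000
    assert set(a["chr"]) <= set("ACGT")
    with pytest.raises(ValueError):
        build_reference(1, {"chr": 0})


# ---------------------------------------------------------------------------
# haplotype construction
# ---------------------------------------------------------------------------

def test_single_copy_haplotype_is_identity(toy_ref, toy_arch_ss):
    hap = build_haplotype(toy_ref, toy_arch_ss)
    assert hap.sequence == toy_ref["chr"]


def test_tandem_junction_is_suffix_then_prefix(toy_ref, toy_arch_dd):
    hap = build_haplotype(toy_ref, toy_arch_dd)
    ref = toy_ref["chr"]
    bp5, bp3 = toy_arch_dd.bp5, toy_arch_dd.bp3
    assert len(hap) == len(ref) + (bp3 - bp5)
    junction = bp3  # haplotype coordinate where copy 2 begins
    assert hap.sequence[junction - 30 : junction] == ref[bp3 - 30 : bp3]
    assert hap.sequence[junction : junction + 30] == ref[bp5 : bp5 + 30]


def test_deletion_must_lie_inside_amplicon():
    with pytest.raises(ValueError):
        AmpliconArchitecture("chr", 100, 200, 2, deletions=((0, 50, 150),))
    with pytest.raises(ValueError):
        AmpliconArchitecture("chr", 100, 200, 1, deletions=((0, 120, 130),))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(data=st.data())
def test_haplotype_length_formula_and_roundtrip(data):
    """Length conservation and byte-exact coordinate-map round-trip hold for
    arbitrary valid architectures."""
    ref = build_reference(7, {"chr": 5000})
    bp5 = data.draw(st.integers(0, 3000))
    unit = data.draw(st.integers(10, 1500))
    bp3 = bp5 + unit
    copies = data.draw(st.integers(1, 5))
    deletions = []
    if copies > 1 and unit > 4:
        n_del = data.draw(st.integers(0, min(copies, 3)))
        used = set()
        for _ in range(n_del):
            ci = data.draw(st.integers(0, copies - 1))
            if ci in used:
                continue
            used.add(ci)
            ds = data.draw(st.integers(bp5 + 1, bp3 - 2))
            de = data.draw(st.integers(ds + 1, bp3 - 1))
            deletions.append((ci, ds, de))
    arch = AmpliconArchitecture("chr", bp5, bp3, copies, tuple(deletions))
    hap = build_haplotype(ref, arch)
    deleted = sum(de - ds for _, ds, de in deletions)
    assert len(hap) == 5000 + (copies - 1) * unit - deleted
    rebuilt = "".join(
        ref["chr"][seg.ref_start : seg.ref_end] for seg in hap.segments
    )
    assert rebuilt == hap.sequence


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def test_read_counts_match_coverage_expectation():
    ref = build_reference(3, {"chr": 100_000})
    geno = homozygote(ref, AmpliconArchitecture("chr", 40_000, 60_000, 1))
    sim = simulate_read_pairs(geno, ReadProfile(coverage=30.0, seed=5))
    # 30x over 100 kb at 100 bp reads -> 30e5/100 = 30,000 reads = 15,000 pairs
    assert sim.n_pairs * 2 == pytest.approx(30_000, rel=0.03)


def test_error_free_reads_are_exact_substrings():
    ref = build_reference(3, {"chr": 20_000})
    geno = homozygote(ref, AmpliconArchitecture("chr", 5_000, 8_000, 2))
    sim = simulate_read_pairs(geno, ReadProfile(coverage=10.0, seed=9))
    hap = geno.haplotypes[0].sequence
    for _, seq1, seq2 in sim.read_sequences():
        assert seq1 in hap and seq2 in hap


def test_simulation_is_byte_deterministic():
    ref = build_reference(3, {"chr": 20_000})
    geno = homozygote(ref, AmpliconArchitecture("chr", 5_000, 8_000, 2))
    prof = ReadProfile(coverage=5.0, error_rate=0.01, seed=77)
    a = simulate_read_pairs(geno, prof)
    b = simulate_read_pairs(geno, prof)
    assert list(a.read_sequences()) == list(b.read_sequences())
    assert np.array_equal(a.start, b.start)


def test_substitution_errors_appear_at_requested_rate():
    ref = build_reference(3, {"chr": 50_000})
    geno = homozygote(ref, AmpliconArchitecture("chr", 10_000, 20_000, 1))
    rate = 0.01
    sim = simulate_read_pairs(geno, ReadProfile(coverage=10.0, error_rate=rate, seed=4))
    hap = geno.haplotypes[0].sequence
    mismatches = total = 0
    for i, (_, seq1, seq2) in enumerate(sim.read_sequences()):
        s = int(sim.start[i])
        ins = int(sim.insert[i])
        for seq, true in ((seq1, hap[s : s + 100]), (seq2, hap[s + ins - 100 : s + ins])):
            mismatches += sum(a != b for a, b in zip(seq, true))
            total += len(seq)
    assert mismatches / total == pytest.approx(rate, rel=0.15)


# ---------------------------------------------------------------------------
# oracle projection (hand-computed toy)
# ---------------------------------------------------------------------------

def _toy_simulation(starts, read_length=10, insert=30):
    """A DD-like toy: 200 bp reference, amplicon [50, 70) x 2, reads placed
    by hand so every projection can be verified against string arithmetic."""
    ref = build_reference(11, {"chr": 200})
    geno = homozygote(ref, AmpliconArchitecture("chr", 50, 70, 2))
    profile = ReadProfile(read_length=read_length, insert_mean=insert, insert_sd=0.0,
                          coverage=1.0, seed=0)
    sim = ReadSimulation(
        genotype=geno,
        profile=profile,
        hap_index=np.zeros(len(starts), dtype=np.int8),
        start=np.array(starts, dtype=np.int64),
        insert=np.full(len(starts), insert, dtype=np.int64),
    )
    return ref, geno, sim


def test_projection_matches_hand_computed_coordinates():
    # haplotype: ref[0:70) + ref[50:200) ; junction at haplotype position 70
    ref, geno, sim = _toy_simulation([10, 64, 67, 75], read_length=10, insert=30)
    records = [r for r in project_alignments(sim, min_anchor=4) if r.is_first]
    ref_seq = ref["chr"]

    flank = records[0]  # fully left of the junction: plain match
    assert (flank.pos, flank.cigar) == (10, "10M")
    assert flank.seq == ref_seq[10:20]

    right_clip = records[1]  # 6 bases before the junction, 4 after
    assert (right_clip.pos, right_clip.cigar) == (64, "6M4S")
    assert right_clip.seq[6:] == ref_seq[50:54]  # clip = amplicon prefix

    left_clip = records[2]  # 3 before the junction, 7 after -> anchor on copy 2
    assert (left_clip.pos, left_clip.cigar) == (50, "3S7M")
    assert left_clip.seq[:3] == ref_seq[67:70]  # clip = amplicon suffix

    inside_copy2 = records[3]  # fully inside copy 2: maps into the amplicon
    assert (inside_copy2.pos, inside_copy2.cigar) == (55, "10M")
    assert inside_copy2.seq == ref_seq[55:65]


def test_projection_unmapped_below_min_anchor():
    ref, geno, sim = _toy_simulation([68], read_length=10, insert=30)
    rec = next(r for r in project_alignments(sim, min_anchor=9) if r.is_first)
    assert rec.is_unmapped and rec.cigar == "*"


def test_junction_straddling_pair_is_discordant():
    # read 1 ends before the junction (copy 1), read 2 starts after it (copy 2)
    ref, geno, sim = _toy_simulation([55], read_length=10, insert=30)
    recs = list(project_alignments(sim, min_anchor=4))
    r1, r2 = recs
    assert r1.pos == 55 and r2.pos == 55 + 30 - 10 - 20  # copy 2 offset folds back
    assert abs(r1.tlen) == pytest.approx(20 - 30 + 2 * 10)  # unit - insert + 2L
    assert not (r1.flag & 0x2)  # not proper: span contradicts the insert model


# ---------------------------------------------------------------------------
# qPCR simulator
# ---------------------------------------------------------------------------

def test_qpcr_noise_free_closed_forms():
    plate = simulate_qpcr(
        {"ss": {"ace1": 2.0}, "six": {"ace1": 6.0}},
        {"ace1": 2.0},
        baseline_cq=24.0,
        noise=NoiseModel(0.0),
        replicates=2,
        calibrator="ss",
        seed=1,
    )
    ss_cq = plate.loc[plate["sample"] == "ss", "Cq"].unique()
    six_cq = plate.loc[plate["sample"] == "six", "Cq"].unique()
    assert ss_cq == pytest.approx(24.0)
    assert six_cq == pytest.approx(24.0 - math.log2(3.0))
    # 10-fold dilution steps of log2(10) cycles at E = 2
    std = plate[plate["role"] == "standard"].sort_values("dilution_log10")
    steps = std.groupby("dilution_log10")["Cq"].first().diff().dropna()
    assert np.allclose(steps, -math.log2(10.0))


def test_qpcr_plate_is_deterministic_and_validates_copies():
    kwargs = dict(
        samples={"s": {"ace1": 4.0}}, efficiencies={"ace1": 1.9},
        noise=NoiseModel(0.2), calibrator=None, seed=8,
    )
    assert simulate_qpcr(**kwargs).equals(simulate_qpcr(**kwargs))
    with pytest.raises(ValueError):
        simulate_qpcr({"s": {"ace1": 0.0}}, {"ace1": 2.0})


# ---------------------------------------------------------------------------
# bioassay simulator
# ---------------------------------------------------------------------------

def test_bioassay_mortality_behaviour():
    lc50, slope = 0.27, 4.0
    doses = [lc50 * 10**e for e in (-0.6, -0.3, 0.0, 0.3, 0.6)]
    table = simulate_bioassay(lc50, slope, natural_mortality=0.0, doses=doses,
                              n_per_cup=2000, replicates=2, seed=3)
    by_dose = table[table["dose"] > 0].groupby("dose").apply(
        lambda g: g["dead"].sum() / g["n"].sum(), include_groups=False
    )
    # monotone increasing in dose, ~50% at the LC50
    assert by_dose.is_monotonic_increasing
    assert by_dose.loc[lc50] == pytest.approx(0.5, abs=0.05)
    # controls reflect natural mortality only
    noisy = simulate_bioassay(lc50, slope, natural_mortality=0.1, doses=doses,
                              n_per_cup=5000, replicates=2, seed=3)
    controls = noisy[noisy["dose"] == 0]
    assert controls["dead"].sum() / controls["n"].sum() == pytest.approx(0.1, abs=0.02)
    # determinism
    assert table.equals(
        simulate_bioassay(lc50, slope, 0.0, doses, n_per_cup=2000, replicates=2, seed=3)
    )


# ---------------------------------------------------------------------------
# activity simulator
# ---------------------------------------------------------------------------

def test_activities_are_additive_in_copy_number():
    a_r, a_s = 0.22, 1.0
    r3 = simulate_activities(6, 0, a_r, a_s, sd=0.0, n_individuals=5, genotype="R3R3")
    r5 = simulate_activities(10, 0, a_r, a_s, sd=0.0, n_individuals=5, genotype="R5R5")
    assert np.allclose(r3["A_R"], 6 * a_r)
    assert float(r5["A_R"].mean() / r3["A_R"].mean()) == pytest.approx(10 / 6)
    ss = simulate_activities(0, 2, a_r, a_s, sd=0.0, n_individuals=5, genotype="SS")
    # per-copy resistant activity configured at 0.22 of the susceptible copy
    assert (r3["A_R"].mean() / 6) / (ss["A_TOT"].mean() / 2) == pytest.approx(0.22)
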
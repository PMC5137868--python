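"""Tests of evidence collection, junction resolution and in-silico PCR."""

import numpy as np
import pytest

from ampliscan import (
    AlignmentRecord,
    AmpliconArchitecture,
    build_reference,
    collect_discordant_pairs,
    collect_softclipped,
    insert_size_profile,
    insilico_pcr,
    resolve_junction,
    resolve_junctions,
)
from ampliscan.junction import NoCallError
from ampliscan.simulate import build_haplotype, homozygote

from conftest import TOY_CHROM, simulate_library


def _clip_evidence(records, pairs_from=None, insert_mean=250, insert_sd=25.0):
    evidence = collect_softclipped(records)
    evidence.pairs = collect_discordant_pairs(
        pairs_from if pairs_from is not None else records, insert_mean, insert_sd
    ).pairs
    return evidence


# ---------------------------------------------------------------------------
# soft-clip collection
# ---------------------------------------------------------------------------

def test_softclip_parsing_sides_and_min_clip():
    records = [
        AlignmentRecord("a", 0, "chr", 500, 60, "30S70M", "*", -1, 0, "C" * 100),
        AlignmentRecord("b", 0, "chr", 200, 60, "95M5S", "*", -1, 0, "G" * 100),
        AlignmentRecord("c", 0, "chr", 300, 60, "100M", "*", -1, 0, "T" * 100),
    ]
    clips = collect_softclipped(records, min_clip=10).clips
    assert len(clips) == 1
    clip = clips[0]
    assert clip.side == "left" and clip.boundary == 500 and clip.clip_length == 30


def test_malformed_cigar_names_the_record():
    bad = AlignmentRecord("oops", 0, "chr", 0, 60, "10Q90M", "*", -1, 0, "A" * 100)
    with pytest.raises(ValueError, match="oops"):
        collect_softclipped([bad])


def test_all_match_library_has_no_clips(ss_records):
    assert collect_softclipped(ss_records).clips == []


# ---------------------------------------------------------------------------
# discordant pairs
# ---------------------------------------------------------------------------

def _pair(qname, pos1, pos2, tlen):
    r1 = AlignmentRecord(qname, 0x1 | 0x40 | 0x20, "chr", pos1, 60, "100M",
                         "chr", pos2, tlen, "A" * 100)
    r2 = AlignmentRecord(qname, 0x1 | 0x80 | 0x10, "chr", pos2, 60, "100M",
                         "chr", pos1, -tlen, "A" * 100)
    return [r1, r2]


def test_span_threshold_separates_concordant_from_discordant():
    # outer spans: 300 bp sits inside mean + 4 sd; 200 kb is far outside
    records = _pair("near", 1000, 1200, 300) + _pair("far", 1000, 200_900, 200_000)
    evidence = collect_discordant_pairs(records, insert_mean=250, insert_sd=30, k_sd=4)
    assert [p.qname for p in evidence.pairs] == ["far"]


def test_concordant_simulated_library_yields_no_discordant_pairs(ss_records):
    evidence = collect_discordant_pairs(ss_records, 250, 25)
    assert evidence.pairs == []


def test_discordant_spans_cluster_near_amplicon_length(dd_records, toy_arch_dd):
    evidence = collect_discordant_pairs(dd_records, 250, 25)
    assert evidence.pairs
    unit = toy_arch_dd.unit_length
    # outer template span = unit - insert + 2 * read_length
    expected = unit - 250 + 200
    spans = np.array([p.span for p in evidence.pairs])
    assert abs(np.median(spans) - expected) <= 2 * 25


# ---------------------------------------------------------------------------
# insert-size profile
# ---------------------------------------------------------------------------

def test_insert_profile_modes(ss_records, dd_records, toy_arch_dd):
    region = (toy_arch_dd.bp5 - 1000, toy_arch_dd.bp3 + 1000)
    ss = insert_size_profile(ss_records, region)
    assert ss.modes()[0] == (250 // 200) * 200
    assert max(ss.counts) <= 250 + 10 * 25  # no long-span mass
    dd = insert_size_profile(dd_records, region)
    long_bins = [b for b in dd.counts if b > toy_arch_dd.unit_length // 2]
    assert long_bins  # second mode near the amplicon length
    assert min(abs(b - toy_arch_dd.unit_length) for b in long_bins) <= 1000


# ---------------------------------------------------------------------------
# junction resolution
# ---------------------------------------------------------------------------

def test_junction_recovery_is_exact_on_error_free_library(toy_ref, toy_arch_dd, dd_records):
    call = resolve_junction(_clip_evidence(dd_records), toy_ref)
    assert (call.bp5, call.bp3) == (toy_arch_dd.bp5 + 1, toy_arch_dd.bp3)
    assert call.amplicon_length == toy_arch_dd.unit_length
    assert call.clip_support >= 3 and call.discordant_support > 0
    # consensus equals reference suffix + prefix across the junction
    ref = toy_ref[TOY_CHROM]
    truth = ref[toy_arch_dd.bp3 - 150 : toy_arch_dd.bp3] + ref[toy_arch_dd.bp5 : toy_arch_dd.bp5 + 150]
    assert call.consensus in truth


def test_no_call_on_single_copy_library(toy_ref, ss_records):
    with pytest.raises(NoCallError):
        resolve_junction(_clip_evidence(ss_records), toy_ref)


def test_deletion_junction_resolved_alongside_tandem(toy_ref):
    arch = AmpliconArchitecture(
        TOY_CHROM, 80_000, 120_000, 3, deletions=((1, 90_000, 101_000),), label="R3"
    )
    records = simulate_library(toy_ref, arch, seed=321)
    calls = resolve_junctions(_clip_evidence(records), toy_ref)
    kinds = {c.kind for c in calls}
    assert kinds == {"tandem", "deletion"}
    tandem = next(c for c in calls if c.tandem)
    deletion = next(c for c in calls if not c.tandem)
    assert (tandem.bp5, tandem.bp3) == (80_001, 120_000)
    assert (deletion.bp3, deletion.bp5) == (90_000, 101_001)
    assert deletion.deletion_length == 11_000


def test_random_architecture_oracle_recovery():
    """Breakpoints recovered exactly over random architectures (error-free)."""
    rng = np.random.default_rng(5)
    ref = build_reference(55, {"chr": 200_000})
    for trial in range(10):
        unit = int(rng.integers(5_000, 50_000))
        bp5 = int(rng.integers(10_000, 200_000 - unit - 10_000))
        copies = int(rng.integers(2, 6))
        arch = AmpliconArchitecture("chr", bp5, bp5 + unit, copies)
        records = simulate_library(ref, arch, seed=7000 + trial)
        call = resolve_junction(_clip_evidence(records), ref)
        assert (call.bp5, call.bp3) == (bp5 + 1, bp5 + unit)
        assert call.amplicon_length == unit


def test_breakpoints_robust_to_sequencing_errors(toy_ref, toy_arch_dd):
    """With 0.5% substitution errors at 30x, recovery stays exact in >= 95%
    of replicates and never drifts beyond +/-2 bp (failures are no-calls)."""
    exact = 0
    replicates = 20
    for seed in range(replicates):
        records = simulate_library(toy_ref, toy_arch_dd, seed=5000 + seed, error_rate=0.005)
        try:
            call = resolve_junction(_clip_evidence(records), toy_ref)
        except NoCallError:
            continue
        assert abs(call.bp5 - (toy_arch_dd.bp5 + 1)) <= 2
        assert abs(call.bp3 - toy_arch_dd.bp3) <= 2
        if (call.bp5, call.bp3) == (toy_arch_dd.bp5 + 1, toy_arch_dd.bp3):
            exact += 1
    assert exact / replicates >= 0.95


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def test_junction_primers_amplify_only_duplicated_template(toy_ref, toy_arch_dd, toy_arch_ss):
    ref_seq = toy_ref[TOY_CHROM]
    bp5, bp3 = toy_arch_dd.bp5, toy_arch_dd.bp3
    # forward primer upstream of the 3' breakpoint, reverse just after the 5'
    fwd = ref_seq[bp3 - 260 : bp3 - 240]
    rev_site = ref_seq[bp5 + 180 : bp5 + 200]
    rev = _revcomp(rev_site)
    dd_hap = build_haplotype(toy_ref, toy_arch_dd)
    ss_hap = build_haplotype(toy_ref, toy_arch_ss)
    assert insilico_pcr(ss_hap.sequence, fwd, rev) == []
    products = insilico_pcr(dd_hap.sequence, fwd, rev)
    assert len(products) == 1  # one junction -> exactly one product
    product = products[0]
    assert product.length == 260 + 200  # suffix side + prefix side
    junction_pos = bp3  # junction coordinate within the haplotype
    assert product.start < junction_pos <= product.end


def test_pcr_product_length_convention():
    template = build_reference(9, {"t": 2000})["t"]
    fwd = template[100:120]
    rev = _revcomp(template[580:600])
    (product,) = insilico_pcr(template, fwd, rev)
    assert (product.start, product.end, product.length) == (100, 600, 500)
    assert product.sequence == template[100:600]
    # swapped primer roles find the same product
    (swapped,) = insilico_pcr(template, rev, fwd)
    assert swapped.length == 500
    with pytest.raises(ValueError):
        insilico_pcr(template, "ACGT", rev)


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
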
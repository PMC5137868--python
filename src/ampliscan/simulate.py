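"""Synthetic data generation with known truth.

Everything the analysis pipeline consumes can be produced here: random
reference chromosomes, haplotypes carrying tandem amplicons (optionally with
intra-amplicon deletions in a subset of copies), paired-end reads with oracle
alignments projected analytically onto the reference, qPCR plates with
standard-dilution series, probit-distributed larval mortality tables, and
Gaussian per-copy enzyme-activity tables.

Reads are *projected*, not mapped: because the simulator knows the exact
haplotype-to-reference coordinate map, each read's reference position, CIGAR
(match/soft-clip) and mate geometry are computed analytically.  This
reproduces exactly the alignment signatures a short-read aligner produces
around a tandem junction -- soft-clipped reads at the breakpoints and
discordant pairs with apparent spans close to the amplicon length -- while
keeping the whole pipeline deterministic and free of external binaries.

Coordinates are 0-based half-open internally; reports use 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .sam import AlignmentRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ALPHABET = frozenset("ACGT")

__all__ = [
    "ReferenceGenome",
    "AmpliconArchitecture",
    "Haplotype",
    "DiploidGenotype",
    "ReadProfile",
    "NoiseModel",
    "ReadSimulation",
    "build_reference",
    "build_haplotype",
    "homozygote",
    "heterozygote",
    "simulate_read_pairs",
    "project_alignments",
    "simulate_qpcr",
    "simulate_bioassay",
    "simulate_activities",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceGenome:
    """A set of named chromosome sequences restricted to the ACGT alphabet."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference must contain at least one sequence")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - _ALPHABET:
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"chromosome {name!r} contains non-ACGT symbols {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]


@dataclass(frozen=True)
class AmpliconArchitecture:
    """Ground-truth description of a tandem amplification on one chromosome.

    ``bp5``/``bp3`` delimit the amplified unit as a 0-based half-open
    reference interval.  ``copy_count`` copies are laid head-to-tail in place
    of the single reference copy.  ``deletions`` lists intervals removed from
    individual copies as ``(copy_index, del_start, del_end)`` in reference
    coordinates, strictly inside the amplicon.
    """

    chromosome: str
    bp5: int
    bp3: int
    copy_count: int = 1
    deletions: tuple[tuple[int, int, int], ...] = ()
    label: str = "allele"

    def __post_init__(self) -> None:
        if self.bp5 < 0 or self.bp5 >= self.bp3:
            raise ValueError("amplicon requires 0 <= bp5 < bp3")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")
        if self.copy_count == 1 and self.deletions:
            raise ValueError("a single-copy allele cannot carry intra-amplicon deletions")
        per_copy: dict[int, list[tuple[int, int]]] = {}
        for copy_index, dstart, dend in self.deletions:
            if not 0 <= copy_index < self.copy_count:
                raise ValueError(f"deletion copy_index {copy_index} out of range")
            if not (self.bp5 < dstart < dend < self.bp3):
                raise ValueError(
                    f"deletion [{dstart},{dend}) not strictly inside amplicon "
                    f"({self.bp5},{self.bp3})"
                )
            per_copy.setdefault(copy_index, []).append((dstart, dend))
        for copy_index, intervals in per_copy.items():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping deletions within copy {copy_index}")

    @property
    def unit_length(self) -> int:
        return self.bp3 - self.bp5

    def deletions_for_copy(self, copy_index: int) -> list[tuple[int, int]]:
        return sorted((s, e) for ci, s, e in self.deletions if ci == copy_index)


@dataclass(frozen=True)
class Segment:
    """One colinear block of a haplotype: ``[hap_start, hap_end)`` on the
    haplotype maps to ``[ref_start, ref_start + length)`` on the reference,
    same strand."""

    hap_start: int
    hap_end: int
    ref_start: int

    @property
    def length(self) -> int:
        return self.hap_end - self.hap_start

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length


@dataclass(frozen=True)
class Haplotype:
    """A realized chromosome sequence plus its reference coordinate map."""

    sequence: str
    segments: tuple[Segment, ...]
    architecture: AmpliconArchitecture

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.hap_start != pos:
                raise ValueError("segments must tile the haplotype without gaps/overlaps")
            pos = seg.hap_end
        if pos != len(self.sequence):
            raise ValueError("segments do not cover the full haplotype")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def chromosome(self) -> str:
        return self.architecture.chromosome


@dataclass(frozen=True)
class DiploidGenotype:
    haplotypes: tuple[Haplotype, Haplotype]
    label: str = ""

    def __post_init__(self) -> None:
        a, b = self.haplotypes
        if a.chromosome != b.chromosome:
            raise ValueError("both haplotypes must derive from the same chromosome")


@dataclass(frozen=True)
class ReadProfile:
    """Paired-end library model.

    ``insert_mean``/``insert_sd`` describe the full fragment (outer template)
    length; inserts are Gaussian, truncated below at ``read_length``.
    ``coverage`` is the total fold depth over the reference contributed by the
    whole diploid library (each haplotype is sampled at ``coverage / 2``).
    """

    read_length: int = 100
    insert_mean: int = 250
    insert_sd: float = 25.0
    error_rate: float = 0.0
    coverage: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement-noise scale shared by the assay simulators."""

    sd: float = 0.0
    binomial_sampling: bool = True

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


# ---------------------------------------------------------------------------
# Reference and haplotype construction
# ---------------------------------------------------------------------------

def build_reference(seed: int, lengths: Mapping[str, int]) -> ReferenceGenome:
    """Draw a random reference genome with uniform i.i.d. base composition."""
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    for name, length in lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} must have positive length")
        idx = rng.integers(0, 4, size=length, dtype=np.uint8)
        sequences[name] = _BASES[idx].tobytes().decode("ascii")
    return ReferenceGenome(sequences)


def build_haplotype(ref: ReferenceGenome, arch: AmpliconArchitecture) -> Haplotype:
    """Realize an amplicon architecture as a haplotype sequence.

    The ``copy_count`` copies of ``[bp5, bp3)`` are laid strictly head-to-tail
    (tandem), each minus its own deletions; flanks are untouched.  The
    resulting length is ``ref_len + (copy_count - 1) * unit - total_deleted``.
    """
    chrom_seq = ref[arch.chromosome]
    if arch.bp3 > len(chrom_seq):
        raise ValueError("amplicon extends past the end of the chromosome")

    parts: list[str] = []
    segments: list[Segment] = []
    pos = 0

    def emit(ref_start: int, ref_end: int) -> None:
        nonlocal pos
        if ref_end <= ref_start:
            return
        parts.append(chrom_seq[ref_start:ref_end])
        # merge blocks that continue the previous one colinearly (e.g. the
        # last amplicon copy running into the 3' flank): a read crossing such
        # a boundary is a plain contiguous alignment, not a junction read
        if segments and segments[-1].ref_end == ref_start:
            prev = segments.pop()
            segments.append(Segment(prev.hap_start, pos + (ref_end - ref_start), prev.ref_start))
        else:
            segments.append(Segment(pos, pos + (ref_end - ref_start), ref_start))
        pos += ref_end - ref_start

    emit(0, arch.bp5)
    for copy_index in range(arch.copy_count):
        cursor = arch.bp5
        for dstart, dend in arch.deletions_for_copy(copy_index):
            emit(cursor, dstart)
            cursor = dend
        emit(cursor, arch.bp3)
    emit(arch.bp3, len(chrom_seq))

    return Haplotype("".join(parts), tuple(segments), arch)


def homozygote(ref: ReferenceGenome, arch: AmpliconArchitecture, label: str = "") -> DiploidGenotype:
    hap = build_haplotype(ref, arch)
    return DiploidGenotype((hap, hap), label or f"{arch.label}{arch.label}")


def heterozygote(
    ref: ReferenceGenome,
    arch1: AmpliconArchitecture,
    arch2: AmpliconArchitecture,
    label: str = "",
) -> DiploidGenotype:
    return DiploidGenotype(
        (build_haplotype(ref, arch1), build_haplotype(ref, arch2)),
        label or f"{arch1.label}{arch2.label}",
    )


# ---------------------------------------------------------------------------
# Read-pair simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimulation:
    """Fragment placements plus a sparse substitution-error set.

    Fragments are stored as parallel arrays (haplotype index, 0-based start,
    insert length).  Read 1 covers ``[start, start + L)`` of the haplotype
    and is forward; read 2 covers ``[start + insert - L, start + insert)``
    and is reverse-complement on the physical strand, though sequences are
    stored haplotype-forward (as an aligner would report them).
    """

    genotype: DiploidGenotype
    profile: ReadProfile
    hap_index: np.ndarray
    start: np.ndarray
    insert: np.ndarray
    # substitution errors: parallel arrays (pair index, mate 0/1, offset, new base char)
    err_pair: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    err_mate: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    err_offset: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    err_base: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U1"))

    @property
    def n_pairs(self) -> int:
        return len(self.start)

    def _error_map(self) -> dict[tuple[int, int], list[tuple[int, str]]]:
        emap: dict[tuple[int, int], list[tuple[int, str]]] = {}
        for p, m, o, b in zip(self.err_pair, self.err_mate, self.err_offset, self.err_base):
            emap.setdefault((int(p), int(m)), []).append((int(o), str(b)))
        return emap

    def read_sequences(self) -> Iterator[tuple[str, str, str]]:
        """Yield ``(name, seq1, seq2)`` per pair, errors applied, deterministic."""
        L = self.profile.read_length
        haps = [h.sequence for h in self.genotype.haplotypes]
        emap = self._error_map()
        for i in range(self.n_pairs):
            hap = haps[self.hap_index[i]]
            s = int(self.start[i])
            ins = int(self.insert[i])
            seq1 = hap[s : s + L]
            seq2 = hap[s + ins - L : s + ins]
            for mate, seq in ((0, seq1), (1, seq2)):
                hits = emap.get((i, mate))
                if hits:
                    chars = list(seq)
                    for off, base in hits:
                        chars[off] = base
                    if mate == 0:
                        seq1 = "".join(chars)
                    else:
                        seq2 = "".join(chars)
            yield f"sim:{self.hap_index[i]}:{i}", seq1, seq2


def simulate_read_pairs(genotype: DiploidGenotype, profile: ReadProfile) -> ReadSimulation:
    """Draw fragment placements for a whole diploid library.

    The expected pair count per haplotype is
    ``(coverage / 2) * hap_length / (2 * read_length)`` so the library totals
    ``coverage`` fold depth over the reference.  Fragment starts are uniform;
    fragments falling off the 3' end are shifted inward (no wrap-around).
    """
    rng = np.random.default_rng(profile.seed)
    L = profile.read_length
    hap_idx_parts: list[np.ndarray] = []
    start_parts: list[np.ndarray] = []
    insert_parts: list[np.ndarray] = []
    for hidx, hap in enumerate(genotype.haplotypes):
        hap_len = len(hap)
        n = int(round(profile.coverage / 2.0 * hap_len / (2.0 * L)))
        inserts = np.rint(rng.normal(profile.insert_mean, profile.insert_sd, size=n)).astype(np.int64)
        np.clip(inserts, L, hap_len, out=inserts)
        starts = rng.integers(0, hap_len, size=n, dtype=np.int64)
        np.minimum(starts, hap_len - inserts, out=starts)
        hap_idx_parts.append(np.full(n, hidx, dtype=np.int8))
        start_parts.append(starts)
        insert_parts.append(inserts)

    sim = ReadSimulation(
        genotype=genotype,
        profile=profile,
        hap_index=np.concatenate(hap_idx_parts),
        start=np.concatenate(start_parts),
        insert=np.concatenate(insert_parts),
    )

    if profile.error_rate > 0:
        total_bases = 2 * L * sim.n_pairs
        k = rng.binomial(total_bases, profile.error_rate)
        flat = np.sort(rng.integers(0, total_bases, size=k))
        sim.err_pair = flat // (2 * L)
        rem = flat % (2 * L)
        sim.err_mate = (rem // L).astype(np.int8)
        sim.err_offset = (rem % L).astype(np.int32)
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=k)
        haps = [np.frombuffer(h.sequence.encode(), dtype=np.uint8) for h in genotype.haplotypes]
        lut = np.zeros(256, dtype=np.uint8)
        lut[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4)
        orig = np.empty(k, dtype=np.uint8)
        for i in range(k):
            p = sim.err_pair[i]
            hap = haps[sim.hap_index[p]]
            s = sim.start[p]
            base_pos = (
                s + sim.err_offset[i]
                if sim.err_mate[i] == 0
                else s + sim.insert[p] - L + sim.err_offset[i]
            )
            orig[i] = hap[base_pos]
        new_code = (lut[orig] + shift) % 4
        sim.err_base = _BASES[new_code].tobytes().decode("ascii")
        sim.err_base = np.array(list(sim.err_base), dtype="U1")
    return sim


# ---------------------------------------------------------------------------
# Oracle alignment projection
# ---------------------------------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_FIRST = 0x40
_FLAG_SECOND = 0x80


def _project_interval(
    bounds: np.ndarray,
    ref_starts: np.ndarray,
    hap_starts: np.ndarray,
    s: int,
    e: int,
    min_anchor: int,
) -> tuple[int, str, bool] | None:
    """Project a haplotype interval [s, e) through the segment map.

    Returns ``(ref_pos, cigar, mapped)``; ``None`` marks an unmapped read
    (longest colinear portion shorter than ``min_anchor``).  A read spanning a
    junction keeps the longer portion matched (5' portion on ties) and
    soft-clips the remainder.
    """
    first = int(np.searchsorted(bounds, s, side="right")) - 1
    last = int(np.searchsorted(bounds, e - 1, side="right")) - 1
    if first == last:
        ref_pos = int(ref_starts[first]) + (s - int(hap_starts[first]))
        return ref_pos, f"{e - s}M", True
    best, best_len = first, 0
    for seg in range(first, last + 1):
        ov = min(e, int(bounds[seg + 1])) - max(s, int(bounds[seg]))
        if ov > best_len:
            best, best_len = seg, ov
    if best_len < min_anchor:
        return None
    ms = max(s, int(bounds[best]))
    me = min(e, int(bounds[best + 1]))
    ref_pos = int(ref_starts[best]) + (ms - int(hap_starts[best]))
    cigar = ""
    if ms > s:
        cigar += f"{ms - s}S"
    cigar += f"{me - ms}M"
    if e > me:
        cigar += f"{e - me}S"
    return ref_pos, cigar, True


def project_alignments(sim: ReadSimulation, min_anchor: int = 20) -> Iterator[AlignmentRecord]:
    """Stream oracle alignments for every simulated read pair.

    Reads fully inside one colinear segment yield an all-match CIGAR at the
    projected reference position.  Junction-spanning reads are anchored on the
    longer portion with the remainder soft-clipped (sequence preserved), which
    is exactly the signature a local aligner leaves at a tandem junction.
    Reads with no portion of at least ``min_anchor`` colinear bases are
    emitted unmapped.
    """
    L = sim.profile.read_length
    chrom = sim.genotype.haplotypes[0].chromosome
    maps = []
    for hap in sim.genotype.haplotypes:
        hap_starts = np.array([seg.hap_start for seg in hap.segments], dtype=np.int64)
        bounds = np.append(hap_starts, len(hap))
        ref_starts = np.array([seg.ref_start for seg in hap.segments], dtype=np.int64)
        maps.append((bounds, ref_starts, hap_starts))

    emap = sim._error_map()
    haps = [h.sequence for h in sim.genotype.haplotypes]
    for i in range(sim.n_pairs):
        hidx = int(sim.hap_index[i])
        bounds, ref_starts, hap_starts = maps[hidx]
        s = int(sim.start[i])
        ins = int(sim.insert[i])
        s2 = s + ins - L
        proj1 = _project_interval(bounds, ref_starts, hap_starts, s, s + L, min_anchor)
        proj2 = _project_interval(bounds, ref_starts, hap_starts, s2, s2 + L, min_anchor)
        name = f"sim:{hidx}:{i}"
        hap = haps[hidx]
        seq1 = hap[s : s + L]
        seq2 = hap[s2 : s2 + L]
        for mate, seq in ((0, seq1), (1, seq2)):
            hits = emap.get((i, mate))
            if hits:
                chars = list(seq)
                for off, base in hits:
                    chars[off] = base
                if mate == 0:
                    seq1 = "".join(chars)
                else:
                    seq2 = "".join(chars)

        flag1 = _FLAG_PAIRED | _FLAG_FIRST | _FLAG_MATE_REVERSE
        flag2 = _FLAG_PAIRED | _FLAG_SECOND | _FLAG_REVERSE
        if proj1 is None:
            flag1 |= _FLAG_UNMAPPED
        if proj2 is None:
            flag2 |= _FLAG_UNMAPPED

        pos1, cig1 = (proj1[0], proj1[1]) if proj1 else (-1, "*")
        pos2, cig2 = (proj2[0], proj2[1]) if proj2 else (-1, "*")

        tlen1 = tlen2 = 0
        if proj1 and proj2:
            end1 = pos1 + _aligned_span(cig1)
            end2 = pos2 + _aligned_span(cig2)
            left = min(pos1, pos2)
            right = max(end1, end2)
            span = right - left
            tlen1 = span if pos1 <= pos2 else -span
            tlen2 = -tlen1
            concordant = (
                pos1 <= pos2
                and abs(span - sim.profile.insert_mean) <= 4 * sim.profile.insert_sd + L
            )
            if concordant:
                flag1 |= _FLAG_PROPER
                flag2 |= _FLAG_PROPER

        yield AlignmentRecord(
            qname=name, flag=flag1, chrom=chrom, pos=pos1, mapq=60, cigar=cig1,
            rnext=chrom if proj2 else "*", pnext=pos2, tlen=tlen1, seq=seq1,
        )
        yield AlignmentRecord(
            qname=name, flag=flag2, chrom=chrom, pos=pos2, mapq=60, cigar=cig2,
            rnext=chrom if proj1 else "*", pnext=pos1, tlen=tlen2, seq=seq2,
        )


def _aligned_span(cigar: str) -> int:
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "M":
                span += int(num)
            num = ""
    return span


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    samples: Mapping[str, Mapping[str, float]],
    efficiencies: Mapping[str, float],
    baseline_cq: float = 24.0,
    noise: NoiseModel = NoiseModel(0.0),
    replicates: int = 4,
    dilution_points: int = 5,
    calibrator: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a relative-quantification qPCR plate.

    ``samples`` maps sample name -> {locus -> copies per diploid genome}.
    Unknown-sample wells follow ``Cq = baseline - log_E(copies / 2) + eps``
    so that a two-copy (single-copy-per-chromosome) diploid sits exactly at
    the baseline.  Each locus also gets a 10-fold standard-dilution series:
    dilution step ``k`` has ``Cq = baseline + k * log_E(10) + eps``.

    Returns a tidy well table with columns
    ``sample, locus, role, dilution_log10, Cq``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for locus, eff in efficiencies.items():
        if not 1.0 < eff <= 2.0:
            raise ValueError(f"efficiency for {locus!r} must lie in (1, 2]")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for locus, eff in efficiencies.items():
        log_e_10 = math.log(10.0) / math.log(eff)
        for k in range(dilution_points):
            for _ in range(replicates):
                cq = baseline_cq + k * log_e_10 + rng.normal(0.0, noise.sd)
                rows.append(
                    dict(sample=f"std:{locus}", locus=locus, role="standard",
                         dilution_log10=float(-k), Cq=cq)
                )
    for sample, loci in samples.items():
        role = "calibrator" if sample == calibrator else "unknown"
        for locus, copies in loci.items():
            if copies <= 0:
                raise ValueError(f"copies for {sample!r}/{locus!r} must be positive")
            eff = efficiencies[locus]
            true_cq = baseline_cq - math.log(copies / 2.0) / math.log(eff)
            for _ in range(replicates):
                rows.append(
                    dict(sample=sample, locus=locus, role=role,
                         dilution_log10=float("nan"),
                         Cq=true_cq + rng.normal(0.0, noise.sd))
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bioassay simulation
# ---------------------------------------------------------------------------

def simulate_bioassay(
    true_lc50: float,
    probit_slope: float,
    natural_mortality: float = 0.0,
    doses: Sequence[float] = (),
    n_per_cup: int = 25,
    replicates: int = 4,
    strain: str = "strain",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dose-mortality bioassay with dose-0 controls.

    Death counts are Binomial(n, p) with
    ``p = c + (1 - c) * Phi(slope * (log10 d - log10 LC50))`` where ``c`` is
    the natural (control) mortality.  Dose 0 rows are the controls.
    """
    from scipy.stats import norm

    if true_lc50 <= 0 or probit_slope <= 0:
        raise ValueError("LC50 and slope must be positive")
    if not all(d > 0 for d in doses):
        raise ValueError("doses must be positive (controls are added automatically)")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in (0.0, *doses):
        if dose == 0.0:
            p = natural_mortality
        else:
            z = probit_slope * (math.log10(dose) - math.log10(true_lc50))
            p = natural_mortality + (1.0 - natural_mortality) * norm.cdf(z)
        for rep in range(replicates):
            dead = int(rng.binomial(n_per_cup, p))
            rows.append(dict(strain=strain, dose=dose, replicate=rep + 1,
                             n=n_per_cup, dead=dead))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Enzyme-activity simulation
# ---------------------------------------------------------------------------

def simulate_activities(
    n_r: int,
    n_s: int,
    a_r: float,
    a_s: float,
    sd: float = 0.0,
    n_individuals: int = 20,
    genotype: str = "",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-individual enzyme activities under strict additivity.

    The insensitive-enzyme activity is Gaussian around ``n_r * a_r`` and the
    susceptible-enzyme activity around ``n_s * a_s`` (both truncated at 0);
    the total is their sum.  ``n_r``/``n_s`` are copies per diploid genome.
    """
    if a_r < 0 or a_s < 0:
        raise ValueError("per-copy activities must be >= 0")
    rng = np.random.default_rng(seed)
    ar = np.clip(rng.normal(n_r * a_r, sd, size=n_individuals), 0.0, None)
    as_ = np.clip(rng.normal(n_s * a_s, sd, size=n_individuals), 0.0, None)
    return pd.DataFrame(
        dict(
            individual=[f"{genotype or 'ind'}-{i+1}" for i in range(n_individuals)],
            genotype=genotype,
            n_r=n_r,
            n_s=n_s,
            A_R=ar,
            A_TOT=ar + as_,
        )
    )
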
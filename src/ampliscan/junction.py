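"""Base-resolution breakpoint and junction reconstruction.

A tandem amplification leaves two alignment signatures on the single-copy
reference: reads crossing the inter-amplicon junction align only partially
(soft-clipped, with the clip boundary pinned to a breakpoint), and read pairs
straddling the junction map with an apparent span close to the amplicon
length.  Clustering clip boundaries and voting a per-column consensus over
the clipped and anchored bases recovers both breakpoints exactly and
reconstructs the junction sequence.  An intra-amplicon deletion produces a
second, independent clip cluster pair, resolved the same way.

A small exact-match in-silico PCR completes the module: a primer pair placed
on either side of the junction yields a product only on templates that carry
the tandem junction, which is the logic of the duplication diagnostic test.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sam import AlignmentRecord
from .simulate import ReferenceGenome

__all__ = [
    "SoftClip",
    "DiscordantPair",
    "EvidenceSet",
    "InsertSizeProfile",
    "JunctionCall",
    "NoCallError",
    "AmbiguousCallError",
    "insert_size_profile",
    "collect_discordant_pairs",
    "collect_evidence",
    "collect_softclipped",
    "resolve_junctions",
    "resolve_junction",
    "insilico_pcr",
]


@dataclass(frozen=True)
class SoftClip:
    """One terminal soft-clip: the clip boundary on the reference, which side
    of the read was clipped, the clipped sequence and the anchored portion."""

    qname: str
    side: str  # "left": clip precedes the match; "right": clip follows it
    boundary: int  # 0-based: first matched base (left) / exclusive match end (right)
    clip_seq: str
    anchor_seq: str

    @property
    def clip_length(self) -> int:
        return len(self.clip_seq)


@dataclass(frozen=True)
class DiscordantPair:
    """A pair whose apparent span or orientation contradicts the insert model.

    ``span`` is the outer template span on the reference (|TLEN|)."""

    qname: str
    span: int
    left_pos: int
    right_end: int
    orientation: str  # "FR" (inward) or the anomaly class observed


@dataclass
class EvidenceSet:
    clips: list[SoftClip] = field(default_factory=list)
    pairs: list[DiscordantPair] = field(default_factory=list)
    skipped_unpaired: int = 0


@dataclass
class InsertSizeProfile:
    """Histogram of apparent pair spans near a region, 200 bp bins by default."""

    region: tuple[int, int]
    bin_width: int
    counts: dict[int, float]  # bin lower edge -> (normalized) pair count

    def modes(self) -> list[int]:
        """Bin lower edges sorted by decreasing mass."""
        return [b for b, _ in sorted(self.counts.items(), key=lambda kv: -kv[1])]


@dataclass
class JunctionCall:
    """A resolved junction: 1-based breakpoints, consensus and support.

    For a tandem-duplication junction ``bp5 <= bp3`` and the amplified unit is
    ``[bp5, bp3]`` (length ``bp3 - bp5 + 1``).  For an intra-amplicon deletion
    the clip evidence joins a left flank ending at ``bp3`` to a right flank
    starting at ``bp5`` with ``bp5 > bp3 + 1``; the deleted interval is
    ``[bp3 + 1, bp5 - 1]``.
    """

    bp5: int
    bp3: int
    consensus: str
    clip_support: int
    discordant_support: int
    kind: str  # "tandem" | "deletion"

    @property
    def tandem(self) -> bool:
        return self.kind == "tandem"

    @property
    def amplicon_length(self) -> int:
        if not self.tandem:
            raise ValueError("amplicon length is defined for tandem junctions only")
        return self.bp3 - self.bp5 + 1

    @property
    def deletion_length(self) -> int:
        if self.tandem:
            raise ValueError("deletion length is defined for deletion junctions only")
        return self.bp5 - self.bp3 - 1


class NoCallError(ValueError):
    """Raised when junction evidence is insufficient for a confident call."""


class AmbiguousCallError(ValueError):
    """Raised when clip boundaries form inconsistent clusters."""


# ---------------------------------------------------------------------------
# Evidence collection
# ---------------------------------------------------------------------------

def insert_size_profile(
    alignments: Iterable[AlignmentRecord],
    region: tuple[int, int],
    bin_width: int = 200,
    normalizer: float | None = None,
) -> InsertSizeProfile:
    """Histogram apparent spans for pairs with at least one read in ``region``.

    Each pair is counted once (from its leftmost record, TLEN > 0).  Counts
    are divided by ``normalizer`` (e.g. the mean DOC outside the candidate
    region) when given.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    start, end = region
    counts: Counter[int] = Counter()
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.tlen <= 0:
            continue
        # count a pair once, from its leftmost record; either end in the region
        read_hit = rec.pos < end and rec.reference_end > start
        mate_hit = rec.pnext < end and rec.pnext + len(rec.seq) > start
        if read_hit or mate_hit:
            counts[(rec.tlen // bin_width) * bin_width] += 1
    scale = 1.0 / normalizer if normalizer else 1.0
    return InsertSizeProfile(region, bin_width, {b: c * scale for b, c in counts.items()})


def collect_discordant_pairs(
    alignments: Iterable[AlignmentRecord],
    insert_mean: float,
    insert_sd: float,
    k_sd: float = 4.0,
) -> EvidenceSet:
    """Select pairs whose span exceeds ``mean + k_sd * sd`` or whose
    orientation is not forward-reverse inward.

    Pairs are matched by query name; records whose mate never appears are
    counted in ``skipped_unpaired``.
    """
    evidence = EvidenceSet()
    pending: dict[str, AlignmentRecord] = {}
    threshold = insert_mean + k_sd * insert_sd
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary:
            continue
        mate = pending.pop(rec.qname, None)
        if mate is None:
            pending[rec.qname] = rec
            continue
        pair = _pair_discordance(mate, rec, threshold)
        if pair is not None:
            evidence.pairs.append(pair)
    evidence.skipped_unpaired = len(pending)
    evidence.pairs.sort(key=lambda p: (p.left_pos, p.qname))
    return evidence


def collect_evidence(
    alignments: Iterable[AlignmentRecord],
    insert_mean: float,
    insert_sd: float,
    min_clip: int = 10,
    k_sd: float = 4.0,
) -> EvidenceSet:
    """Single-pass soft-clip + discordant-pair collection.

    Equivalent to running :func:`collect_softclipped` and
    :func:`collect_discordant_pairs` but consumes the record stream once,
    which matters for large simulated libraries.
    """
    clip_candidates: list[AlignmentRecord] = []
    pending: dict[str, AlignmentRecord] = {}
    threshold = insert_mean + k_sd * insert_sd
    pairs: list[DiscordantPair] = []
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary:
            continue
        if "S" in rec.cigar:
            clip_candidates.append(rec)
        mate = pending.pop(rec.qname, None)
        if mate is None:
            pending[rec.qname] = rec
            continue
        pair = _pair_discordance(mate, rec, threshold)
        if pair is not None:
            pairs.append(pair)
    evidence = collect_softclipped(clip_candidates, min_clip)
    evidence.pairs = sorted(pairs, key=lambda p: (p.left_pos, p.qname))
    evidence.skipped_unpaired = len(pending)
    return evidence


def _pair_discordance(
    a: AlignmentRecord, b: AlignmentRecord, threshold: float
) -> DiscordantPair | None:
    left, right = (a, b) if a.pos <= b.pos else (b, a)
    span = max(left.reference_end, right.reference_end) - left.pos
    inward = (not left.is_reverse) and right.is_reverse
    if span <= threshold and inward:
        return None
    orientation = "FR" if inward else ("RF" if left.is_reverse and not right.is_reverse else "tandem")
    return DiscordantPair(a.qname, span, left.pos, right.reference_end, orientation)


def collect_softclipped(
    alignments: Iterable[AlignmentRecord],
    min_clip: int = 10,
) -> EvidenceSet:
    """Extract reads with a terminal soft-clip of at least ``min_clip`` bases."""
    evidence = EvidenceSet()
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary:
            continue
        ops = rec.cigartuples()  # raises naming the record on malformed CIGAR
        if not ops:
            continue
        match_len = sum(n for op, n in ops if op == "M")
        consumed = 0
        if ops[0][0] == "S":
            n = ops[0][1]
            if n >= min_clip:
                evidence.clips.append(
                    SoftClip(
                        qname=rec.qname,
                        side="left",
                        boundary=rec.pos,
                        clip_seq=rec.seq[:n],
                        anchor_seq=rec.seq[n : n + match_len],
                    )
                )
            consumed = n
        if ops[-1][0] == "S" and len(ops) > 1:
            n = ops[-1][1]
            if n >= min_clip:
                evidence.clips.append(
                    SoftClip(
                        qname=rec.qname,
                        side="right",
                        boundary=rec.reference_end,
                        clip_seq=rec.seq[len(rec.seq) - n :],
                        anchor_seq=rec.seq[consumed : len(rec.seq) - n],
                    )
                )
    evidence.clips.sort(key=lambda c: (c.boundary, c.side, c.qname))
    return evidence


# ---------------------------------------------------------------------------
# Junction resolution
# ---------------------------------------------------------------------------

def _cluster_boundaries(clips: list[SoftClip], tolerance: int) -> list[tuple[int, list[SoftClip]]]:
    """Group clips whose boundaries lie within ``tolerance`` of each other;
    each cluster is keyed by its modal boundary."""
    clusters: list[tuple[int, list[SoftClip]]] = []
    current: list[SoftClip] = []
    for clip in sorted(clips, key=lambda c: c.boundary):
        if current and clip.boundary - current[-1].boundary > tolerance:
            clusters.append((_modal([c.boundary for c in current]), current))
            current = []
        current.append(clip)
    if current:
        clusters.append((_modal([c.boundary for c in current]), current))
    return clusters


def _modal(values: list[int]) -> int:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def _column_vote(columns: dict[int, Counter]) -> str:
    out = []
    for pos in sorted(columns):
        votes = columns[pos]
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out.append("N")  # majority tie
        else:
            out.append(top[0][0])
    return "".join(out)


def _clip_consensus(cluster: list[SoftClip], side: str, boundary: int) -> str:
    """Majority consensus of the clipped sequences, aligned on the boundary.

    Right-side clips read forward from the junction (column 0 = first clipped
    base); left-side clips read backward (column -1 = last clipped base).
    Only clips at the modal boundary vote, so off-by-one boundaries from
    sequencing errors cannot shear the alignment.
    """
    columns: dict[int, Counter] = defaultdict(Counter)
    for clip in cluster:
        if clip.boundary != boundary:
            continue
        if side == "right":
            for j, base in enumerate(clip.clip_seq):
                columns[j][base] += 1
        else:
            for j, base in enumerate(reversed(clip.clip_seq)):
                columns[-j - 1][base] += 1
    return _column_vote(columns)


def _mismatch_rate(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 1.0
    return sum(x != y for x, y in zip(a[:n], b[:n])) / n


def resolve_junctions(
    evidence: EvidenceSet,
    ref: ReferenceGenome,
    chromosome: str | None = None,
    min_support: int = 3,
    tolerance: int = 2,
    max_mismatch_rate: float = 0.1,
    insert_mean: float | None = None,
) -> list[JunctionCall]:
    """Resolve every junction supported by the clip evidence.

    Right-side and left-side clip boundaries are clustered independently
    (within ``tolerance`` bp); clusters with at least ``min_support`` clips on
    each side are paired by requiring the right cluster's clipped consensus to
    match the reference starting at the left cluster's boundary (and vice
    versa) at a mismatch rate of at most ``max_mismatch_rate``.  A pairing
    with the left boundary upstream of the right is a head-to-tail tandem
    junction; downstream, an intra-amplicon deletion.

    Discordant-pair support is attributed to the junction whose implied span
    best matches each pair.  Raises :class:`NoCallError` when no cluster pair
    reaches ``min_support`` and :class:`AmbiguousCallError` when a clipped
    consensus matches two reference positions inconsistently.
    """
    if chromosome is None:
        chromosome = next(iter(ref.sequences))
    chrom_seq = ref[chromosome]

    rights = _cluster_boundaries([c for c in evidence.clips if c.side == "right"], tolerance)
    lefts = _cluster_boundaries([c for c in evidence.clips if c.side == "left"], tolerance)
    rights = [(b, cl) for b, cl in rights if len(cl) >= min_support]
    lefts = [(b, cl) for b, cl in lefts if len(cl) >= min_support]
    if not rights or not lefts:
        raise NoCallError(
            f"insufficient clip support: {sum(len(c) for _, c in rights)} right / "
            f"{sum(len(c) for _, c in lefts)} left clips in clusters of >= {min_support}"
        )

    calls: list[JunctionCall] = []
    used_left: set[int] = set()
    for r_boundary, r_cluster in rights:
        r_cons = _clip_consensus(r_cluster, "right", r_boundary)
        matches = []
        for l_boundary, l_cluster in lefts:
            fwd = _mismatch_rate(r_cons, chrom_seq[l_boundary : l_boundary + len(r_cons)])
            l_cons = _clip_consensus(l_cluster, "left", l_boundary)
            back_ref = chrom_seq[max(0, r_boundary - len(l_cons)) : r_boundary]
            rev = _mismatch_rate(l_cons[::-1], back_ref[::-1])
            if fwd <= max_mismatch_rate and rev <= max_mismatch_rate:
                matches.append((fwd + rev, l_boundary, l_cluster))
        if not matches:
            continue
        matches.sort()
        if len(matches) > 1 and matches[1][0] <= max_mismatch_rate:
            raise AmbiguousCallError(
                f"right-clip cluster at {r_boundary + 1} matches multiple left clusters: "
                f"{[m[1] + 1 for m in matches]}"
            )
        _, l_boundary, l_cluster = matches[0]
        used_left.add(l_boundary)
        kind = "tandem" if l_boundary < r_boundary else "deletion"
        consensus = _junction_consensus(r_cluster, l_cluster, r_boundary, l_boundary)
        calls.append(
            JunctionCall(
                bp5=l_boundary + 1,
                bp3=r_boundary,
                consensus=consensus,
                clip_support=len(r_cluster) + len(l_cluster),
                discordant_support=0,
                kind=kind,
            )
        )

    if not calls:
        raise NoCallError("clip clusters could not be paired against the reference")

    # attribute each discordant pair to the junction whose implied span fits best
    for pair in evidence.pairs:
        best = None
        best_err = None
        for call in calls:
            implied = call.amplicon_length if call.tandem else call.deletion_length
            err = abs(pair.span - implied)
            if best_err is None or err < best_err:
                best, best_err = call, err
        if best is not None and insert_mean is not None:
            if best_err > 4 * insert_mean:
                continue
        if best is not None:
            best.discordant_support += 1

    calls.sort(key=lambda c: (not c.tandem, -c.clip_support))
    return calls


def _junction_consensus(
    r_cluster: list[SoftClip],
    l_cluster: list[SoftClip],
    r_boundary: int,
    l_boundary: int,
) -> str:
    """Positional-vote consensus across the junction.

    Column 0 is the first base after the junction.  Right-side clips
    contribute anchored bases on the left of the junction and clipped bases on
    the right; left-side clips the converse.
    """
    columns: dict[int, Counter] = defaultdict(Counter)
    for clip in r_cluster:
        if clip.boundary != r_boundary:
            continue
        for j, base in enumerate(reversed(clip.anchor_seq)):
            columns[-j - 1][base] += 1
        for j, base in enumerate(clip.clip_seq):
            columns[j][base] += 1
    for clip in l_cluster:
        if clip.boundary != l_boundary:
            continue
        for j, base in enumerate(reversed(clip.clip_seq)):
            columns[-j - 1][base] += 1
        for j, base in enumerate(clip.anchor_seq):
            columns[j][base] += 1
    return _column_vote(columns)


def resolve_junction(
    evidence: EvidenceSet,
    ref: ReferenceGenome,
    chromosome: str | None = None,
    **kwargs,
) -> JunctionCall:
    """Resolve the primary (best-supported tandem) junction."""
    calls = resolve_junctions(evidence, ref, chromosome, **kwargs)
    tandem = [c for c in calls if c.tandem]
    if not tandem:
        raise NoCallError("no tandem junction among resolved calls")
    return tandem[0]


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PcrProduct:
    start: int  # 0-based start of the forward primer on the template
    end: int  # 0-based exclusive end of the reverse primer binding site
    length: int
    sequence: str


def _find_all(template: str, query: str) -> list[int]:
    hits, i = [], template.find(query)
    while i != -1:
        hits.append(i)
        i = template.find(query, i + 1)
    return hits


def insilico_pcr(
    template: str,
    forward: str,
    reverse: str,
    max_product: int = 5000,
) -> list[PcrProduct]:
    """Predict PCR products by exact primer matching on both strands.

    Every pairing of a plus-strand forward-primer site with a downstream
    minus-strand reverse-primer site within ``max_product`` yields a product
    (primers included: length = reverse 3' end - forward 5' start, both on the
    template).  Primer roles are also tried swapped so template orientation
    does not matter.
    """
    if len(forward) < 15 or len(reverse) < 15:
        raise ValueError("primers must be at least 15 nt")
    template = template.upper()
    products: set[PcrProduct] = set()
    for fwd, rev in ((forward.upper(), reverse.upper()), (reverse.upper(), forward.upper())):
        rev_site = _revcomp(rev)
        fwd_hits = _find_all(template, fwd)
        rev_hits = _find_all(template, rev_site)
        for f in fwd_hits:
            for r in rev_hits:
                end = r + len(rev_site)
                if end - f < max(len(fwd), len(rev)):
                    continue
                if 0 < end - f <= max_product:
                    products.add(PcrProduct(f, end, end - f, template[f:end]))
    return sorted(products, key=lambda p: (p.start, p.end))
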
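"""Alignment records and standard-format I/O (SAM, FASTA, FASTQ).

The in-memory currency of the genomic pipeline is :class:`AlignmentRecord`,
a minimal mapped-read representation (position, CIGAR, mate geometry, flags).
File round-trips go through :mod:`pysam` for SAM and Biopython for
FASTA/FASTQ; the analysis functions themselves only ever see records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(slots=True)
class AlignmentRecord:
    """One mapped (or unmapped) read in SAM semantics, 0-based positions."""

    qname: str
    flag: int
    chrom: str
    pos: int  # 0-based leftmost aligned base; -1 when unmapped
    mapq: int
    cigar: str  # "*" when unmapped; ops restricted to M and S in this package
    rnext: str
    pnext: int
    tlen: int
    seq: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    @property
    def is_first(self) -> bool:
        return bool(self.flag & FLAG_FIRST)

    def cigartuples(self) -> list[tuple[str, int]]:
        """Parse the CIGAR into (op, length) tuples; raises on malformed input."""
        if self.cigar == "*":
            return []
        tuples = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(self.cigar)]
        if "".join(f"{n}{op}" for op, n in tuples) != self.cigar:
            raise ValueError(f"malformed CIGAR {self.cigar!r} in record {self.qname!r}")
        return tuples

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned portion on the reference."""
        span = sum(n for op, n in self.cigartuples() if op in "MDN=X")
        return self.pos + span


# ---------------------------------------------------------------------------
# SAM I/O (via pysam)
# ---------------------------------------------------------------------------

def write_sam(path: str, records: Iterable[AlignmentRecord], lengths: Mapping[str, int]) -> int:
    """Write records as coordinate-sorted SAM; returns the record count."""
    import pysam

    names = list(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(lengths[name])} for name in names],
    }
    tid = {name: i for i, name in enumerate(names)}
    recs = sorted(records, key=lambda r: (r.is_unmapped, tid.get(r.chrom, 0), r.pos))
    n = 0
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.flag = rec.flag
            if not rec.is_unmapped:
                a.reference_id = tid[rec.chrom]
                a.reference_start = rec.pos
                a.cigarstring = rec.cigar
            a.mapping_quality = rec.mapq
            if rec.rnext != "*" and rec.pnext >= 0:
                a.next_reference_id = tid[rec.rnext]
                a.next_reference_start = rec.pnext
            a.template_length = rec.tlen
            a.query_sequence = rec.seq
            a.query_qualities = [40] * len(rec.seq)
            out.write(a)
            n += 1
    return n


def read_sam(path: str) -> Iterator[AlignmentRecord]:
    """Stream a SAM/BAM file as :class:`AlignmentRecord` objects."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            yield AlignmentRecord(
                qname=a.query_name or "",
                flag=a.flag,
                chrom=a.reference_name or "*",
                pos=a.reference_start if a.reference_start is not None else -1,
                mapq=a.mapping_quality,
                cigar=a.cigarstring or "*",
                rnext=a.next_reference_name or "*",
                pnext=a.next_reference_start if a.next_reference_start is not None else -1,
                tlen=a.template_length,
                seq=a.query_sequence or "",
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ (via Biopython)
# ---------------------------------------------------------------------------

def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq_pairs(
    prefix: str, pairs: Iterable[tuple[str, str, str]], quality: int = 40
) -> tuple[str, str]:
    """Write paired reads to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
    with open(paths[0], "w") as f1, open(paths[1], "w") as f2:
        for name, seq1, seq2 in pairs:
            for fh, seq in ((f1, seq1), (f2, seq2)):
                rec = SeqRecord(Seq(seq), id=name, description="")
                rec.letter_annotations["phred_quality"] = [quality] * len(seq)
                SeqIO.write([rec], fh, "fastq")
    return paths
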
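"""Alignment, FASTA and report I/O plus the standard alignment filters.

Alignments are consumed from SAM/BAM via pysam and normalised into
lightweight :class:`AlignmentRecord` objects carrying the pool barcode.
The barcode may travel either as a per-read ``BX`` tag or as the
read-group (``RG``) label; both dialects are accepted and collapsed to a
single string key.  All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

import pysam

__all__ = [
    "AlignmentRecord",
    "ScaffoldSequence",
    "read_alignments",
    "write_alignments",
    "filter_alignments",
    "tally_and_filter_barcodes",
    "compute_raw_coverage",
    "read_fasta",
    "write_fasta",
]


@dataclasses.dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One aligned read with its pool barcode.

    ``pos`` is the 0-based leftmost reference coordinate and
    ``aligned_length`` the reference span consumed by the alignment.
    ``barcode`` is the pool label (14 bp index plus sample designator)
    or ``None`` when the read carries no barcode.
    """

    scaffold_id: str
    pos: int
    aligned_length: int
    mapq: int
    barcode: str | None = None
    is_proper_pair: bool = True
    is_unmapped: bool = False
    is_duplicate: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative alignment position: {self.pos}")
        if not self.is_unmapped and self.aligned_length <= 0:
            raise ValueError("mapped record must have aligned_length > 0")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"MAPQ out of range [0, 60]: {self.mapq}")

    @property
    def end(self) -> int:
        """Exclusive end coordinate of the alignment span."""
        return self.pos + self.aligned_length


@dataclasses.dataclass(frozen=True, slots=True)
class ScaffoldSequence:
    """A named assembly element over the {A, C, G, T, N} alphabet."""

    scaffold_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _barcode_of(aln: pysam.AlignedSegment) -> str | None:
    # Per-read BX tag wins; fall back to the read-group label.
    if aln.has_tag("BX"):
        return str(aln.get_tag("BX"))
    if aln.has_tag("RG"):
        return str(aln.get_tag("RG"))
    return None


def read_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` from a SAM/BAM file in file order.

    pysam already exposes 0-based coordinates, so no further shifting is
    applied.  Records without a barcode are yielded with ``barcode=None``.

    Raises
    ------
    OSError
        If the file is missing, truncated, or not SAM/BAM.
    ValueError
        If a mapped record carries a negative position.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for aln in handle:
            if aln.is_unmapped:
                yield AlignmentRecord(
                    scaffold_id=aln.reference_name or "*",
                    pos=max(aln.reference_start, 0),
                    aligned_length=0,
                    mapq=aln.mapping_quality,
                    barcode=_barcode_of(aln),
                    is_proper_pair=aln.is_proper_pair,
                    is_unmapped=True,
                    is_duplicate=aln.is_duplicate,
                    is_supplementary=aln.is_supplementary,
                )
                continue
            if aln.reference_start < 0:
                raise ValueError(
                    f"mapped record {aln.query_name!r} has negative position"
                )
            span = aln.reference_length or 0
            if span <= 0:
                # Degenerate CIGAR; fall back to the query length.
                span = aln.query_length or 1
            yield AlignmentRecord(
                scaffold_id=aln.reference_name,
                pos=aln.reference_start,
                aligned_length=span,
                mapq=aln.mapping_quality,
                barcode=_barcode_of(aln),
                is_proper_pair=aln.is_proper_pair,
                is_unmapped=False,
                is_duplicate=aln.is_duplicate,
                is_supplementary=aln.is_supplementary,
            )


def write_alignments(
    path: str | Path,
    records: Iterable[AlignmentRecord],
    scaffold_lengths: dict[str, int],
) -> int:
    """Write records as a SAM file with BX barcode tags; return the count.

    The header is synthesised from ``scaffold_lengths``.  Each record is
    emitted as a minimal single-end alignment whose CIGAR consumes
    ``aligned_length`` reference bases, so a read-back through
    :func:`read_alignments` restores every field.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": int(length)}
            for name, length in scaffold_lengths.items()
        ],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, rec in enumerate(records):
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = f"read{i}"
            aln.query_sequence = "*"
            aln.mapping_quality = rec.mapq
            aln.is_unmapped = rec.is_unmapped
            aln.is_paired = True
            aln.is_proper_pair = rec.is_proper_pair
            aln.is_duplicate = rec.is_duplicate
            aln.is_supplementary = rec.is_supplementary
            if not rec.is_unmapped:
                aln.reference_id = out.header.get_tid(rec.scaffold_id)
                aln.reference_start = rec.pos
                aln.cigarstring = f"{rec.aligned_length}M"
            if rec.barcode is not None:
                aln.set_tag("BX", rec.barcode)
            out.write(aln)
            n += 1
    return n


def filter_alignments(
    records: Iterable[AlignmentRecord], min_mapq: int = 10
) -> Iterator[AlignmentRecord]:
    """Keep trusted alignments: MAPQ strictly above ``min_mapq``, properly
    paired, and none of unmapped / PCR duplicate / supplementary.

    The strict ``mapq > min_mapq`` keep rule makes the trusted set exactly
    complementary to the low-confidence set used for the repeat mask
    (``mapq <= min_mapq``).  Order is preserved; the filter is idempotent.
    """
    for rec in records:
        if rec.is_unmapped or rec.is_duplicate or rec.is_supplementary:
            continue
        if not rec.is_proper_pair:
            continue
        if rec.mapq > min_mapq:
            yield rec


def tally_and_filter_barcodes(
    records: Iterable[AlignmentRecord], min_reads: int = 50
) -> tuple[set[str], list[AlignmentRecord]]:
    """Drop barcodes supported by fewer than ``min_reads`` reads.

    Pools with very few reads carry no usable linkage information, so
    only barcodes seen ``min_reads`` or more times are retained.  Reads
    without a barcode are discarded before tallying.

    Returns the retained barcode set and the surviving records, in input
    order.
    """
    kept = [rec for rec in records if rec.barcode is not None]
    tally = Counter(rec.barcode for rec in kept)
    retained = {bc for bc, n in tally.items() if n >= min_reads}
    return retained, [rec for rec in kept if rec.barcode in retained]


def compute_raw_coverage(
    n_reads: int, read_lengths: tuple[int, int], genome_size: int
) -> float:
    """Raw sequence coverage: reads x mean read length / genome size.

    Read pairs with asymmetric lengths (e.g. an 88 bp read one and a
    98 bp read two after barcode trimming) use the mean of the two.
    Reported to two decimals.
    """
    if genome_size <= 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    mean_len = sum(read_lengths) / len(read_lengths)
    return round(n_reads * mean_len / genome_size, 2)


def read_fasta(path: str | Path) -> Iterator[ScaffoldSequence]:
    """Stream scaffolds from a FASTA file (uppercased)."""
    from Bio import SeqIO

    for seq_rec in SeqIO.parse(str(path), "fasta"):
        yield ScaffoldSequence(seq_rec.id, str(seq_rec.seq).upper())


def write_fasta(path: str | Path, scaffolds: Iterable[ScaffoldSequence]) -> int:
    """Write scaffolds to FASTA (60-column wrap); return the count."""
    n = 0
    with open(path, "w") as out:
        for scaf in scaffolds:
            out.write(f">{scaf.scaffold_id}\n")
            seq = scaf.sequence
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")
            n += 1
    return n
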
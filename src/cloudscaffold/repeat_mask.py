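"""Exclusion masks: low-mapping-quality repeat intervals and N-gap runs.

Reads that align ambiguously (low MAPQ) mark repetitive territory.
Collecting their spans and unioning nearby intervals yields a targeted
repeat mask without any sequence-level repeat annotation; runs of N in
the assembly are masked the same way.  Scaffold-end graph nodes exclude
masked bases so that only uniquely-placed reads contribute barcodes.
"""

from __future__ import annotations

import bisect
from pathlib import Path
from typing import Iterable, Iterator

from cloudscaffold.io_formats import AlignmentRecord, ScaffoldSequence

__all__ = [
    "GenomicIntervalSet",
    "mapq_mask",
    "merge_intervals",
    "n_intervals",
    "read_bed",
    "write_bed",
]

_VALID_BASES = frozenset("ACGTN")


class GenomicIntervalSet:
    """0-based half-open intervals grouped by scaffold.

    Intervals may be added in any order; :meth:`normalized` sorts and
    fuses overlapping/touching intervals per scaffold.  Query helpers
    (:meth:`covered`, :meth:`overlap_length`) require a normalized set
    and use bisection.
    """

    def __init__(
        self, intervals: dict[str, list[tuple[int, int]]] | None = None
    ) -> None:
        self._data: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for scaffold, ivals in intervals.items():
                for start, end in ivals:
                    self.add(scaffold, start, end)

    def add(self, scaffold: str, start: int, end: int) -> None:
        if not 0 <= start < end:
            raise ValueError(f"invalid interval ({start}, {end})")
        self._data.setdefault(scaffold, []).append((int(start), int(end)))

    def scaffolds(self) -> list[str]:
        return sorted(self._data)

    def intervals(self, scaffold: str) -> list[tuple[int, int]]:
        return list(self._data.get(scaffold, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomicIntervalSet):
            return NotImplemented
        return self._data == other._data

    def total_length(self) -> int:
        """Sum of interval lengths (meaningful after normalization)."""
        return sum(e - s for ivals in self._data.values() for s, e in ivals)

    def normalized(self, max_gap: int = 0) -> "GenomicIntervalSet":
        """Sorted, disjoint copy; intervals closer than ``max_gap`` fuse.

        With ``max_gap=0`` only overlapping or touching intervals merge;
        ``max_gap=g`` additionally unions intervals separated by a gap
        strictly smaller than ``g`` base pairs.
        """
        out = GenomicIntervalSet()
        for scaffold, ivals in self._data.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(ivals):
                if merged and start - merged[-1][1] < max(max_gap, 1):
                    prev_s, prev_e = merged[-1]
                    merged[-1] = (prev_s, max(prev_e, end))
                else:
                    merged.append((start, end))
            out._data[scaffold] = merged
        return out

    def covered(self, scaffold: str, pos: int) -> bool:
        """True if ``pos`` lies inside a masked interval (normalized set)."""
        ivals = self._data.get(scaffold)
        if not ivals:
            return False
        i = bisect.bisect_right(ivals, (pos, float("inf"))) - 1
        return i >= 0 and ivals[i][0] <= pos < ivals[i][1]

    def overlap_length(self, scaffold: str, start: int, end: int) -> int:
        """Masked bases within [start, end) on a normalized set."""
        total = 0
        for s, e in self._data.get(scaffold, []):
            if s >= end:
                break
            if e > start:
                total += min(e, end) - max(s, start)
        return total

    def union(self, other: "GenomicIntervalSet") -> "GenomicIntervalSet":
        out = GenomicIntervalSet()
        for src in (self, other):
            for scaffold, ivals in src._data.items():
                for s, e in ivals:
                    out.add(scaffold, s, e)
        return out


def mapq_mask(
    records: Iterable[AlignmentRecord], max_mapq: int = 10
) -> GenomicIntervalSet:
    """Collect the spans of low-confidence alignments (MAPQ <= ``max_mapq``).

    Must be applied to the unfiltered stream — the trusted-alignment
    filter would have discarded exactly the records that define this
    mask.  The result is raw (unmerged); follow with
    :func:`merge_intervals`.
    """
    out = GenomicIntervalSet()
    for rec in records:
        if rec.is_unmapped or rec.aligned_length <= 0:
            continue
        if rec.mapq <= max_mapq:
            out.add(rec.scaffold_id, rec.pos, rec.end)
    return out


def merge_intervals(
    intervals: GenomicIntervalSet, max_gap: int = 40
) -> GenomicIntervalSet:
    """Union intervals separated by strictly less than ``max_gap`` bp.

    Produces the nonredundant mask: sorted, disjoint, with sub-40 bp
    slivers of putatively unique sequence absorbed into their flanking
    repeat intervals.
    """
    return intervals.normalized(max_gap=max_gap)


def n_intervals(assembly: Iterable[ScaffoldSequence]) -> GenomicIntervalSet:
    """Maximal runs of N per scaffold, as a mask.

    Raises
    ------
    ValueError
        If a sequence contains characters outside {A, C, G, T, N}.
    """
    out = GenomicIntervalSet()
    for scaf in assembly:
        seq = scaf.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"non-nucleotide characters in {scaf.scaffold_id!r}: {sorted(bad)}"
            )
        start = None
        for i, base in enumerate(seq):
            if base == "N":
                if start is None:
                    start = i
            elif start is not None:
                out.add(scaf.scaffold_id, start, i)
                start = None
        if start is not None:
            out.add(scaf.scaffold_id, start, len(seq))
    return out


def read_bed(path: str | Path) -> GenomicIntervalSet:
    """Read a >=3 column BED file (0-based half-open, native)."""
    out = GenomicIntervalSet()
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            out.add(fields[0], int(fields[1]), int(fields[2]))
    return out


def write_bed(path: str | Path, intervals: GenomicIntervalSet) -> int:
    """Write intervals as 3-column BED; returns the number of lines."""
    n = 0
    with open(path, "w") as out:
        for scaffold in intervals.scaffolds():
            for start, end in intervals.intervals(scaffold):
                out.write(f"{scaffold}\t{start}\t{end}\n")
                n += 1
    return n


def iter_intervals(
    intervals: GenomicIntervalSet,
) -> Iterator[tuple[str, int, int]]:
    for scaffold in intervals.scaffolds():
        for start, end in intervals.intervals(scaffold):
            yield scaffold, start, end
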
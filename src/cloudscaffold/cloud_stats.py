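"""Read-cloud demarcation and physical-coverage / contiguity statistics.

The length distribution of demarcated read clouds is the working proxy
for the molecular-weight distribution of the HMW input DNA: each cloud
is the footprint one long fragment leaves as sparse same-barcode reads.
Clouds are demarcated on the larger scaffolds only (window bookkeeping
on short elements is dominated by edge effects) and one window width is
subtracted from each length estimate, since a multi-window cloud is on
average padded by half a window at either end.
"""

from __future__ import annotations

import dataclasses
import statistics
from typing import Iterable, Mapping, Sequence

from cloudscaffold.io_formats import AlignmentRecord

__all__ = [
    "ReadCloud",
    "AssemblyStats",
    "demarcate_clouds",
    "cloud_length_stats",
    "cloud_density",
    "physical_coverage",
    "coverage_scaling_factor",
    "assembly_stats",
]


@dataclasses.dataclass(frozen=True, slots=True)
class ReadCloud:
    """A maximal run of same-barcode occupied windows on one scaffold."""

    scaffold_id: str
    barcode: str
    first_window: int
    n_windows: int
    n_reads: int
    adjusted_length: int

    def __post_init__(self) -> None:
        if self.n_windows < 1 or self.n_reads < 1:
            raise ValueError("cloud must contain at least one window and read")
        if self.adjusted_length < 0:
            raise ValueError("adjusted_length must be non-negative")


@dataclasses.dataclass(frozen=True, slots=True)
class AssemblyStats:
    """Length-weighted contiguity summary of an assembly."""

    max_length: int
    n50: int
    n10: int
    n90: int
    ng50: int
    total_length: int
    n_elements: int


def demarcate_clouds(
    records: Iterable[AlignmentRecord],
    scaffold_lengths: Mapping[str, int],
    window_size: int = 5000,
    min_scaffold_len: int = 500_000,
) -> list[ReadCloud]:
    """Bin filtered reads into fixed windows and call same-barcode runs.

    Reads on scaffolds no longer than ``min_scaffold_len`` are ignored.
    A window is occupied by a barcode when at least one of its reads has
    its leftmost position inside that window.  Each maximal run of
    consecutive occupied windows becomes one cloud with
    ``adjusted_length = (n_windows - 1) * window_size``; single-window
    clouds therefore contribute reads but zero length.

    Raises
    ------
    KeyError
        If a record names a scaffold absent from ``scaffold_lengths``.
    """
    # (scaffold, barcode) -> {window: read_count}
    occupancy: dict[tuple[str, str], dict[int, int]] = {}
    for rec in records:
        if rec.barcode is None:
            continue
        if rec.scaffold_id not in scaffold_lengths:
            raise KeyError(f"unknown scaffold {rec.scaffold_id!r}")
        if scaffold_lengths[rec.scaffold_id] <= min_scaffold_len:
            continue
        window = rec.pos // window_size
        counts = occupancy.setdefault((rec.scaffold_id, rec.barcode), {})
        counts[window] = counts.get(window, 0) + 1

    clouds: list[ReadCloud] = []
    for (scaffold, barcode), counts in occupancy.items():
        windows = sorted(counts)
        run_start = windows[0]
        run_reads = counts[windows[0]]
        prev = windows[0]
        for w in windows[1:]:
            if w == prev + 1:
                run_reads += counts[w]
            else:
                n_win = prev - run_start + 1
                clouds.append(
                    ReadCloud(
                        scaffold, barcode, run_start, n_win, run_reads,
                        (n_win - 1) * window_size,
                    )
                )
                run_start, run_reads = w, counts[w]
            prev = w
        n_win = prev - run_start + 1
        clouds.append(
            ReadCloud(
                scaffold, barcode, run_start, n_win, run_reads,
                (n_win - 1) * window_size,
            )
        )
    return clouds


def cloud_length_stats(clouds: Sequence[ReadCloud]) -> tuple[float, int]:
    """Median and length-weighted N50 of adjusted cloud lengths.

    The N50 is the cloud length at which the descending cumulative sum
    first reaches half the total: half the physical coverage comes from
    clouds at least this long.
    """
    if not clouds:
        raise ValueError("cannot summarise an empty cloud set")
    lengths = sorted((c.adjusted_length for c in clouds), reverse=True)
    median = statistics.median(lengths)
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if 2 * cum >= total:
            n50 = length
            break
    return median, n50


def cloud_density(clouds: Sequence[ReadCloud]) -> float:
    """Pooled aligned reads per kilobase of cloud length.

    A single ratio of totals (not a mean of per-cloud ratios): total
    reads divided by total adjusted length in kb.
    """
    total_reads = sum(c.n_reads for c in clouds)
    total_kb = sum(c.adjusted_length for c in clouds) / 1000.0
    if total_kb <= 0:
        raise ValueError("total adjusted cloud length is zero")
    return total_reads / total_kb


def coverage_scaling_factor(n_aligned_all: int, n_aligned_large: int) -> float:
    """Ratio lifting large-scaffold physical coverage to the whole genome.

    Clouds are demarcated only on the larger scaffolds; the observed
    coverage is scaled by all aligned reads over reads aligned to those
    scaffolds.
    """
    if n_aligned_large <= 0:
        raise ValueError("no reads aligned to the large-scaffold subset")
    return n_aligned_all / n_aligned_large


def physical_coverage(
    clouds: Sequence[ReadCloud], scaling: float, genome_size: int
) -> float:
    """Genome-wide physical coverage in HMW fragments (x)."""
    if genome_size <= 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    if scaling < 1:
        raise ValueError("scaling factor must be >= 1")
    total = sum(c.adjusted_length for c in clouds)
    return total * scaling / genome_size


def assembly_stats(
    lengths: Sequence[int], genome_size: int | None = None
) -> AssemblyStats:
    """N50 / N10 / N90 (vs. total length) and NG50 (vs. genome size).

    Nxx is the element length at which the descending cumulative length
    first reaches xx% of the total assembly length; NG50 is identical
    but measured against half the assumed genome size.  All reported
    values are lengths of actual input elements; NG50 is 0 when the
    assembly never reaches half the genome size.
    """
    if not lengths:
        raise ValueError("cannot compute contiguity of an empty assembly")
    if any(x <= 0 for x in lengths):
        raise ValueError("element lengths must be positive")
    desc = sorted(lengths, reverse=True)
    total = sum(desc)

    def n_stat(target: float) -> int:
        cum = 0
        for length in desc:
            cum += length
            if cum >= target:
                return length
        return 0

    return AssemblyStats(
        max_length=desc[0],
        n50=n_stat(total * 0.50),
        n10=n_stat(total * 0.10),
        n90=n_stat(total * 0.90),
        ng50=n_stat(genome_size * 0.50) if genome_size else 0,
        total_length=total,
        n_elements=len(desc),
    )
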
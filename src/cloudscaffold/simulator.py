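"""Synthetic linked-read libraries with full truth tables.

The simulator emulates the statistical structure of a GemCode-style
read-cloud library on a repeat-rich conifer-like genome, so that every
pipeline stage can be exercised offline:

* a genome in which ~79% of bases lie in planted copies of repeat
  families, a sub-fraction of which are *mapping-ambiguous* (recently
  expanded, near-identical copies) — only reads from ambiguous
  territory receive low mapping quality, mirroring the fact that a
  MAPQ-derived exclusion mask is far more targeted than a sequence-level
  repeat annotation;
* HMW fragments drawn from a lognormal law pinned to a 50 kb median and
  an 80 kb length-weighted N50, partitioned into barcoded pools with
  Poisson fragment counts;
* sparse read sampling along each fragment such that the density of
  *trusted* (filter-surviving) reads within a cloud is the configured
  reads-per-kb — the quantity a pipeline actually observes.

Alignment is emulated, not performed: reads are placed at their true
loci and MAPQ is assigned by territory.  All randomness flows from the
single config seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from cloudscaffold.io_formats import AlignmentRecord, ScaffoldSequence
from cloudscaffold.repeat_mask import GenomicIntervalSet
from cloudscaffold.calibration import ChildRecord, LiftTable

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "ReadTruth",
    "DraftTruth",
    "SimulatedLibrary",
    "simulate_genome",
    "fragment_and_pool",
    "sample_reads",
    "make_draft",
    "simulate_library",
]

GENOME_ID = "genome"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Study conditions for one synthetic library.

    Defaults emulate, at desk scale, a 5 Mb slice of a large repetitive
    genome sequenced with one read-cloud library: 79% of bases in
    planted repeats, HMW fragments with a 50 kb median and 80 kb
    length-weighted N50, pools sized so total physical coverage is
    ~24x, and ~1 trusted read per kilobase within each cloud.
    ``mapq_ambiguous_fraction`` is the fraction of repeat bases whose
    copies are recent enough to defeat unique mapping; reads starting
    there draw MAPQ <= ``mapq_in_repeat``.
    """

    genome_length: int = 5_000_000
    repeat_fraction: float = 0.79
    n_repeat_families: int = 20
    repeat_length_range: tuple[int, int] = (500, 3000)
    mapq_ambiguous_fraction: float = 0.48
    ambiguous_length_range: tuple[int, int] = (100, 300)
    fragment_median: int = 50_000
    fragment_n50: int = 80_000
    n_pools: int = 512
    fragments_per_pool_mean: float = 3.7
    read_density: float = 1.0
    read_length: int = 100
    mapq_in_repeat: int = 10
    duplicate_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must lie in [0, 1)")
        if not 0.0 <= self.mapq_ambiguous_fraction <= 1.0:
            raise ValueError("mapq_ambiguous_fraction must lie in [0, 1]")
        if self.read_density <= 0:
            raise ValueError("read_density must be positive")
        if min(
            self.genome_length,
            self.fragment_median,
            self.fragment_n50,
            self.read_length,
        ) <= 0:
            raise ValueError("all lengths must be positive")
        if self.repeat_fraction > 0 and self.n_repeat_families < 1:
            raise ValueError("need at least one repeat family to plant repeats")
        if self.repeat_length_range[1] > self.genome_length:
            raise ValueError("repeat unit longer than the genome")
        if self.fragment_n50 < self.fragment_median:
            raise ValueError("length-weighted N50 cannot be below the median")

    @property
    def raw_read_rate(self) -> float:
        """Raw per-kb sampling rate along a fragment.

        Chosen so that after MAPQ filtering the surviving (trusted)
        density within a cloud is ``read_density`` on average.
        """
        ambiguous_share = self.repeat_fraction * self.mapq_ambiguous_fraction
        return self.read_density / (1.0 - ambiguous_share)

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the fragment-length law.

        A lognormal has median e^mu; its length-weighted distribution is
        again lognormal with median e^(mu + sigma^2), so two summary
        points pin both parameters: mu = ln(median),
        sigma = sqrt(ln(N50 / median)).
        """
        mu = float(np.log(self.fragment_median))
        sigma = float(np.sqrt(np.log(self.fragment_n50 / self.fragment_median)))
        return mu, sigma


@dataclasses.dataclass(frozen=True, slots=True)
class SimulatedGenome:
    sequence: ScaffoldSequence
    repeats: GenomicIntervalSet  # all planted repeat copies, merged
    ambiguous: GenomicIntervalSet  # mapping-ambiguous subset, merged


@dataclasses.dataclass(frozen=True, slots=True)
class ReadTruth:
    """Provenance of one simulated read."""

    fragment_id: int
    barcode: str
    locus: int  # true leftmost genome coordinate
    in_repeat: bool
    in_ambiguous: bool


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedGenome:
    """Random genome with planted repeat-family copies.

    Copies of ``n_repeat_families`` consensus units are stamped at
    random loci until the merged repeat annotation covers
    ``repeat_fraction`` of the genome.  Each copy is independently
    flagged mapping-ambiguous with probability
    ``mapq_ambiguous_fraction``.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.genome_length
    genome = rng.choice(_BASES, size=n)
    repeat_mask = np.zeros(n, dtype=bool)
    ambiguous_mask = np.zeros(n, dtype=bool)

    if config.repeat_fraction > 0:
        lo, hi = config.repeat_length_range
        fam_lengths = rng.integers(lo, hi + 1, size=config.n_repeat_families)
        families = [rng.choice(_BASES, size=int(L)) for L in fam_lengths]
        target = int(config.repeat_fraction * n)
        covered = 0
        copies: list[tuple[int, int]] = []
        # Overlaps slow convergence near high fractions; cap the loop.
        max_iter = int(40 * n / max(int(fam_lengths.mean()), 1))
        iterations = 0
        while covered < target:
            if iterations >= max_iter:
                raise ValueError(
                    "could not reach the requested repeat_fraction; "
                    "repeat units too short for the target"
                )
            iterations += 1
            fam = int(rng.integers(config.n_repeat_families))
            unit = families[fam]
            pos = int(rng.integers(0, n - len(unit) + 1))
            genome[pos : pos + len(unit)] = unit
            before = int(repeat_mask[pos : pos + len(unit)].sum())
            repeat_mask[pos : pos + len(unit)] = True
            covered += len(unit) - before
            copies.append((pos, len(unit)))

        # Mapping-ambiguous territory is planted as short intervals
        # *inside* repeat copies, against its own coverage target: the
        # bulk annotation is dominated by old, diverged elements that
        # still map uniquely, while only young near-identical insertions
        # (a few hundred bp) defeat unique mapping.  Short ambiguous
        # runs also mean a cloud's trusted reads rarely skip a whole
        # demarcation window.
        amb_target = int(
            config.repeat_fraction * config.mapq_ambiguous_fraction * n
        )
        if config.mapq_ambiguous_fraction >= 1.0:
            ambiguous_mask = repeat_mask.copy()
        elif amb_target > 0 and copies:
            # Uniform over repeat territory: sample an offset into the
            # merged repeat runs by inverse CDF, clip the interval to its
            # run.  Sampling per copy instead would concentrate ambiguity
            # where copies pile up.
            padded = np.concatenate(([False], repeat_mask, [False]))
            flanks = np.flatnonzero(padded[1:] != padded[:-1])
            run_starts, run_ends = flanks[::2], flanks[1::2]
            run_cum = np.concatenate(([0], np.cumsum(run_ends - run_starts)))
            lo_a, hi_a = config.ambiguous_length_range
            amb_covered = 0
            iterations = 0
            amb_max_iter = int(40 * n / max(lo_a, 1))
            while amb_covered < amb_target:
                if iterations >= amb_max_iter:
                    raise ValueError(
                        "could not reach the ambiguous coverage target"
                    )
                iterations += 1
                offset = int(rng.integers(0, run_cum[-1]))
                run = int(np.searchsorted(run_cum, offset, side="right") - 1)
                a_pos = int(run_starts[run]) + (offset - int(run_cum[run]))
                a_len = int(rng.integers(lo_a, hi_a + 1))
                a_end = min(a_pos + a_len, int(run_ends[run]))
                before = int(ambiguous_mask[a_pos:a_end].sum())
                ambiguous_mask[a_pos:a_end] = True
                amb_covered += (a_end - a_pos) - before

    seq = ScaffoldSequence(GENOME_ID, genome.tobytes().decode("ascii"))
    return SimulatedGenome(
        sequence=seq,
        repeats=_mask_to_intervals(repeat_mask),
        ambiguous=_mask_to_intervals(ambiguous_mask),
    )


def _mask_to_intervals(mask: np.ndarray) -> GenomicIntervalSet:
    out = GenomicIntervalSet()
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for start, end in zip(edges[::2], edges[1::2]):
        out.add(GENOME_ID, int(start), int(end))
    return out.normalized()


def fragment_and_pool(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[tuple[int, int]]]:
    """Partition HMW fragments into barcoded pools.

    Fragment lengths follow the lognormal law pinned by the configured
    median and length-weighted N50; each of ``n_pools`` barcodes
    receives a Poisson(``fragments_per_pool_mean``) number of fragments
    dropped uniformly on the genome (clipped at the right end).
    """
    mu, sigma = config.lognormal_params
    pools: dict[str, list[tuple[int, int]]] = {}
    counts = rng.poisson(config.fragments_per_pool_mean, size=config.n_pools)
    for i, count in enumerate(counts):
        barcode = f"BC{i:06d}-1"
        frags: list[tuple[int, int]] = []
        for _ in range(int(count)):
            length = max(int(rng.lognormal(mu, sigma)), config.read_length)
            start = int(rng.integers(0, config.genome_length))
            end = min(start + length, config.genome_length)
            frags.append((start, end))
        pools[barcode] = frags
    return pools


def sample_reads(
    pools: Mapping[str, Sequence[tuple[int, int]]],
    genome: SimulatedGenome,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[AlignmentRecord], list[ReadTruth]]:
    """Sparse read sampling along each fragment, with territory MAPQ.

    Reads are placed uniformly at the raw per-kb rate derived from
    ``read_density``; a read starting in mapping-ambiguous territory
    draws MAPQ in [0, ``mapq_in_repeat``], all others in [30, 60].  A
    small configurable fraction is flagged as PCR duplicate to exercise
    the filters.
    """
    records: list[AlignmentRecord] = []
    truths: list[ReadTruth] = []
    rate = config.raw_read_rate
    fragment_id = 0
    for barcode in sorted(pools):
        for start, end in pools[barcode]:
            span = end - start
            n_reads = int(rng.poisson(rate * span / 1000.0))
            max_start = max(end - config.read_length, start)
            positions = np.sort(rng.integers(start, max_start + 1, size=n_reads))
            for pos in positions:
                pos = int(pos)
                in_amb = genome.ambiguous.covered(GENOME_ID, pos)
                in_rep = genome.repeats.covered(GENOME_ID, pos)
                if in_amb:
                    mapq = int(rng.integers(0, config.mapq_in_repeat + 1))
                else:
                    mapq = int(rng.integers(30, 61))
                length = min(config.read_length, config.genome_length - pos)
                rec = AlignmentRecord(
                    scaffold_id=GENOME_ID,
                    pos=pos,
                    aligned_length=length,
                    mapq=mapq,
                    barcode=barcode,
                    is_proper_pair=True,
                )
                records.append(rec)
                truths.append(
                    ReadTruth(fragment_id, barcode, pos, in_rep, in_amb)
                )
                # PCR duplicates are extra flagged copies of a library
                # molecule, not losses from it.
                if rng.random() < config.duplicate_fraction:
                    records.append(
                        dataclasses.replace(rec, is_duplicate=True)
                    )
                    truths.append(
                        ReadTruth(fragment_id, barcode, pos, in_rep, in_amb)
                    )
            fragment_id += 1
    return records, truths


@dataclasses.dataclass(frozen=True, slots=True)
class DraftTruth:
    """True order and orientation of draft pieces cut from the genome.

    ``pieces`` is in genome order; ``emitted_order`` gives the shuffled
    order in which the draft FASTA lists them.
    """

    piece_ids: tuple[str, ...]  # genome order
    offsets: tuple[int, ...]
    lengths: tuple[int, ...]
    forward: tuple[bool, ...]
    emitted_order: tuple[int, ...]

    def true_adjacencies(self) -> set[frozenset[str]]:
        return {
            frozenset((self.piece_ids[i], self.piece_ids[i + 1]))
            for i in range(len(self.piece_ids) - 1)
        }

    def to_lift_table(self) -> LiftTable:
        last = len(self.piece_ids) - 1
        return LiftTable(
            [
                ChildRecord(
                    child_id=self.piece_ids[i],
                    parent_id=GENOME_ID,
                    parent_offset=self.offsets[i],
                    length=self.lengths[i],
                    index_in_parent=i,
                    is_terminal=i in (0, last),
                )
                for i in range(len(self.piece_ids))
            ]
        )

    def lift_reads(
        self, records: Sequence[AlignmentRecord]
    ) -> list[AlignmentRecord]:
        """Re-express genome-coordinate reads in draft-piece coordinates.

        Membership follows the leftmost base; spans are clipped at piece
        boundaries; positions on reverse-oriented pieces are flipped.
        """
        bounds = np.array(self.offsets)
        out: list[AlignmentRecord] = []
        for rec in records:
            i = int(np.searchsorted(bounds, rec.pos, side="right") - 1)
            local = rec.pos - self.offsets[i]
            span = min(rec.aligned_length, self.lengths[i] - local)
            span = max(span, 1)
            if self.forward[i]:
                pos = local
            else:
                pos = self.lengths[i] - (local + span)
            out.append(
                dataclasses.replace(
                    rec, scaffold_id=self.piece_ids[i], pos=pos,
                    aligned_length=span,
                )
            )
        return out

    def piece_lengths(self) -> dict[str, int]:
        return dict(zip(self.piece_ids, self.lengths))


def make_draft(
    genome: ScaffoldSequence,
    piece_length: int,
    rng: np.random.Generator,
) -> tuple[list[ScaffoldSequence], DraftTruth]:
    """Cut the genome into consecutive pieces, shuffled and re-oriented.

    The final piece absorbs the remainder when the genome length is not
    a multiple of ``piece_length``.  The returned truth table suffices
    to classify any join between pieces as true-adjacent or not.
    """
    if piece_length > len(genome.sequence):
        raise ValueError("piece_length exceeds the genome length")
    from cloudscaffold.scaffolder import reverse_complement

    n = len(genome.sequence)
    n_pieces = max(n // piece_length, 1)
    offsets = [i * piece_length for i in range(n_pieces)]
    lengths = [
        (n - offsets[i]) if i == n_pieces - 1 else piece_length
        for i in range(n_pieces)
    ]
    ids = tuple(f"piece_{i:04d}" for i in range(n_pieces))
    forward = tuple(bool(b) for b in rng.random(n_pieces) < 0.5)
    order = tuple(int(i) for i in rng.permutation(n_pieces))

    pieces = []
    for i in order:
        seq = genome.sequence[offsets[i] : offsets[i] + lengths[i]]
        if not forward[i]:
            seq = reverse_complement(seq)
        pieces.append(ScaffoldSequence(ids[i], seq))
    truth = DraftTruth(ids, tuple(offsets), tuple(lengths), forward, order)
    return pieces, truth


@dataclasses.dataclass(frozen=True, slots=True)
class SimulatedLibrary:
    """One fully simulated library: genome, pools, reads, truth."""

    config: SimulationConfig
    genome: SimulatedGenome
    pools: dict[str, list[tuple[int, int]]]
    records: list[AlignmentRecord]
    read_truth: list[ReadTruth]


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Run the full generative model from the single config seed."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    pools = fragment_and_pool(config, rng)
    records, truths = sample_reads(pools, genome, config, rng)
    return SimulatedLibrary(config, genome, pools, records, truths)
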
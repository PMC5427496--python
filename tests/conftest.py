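"""Shared fixtures: a small simulated library and draft problem."""

from __future__ import annotations

import numpy as np
import pytest

from cloudscaffold import io_formats, repeat_mask
from cloudscaffold.simulator import (
    SimulationConfig,
    make_draft,
    simulate_library,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 1 Mb library small enough for per-test use."""
    return SimulationConfig(genome_length=1_000_000, n_pools=110, seed=11)


@pytest.fixture(scope="session")
def small_library(small_config):
    return simulate_library(small_config)


@pytest.fixture(scope="session")
def small_problem(small_config, small_library):
    """Draft pieces + draft-coordinate reads + mask, ready to scaffold."""
    rng = np.random.default_rng(small_config.seed + 1)
    pieces, truth = make_draft(
        small_library.genome.sequence, 50_000, rng
    )
    records = truth.lift_reads(small_library.records)
    mask = repeat_mask.merge_intervals(repeat_mask.mapq_mask(records))
    filtered = list(io_formats.filter_alignments(records))
    _, kept = io_formats.tally_and_filter_barcodes(filtered)
    return {
        "pieces": pieces,
        "truth": truth,
        "records": records,
        "mask": mask,
        "kept": kept,
    }
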
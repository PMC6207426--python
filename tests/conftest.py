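"""Shared fixtures: small synthetic sessions and one full pipeline run.

Everything is generated programmatically with fixed seeds; the expensive
end-to-end pipeline (14 tetrodes, 240 s run + 300 s rest) is session-scoped
and shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from replaydetect import encoding, synthetic
from replaydetect.pipeline import run_synthetic_pipeline

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def maze():
    return synthetic.MazeSpec()


@pytest.fixture(scope="session")
def grid(maze):
    return encoding.MazeGrid.from_maze(maze)


@pytest.fixture(scope="session")
def small_cells(maze):
    return synthetic.make_default_population(maze, n_tetrodes=6, cells_per_tetrode=3, seed=11)


@pytest.fixture(scope="session")
def small_run(maze, small_cells):
    """Short run epoch (positions with recomputed speed, spikes)."""
    pos, spikes = synthetic.simulate_run_epoch(maze, small_cells, duration=90.0, seed=12)
    return encoding.compute_speed(pos), spikes


@pytest.fixture(scope="session")
def small_model(small_run, grid):
    pos, spikes = small_run
    return encoding.build_encoding_model(spikes, pos, grid, compression_threshold=1.8)


@pytest.fixture(scope="session")
def e2e():
    """Full 14-tetrode pipeline at the default study conditions."""
    return run_synthetic_pipeline(
        seed=1, n_tetrodes=14, run_duration=240.0, rest_duration=300.0, n_shuffles=200
    )


def make_stream(posterior, mua_counts, grid, bin_size=0.010, t0=0.0):
    """Assemble a PosteriorStream from raw arrays (test scaffolding)."""
    from replaydetect.decoding import PosteriorStream

    posterior = np.asarray(posterior, float)
    return PosteriorStream(
        bin_size=bin_size,
        bin_starts=t0 + bin_size * np.arange(len(posterior)),
        posterior=posterior,
        mua_counts=np.asarray(mua_counts, int),
        map_index=posterior.argmax(axis=1),
        grid=grid,
    )


def concentrated_rows(grid, bin_indices, peak=0.9):
    """Posterior rows with ``peak`` mass at given grid bins, remainder uniform."""
    bin_indices = np.asarray(bin_indices, int)
    G = grid.n_bins
    rows = np.full((len(bin_indices), G), (1.0 - peak) / (G - 1))
    rows[np.arange(len(bin_indices)), bin_indices] = peak
    return rows
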
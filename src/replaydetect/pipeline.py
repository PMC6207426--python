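"""End-to-end convenience pipeline on synthetic sessions.

Wires the full method together the way an experiment would run it: build
the encoding model from the run epoch, decode the rest epoch in 10 ms
bins, derive the offline reference events (with a lower compression level
for higher decoding fidelity), replay the online detector over the saved
posteriors, and score the detections against the reference. Used by the
command-line tools, the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decoding, encoding, evaluation, offline, online, synthetic
from .session_io import SessionBundle


@dataclass
class PipelineResult:
    bundle: SessionBundle
    cells: synthetic.PlaceCellPopulation
    grid: encoding.MazeGrid
    model_online: encoding.EncodingModel
    model_offline: encoding.EncodingModel
    stream_online: decoding.PosteriorStream
    stream_offline: decoding.PosteriorStream
    bursts: list
    reference: list
    detections: list
    counts: evaluation.ConfusionCounts
    assignments: list
    metrics: evaluation.PerformanceMetrics
    config: online.DetectorConfig
    run_counts_by_tetrode: dict[int, np.ndarray]
    epoch: tuple[float, float]


def run_epoch_counts(
    spikes: pd.DataFrame, epoch: tuple[float, float], bin_size: float = 0.010
) -> dict[int, np.ndarray]:
    """Per-tetrode spike counts on the decoding-bin grid of an epoch."""
    n = int(np.floor((epoch[1] - epoch[0]) / bin_size))
    edges = epoch[0] + bin_size * np.arange(n + 1)
    out = {}
    for k, sub in spikes.groupby("tetrode_id"):
        out[int(k)], _ = np.histogram(np.asarray(sub["t"], float), bins=edges)
    return out


def run_synthetic_pipeline(
    seed: int = 0,
    n_tetrodes: int = 14,
    cells_per_tetrode: int = 4,
    run_duration: float = 240.0,
    rest_duration: float = 300.0,
    compression_online: float = 1.8,
    compression_offline: float = 1.15,
    theta_mua: float = 2.5,
    theta_sharp: float = 0.5,
    n_bins: int = 3,
    lockout: float = 0.075,
    n_shuffles: int = 200,
    bin_size: float = 0.010,
    **burst_kwargs,
) -> PipelineResult:
    """Simulate a session and run the whole detection/evaluation chain.

    Detector thresholds default to the live rest-epoch settings
    (theta_mua 2.5 z-units, theta_sharp 0.5, 3-bin window, 75 ms lock-out);
    the online model uses compression 1.8, the offline reference a lower
    1.15 for higher decoding fidelity. ``n_shuffles`` controls the size of
    the shuffle nulls behind the offline content scores.
    """
    bundle, cells = synthetic.simulate_session(
        n_tetrodes=n_tetrodes,
        cells_per_tetrode=cells_per_tetrode,
        run_duration=run_duration,
        rest_duration=rest_duration,
        seed=seed,
        **burst_kwargs,
    )
    maze = synthetic.MazeSpec()
    grid = encoding.MazeGrid.from_maze(maze)

    pos = bundle.positions["RUN1"]
    pos = encoding.compute_speed(pos)  # recompute speed from the 1D trace
    run_spikes = bundle.spikes["RUN1"]
    rest_spikes = bundle.spikes["REST"]
    rest_epoch = bundle.epochs["REST"]

    model_online = encoding.build_encoding_model(
        run_spikes, pos, grid, compression_threshold=compression_online
    )
    model_offline = encoding.build_encoding_model(
        run_spikes, pos, grid, compression_threshold=compression_offline
    )

    stream_online = decoding.decode_stream(model_online, rest_spikes, bin_size, *rest_epoch)
    stream_offline = decoding.decode_stream(model_offline, rest_spikes, bin_size, *rest_epoch)

    mua = offline.detrend_and_zscore(offline.compute_mua(rest_spikes, rest_epoch))
    bursts = offline.detect_bursts(mua)
    reference = offline.reference_from_stream(
        stream_offline, bursts, n_shuffles=n_shuffles, seed=seed
    )

    run_counts = run_epoch_counts(run_spikes, bundle.epochs["RUN1"], bin_size)
    mua_norm = online.estimate_mua_norm(np.sum(list(run_counts.values()), axis=0))
    config = online.DetectorConfig(
        theta_mua=theta_mua,
        theta_sharp=theta_sharp,
        n_bins=n_bins,
        bin_size=bin_size,
        lockout=lockout,
        mua_norm=mua_norm,
    )
    detections = online.detect_stream(stream_online, config)
    counts, assignments = evaluation.match_detections(detections, reference, rest_duration)
    metrics = evaluation.compute_metrics(counts, rest_duration, assignments)

    return PipelineResult(
        bundle=bundle,
        cells=cells,
        grid=grid,
        model_online=model_online,
        model_offline=model_offline,
        stream_online=stream_online,
        stream_offline=stream_offline,
        bursts=bursts,
        reference=reference,
        detections=detections,
        counts=counts,
        assignments=assignments,
        metrics=metrics,
        config=config,
        run_counts_by_tetrode=run_counts,
        epoch=rest_epoch,
    )
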
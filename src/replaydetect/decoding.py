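"""Bayesian position decoding from unsorted spikes.

Per decoding bin of width ``delta`` (default 10 ms), the posterior over the
grid of maze positions combines all tetrodes under conditional
independence:

    log P(x | A_1..K)  =  sum_k [ sum_i log lambda_k(a_i, x) ]
                          -  delta * sum_k lambda_k(x)  +  const

with a uniform prior. The per-bin ``delta**n`` prefactor and the evidence
are constant across positions and cancel on normalization; the exponential
uses a max-subtraction for numerical stability. Rates are floored (see
:mod:`.encoding`) so a mark far from every kernel component cannot produce
``log(0)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import EncodingModel, MazeGrid, build_encoding_model

DEFAULT_BIN_SIZE = 0.010  # s


@dataclass
class PosteriorStream:
    """Sequence of per-bin posteriors plus multi-unit spike counts.

    ``posterior`` rows each sum to 1; ``map_index`` is the per-row argmax
    (ties broken toward the lowest grid index); ``mua_counts`` is the total
    spike count over all tetrodes per bin.
    """

    bin_size: float
    bin_starts: np.ndarray  # (B,) s
    posterior: np.ndarray  # (B, G)
    mua_counts: np.ndarray  # (B,) int
    map_index: np.ndarray  # (B,) int
    grid: MazeGrid

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)

    @property
    def map_arm(self) -> np.ndarray:
        return self.grid.arm_ids[self.map_index]

    def slice(self, i0: int, i1: int) -> "PosteriorStream":
        return PosteriorStream(
            bin_size=self.bin_size,
            bin_starts=self.bin_starts[i0:i1],
            posterior=self.posterior[i0:i1],
            mua_counts=self.mua_counts[i0:i1],
            map_index=self.map_index[i0:i1],
            grid=self.grid,
        )


def _normalize_log(loglik: np.ndarray) -> np.ndarray:
    shifted = loglik - loglik.max(axis=-1, keepdims=True)
    p = np.exp(shifted)
    return p / p.sum(axis=-1, keepdims=True)


def decode_bin(model: EncodingModel, spikes_in_bin: dict, delta: float) -> np.ndarray:
    """Posterior row for one bin.

    ``spikes_in_bin`` maps tetrode id -> (n, 4) array of amplitude marks
    observed in the bin (tetrodes with no spikes may be omitted).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    loglik = np.zeros(model.grid.n_bins)
    for k, m in model.tetrode_models.items():
        loglik -= delta * m.lam_x
        amps = spikes_in_bin.get(k)
        if amps is None or len(amps) == 0:
            continue
        amps = np.atleast_2d(np.asarray(amps, float))
        if amps.shape[1] != 4:
            raise ValueError("amplitude vectors must have 4 channels")
        loglik += np.log(m.joint_rate(amps)).sum(axis=0)
    return _normalize_log(loglik)


def decode_stream(
    model: EncodingModel,
    spikes: pd.DataFrame,
    bin_size: float = DEFAULT_BIN_SIZE,
    t0: float = 0.0,
    t1: float = None,
) -> PosteriorStream:
    """Decode a spike stream into non-overlapping half-open bins.

    Bin ``k`` covers ``[t0 + k*bin_size, t0 + (k+1)*bin_size)``; a spike
    exactly at a boundary belongs to the later bin. Only full bins inside
    ``[t0, t1)`` are produced. Empty bins yield the no-spike likelihood
    ``exp(-delta * sum_k lambda_k(x))``, normalized.
    """
    if t1 is None:
        t1 = float(np.asarray(spikes["t"], float).max()) + bin_size if len(spikes) else t0
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    n_bins = int(np.floor((t1 - t0) / bin_size + 1e-9))
    G = model.grid.n_bins

    base = np.zeros(G)
    for m in model.tetrode_models.values():
        base -= bin_size * m.lam_x
    loglik = np.tile(base, (n_bins, 1))
    mua = np.zeros(n_bins, dtype=int)

    t = np.asarray(spikes["t"], float)
    tet = np.asarray(spikes["tetrode_id"], int)
    amps = np.asarray(spikes[["a1", "a2", "a3", "a4"]], float)
    bin_idx = np.floor((t - t0) / bin_size).astype(int)
    inside = (bin_idx >= 0) & (bin_idx < n_bins)

    for k, m in model.tetrode_models.items():
        sel = inside & (tet == k)
        if not np.any(sel):
            continue
        idx = bin_idx[sel]
        # chunk the (n_spikes, G) log-rate matrix to bound memory
        a = amps[sel]
        for c0 in range(0, len(idx), 20_000):
            c1 = min(c0 + 20_000, len(idx))
            logl = np.log(m.joint_rate(a[c0:c1]))
            np.add.at(loglik, idx[c0:c1], logl)
    np.add.at(mua, bin_idx[inside], 1)

    posterior = _normalize_log(loglik)
    return PosteriorStream(
        bin_size=bin_size,
        bin_starts=t0 + bin_size * np.arange(n_bins),
        posterior=posterior,
        mua_counts=mua,
        map_index=posterior.argmax(axis=1),
        grid=model.grid,
    )


# ---------------------------------------------------------------------------
# Cross-validated run decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodingQuality:
    """Cross-validated run-decoding performance."""

    median_error: float  # cm, across-arm path distance
    median_in_arm_error: float  # cm, over arm-correct bins only
    fraction_arm_correct: float
    errors: np.ndarray  # per test bin
    in_arm_errors: np.ndarray


def _run_segments(speed: np.ndarray, threshold: float) -> list[np.ndarray]:
    qual = speed > threshold
    edges = np.flatnonzero(np.diff(qual.astype(int)))
    bounds = np.concatenate([[0], edges + 1, [len(qual)]])
    return [
        np.arange(bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
        if qual[bounds[i]]
    ]


def crossvalidate_run_decoding(
    spikes: pd.DataFrame,
    pos: pd.DataFrame,
    grid: MazeGrid,
    folds: int = 2,
    bin_size: float = 0.200,
    speed_threshold: float = 8.5,
    compression: float = 1.8,
) -> DecodingQuality:
    """K-fold cross-validated decoding of the animal's own position.

    Contiguous above-threshold run segments are assigned to folds in
    alternation; for each fold a model is built from the remaining
    segments and evaluated on ``bin_size`` bins of the held-out segments.
    The per-bin error is the path distance (through the central platform
    for cross-arm mistakes) between the MAP estimate and the true mean
    position; the in-arm error is computed over arm-correct bins only.
    """
    if folds < 2:
        raise ValueError("cross-validation requires at least 2 folds")
    pt = np.asarray(pos["t"], float)
    speed = np.asarray(pos["speed"], float)
    segments = _run_segments(speed, speed_threshold)
    if len(segments) < folds:
        raise ValueError("not enough run segments for the requested number of folds")

    spike_t = np.asarray(spikes["t"], float)
    errors, in_arm_errors, arm_correct = [], [], []

    for f in range(folds):
        train_idx = np.concatenate([s for i, s in enumerate(segments) if i % folds != f])
        test_segs = [s for i, s in enumerate(segments) if i % folds == f]
        train_pos = pos.iloc[train_idx]
        tmask = np.zeros(len(spike_t), dtype=bool)
        for s in [seg for i, seg in enumerate(segments) if i % folds != f]:
            tmask |= (spike_t >= pt[s[0]]) & (spike_t < pt[s[-1]])
        model = build_encoding_model(
            spikes[tmask], train_pos, grid,
            speed_threshold=speed_threshold, compression_threshold=compression,
        )

        n_test_bins = 0
        for seg in test_segs:
            seg_t0, seg_t1 = pt[seg[0]], pt[seg[-1]]
            for b0 in np.arange(seg_t0, seg_t1 - bin_size + 1e-9, bin_size):
                in_bin = (spike_t >= b0) & (spike_t < b0 + bin_size)
                per_tet = {
                    int(k): np.asarray(sub[["a1", "a2", "a3", "a4"]], float)
                    for k, sub in spikes[in_bin].groupby("tetrode_id")
                }
                row = decode_bin(model, per_tet, bin_size)
                map_idx = int(row.argmax())
                map_arm = int(grid.arm_ids[map_idx])
                map_pos = float(grid.centers[map_idx])

                in_pos = (pt >= b0) & (pt < b0 + bin_size)
                arms = np.asarray(pos["arm"], int)[in_pos]
                lins = np.asarray(pos["lin_pos"], float)[in_pos]
                if len(arms) == 0:
                    continue
                true_arm = int(np.bincount(arms).argmax())
                true_pos = float(lins[arms == true_arm].mean())
                if map_arm == true_arm:
                    err = abs(map_pos - true_pos)
                    in_arm_errors.append(err)
                    arm_correct.append(True)
                else:
                    err = map_pos + true_pos
                    arm_correct.append(False)
                errors.append(err)
                n_test_bins += 1
        if n_test_bins == 0:
            raise ValueError(f"fold {f} has zero test bins")

    errors = np.asarray(errors)
    in_arm = np.asarray(in_arm_errors)
    return DecodingQuality(
        median_error=float(np.median(errors)),
        median_in_arm_error=float(np.median(in_arm)) if len(in_arm) else float("nan"),
        fraction_arm_correct=float(np.mean(arm_correct)),
        errors=errors,
        in_arm_errors=in_arm,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_posteriors(stream: PosteriorStream, path: str | Path) -> None:
    """Binary array archive plus JSON sidecar describing bins and grid."""
    path = Path(path)
    np.savez_compressed(
        path,
        posterior=stream.posterior,
        bin_starts=stream.bin_starts,
        mua_counts=stream.mua_counts,
        grid_centers=stream.grid.centers,
        grid_arm_ids=stream.grid.arm_ids,
    )
    sidecar = {
        "bin_size": stream.bin_size,
        "n_bins": int(stream.n_bins),
        "grid": {
            "spacing": stream.grid.spacing,
            "arm_length": stream.grid.arm_length,
            "n_arms": stream.grid.n_arms,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_posteriors(path: str | Path) -> PosteriorStream:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        grid = MazeGrid(
            spacing=sidecar["grid"]["spacing"],
            arm_length=sidecar["grid"]["arm_length"],
            n_arms=sidecar["grid"]["n_arms"],
            centers=data["grid_centers"],
            arm_ids=data["grid_arm_ids"],
        )
        posterior = data["posterior"]
        return PosteriorStream(
            bin_size=sidecar["bin_size"],
            bin_starts=data["bin_starts"],
            posterior=posterior,
            mua_counts=data["mua_counts"].astype(int),
            map_index=posterior.argmax(axis=1),
            grid=grid,
        )
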
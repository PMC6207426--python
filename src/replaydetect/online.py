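"""Streaming replay-content classifier.

On every new 10 ms posterior bin the detector evaluates three criteria over
the trailing window of ``n_bins`` bins (T = n_bins x bin_size, 30 ms by
default):

1. **Burst** — the z-scored mean multi-unit spike count over the window
   exceeds ``theta_mua``. The z-scoring mean/SD are estimated from per-bin
   total spike counts of a reference epoch (typically the encoding epoch)
   and carried in the config, so raw counts-per-bin thresholds can be
   configured instead by setting ``mua_norm=(0, 1)``-style values.
2. **Sharpness** — the integrated posterior probability within
   ``sharp_radius`` (~14 cm) of the MAP estimate, restricted to the MAP's
   arm, exceeds ``theta_sharp`` both in the most recent bin and on average
   over the window.
3. **Consistency** — the MAP estimates of all window bins fall on the same
   target arm.

A detection fires at the end of the triggering bin, labeled with the
consistent arm, and is followed by a lock-out (default 75 ms) during which
no further detections are emitted. The scan is strictly causal: bin ``k``
uses only bins ``<= k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import PosteriorStream
from .encoding import MazeGrid


@dataclass
class DetectorConfig:
    theta_mua: float  # z-units of windowed mean MUA
    theta_sharp: float  # probability
    n_bins: int = 3
    bin_size: float = 0.010  # s
    sharp_radius: float = 14.0  # cm
    lockout: float = 0.075  # s
    target_arms: tuple[int, ...] | None = None  # None = all arms
    mua_norm: tuple[float, float] | None = None  # (mean, sd) spikes/bin
    emit_unknown: bool = False  # burst-only detections labeled "unknown"

    def __post_init__(self):
        if not (0.0 <= self.theta_sharp <= 1.0):
            raise ValueError("theta_sharp must lie in [0, 1]")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.lockout < 0:
            raise ValueError("lockout must be >= 0")

    def with_thresholds(self, theta_mua: float, theta_sharp: float) -> "DetectorConfig":
        return DetectorConfig(
            theta_mua=theta_mua,
            theta_sharp=theta_sharp,
            n_bins=self.n_bins,
            bin_size=self.bin_size,
            sharp_radius=self.sharp_radius,
            lockout=self.lockout,
            target_arms=self.target_arms,
            mua_norm=self.mua_norm,
            emit_unknown=self.emit_unknown,
        )


@dataclass
class DetectionEvent:
    detection_time: float  # end of the triggering window (s)
    content: int | str  # arm index, or "unknown" for burst-only detections
    window_start: float
    mua_z: float
    sharp_last: float
    sharp_mean: float


def estimate_mua_norm(mua_counts: np.ndarray) -> tuple[float, float]:
    """Mean/SD of per-bin total spike counts, for detector z-scoring."""
    counts = np.asarray(mua_counts, float)
    sd = float(counts.std())
    if sd == 0:
        raise ValueError("MUA counts have zero variance; cannot z-score")
    return float(counts.mean()), sd


def sharpness(posterior_row: np.ndarray, grid: MazeGrid, radius: float = 14.0) -> float:
    """Integrated probability near the MAP, on the MAP's arm only.

    Sums the probability of grid bins on the MAP estimate's arm whose
    centers lie within ``radius`` cm of the MAP bin center; at an arm end
    the window is truncated to the bins that exist.
    """
    row = np.asarray(posterior_row, float)
    map_idx = int(row.argmax())
    return float(_sharpness_rows(row[None, :], np.array([map_idx]), grid, radius)[0])


def _sharpness_rows(
    posterior: np.ndarray, map_index: np.ndarray, grid: MazeGrid, radius: float
) -> np.ndarray:
    """Vectorized sharpness for a whole stream."""
    bpa = grid.bins_per_arm
    half = int(np.floor(radius / grid.spacing))  # bins within radius, per side
    arm = map_index // bpa
    local = map_index - arm * bpa
    lo = arm * bpa + np.maximum(local - half, 0)
    hi = arm * bpa + np.minimum(local + half, bpa - 1)
    csum = np.cumsum(posterior, axis=1)
    first = csum[np.arange(len(map_index)), lo] - posterior[np.arange(len(map_index)), lo]
    return csum[np.arange(len(map_index)), hi] - first


def detect_stream(posteriors: PosteriorStream, config: DetectorConfig) -> list[DetectionEvent]:
    """Run the streaming classifier over a posterior stream.

    Returns detections in time order. Raises if ``config.mua_norm`` is
    unset or the stream is shorter than the window.
    """
    if config.mua_norm is None:
        raise ValueError("DetectorConfig.mua_norm is required for the burst criterion")
    B = posteriors.n_bins
    n = config.n_bins
    if B < n:
        raise ValueError("stream shorter than the detection window")
    grid = posteriors.grid

    mean, sd = config.mua_norm
    z = (np.asarray(posteriors.mua_counts, float) - mean) / sd
    kernel = np.ones(n) / n
    z_window = np.convolve(z, kernel, mode="full")[n - 1 : B]  # causal mean over last n bins

    sharp = _sharpness_rows(posteriors.posterior, posteriors.map_index, grid, config.sharp_radius)
    sharp_window = np.convolve(sharp, kernel, mode="full")[n - 1 : B]

    map_arm = posteriors.map_arm
    consistent = np.ones(B - n + 1, dtype=bool)
    for j in range(1, n):
        consistent &= map_arm[n - 1 - j : B - j] == map_arm[n - 1 : B]
    targets = (
        set(range(grid.n_arms)) if config.target_arms is None else set(config.target_arms)
    )
    on_target = np.isin(map_arm[n - 1 : B], sorted(targets))

    burst_ok = z_window > config.theta_mua
    sharp_ok = (sharp[n - 1 : B] > config.theta_sharp) & (sharp_window > config.theta_sharp)
    content_ok = consistent & on_target
    full_ok = burst_ok & sharp_ok & content_ok
    candidate = full_ok | (burst_ok if config.emit_unknown else False)

    events: list[DetectionEvent] = []
    last_time = -np.inf
    for j in np.flatnonzero(candidate):
        k = j + n - 1  # absolute bin index
        det_time = float(posteriors.bin_starts[k] + posteriors.bin_size)
        if det_time - last_time < config.lockout:
            continue
        content: int | str = int(map_arm[k]) if full_ok[j] else "unknown"
        events.append(
            DetectionEvent(
                detection_time=det_time,
                content=content,
                window_start=det_time - n * config.bin_size,
                mua_z=float(z_window[j]),
                sharp_last=float(sharp[k]),
                sharp_mean=float(sharp_window[j]),
            )
        )
        last_time = det_time
    return events


def playback_equivalence(posteriors: PosteriorStream, config: DetectorConfig) -> list[DetectionEvent]:
    """Offline playback of the online algorithm.

    This is, by construction, the very same code path as
    :func:`detect_stream`; the name documents that parameter sweeps re-run
    the streaming detector on saved posteriors rather than a re-derived
    variant of it.
    """
    return detect_stream(posteriors, config)
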
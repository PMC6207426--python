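"""Clusterless (spike-sorting-less) encoding models.

Each tetrode is modeled as a marked Poisson point process: spikes occur at
a rate that depends jointly on the animal's linearized position ``x`` and
the spike's 4-channel peak-amplitude mark ``a``. The model consists of

* the mean firing rate ``mu`` (qualifying spikes / qualifying time),
* the joint spike density ``p(a, x)`` and its position marginal ``p(x)``,
* the position occupancy density ``pi(x)``,

from which the rate functions are obtained as ``lambda(a, x) =
mu * p(a, x) / pi(x)`` and ``lambda(x) = mu * p(x) / pi(x)``. Densities are
kernel estimates with Gaussian bandwidths of 8 cm (position) and 30 µV
(each amplitude channel), compressed online by merging each new sample into
its nearest existing kernel component whenever the bandwidth-normalized
Euclidean distance falls below a compression threshold. At threshold 0 the
estimator is the exact (uncompressed) KDE over all samples.

Maze arms are treated as separate linear tracks: position kernels never
leak probability across arms. Internally this is realized by embedding the
per-arm linear coordinate on a "gapped" axis in which arms are separated by
a gap large enough that cross-arm Gaussian weights underflow to exactly
zero.

Only samples taken while the animal ran faster than a speed threshold
(default 8.5 cm/s) enter the model. Densities and rates are evaluated once
on a regular grid of positions (2.15 cm spacing) and cached, along with
per-component position profiles, so that decoding a spike reduces to a
small matrix product.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .synthetic import MazeSpec

POSITION_BANDWIDTH = 8.0  # cm
AMPLITUDE_BANDWIDTH = 30.0  # µV per channel
RATE_FLOOR = 1e-10  # Hz; avoids log(0) for marks far from every component
ARM_GAP = 1.0e4  # cm of dead space between arms on the gapped position axis

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Maze grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MazeGrid:
    """Regular evaluation grid over the maze arms.

    Bins are ordered arm-by-arm, then by distance from the platform;
    ``centers`` holds the within-arm coordinate, ``arm_ids`` the arm of
    each bin, and ``gapped_centers`` the embedding used for kernel
    evaluation.
    """

    spacing: float
    arm_length: float
    n_arms: int
    centers: np.ndarray  # (G,) within-arm cm
    arm_ids: np.ndarray  # (G,) int

    @classmethod
    def from_maze(cls, maze: MazeSpec) -> "MazeGrid":
        n_bins = int(np.floor(maze.arm_length / maze.grid_spacing))
        local = (np.arange(n_bins) + 0.5) * maze.grid_spacing
        centers = np.tile(local, maze.n_arms)
        arm_ids = np.repeat(np.arange(maze.n_arms), n_bins)
        return cls(
            spacing=maze.grid_spacing,
            arm_length=maze.arm_length,
            n_arms=maze.n_arms,
            centers=centers,
            arm_ids=arm_ids,
        )

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    @property
    def bins_per_arm(self) -> int:
        return self.n_bins // self.n_arms

    @property
    def gapped_centers(self) -> np.ndarray:
        return self.arm_ids * (self.arm_length + ARM_GAP) + self.centers

    def gapped_coord(self, arm, lin_pos) -> np.ndarray:
        return np.asarray(arm) * (self.arm_length + ARM_GAP) + np.asarray(lin_pos, float)

    def arm_slice(self, arm: int) -> slice:
        b = self.bins_per_arm
        return slice(arm * b, (arm + 1) * b)


# ---------------------------------------------------------------------------
# Position cleaning, projection, speed
# ---------------------------------------------------------------------------

def clean_and_project_positions(
    raw: pd.DataFrame,
    maze: MazeSpec,
    max_gap: float = 0.5,
    max_dist: float = 10.0,
) -> pd.DataFrame:
    """Project 2D tracking coordinates onto the maze-arm center lines.

    Points farther than ``max_dist`` cm from every arm are treated as
    tracking errors and marked missing; missing runs spanning at most
    ``max_gap`` seconds are linearly interpolated in 2D and re-projected,
    longer runs (and runs touching the epoch boundary) are dropped with a
    warning. Output columns: t, x, y, arm, lin_pos.
    """
    t = np.asarray(raw["t"], float)
    x = np.asarray(raw["x"], float)
    y = np.asarray(raw["y"], float)
    missing = ~(np.isfinite(x) & np.isfinite(y))

    def project(xv, yv):
        angles = np.asarray(maze.arm_angles)
        s = xv[:, None] * np.cos(angles)[None, :] + yv[:, None] * np.sin(angles)[None, :]
        s = np.clip(s, 0.0, maze.arm_length)
        dx = xv[:, None] - s * np.cos(angles)[None, :]
        dy = yv[:, None] - s * np.sin(angles)[None, :]
        dist = np.hypot(dx, dy)
        arm = np.argmin(dist, axis=1)
        idx = np.arange(len(xv))
        return arm, s[idx, arm], dist[idx, arm]

    arm = np.zeros(len(t), dtype=int)
    lin = np.full(len(t), np.nan)
    ok = ~missing
    if np.any(ok):
        a, s, d = project(x[ok], y[ok])
        off_maze = d > max_dist
        a = np.where(off_maze, -1, a)
        arm[ok] = a
        lin[ok] = np.where(off_maze, np.nan, s)
        missing = missing.copy()
        missing[np.where(ok)[0][off_maze]] = True

    # interpolate short missing runs in 2D, then re-project
    keep = np.ones(len(t), dtype=bool)
    i = 0
    n = len(t)
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        at_edge = i == 0 or j == n
        span = t[min(j, n - 1)] - t[i - 1] if not at_edge else np.inf
        if at_edge or span > max_gap:
            keep[i:j] = False
            warnings.warn(
                f"dropping {j - i} position samples (gap too long or at epoch edge)",
                stacklevel=2,
            )
        else:
            frac = (t[i:j] - t[i - 1]) / (t[j] - t[i - 1])
            x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
            a, s, _ = project(x[i:j], y[i:j])
            arm[i:j] = a
            lin[i:j] = s
        i = j

    out = pd.DataFrame({"t": t, "x": x, "y": y, "arm": arm, "lin_pos": lin})[keep]
    return out.reset_index(drop=True)


def compute_speed(pos: pd.DataFrame, kernel_bw: float = 0.2) -> pd.DataFrame:
    """Running speed as |d/dt| of the Gaussian-smoothed linear position.

    The position signal is segmented at arm transitions and at sampling
    discontinuities so that no gradient is taken across arms; within each
    segment the 1D position is smoothed with a Gaussian kernel of
    ``kernel_bw`` seconds before differentiation.
    """
    if len(pos) < 3:
        raise ValueError("need at least 3 position samples to estimate speed")
    t = np.asarray(pos["t"], float)
    lin = np.asarray(pos["lin_pos"], float)
    arm = np.asarray(pos["arm"], int)
    dt = np.median(np.diff(t))
    breaks = np.where((np.diff(arm) != 0) | (np.diff(t) > 2.5 * dt))[0] + 1
    speed = np.zeros(len(t))
    for seg in np.split(np.arange(len(t)), breaks):
        if len(seg) < 3:
            continue
        smooth = gaussian_filter1d(lin[seg], sigma=kernel_bw / dt, mode="nearest")
        speed[seg] = np.abs(np.gradient(smooth, t[seg]))
    out = pos.copy()
    out["speed"] = speed
    return out


# ---------------------------------------------------------------------------
# Compressed kernel density estimator
# ---------------------------------------------------------------------------

class CompressedDensity:
    """Online-compressed Gaussian KDE with a fixed diagonal bandwidth.

    Components are (mean, weight) pairs sharing one kernel. Inserting a
    sample either merges it into the nearest component (weighted mean
    update, weight + 1) when the bandwidth-normalized Euclidean distance is
    below ``threshold``, or appends a fresh unit-weight component. The
    estimate is the weight-normalized sum of kernels centered on the
    component means.
    """

    def __init__(self, bandwidths: np.ndarray, threshold: float):
        self.bandwidths = np.asarray(bandwidths, float)
        self.threshold = float(threshold)
        self.ndim = len(self.bandwidths)
        self._means = np.empty((0, self.ndim))
        self._weights = np.empty(0)

    @property
    def means(self) -> np.ndarray:
        return self._means

    @property
    def weights(self) -> np.ndarray:
        return self._weights

    @property
    def n_components(self) -> int:
        return len(self._weights)

    @property
    def total_weight(self) -> float:
        return float(self._weights.sum())

    def insert(self, sample) -> None:
        sample = np.asarray(sample, float)
        if sample.shape != (self.ndim,) or not np.all(np.isfinite(sample)):
            raise ValueError("sample must be a finite vector matching the density dimension")
        if self.n_components:
            z = (self._means - sample[None, :]) / self.bandwidths[None, :]
            d2 = np.einsum("ij,ij->i", z, z)
            c = int(np.argmin(d2))
            if np.sqrt(d2[c]) < self.threshold:
                w = self._weights[c]
                self._means[c] = (w * self._means[c] + sample) / (w + 1.0)
                self._weights[c] = w + 1.0
                return
        self._means = np.vstack([self._means, sample[None, :]])
        self._weights = np.append(self._weights, 1.0)

    def insert_many(self, samples) -> None:
        for s in np.asarray(samples, float):
            self.insert(s)

    def evaluate(self, points) -> np.ndarray:
        """Density at ``points`` (m, ndim); normalized Gaussian product kernels."""
        points = np.atleast_2d(np.asarray(points, float))
        if self.n_components == 0:
            return np.zeros(len(points))
        log_norm = -0.5 * self.ndim * _LOG_2PI - np.log(self.bandwidths).sum()
        z = (points[:, None, :] - self._means[None, :, :]) / self.bandwidths[None, None, :]
        logk = log_norm - 0.5 * np.einsum("mcj,mcj->mc", z, z)
        return (np.exp(logk) @ self._weights) / self.total_weight


def compress_insert(density: CompressedDensity, sample, threshold: float) -> CompressedDensity:
    """Functional wrapper over :meth:`CompressedDensity.insert` (mutates and returns)."""
    density.threshold = float(threshold)
    density.insert(sample)
    return density


# ---------------------------------------------------------------------------
# Per-tetrode and whole-array models
# ---------------------------------------------------------------------------

@dataclass
class TetrodeEncodingModel:
    """Cached rate functions for one tetrode on a shared maze grid."""

    mu: float  # Hz
    joint: CompressedDensity  # 5-dim: gapped position + 4 amplitudes
    occupancy: CompressedDensity  # 1-dim gapped position
    px: np.ndarray  # (G,) marginal spike-position density, sums to 1/spacing
    pi: np.ndarray  # (G,) occupancy density, sums to 1/spacing
    lam_x: np.ndarray  # (G,) marginal rate lambda(x), Hz
    pos_profiles: np.ndarray  # (C, G) per-component position kernel on the grid
    mask: np.ndarray = field(default=None)  # (G,) bool, True where occupancy ~ 0

    def amp_log_kernels(self, amps: np.ndarray) -> np.ndarray:
        """Log amplitude-kernel weights, (n_spikes, C)."""
        m = self.joint.means[:, 1:]
        bw = AMPLITUDE_BANDWIDTH
        z = (np.atleast_2d(amps)[:, None, :] - m[None, :, :]) / bw
        log_norm = -2.0 * _LOG_2PI - 4.0 * np.log(bw)
        return log_norm - 0.5 * np.einsum("scj,scj->sc", z, z)

    def joint_rate(self, amps: np.ndarray) -> np.ndarray:
        """lambda(a, x) on the grid for a batch of amplitude marks, (n_spikes, G)."""
        amps = np.atleast_2d(amps)
        if amps.shape[1] != 4:
            raise ValueError("amplitude vectors must have 4 channels")
        w = np.exp(self.amp_log_kernels(amps)) * self.joint.weights[None, :]
        p_ax = (w @ self.pos_profiles) / self.joint.total_weight
        lam = self.mu * p_ax / self._pi_floor[None, :]
        if self.mask is not None:
            lam[:, self.mask] = RATE_FLOOR
        return np.maximum(lam, RATE_FLOOR)

    @property
    def _pi_floor(self) -> np.ndarray:
        return self._pi_floor_arr

    def finalize(self, grid: MazeGrid, epsilon: float = 1e-3) -> None:
        """Apply the occupancy floor/mask and (re)cache lambda(x)."""
        floor = epsilon * self.pi.max()
        self.mask = self.pi < floor
        self._pi_floor_arr = np.maximum(self.pi, floor)
        lam = self.mu * self.px / self._pi_floor_arr
        lam[self.mask] = RATE_FLOOR
        self.lam_x = np.maximum(lam, RATE_FLOOR)


def occupancy_zero_handling(model: TetrodeEncodingModel, epsilon: float = 1e-3, grid=None):
    """Mask grid bins whose occupancy is below ``epsilon`` * max occupancy.

    Rates at masked bins are floored so downstream posteriors stay finite
    and normalized. Returns the (updated) model.
    """
    model.finalize(grid, epsilon)
    return model


@dataclass
class EncodingModel:
    """Per-tetrode encoding models sharing one grid (the K tetrodes of the array)."""

    tetrode_models: dict[int, TetrodeEncodingModel]
    grid: MazeGrid
    speed_threshold: float
    compression_threshold: float

    @property
    def tetrode_ids(self) -> list[int]:
        return sorted(self.tetrode_models)

    def subset(self, tetrodes) -> "EncodingModel":
        return EncodingModel(
            tetrode_models={k: self.tetrode_models[k] for k in tetrodes},
            grid=self.grid,
            speed_threshold=self.speed_threshold,
            compression_threshold=self.compression_threshold,
        )


def position_at(pos: pd.DataFrame, times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-sample (arm, lin_pos, speed) lookup at arbitrary times."""
    pt = np.asarray(pos["t"], float)
    idx = np.clip(np.searchsorted(pt, times), 1, len(pt) - 1)
    idx = idx - (np.abs(times - pt[idx - 1]) <= np.abs(times - pt[idx]))
    return (
        np.asarray(pos["arm"], int)[idx],
        np.asarray(pos["lin_pos"], float)[idx],
        np.asarray(pos["speed"], float)[idx],
    )


def build_encoding_model(
    spikes: pd.DataFrame,
    pos: pd.DataFrame,
    grid: MazeGrid,
    speed_threshold: float = 8.5,
    compression_threshold: float = 1.8,
    tetrodes=None,
    occupancy_epsilon: float = 1e-3,
) -> EncodingModel:
    """Build the clusterless encoding model from a run epoch.

    Only spikes and position samples at running speed above
    ``speed_threshold`` enter the model. Raises if no position sample
    qualifies, or if any tetrode ends up with zero qualifying spikes.
    """
    pt = np.asarray(pos["t"], float)
    speed = np.asarray(pos["speed"], float)
    qual_pos = speed > speed_threshold
    if not np.any(qual_pos):
        raise ValueError("no position samples above the speed threshold; cannot encode")
    dt = np.median(np.diff(pt))
    qual_time = float(qual_pos.sum()) * dt

    spike_t = np.asarray(spikes["t"], float)
    s_arm, s_lin, s_speed = position_at(pos, spike_t)
    qual_spike = (s_speed > speed_threshold) & np.isfinite(s_lin)

    if tetrodes is None:
        tetrodes = np.unique(np.asarray(spikes["tetrode_id"], int)).tolist()
    spike_tet = np.asarray(spikes["tetrode_id"], int)
    amps = np.asarray(spikes[["a1", "a2", "a3", "a4"]], float)
    gpos = grid.gapped_coord(s_arm, s_lin)

    # shared occupancy samples
    occ_gpos = grid.gapped_coord(
        np.asarray(pos["arm"], int)[qual_pos], np.asarray(pos["lin_pos"], float)[qual_pos]
    )
    occupancy = CompressedDensity(np.array([POSITION_BANDWIDTH]), compression_threshold)
    occupancy.insert_many(occ_gpos[:, None])
    pi = occupancy.evaluate(grid.gapped_centers[:, None])
    pi = pi / (pi.sum() * grid.spacing)

    missing = [int(k) for k in tetrodes if not np.any(qual_spike & (spike_tet == k))]
    if missing:
        raise ValueError(f"tetrodes with zero qualifying spikes: {missing}")

    models: dict[int, TetrodeEncodingModel] = {}
    log_pos_norm = -0.5 * _LOG_2PI - np.log(POSITION_BANDWIDTH)
    for k in tetrodes:
        sel = qual_spike & (spike_tet == k)
        samples = np.column_stack([gpos[sel], amps[sel]])
        bw = np.array([POSITION_BANDWIDTH] + [AMPLITUDE_BANDWIDTH] * 4)
        joint = CompressedDensity(bw, compression_threshold)
        joint.insert_many(samples)

        z = (grid.gapped_centers[None, :] - joint.means[:, :1]) / POSITION_BANDWIDTH
        pos_profiles = np.exp(log_pos_norm - 0.5 * z**2)
        px = (joint.weights @ pos_profiles) / joint.total_weight
        px = px / (px.sum() * grid.spacing)

        m = TetrodeEncodingModel(
            mu=float(sel.sum() / qual_time),
            joint=joint,
            occupancy=occupancy,
            px=px,
            pi=pi,
            lam_x=np.zeros(grid.n_bins),
            pos_profiles=pos_profiles,
        )
        m.finalize(grid, occupancy_epsilon)
        models[int(k)] = m

    return EncodingModel(
        tetrode_models=models,
        grid=grid,
        speed_threshold=speed_threshold,
        compression_threshold=compression_threshold,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: EncodingModel, path: str | Path) -> None:
    """Serialize an :class:`EncodingModel` to a single ``.npz`` archive."""
    arrays: dict[str, np.ndarray] = {
        "grid_centers": model.grid.centers,
        "grid_arm_ids": model.grid.arm_ids,
    }
    meta = {
        "speed_threshold": model.speed_threshold,
        "compression_threshold": model.compression_threshold,
        "grid": {
            "spacing": model.grid.spacing,
            "arm_length": model.grid.arm_length,
            "n_arms": model.grid.n_arms,
        },
        "tetrodes": model.tetrode_ids,
        "mu": {str(k): m.mu for k, m in model.tetrode_models.items()},
    }
    for k, m in model.tetrode_models.items():
        arrays[f"t{k}_means"] = m.joint.means
        arrays[f"t{k}_weights"] = m.joint.weights
        arrays[f"t{k}_px"] = m.px
        arrays[f"t{k}_pi"] = m.pi
        arrays[f"t{k}_profiles"] = m.pos_profiles
    arrays["occ_means"] = next(iter(model.tetrode_models.values())).occupancy.means
    arrays["occ_weights"] = next(iter(model.tetrode_models.values())).occupancy.weights
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> EncodingModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        grid = MazeGrid(
            spacing=meta["grid"]["spacing"],
            arm_length=meta["grid"]["arm_length"],
            n_arms=meta["grid"]["n_arms"],
            centers=data["grid_centers"],
            arm_ids=data["grid_arm_ids"],
        )
        occupancy = CompressedDensity(
            np.array([POSITION_BANDWIDTH]), meta["compression_threshold"]
        )
        occupancy._means = data["occ_means"]
        occupancy._weights = data["occ_weights"]
        models = {}
        for k in meta["tetrodes"]:
            joint = CompressedDensity(
                np.array([POSITION_BANDWIDTH] + [AMPLITUDE_BANDWIDTH] * 4),
                meta["compression_threshold"],
            )
            joint._means = data[f"t{k}_means"]
            joint._weights = data[f"t{k}_weights"]
            m = TetrodeEncodingModel(
                mu=meta["mu"][str(k)],
                joint=joint,
                occupancy=occupancy,
                px=data[f"t{k}_px"],
                pi=data[f"t{k}_pi"],
                lam_x=np.zeros(grid.n_bins),
                pos_profiles=data[f"t{k}_profiles"],
            )
            m.finalize(grid)
            models[int(k)] = m
    return EncodingModel(
        tetrode_models=models,
        grid=grid,
        speed_threshold=meta["speed_threshold"],
        compression_threshold=meta["compression_threshold"],
    )
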
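"""Synthetic 3-arm radial-maze sessions with known ground truth.

The generator emulates the recording conditions the detection pipeline is
designed for: a rat running out-and-back traversals of the arms of a radial
maze (run epochs, used to build the encoding model) and resting periods in
which the population intermittently produces brief high-rate bursts, a
subset of which carry a time-compressed constant-velocity sweep of a
"virtual" position along one or two arms (replay events).

Spiking is an inhomogeneous Poisson process realized by thinning on a 1 ms
simulation step — finer than both the 10 ms decoding bin and the 1 ms MUA
histogram used downstream. Each spike carries a 4-channel peak-amplitude
mark drawn as the generating cell's amplitude signature plus isotropic
Gaussian noise, which is what makes the session decodable without spike
sorting.

Default burst statistics follow the reference in vivo sessions this tool
models: a burst rate of ~0.4 Hz during rest, log-normal burst durations
with median 83 ms and IQR [65.3, 119.8] ms, ~35% of bursts carrying replay
and ~25% of replay events spanning two arms (joint events, switching arm at
the event midpoint). The replay sweep speed defaults to 600 cm/s, i.e.
roughly a 20-fold time compression of a 30 cm/s run, so a 90 cm arm is
traversed in ~150 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIM_DT = 0.001  # 1 ms simulation step

#: Log-normal burst-duration parameters matched to the reference rest-epoch
#: statistics (median 83 ms, inter-quartile range [65.3, 119.8] ms).
DEFAULT_BURST_DURATION = (0.083, (0.0653, 0.1198))


@dataclass(frozen=True)
class MazeSpec:
    """Geometry of an n-arm radial maze (arms as rays from a central platform)."""

    n_arms: int = 3
    arm_length: float = 90.0  # cm
    arm_angles: tuple[float, ...] = ()  # radians; default evenly spaced
    grid_spacing: float = 2.15  # cm

    def __post_init__(self):
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be > 0")
        if not self.arm_angles:
            angles = tuple(2 * math.pi * i / self.n_arms for i in range(self.n_arms))
            object.__setattr__(self, "arm_angles", angles)
        elif len(self.arm_angles) != self.n_arms:
            raise ValueError("arm_angles must have one entry per arm")

    def to_xy(self, arm: np.ndarray, lin_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (arm index, distance from platform) to 2D coordinates."""
        angles = np.asarray(self.arm_angles)[np.asarray(arm, dtype=int)]
        lin = np.asarray(lin_pos, dtype=float)
        return lin * np.cos(angles), lin * np.sin(angles)


@dataclass
class PlaceCellPopulation:
    """Generative stand-in for a recorded CA1 ensemble.

    Arrays are aligned per cell. ``tetrode`` assigns each cell to the
    tetrode on which its spikes (and amplitude marks) appear.
    """

    tetrode: np.ndarray  # (n,) int
    arm: np.ndarray  # (n,) int — arm hosting the place field
    center: np.ndarray  # (n,) cm from platform
    width: np.ndarray  # (n,) cm (Gaussian field SD)
    peak_rate: np.ndarray  # (n,) Hz
    background_rate: np.ndarray  # (n,) Hz
    signature: np.ndarray  # (n, 4) µV
    noise_sd: np.ndarray  # (n,) µV

    def __post_init__(self):
        if np.any(self.peak_rate < 0) or np.any(self.background_rate < 0):
            raise ValueError("rates must be >= 0")
        if np.any(self.width <= 0):
            raise ValueError("field widths must be > 0")

    @property
    def n_cells(self) -> int:
        return len(self.center)

    @property
    def tetrode_ids(self) -> np.ndarray:
        return np.unique(self.tetrode)

    def rates_at(self, arm: np.ndarray, lin_pos: np.ndarray) -> np.ndarray:
        """Per-cell place-field rate (Hz) for positions given as (arm, lin_pos).

        Distance between a position and a field on another arm is the path
        distance through the central platform.
        """
        arm = np.asarray(arm, dtype=int)
        lin = np.asarray(lin_pos, dtype=float)
        same = arm[:, None] == self.arm[None, :]
        d = np.where(
            same,
            np.abs(lin[:, None] - self.center[None, :]),
            lin[:, None] + self.center[None, :],
        )
        bumps = np.exp(-0.5 * (d / self.width[None, :]) ** 2)
        return self.background_rate[None, :] + self.peak_rate[None, :] * bumps


def make_default_population(
    maze: MazeSpec,
    n_tetrodes: int = 14,
    cells_per_tetrode: int = 4,
    seed: int = 0,
    peak_rate: float = 20.0,
    background_rate: float = 0.5,
    field_width: float = 8.0,
    amplitude_noise_sd: float = 10.0,
) -> PlaceCellPopulation:
    """Build a population whose fields tile all arms approximately uniformly.

    Amplitude signatures within a tetrode are re-drawn until their mean
    pairwise distance exceeds 3x the amplitude noise SD, so marks carry
    usable cell identity.
    """
    if n_tetrodes < 1:
        raise ValueError("n_tetrodes must be >= 1")
    if cells_per_tetrode < 1:
        raise ValueError("cells_per_tetrode must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_tetrodes * cells_per_tetrode

    # even tiling of the concatenated track, with jitter
    track = maze.n_arms * maze.arm_length
    centers_global = (np.arange(n) + 0.5) / n * track
    centers_global += rng.uniform(-0.25, 0.25, size=n) * track / n
    centers_global = np.clip(centers_global, 0.0, track - 1e-9)
    arm = (centers_global // maze.arm_length).astype(int)
    center = centers_global - arm * maze.arm_length
    order = rng.permutation(n)  # decouple tetrode id from maze location
    tetrode = np.repeat(np.arange(n_tetrodes), cells_per_tetrode)[np.argsort(order)]

    signature = np.empty((n, 4))
    for k in range(n_tetrodes):
        idx = np.where(tetrode == k)[0]
        while True:
            sig = rng.uniform(60.0, 300.0, size=(len(idx), 4))
            if len(idx) == 1:
                break
            diffs = sig[:, None, :] - sig[None, :, :]
            dist = np.sqrt((diffs**2).sum(-1))
            iu = np.triu_indices(len(idx), k=1)
            if dist[iu].mean() > 3.0 * amplitude_noise_sd:
                break
        signature[idx] = sig

    return PlaceCellPopulation(
        tetrode=tetrode,
        arm=arm,
        center=center,
        width=np.full(n, field_width),
        peak_rate=np.full(n, peak_rate),
        background_rate=np.full(n, background_rate),
        signature=signature,
        noise_sd=np.full(n, amplitude_noise_sd),
    )


# ---------------------------------------------------------------------------
# Poisson thinning engine
# ---------------------------------------------------------------------------

def _draw_spikes(rate_fn, n_steps: int, t0: float, cells: PlaceCellPopulation, rng) -> pd.DataFrame:
    """Thin a per-cell rate function to spikes on the 1 ms grid.

    ``rate_fn(i0, i1)`` must return the (i1-i0, n_cells) rate matrix in Hz
    for simulation steps [i0, i1). Spike times get a uniform sub-step
    offset; amplitude marks are signature + isotropic Gaussian noise.
    """
    chunks = []
    chunk = 50_000
    for i0 in range(0, n_steps, chunk):
        i1 = min(i0 + chunk, n_steps)
        rates = rate_fn(i0, i1)
        p = rates * SIM_DT
        hits = rng.random(p.shape) < p
        step_idx, cell_idx = np.nonzero(hits)
        if step_idx.size == 0:
            continue
        t = t0 + (i0 + step_idx + rng.random(step_idx.size)) * SIM_DT
        amps = cells.signature[cell_idx] + rng.normal(
            0.0, cells.noise_sd[cell_idx][:, None], size=(cell_idx.size, 4)
        )
        chunks.append(
            pd.DataFrame(
                {
                    "tetrode_id": cells.tetrode[cell_idx],
                    "t": t,
                    "a1": amps[:, 0],
                    "a2": amps[:, 1],
                    "a3": amps[:, 2],
                    "a4": amps[:, 3],
                }
            )
        )
    if not chunks:
        from .session_io import empty_spike_table

        return empty_spike_table()
    out = pd.concat(chunks, ignore_index=True)
    out = out.sort_values("t", kind="stable", ignore_index=True)
    out["tetrode_id"] = out["tetrode_id"].astype("int64")
    return out


# ---------------------------------------------------------------------------
# Run epochs
# ---------------------------------------------------------------------------

def simulate_run_epoch(
    maze: MazeSpec,
    cells: PlaceCellPopulation,
    duration: float,
    run_speed: float = 30.0,
    pause_s: float = 2.0,
    seed: int = 0,
    t0: float = 0.0,
    position_rate: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an active-exploration epoch.

    The animal repeatedly runs out-and-back traversals (platform -> arm end
    -> platform) cycling through the arms, pausing ``pause_s`` seconds at
    each distal reward platform. Returns (position table, spike table) with
    epoch-absolute times starting at ``t0``.
    """
    traversal = 2 * maze.arm_length / run_speed + pause_s
    if duration < traversal:
        raise ValueError(
            f"duration {duration} s too short for one traversal ({traversal:.1f} s)"
        )
    rng = np.random.default_rng(seed)

    # piecewise-linear trajectory segments: (t_start, arm, p0, v)
    seg_t, seg_arm, seg_p0, seg_v = [], [], [], []
    t = 0.0
    arm = 0
    while t < duration:
        L = maze.arm_length
        seg_t += [t, t + L / run_speed, t + L / run_speed + pause_s]
        seg_arm += [arm, arm, arm]
        seg_p0 += [0.0, L, L]
        seg_v += [run_speed, 0.0, -run_speed]
        t += traversal
        arm = (arm + 1) % maze.n_arms
    seg_t = np.asarray(seg_t)
    seg_arm = np.asarray(seg_arm)
    seg_p0 = np.asarray(seg_p0)
    seg_v = np.asarray(seg_v)

    def pos_at(times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = np.searchsorted(seg_t, times, side="right") - 1
        lin = np.clip(seg_p0[i] + seg_v[i] * (times - seg_t[i]), 0.0, maze.arm_length)
        return seg_arm[i], lin, np.abs(seg_v[i])

    n_steps = int(round(duration / SIM_DT))
    step_mid = (np.arange(n_steps) + 0.5) * SIM_DT

    def rate_fn(i0, i1):
        a, lin, _ = pos_at(step_mid[i0:i1])
        return cells.rates_at(a, lin)

    spikes = _draw_spikes(rate_fn, n_steps, t0, cells, rng)

    tp = np.arange(0.0, duration, 1.0 / position_rate)
    a, lin, v = pos_at(tp)
    x, y = maze.to_xy(a, lin)
    position = pd.DataFrame(
        {"t": t0 + tp, "x": x, "y": y, "arm": a, "lin_pos": lin, "speed": v}
    )
    return position, spikes


# ---------------------------------------------------------------------------
# Rest / burst epochs
# ---------------------------------------------------------------------------

@dataclass
class BurstSchedule:
    """Ground-truth schedule for one rest-epoch population burst."""

    onset: float
    duration: float
    kind: str  # "replay" | "non_replay"
    arm: int = -1
    arm2: int = -1  # second arm for joint events, -1 otherwise
    start_pos: float = float("nan")
    velocity: float = float("nan")  # signed, cm/s
    gain: float = 1.0


def _schedule_bursts(
    duration: float,
    burst_rate: float,
    p_replay: float,
    p_joint: float,
    duration_dist,
    replay_speed: float,
    gain_replay: float,
    gain_non_replay: float,
    maze: MazeSpec,
    rng,
    min_gap: float = 0.05,
) -> list[BurstSchedule]:
    median, (q1, q3) = duration_dist
    sigma = math.log(q3 / q1) / (2 * 0.6744897501960817)
    mu = math.log(median)

    n = rng.poisson(burst_rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n))
    bursts: list[BurstSchedule] = []
    t_free = 0.0
    for onset in onsets:
        if onset < t_free:
            continue
        dur = float(np.exp(rng.normal(mu, sigma)))
        if onset + dur > duration:
            continue
        is_replay = rng.random() < p_replay
        if not is_replay:
            bursts.append(
                BurstSchedule(onset=onset, duration=dur, kind="non_replay", gain=gain_non_replay)
            )
        else:
            arm = int(rng.integers(maze.n_arms))
            # joint (two-arm) content needs time to express: a sweep must
            # cover a meaningful stretch of both arms, so only long bursts
            # (> 100 ms, the putative-joint duration class) can carry it
            joint = (rng.random() < p_joint) and dur > 0.100
            v = replay_speed * (1 if rng.random() < 0.5 else -1)
            L = maze.arm_length
            if joint:
                arm2 = int((arm + 1 + rng.integers(maze.n_arms - 1)) % maze.n_arms)
                # inward sweep on arm, outward on arm2; start so the sweep
                # reaches the platform at the midpoint (clipped otherwise)
                start = min(L, abs(v) * dur / 2)
                bursts.append(
                    BurstSchedule(
                        onset=onset,
                        duration=dur,
                        kind="replay",
                        arm=arm,
                        arm2=arm2,
                        start_pos=start,
                        velocity=v,
                        gain=gain_replay,
                    )
                )
            else:
                span = min(abs(v) * dur, L)
                start = rng.uniform(0.0, L - span) if v > 0 else rng.uniform(span, L)
                bursts.append(
                    BurstSchedule(
                        onset=onset,
                        duration=dur,
                        kind="replay",
                        arm=arm,
                        arm2=-1,
                        start_pos=start,
                        velocity=v,
                        gain=gain_replay,
                    )
                )
        t_free = onset + dur + min_gap
    return bursts


def replay_position(burst: BurstSchedule, times: np.ndarray, maze: MazeSpec):
    """Virtual (arm, lin_pos) of a scheduled replay sweep at epoch times."""
    rel = np.asarray(times, dtype=float) - burst.onset
    L = maze.arm_length
    if burst.arm2 < 0:
        lin = np.clip(burst.start_pos + burst.velocity * rel, 0.0, L)
        arm = np.full(rel.shape, burst.arm, dtype=int)
    else:
        half = burst.duration / 2
        first = rel < half
        lin_first = np.clip(burst.start_pos - abs(burst.velocity) * rel, 0.0, L)
        lin_second = np.clip(abs(burst.velocity) * (rel - half), 0.0, L)
        lin = np.where(first, lin_first, lin_second)
        arm = np.where(first, burst.arm, burst.arm2)
    return arm, lin


def simulate_burst_epoch(
    maze: MazeSpec,
    cells: PlaceCellPopulation,
    duration: float,
    burst_rate: float = 0.4,
    p_replay: float = 0.35,
    p_joint: float = 0.25,
    duration_dist=DEFAULT_BURST_DURATION,
    replay_speed: float = 600.0,
    gain_replay: float = 5.0,
    gain_non_replay: float = 20.0,
    seed: int = 0,
    t0: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a rest epoch with scheduled population bursts.

    Outside bursts every cell fires at its background rate. During
    non-replay bursts all background rates scale by ``gain_non_replay`` with
    no spatial structure; during replay bursts each cell fires according to
    its place tuning evaluated at the virtual replay position, scaled by
    ``gain_replay``. Returns (spike table, ground-truth event table); event
    times are epoch-absolute.
    """
    if not (0.0 <= p_replay <= 1.0) or not (0.0 <= p_joint <= 1.0):
        raise ValueError("p_replay and p_joint must lie in [0, 1]")
    if burst_rate * duration < 1:
        raise ValueError("expected burst count below 1; increase duration or burst_rate")
    rng = np.random.default_rng(seed)
    bursts = _schedule_bursts(
        duration, burst_rate, p_replay, p_joint, duration_dist, replay_speed,
        gain_replay, gain_non_replay, maze, rng,
    )

    n_steps = int(round(duration / SIM_DT))
    step_mid = (np.arange(n_steps) + 0.5) * SIM_DT
    onsets = np.asarray([b.onset for b in bursts])

    def rate_fn(i0, i1):
        tm = step_mid[i0:i1]
        rates = np.broadcast_to(cells.background_rate[None, :], (len(tm), cells.n_cells)).copy()
        j = np.searchsorted(onsets, tm, side="right") - 1
        for bi in np.unique(j[j >= 0]):
            b = bursts[bi]
            in_b = (j == bi) & (tm >= b.onset) & (tm < b.onset + b.duration)
            if not np.any(in_b):
                continue
            if b.kind == "non_replay":
                rates[in_b] = cells.background_rate[None, :] * b.gain
            else:
                arm, lin = replay_position(b, tm[in_b], maze)
                tuned = cells.rates_at(arm, lin) - cells.background_rate[None, :]
                rates[in_b] = cells.background_rate[None, :] + b.gain * tuned
        return rates

    spikes = _draw_spikes(rate_fn, n_steps, t0, cells, rng)

    truth = pd.DataFrame(
        {
            "t": [t0 + b.onset for b in bursts],
            "label": [b.kind for b in bursts],
            "duration": [b.duration for b in bursts],
            "arm": [b.arm for b in bursts],
            "arm2": [b.arm2 for b in bursts],
            "start_pos": [b.start_pos for b in bursts],
            "velocity": [b.velocity for b in bursts],
            "gain": [b.gain for b in bursts],
        }
    )
    return spikes, truth


# ---------------------------------------------------------------------------
# Whole-session convenience
# ---------------------------------------------------------------------------

def simulate_session(
    n_tetrodes: int = 14,
    cells_per_tetrode: int = 4,
    run_duration: float = 300.0,
    rest_duration: float = 300.0,
    seed: int = 0,
    maze: MazeSpec | None = None,
    **burst_kwargs,
):
    """Simulate a RUN1 + REST session bundle with ground truth.

    Returns a :class:`~replaydetect.session_io.SessionBundle` whose REST
    event table is the scheduled-burst ground truth.
    """
    from .session_io import SessionBundle

    maze = maze or MazeSpec()
    rng = np.random.default_rng(seed)
    s_pop, s_run, s_rest = rng.integers(0, 2**31 - 1, size=3)
    cells = make_default_population(maze, n_tetrodes, cells_per_tetrode, seed=int(s_pop))
    pos, run_spikes = simulate_run_epoch(maze, cells, run_duration, seed=int(s_run), t0=0.0)
    rest_t0 = run_duration + 10.0
    rest_spikes, truth = simulate_burst_epoch(
        maze, cells, rest_duration, seed=int(s_rest), t0=rest_t0, **burst_kwargs
    )
    bundle = SessionBundle(
        epochs={"RUN1": (0.0, run_duration), "REST": (rest_t0, rest_t0 + rest_duration)},
        tetrodes=sorted(int(t) for t in cells.tetrode_ids),
        spikes={"RUN1": run_spikes, "REST": rest_spikes},
        positions={"RUN1": pos},
        events={"REST": truth},
        meta={"n_tetrodes": int(n_tetrodes), "seed": int(seed)},
    )
    return bundle, cells
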
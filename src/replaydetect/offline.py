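"""Offline reference replay detection and content scoring.

With no ground truth available in vivo, replay labels are produced by an
offline pipeline with access to the complete recording:

1. **Burst detection.** A multi-unit activity (MUA) rate signal is built
   from all spikes (1 ms histogram, Gaussian-smoothed with 15 ms
   bandwidth), detrended with a two-sided exponentially weighted moving
   average (span 7.5 s on a 10 ms grid, half-life 2.6 s) and z-scored.
   Population bursts are maximal periods with z > 0.5, merged when
   separated by < 20 ms, and kept when the merged peak reaches z >= 2.5.
2. **Content scoring.** Each burst's 10 ms posteriors are scored for
   arm-concentration (bias and its shuffle-null z-score), for linear
   spatial-temporal structure (line fit score: posterior mass within 15 cm
   of the best constant-velocity trajectory, found by exhaustive discrete
   line search), and for time-position correlation (mean absolute Pearson
   |r| over trajectories sampled from the posterior, plus its shuffle-null
   z-score). The shuffle null circularly shifts each bin's probability
   vector along the concatenated position axis, independently per bin.
3. **Classification.** A (sub)event contains replay when bias_max score > 3
   and line fit score > 0.1. Long bursts (> 100 ms) are additionally scored
   as two halves (the central bin shared when the bin count is odd) and are
   split into two sub-events when a half qualifies as replay and shows a
   larger bias_max than the whole — the signature of joint events that
   sweep two arms, switching at the event midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .encoding import MazeGrid

MUA_DT = 0.001  # s, histogram bin
MUA_SMOOTH_BW = 0.015  # s, Gaussian kernel bandwidth
TREND_SUBSAMPLE = 10  # 1 ms samples per trend sample (10 ms grid)


# ---------------------------------------------------------------------------
# MUA signal
# ---------------------------------------------------------------------------

@dataclass
class MuaSignal:
    t: np.ndarray  # (N,) bin centers, s
    rate: np.ndarray  # (N,) smoothed rate, Hz
    z: np.ndarray | None = None  # detrended, z-scored
    trend: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def compute_mua(spikes: pd.DataFrame, epoch: tuple[float, float]) -> MuaSignal:
    """Smoothed multi-unit rate: 1 ms histogram of all spikes, 15 ms Gaussian kernel."""
    t0, t1 = epoch
    if not t1 > t0:
        raise ValueError("epoch must be non-empty")
    n = int(round((t1 - t0) / MUA_DT))
    edges = t0 + MUA_DT * np.arange(n + 1)
    hist, _ = np.histogram(np.asarray(spikes["t"], float), bins=edges)
    smoothed = gaussian_filter1d(hist.astype(float), sigma=MUA_SMOOTH_BW / MUA_DT, mode="nearest")
    return MuaSignal(t=t0 + MUA_DT * (np.arange(n) + 0.5), rate=smoothed / MUA_DT)


def _ewma(x: np.ndarray, alpha: float) -> np.ndarray:
    zi = np.array([(1.0 - alpha) * x[0]])  # steady-state start at the first value
    y, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=zi)
    return y


def detrend_and_zscore(mua: MuaSignal, span_samples: int = 750) -> MuaSignal:
    """Remove slow MUA fluctuations and standardize.

    The trend is an exponentially weighted moving average of the 10
    ms-subsampled rate, run forward and backward over the signal and
    averaged (which makes the trend exactly equivariant under time
    reversal), then linearly interpolated back to the 1 ms grid. The
    detrended signal is z-scored by its epoch mean and SD.
    """
    x = mua.rate
    n_sub = len(x) // TREND_SUBSAMPLE
    if n_sub <= span_samples // 10:
        raise ValueError("signal shorter than the detrending span")
    sub = x[: n_sub * TREND_SUBSAMPLE].reshape(n_sub, TREND_SUBSAMPLE).mean(axis=1)
    alpha = 2.0 / (span_samples + 1.0)
    trend_sub = 0.5 * (_ewma(sub, alpha) + _ewma(sub[::-1], alpha)[::-1])
    t_sub = mua.t[: n_sub * TREND_SUBSAMPLE].reshape(n_sub, TREND_SUBSAMPLE).mean(axis=1)
    trend = np.interp(mua.t, t_sub, trend_sub)
    detrended = x - trend
    sd = detrended.std()
    if sd == 0:
        raise ValueError("constant MUA signal; cannot z-score")
    z = (detrended - detrended.mean()) / sd
    return MuaSignal(t=mua.t, rate=mua.rate, z=z, trend=trend)


# ---------------------------------------------------------------------------
# Burst detection
# ---------------------------------------------------------------------------

@dataclass
class BurstInterval:
    onset: float
    offset: float
    peak_z: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def detect_bursts(
    mua: MuaSignal,
    enter: float = 0.5,
    peak_min: float = 2.5,
    merge_gap: float = 0.020,
) -> list[BurstInterval]:
    """Population bursts from the z-scored detrended MUA.

    Maximal intervals with z > ``enter`` are merged while separated by less
    than ``merge_gap`` (iterated to a fixpoint); the peak requirement
    ``peak_min`` is applied to the merged intervals.
    """
    if mua.z is None:
        raise ValueError("detrend_and_zscore must run first")
    above = mua.z > enter
    if not np.any(above):
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[above[edges + 1]] + 1)
    ends = list(edges[~above[edges + 1]] + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [len(above)]
    dt = mua.dt
    t0 = mua.t[0] - dt / 2
    intervals = [(t0 + s * dt, t0 + e * dt, s, e) for s, e in zip(starts, ends)]

    merged = True
    while merged:
        merged = False
        out = []
        for iv in intervals:
            if out and iv[0] - out[-1][1] < merge_gap:
                prev = out[-1]
                out[-1] = (prev[0], iv[1], prev[2], iv[3])
                merged = True
            else:
                out.append(iv)
        intervals = out

    bursts = []
    for a, b, s, e in intervals:
        peak = float(mua.z[s:e].max())
        if peak >= peak_min:
            bursts.append(BurstInterval(onset=a, offset=b, peak_z=peak))
    return bursts


# ---------------------------------------------------------------------------
# Content measures
# ---------------------------------------------------------------------------

def bias_measures(posteriors: np.ndarray, grid: MazeGrid) -> tuple[np.ndarray, float]:
    """Per-arm bias (time-averaged posterior mass) and transformed bias_max.

    The per-arm biases sum to 1; the maximum lies in [1/n_arms, 1] and is
    linearly rescaled to bias_max in [0, 1].
    """
    P = np.atleast_2d(posteriors)
    bpa = grid.bins_per_arm
    bias = P.reshape(len(P), grid.n_arms, bpa).sum(axis=2).mean(axis=0)
    lo = 1.0 / grid.n_arms
    return bias, float((bias.max() - lo) / (1.0 - lo))


def shuffle_posteriors(posteriors: np.ndarray, n: int = 2000, seed: int = 0):
    """Yield ``n`` shuffled copies: each bin's probability vector circularly
    shifted along the concatenated position axis by an independent uniform
    offset. Per-bin mass is preserved exactly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    P = np.atleast_2d(posteriors)
    B, G = P.shape
    rng = np.random.default_rng(seed)
    cols = np.arange(G)
    for _ in range(n):
        offsets = rng.integers(0, G, size=B)
        idx = (cols[None, :] - offsets[:, None]) % G
        yield P[np.arange(B)[:, None], idx]


def _shuffled_stack(P: np.ndarray, n: int, rng) -> np.ndarray:
    """(n, B, G) stack of circular-shift shuffles (vectorized)."""
    B, G = P.shape
    offsets = rng.integers(0, G, size=(n, B))
    idx = (np.arange(G)[None, None, :] - offsets[:, :, None]) % G
    return P[np.arange(B)[None, :, None], idx]


def bias_max_score(posteriors: np.ndarray, grid: MazeGrid, n_shuffles: int = 2000, seed: int = 0) -> float:
    """Z-score of bias_max against the per-bin circular-shift null."""
    P = np.atleast_2d(posteriors)
    _, observed = bias_measures(P, grid)
    rng = np.random.default_rng(seed)
    stack = _shuffled_stack(P, n_shuffles, rng)
    bias = stack.reshape(n_shuffles, len(P), grid.n_arms, grid.bins_per_arm).sum(3).mean(1)
    lo = 1.0 / grid.n_arms
    null = (bias.max(axis=1) - lo) / (1.0 - lo)
    sd = null.std()
    if sd == 0:
        warnings.warn("degenerate shuffle null (sd = 0); bias_max score set to 0", stacklevel=2)
        return 0.0
    return float((observed - null.mean()) / sd)


def _renormalize_rows(P: np.ndarray) -> np.ndarray:
    s = P.sum(axis=1, keepdims=True)
    out = np.where(s > 0, P / np.where(s > 0, s, 1.0), 1.0 / P.shape[1])
    return out


def line_fit_score(
    arm_posteriors: np.ndarray,
    arm_centers: np.ndarray,
    band: float = 15.0,
    bin_size: float = 0.010,
    velocities: np.ndarray | None = None,
) -> float:
    """Best constant-velocity trajectory fit by exhaustive discrete search.

    ``arm_posteriors`` is the (B, bins-in-arm) posterior restricted to one
    arm; rows are renormalized to the arm. Candidate lines have intercepts
    at every arm bin center and velocities -1500..1500 cm/s in 75 cm/s
    steps; a line's score is the mean over bins of the renormalized mass
    within ``band`` cm of the line's position at the bin center (positions
    beyond the arm ends contribute whatever mass lies in the clipped band).
    Returns the maximum over lines.
    """
    P = np.atleast_2d(arm_posteriors)
    if len(P) < 2:
        raise ValueError("line fit requires at least 2 bins")
    P = _renormalize_rows(P)
    centers = np.asarray(arm_centers, float)
    if velocities is None:
        velocities = np.arange(-1500.0, 1500.0 + 1e-9, 75.0)
    tb = bin_size * np.arange(len(P))  # time of bin centers relative to the first

    # line positions: (n_lines, B)
    pos = centers[:, None, None] + velocities[None, :, None] * tb[None, None, :]
    pos = pos.reshape(-1, len(P))

    csum = np.cumsum(P, axis=1)
    lo = np.searchsorted(centers, pos - band, side="left")
    hi = np.searchsorted(centers, pos + band, side="right") - 1
    rows = np.broadcast_to(np.arange(len(P))[None, :], pos.shape)
    upper = np.where(hi >= 0, csum[rows, np.clip(hi, 0, None)], 0.0)
    lower = np.where(lo > 0, csum[rows, np.clip(lo - 1, 0, None)], 0.0)
    mass = np.where(hi >= lo, upper - lower, 0.0)
    return float(mass.mean(axis=1).max())


def sample_trajectories(
    arm_posteriors: np.ndarray, arm_centers: np.ndarray, n_traj: int, rng
) -> np.ndarray:
    """(n_traj, B) positions sampled independently per bin from the arm posterior."""
    P = _renormalize_rows(np.atleast_2d(arm_posteriors))
    B = len(P)
    cdf = np.cumsum(P, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random((n_traj, B))
    out = np.empty((n_traj, B))
    for b in range(B):
        out[:, b] = arm_centers[np.searchsorted(cdf[b], u[:, b], side="right")]
    return out


def trajectory_abs_correlation(
    arm_posteriors: np.ndarray,
    arm_centers: np.ndarray,
    n_traj: int = 2000,
    seed: int = 0,
    mode: str = "mean",
    rng=None,
) -> float:
    """Mean absolute Pearson correlation between time and sampled position.

    ``mode="mean"`` averages |r| over per-trajectory correlations (the
    default); ``mode="pooled"`` computes one correlation over all sampled
    (time, position) points. Trajectories with zero position variance are
    skipped; if every trajectory degenerates, raises.
    """
    P = np.atleast_2d(arm_posteriors)
    if len(P) < 3:
        raise ValueError("correlation requires at least 3 bins")
    rng = np.random.default_rng(seed) if rng is None else rng
    X = sample_trajectories(P, np.asarray(arm_centers, float), n_traj, rng)
    B = X.shape[1]
    t = np.arange(B, dtype=float)
    if mode == "pooled":
        tt = np.tile(t, n_traj)
        xx = X.ravel()
        if xx.std() == 0:
            raise ValueError("all sampled positions identical; correlation undefined")
        return float(abs(np.corrcoef(tt, xx)[0, 1]))
    tc = t - t.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((tc**2).sum() * (Xc**2).sum(axis=1))
    valid = denom > 0
    if not np.any(valid):
        raise ValueError("all trajectories degenerate; correlation undefined")
    r = (Xc[valid] @ tc) / denom[valid]
    return float(np.abs(r).mean())


def sequence_score(
    posteriors: np.ndarray,
    grid: MazeGrid,
    n_shuffles: int = 2000,
    n_traj: int = 2000,
    n_traj_null: int = 100,
    seed: int = 0,
    mode: str = "mean",
) -> float:
    """Z-score of |r| against the circular-shift shuffle null.

    The same trajectory-sampling estimator is applied to each shuffled
    posterior (restricted to the shuffle's own bias_max arm), with a
    reduced per-shuffle trajectory count ``n_traj_null`` for speed.
    """
    P = np.atleast_2d(posteriors)
    rng = np.random.default_rng(seed)
    bias, _ = bias_measures(P, grid)
    arm = int(bias.argmax())
    sl = grid.arm_slice(arm)
    observed = trajectory_abs_correlation(
        P[:, sl], grid.centers[sl], n_traj=n_traj, mode=mode, rng=rng
    )
    null = []
    for S in shuffle_posteriors(P, n_shuffles, seed=int(rng.integers(2**31 - 1))):
        b, _ = bias_measures(S, grid)
        a = int(b.argmax())
        s = grid.arm_slice(a)
        try:
            null.append(
                trajectory_abs_correlation(
                    S[:, s], grid.centers[s], n_traj=n_traj_null, mode=mode, rng=rng
                )
            )
        except ValueError:
            continue
    null = np.asarray(null)
    sd = null.std()
    if sd == 0:
        warnings.warn("degenerate |r| null (sd = 0); sequence score set to 0", stacklevel=2)
        return 0.0
    return float((observed - null.mean()) / sd)


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

@dataclass
class ContentMeasures:
    bias: np.ndarray
    bias_max: float  # transformed to [0, 1]
    bias_max_score: float  # z
    arm: int  # arm associated with bias_max
    line_fit_score: float
    abs_corr: float = float("nan")
    sequence_score: float = float("nan")
    corr_skipped: bool = False

    def is_replay(self, bias_z_min: float = 3.0, line_fit_min: float = 0.1) -> bool:
        return self.bias_max_score > bias_z_min and self.line_fit_score > line_fit_min


@dataclass
class SubEvent:
    interval: tuple[float, float]
    replay: bool
    arm: int
    measures: ContentMeasures
    half: int | None = None  # 0/1 for split halves, None for whole events


@dataclass
class ReferenceEvent:
    interval: BurstInterval
    structure: str  # "whole" | "split"
    subevents: list[SubEvent]
    duration_class: str  # "short" (<= 100 ms) | "long"

    @property
    def has_replay(self) -> bool:
        return any(s.replay for s in self.subevents)


def _score(
    P: np.ndarray,
    grid: MazeGrid,
    n_shuffles: int,
    seed: int,
    bin_size: float,
    with_sequence: bool,
    n_traj: int,
) -> ContentMeasures:
    bias, bias_max = bias_measures(P, grid)
    arm = int(bias.argmax())
    z = bias_max_score(P, grid, n_shuffles=n_shuffles, seed=seed)
    sl = grid.arm_slice(arm)
    lf = line_fit_score(P[:, sl], grid.centers[sl], bin_size=bin_size) if len(P) >= 2 else float("nan")
    m = ContentMeasures(
        bias=bias, bias_max=bias_max, bias_max_score=z, arm=arm, line_fit_score=lf
    )
    if len(P) < 3:
        m.corr_skipped = True
    elif with_sequence:
        m.abs_corr = trajectory_abs_correlation(
            P[:, sl], grid.centers[sl], n_traj=n_traj, seed=seed + 1
        )
        m.sequence_score = sequence_score(
            P, grid, n_shuffles=n_shuffles, n_traj=n_traj, seed=seed + 2
        )
    return m


def burst_bin_range(burst: BurstInterval, bin_starts: np.ndarray, bin_size: float) -> tuple[int, int]:
    """Indices [i0, i1) of decoding bins overlapping [onset, offset)."""
    i0 = int(np.searchsorted(bin_starts + bin_size, burst.onset, side="right"))
    i1 = int(np.searchsorted(bin_starts, burst.offset, side="left"))
    return i0, max(i1, i0)


def classify_events(
    bursts: list[BurstInterval],
    posteriors_per_burst: list[np.ndarray],
    grid: MazeGrid,
    bias_z_min: float = 3.0,
    line_fit_min: float = 0.1,
    split_min: float = 0.100,
    n_shuffles: int = 2000,
    seed: int = 0,
    bin_size: float = 0.010,
    with_sequence_scores: bool = False,
    n_traj: int = 2000,
) -> list[ReferenceEvent]:
    """Label bursts with replay content and apply the joint-event split rule.

    Every burst is scored whole; bursts longer than ``split_min`` are also
    scored as first/second halves (central bin shared when odd). A long
    burst splits when either half qualifies as replay and the whole event's
    bias_max is below the larger of the two halves' — the expected pattern
    when two arms are replayed in succession. Bursts shorter than 3 bins
    are scored whole only, with the correlation measures flagged skipped.
    """
    events: list[ReferenceEvent] = []
    for i, (burst, P) in enumerate(zip(bursts, posteriors_per_burst)):
        P = np.atleast_2d(P)
        if P.shape[0] == 0:
            continue
        s = seed + 7919 * i
        whole = _score(P, grid, n_shuffles, s, bin_size, with_sequence_scores, n_traj)
        duration_class = "long" if burst.duration > split_min else "short"
        structure = "whole"
        subevents = [
            SubEvent(
                interval=(burst.onset, burst.offset),
                replay=whole.is_replay(bias_z_min, line_fit_min),
                arm=whole.arm,
                measures=whole,
            )
        ]
        B = P.shape[0]
        if duration_class == "long" and B >= 2:
            cut_hi = int(np.ceil(B / 2))  # first half: bins [0, ceil(B/2))
            cut_lo = B // 2  # second half: bins [floor(B/2), B)
            mid_t = burst.onset + burst.duration / 2
            halves = []
            for h, (a, b, iv) in enumerate(
                [
                    (0, cut_hi, (burst.onset, mid_t)),
                    (cut_lo, B, (mid_t, burst.offset)),
                ]
            ):
                m = _score(P[a:b], grid, n_shuffles, s + 13 * (h + 1), bin_size,
                           with_sequence_scores, n_traj)
                halves.append(
                    SubEvent(
                        interval=iv,
                        replay=m.is_replay(bias_z_min, line_fit_min),
                        arm=m.arm,
                        measures=m,
                        half=h,
                    )
                )
            if (halves[0].replay or halves[1].replay) and whole.bias_max < max(
                halves[0].measures.bias_max, halves[1].measures.bias_max
            ):
                structure = "split"
                subevents = halves
        events.append(
            ReferenceEvent(
                interval=burst,
                structure=structure,
                subevents=subevents,
                duration_class=duration_class,
            )
        )
    return events


def reference_from_stream(
    stream,
    bursts: list[BurstInterval],
    **kwargs,
) -> list[ReferenceEvent]:
    """Classify bursts using posteriors pulled from a decoded stream."""
    posts = []
    kept = []
    for b in bursts:
        i0, i1 = burst_bin_range(b, stream.bin_starts, stream.bin_size)
        if i1 > i0:
            posts.append(stream.posterior[i0:i1])
            kept.append(b)
    return classify_events(kept, posts, stream.grid, bin_size=stream.bin_size, **kwargs)


# ---------------------------------------------------------------------------
# Tabular round trip (for the CLI and result files)
# ---------------------------------------------------------------------------

def reference_to_frame(events: list[ReferenceEvent]) -> pd.DataFrame:
    """Flatten reference events to one row per (sub)event."""
    rows = []
    for i, e in enumerate(events):
        for s in e.subevents:
            m = s.measures
            rows.append(
                {
                    "event": i,
                    "onset": e.interval.onset,
                    "offset": e.interval.offset,
                    "peak_z": e.interval.peak_z,
                    "structure": e.structure,
                    "duration_class": e.duration_class,
                    "half": -1 if s.half is None else s.half,
                    "sub_start": s.interval[0],
                    "sub_end": s.interval[1],
                    "replay": bool(s.replay),
                    "arm": s.arm,
                    "bias_max": m.bias_max,
                    "bias_max_score": m.bias_max_score,
                    "line_fit_score": m.line_fit_score,
                    "abs_corr": m.abs_corr,
                    "sequence_score": m.sequence_score,
                }
            )
    return pd.DataFrame(rows)


def reference_from_frame(df: pd.DataFrame) -> list[ReferenceEvent]:
    """Inverse of :func:`reference_to_frame` (measure vectors are not restored)."""
    events = []
    for _, g in df.groupby("event", sort=True):
        first = g.iloc[0]
        interval = BurstInterval(
            onset=float(first["onset"]), offset=float(first["offset"]),
            peak_z=float(first["peak_z"]),
        )
        subevents = []
        for _, r in g.iterrows():
            m = ContentMeasures(
                bias=np.empty(0),
                bias_max=float(r["bias_max"]),
                bias_max_score=float(r["bias_max_score"]),
                arm=int(r["arm"]),
                line_fit_score=float(r["line_fit_score"]),
                abs_corr=float(r["abs_corr"]),
                sequence_score=float(r["sequence_score"]),
            )
            subevents.append(
                SubEvent(
                    interval=(float(r["sub_start"]), float(r["sub_end"])),
                    replay=bool(r["replay"]),
                    arm=int(r["arm"]),
                    measures=m,
                    half=None if int(r["half"]) < 0 else int(r["half"]),
                )
            )
        events.append(
            ReferenceEvent(
                interval=interval,
                structure=str(first["structure"]),
                subevents=subevents,
                duration_class=str(first["duration_class"]),
            )
        )
    return events
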
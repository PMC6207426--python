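"""Detection-performance evaluation.

Online detections are matched against the offline reference events; each
reference (sub)event contributes exactly one cell of the confusion matrix
and each detection is accounted for exactly once:

* replay reference burst, detected      -> TP (TP_acc when arms agree)
* replay reference burst, undetected    -> FN
* non-replay reference burst, detected  -> FP_burst
* non-replay reference burst, ignored   -> TN
* detection outside every burst         -> FP_non_burst
* later detections in a burst           -> ignored (first-only rule)

Split (putative joint) events follow special rules: a first detection in
the first half scores that half only; a first detection in the second half
scores the first half as TN/FN and the second as TP/FP; an undetected
split event counts a single FN.

From the counts the usual rates are derived along with the prevalence-free
measures informedness (= sensitivity + specificity - 1), markedness
(= 1 - FOR - FDR) and the Matthews correlation coefficient
(= sign-consistent sqrt(informedness x markedness); FP_non_burst is
reported as a per-minute rate and excluded from the MCC). Significance of
an MCC uses chi2 = N * MCC^2 with 1 df; two MCCs are compared via the
Fisher z-transform.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import PosteriorStream, decode_stream
from .encoding import EncodingModel
from .offline import ReferenceEvent
from .online import DetectionEvent, DetectorConfig, estimate_mua_norm, playback_equivalence

# ---------------------------------------------------------------------------
# Published in vivo benchmark (three sessions, REST and RUN2 epochs).
# Used as golden inputs for recomputing the derived performance measures.
# ---------------------------------------------------------------------------

INVIVO_PERFORMANCE = pd.DataFrame(
    [
        # dataset, epoch, sensitivity, specificity, FOR, FDR, informedness, markedness, mcc
        (1, "REST", 0.95, 0.74, 0.01, 0.65, 0.69, 0.34, 0.49),
        (1, "RUN2", 0.60, 0.68, 0.35, 0.36, 0.29, 0.29, 0.29),
        (2, "REST", 0.86, 0.75, 0.02, 0.72, 0.61, 0.26, 0.40),
        (2, "RUN2", 0.69, 0.80, 0.18, 0.34, 0.49, 0.48, 0.48),
        (3, "REST", 0.95, 0.44, 0.03, 0.68, 0.40, 0.30, 0.34),
        (3, "RUN2", 0.71, 0.57, 0.28, 0.44, 0.28, 0.28, 0.28),
    ],
    columns=[
        "dataset", "epoch", "sensitivity", "specificity", "false_omission_rate",
        "false_discovery_rate", "informedness", "markedness", "mcc",
    ],
)

#: Reference burst counts per epoch in the same sessions (for sample sizes).
INVIVO_BURST_COUNTS = pd.DataFrame(
    [
        (1, "REST", 297, 42),
        (1, "RUN2", 663, 345),
        (2, "REST", 537, 68),
        (2, "RUN2", 808, 315),
        (3, "REST", 487, 134),
        (3, "RUN2", 714, 334),
    ],
    columns=["dataset", "epoch", "n_bursts", "n_replay_bursts"],
)


def derived_benchmark_metrics() -> pd.DataFrame:
    """Recompute informedness/markedness/MCC from the benchmark's printed rates."""
    df = INVIVO_PERFORMANCE.copy()
    df["informedness_recomputed"] = df["sensitivity"] + df["specificity"] - 1.0
    df["markedness_recomputed"] = 1.0 - df["false_omission_rate"] - df["false_discovery_rate"]
    df["mcc_recomputed"] = np.sqrt(
        df["informedness_recomputed"] * df["markedness_recomputed"]
    )
    return df


# ---------------------------------------------------------------------------
# Matching and confusion counts
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int = 0
    TP_acc: int = 0
    FP_burst: int = 0
    FP_non_burst: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self):
        if self.TP_acc > self.TP:
            raise ValueError("TP_acc cannot exceed TP")

    @property
    def n_events(self) -> int:
        """Reference (sub)events entering the 2x2 matrix."""
        return self.TP + self.FP_burst + self.TN + self.FN


@dataclass
class Assignment:
    """First detection matched to a reference (sub)event."""

    burst_onset: float
    burst_duration: float
    detection_time: float
    outcome: str  # "TP" | "FP_burst"
    arm_match: bool


def match_detections(
    detections: list[DetectionEvent],
    reference: list[ReferenceEvent],
    epoch_duration: float,
) -> tuple[ConfusionCounts, list[Assignment]]:
    """Match online detections to reference events; build the confusion counts.

    A detection belongs to a burst when its time lies inside the half-open
    window [onset, offset); only the first detection per reference burst
    counts. Raises on overlapping reference bursts.
    """
    ref = sorted(reference, key=lambda e: e.interval.onset)
    for a, b in zip(ref, ref[1:]):
        if b.interval.onset < a.interval.offset:
            raise ValueError("overlapping reference bursts")
    onsets = np.array([e.interval.onset for e in ref])
    offsets = np.array([e.interval.offset for e in ref])

    det_times = np.array([d.detection_time for d in detections])
    order = np.argsort(det_times, kind="stable")
    first_in_burst: dict[int, DetectionEvent] = {}
    counts = ConfusionCounts()
    for oi in order:
        d = detections[oi]
        j = int(np.searchsorted(onsets, d.detection_time, side="right")) - 1
        if j >= 0 and d.detection_time < offsets[j]:
            if j not in first_in_burst:
                first_in_burst[j] = d
        else:
            counts.FP_non_burst += 1

    assignments: list[Assignment] = []

    def score_subevent(sub, det, burst):
        nonlocal counts
        arm_match = det is not None and det.content == sub.arm
        if det is None:
            if sub.replay:
                counts.FN += 1
            else:
                counts.TN += 1
            return
        if sub.replay:
            counts.TP += 1
            if arm_match:
                counts.TP_acc += 1
            assignments.append(
                Assignment(burst.onset, burst.duration, det.detection_time, "TP", arm_match)
            )
        else:
            counts.FP_burst += 1
            assignments.append(
                Assignment(burst.onset, burst.duration, det.detection_time, "FP_burst", arm_match)
            )

    for j, event in enumerate(ref):
        det = first_in_burst.get(j)
        burst = event.interval
        if event.structure == "whole":
            score_subevent(event.subevents[0], det, burst)
        else:
            first_half, second_half = event.subevents
            if det is None:
                counts.FN += 1
            elif det.detection_time < first_half.interval[1]:
                score_subevent(first_half, det, burst)  # second half not taken into account
            else:
                score_subevent(first_half, None, burst)
                score_subevent(second_half, det, burst)
    return counts, assignments


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class PerformanceMetrics:
    sensitivity: float
    specificity: float
    false_omission_rate: float
    false_discovery_rate: float
    content_accuracy: float
    informedness: float
    markedness: float
    mcc: float
    out_of_burst_rate: float  # per minute
    median_absolute_latency: float = float("nan")  # ms
    median_relative_latency: float = float("nan")  # fraction of burst duration
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "sensitivity", "specificity", "false_omission_rate",
                "false_discovery_rate", "content_accuracy", "informedness",
                "markedness", "mcc", "out_of_burst_rate",
                "median_absolute_latency", "median_relative_latency",
            )
        }


def _ratio(num: float, den: float):
    return num / den if den > 0 else float("nan")


def compute_metrics(
    c: ConfusionCounts,
    epoch_duration: float,
    assignments: list[Assignment] | None = None,
) -> PerformanceMetrics:
    """Derive all performance measures from confusion counts.

    Metrics with zero denominators are reported as NaN and listed in
    ``undefined`` so that aggregation across epochs can skip them.
    """
    sens = _ratio(c.TP, c.TP + c.FN)
    spec = _ratio(c.TN, c.TN + c.FP_burst)
    for_ = _ratio(c.FN, c.FN + c.TN)
    fdr = _ratio(c.FP_burst, c.FP_burst + c.TP)
    acc = _ratio(c.TP_acc, c.TP)
    inf = sens + spec - 1.0
    mark = 1.0 - for_ - fdr
    if math.isnan(inf) or math.isnan(mark):
        mcc = float("nan")
    else:
        prod = inf * mark
        mcc = math.copysign(math.sqrt(abs(prod)), inf) if prod >= 0 else float("nan")
    undefined = tuple(
        name
        for name, v in [
            ("sensitivity", sens), ("specificity", spec),
            ("false_omission_rate", for_), ("false_discovery_rate", fdr),
            ("content_accuracy", acc), ("mcc", mcc),
        ]
        if isinstance(v, float) and math.isnan(v)
    )
    abs_ms, rel = latencies(assignments or [])
    return PerformanceMetrics(
        sensitivity=sens,
        specificity=spec,
        false_omission_rate=for_,
        false_discovery_rate=fdr,
        content_accuracy=acc,
        informedness=inf,
        markedness=mark,
        mcc=mcc,
        out_of_burst_rate=c.FP_non_burst / (epoch_duration / 60.0),
        median_absolute_latency=float(np.median(abs_ms)) if len(abs_ms) else float("nan"),
        median_relative_latency=float(np.median(rel)) if len(rel) else float("nan"),
        undefined=undefined,
    )


def latencies(assignments: list[Assignment]) -> tuple[np.ndarray, np.ndarray]:
    """Per matched first-detection latency.

    Absolute latency (ms) is detection time minus burst onset — in
    simulated playback the detection time is the end of the triggering
    window, so this is the identification latency. Relative latency is the
    absolute latency divided by the burst duration.
    """
    if not assignments:
        return np.empty(0), np.empty(0)
    abs_s = np.array([a.detection_time - a.burst_onset for a in assignments])
    rel = abs_s / np.array([a.burst_duration for a in assignments])
    return abs_s * 1000.0, rel


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def mcc_chi2(mcc: float, n: int) -> tuple[float, float]:
    """chi2 = n * mcc^2 with 1 df, and its p-value."""
    if n <= 0:
        raise ValueError("n must be > 0")
    chi2 = n * mcc**2
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def compare_mcc(mcc1: float, n1: int, mcc2: float, n2: int) -> tuple[float, float]:
    """Two-correlation z-test on Fisher-transformed MCCs (two-sided)."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both groups")
    if abs(mcc1) >= 1 or abs(mcc2) >= 1:
        raise ValueError("|mcc| must be < 1 for the Fisher transform")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(mcc1) - math.atanh(mcc2)) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    theta_mua_grid: np.ndarray
    theta_sharp_grid: np.ndarray
    mcc: np.ndarray  # (len(mua), len(sharp))
    out_of_burst: np.ndarray
    argmax: tuple[int, int]
    best_metrics: PerformanceMetrics

    @property
    def best_thresholds(self) -> tuple[float, float]:
        i, j = self.argmax
        return float(self.theta_mua_grid[i]), float(self.theta_sharp_grid[j])


def sweep_parameters(
    posteriors: PosteriorStream,
    reference: list[ReferenceEvent],
    mua_grid,
    sharp_grid,
    config: DetectorConfig,
    epoch_duration: float,
) -> SweepResult:
    """MCC / out-of-burst-rate maps over (theta_mua, theta_sharp).

    Each cell replays the streaming detector (identical code path,
    including the lock-out) on the saved posteriors. The argmax cell
    maximizes MCC with deterministic tie-breaking toward the lowest
    theta_mua, then the lowest theta_sharp; NaN cells never win.
    """
    mua_grid = np.asarray(mua_grid, float)
    sharp_grid = np.asarray(sharp_grid, float)
    mcc_map = np.full((len(mua_grid), len(sharp_grid)), np.nan)
    oob_map = np.full_like(mcc_map, np.nan)
    best = (-np.inf, None, None)
    for i, tm in enumerate(mua_grid):
        for j, ts in enumerate(sharp_grid):
            dets = playback_equivalence(posteriors, config.with_thresholds(tm, ts))
            counts, assign = match_detections(dets, reference, epoch_duration)
            m = compute_metrics(counts, epoch_duration, assign)
            mcc_map[i, j] = m.mcc
            oob_map[i, j] = m.out_of_burst_rate
            if not math.isnan(m.mcc) and m.mcc > best[0]:
                best = (m.mcc, (i, j), m)
    if best[1] is None:
        raise ValueError("no sweep cell produced a defined MCC")
    return SweepResult(
        theta_mua_grid=mua_grid,
        theta_sharp_grid=sharp_grid,
        mcc=mcc_map,
        out_of_burst=oob_map,
        argmax=best[1],
        best_metrics=best[2],
    )


# ---------------------------------------------------------------------------
# Tetrode subsampling
# ---------------------------------------------------------------------------

def subsample_tetrodes(
    model: EncodingModel,
    run_counts_by_tetrode: dict[int, np.ndarray],
    test_spikes: pd.DataFrame,
    epoch: tuple[float, float],
    reference: list[ReferenceEvent],
    n_range,
    config: DetectorConfig,
    mua_grid,
    sharp_grid,
    max_combos: int = 50,
    seed: int = 0,
    bin_size: float = 0.010,
) -> pd.DataFrame:
    """Detection performance as a function of the number of tetrodes.

    For each subset size ``n`` the harness evaluates all tetrode
    combinations, or ``max_combos`` random distinct ones (whichever is
    smaller): the encoding model is restricted to the subset (per-tetrode
    models are independent, so the restriction equals a rebuild from the
    subset's spikes), the test epoch is re-decoded, thresholds are
    re-optimized by a sweep, and the optimal-cell metrics are recorded.
    The reference stays fixed — computed from the full array — so results
    measure detector degradation, not reference degradation.

    ``run_counts_by_tetrode`` maps tetrode id -> per-bin spike counts in
    the encoding epoch, summed over the subset to re-estimate the MUA
    normalization for each combination.
    """
    rng = np.random.default_rng(seed)
    all_tetrodes = model.tetrode_ids
    T = len(all_tetrodes)
    rows = []
    epoch_duration = epoch[1] - epoch[0]
    for n in n_range:
        if n > T:
            raise ValueError(f"requested {n} tetrodes but only {T} available")
        total = math.comb(T, n)
        if total <= max_combos:
            combos = list(itertools.combinations(all_tetrodes, n))
        else:
            seen = set()
            while len(seen) < max_combos:
                seen.add(tuple(sorted(rng.choice(all_tetrodes, size=n, replace=False).tolist())))
            combos = sorted(seen)
        for ci, combo in enumerate(combos):
            sub_model = model.subset(list(combo))
            sub_spikes = test_spikes[test_spikes["tetrode_id"].isin(combo)]
            stream = decode_stream(sub_model, sub_spikes, bin_size, epoch[0], epoch[1])
            counts = np.sum([run_counts_by_tetrode[k] for k in combo], axis=0)
            cfg = DetectorConfig(
                theta_mua=config.theta_mua,
                theta_sharp=config.theta_sharp,
                n_bins=config.n_bins,
                bin_size=bin_size,
                sharp_radius=config.sharp_radius,
                lockout=config.lockout,
                target_arms=config.target_arms,
                mua_norm=estimate_mua_norm(counts),
            )
            sweep = sweep_parameters(stream, reference, mua_grid, sharp_grid, cfg, epoch_duration)
            m = sweep.best_metrics
            tm, ts = sweep.best_thresholds
            rows.append(
                {
                    "n_tetrodes": n,
                    "combo": ci,
                    "tetrodes": ",".join(map(str, combo)),
                    "theta_mua": tm,
                    "theta_sharp": ts,
                    "mcc": m.mcc,
                    "content_accuracy": m.content_accuracy,
                    "median_relative_latency": m.median_relative_latency,
                    "out_of_burst_rate": m.out_of_burst_rate,
                }
            )
    return pd.DataFrame(rows)
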
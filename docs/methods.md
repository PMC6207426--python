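# Methods notes

This note records the model assumptions, parameter choices, numerical
details and known limitations of `replaydetect`. It documents decisions;
every number quoted as a result elsewhere is produced by the test suite or
by `scripts/acceptance.py`, not here.

## Decoding model

Position is decoded on a discrete 1D grid over the maze arms. Each arm of
length `L` (default 90 cm) gets `floor(L / 2.15) = 41` bins with centers
at `(i + 0.5) · 2.15` cm; arms are concatenated arm-by-arm into a global
index (123 bins for 3 arms). Arms are treated as *separate linear tracks*:
no kernel mass crosses arm boundaries. Internally this is implemented by
embedding the per-arm coordinate on a gapped axis (10⁴ cm of dead space
between arms), chosen large enough that cross-arm Gaussian weights
underflow to exactly 0.0 in double precision — equivalent to explicit
masking but keeping every evaluation a single dense kernel sum.

Per tetrode, spiking is a marked Poisson process with joint rate
`λ(a,x) = μ p(a,x)/π(x)` and marginal `λ(x) = μ p(x)/π(x)`:

* `μ` — mean rate: qualifying spikes / qualifying time. Qualifying means
  running speed > 8.5 cm/s (the standard run/rest split for place-field
  estimation); **occupancy `π(x)` uses the same speed-filtered samples**,
  keeping numerator and denominator on the same behavioral epoch.
* `p(a,x)`, `p(x)`, `π(x)` — Gaussian KDEs with fixed diagonal bandwidths
  of 8 cm (position) and 30 µV (each amplitude channel). `p(x)` and `π(x)`
  are normalized to sum to 1 over the grid (times bin width), which makes
  `Σ λ(x) π(x) Δx = μ` an exact identity up to occupancy flooring — the
  test suite asserts it at 1%.
* Spike positions are looked up at the nearest position sample (50 Hz in
  the simulator); linearization error at run speeds is ≲ 0.6 cm, well
  under the 8 cm kernel.

**Compression.** The density estimator is compressed online: a new sample
merges into the nearest component when its bandwidth-normalized Euclidean
distance is below the compression threshold (weighted-mean update,
weight + 1), else it starts a unit-weight component. The update is
moment-free — components keep the fixed kernel, no covariance tracking —
which makes evaluation a plain weighted kernel sum and decoding a small
matrix product against precomputed per-component position profiles. The
cost of that simplicity is an O(threshold²) density perturbation: ~0.7% of
peak at threshold 0.5 and ~2.4% at 1.0 on uniform 1D data. What matters
for detection is decision stability, which holds: at threshold 2.0 fewer
than 10% of informative candidate-burst posteriors (MAP probability
> 0.05) change their MAP arm relative to the uncompressed model. At
threshold 0 the estimator is exactly the dense KDE — the suite verifies
equality with an independently coded brute-force decoder at 1e-8. Default
thresholds: 1.8 for the online model, 1.15 for the offline reference
(higher fidelity at higher cost).

**Numerical choices.** Kernels are *not* truncated: on a 123-bin grid the
exact evaluation is cheap, and truncation would break the brute-force
equivalence at tolerances far above rounding error. Rates are floored at
1e-10 Hz so a mark far from every component cannot produce `log 0`. Grid
bins with occupancy below 1e-3 of the maximum are masked (rates floored),
keeping posteriors finite and normalized when an arm was never visited.
Posteriors are computed in log space with max-subtraction; the `Δⁿ`
prefactor and the evidence cancel on normalization and are dropped. MAP
ties break toward the lowest grid index (numpy argmax), deterministically.
Decoding bins are half-open `[t0 + kΔ, t0 + (k+1)Δ)`; a spike exactly on a
boundary belongs to the later bin.

## Online detector

Criteria over the trailing `n_bins = 3` bins of 10 ms (window T = 30 ms):

* **Burst**: z-scored mean MUA count > `θ_mua`. The z-scale is
  mean/SD of per-bin total counts from a reference epoch (the encoding
  epoch by default). The published threshold values (2.5 / 3) are on an
  unstated scale; z-units make them commensurate with the offline
  detector's z-scores and the sweep ranges, and raw counts-per-bin
  thresholds remain configurable through `mua_norm`.
* **Sharpness**: integrated probability within 14 cm of the MAP *on the
  MAP's arm only* — 6 bins per side at 2.15 cm spacing (12.9 cm reach),
  truncated at arm ends — required of the latest bin and of the window
  mean.
* **Consistency**: all window MAPs on one target arm. Same-arm membership
  only; monotonicity of positions is deliberately not required.

Criteria are evaluated at bin boundaries (not mid-bin), detections are
stamped at the window end, and a 75 ms lock-out follows each detection.
The playback engine used by parameter sweeps *is* `detect_stream` — one
code path, so simulated-time results equal streaming results by
construction. Burst-only "unknown" detections can be enabled but default
off. The structural minimum identification latency is `n_bins × bin_size`
from window start.

## Offline reference

MUA: 1 ms spike histogram, Gaussian-smoothed (15 ms bandwidth). The trend
is an EWMA (span 750 samples on the 10 ms-subsampled signal, α = 2/751,
half-life 2.6 s) **averaged over a forward and a backward pass**; the
average (rather than forward-then-backward composition) makes the trend
operator exactly equivariant under time reversal, including edge effects,
while keeping the same pass-band. The trend is linearly interpolated back
to 1 ms, subtracted, and the residual z-scored over the epoch.

Bursts: maximal runs of z > 0.5, merged at gaps < 20 ms (iterated to a
fixpoint), kept when the *merged* interval peaks at z ≥ 2.5. Onsets and
offsets resolve at 1 ms; a burst's posteriors are the 10 ms bins
overlapping `[onset, offset)`.

Content scores (per burst, and per half for bursts > 100 ms, sharing the
central bin when the count is odd):

* **bias** — time-averaged per-arm posterior mass; `bias_max` rescaled
  from `[1/n_arms, 1]` to `[0, 1]`; z-scored against 2000 shuffles
  (default; configurable) in which each bin's probability vector is
  circularly shifted along the concatenated position axis by an
  independent uniform offset. Degenerate nulls (SD 0, e.g. exactly
  uniform posteriors) score 0 with a warning.
* **line fit** — per-bin within-arm renormalization, then an exhaustive
  discrete search over constant-velocity lines: intercepts at all 41 arm
  bins, velocities −1500…1500 cm/s in 75 cm/s steps (covers an arm
  traversal in ≥ 60 ms); a line scores the mean per-bin mass within
  ±15 cm, clipped at arm ends; the score is the max. Exhaustive search
  *defines* the implementation — the "modified radon" interpolation
  details are unspecified upstream, and the line grid is configuration.
* **|r|** — mean absolute Pearson correlation between bin index and
  positions sampled per bin from the within-arm posterior (2000
  trajectories). Mean-of-|r| is the default aggregation; a pooled-samples
  mode is exposed because the verbal definition admits both readings.
  Zero-variance trajectories are skipped; all-degenerate input raises.
* **sequence score** — z of |r| against the same shuffle null, with a
  reduced per-shuffle trajectory count (default 100) for tractability.

Classification: replay iff bias-max score > 3 *and* line-fit score > 0.1
(strict inequalities). Long bursts split into two sub-events when either
half classifies as replay and the whole event's `bias_max` is below the
*larger* of the two halves' — read as "a half shows stronger arm
concentration than the whole", the signature of an arm switch at the
midpoint. The midpoint is used both for measure computation and for
labeling. Bursts shorter than 3 bins skip the correlation measures
(flagged) and are never split.

## Synthetic sessions

The generator emulates the in vivo study conditions, not CA1 biophysics:

* Maze: three 90 cm arms from a central platform, arms as rays at evenly
  spaced angles; 2D coordinates are emitted so the projection step is
  exercised.
* Run epochs: out-and-back arm traversals at 30 cm/s with 2 s reward
  pauses; place cells (default 14 tetrodes × 4 cells) with Gaussian
  fields (8 cm SD, 20 Hz peak, 0.5 Hz background) tiling the arms;
  inhomogeneous-Poisson spiking by thinning at a 1 ms step (finer than
  both the 10 ms decode bin and the 1 ms MUA histogram); marks =
  per-cell signature (uniform 60–300 µV per channel, re-drawn until
  within-tetrode mean pairwise separation exceeds 3× the 10 µV mark
  noise) + isotropic Gaussian noise.
* Rest epochs: bursts arrive at 0.4 Hz (the benchmark rest-epoch rate)
  with log-normal durations matched to the published median/IQR
  (83 ms, [65.3, 119.8] ms) — the distribution family is a modeling
  choice; only median and IQR are constrained by data. 35% of bursts
  carry replay; of the replay bursts that are long enough (> 100 ms),
  25% are joint two-arm events. Joint content is restricted to long
  bursts because a two-arm sweep cannot be expressed in less: at the
  default 600 cm/s (≈ 20× run speed — replay speed is a design choice,
  only durations are published) a 50 ms "joint" event would cover ~15 cm
  per arm and would be unclassifiable by construction. Joint sweeps run
  inward on the first arm and outward on the second, switching at the
  event midpoint. Non-replay bursts scale every cell's background rate
  by a common gain (default 20) — strong MUA with no consistent spatial
  content; replay bursts drive cells through their tuning at the virtual
  position with gain 5, so both burst kinds produce comparable population
  rates (~400 Hz).

**What passing on synthetic data does and does not show.** The simulator
has no theta dynamics, phase precession, ripple LFP, directional place
fields, forward/reverse asymmetry beyond signed velocity, or firing-rate
heterogeneity across cells. Synthetic replay is cleaner than real replay,
so absolute performance numbers (e.g. content accuracy near 1.0) are
upper bounds; the value of the synthetic end-to-end checks is structural —
they verify that the decoding, detection, reference and scoring stages
compose correctly, that detection improves with tetrode count, and that
latencies sit where the window arithmetic says they must.

## Evaluation details

Burst membership of a detection is half-open `[onset, offset)`; only the
first detection per reference burst counts. `FP_non_burst` is reported as
a per-minute rate and excluded from the MCC (and from its argmax in
sweeps). MCC is computed as `sign(informedness) ·
sqrt(informedness × markedness)` — for a 2×2 table both factors share the
numerator `TP·TN − FP·FN`, so the sign is consistent and the identity
with the standard formula holds (property-tested). Metrics with zero
denominators are NaN and flagged, never silently 0. `N` for the χ² test
is the number of reference (sub)events entering the 2×2 table. Sweep
argmax ties break toward the lowest `θ_mua`, then the lowest `θ_sharp`.

In the subsampling harness the per-tetrode encoding models are
independent given the shared occupancy, so restricting the full model to
a tetrode subset is identical to rebuilding from the subset's spikes; the
harness exploits this, re-estimates the MUA normalization per subset, and
re-optimizes thresholds per subset against the *fixed* full-data
reference.

## Problem sizes

Default study-scale runs used throughout the suite and the reproduction
script: 240 s run epoch, 300 s rest epoch, 14 tetrodes × 4 cells,
200-shuffle nulls for reference scoring, subsampling at
n ∈ {2, 4, 6, 8, 10, 12, 14} with 3 combinations per size over a 3×3
threshold grid. These sizes give ~120 reference bursts and stable
qualitative behavior; shuffle counts and grids are configurable up to the
published 2000-shuffle / dense-grid settings.

## Known limitations

* The merge rule of the compressed estimator is a faithful stand-in for
  the cited online compressed-KDE scheme, isolated behind
  `compress_insert` so it can be swapped; moment-matching merges would
  lower the density error at equal compression.
* The MUA normalization underlying `θ_mua` (z-units against the encoding
  epoch) is one defensible reading of an under-specified quantity; raw
  thresholds are configurable.
* End-to-end MCC on synthetic rest epochs varies noticeably with the
  session seed (≈ 0.2–0.5 at the default sizes) because non-replay bursts
  pass the content criteria by chance at a population-dependent rate —
  the same false-positive mode described for the live system.
* No real-time guarantees are made or measured; the streaming detector is
  causal but runs in simulated time.
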
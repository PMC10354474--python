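"""Behavioural regimes of the coupled pair, leadership, and parameter sweeps.

Five regimes are distinguished as the coupling strength d grows at fixed
tonic input c: constant parallel swimming, aperiodic leadership switching,
periodic leadership switching, one-leader-one-follower swimming, and
leaderless turn-taking.  Classification rests on the same diagnostics the
Lorenz-map analysis uses: the geometry of the successive-maxima return map of
the distance difference x1 - x2 (fixed point / closed loop / scatter),
resolved into leader-follower vs turn-taking by the symmetry of the extrema.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .params import ModelParams, CouplingParams
from .integrate import SimSettings, Trajectory, simulate
from .analysis import find_extrema, lorenz_map, peak_acf, limit_cycle_period

__all__ = [
    "RegimeLabel",
    "LeadershipRecord",
    "HeatmapResult",
    "BoundaryScan",
    "leadership",
    "classify",
    "sweep_period_vs_c",
    "heatmap_bifurcation",
    "regime_boundaries",
]


class RegimeLabel(str, Enum):
    CONSTANT_TOGETHER = "CONSTANT_TOGETHER"
    APERIODIC_SWITCHING = "APERIODIC_SWITCHING"
    PERIODIC_SWITCHING = "PERIODIC_SWITCHING"
    LEADER_FOLLOWER = "LEADER_FOLLOWER"
    NO_LEADER_TURNTAKING = "NO_LEADER_TURNTAKING"
    UNCLASSIFIED = "UNCLASSIFIED"


# ---------------------------------------------------------------------------
# leadership

@dataclass(frozen=True)
class LeadershipRecord:
    """Who is in front, when the roles swap, and how long tenures last.

    ``sign`` is the (smoothed) sign of x1 - x2 at every sample: +1 while fish
    1 leads.  ``switch_times`` are the accepted leadership changes.
    ``bursts_per_tenure`` counts the leading fish's burst onsets between
    consecutive switches (interior tenures only).
    """

    times: np.ndarray
    sign: np.ndarray
    switch_times: np.ndarray
    bursts_per_tenure: np.ndarray

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)


def _burst_onsets(traj: Trajectory, fish: int) -> np.ndarray:
    """Times where the fish's acceleration turns positive (burst starts)."""
    acc = traj.derivatives()[:, (1, 4)[fish] if traj.kind == "pair" else 1]
    s = np.sign(acc)
    idx = np.nonzero((s[:-1] <= 0) & (s[1:] > 0))[0]
    return traj.times[idx]


def _estimated_burst_period(traj: Trajectory) -> float | None:
    res = limit_cycle_period(traj, "v1", transient=0.0, min_cycles=3)
    return None if res is None else res[0]


def _smooth(y: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return y
    kernel = np.ones(n) / n
    pad = n // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="same")[pad : pad + len(y)]


def leadership(
    traj: Trajectory,
    transient: float | None = None,
    dwell: float = 1.0,
    magnitude: float = 0.1,
    smooth: float | None = None,
) -> LeadershipRecord:
    """Extract the leadership record from a pair trajectory.

    The leader is the fish with the larger position.  Because the follower
    briefly overtakes the leader during every burst cycle in parts of
    parameter space, the raw sign of x1 - x2 flips far more often than the
    leadership the eye sees; the sign is therefore taken on x1 - x2 smoothed
    over one burst period (``smooth`` seconds; None = estimate the burst
    period from the speed channel, 0 = no smoothing).  A sign change counts
    as a switch only when the new sign persists longer than ``dwell`` seconds
    and the excursion exceeds ``magnitude`` cm.
    """
    sub = traj.post_transient(transient)
    t = sub.times
    s = sub.separation()
    dt = t[1] - t[0]

    if smooth is None:
        period = _estimated_burst_period(sub)
        smooth = period if period is not None else 0.0
    sm = _smooth(s, int(round(smooth / dt))) if smooth > 0 else s

    if float(np.max(np.abs(s))) < magnitude:
        return LeadershipRecord(t, np.zeros_like(s), np.array([]), np.array([], int))

    sign = np.sign(sm)
    sign[sign == 0] = 1
    flips = np.nonzero(sign[1:] != sign[:-1])[0] + 1

    # accept a flip only if the new sign persists for >= dwell
    accepted: list[int] = []
    for i, idx in enumerate(flips):
        nxt = flips[i + 1] if i + 1 < len(flips) else len(s)
        if (nxt - idx) * dt >= dwell:
            if accepted and sign[accepted[-1]] == sign[idx]:
                continue  # same leader as the previous accepted tenure
            accepted.append(idx)
    switch_times = t[np.array(accepted, int)] if accepted else np.array([])

    # bursts of the current leader inside each interior tenure
    counts = []
    for j in range(len(accepted) - 1):
        lo, hi = t[accepted[j]], t[accepted[j + 1]]
        lead_fish = 0 if sign[accepted[j]] > 0 else 1
        onsets = _burst_onsets(sub, lead_fish)
        counts.append(int(np.sum((onsets >= lo) & (onsets < hi))))
    return LeadershipRecord(t, sign, switch_times, np.array(counts, int))


# ---------------------------------------------------------------------------
# classification

def classify(
    traj: Trajectory,
    transient: float | None = None,
    speed_amplitude_tol: float = 0.05,
    fixed_point_tol: float = 0.25,
    asymmetry_tol: float = 0.15,
    acf_strength: float = 0.6,
    min_extrema: int = 10,
) -> RegimeLabel:
    """Assign one of the five behavioural regime labels to a pair trajectory.

    Decision tree:

    1. If the post-transient speed amplitude of both fish (final quarter of
       the window) is below ``speed_amplitude_tol``, the pair has converged to
       the constant, zero-separation regime -> CONSTANT_TOGETHER.
    2. Otherwise the local maxima M_n and minima N_n of x1 - x2 are extracted
       (fewer than ``min_extrema`` maxima -> UNCLASSIFIED).
    3. If the late-time M_n form a fixed point (spread < ``fixed_point_tol``
       cm), the attractor is a rigid cycle of the pair: symmetric extrema
       (|median M + median N| small relative to their size) mean the fish
       alternate the front position -> NO_LEADER_TURNTAKING; asymmetric
       extrema mean one fish stays in front on average -> LEADER_FOLLOWER.
    4. Otherwise the maxima wander: a closed-loop return map or a strong
       peak-ACF period (value > ``acf_strength``) -> PERIODIC_SWITCHING,
       else -> APERIODIC_SWITCHING.
    """
    sub = traj.post_transient(transient)
    t = sub.times

    # (1) constant regime, judged on the final quarter so slow decay counts
    tail = t >= t[0] + 0.75 * (t[-1] - t[0])
    amp = max(
        float(sub.speed(0)[tail].max() - sub.speed(0)[tail].min()),
        float(sub.speed(1)[tail].max() - sub.speed(1)[tail].min()),
    )
    if amp < speed_amplitude_tol:
        return RegimeLabel.CONSTANT_TOGETHER

    s = sub.separation()
    peaks = find_extrema(s, t)
    if peaks.n_maxima < min_extrema:
        return RegimeLabel.UNCLASSIFIED

    # last ten extrema: transients of the slow attractor have decayed there
    M = peaks.maxima[-10:]
    N = peaks.minima[-10:]

    # the genuine rigid-cycle regimes have O(5-20 cm) excursions; a tiny
    # "fixed point" is a decaying or marginal oscillation, left to step (4)
    if float(M.max() - M.min()) < fixed_point_tol and max(abs(M).max(), abs(N).max()) > 2.0:
        m_fix, n_fix = float(np.median(M)), float(np.median(N))
        spread = abs(m_fix) + abs(n_fix)
        asym = abs(m_fix + n_fix) / spread if spread > 0 else 0.0
        if asym < asymmetry_tol:
            return RegimeLabel.NO_LEADER_TURNTAKING
        return RegimeLabel.LEADER_FOLLOWER

    lm = lorenz_map(peaks, eps=0.05)
    if lm.geometry == "periodic":
        return RegimeLabel.PERIODIC_SWITCHING
    acf_res = peak_acf(peaks) if peaks.n_maxima >= 3 else None
    if (
        acf_res is not None
        and acf_res.dominant_lag is not None
        and acf_res.dominant_value is not None
        and acf_res.dominant_value > acf_strength
    ):
        return RegimeLabel.PERIODIC_SWITCHING
    return RegimeLabel.APERIODIC_SWITCHING


# ---------------------------------------------------------------------------
# sweeps

#: Default settings for regime classification sweeps.  The slow switching
#: cycle spans ~500 model-seconds, so classification windows must hold
#: several of them; local tolerances are relaxed (classification is
#: qualitative and is checked for tolerance-invariance in the test suite).
SWEEP_SETTINGS = SimSettings(t_end=4000.0, transient=500.0, rtol=1e-6, atol=1e-8)

def sweep_period_vs_c(
    p: ModelParams,
    c_grid: Sequence[float],
    settings: SimSettings | None = None,
    initial: Sequence[float] = (0.0, 0.0),
):
    """Single-fish limit-cycle period as a function of the tonic input c.

    Returns a DataFrame with columns c and period; period is NaN below the
    oscillation onset (no cycle).
    """
    import pandas as pd

    settings = settings or SimSettings(t_end=500.0, transient=250.0)
    rows = []
    for c in c_grid:
        traj = simulate(initial, p.with_c(float(c)), settings=settings)
        res = limit_cycle_period(traj, "v1")
        rows.append({"c": float(c), "period": np.nan if res is None else res[0]})
    return pd.DataFrame(rows)


HEATMAP_EDGES = np.round(np.linspace(-35.05, 35.05, 702), 6)  # 701 bins of 0.1 cm


@dataclass(frozen=True)
class HeatmapResult:
    """2-D histogram of distance-difference extrema over a d grid.

    ``counts[i, j]`` is the number of extrema (maxima and minima pooled) of
    x1 - x2 falling in distance bin i for coupling value d_grid[j], pooled
    over replicates.  Extrema outside [-35, 35] cm land in ``overflow``.
    """

    d_grid: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    overflow: np.ndarray
    n_reps: int
    seed: int


def _pair_ic(x1_start: float) -> np.ndarray:
    return np.array([0.0, 0.0, x1_start, 0.0, 0.0, 0.0])


def heatmap_bifurcation(
    p: ModelParams,
    cp_template: CouplingParams,
    d_grid: Sequence[float] | None = None,
    n_reps: int = 10,
    seed: int = 0,
    settings: SimSettings | None = None,
    x1_starts: Sequence[float] | None = None,
) -> HeatmapResult:
    """Heat-map bifurcation diagram in the coupling strength d.

    For each d and each replicate the pair starts from rest with fish 1 at a
    uniform random position in [-20, 20] cm (or at the fixed positions in
    ``x1_starts``, reused for every d); the post-transient local maxima M_n
    and minima N_n of x1 - x2 are pooled into 701 fixed 0.1 cm bins.
    Deterministic for a fixed seed.
    """
    if d_grid is None:
        d_grid = np.round(np.arange(0.0, 0.1 + 1e-12, 0.0005), 6)
    d_grid = np.asarray(d_grid, float)
    settings = settings or SimSettings()
    if x1_starts is not None:
        n_reps = len(x1_starts)
        starts = np.tile(np.asarray(x1_starts, float), (len(d_grid), 1))
    else:
        rng = np.random.default_rng(seed)
        starts = rng.uniform(-20.0, 20.0, size=(len(d_grid), n_reps))

    counts = np.zeros((len(HEATMAP_EDGES) - 1, len(d_grid)), dtype=np.int64)
    overflow = np.zeros(len(d_grid), dtype=np.int64)
    for j, d in enumerate(d_grid):
        cp = cp_template.with_d(float(d))
        for r in range(n_reps):
            traj = simulate(_pair_ic(starts[j, r]), p, cp, settings)
            sub = traj.post_transient()
            peaks = find_extrema(sub.separation(), sub.times)
            vals = np.concatenate([peaks.maxima, peaks.minima])
            inside = (vals >= HEATMAP_EDGES[0]) & (vals <= HEATMAP_EDGES[-1])
            overflow[j] += int(np.sum(~inside))
            h, _ = np.histogram(vals[inside], bins=HEATMAP_EDGES)
            counts[:, j] += h
    return HeatmapResult(d_grid, HEATMAP_EDGES.copy(), counts, overflow, n_reps, seed)


@dataclass(frozen=True)
class BoundaryScan:
    """Majority regime label along a d grid, plus the label-change points."""

    d_grid: np.ndarray
    labels: list  # majority RegimeLabel per d
    replicate_labels: list  # list (per d) of per-replicate labels
    boundaries: list  # (d_mid, from_label, to_label)
    monotone: bool

    def first_d_with(self, *wanted: RegimeLabel) -> float | None:
        """Smallest d whose majority label is one of ``wanted``."""
        for d, lab in zip(self.d_grid, self.labels):
            if lab in wanted:
                return float(d)
        return None


def regime_boundaries(
    p: ModelParams,
    cp_template: CouplingParams,
    d_lo: float,
    d_hi: float,
    resolution: float = 0.0005,
    n_reps: int = 10,
    seed: int = 0,
    settings: SimSettings | None = None,
    **classify_kw,
) -> BoundaryScan:
    """Classify the pair on a d grid and report regime-change midpoints.

    Each grid point is classified for ``n_reps`` random initial separations
    (majority vote).  Boundaries are grid midpoints, not root-polished values:
    regime edges can be fuzzy, and precision beyond the grid is not claimed.
    Non-monotone label sequences are reported (``monotone=False``), never
    suppressed.
    """
    d_grid = np.round(np.arange(d_lo, d_hi + resolution / 2, resolution), 10)
    settings = settings or SWEEP_SETTINGS
    rng = np.random.default_rng(seed)
    starts = rng.uniform(-20.0, 20.0, size=(len(d_grid), n_reps))

    majority, per_rep = [], []
    for j, d in enumerate(d_grid):
        cp = cp_template.with_d(float(d))
        labs = []
        for r in range(n_reps):
            traj = simulate(_pair_ic(starts[j, r]), p, cp, settings)
            labs.append(classify(traj, **classify_kw))
        per_rep.append(labs)
        values, freq = np.unique([l.value for l in labs], return_counts=True)
        majority.append(RegimeLabel(values[np.argmax(freq)]))

    boundaries = [
        (float(0.5 * (d_grid[i] + d_grid[i + 1])), majority[i], majority[i + 1])
        for i in range(len(majority) - 1)
        if majority[i] != majority[i + 1]
    ]
    seen, monotone = [], True
    for lab in majority:
        if lab in seen and seen[-1] != lab:
            monotone = False
        if not seen or seen[-1] != lab:
            seen.append(lab)
    return BoundaryScan(d_grid, majority, per_rep, boundaries, monotone)
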
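"""Observables extracted from trajectories.

This module hosts the core diagnostics: burst/glide phase segmentation
(by the analytic sign of dv/dt), limit-cycle period measurement, local-extrema
extraction of the distance difference, the Lorenz return map of successive
maxima, and the autocorrelation function of the peak sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .integrate import Trajectory

__all__ = [
    "PeakSequence",
    "Phase",
    "PhaseSegmentation",
    "LorenzMap",
    "AcfResult",
    "find_extrema",
    "segment_burst_glide",
    "segment_speed_series",
    "limit_cycle_period",
    "lorenz_map",
    "peak_acf",
]


@dataclass(frozen=True)
class PeakSequence:
    """Ordered local maxima M_n and minima N_n of a scalar series."""

    max_times: np.ndarray
    maxima: np.ndarray
    min_times: np.ndarray
    minima: np.ndarray

    def __post_init__(self):
        for t in (self.max_times, self.min_times):
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("extremum times must be strictly increasing")

    @property
    def n_maxima(self) -> int:
        return len(self.maxima)

    def alternates(self) -> bool:
        """True when maxima and minima strictly interleave in time."""
        kinds = np.concatenate([np.ones(len(self.max_times)), -np.ones(len(self.min_times))])
        order = np.argsort(np.concatenate([self.max_times, self.min_times]))
        k = kinds[order]
        return bool(np.all(k[1:] != k[:-1]))


def _parabolic_refine(y: np.ndarray, t: np.ndarray, idx: np.ndarray):
    """Sub-sample refinement of extremum positions by a 3-point parabola."""
    dt = t[1] - t[0]
    tt, vv = [], []
    for i in idx:
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            tt.append(t[i] + delta * dt)
            vv.append(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
        else:
            tt.append(t[i])
            vv.append(y[i])
    return np.array(tt), np.array(vv)


def find_extrema(series: Sequence[float], times: Sequence[float], prominence: float = 1e-3) -> PeakSequence:
    """Strict local extrema of a sampled series, with parabolic refinement.

    Extrema with prominence below ``prominence`` (default 1e-3, i.e. numerical
    ripple) are discarded, and alternation is enforced by keeping only the
    most extreme point of any same-sign run.  Returns an empty sequence for a
    constant series.
    """
    y = np.asarray(series, float)
    t = np.asarray(times, float)
    imax, _ = _scipy_find_peaks(y, prominence=prominence)
    imin, _ = _scipy_find_peaks(-y, prominence=prominence)

    # enforce alternation on the merged index sequence
    merged = sorted([(i, +1) for i in imax] + [(i, -1) for i in imin])
    kept: list[tuple[int, int]] = []
    for i, kind in merged:
        if kept and kept[-1][1] == kind:
            j, _ = kept[-1]
            better = (kind > 0 and y[i] > y[j]) or (kind < 0 and y[i] < y[j])
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    imax = np.array([i for i, kind in kept if kind > 0], int)
    imin = np.array([i for i, kind in kept if kind < 0], int)

    mt, mv = _parabolic_refine(y, t, imax)
    nt, nv = _parabolic_refine(y, t, imin)
    return PeakSequence(mt, mv, nt, nv)


@dataclass(frozen=True)
class Phase:
    kind: str  # "burst", "glide" or "constant"
    t_start: float
    t_end: float
    displacement: float
    peak_speed: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class PhaseSegmentation:
    """Alternating burst (dv/dt > 0) and glide (dv/dt < 0) intervals."""

    phases: tuple[Phase, ...]

    @property
    def is_constant(self) -> bool:
        return len(self.phases) == 1 and self.phases[0].kind == "constant"

    def of_kind(self, kind: str) -> list[Phase]:
        return [ph for ph in self.phases if ph.kind == kind]

    @property
    def total_displacement(self) -> float:
        return float(sum(ph.displacement for ph in self.phases))


def segment_burst_glide(
    traj: Trajectory,
    fish: int = 0,
    transient: float | None = None,
    accel_tol: float = 1e-3,
) -> PhaseSegmentation:
    """Split a trajectory into burst and glide phases.

    A fish bursts while it accelerates (dv/dt = g(b) - kv > 0) and glides
    while it decelerates.  The acceleration is evaluated from the model
    right-hand side, not from finite differences of the sampled speed, so the
    boundaries are free of interpolation noise; boundary instants are then
    localized by linear interpolation of dv/dt between samples.  Per-phase
    displacement is the trapezoidal integral of v (model length units).
    """
    sub = traj.post_transient(transient)
    t = sub.times
    v = sub.speed(fish)
    deriv = sub.derivatives()
    a = deriv[:, 1] if sub.kind == "single" else deriv[:, (1, 4)[fish]]

    if np.max(np.abs(a)) < accel_tol:
        disp = float(np.trapezoid(v, t))
        return PhaseSegmentation((Phase("constant", t[0], t[-1], disp, float(v.max())),))

    sgn = np.sign(a)
    # boundary between samples i, i+1 where the analytic acceleration flips
    flips = np.nonzero(sgn[1:] * sgn[:-1] < 0)[0]
    bounds = [t[0]]
    for i in flips:
        frac = a[i] / (a[i] - a[i + 1])
        bounds.append(t[i] + frac * (t[i + 1] - t[i]))
    bounds.append(t[-1])

    phases = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        m = (t >= lo) & (t <= hi)
        tm, vm = t[m], v[m]
        # extend to the exact interpolated boundaries
        tm = np.concatenate([[lo], tm, [hi]])
        vm = np.concatenate([[np.interp(lo, t, v)], vm, [np.interp(hi, t, v)]])
        mid = 0.5 * (lo + hi)
        kind = "burst" if np.interp(mid, t, a) > 0 else "glide"
        phases.append(Phase(kind, float(lo), float(hi), float(np.trapezoid(vm, tm)), float(vm.max())))
    return PhaseSegmentation(tuple(phases))


def segment_speed_series(
    times: Sequence[float],
    speeds: Sequence[float],
    smooth: float = 0.25,
    accel_tol: float = 1e-3,
) -> PhaseSegmentation:
    """Burst/glide segmentation of an external (tracked) speed series.

    For tracked data no model right-hand side is available, so the
    acceleration is estimated by finite differences of the speed after a
    moving-average smoothing of ``smooth`` seconds (suppresses tracking
    jitter).  Phase displacement is the trapezoidal integral of the raw
    speed.
    """
    t = np.asarray(times, float)
    v = np.asarray(speeds, float)
    dt = float(np.median(np.diff(t)))
    n = max(1, int(round(smooth / dt)))
    if n > 1:
        pad = n // 2
        vs = np.convolve(np.pad(v, pad, mode="edge"), np.ones(n) / n, mode="same")[pad : pad + len(v)]
    else:
        vs = v
    a = np.gradient(vs, t)

    if np.max(np.abs(a)) < accel_tol:
        return PhaseSegmentation((Phase("constant", t[0], t[-1], float(np.trapezoid(v, t)), float(v.max())),))

    sgn = np.sign(a)
    flips = np.nonzero(sgn[1:] * sgn[:-1] < 0)[0]
    bounds = [t[0]] + [t[i] + a[i] / (a[i] - a[i + 1]) * (t[i + 1] - t[i]) for i in flips] + [t[-1]]
    phases = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        m = (t >= lo) & (t <= hi)
        tm = np.concatenate([[lo], t[m], [hi]])
        vm = np.concatenate([[np.interp(lo, t, v)], v[m], [np.interp(hi, t, v)]])
        kind = "burst" if np.interp(0.5 * (lo + hi), t, a) > 0 else "glide"
        phases.append(Phase(kind, float(lo), float(hi), float(np.trapezoid(vm, tm)), float(vm.max())))
    return PhaseSegmentation(tuple(phases))


def limit_cycle_period(
    traj: Trajectory,
    channel: str = "v1",
    transient: float | None = None,
    amplitude_threshold: float = 0.05,
    min_cycles: int = 5,
):
    """Mean spacing of successive maxima of a channel, with dispersion.

    Returns (period, spread) where spread is the standard deviation of the
    individual spacings, or None when the channel's post-transient amplitude
    is below ``amplitude_threshold`` or fewer than ``min_cycles`` cycles are
    available (no limit cycle).
    """
    sub = traj.post_transient(transient)
    y = sub.channel(channel)
    if float(y.max() - y.min()) < amplitude_threshold:
        return None
    peaks = find_extrema(y, sub.times)
    if peaks.n_maxima < min_cycles:
        return None
    gaps = np.diff(peaks.max_times)
    return float(gaps.mean()), float(gaps.std())


@dataclass(frozen=True)
class LorenzMap:
    """Lag-1 return map of successive maxima, with a geometry label.

    geometry is "fixed_point" (all maxima agree within eps), "periodic"
    (the sequence repeats with some period p within eps), or "aperiodic".
    """

    pairs: np.ndarray  # shape (n-1, 2): (M_n, M_{n+1})
    geometry: str
    fixed_point: float | None = None
    period: int | None = None


def lorenz_map(peaks: PeakSequence, eps: float = 0.05) -> LorenzMap:
    """Return map M_n -> M_{n+1} of the maxima of a peak sequence.

    ``eps`` (cm) is the diagonal tolerance used to call a fixed point and the
    per-point tolerance for closed-loop (periodic) detection.
    """
    M = peaks.maxima
    if len(M) < 2:
        raise ValueError("need at least two maxima for a return map")
    pairs = np.column_stack([M[:-1], M[1:]])

    if float(M.max() - M.min()) < eps:
        return LorenzMap(pairs, "fixed_point", fixed_point=float(np.median(M)))
    # closed loop: smallest shift p under which the sequence repeats; p is
    # capped at n/3 so at least two full revolutions support the claim
    tol = max(eps, 0.03 * float(M.max() - M.min()))
    for p in range(2, len(M) // 3 + 1):
        if float(np.max(np.abs(M[p:] - M[:-p]))) < tol:
            return LorenzMap(pairs, "periodic", period=p)
    return LorenzMap(pairs, "aperiodic")


@dataclass(frozen=True)
class AcfResult:
    lags: np.ndarray
    acf: np.ndarray
    noise_band: float
    dominant_lag: int | None = None
    dominant_value: float | None = None


def peak_acf(peaks: PeakSequence | np.ndarray, max_lag: int = 40) -> AcfResult:
    """Sample autocorrelation of the de-meaned maxima sequence M_n.

    The dominant period is the lag of the first local ACF maximum exceeding
    the 95% white-noise band 1.96/sqrt(n); ``dominant_lag`` is None when no
    local maximum is significant.
    """
    from statsmodels.tsa.stattools import acf as _acf

    M = peaks.maxima if isinstance(peaks, PeakSequence) else np.asarray(peaks, float)
    if len(M) < 3:
        raise ValueError("need at least three maxima for an ACF")
    max_lag = min(max_lag, len(M) - 1)
    A = _acf(M - M.mean(), nlags=max_lag, fft=True)
    band = 1.96 / np.sqrt(len(M))

    # a dominant period must rise strictly into a local maximum; lag 1 never
    # qualifies (A[0] = 1 by definition, so the ACF cannot rise into lag 1)
    dom, domval = None, None
    for lag in range(2, max_lag):
        if A[lag] > A[lag - 1] and A[lag] >= A[lag + 1] and A[lag] > band:
            dom, domval = lag, float(A[lag])
            break
    return AcfResult(np.arange(max_lag + 1), A, float(band), dom, domval)
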
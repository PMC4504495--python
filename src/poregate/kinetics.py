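"""Wet/dry dwell-time kinetics: episode extraction, survival curves,
double-exponential decay fits, first-order rates, and state free-energy
differences.

Dwell times come from maximal constant-state runs of a frame-sampled
trajectory.  Runs cut off by the end of a trajectory are right-censored
(their true length is longer than observed); the default estimator is
Kaplan-Meier with those runs entered as censored observations, with a naive
estimator restricted to fully observed runs as the cross-check.  Survival
curves S(t) are fit to
S(t) = A exp(-t/tau1) + (1-A) exp(-t/tau2); the mean lifetime is the
integral A tau1 + (1-A) tau2 and the first-order rate is its reciprocal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import optimize

from .constants import KB_KCAL_MOL_K, NS_PER_S


@dataclass(frozen=True)
class Episode:
    state: str
    start: float                # ns
    duration: float             # ns
    left_censored: bool = False
    right_censored: bool = False

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass
class EpisodeSet:
    episodes: list
    source: str = ""
    dt: float = 0.0

    def __iter__(self):
        return iter(self.episodes)

    def __len__(self):
        return len(self.episodes)

    def for_state(self, state: str):
        return [e for e in self.episodes if e.state == state]


@dataclass
class SurvivalCurve:
    """Empirical survival S(t) of dwell times for one state.

    ``t`` is the dwell-time grid in ns; ``s`` is non-increasing with
    s(0) = 1; ``n_at_risk`` counts episodes still at risk at each grid time.
    """

    t: np.ndarray
    s: np.ndarray
    n_at_risk: np.ndarray
    state: str
    censoring: str
    n_episodes: int
    n_censored: int

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.s.size == 0 or abs(self.s[0] - 1.0) > 1e-12:
            raise ValueError("survival must start at 1")
        if np.any(np.diff(self.s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.s < -1e-12) | (self.s > 1 + 1e-12)):
            raise ValueError("survival must lie in [0, 1]")

    def at(self, times):
        """Right-continuous step interpolation of S at arbitrary times."""
        idx = np.searchsorted(self.t, np.asarray(times, dtype=float),
                              side="right") - 1
        return self.s[np.clip(idx, 0, self.s.size - 1)]


def extract_episodes(series) -> EpisodeSet:
    """Maximal wet/dry runs of a hydration series, with censoring flags.

    Requires time-ordered frames on a uniform grid.  Episode duration is
    run length x dt; the first run is left-censored and the last run
    right-censored (a single run is both).
    """
    wet = np.asarray(series.wet, dtype=bool)
    t = np.asarray(series.time, dtype=float)
    if wet.size == 0:
        raise ValueError("empty series")
    if t.size < 2:
        raise ValueError("need at least two frames to define dt")
    steps = np.diff(t)
    dt = float(steps[0])
    if not np.allclose(steps, dt):
        raise ValueError("frames must be uniformly spaced")
    change = np.flatnonzero(np.diff(wet.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [wet.size]))
    episodes = []
    n_runs = bounds.size - 1
    for k in range(n_runs):
        i0, i1 = bounds[k], bounds[k + 1]
        episodes.append(Episode(
            state="wet" if wet[i0] else "dry",
            start=t[i0],
            duration=(i1 - i0) * dt,
            left_censored=(k == 0),
            right_censored=(k == n_runs - 1)))
    return EpisodeSet(episodes=episodes,
                      source=getattr(series, "source", ""), dt=dt)


def pool_episodes(ensemble) -> EpisodeSet:
    """Concatenate the episodes of every trajectory in an ensemble."""
    pooled, dt = [], 0.0
    for series in ensemble:
        es = series if isinstance(series, EpisodeSet) else extract_episodes(series)
        pooled.extend(es.episodes)
        dt = es.dt
    return EpisodeSet(episodes=pooled, source="pooled", dt=dt)


def survival_curve(episodes: EpisodeSet, state: str,
                   censoring: str = "kaplan_meier",
                   min_duration: float = 0.0) -> SurvivalCurve:
    """Empirical survival of dwell times in one state.

    An episode's event is its termination by a state transition, so an
    episode is an observed event unless it is right-censored (cut off by the
    end of its trajectory).  First episodes start fresh at t = 0 --
    trajectories are initiated in a known state -- so the left-censoring
    flag only records window bookkeeping and does not suppress the event
    (under exponential dwell times this convention is unbiased either way,
    by memorylessness).  ``naive`` uses episodes with observed ends only:
    S(t) = fraction with duration >= t.  ``kaplan_meier`` is the
    product-limit estimator with right-censored episodes entered as
    censored observations.  Episodes shorter than ``min_duration``
    (frame-level flicker) are dropped first.
    """
    eps = [e for e in episodes.for_state(state) if e.duration >= min_duration]
    if not eps:
        raise ValueError(f"no episodes of state {state!r}")
    durations = np.array([e.duration for e in eps])
    observed = np.array([not e.right_censored for e in eps])
    n_cens = int(np.count_nonzero(~observed))
    if censoring == "naive":
        d = durations[observed]
        if d.size == 0:
            raise ValueError("naive estimator requires uncensored episodes")
        uniq = np.unique(d)
        # S(t) = fraction with duration >= t (inclusive at each event); a
        # paired point just past each event records the post-event fraction
        # so the right-continuous step representation is exact everywhere
        after = uniq * (1 + 1e-12) + 1e-15
        t = np.unique(np.concatenate(([0.0], uniq, after)))
        s = np.array([np.mean(d >= ti) for ti in t])
        at_risk = np.array([np.count_nonzero(d >= ti) for ti in t])
        return SurvivalCurve(t, s, at_risk, state, "naive", len(eps), n_cens)
    if censoring == "kaplan_meier":
        km = KaplanMeierFitter()
        km.fit(durations, event_observed=observed)
        t = km.survival_function_.index.to_numpy(dtype=float)
        s = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = np.array([np.count_nonzero(durations >= ti) for ti in t])
        return SurvivalCurve(t, s, at_risk, state, "kaplan_meier",
                             len(eps), n_cens)
    raise ValueError(f"unknown censoring mode {censoring!r}")


@dataclass
class BiexpFit:
    """S(t) = A exp(-t/tau1) + (1-A) exp(-t/tau2), tau1 <= tau2.

    ``integral`` (= mean lifetime tau) is A tau1 + (1-A) tau2 in ns;
    ``rate`` is 1/tau converted to 1/s; ``half_life`` solves S(t) = 1/2.
    ``single_exponential`` flags fits that collapsed to one time constant.
    """

    amplitude: float
    tau1: float
    tau2: float
    integral: float
    mean_lifetime: float
    half_life: float
    rate: float
    single_exponential: bool = False
    sse: float = float("nan")

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        return (self.amplitude * np.exp(-t / self.tau1)
                + (1.0 - self.amplitude) * np.exp(-t / self.tau2))


def _half_life(a, t1, t2):
    f = lambda t: a * np.exp(-t / t1) + (1 - a) * np.exp(-t / t2) - 0.5
    hi = 10.0 * max(t1, t2)
    return float(optimize.brentq(f, 0.0, hi))


def _make_fit(a, t1, t2, sse, single):
    if t1 > t2:
        a, t1, t2 = 1.0 - a, t2, t1
    integral = a * t1 + (1.0 - a) * t2
    return BiexpFit(amplitude=float(a), tau1=float(t1), tau2=float(t2),
                    integral=float(integral), mean_lifetime=float(integral),
                    half_life=_half_life(a, t1, t2),
                    rate=float(NS_PER_S / integral),
                    single_exponential=single, sse=float(sse))


def fit_biexponential(curve: SurvivalCurve, n_grid: int = 200,
                      improvement_factor: float = 0.2) -> BiexpFit:
    """Least-squares double-exponential fit of a survival curve.

    The curve is evaluated on a log-spaced dwell-time grid spanning the
    observed decay; a single-exponential fit provides starting values, and
    the biexponential solution is kept only when it reduces the sum of
    squares below ``improvement_factor`` times the single-exponential one
    (otherwise the fit is flagged ``single_exponential`` with
    tau1 = tau2).  Needs at least four distinct time points.
    """
    t_pos = curve.t[curve.t > 0]
    if np.unique(curve.t).size < 4:
        raise ValueError("need at least four distinct time points")
    t_lo = t_pos.min()
    drops = np.flatnonzero(np.diff(curve.s) < 0)
    # fit up to the last observed event; beyond it the empirical curve is flat
    t_hi = float(curve.t[drops.max() + 1]) if drops.size else float(curve.t[-1])
    grid = np.geomspace(t_lo, t_hi, n_grid)
    # linear interpolation between curve points; pure step lookup biases
    # the fitted lifetime upward by ~half a step
    y = np.interp(grid, curve.t, curve.s)

    # single-exponential start from the log-linear slope where S > 0
    pos = y > 0
    slope = np.polyfit(grid[pos], np.log(y[pos]), 1)[0]
    tau0 = -1.0 / slope if slope < 0 else 10.0 * t_hi
    tau0 = float(np.clip(tau0, t_lo / 10.0, 100.0 * t_hi))

    def single_resid(log_tau):
        return np.exp(-grid / np.exp(log_tau)) - y

    res1 = optimize.least_squares(single_resid, x0=[np.log(tau0)])
    tau_s = float(np.exp(res1.x[0]))
    sse1 = float(2.0 * res1.cost)

    def biexp_resid(p):
        a = 1.0 / (1.0 + np.exp(-p[0]))        # logistic keeps A in (0, 1)
        t1, t2 = np.exp(p[1]), np.exp(p[2])
        return a * np.exp(-grid / t1) + (1 - a) * np.exp(-grid / t2) - y

    best = None
    lb, ub = np.log(t_lo / 100.0), np.log(1e3 * t_hi)
    for t1f, t2f in ((0.3, 3.0), (0.1, 1.0), (1.0, 10.0)):
        x0 = [0.0,
              float(np.clip(np.log(tau_s * t1f), lb + 1e-9, ub - 1e-9)),
              float(np.clip(np.log(tau_s * t2f), lb + 1e-9, ub - 1e-9))]
        try:
            res2 = optimize.least_squares(
                biexp_resid, x0=x0, bounds=([-12, lb, lb], [12, ub, ub]))
        except Exception:
            continue
        if best is None or res2.cost < best.cost:
            best = res2
    if best is not None and 2.0 * best.cost < improvement_factor * sse1:
        a = 1.0 / (1.0 + np.exp(-best.x[0]))
        return _make_fit(a, np.exp(best.x[1]), np.exp(best.x[2]),
                         2.0 * best.cost, single=False)
    if best is None:
        warnings.warn("biexponential fit failed to converge; "
                      "falling back to single exponential", RuntimeWarning)
    return _make_fit(1.0, tau_s, tau_s, sse1, single=True)


@dataclass
class RateEstimate:
    """A first-order rate with its split-half uncertainty (both 1/s)."""

    rate: float
    uncertainty: float
    state: str
    n_episodes: int
    fit: BiexpFit
    half_rates: tuple = ()


def _rate_from_series(series_list, state, censoring, min_duration):
    pooled = pool_episodes(series_list)
    curve = survival_curve(pooled, state, censoring, min_duration)
    fit = fit_biexponential(curve)
    return fit, len(pooled.for_state(state))


def ensemble_rates(ensemble, state: str, censoring: str = "kaplan_meier",
                   min_duration: float = 0.0) -> RateEstimate:
    """Pooled escape rate from one state, with split-half uncertainty.

    ``state="dry"`` yields the wetting rate (reciprocal mean dry lifetime);
    ``state="wet"`` the dewetting rate.  The uncertainty is the standard
    deviation of the two estimates obtained from the first and second half
    of the ensemble (by index).
    """
    series_list = list(ensemble)
    fit, n_eps = _rate_from_series(series_list, state, censoring, min_duration)
    try:
        sh = split_half_uncertainty(
            series_list,
            lambda half: _rate_from_series(half, state, censoring,
                                           min_duration)[0].rate)
    except ValueError as exc:
        # a half-ensemble too sparse to fit leaves the rate usable but the
        # uncertainty undefined
        warnings.warn(f"split-half uncertainty unavailable: {exc}",
                      RuntimeWarning)
        return RateEstimate(rate=fit.rate, uncertainty=float("nan"),
                            state=state, n_episodes=n_eps, fit=fit)
    return RateEstimate(rate=fit.rate, uncertainty=sh.sd, state=state,
                        n_episodes=n_eps, fit=fit,
                        half_rates=(sh.first, sh.second))


def state_free_energy(integral_a: float, integral_b: float,
                      temperature: float) -> float:
    """Free-energy difference from the ratio of survival-curve integrals.

    delta G = -k_B T ln(integral_a / integral_b) in kcal/mol, with
    k_B = 0.0019872 kcal/mol/K.  Exactly antisymmetric in its arguments.
    """
    if integral_a <= 0 or integral_b <= 0:
        raise ValueError("integrals must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    # log difference rather than log ratio: antisymmetry is then exact
    return float(KB_KCAL_MOL_K * temperature
                 * (np.log(integral_b) - np.log(integral_a)))


@dataclass
class SplitHalf:
    sd: float
    first: float
    second: float
    sizes: tuple


def split_half_uncertainty(ensemble, estimator) -> SplitHalf:
    """Standard deviation of an estimator over the two index halves.

    The ensemble is split first/second by index (odd sizes give the larger
    first half, recorded in ``sizes``); the estimator is applied to each
    half and the sd (ddof=1) of the two values returned.
    """
    items = list(ensemble)
    if len(items) < 2:
        raise ValueError("need at least two ensemble members to split")
    mid = (len(items) + 1) // 2
    a = float(estimator(items[:mid]))
    b = float(estimator(items[mid:]))
    return SplitHalf(sd=float(np.std([a, b], ddof=1)), first=a, second=b,
                     sizes=(mid, len(items) - mid))
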
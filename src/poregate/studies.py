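"""Canonical recovery studies: the generator's study conditions wired to the
estimators they exercise.

These functions define, in one place, the synthetic experiments the package
uses to demonstrate parameter recovery: the massively repeated wetting
ensemble (700 x 35 ns, wetting rate 8.2e6 1/s, ~1% wet occupancy) analyzed
for dwell-time rates, and the umbrella-sampling design (261 windows every
0.05 nm over -8..5 nm) analyzed by WHAM for Gaussian gate barriers of
5/25/45 kcal/mol plus a flat-profile null.  Umbrella spring constants are
matched to profile stiffness: stiff enough that every window samples the
barrier top (k > |G''|max = H / width^2), soft enough that neighboring
windows overlap well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import kinetics, pmf, synthetic
from .constants import DEFAULT_TEMPERATURE_K

#: Ensemble design of the wetting-kinetics study.
KINETICS_STUDY = {"n_traj": 700, "duration": 35.0, "dt": 0.02,
                  "wetting_rate": 8.2e6, "wet_occupancy": 0.01}

#: Umbrella design shared by all barrier studies.
UMBRELLA_RANGE = (-8.0, 5.0)
UMBRELLA_SPACING = 0.05

#: Per-profile sampling settings: spring constant (kcal/mol/nm^2),
#: samples per window, WHAM bin width (nm).  Height 0 is the flat null.
BARRIER_STUDIES = {
    0.0: {"spring_k": 30.0, "n_samples": 30_000, "bin_width": 0.02},
    5.0: {"spring_k": 150.0, "n_samples": 20_000, "bin_width": 0.01},
    25.0: {"spring_k": 500.0, "n_samples": 20_000, "bin_width": 0.01},
    45.0: {"spring_k": 1000.0, "n_samples": 10_000, "bin_width": 0.005},
}

#: Two-sided 95% Student-t quantile at 1 degree of freedom, the correct
#: multiplier for an uncertainty estimated from a two-way split.
T_95_DF1 = 12.706


@dataclass
class KineticsRepeat:
    wetting_rate: float
    wetting_sd: float
    wetting_halves: tuple
    dewetting_rate: float
    dewetting_sd: float
    dewetting_halves: tuple


def kinetics_recovery_repeat(seed: int,
                             censoring: str = "kaplan_meier") -> KineticsRepeat:
    """One seeded realization of the wetting-kinetics recovery study."""
    model = synthetic.default_wetting_model(
        wetting_rate=KINETICS_STUDY["wetting_rate"],
        wet_occupancy=KINETICS_STUDY["wet_occupancy"])
    ens = synthetic.simulate_wetting_ensemble(
        model, KINETICS_STUDY["n_traj"], KINETICS_STUDY["duration"],
        KINETICS_STUDY["dt"], seed=seed)
    wet = kinetics.ensemble_rates(ens, "dry", censoring)
    dew = kinetics.ensemble_rates(ens, "wet", censoring)
    return KineticsRepeat(wet.rate, wet.uncertainty, wet.half_rates,
                          dew.rate, dew.uncertainty, dew.half_rates)


def true_kinetics_rates() -> dict:
    occ = KINETICS_STUDY["wet_occupancy"]
    k_wet = KINETICS_STUDY["wetting_rate"]
    return {"wetting": k_wet, "dewetting": k_wet * (1 - occ) / occ}


def covers_truth(estimate: float, split_half_sd: float, truth: float) -> bool:
    """95% confidence interval from a two-point split-half uncertainty.

    The sd of two half-estimates has one degree of freedom, so the interval
    is estimate +- t_{0.975,1} * sd / sqrt(2).
    """
    half_width = T_95_DF1 * split_half_sd / np.sqrt(2.0)
    return bool(abs(estimate - truth) <= half_width)


def kinetics_recovery_study(n_repeats: int = 50, seed: int = 0) -> dict:
    """Repeat the kinetics study; report mean recovered rates and coverage.

    Repeat seeds are spawned from ``seed``.  Coverage is the fraction of
    repeats whose split-half 95% interval contains the generator truth.
    """
    truths = true_kinetics_rates()
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    reps = [kinetics_recovery_repeat(int(s)) for s in seeds]
    wet_rates = np.array([r.wetting_rate for r in reps])
    dew_rates = np.array([r.dewetting_rate for r in reps])
    return {
        "n_repeats": n_repeats,
        "true_wetting_rate": truths["wetting"],
        "true_dewetting_rate": truths["dewetting"],
        "mean_wetting_rate": float(wet_rates.mean()),
        "mean_dewetting_rate": float(dew_rates.mean()),
        "wetting_rate_sd": float(wet_rates.std(ddof=1)),
        "dewetting_rate_sd": float(dew_rates.std(ddof=1)),
        "wetting_coverage": float(np.mean([
            covers_truth(r.wetting_rate, r.wetting_sd, truths["wetting"])
            for r in reps])),
        "dewetting_coverage": float(np.mean([
            covers_truth(r.dewetting_rate, r.dewetting_sd,
                         truths["dewetting"]) for r in reps])),
    }


#: Wetted-fraction bands (% of trajectory, lo/hi) and trajectory counts that
#: reproduce the published per-condition count table: 700 simulations per
#: regulatory-ion condition, counted at thresholds >0 / >=0.05 / >=1 / >=5 /
#: >=10 / >=20 % of frames wet.
COUNT_TABLE_BANDS = {
    "no_ions": [((0.01, 0.04), 75), ((0.05, 0.9), 22), ((1.0, 4.9), 50),
                ((5.0, 9.9), 15), ((10.0, 19.9), 3), ((20.0, 40.0), 10)],
    "with_ions": [((0.01, 0.04), 52), ((0.05, 0.9), 6), ((1.0, 4.9), 19),
                  ((5.0, 9.9), 2), ((10.0, 19.9), 3), ((20.0, 40.0), 1)],
}


def published_count_table_conditions(n_traj: int = 700,
                                     n_frames: int = 10_000) -> dict:
    """Synthetic two-condition ensembles matching the published count table.

    Each condition gets ``n_traj`` hydration series whose wet fractions sit
    inside the stated percentage bands (remaining trajectories fully dry),
    so the threshold table reproduces the printed counts and ratios exactly.
    """
    out = {}
    for label, bands in COUNT_TABLE_BANDS.items():
        series = []
        for (lo, hi), count in bands:
            wet_frames = max(1, int(round(0.5 * (lo + hi) / 100.0 * n_frames)))
            for _ in range(count):
                wet = np.zeros(n_frames, dtype=bool)
                wet[:wet_frames] = True
                series.append(_flat_series(wet))
        while len(series) < n_traj:
            series.append(_flat_series(np.zeros(n_frames, dtype=bool)))
        out[label] = series
    return out


def _flat_series(wet):
    from .hydration import HydrationSeries

    n = wet.size
    return HydrationSeries(
        time=0.0035 * np.arange(n), n_wat=np.where(wet, 15, 2),
        z_gap=np.where(wet, 0.30, 1.0), z_gap_center=np.zeros(n), wet=wet)


def barrier_recovery_study(height: float, seed: int = 0,
                           temperature: float = DEFAULT_TEMPERATURE_K) -> dict:
    """Sample the umbrella design for one profile and recover it by WHAM.

    ``height`` selects a Gaussian gate barrier (kcal/mol); 0 is the flat
    null.  Returns the recovered barrier (or, for the null, the maximum
    absolute deviation of the profile from flatness over the windowed span).
    """
    if height not in BARRIER_STUDIES:
        raise ValueError(f"no study settings for height {height}")
    cfg = BARRIER_STUDIES[height]
    spec = synthetic.gaussian_barrier_pmf(height, temperature=temperature)
    centers = pmf.make_windows(*UMBRELLA_RANGE, UMBRELLA_SPACING)
    windows = synthetic.sample_umbrella_windows(
        spec, centers, spring_k=cfg["spring_k"],
        n_samples=cfg["n_samples"], seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = pmf.wham(windows, temperature=temperature,
                           bin_width=cfg["bin_width"])
    out = {"height": height, "n_windows": len(windows),
           "n_samples_per_window": cfg["n_samples"],
           "converged": profile.converged}
    span = (profile.z >= UMBRELLA_RANGE[0]) & (profile.z <= UMBRELLA_RANGE[1])
    if height == 0.0:
        out["max_abs_deviation"] = float(np.nanmax(np.abs(profile.g[span])))
    else:
        out["barrier"] = float(profile.barrier)
        out["relative_error"] = float(abs(profile.barrier - height) / height)
    return out
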
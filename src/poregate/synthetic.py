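"""Synthetic ensembles with the statistical structure the analysis assumes.

This module is the study-condition generator: wet/dry (optionally
stably-superhydrated, SSH) pore dynamics as a continuous-time Markov chain
sampled at frame times, state-conditional water counts (dry: peaked-discrete
around 2; transiently wet: normal, mean 15, sigma 3; SSH: right-skewed around
22), a pore diameter linearly coupled to hydration
(d = 0.37 + 0.0067 * N_wat nm, with Gaussian noise), axial water placements
with controlled column connectivity, Boltzmann-exact umbrella-window samples
for a prescribed 1-D free-energy profile, and ring-atom pore fixtures of
known diameter.

Everything is reproducible bit-for-bit under a fixed seed.  Time is ns
internally; rates are given in 1/s; energies in kcal/mol; lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import (DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K,
                        WET_THRESHOLD_NM)
from .hydration import GATE_REGION
from .pmf import UmbrellaWindow

#: Observed wetting rate of the gate without regulatory ions (1/s).
DEFAULT_WETTING_RATE = 8.2e6
#: Observed wetting rate with regulatory ions bound (1/s).
REGULATED_WETTING_RATE = 4.1e6


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_nwat(spec: dict, size: int, rng) -> np.ndarray:
    """Draw water counts from a state-conditional distribution spec.

    Families: ``poisson`` (mean), ``normal`` (mean, sd), ``skewnorm``
    (mean, sd, alpha).  Continuous draws are rounded; all counts are
    truncated at zero.
    """
    family = spec["family"]
    if family == "poisson":
        x = rng.poisson(spec["mean"], size=size)
    elif family == "normal":
        x = np.rint(rng.normal(spec["mean"], spec["sd"], size=size))
    elif family == "skewnorm":
        a = spec.get("alpha", 4.0)
        # convert target mean/sd to skewnorm loc/scale
        delta = a / np.sqrt(1.0 + a * a)
        mu_z = delta * np.sqrt(2.0 / np.pi)
        sd_z = np.sqrt(1.0 - mu_z**2)
        scale = spec["sd"] / sd_z
        loc = spec["mean"] - scale * mu_z
        x = np.rint(stats.skewnorm.rvs(a, loc=loc, scale=scale, size=size,
                                       random_state=rng))
    else:
        raise ValueError(f"unknown N_wat distribution family {family!r}")
    return np.maximum(x, 0).astype(int)


@dataclass
class WettingModel:
    """Two- or three-state Markov model of gate hydration.

    ``rate_matrix`` holds transition rates in 1/s; off-diagonal entries are
    the state-to-state rates and the diagonal is set to minus the row sum at
    construction.  ``nwat_dists`` maps each state label to a distribution
    spec for the water count.  ``coupling_*`` define the linear
    diameter-hydration relation d = intercept + slope * N_wat + noise.
    """

    states: tuple = ("dry", "wet")
    rate_matrix: np.ndarray = None
    nwat_dists: dict = None
    coupling_intercept: float = 0.37
    coupling_slope: float = 0.0067
    coupling_noise: float = 0.01
    region: tuple = (GATE_REGION.z_lo, GATE_REGION.z_hi)

    def __post_init__(self):
        n = len(self.states)
        q = np.array(self.rate_matrix, dtype=float)
        if q.shape != (n, n):
            raise ValueError("rate_matrix shape must match number of states")
        off = q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("transition rates must be non-negative")
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        self.rate_matrix = q
        if self.nwat_dists is None or set(self.nwat_dists) != set(self.states):
            raise ValueError("nwat_dists must cover every state")
        if not self.region[1] - self.region[0] > 0:
            raise ValueError("gate region must have positive length")

    @property
    def region_length(self) -> float:
        return self.region[1] - self.region[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of the generator, normalized to a probability."""
        w, v = np.linalg.eig(self.rate_matrix.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def default_wetting_model(wetting_rate: float = DEFAULT_WETTING_RATE,
                          wet_occupancy: float = 0.01,
                          three_state: bool = False,
                          ssh_rate: float = 2.0e5) -> WettingModel:
    """The default study conditions.

    Two states dry <-> wet with the stated wetting rate (1/s) and the
    dewetting rate fixed by the target stationary wet occupancy
    (k_dewet = k_wet * (1 - occ) / occ).  The optional third state (SSH)
    is reachable from wet only, entered/left at ``ssh_rate``.
    """
    if not 0 < wet_occupancy < 1:
        raise ValueError("wet_occupancy must be in (0, 1)")
    k_dewet = wetting_rate * (1.0 - wet_occupancy) / wet_occupancy
    dists = {
        "dry": {"family": "poisson", "mean": 2.0},
        "wet": {"family": "normal", "mean": 15.0, "sd": 3.0},
        "ssh": {"family": "skewnorm", "mean": 22.0, "sd": 4.0, "alpha": 4.0},
    }
    if three_state:
        q = np.array([[0.0, wetting_rate, 0.0],
                      [k_dewet, 0.0, ssh_rate],
                      [0.0, ssh_rate, 0.0]])
        return WettingModel(states=("dry", "wet", "ssh"), rate_matrix=q,
                            nwat_dists=dists)
    q = np.array([[0.0, wetting_rate], [k_dewet, 0.0]])
    return WettingModel(states=("dry", "wet"), rate_matrix=q,
                        nwat_dists={k: dists[k] for k in ("dry", "wet")})


@dataclass
class TrajectoryTrace:
    """Per-frame record of one synthetic trajectory."""

    time: np.ndarray            # ns
    state: np.ndarray           # labels
    n_wat: np.ndarray
    z_gap: np.ndarray           # nm; NaN when positions were not generated
    d_mean: np.ndarray          # nm
    wet: np.ndarray
    water_z: list | None = None  # per-frame sorted axial positions, or None
    source: str = ""


@dataclass
class WettingEnsemble:
    model: WettingModel
    trajectories: list
    seed: int | None
    dt: float
    duration: float

    def __len__(self):
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


def _simulate_ctmc(model: WettingModel, n_traj: int, duration: float,
                   rng, start_states):
    """Exact (event-driven) CTMC realizations; returns per-trajectory event
    lists [(time_ns, new_state), ...]."""
    q_ns = model.rate_matrix * 1.0e-9  # 1/s -> 1/ns
    n_states = len(model.states)
    exit_rates = -np.diag(q_ns)
    jump_probs = np.zeros((n_states, n_states))
    for s in range(n_states):
        if exit_rates[s] > 0:
            jump_probs[s] = q_ns[s] / exit_rates[s]
            jump_probs[s, s] = 0.0
    events = [[] for _ in range(n_traj)]
    t = np.zeros(n_traj)
    state = np.array(start_states, dtype=int).copy()
    active = np.ones(n_traj, dtype=bool)
    while np.any(active):
        idx = np.flatnonzero(active)
        rates = exit_rates[state[idx]]
        waits = np.full(idx.size, np.inf)
        pos = rates > 0
        waits[pos] = rng.exponential(1.0 / rates[pos])
        t[idx] += waits
        done = t[idx] >= duration
        active[idx[done]] = False
        live = idx[~done]
        if live.size:
            u = rng.random(live.size)
            cum = np.cumsum(jump_probs[state[live]], axis=1)
            nxt = (u[:, None] < cum).argmax(axis=1)
            for j, traj in enumerate(live):
                events[traj].append((t[traj], int(nxt[j])))
            state[live] = nxt
    return events


def simulate_wetting_ensemble(model: WettingModel, n_traj: int,
                              duration: float, dt: float, seed=None,
                              start_state: str = "dry",
                              include_positions: bool = False,
                              wet_threshold: float = WET_THRESHOLD_NM
                              ) -> WettingEnsemble:
    """Simulate an ensemble of frame-sampled wetting trajectories.

    The hidden state follows the continuous-time Markov chain exactly
    (event-driven sampling); frames record the state occupied at each frame
    time (point sampling at 0, dt, 2dt, ...).  Water counts are drawn per
    frame from the state-conditional distribution, and the mean gate
    diameter is intercept + slope * N_wat + Gaussian noise.

    With ``include_positions`` the per-frame axial water positions are
    generated by :func:`place_waters` and z_gap / the wet flag are computed
    from them; otherwise z_gap is NaN and the wet flag reflects the hidden
    state (wet-state placements are connected by construction).

    ``start_state`` is a state label or ``"stationary"`` to draw each
    trajectory's initial state from the chain's stationary distribution.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    rng = _as_rng(seed)
    if start_state == "stationary":
        starts = rng.choice(len(model.states), size=n_traj,
                            p=model.stationary_distribution())
    else:
        starts = np.full(n_traj, list(model.states).index(start_state))
    n_frames = int(round(duration / dt))
    times = dt * np.arange(n_frames)
    events = _simulate_ctmc(model, n_traj, duration, rng, starts)

    dry_idx = list(model.states).index("dry") if "dry" in model.states else -1
    labels = np.array(model.states)
    trajectories = []
    for k in range(n_traj):
        ev = events[k]
        state_idx = np.full(n_frames, starts[k])
        if ev:
            ev_t = np.array([e[0] for e in ev])
            ev_s = np.array([e[1] for e in ev])
            pos = np.searchsorted(ev_t, times, side="right")
            state_idx = np.where(pos > 0, ev_s[np.minimum(pos, len(ev)) - 1],
                                 starts[k])
        n_wat = np.zeros(n_frames, dtype=int)
        for s, label in enumerate(model.states):
            mask = state_idx == s
            if np.any(mask):
                n_wat[mask] = _sample_nwat(model.nwat_dists[label],
                                           int(mask.sum()), rng)
        d_mean = (model.coupling_intercept + model.coupling_slope * n_wat
                  + rng.normal(0.0, model.coupling_noise, n_frames))
        if include_positions:
            water_z, z_gap, wet = [], np.empty(n_frames), np.empty(n_frames,
                                                                   dtype=bool)
            for i in range(n_frames):
                st = "dry" if state_idx[i] == dry_idx else "wet"
                zpos = place_waters(n_wat[i], model.region, st, rng,
                                    threshold=wet_threshold)
                water_z.append(zpos)
                anchored = np.concatenate(([model.region[0]], zpos,
                                           [model.region[1]]))
                z_gap[i] = np.max(np.diff(anchored))
                wet[i] = z_gap[i] <= wet_threshold
        else:
            water_z = None
            z_gap = np.full(n_frames, np.nan)
            wet = state_idx != dry_idx
        trajectories.append(TrajectoryTrace(
            time=times, state=labels[state_idx], n_wat=n_wat, z_gap=z_gap,
            d_mean=d_mean, wet=wet, water_z=water_z, source=f"traj{k:05d}"))
    return WettingEnsemble(model=model, trajectories=trajectories,
                          seed=seed if isinstance(seed, (int, np.integer))
                          else None, dt=dt, duration=duration)


def place_waters(n: int, region, state: str, seed=None,
                 threshold: float = WET_THRESHOLD_NM) -> np.ndarray:
    """Axial water positions with controlled column connectivity.

    Placement is uniform with connectivity repair.  For ``state="wet"`` and
    enough waters to span the region (n >= ceil(length/threshold) - 1 gaps
    constraint), positions are repaired until the largest anchored gap is at
    most ``threshold``; if n is too small to connect, a best-effort placement
    is returned (the caller sees a gap above threshold).  For ``state="dry"``
    a dehydrated stretch wider than ``threshold`` is carved out whenever
    geometrically possible.

    Returns sorted positions (nm); n = 0 gives an empty array.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    z_lo, z_hi = float(region[0]), float(region[1])
    length = z_hi - z_lo
    rng = _as_rng(seed)
    if n == 0:
        return np.array([])
    z = np.sort(rng.uniform(z_lo, z_hi, n))
    if state == "wet":
        # minimum waters for n+1 anchored gaps all <= threshold
        if (n + 1) * threshold < length:
            return z  # cannot connect: best effort
        for _ in range(10 * n):
            anchored = np.concatenate(([z_lo], z, [z_hi]))
            gaps = np.diff(anchored)
            i = int(np.argmax(gaps))
            if gaps[i] <= threshold:
                return z
            # relocate the most redundant water into the widest gap
            j = int(np.argmin(gaps[:-1] + gaps[1:]))  # water index j
            z = np.delete(z, j)
            anchored = np.concatenate(([z_lo], z, [z_hi]))
            gaps = np.diff(anchored)
            i = int(np.argmax(gaps))
            z = np.sort(np.append(z, anchored[i] + 0.5 * gaps[i]))
        # deterministic fallback: evenly spread interior points
        return z_lo + length * (np.arange(1, n + 1) / (n + 1.0))
    elif state == "dry":
        width = min(1.3 * threshold + 0.12, length - 1e-9)
        if width <= threshold:
            return z  # region too short to dewet beyond threshold
        lo = z_lo + 0.5 * width
        hi = z_hi - 0.5 * width
        c = rng.uniform(lo, hi) if hi > lo else 0.5 * (z_lo + z_hi)
        # resample waters falling inside the dry window into the wet margins
        inside = (z > c - 0.5 * width) & (z < c + 0.5 * width)
        n_in = int(inside.sum())
        if n_in:
            left = (c - 0.5 * width) - z_lo
            right = z_hi - (c + 0.5 * width)
            u = rng.uniform(0.0, left + right, n_in)
            moved = np.where(u < left, z_lo + u, c + 0.5 * width + (u - left))
            z = np.sort(np.concatenate((z[~inside], moved)))
        return z
    raise ValueError(f"unknown state {state!r}")


def sample_umbrella_windows(pmf_spec, centers, spring_k: float,
                            n_samples: int, seed=None,
                            sample_dt: float = 1.0e-3,
                            grid_refine: float = 0.002):
    """Boltzmann-exact biased samples for each restraint center.

    Samples are drawn from p_i(z) proportional to
    exp(-beta (G(z) + k (z - z_i)^2 / 2)) by inverse-CDF interpolation on a
    refined grid (spacing ``grid_refine`` nm), so they are exact up to grid
    resolution.  Returns a list of :class:`~poregate.pmf.UmbrellaWindow`.
    """
    if spring_k <= 0:
        raise ValueError("spring_k must be positive")
    if pmf_spec.temperature <= 0:
        raise ValueError("temperature must be positive")
    z0, z1 = pmf_spec.z_grid[0], pmf_spec.z_grid[-1]
    tol = 1e-9 * max(1.0, abs(z1 - z0))
    for c in centers:
        if not z0 - tol <= c <= z1 + tol:
            raise ValueError(f"center {c} outside the PMF grid span")
    rng = _as_rng(seed)
    beta = 1.0 / (KB_KCAL_MOL_K * pmf_spec.temperature)
    fine = np.arange(z0, z1 + 0.5 * grid_refine, grid_refine)
    g_fine = np.interp(fine, pmf_spec.z_grid, pmf_spec.g_values)
    windows = []
    for c in centers:
        u_tot = g_fine + 0.5 * spring_k * (fine - c) ** 2
        logw = -beta * (u_tot - u_tot.min())
        w = np.exp(logw)
        cdf = np.concatenate(([0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                               * np.diff(fine))))
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_samples), cdf, fine)
        windows.append(UmbrellaWindow(center=float(c), spring_k=spring_k,
                                      samples=samples, sample_dt=sample_dt))
    return windows


@dataclass(frozen=True)
class PmfSpec:
    """A prescribed 1-D free-energy profile used as sampler ground truth."""

    z_grid: np.ndarray
    g_values: np.ndarray
    barrier_region: tuple = (-1.0, 1.0)
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        z = np.asarray(self.z_grid, dtype=float)
        g = np.asarray(self.g_values, dtype=float)
        if z.ndim != 1 or z.shape != g.shape:
            raise ValueError("z_grid and g_values must be matching 1-D arrays")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z_grid must be strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("g_values must be finite")
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "g_values", g)

    def g(self, z):
        return np.interp(z, self.z_grid, self.g_values)


def gaussian_barrier_pmf(height: float, center: float = 0.0,
                         width: float = 0.35, z_range=(-8.0, 5.0),
                         spacing: float = 0.01,
                         temperature: float = DEFAULT_TEMPERATURE_K) -> PmfSpec:
    """A flat profile with a Gaussian gate barrier of the given height
    (kcal/mol) and standard-deviation width (nm)."""
    z = np.arange(z_range[0], z_range[1] + 0.5 * spacing, spacing)
    g = height * np.exp(-0.5 * ((z - center) / width) ** 2)
    return PmfSpec(z_grid=z, g_values=g, temperature=temperature)


@dataclass
class PoreFixture:
    """Ring-atom pore wall of analytically known diameter."""

    coords: np.ndarray          # (N, 3) nm
    radii: np.ndarray           # per-atom vdW radii, nm
    z_grid: np.ndarray
    true_diameter: np.ndarray   # 2 * (radius_profile - vdw), per grid z


def build_pore_fixture(radius_profile, ring_atoms: int, vdw_radius: float,
                       z_grid, seed=None) -> PoreFixture:
    """Place rings of atoms whose centers lie at ``radius_profile(z)``.

    The true pore diameter at z is ``2 * (radius_profile(z) - vdw_radius)``,
    which must be positive everywhere.  Ring phases are randomized so the
    fixture does not align with any lab axis.
    """
    if ring_atoms < 1:
        raise ValueError("need at least one atom per ring")
    z_grid = np.asarray(z_grid, dtype=float)
    radii_at_z = np.array([float(radius_profile(z)) for z in z_grid])
    if np.any(radii_at_z - vdw_radius <= 0):
        raise ValueError("radius_profile must exceed vdw_radius everywhere")
    rng = _as_rng(seed)
    coords = []
    for z, r in zip(z_grid, radii_at_z):
        phase = rng.uniform(0, 2 * np.pi)
        ang = phase + 2 * np.pi * np.arange(ring_atoms) / ring_atoms
        ring = np.column_stack((r * np.cos(ang), r * np.sin(ang),
                                np.full(ring_atoms, z)))
        coords.append(ring)
    coords = np.vstack(coords)
    return PoreFixture(coords=coords,
                       radii=np.full(len(coords), float(vdw_radius)),
                       z_grid=z_grid,
                       true_diameter=2.0 * (radii_at_z - vdw_radius))
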
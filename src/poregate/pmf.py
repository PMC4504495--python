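"""Umbrella-sampling free-energy profiles via the weighted histogram analysis
method (WHAM).

A set of harmonic-restraint windows along the pore axis z is combined by
standard discrete-histogram WHAM: iterate the window free energies f_i and
the unbiased bin probabilities p_b to self-consistency,

    p_b = sum_i H_ib / sum_i N_i exp(beta (f_i - U_i(z_b))),
    exp(-beta f_i) = sum_b p_b exp(-beta U_i(z_b)),

with U_i(z) = k_i (z - z_i0)^2 / 2.  The profile G(z) = -kT ln p(z) is zeroed
on a bulk reference interval, and the gate barrier is the maximum of G inside
the gate interval relative to the bulk mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL_MOL_K


@dataclass
class UmbrellaWindow:
    """One harmonic-restraint window.

    ``center`` (nm), ``spring_k`` (kcal/mol/nm^2), ``samples`` of the
    restrained coordinate (nm), with ``sample_dt`` ns between samples and an
    optional initial ``equilibration_discard`` (ns) removed before analysis.
    """

    center: float
    spring_k: float
    samples: np.ndarray
    sample_dt: float = 1.0e-3
    equilibration_discard: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.spring_k <= 0:
            raise ValueError("spring_k must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.production_samples().size == 0:
            raise ValueError("no samples left after equilibration discard")

    def production_samples(self) -> np.ndarray:
        skip = int(round(self.equilibration_discard / self.sample_dt))
        return self.samples[skip:]

    def bias(self, z):
        return 0.5 * self.spring_k * (np.asarray(z, dtype=float) - self.center) ** 2


@dataclass
class FreeEnergyProfile:
    """Unbiased free-energy profile G(z) with its gate-barrier annotation."""

    z: np.ndarray               # bin centers, nm
    g: np.ndarray               # kcal/mol; NaN on unsampled bins
    uncertainty: np.ndarray     # kcal/mol per bin (zeros unless bootstrapped)
    reference_region: tuple
    temperature: float
    barrier: float | None = None
    barrier_location: float | None = None
    converged: bool = True
    n_iterations: int = 0
    window_free_energies: np.ndarray | None = None


def make_windows(z_min: float, z_max: float, spacing: float,
                 rel_tol: float = 1e-6) -> np.ndarray:
    """Inclusive arithmetic sequence of window centers.

    The range must be commensurate with the spacing: count is
    round((z_max - z_min)/spacing) + 1 and the implied endpoint must match
    z_max to within ``rel_tol`` of the spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not z_min < z_max:
        raise ValueError("require z_min < z_max")
    n_int = (z_max - z_min) / spacing
    if n_int < 1:
        raise ValueError("spacing exceeds the requested range")
    n = int(round(n_int))
    if abs(n_int - n) > rel_tol * max(1.0, n):
        raise ValueError("range is not commensurate with spacing")
    return np.linspace(z_min, z_max, n + 1)


def _histograms(windows, bin_width, z_range):
    samples = [w.production_samples() for w in windows]
    if z_range is None:
        lo = min(s.min() for s in samples)
        hi = max(s.max() for s in samples)
    else:
        lo, hi = z_range
    # Align bin edges on multiples of bin_width so reference/gate intervals
    # are stable across calls.
    lo = np.floor(lo / bin_width) * bin_width
    hi = np.ceil(hi / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    hist = np.empty((len(windows), nbins))
    for i, s in enumerate(samples):
        hist[i], _ = np.histogram(s, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return hist, centers


def _check_overlap(windows, hist):
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hist[a] > 0) & (hist[b] > 0)):
            raise ValueError(
                "no histogram overlap between neighboring windows at "
                f"z = {windows[a].center:.3f} and {windows[b].center:.3f} nm")


def _bin_averaged_boltzmann(windows, centers, bin_width, kt, n_quad=7):
    """Bias Boltzmann factors averaged over each bin (midpoint quadrature).

    Evaluating exp(-U_i/kT) only at bin centers biases the profile when the
    biased distributions are not much wider than a bin; averaging over the
    bin is the correct discrete kernel.  Underflow to zero far from a
    window is harmless: nearby windows dominate the denominators.
    """
    offsets = bin_width * ((np.arange(n_quad) + 0.5) / n_quad - 0.5)
    sub = centers[None, :] + offsets[:, None]          # (n_quad, n_bins)
    boltz = np.zeros((len(windows), centers.size))
    for i, w in enumerate(windows):
        boltz[i] = np.exp(-w.bias(sub) / kt).mean(axis=0)
    return boltz


def _stitch_initial_f(windows, hist, bias_matrix, kt):
    """Starting window free energies by pairwise overlap matching.

    For neighboring windows the difference f_j - f_i equals
    kT ln(p_j(b)/p_i(b)) + U_j(b) - U_i(b) on any jointly sampled bin;
    chaining the count-weighted means gives an excellent initial guess that
    cuts the self-consistent iteration count by orders of magnitude.
    """
    order = np.argsort([w.center for w in windows])
    dens = hist / np.maximum(hist.sum(axis=1, keepdims=True), 1)
    f = np.zeros(len(windows))
    for i, j in zip(order[:-1], order[1:]):
        both = (hist[i] > 0) & (hist[j] > 0)
        if not np.any(both):
            continue
        delta = (kt * np.log(dens[j, both] / dens[i, both])
                 + bias_matrix[j, both] - bias_matrix[i, both])
        w = hist[i, both] * hist[j, both] / (hist[i, both] + hist[j, both])
        f[j] = f[i] + float(np.average(delta, weights=w))
    return f - f[0]


def _wham_iterate(hist, bias_matrix, kt, tol, max_iter, boltz, f_init=None):
    n_i = hist.sum(axis=1)
    total_b = hist.sum(axis=0)
    f = np.zeros(hist.shape[0]) if f_init is None else f_init.copy()
    sampled = total_b > 0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        c = np.exp(f / kt)
        denom = (n_i * c) @ boltz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sampled & (denom > 0), total_b / denom, 0.0)
        zs = boltz @ p
        f_new = -kt * np.log(zs)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    p_sum = p.sum()
    if p_sum > 0:
        p = p / p_sum
    return p, f, converged, n_iter


def wham(windows, temperature: float, bin_width: float = 0.05,
         tol: float = 1e-7, max_iter: int = 100_000,
         z_range=None, reference_region=(-8.0, -6.0),
         gate=(-1.0, 1.0), n_bootstrap: int = 0,
         seed=None) -> FreeEnergyProfile:
    """Self-consistent WHAM over a set of umbrella windows.

    ``tol`` is the convergence threshold on max |delta f_i| in kcal/mol.
    Per-bin uncertainties come from a window-level bootstrap (``n_bootstrap``
    resamples of each window's samples); they are zero when disabled.
    Non-overlapping neighbor windows raise; non-convergence returns a profile
    flagged ``converged=False`` with a warning.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not windows:
        raise ValueError("no umbrella windows supplied")
    kt = KB_KCAL_MOL_K * temperature
    hist, centers = _histograms(windows, bin_width, z_range)
    if len(windows) > 1:
        _check_overlap(windows, hist)
    bias_matrix = np.stack([w.bias(centers) for w in windows])
    boltz = _bin_averaged_boltzmann(windows, centers, bin_width, kt)
    f_init = _stitch_initial_f(windows, hist, bias_matrix, kt) \
        if len(windows) > 1 else None
    p, f, converged, n_iter = _wham_iterate(hist, bias_matrix, kt, tol,
                                            max_iter, boltz, f_init)
    if not converged:
        warnings.warn(f"WHAM did not converge in {max_iter} iterations; "
                      "returning partial result", RuntimeWarning)

    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -kt * np.log(p), np.nan)
    ref = (centers >= reference_region[0]) & (centers <= reference_region[1])
    if not np.any(ref & np.isfinite(g)):
        raise ValueError("reference region contains no sampled bins")
    g = g - np.nanmin(g[ref])

    unc = np.zeros_like(g)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_bootstrap):
            boot = []
            for w in windows:
                s = w.production_samples()
                boot.append(UmbrellaWindow(
                    w.center, w.spring_k,
                    rng.choice(s, size=s.size, replace=True),
                    sample_dt=w.sample_dt))
            bh, _ = _histograms(boot, bin_width, (centers[0] - bin_width / 2,
                                                  centers[-1] + bin_width / 2))
            bp, _, _, _ = _wham_iterate(bh, bias_matrix, kt, tol, max_iter,
                                        boltz, f)
            with np.errstate(divide="ignore"):
                bg = np.where(bp > 0, -kt * np.log(bp), np.nan)
            bg = bg - np.nanmin(bg[ref])
            reps.append(bg)
        unc = np.nanstd(np.stack(reps), axis=0)

    profile = FreeEnergyProfile(centers, g, unc, tuple(reference_region),
                                temperature, converged=converged,
                                n_iterations=n_iter,
                                window_free_energies=f)
    try:
        profile.barrier, profile.barrier_location = _barrier(profile, gate,
                                                             reference_region)
    except ValueError:
        profile.barrier = None
    return profile


def _barrier(profile, gate, bulk):
    z, g = profile.z, profile.g
    in_gate = (z >= gate[0]) & (z <= gate[1])
    in_bulk = (z >= bulk[0]) & (z <= bulk[1])
    if not np.any(in_gate):
        raise ValueError("gate interval contains no bins")
    if np.any(~np.isfinite(g[in_gate])):
        raise ValueError("gate interval contains unsampled bins")
    if not np.any(in_bulk & np.isfinite(g)):
        raise ValueError("bulk interval contains no sampled bins")
    bulk_mean = float(np.nanmean(g[in_bulk]))
    idx = np.flatnonzero(in_gate)
    top = idx[np.argmax(g[idx])]
    return float(g[top] - bulk_mean), float(z[top])


def barrier_height(profile: FreeEnergyProfile, gate=(-1.0, 1.0),
                   bulk=None) -> float:
    """Gate barrier: max G over the gate interval minus the bulk-mean G.

    Invariant under a constant shift of the whole profile.  Raises when the
    gate contains unsampled bins or the bulk interval is unsampled.
    """
    if bulk is None:
        bulk = profile.reference_region
    value, _ = _barrier(profile, gate, bulk)
    return value


def convergence_blocks(windows, equilibration_times, production: float,
                       **wham_kwargs):
    """Barrier as a function of per-window equilibration discard.

    For each t_eq, re-runs WHAM on the sample slice [t_eq, t_eq + production)
    of every window.  Windows too short for a slice cause that row to be
    skipped with a diagnostic entry instead of a barrier.
    """
    rows = []
    for t_eq in equilibration_times:
        sliced = []
        ok = True
        for w in windows:
            i0 = int(round(t_eq / w.sample_dt))
            i1 = int(round((t_eq + production) / w.sample_dt))
            part = w.samples[i0:i1]
            if part.size == 0:
                ok = False
                break
            sliced.append(UmbrellaWindow(w.center, w.spring_k, part,
                                         sample_dt=w.sample_dt))
        if not ok:
            rows.append({"t_eq": t_eq, "barrier": None,
                         "skipped": "insufficient samples"})
            continue
        prof = wham(sliced, **wham_kwargs)
        rows.append({"t_eq": t_eq, "barrier": prof.barrier,
                     "converged": prof.converged})
    return rows


@dataclass
class WindowHydration:
    """Mean gate hydration versus restrained-ion position."""

    centers: np.ndarray
    mean_nwat: np.ndarray
    nwat_us: float              # mean over windows whose center is in the gate
    skipped: list


def hydration_by_window(windows, nwat_traces, time_slice=(0.0, 1.0),
                        gate=(-1.0, 1.0)) -> WindowHydration:
    """Per-window mean N_wat over a time slice, and the gate-window average.

    ``nwat_traces`` is a list aligned with ``windows``; each entry is a
    per-sample N_wat series (or None for missing water data, in which case
    the window is skipped and flagged).
    """
    centers, means, skipped = [], [], []
    for w, trace in zip(windows, nwat_traces):
        if trace is None:
            skipped.append(w.center)
            continue
        trace = np.asarray(trace, dtype=float)
        i0 = int(round(time_slice[0] / w.sample_dt))
        i1 = int(round(time_slice[1] / w.sample_dt))
        part = trace[i0:i1]
        if part.size == 0:
            skipped.append(w.center)
            continue
        centers.append(w.center)
        means.append(float(part.mean()))
    centers = np.asarray(centers)
    means = np.asarray(means)
    in_gate = (centers >= gate[0]) & (centers <= gate[1])
    nwat_us = float(means[in_gate].mean()) if np.any(in_gate) else float("nan")
    return WindowHydration(centers, means, nwat_us, skipped)
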
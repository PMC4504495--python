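"""Per-frame pore-hydration metrics and ensemble summaries.

The two metrics of hydrophobic hydration are the number of water molecules in
a pore region, N_wat, and the length of the longest dehydrated stretch along
the pore axis, z_gap, computed with anchor points at the region ends so that
"wet" means an end-to-end connected water column.  A frame is wet when
z_gap <= 0.38 nm (inclusive), the span of a water-water contact.

On top of the per-frame metrics this module builds ensemble time courses
P_wet(t), wetted-fraction threshold tables with between-condition ratios,
normalized N_wat / z_gap distributions, and the classification of stably
superhydrated (SSH) trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import WET_THRESHOLD_NM
from .regression import fit_line


@dataclass(frozen=True)
class RegionSpec:
    """An axial pore region: a cylinder around the pore (z) axis.

    ``z_lo``/``z_hi`` are nm relative to the axial origin (by convention the
    center of mass of the gate backbone atoms); ``cylinder_radius`` is the
    lateral cutoff used when counting waters.  The default radius, 0.8 nm, is
    slightly above the hexahydrated-Mg2+ radius.
    """

    name: str
    z_lo: float
    z_hi: float
    cylinder_radius: float = 0.8
    reference: str = "gate-backbone-com"

    def __post_init__(self):
        if not self.z_lo < self.z_hi:
            raise ValueError("require z_lo < z_hi")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")

    @property
    def length(self) -> float:
        return self.z_hi - self.z_lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.z_lo + self.z_hi)


#: The hydrophobic gate: a 1.9-nm constriction centered on the axial origin.
GATE_REGION = RegionSpec("MM", -0.95, 0.95)

#: The shorter lower constriction, centered 2.3 nm below the gate.
LOWER_CONSTRICTION = RegionSpec("LC", -2.65, -1.95)


@dataclass
class HydrationSeries:
    """Per-frame hydration metrics for one trajectory.

    ``z_gap`` may be NaN for frames whose water coordinates were unavailable;
    such frames are listed in ``flagged_frames`` rather than dropped.
    """

    time: np.ndarray
    n_wat: np.ndarray
    z_gap: np.ndarray
    z_gap_center: np.ndarray
    wet: np.ndarray
    threshold: float = WET_THRESHOLD_NM
    source: str = ""
    flagged_frames: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time)
        for name in ("n_wat", "z_gap", "z_gap_center", "wet"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def wet_fraction(self) -> float:
        """Fraction of frames (0..1) with a connected water column."""
        return float(np.mean(self.wet))


def axial_gap(water_z, region: RegionSpec):
    """Largest axial distance between consecutive water oxygens in a region.

    ``water_z`` must be sorted axial positions restricted to the region's
    cylinder.  Anchor entries are inserted at ``z_lo`` and ``z_hi`` before
    scanning consecutive pairs, so a column must reach both region ends to
    yield a small gap (end-to-end connectivity).

    Returns ``(z_gap, z_gap_center)`` where the center is the midpoint of the
    largest gap.  An empty region gives ``(region.length, region.midpoint)``.
    """
    z = np.asarray(water_z, dtype=float)
    if z.size and np.any(np.diff(z) < 0):
        raise ValueError("water_z must be sorted ascending")
    if z.size and (z[0] < region.z_lo - 1e-9 or z[-1] > region.z_hi + 1e-9):
        raise ValueError("water_z contains positions outside the region")
    anchored = np.concatenate(([region.z_lo], z, [region.z_hi]))
    gaps = np.diff(anchored)
    i = int(np.argmax(gaps))
    return float(gaps[i]), float(0.5 * (anchored[i] + anchored[i + 1]))


def count_waters(coords, region: RegionSpec) -> int:
    """Number of water oxygens inside the region's cylinder.

    ``coords`` is an (N, 3) array in nm, frame pre-aligned so the pore axis is
    the z axis through the origin.  Both the axial interval and the radial
    cutoff are closed (boundary atoms count).
    """
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    if xyz.size == 0:
        return 0
    z = xyz[:, 2]
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    inside = (z >= region.z_lo) & (z <= region.z_hi) & (r <= region.cylinder_radius)
    return int(np.count_nonzero(inside))


def classify_wet(z_gap: float, threshold: float = WET_THRESHOLD_NM) -> bool:
    """True iff the region is end-to-end hydrated: z_gap <= threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if z_gap < 0:
        raise ValueError("z_gap must be non-negative")
    return bool(z_gap <= threshold)


def hydration_series(trajectory, region: RegionSpec,
                     threshold: float = WET_THRESHOLD_NM) -> HydrationSeries:
    """Apply the per-frame metrics to a whole trajectory.

    ``trajectory`` is either a generator trace (an object with ``time`` and
    per-frame axial water positions ``water_z``) or an iterable of
    ``(time, coords)`` pairs with (N, 3) water-oxygen coordinates in nm.
    Frames with missing water records (``None``) are flagged, with NaN
    metrics, rather than silently skipped.
    """
    if hasattr(trajectory, "water_z"):
        times = np.asarray(trajectory.time, dtype=float)
        frames = trajectory.water_z
        if frames is None:
            raise ValueError(
                "trace carries no water positions; use its stored columns "
                "or regenerate with include_positions=True")
        axial_only = True
        source = getattr(trajectory, "source", "")
    else:
        pairs = list(trajectory)
        times = np.asarray([t for t, _ in pairs], dtype=float)
        frames = [c for _, c in pairs]
        axial_only = False
        source = ""
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("frames must be strictly time-ordered")

    n = times.size
    n_wat = np.zeros(n, dtype=int)
    z_gap = np.full(n, np.nan)
    z_center = np.full(n, np.nan)
    wet = np.zeros(n, dtype=bool)
    flagged = []
    for i, frame in enumerate(frames):
        if frame is None:
            flagged.append(i)
            continue
        if axial_only:
            z = np.sort(np.asarray(frame, dtype=float))
            z = z[(z >= region.z_lo) & (z <= region.z_hi)]
        else:
            xyz = np.asarray(frame, dtype=float).reshape(-1, 3)
            r = np.hypot(xyz[:, 0], xyz[:, 1])
            keep = (xyz[:, 2] >= region.z_lo) & (xyz[:, 2] <= region.z_hi) \
                & (r <= region.cylinder_radius)
            z = np.sort(xyz[keep, 2])
        n_wat[i] = z.size
        z_gap[i], z_center[i] = axial_gap(z, region)
        wet[i] = classify_wet(z_gap[i], threshold)
    return HydrationSeries(times, n_wat, z_gap, z_center, wet,
                           threshold=threshold, source=source,
                           flagged_frames=flagged,
                           meta={"region": region.name})


def wetting_fraction_timecourse(ensemble):
    """Fraction of trajectories wet at each time point, with a linear fit.

    All series must share the time grid.  Returns ``(t, P, fit)`` where ``P``
    is the wet fraction per time point and ``fit`` the least-squares line of
    P on t over the full span.
    """
    series = list(ensemble)
    if not series:
        raise ValueError("empty ensemble")
    t0 = np.asarray(series[0].time, dtype=float)
    wet = np.empty((len(series), t0.size), dtype=bool)
    for i, s in enumerate(series):
        if len(s) != t0.size or not np.allclose(s.time, t0):
            raise ValueError("ragged time grids across the ensemble")
        wet[i] = s.wet
    p = wet.mean(axis=0)
    fit = fit_line(t0, p, min_points=2)
    return t0, p, fit


def threshold_table(ensembles: dict, thresholds, ratio_ndigits: int = 1):
    """Count trajectories wetted for at least given percentages of frames.

    ``ensembles`` maps exactly two condition labels (numerator first, e.g.
    without / with regulatory ions) to lists of :class:`HydrationSeries`.
    ``thresholds`` are percentages of the trajectory; a threshold of 0 counts
    strictly-positive wet fractions (the ">0" row), any other value is
    inclusive (">= theta").  Ratios are numerator/denominator counts rounded
    half-even to ``ratio_ndigits``; division by zero yields None (undefined).

    Returns a list of dict rows: threshold_pct, counts per condition, ratio.
    """
    if len(ensembles) != 2:
        raise ValueError("threshold_table expects exactly two conditions")
    for label, ens in ensembles.items():
        if not ens:
            raise ValueError(f"empty ensemble for condition {label!r}")
    labels = list(ensembles)
    pct = {label: np.array([100.0 * s.wet_fraction for s in ens])
           for label, ens in ensembles.items()}
    rows = []
    for theta in thresholds:
        counts = {}
        for label in labels:
            if theta == 0:
                counts[label] = int(np.count_nonzero(pct[label] > 0))
            else:
                counts[label] = int(np.count_nonzero(pct[label] >= theta))
        num, den = counts[labels[0]], counts[labels[1]]
        ratio = None if den == 0 else float(np.round(num / den, ratio_ndigits))
        rows.append({"threshold_pct": theta,
                     labels[0]: num, labels[1]: den,
                     "ratio": ratio})
    return rows


@dataclass
class Histogram:
    """A normalized discrete or binned distribution (probabilities sum to 1
    unless ``empty``)."""

    values: np.ndarray          # bin centers (N_wat integers or z_gap bin mids)
    probs: np.ndarray
    empty: bool = False

    def mean(self) -> float:
        return float(np.sum(self.values * self.probs))

    def std(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum((self.values - m) ** 2 * self.probs)))


def hydration_distributions(ensemble, wet_only: bool = False, exclude=None,
                            zgap_bin_width: float = 0.02):
    """Normalized histograms of N_wat (unit bins) and z_gap over an ensemble.

    ``wet_only`` restricts to frames with a connected water column; ``exclude``
    is an optional collection of trajectory indices (e.g. SSH runs) left out
    of the analysis.  NaN z_gap frames contribute to the N_wat histogram only.
    """
    exclude = set(exclude or ())
    nwat_parts, zgap_parts = [], []
    for i, s in enumerate(ensemble):
        if i in exclude:
            continue
        mask = s.wet if wet_only else np.ones(len(s), dtype=bool)
        nwat_parts.append(np.asarray(s.n_wat)[mask])
        zgap_parts.append(np.asarray(s.z_gap)[mask])
    nwat = np.concatenate(nwat_parts) if nwat_parts else np.array([], dtype=int)
    zgap = np.concatenate(zgap_parts) if zgap_parts else np.array([])
    zgap = zgap[np.isfinite(zgap)]

    if nwat.size == 0:
        nwat_hist = Histogram(np.array([]), np.array([]), empty=True)
    else:
        counts = np.bincount(nwat.astype(int))
        nwat_hist = Histogram(np.arange(counts.size), counts / counts.sum())
    if zgap.size == 0:
        zgap_hist = Histogram(np.array([]), np.array([]), empty=True)
    else:
        nbins = max(1, int(np.ceil(zgap.max() / zgap_bin_width)))
        counts, edges = np.histogram(zgap, bins=nbins,
                                     range=(0.0, nbins * zgap_bin_width))
        zgap_hist = Histogram(0.5 * (edges[:-1] + edges[1:]),
                              counts / counts.sum())
    return nwat_hist, zgap_hist


def classify_ssh(series: HydrationSeries, frac_wet_min: float = 20.0,
                 frac_high_min: float = 20.0, nwat_high: int = 20) -> bool:
    """Stably-superhydrated classification of one trajectory.

    True iff the percentage of wet frames is >= ``frac_wet_min`` AND the
    percentage of frames with N_wat strictly greater than ``nwat_high`` is
    >= ``frac_high_min``.  Thresholds are percentages in [0, 100].
    """
    for v in (frac_wet_min, frac_high_min):
        if not 0.0 <= v <= 100.0:
            raise ValueError("SSH thresholds must be percentages in [0, 100]")
    pct_wet = 100.0 * series.wet_fraction
    pct_high = 100.0 * float(np.mean(np.asarray(series.n_wat) > nwat_high))
    return bool(pct_wet >= frac_wet_min and pct_high >= frac_high_min)
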
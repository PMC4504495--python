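"""Hydration metrics: axial gaps, water counts, wetting classification,
time courses, threshold tables, distributions and SSH labeling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poregate import hydration as hyd
from poregate.hydration import GATE_REGION, RegionSpec


def brute_force_gap(water_z, region):
    anchored = sorted([region.z_lo, region.z_hi, *water_z])
    best, center = -1.0, None
    for a, b in zip(anchored[:-1], anchored[1:]):
        if b - a > best:
            best, center = b - a, 0.5 * (a + b)
    return best, center


class TestAxialGap:
    def test_empty_region(self):
        gap, center = hyd.axial_gap([], GATE_REGION)
        assert gap == pytest.approx(1.9)
        assert center == pytest.approx(0.0)

    def test_regular_spacing(self):
        z = np.arange(-0.95, 0.951, 0.30)[1:]  # every 0.30 nm from anchor
        gap, _ = hyd.axial_gap(np.round(z, 10), GATE_REGION)
        assert gap == pytest.approx(0.30, abs=1e-9)

    def test_documented_example(self):
        gap, center = hyd.axial_gap([-0.50, -0.10, 0.30, 0.70], GATE_REGION)
        assert gap == pytest.approx(0.45)
        assert center == pytest.approx(-0.725)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            hyd.axial_gap([0.5, -0.5], GATE_REGION)

    @given(st.lists(st.floats(-0.95, 0.95), max_size=30))
    def test_matches_brute_force(self, zs):
        zs = sorted(zs)
        gap, center = hyd.axial_gap(zs, GATE_REGION)
        bgap, bcenter = brute_force_gap(zs, GATE_REGION)
        assert gap == pytest.approx(bgap)
        assert center == pytest.approx(bcenter)

    @given(st.lists(st.floats(-0.9, 0.9), min_size=1, max_size=15),
           st.floats(-5, 5))
    def test_wet_classification_translation_invariant(self, zs, shift):
        zs = sorted(zs)
        shifted = RegionSpec("r", GATE_REGION.z_lo + shift,
                             GATE_REGION.z_hi + shift)
        g0, _ = hyd.axial_gap(zs, GATE_REGION)
        g1, _ = hyd.axial_gap([z + shift for z in zs], shifted)
        assert hyd.classify_wet(g0) == hyd.classify_wet(g1)


class TestCountWaters:
    def test_empty_frame(self):
        assert hyd.count_waters(np.empty((0, 3)), GATE_REGION) == 0

    def test_cylinder_selection(self):
        inside = np.column_stack([np.zeros(5), np.zeros(5),
                                  np.linspace(-0.9, 0.9, 5)])
        outside = np.array([[0.9, 0.0, 0.0], [0.0, 0.0, 1.2],
                            [0.85, 0.0, -0.5]])
        frame = np.vstack([inside, outside])
        assert hyd.count_waters(frame, GATE_REGION) == 5

    def test_boundary_is_inclusive(self):
        frame = np.array([[0.0, 0.0, 0.95], [0.8, 0.0, 0.0]])
        assert hyd.count_waters(frame, GATE_REGION) == 2


class TestClassifyWet:
    @pytest.mark.parametrize("gap,expected", [
        (0.38, True),    # criterion is inclusive
        (0.381, False),
        (0.0, True),
    ])
    def test_threshold(self, gap, expected):
        assert hyd.classify_wet(gap) is expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            hyd.classify_wet(0.1, threshold=-0.1)


class TestHydrationSeries:
    def test_generator_wet_frames_are_connected(self, mixed_ensemble):
        trace = max(mixed_ensemble, key=lambda t: t.wet.mean())
        series = hyd.hydration_series(trace, GATE_REGION)
        assert len(series) == len(trace.time)
        # wet-state frames with enough waters to span the region connect
        feasible = trace.n_wat >= int(np.ceil(1.9 / 0.38))
        wet_state = trace.state == "wet"
        assert np.all(series.wet[wet_state & feasible])

    def test_all_dry_trajectory(self):
        frames = [(float(t), np.empty((0, 3))) for t in range(10)]
        series = hyd.hydration_series(frames, GATE_REGION)
        assert series.wet_fraction == 0.0
        assert np.all(series.z_gap == pytest.approx(1.9))

    def test_missing_frame_flagged(self):
        frames = [(0.0, np.empty((0, 3))), (1.0, None),
                  (2.0, np.empty((0, 3)))]
        series = hyd.hydration_series(frames, GATE_REGION)
        assert series.flagged_frames == [1]
        assert np.isnan(series.z_gap[1])


def make_series(wet_flags, dt=1.0):
    n = len(wet_flags)
    wet = np.asarray(wet_flags, dtype=bool)
    return hyd.HydrationSeries(
        time=dt * np.arange(n), n_wat=np.where(wet, 15, 2),
        z_gap=np.where(wet, 0.3, 1.0), z_gap_center=np.zeros(n), wet=wet)


class TestTimecourse:
    def test_half_wet(self):
        series = [make_series([1, 1, 1]), make_series([0, 0, 0])]
        t, p, fit = hyd.wetting_fraction_timecourse(series)
        assert np.all(p == 0.5)

    def test_all_dry_zero_slope(self):
        series = [make_series([0, 0, 0, 0])] * 3
        _, p, fit = hyd.wetting_fraction_timecourse(series)
        assert np.all(p == 0.0)
        assert fit.slope == 0.0

    def test_ragged_grids_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            hyd.wetting_fraction_timecourse(
                [make_series([0, 1]), make_series([0, 1, 0])])


class TestThresholdTable:
    @staticmethod
    def build_condition(band_counts, n_total, n_frames=10000):
        """Trajectories with wet fractions placed inside given % bands."""
        series = []
        for (lo_pct, hi_pct), count in band_counts:
            frames = int(round(0.5 * (lo_pct + hi_pct) / 100.0 * n_frames))
            frames = max(frames, 1) if hi_pct > 0 else 0
            for _ in range(count):
                flags = np.zeros(n_frames, dtype=bool)
                flags[:frames] = True
                series.append(make_series(flags))
        while len(series) < n_total:
            series.append(make_series(np.zeros(n_frames, dtype=bool)))
        return series

    def test_reproduces_published_count_table(self):
        # wetted-fraction bands chosen to reproduce the study's count table:
        # 175/100/78/28/13/10 without regulatory ions vs 83/31/25/6/4/1 with
        bands_no = [((0.01, 0.04), 75), ((0.05, 0.9), 22), ((1, 4.9), 50),
                    ((5, 9.9), 15), ((10, 19.9), 3), ((20, 40), 10)]
        bands_yes = [((0.01, 0.04), 52), ((0.05, 0.9), 6), ((1, 4.9), 19),
                     ((5, 9.9), 2), ((10, 19.9), 3), ((20, 40), 1)]
        table = hyd.threshold_table(
            {"no_ions": self.build_condition(bands_no, 700),
             "with_ions": self.build_condition(bands_yes, 700)},
            thresholds=[0, 0.05, 1, 5, 10, 20])
        counts_no = [r["no_ions"] for r in table]
        counts_yes = [r["with_ions"] for r in table]
        ratios = [r["ratio"] for r in table]
        assert counts_no == [175, 100, 78, 28, 13, 10]
        assert counts_yes == [83, 31, 25, 6, 4, 1]
        assert ratios == [2.1, 3.2, 3.1, 4.7, 3.2, 10.0]

    def test_identical_conditions_ratio_one(self):
        ens = [make_series([1, 0, 0, 0]), make_series([1, 1, 0, 0])]
        table = hyd.threshold_table({"a": ens, "b": list(ens)},
                                    thresholds=[0, 25])
        assert all(r["ratio"] == 1.0 for r in table)

    def test_zero_denominator_is_undefined(self):
        table = hyd.threshold_table(
            {"a": [make_series([1, 1, 1, 1])],
             "b": [make_series([0, 0, 0, 0])]},
            thresholds=[50])
        assert table[0]["ratio"] is None

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hyd.threshold_table({"a": [], "b": [make_series([0])]}, [0])


class TestDistributions:
    def test_point_mass(self):
        s = make_series([0] * 5)
        s.n_wat[:] = 2
        nwat, _ = hyd.hydration_distributions([s])
        assert nwat.probs[2] == 1.0
        assert nwat.mean() == 2.0

    def test_normalization(self, mixed_ensemble):
        series = [make_series(t.wet) for t in mixed_ensemble]
        for i, t in enumerate(mixed_ensemble):
            series[i].n_wat = t.n_wat
        nwat, zgap = hyd.hydration_distributions(series)
        assert nwat.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert zgap.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_selection_flagged(self):
        s = make_series([0, 0, 0])
        nwat, _ = hyd.hydration_distributions([s], wet_only=True)
        assert nwat.empty

    def test_exclusion_honored(self):
        a, b = make_series([1] * 4), make_series([1] * 4)
        a.n_wat[:] = 30
        nwat, _ = hyd.hydration_distributions([a, b], exclude=[0])
        assert nwat.mean() == pytest.approx(15.0)


class TestClassifySSH:
    def test_persistently_superhydrated(self):
        s = make_series([1] * 10)
        s.n_wat[:] = 25
        assert hyd.classify_ssh(s)

    def test_all_dry(self):
        assert not hyd.classify_ssh(make_series([0] * 10))

    def test_boundary_count_is_strict(self):
        s = make_series([1] * 10)
        s.n_wat[:] = 20  # exactly at the limit: not "high"
        assert not hyd.classify_ssh(s)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            hyd.classify_ssh(make_series([1]), frac_wet_min=150.0)
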
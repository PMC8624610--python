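"""Curve building and kinetic feature extraction (peak, T_int, endpoint)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blicyto import kinetics, synth
from blicyto.kinetics import TimeIntensityCurve
from blicyto.params import KillingModelParams, LuminescenceParams


def _curve(times, values, r=10.0, n=1):
    values = np.asarray(values, dtype=float)
    return TimeIntensityCurve(r, np.asarray(times, float), values, np.zeros_like(values), n)


def _table_from_wells(times, wells: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for wid, series in wells.items():
        for t, v in zip(times, series):
            rows.append(
                {
                    "well_id": wid,
                    "time_min": t,
                    "total_flux": v,
                    "background_corrected_flux": v,
                }
            )
    return pd.DataFrame(rows)


def _layout_for(wells: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": wid,
                "role": "control" if r == 0 else "treated",
                "et_ratio": r,
                "n_cells": 5e4,
            }
            for wid, r in wells.items()
        ]
    )


class TestBuildCurves:
    times = np.arange(0.0, 20.0, 2.0)

    def test_single_well_curve_equals_its_series(self):
        series = np.linspace(10, 1, len(self.times))
        table = _table_from_wells(self.times, {"A1": series})
        curves = kinetics.build_curves(table, _layout_for({"A1": 5.0}))
        c = curves[5.0]
        np.testing.assert_array_equal(c.mean, series)
        np.testing.assert_array_equal(c.sem, 0.0)
        assert c.n == 1

    def test_identical_replicates_have_zero_sem(self):
        series = np.linspace(10, 1, len(self.times))
        table = _table_from_wells(
            self.times, {"A1": series, "B1": series, "C1": series}
        )
        layout = _layout_for({"A1": 5.0, "B1": 5.0, "C1": 5.0})
        c = kinetics.build_curves(table, layout)[5.0]
        np.testing.assert_array_equal(c.mean, series)
        np.testing.assert_array_equal(c.sem, 0.0)
        assert c.n == 3

    def test_sem_matches_analytic_noise_over_replications(self, kp, lp, short_schedule):
        # bootstrap oracle: many seeded triplicates; average SEM should
        # approximate cv * mean / sqrt(3)
        cv, reps = 0.05, 400
        base = synth.simulate_well_curve(0.0, short_schedule, kp, lp, 0.0)
        sems = np.empty((reps, len(base)))
        rng_seeds = np.arange(reps)
        for i, s in enumerate(rng_seeds):
            rng = np.random.default_rng(s)
            trip = np.vstack(
                [
                    synth.simulate_well_curve(0.0, short_schedule, kp, lp, cv, rng)
                    for _ in range(3)
                ]
            )
            sems[i] = trip.std(axis=0, ddof=1) / np.sqrt(3)
        positive = base > 0
        observed = sems.mean(axis=0)[positive]
        analytic = cv * base[positive] / np.sqrt(3)
        np.testing.assert_allclose(observed, analytic, rtol=0.20)

    def test_missing_time_points_reported(self):
        table = _table_from_wells(
            self.times,
            {"A1": np.ones(len(self.times)), "B1": np.ones(len(self.times))},
        )
        table = table[~((table["well_id"] == "A1") & (table["time_min"] == 4.0))]
        with pytest.raises(ValueError, match="missing time points"):
            kinetics.build_curves(table, _layout_for({"A1": 5.0, "B1": 5.0}))

    def test_layout_without_analyzable_wells_rejected(self):
        table = _table_from_wells(self.times, {"A1": np.ones(len(self.times))})
        layout = pd.DataFrame(
            [{"well_id": "A1", "role": "blank", "et_ratio": 0.0, "n_cells": 0.0}]
        )
        with pytest.raises(ValueError, match="no control or treated"):
            kinetics.build_curves(table, layout)


class TestPeak:
    def test_monotone_decreasing_peaks_at_first_sample(self):
        c = _curve([0, 2, 4, 6], [9, 7, 5, 3])
        assert kinetics.peak(c) == (9.0, 0.0)

    def test_equal_maxima_resolve_to_earlier_time(self):
        c = _curve([0, 2, 4, 6], [1, 8, 8, 2])
        assert kinetics.peak(c) == (8.0, 2.0)

    def test_noise_free_control_peaks_at_8_min_sample(self, kp, lp, schedule):
        s = synth.simulate_well_curve(0.0, schedule, kp, lp, 0.0)
        c = _curve(schedule.times, s, r=0.0)
        _, tpk = kinetics.peak(c)
        # analytic Bateman peak 7.98 min; nearest scheduled sample is 8
        assert tpk == 8.0


class TestIntersectionTime:
    def test_linear_crossing_is_exact(self):
        t = np.arange(0.0, 60.0, 2.0)
        treated = _curve(t, 120.0 - t)
        control = _curve(t, np.full_like(t, 100.0), r=0.0)
        tint, censored = kinetics.intersection_time(treated, control, sustain=1)
        assert not censored
        assert tint == pytest.approx(20.0)

    def test_identical_curves_are_censored(self):
        t = np.arange(0.0, 60.0, 2.0)
        c1 = _curve(t, np.full_like(t, 50.0))
        c0 = _curve(t, np.full_like(t, 50.0), r=0.0)
        tint, censored = kinetics.intersection_time(c1, c0)
        assert censored
        assert tint == t[-1]

    def test_schedule_mismatch_rejected(self):
        a = _curve([0, 2, 4], [1, 2, 3])
        b = _curve([0, 3, 6], [1, 2, 3], r=0.0)
        with pytest.raises(ValueError, match="schedule"):
            kinetics.intersection_time(a, b)

    def test_noise_free_tint_decreases_with_dose_vs_dense_oracle(self, kp, lp, schedule):
        control = _curve(
            schedule.times, synth.simulate_well_curve(0.0, schedule, kp, lp, 0.0), r=0.0
        )
        dense_t = np.linspace(0.0, 240.0, 480001)
        n0L0 = kp.n0 * synth.per_cell_emission(dense_t, 0.0, lp, kp)
        tints = []
        for r in (1.25, 2.5, 5.0, 10.0, 20.0, 40.0):
            treated = _curve(
                schedule.times, synth.simulate_well_curve(r, schedule, kp, lp, 0.0), r=r
            )
            tint, censored = kinetics.intersection_time(treated, control)
            assert not censored
            # dense-grid root-finding oracle on the analytic curves
            s_dense = synth.live_cells(dense_t, r, kp) * synth.per_cell_emission(
                dense_t, r, lp, kp
            )
            diff = s_dense - n0L0
            after_peak = dense_t >= dense_t[np.argmax(s_dense)]
            oracle = dense_t[after_peak][np.argmax(diff[after_peak] < 0)]
            # within one inter-sample interval of the schedule
            spacing = np.max(np.diff(schedule.times))
            assert abs(tint - oracle) <= spacing
            tints.append(tint)
        assert np.all(np.diff(tints) < 0)

    @given(scale=st.floats(0.001, 1000.0))
    def test_peak_time_and_tint_invariant_under_rescaling(self, scale):
        t = np.arange(0.0, 40.0, 2.0)
        treated = 100.0 + 20 * np.exp(-(((t - 6) / 5.0) ** 2)) - 2.0 * t
        control = np.full_like(t, 90.0)
        a = kinetics.intersection_time(_curve(t, treated), _curve(t, control, r=0.0))
        b = kinetics.intersection_time(
            _curve(t, scale * treated), _curve(t, scale * control, r=0.0)
        )
        assert a[1] == b[1]
        assert a[0] == pytest.approx(b[0], rel=1e-12)
        assert (
            kinetics.peak(_curve(t, treated))[1]
            == kinetics.peak(_curve(t, scale * treated))[1]
        )


class TestEndpoint:
    t = np.arange(0.0, 241.0, 20.0)

    def test_equal_curves_lose_nothing(self):
        c = _curve(self.t, np.full_like(self.t, 5.0))
        c0 = _curve(self.t, np.full_like(self.t, 5.0), r=0.0)
        sig, loss = kinetics.endpoint(c, c0)
        assert (sig, loss) == (5.0, 0.0)

    def test_extinct_signal_is_total_loss(self):
        treated = np.linspace(10, 0, len(self.t))
        treated[-1] = 0.0
        c = _curve(self.t, treated)
        c0 = _curve(self.t, np.full_like(self.t, 10.0), r=0.0)
        sig, loss = kinetics.endpoint(c, c0)
        assert sig == 0.0
        assert loss == 100.0

    def test_nonpositive_control_rejected(self):
        c = _curve(self.t, np.ones_like(self.t))
        c0 = _curve(self.t, np.zeros_like(self.t), r=0.0)
        with pytest.raises(ValueError, match="undefined"):
            kinetics.endpoint(c, c0)

    def test_noise_free_loss_increases_with_dose(self, kp, lp, schedule):
        control = _curve(
            schedule.times, synth.simulate_well_curve(0.0, schedule, kp, lp, 0.0), r=0.0
        )
        losses = []
        for r in (1.25, 2.5, 5.0, 10.0, 20.0, 40.0):
            c = _curve(
                schedule.times, synth.simulate_well_curve(r, schedule, kp, lp, 0.0), r=r
            )
            losses.append(kinetics.endpoint(c, control)[1])
        assert np.all(np.diff(losses) > 0)


class TestFitLinearity:
    def test_proportional_data_has_unit_adjusted_r2(self):
        cells = np.array([100.0, 1e3, 1e4, 1e5])
        slope, intercept, adj = kinetics.fit_linearity(cells, 2.0 * cells)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert adj == pytest.approx(1.0)

    def test_three_collinear_points_are_exact(self):
        _, _, adj = kinetics.fit_linearity([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert adj == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 4.0])
        # hand-computed normal equations: slope = Sxy/Sxx on centered data
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope_o = sxy / sxx
        intercept_o = y.mean() - slope_o * x.mean()
        resid = y - (slope_o * x + intercept_o)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        adj_o = 1 - (1 - r2) * 2 / 1
        slope, intercept, adj = kinetics.fit_linearity(x, y)
        assert slope == pytest.approx(slope_o)
        assert intercept == pytest.approx(intercept_o)
        assert adj == pytest.approx(adj_o)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kinetics.fit_linearity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            kinetics.fit_linearity([1.0, 2.0], [1.0, 2.0])


class TestDoseResponse:
    def _summary(self, r, peak=1.0, tint=10.0, end=1.0, loss=0.0):
        return kinetics.KineticSummary(r, peak, 5.0, tint, False, end, loss)

    def test_equal_pair_flags_tie(self):
        _, flags = kinetics.dose_response([self._summary(1.0), self._summary(2.0)])
        assert flags == {"peak": "tie", "endpoint": "tie", "t_int": "tie"}

    def test_shuffled_input_sorts_identically(self):
        summaries = [self._summary(r, peak=r) for r in (5.0, 1.25, 40.0, 10.0)]
        a, _ = kinetics.dose_response(summaries)
        b, _ = kinetics.dose_response(list(reversed(summaries)))
        pd.testing.assert_frame_equal(a, b)
        assert list(a["r"]) == sorted(a["r"])

    def test_duplicate_ratios_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            kinetics.dose_response([self._summary(5.0), self._summary(5.0)])

    def test_noise_free_simulation_is_strictly_monotone(self, kp, lp, schedule):
        curves = {
            r: _curve(
                schedule.times,
                synth.simulate_well_curve(r, schedule, kp, lp, 0.0),
                r=r,
            )
            for r in (0.0, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0)
        }
        table, flags = kinetics.dose_response(kinetics.summarize_conditions(curves))
        assert flags["peak"] == "strictly_increasing"
        assert flags["endpoint"] == "strictly_decreasing"
        assert flags["t_int"] == "strictly_decreasing"
        assert not table["t_int_censored"].any()
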
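"""TIC/area reduction, onset/plateau rules, fits, typing, population stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import secretomap as sm
from secretomap.exceptions import FitError
from secretomap.kinetics import KineticsConfig


def maps_of(frames, dt=10.0):
    frames = np.asarray(frames, dtype=float)
    return sm.SecretionMapStack(frames=frames, times=np.arange(len(frames)) * dt)


def curve_of(values, dt=10.0):
    values = np.asarray(values, dtype=float)
    return sm.TICCurve(times=np.arange(len(values)) * dt, values=values)


class TestTICAndArea:
    def test_hand_sum(self):
        maps = maps_of([[[0, 2, 0], [1, 0, 3], [0, 0, 0]]])
        assert sm.tic_curve(maps).values[0] == 6.0

    def test_all_zero_stack(self):
        assert np.all(sm.tic_curve(maps_of(np.zeros((4, 5, 5)))).values == 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_tic_equals_pixel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frames = np.where(rng.random((4, 9, 9)) < 0.4, rng.random((4, 9, 9)) * 10, 0.0)
        tic = sm.tic_curve(maps_of(frames)).values
        oracle = np.zeros(4)
        for t in range(4):
            for r in range(9):
                for c in range(9):
                    if frames[t, r, c] != 0:
                        oracle[t] += frames[t, r, c]
        # exact up to summation-order rounding (pairwise vs sequential)
        np.testing.assert_allclose(tic, oracle, rtol=1e-12, atol=0)

    def test_area_counts_nonzero_pixels(self):
        frames = np.zeros((1, 20, 20))
        frames[0].flat[:100] = 1.0
        area = sm.area_curve(maps_of(frames), pixel_area_um2=0.04515625)
        assert area.values[0] == pytest.approx(4.515625)

    def test_area_full_frame(self):
        area = sm.area_curve(maps_of(np.ones((1, 350, 350))), pixel_area_um2=1.0)
        assert area.values[0] == 122_500.0

    def test_zero_frame_zero_area(self):
        assert sm.area_curve(maps_of(np.zeros((1, 4, 4))), 1.0).values[0] == 0.0

    def test_tic_invariant_under_pixel_permutation(self):
        rng = np.random.default_rng(0)
        frame = rng.random((8, 8))
        shuffled = rng.permutation(frame.ravel()).reshape(8, 8)
        assert sm.tic_curve(maps_of([frame])).values[0] == pytest.approx(
            sm.tic_curve(maps_of([shuffled])).values[0]
        )


class TestDetectOnset:
    def test_first_positive_frame(self):
        assert sm.detect_onset(curve_of([0, 0, 1.2, 3.4])) == 20.0

    def test_all_zero_is_none(self):
        assert sm.detect_onset(curve_of([0, 0, 0, 0])) is None

    def test_persistence_rejects_blip(self):
        assert sm.detect_onset(curve_of([0, 5, 0, 0]), persistence=2) is None

    def test_persistence_returns_first_of_run(self):
        assert sm.detect_onset(curve_of([0, 0, 1, 2, 3]), persistence=3) == 20.0

    def test_floor_gates_small_values(self):
        assert sm.detect_onset(curve_of([0, 2, 2, 9, 9]), floor=5.0) == 30.0


class TestDetectPlateau:
    def test_ramp_then_flat(self):
        plateau = sm.detect_plateau(curve_of([0, 1, 2, 3, 3, 3, 3]))
        assert plateau is not None
        assert plateau.start == 30.0
        assert plateau.end == 60.0  # extends to curve end
        assert plateau.plateau_mean == pytest.approx(3.0)

    def test_pure_ramp_has_no_plateau(self):
        assert sm.detect_plateau(curve_of(np.arange(12.0))) is None

    def test_ramp_flat_ramp_bounded_plateau(self):
        # 12-point type III shape; hand-enumerated expectations:
        # steps: 1,1,1,0,0,0,0,2,2,2,2 -> plateau [t3, t7], second rise at t7
        values = [0, 1, 2, 3, 3, 3, 3, 3, 5, 7, 9, 11]
        plateau = sm.detect_plateau(curve_of(values))
        assert plateau.start == 30.0
        assert plateau.end == 70.0
        # end precedes the third rising step (t9)
        assert plateau.end < 90.0

    def test_epsilon_zero_reproduces_literal_rule(self):
        # tiny persistent increments defeat the literal rule but not eps > 0
        values = np.array([0, 1, 2, 3, 3.001, 3.002, 3.003, 3.004])
        assert sm.detect_plateau(curve_of(values), epsilon=0.0) is None
        assert sm.detect_plateau(curve_of(values), epsilon=0.005) is not None


class TestFitSegment:
    def test_exact_line(self):
        times = np.arange(10) * 10.0
        curve = sm.TICCurve(times=times, values=100.0 * times / 60.0)
        fit = sm.fit_segment(curve, (0, 90))
        assert fit.slope_per_h == pytest.approx(100.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_slope_reported_per_hour_regardless_of_interval(self):
        for dt in (2.0, 10.0):
            times = np.arange(30) * dt
            curve = sm.TICCurve(times=times, values=7.0 * times)  # 7 a.u./min
            fit = sm.fit_segment(curve, (times[0], times[-1]))
            assert fit.slope_per_h == pytest.approx(420.0)

    def test_noisy_line_r_squared_above_09(self):
        rng = np.random.default_rng(0)
        times = np.arange(73) * 10.0
        values = times * 50.0
        values = np.clip(values + rng.normal(0, 0.01 * np.ptp(values), values.size), 0, None)
        fit = sm.fit_segment(sm.TICCurve(times=times, values=values), (0, 720))
        assert fit.r_squared > 0.9

    def test_constant_segment_degenerate(self):
        curve = curve_of([5, 5, 5, 5])
        fit = sm.fit_segment(curve, (0, 30))
        assert fit.degenerate
        assert fit.slope_per_h == 0.0
        assert fit.r_squared == 0.0

    def test_too_few_samples_raises(self):
        with pytest.raises(FitError):
            sm.fit_segment(curve_of([0, 1, 2, 3]), (0, 10))


class TestClassifyAndFit:
    cfg = KineticsConfig(persistence=1)

    def test_linear_curve_is_type_I(self):
        times = np.arange(73) * 10.0
        curve = sm.TICCurve(times=times, values=times * 100.0)
        record = sm.classify_and_fit(curve, self.cfg)
        assert record.secretion_type == "I"
        assert len(record.fits) == 1
        assert record.onset_min == 10.0

    def test_saturating_curve_is_type_II(self):
        times = np.arange(73) * 10.0
        values = 1000.0 * (1 - np.exp(-times / 120.0))
        record = sm.classify_and_fit(sm.TICCurve(times=times, values=values), self.cfg)
        assert record.secretion_type == "II"
        assert len(record.fits) == 1

    def test_ramp_plateau_ramp_is_type_III_with_summed_duration(self):
        times = np.arange(30) * 10.0
        values = np.concatenate(
            [np.linspace(0, 100, 10), np.full(10, 100.0), np.linspace(100, 250, 10)]
        )
        record = sm.classify_and_fit(sm.TICCurve(times=times, values=values), self.cfg)
        assert record.secretion_type == "III"
        assert len(record.fits) == 2
        assert record.duration_min == pytest.approx(
            sum(f.duration_min for f in record.fits)
        )
        # the plateau interval itself is not part of the duration
        assert record.duration_min < times[-1] - record.onset_min

    def test_all_zero_is_ns(self):
        record = sm.classify_and_fit(curve_of(np.zeros(20)), self.cfg)
        assert record.secretion_type == "NS"
        assert record.fits == []

    def test_below_noise_floor_is_ns(self):
        cfg = KineticsConfig(persistence=1, noise_floor=500.0)
        times = np.arange(20) * 10.0
        record = sm.classify_and_fit(sm.TICCurve(times=times, values=times), cfg)
        assert record.secretion_type == "NS"


class TestPopulationSummary:
    def make_record(self, kind, cell_id="c", max_tic=10.0):
        if kind == "NS":
            return sm.KineticsRecord(
                cell_id=cell_id, secretion_type="NS", onset_min=None,
                duration_min=0.0, fits=[], max_tic=max_tic,
            )
        n_fits = 2 if kind == "III" else 1
        fits = [
            sm.LinearFit(slope_per_h=100.0, intercept=0, r_squared=0.99,
                         t_start=0, t_end=100)
            for _ in range(n_fits)
        ]
        return sm.KineticsRecord(
            cell_id=cell_id, secretion_type=kind, onset_min=0.0,
            duration_min=100.0 * n_fits, fits=fits, max_tic=max_tic,
        )

    def test_asc_population_percentages(self):
        # 6 + 4 + 1 secreting of 111: 9.9% secreting; 5.4 / 3.6 / 0.9 per type
        records = (
            [self.make_record("I", f"i{k}") for k in range(6)]
            + [self.make_record("II", f"ii{k}") for k in range(4)]
            + [self.make_record("III", "iii0")]
            + [self.make_record("NS", f"ns{k}") for k in range(100)]
        )
        stats = sm.population_summary(records)
        assert stats.secreting_fraction_pct == 9.9
        assert stats.percentages["I"] == 5.4
        assert stats.percentages["II"] == 3.6
        assert stats.percentages["III"] == 0.9

    def test_all_ns(self):
        stats = sm.population_summary([self.make_record("NS", f"n{k}") for k in range(5)])
        assert stats.secreting_fraction_pct == 0.0

    def test_sample_sd_uses_n_minus_1(self):
        records = [
            self.make_record("I", "a", max_tic=10.0),
            self.make_record("I", "b", max_tic=20.0),
        ]
        stats = sm.population_summary(records)
        mean, sd = stats.max_tic_mean_sd["I"]
        assert mean == pytest.approx(15.0)
        assert sd == pytest.approx(7.0710678, abs=1e-6)

    def test_counts_sum_to_population(self):
        records = [self.make_record(k, str(i)) for i, k in enumerate(["I", "NS", "II"])]
        stats = sm.population_summary(records)
        assert sum(stats.counts.values()) == stats.n_total == 3
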
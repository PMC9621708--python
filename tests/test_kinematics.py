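"""Kinematics chain: marker selection, filtering, events, summaries."""

import numpy as np
import pandas as pd
import pytest

from limbspeech import kinematics as K
from limbspeech.synth import TrialSpec, simulate_biking_kinematics


def _markers_from(times, z, extra=None):
    coords = {"a": np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)}
    if extra is not None:
        coords.update(extra)
    return K.MarkerSeries(times=times, coords=coords)


class TestCircularMarkerSelection:
    def test_circular_beats_stationary(self):
        t = np.arange(0, 10, 0.005)
        circ = np.stack([8 * np.cos(2 * np.pi * t), np.zeros_like(t), 8 * np.sin(2 * np.pi * t)], axis=1)
        stat = np.full((t.size, 3), 5.0)
        m = K.MarkerSeries(times=t, coords={"circ": circ, "stat": stat})
        assert K.find_circular_marker(m) == "circ"

    def test_circular_beats_linear_drift_of_equal_amplitude(self):
        t = np.arange(0, 10, 0.005)
        circ = np.stack([8 * np.cos(2 * np.pi * t), np.zeros_like(t), 8 * np.sin(2 * np.pi * t)], axis=1)
        lin = np.stack([np.zeros_like(t), np.zeros_like(t), np.linspace(-8, 8, t.size)], axis=1)
        m = K.MarkerSeries(times=t, coords={"c": circ, "l": lin})
        # brute-force score comparison is the selection criterion itself
        sc = K.circularity_score(t, circ)
        sl = K.circularity_score(t, lin)
        assert sc > sl
        assert K.find_circular_marker(m) == "c"

    def test_generator_pedal_recovered_over_seeds(self):
        hits = 0
        for seed in range(30):
            spec = TrialSpec("P01", "female", 1, "legMot", duration=20.0,
                             cycle_duration_mean=1.07, cycle_duration_sd=0.12, seed=seed)
            markers, gt = simulate_biking_kinematics(spec)
            hits += K.find_circular_marker(markers) == gt.pedal_marker_id
        assert hits == 30

    def test_no_marker_with_amplitude_raises(self):
        t = np.arange(0, 5, 0.005)
        m = _markers_from(t, 0.2 * np.sin(2 * np.pi * t))
        with pytest.raises(ValueError, match="no circular marker"):
            K.find_circular_marker(m)


class TestPreprocessVertical:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 10, 0.005)
        m = _markers_from(t, 5 * np.sin(2 * np.pi * 2 * t))
        tt, z = K.preprocess_vertical(m, "a")
        core = (tt > 1) & (tt < 9)
        assert np.ptp(z[core]) > 0.99 * 10

    def test_stopband_sinusoid_removed(self):
        t = np.arange(0, 10, 0.005)
        m = _markers_from(t, 5 * np.sin(2 * np.pi * 30 * t))
        tt, z = K.preprocess_vertical(m, "a")
        core = (tt > 1) & (tt < 9)
        assert np.ptp(z[core]) < 0.01 * 10

    def test_constant_signal_unchanged(self):
        t = np.arange(0, 5, 0.005)
        m = _markers_from(t, np.full(t.size, 3.3))
        _, z = K.preprocess_vertical(m, "a")
        assert np.allclose(z, 3.3, atol=1e-9)

    def test_internal_gap_raises(self):
        t = np.concatenate([np.arange(0, 2, 0.005), np.arange(3, 5, 0.005)])
        m = _markers_from(t, np.sin(2 * np.pi * t))
        with pytest.raises(ValueError, match="dropout"):
            K.preprocess_vertical(m, "a")

    def test_output_rate_is_100hz(self):
        t = np.arange(0, 5, 0.005)
        m = _markers_from(t, np.sin(2 * np.pi * t))
        tt, _ = K.preprocess_vertical(m, "a")
        assert np.allclose(np.diff(tt), 0.01)
        assert tt[0] == t[0]


class TestCyclePeaks:
    def test_clean_one_second_cycles(self):
        t = np.arange(0, 10.005, 0.01)
        pos = 8 * np.sin(2 * np.pi * (t - 0.25))  # peaks at 0.5, 1.5, ...
        times, durs, tt, pp = K.detect_cycle_peaks(t, pos)
        assert times.size == 10
        assert np.allclose(durs, 1.0, atol=0.01)

    def test_trims_before_first_peak(self):
        t = np.arange(0, 10.005, 0.01)
        pos = 8 * np.sin(2 * np.pi * (t - 0.25))
        times, _, tt, _ = K.detect_cycle_peaks(t, pos)
        assert tt[0] >= times[0]

    def test_too_few_cycles_raises(self):
        t = np.arange(0, 1.0, 0.01)
        with pytest.raises(ValueError, match="no cycles"):
            K.detect_cycle_peaks(t, np.sin(2 * np.pi * 0.3 * t))

    def test_recall_precision_on_generator_trial(self, leg_trial):
        spec, markers, gt = leg_trial
        pk = K.process_trial(markers)
        det = pk.cycle_peak_times
        truth = gt.true_cycle_peak_times
        d_det = np.abs(det[:, None] - truth[None, :]).min(axis=1)
        truth_in = truth[(truth >= det[0] - 0.05) & (truth <= det[-1] + 0.05)]
        d_tru = np.abs(truth_in[:, None] - det[None, :]).min(axis=1)
        assert np.all(d_det < 0.05)  # precision 1.0 at +/-50 ms
        assert np.all(d_tru < 0.05)  # recall 1.0

    def test_durations_within_reported_range(self, leg_trial):
        _, markers, _ = leg_trial
        pk = K.process_trial(markers)
        assert np.all(pk.cycle_durations >= 0.4)
        assert np.all(pk.cycle_durations <= 3.5)


class TestRotationAngle:
    def test_maps_center_and_extremes(self):
        pos = np.array([-8.0, 0.0, 8.0, 3.0, -3.0])
        ang = K.to_rotation_angle(pos)
        assert ang[0] == pytest.approx(0.0)
        assert ang[1] == pytest.approx(90.0)
        assert ang[2] == pytest.approx(180.0)

    def test_bounded_in_0_180(self, leg_trial):
        _, markers, _ = leg_trial
        pk = K.process_trial(markers)
        assert pk.angle.min() >= 0.0
        assert pk.angle.max() <= 180.0

    def test_noisy_peaks_stay_below_180(self):
        # per-cycle maxima fluctuating below the global radius keep the
        # maximum angle a few degrees under 180 in most cycles
        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 0.01)
        pos = 8 * np.sin(2 * np.pi * t) * (1 + 0.02 * rng.normal(size=t.size))
        ang = K.to_rotation_angle(pos)
        frac_at_ceiling = np.mean(ang > 179.9)
        assert frac_at_ceiling < 0.01

    def test_small_amplitude_raises(self):
        with pytest.raises(ValueError, match="amplitude too small"):
            K.to_rotation_angle(np.array([0.0, 0.3, 0.1, 0.25]))


class TestAcceleration:
    def test_sinusoid_matches_analytic_peak(self):
        t = np.arange(0, 10, 0.01)
        y = np.sin(2 * np.pi * t)
        a = K.compute_acceleration(y, rate=100.0)
        assert np.max(np.abs(a[5:-5])) == pytest.approx((2 * np.pi) ** 2, rel=1e-3)

    def test_linear_ramp_is_zero(self):
        a = K.compute_acceleration(np.linspace(0, 5, 500), rate=100.0)
        assert np.allclose(a, 0.0, atol=1e-8)

    def test_correlates_with_clean_second_derivative(self, noiseless_leg_trial):
        spec, markers, gt = noiseless_leg_trial
        pk = K.process_trial(markers)
        # analytic check: compute second difference of the clean 200 Hz pedal
        z = markers.coords[gt.pedal_marker_id][:, 2] / 100.0
        acc200 = np.empty_like(z)
        acc200[1:-1] = (z[2:] - 2 * z[1:-1] + z[:-2]) * 200.0**2
        acc200[0], acc200[-1] = acc200[1], acc200[-2]
        ref = np.interp(pk.times, markers.times, acc200)
        r = np.corrcoef(pk.acceleration, ref)[0, 1]
        assert r > 0.99


class TestAccelerationPeaks:
    def test_two_peaks_per_cycle_with_effort_modulation(self, leg_trial):
        _, markers, _ = leg_trial
        pk = K.process_trial(markers)
        ratio = pk.acc_peak_times.size / pk.cycle_durations.size
        assert 1.7 < ratio <= 2.3

    def test_uniform_rotation_has_one_peak_per_cycle(self):
        spec = TrialSpec("P01", "female", 1, "legMot", duration=20.0,
                         cycle_duration_mean=1.0, cycle_duration_sd=0.0, seed=0)
        markers, _ = simulate_biking_kinematics(spec, noise_sd_cm=0.0, modulation_depth=0.0)
        pk = K.process_trial(markers)
        ratio = pk.acc_peak_times.size / pk.cycle_durations.size
        assert abs(ratio - 1.0) < 0.15

    def test_recovery_within_30ms_for_95_percent(self, leg_trial):
        _, markers, gt = leg_trial
        pk = K.process_trial(markers)
        d = np.abs(pk.acc_peak_times[:, None] - gt.true_acc_peak_times[None, :]).min(axis=1)
        assert np.mean(d < 0.03) >= 0.95

    def test_events_inside_cycled_span_and_positive(self, leg_trial):
        _, markers, _ = leg_trial
        pk = K.process_trial(markers)
        assert np.all(pk.acc_peak_times >= pk.cycle_peak_times[0])
        assert np.all(pk.acc_peak_times <= pk.cycle_peak_times[-1])
        assert np.all(pk.acc_peak_magnitudes > 0)
        assert np.all(np.diff(pk.acc_peak_times) > 0)


class TestCycleDurationStats:
    def _table(self, arm, leg):
        rows = []
        for p, (a, l) in enumerate(zip(arm, leg)):
            for d in (a, a):
                rows.append({"participant_id": f"P{p}", "day": 1, "condition": "armMot", "cycle_duration": d})
            for d in (l, l):
                rows.append({"participant_id": f"P{p}", "day": 1, "condition": "legMot", "cycle_duration": d})
        return pd.DataFrame(rows)

    def test_identical_generators_give_unit_correlation(self):
        vals = np.linspace(0.9, 1.5, 8)
        _, pairs = K.cycle_duration_stats(self._table(vals, vals))
        r = np.corrcoef(pairs["armMot"], pairs["legMot"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_independent_generators_give_near_zero_correlation(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(50):
            arm = rng.normal(1.3, 0.2, 10)
            leg = rng.normal(1.07, 0.2, 10)
            _, pairs = K.cycle_duration_stats(self._table(arm, leg))
            rs.append(np.corrcoef(pairs["armMot"], pairs["legMot"])[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_pair_count_excludes_missing_cells(self):
        df = self._table(np.array([1.2, 1.3]), np.array([1.0, 1.1]))
        df = df[~((df.participant_id == "P1") & (df.condition == "legMot"))]
        _, pairs = K.cycle_duration_stats(df)
        assert len(pairs) == 1
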
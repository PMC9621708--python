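"""Pairing, surrogate construction, IPU gating, epochs, peak-window means."""

import numpy as np
import pandas as pd
import pytest

from limbspeech import coupling as C
from limbspeech.acoustics import AcousticTracks, IPUAnnotation
from limbspeech.kinematics import PedalKinematics


def _tracks(duration=30.0, seed=0, f0_gaps=False):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 0.01)
    env = 1.0 + 0.2 * np.sin(2 * np.pi * 0.5 * t) + rng.normal(0, 0.05, t.size)
    f0 = 200.0 + rng.normal(0, 3, t.size)
    if f0_gaps:
        f0[rng.random(t.size) < 0.3] = np.nan
    from limbspeech.acoustics import zscale_per_trial

    return AcousticTracks(
        times=t, envelope_raw=env, envelope_z=zscale_per_trial(env),
        f0=f0, sex_range=(100.0, 300.0),
    )


def _kin(duration=30.0, cycle=1.0):
    t = np.arange(0.0, duration, 0.01)
    pos = 8 * np.sin(2 * np.pi * t / cycle)
    acc = -((2 * np.pi / cycle) ** 2) * 0.08 * np.sin(2 * np.pi * t / cycle)
    cyc = np.arange(cycle / 4, duration, cycle)
    accp = np.arange(3 * cycle / 4, duration, cycle)
    return PedalKinematics(
        times=t, position=pos, angle=np.zeros_like(t), acceleration=acc,
        cycle_peak_times=cyc, cycle_durations=np.diff(cyc),
        acc_peak_times=accp, acc_peak_magnitudes=np.full(accp.size, 3.0),
    )


class TestPairing:
    def test_equal_lengths_no_truncation(self):
        pt = C.pair_trial("s", _tracks(30), "m", _kin(30))
        assert pt.common_length == pytest.approx(30.0, abs=0.02)
        assert pt.tracks.times.size == 3000

    def test_longer_motion_truncated(self):
        pt = C.pair_trial("s", _tracks(30), "m", _kin(40))
        assert pt.common_length == pytest.approx(30.0, abs=0.02)
        assert pt.kinematics.acc_peak_times.max() < 30.0

    def test_insufficient_overlap_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            C.pair_trial("s", _tracks(30), "m", _kin(4.0))

    def test_peak_times_stable_through_pairing(self):
        kin = _kin(40)
        pt = C.pair_trial("s", _tracks(30), "m", kin)
        orig = kin.acc_peak_times[kin.acc_peak_times < 30.0]
        assert np.allclose(pt.kinematics.acc_peak_times, orig, atol=0.011)


class TestSurrogates:
    def test_same_participant_pool_rejected(self):
        speech = [("s1", "P01", _tracks())]
        pool = [("m1", "P01", _kin())]
        with pytest.raises(ValueError, match="no donor"):
            C.make_surrogate_pairing(speech, pool, np.random.default_rng(0))

    def test_donor_never_same_participant(self):
        speech = [(f"s{i}", f"P{i:02d}", _tracks(seed=i)) for i in range(4)]
        pool = [(f"m{i}", f"P{i:02d}", _kin()) for i in range(4)]
        paired, mapping = C.make_surrogate_pairing(speech, pool, np.random.default_rng(1))
        for pt in paired:
            assert pt.surrogate
            assert pt.donor_participant_id != pt.speech_trial_id.replace("s", "P").zfill(3)
        for _, row in mapping.iterrows():
            assert row.speech_trial[1:] != row.donor_trial[1:]

    def test_truncation_to_shorter_stream(self):
        speech = [("s1", "P01", _tracks(30))]
        pool = [("m1", "P02", _kin(40))]
        paired, _ = C.make_surrogate_pairing(speech, pool, np.random.default_rng(0))
        assert paired[0].common_length == pytest.approx(30.0, abs=0.02)

    def test_seeded_mapping_reproducible(self):
        speech = [(f"s{i}", f"P{i:02d}", _tracks(seed=i)) for i in range(5)]
        pool = [(f"m{i}", f"P{i:02d}", _kin()) for i in range(5)]
        _, m1 = C.make_surrogate_pairing(speech, pool, np.random.default_rng(7))
        _, m2 = C.make_surrogate_pairing(speech, pool, np.random.default_rng(7))
        pd.testing.assert_frame_equal(m1, m2)


class TestPeakGating:
    def test_boundary_rule(self):
        ipus = IPUAnnotation(intervals=np.array([[0.0, 10.0]]), source="manual")
        peaks = np.array([0.1, 1.0, 5.0, 9.0, 9.9])
        mags = np.arange(5.0)
        kept_t, kept_m = C.select_peaks_within_ipus(peaks, mags, ipus)
        assert kept_t.tolist() == [1.0, 5.0, 9.0]

    def test_no_ipus_retains_nothing(self):
        ipus = IPUAnnotation(intervals=np.empty((0, 2)), source="auto")
        kept_t, _ = C.select_peaks_within_ipus(np.array([1.0, 2.0]), np.ones(2), ipus)
        assert kept_t.size == 0

    def test_count_conservation(self):
        ipus = IPUAnnotation(intervals=np.array([[0.0, 3.0], [5.0, 8.0]]), source="manual")
        peaks = np.linspace(0.3, 7.7, 20)
        kept_t, _ = C.select_peaks_within_ipus(peaks, np.ones(20), ipus)
        dropped = peaks.size - kept_t.size
        assert kept_t.size + dropped == peaks.size
        assert kept_t.size < peaks.size


class TestEpochs:
    def _paired(self, duration=30.0, **kw):
        return C.pair_trial("s", _tracks(duration, **kw), "m", _kin(duration))

    def test_constant_track_constant_epochs(self):
        pt = self._paired()
        pt.tracks.envelope_z = np.full_like(pt.tracks.envelope_z, 7.0)
        es = C.extract_peak_epochs(pt, np.array([5.0, 10.0]), np.ones(2), "envelope_z",
                                   participant_id="P01", sex="f", day=1, condition="legMot")
        assert es.matrix.shape == (2, 41)
        assert np.allclose(es.matrix, 7.0)

    def test_peak_near_trial_start_excluded(self):
        pt = self._paired()
        es = C.extract_peak_epochs(pt, np.array([0.1, 5.0]), np.ones(2), "envelope_z")
        assert es.matrix.shape[0] == 1

    def test_f0_epochs_drop_sparse_rows(self):
        pt = self._paired(f0_gaps=True)
        pt.tracks.f0[400:600] = np.nan  # fully unvoiced stretch
        es = C.extract_peak_epochs(pt, np.array([5.0, 15.0]), np.ones(2), "f0")
        assert es.matrix.shape[0] == 1

    def test_alignment_shift_property(self):
        # shifting the acoustic track by +k samples shifts the average
        # epoch extremum by +k samples
        pt = self._paired()
        t = pt.tracks.times
        bump = np.exp(-((t - 10.0) ** 2) / (2 * 0.03**2))
        for k in (0, 3):
            pt.tracks.envelope_z = np.roll(bump, k)
            es = C.extract_peak_epochs(pt, np.array([10.0]), np.ones(1), "envelope_z")
            assert np.argmax(es.matrix[0]) == 20 + k

    def test_epoch_center_is_t_accpeak(self):
        pt = self._paired()
        es = C.extract_peak_epochs(pt, np.array([12.344]), np.ones(1), "envelope_z")
        # centre sample within 5 ms of T_accPeak
        assert abs(round(12.344 * 100) / 100 - 12.344) <= 0.005
        assert es.matrix.shape == (1, 41)


class TestPeakWindowMean:
    def test_constant_track(self):
        t = np.arange(0, 10, 0.01)
        assert C.peak_window_mean(t, np.full(t.size, 7.0), 5.0) == pytest.approx(7.0)

    def test_linear_ramp_symmetry(self):
        t = np.arange(0, 10, 0.01)
        v = 2.0 * t
        assert C.peak_window_mean(t, v, 5.0) == pytest.approx(10.0, abs=1e-9)

    def test_window_outside_track_missing(self):
        t = np.arange(0, 10, 0.01)
        assert np.isnan(C.peak_window_mean(t, t, 0.01))

    def test_kernel_average_matches_analytic(self):
        # mean of a Gaussian bump over +/-25 ms around its centre
        w = 0.04
        t = np.arange(0, 10, 0.01)
        v = np.exp(-((t - 5.0) ** 2) / (2 * w**2))
        got = C.peak_window_mean(t, v, 5.0)
        tt = t[np.abs(t - 5.0) <= 0.025 + 1e-9] - 5.0
        expected = np.mean(np.exp(-(tt**2) / (2 * w**2)))
        assert got == pytest.approx(expected, rel=0.05)


class TestCellAverages:
    def _epochs(self, mats, conds):
        meta = pd.DataFrame(
            {
                "participant_id": ["P01"] * len(mats),
                "sex": ["female"] * len(mats),
                "day": [1] * len(mats),
                "condition": conds,
                "t_acc_peak": np.arange(len(mats), dtype=float),
                "acc_peak_magnitude": np.ones(len(mats)),
            }
        )
        return C.EpochSet(measure="envelope_z", matrix=np.asarray(mats), meta=meta)

    def test_identical_epochs_average_to_themselves(self):
        row = np.linspace(0, 1, 41)
        cells = C.average_epochs_by_cell(self._epochs([row, row], ["legMot", "legMot"]))
        assert np.allclose(cells["value"].to_numpy(), row)

    def test_symmetric_deviations_cancel(self):
        base = np.sin(np.linspace(0, 3, 41))
        dev = np.cos(np.linspace(0, 5, 41))
        cells = C.average_epochs_by_cell(
            self._epochs([base + dev, base - dev], ["legMot", "legMot"])
        )
        assert np.allclose(cells["value"].to_numpy(), base, atol=1e-12)

    def test_cell_mean_variance_scales_inversely_with_n(self):
        rng = np.random.default_rng(0)
        var_by_n = {}
        for n in (4, 16):
            means = []
            for _ in range(200):
                mats = rng.normal(0, 1, (n, 41))
                cells = C.average_epochs_by_cell(self._epochs(list(mats), ["legMot"] * n))
                means.append(cells["value"].to_numpy()[0])
            var_by_n[n] = np.var(means)
        assert var_by_n[16] < var_by_n[4] / 2.5


class TestSurrogateValidity:
    def test_env50_indistinguishable_between_true_and_surrogate_under_null(
        self, tiny_track_study
    ):
        # with zero coupling, peak-window envelope values from real pairings
        # (legMot/armMot) and surrogate pairings (armBlock) are draws from
        # the same distribution
        from scipy import stats as sps

        from limbspeech.pipeline import analyze_study

        res = analyze_study(
            tiny_track_study, seed=5, fit_lmms=False, fit_gams=False, fit_f0_models=False
        )
        pm = res.peak_measures.dropna(subset=["env50"])
        true_vals = pm.loc[pm["condition"] != "armBlock", "env50"]
        surr_vals = pm.loc[pm["condition"] == "armBlock", "env50"]
        assert len(true_vals) > 100 and len(surr_vals) > 100
        assert sps.ks_2samp(true_vals, surr_vals).pvalue > 0.01
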
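"""Acoustic extraction: envelope chain, F0 tracker, IQR filter, IPUs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbspeech import acoustics as A

FS = 44100.0


def _am_tone(duration=8.0, f_mod=1.3, depth=0.5, carrier=220.0):
    t = np.arange(0, duration, 1 / FS)
    mod = 1 + depth * np.sin(2 * np.pi * f_mod * t)
    return t, mod, mod * np.sin(2 * np.pi * carrier * t)


class TestAmplitudeEnvelope:
    def test_recovers_slow_am_modulator(self):
        t, mod, x = _am_tone()
        tt, env = A.extract_amplitude_envelope(0.5 * x, FS)
        ref = np.interp(tt, t, mod)
        core = slice(100, -100)
        assert np.corrcoef(env[core], ref[core])[0, 1] > 0.99

    def test_silence_gives_zero(self):
        _, env = A.extract_amplitude_envelope(np.zeros(int(FS * 2)), FS)
        assert np.allclose(env, 0.0)

    def test_fast_am_component_attenuated(self):
        # amplitude modulation at 100 Hz sits far above the 5 Hz cutoff
        t = np.arange(0, 4, 1 / FS)
        x_slow = (1 + 0.5 * np.sin(2 * np.pi * 1.0 * t)) * np.sin(2 * np.pi * 220 * t)
        x_fast = (1 + 0.5 * np.sin(2 * np.pi * 100.0 * t)) * np.sin(2 * np.pi * 220 * t)
        _, env_s = A.extract_amplitude_envelope(0.5 * x_slow, FS)
        _, env_f = A.extract_amplitude_envelope(0.5 * x_fast, FS)
        core = slice(50, -50)
        ripple_slow = np.std(env_s[core])
        ripple_fast = np.std(env_f[core])
        assert ripple_fast < 0.05 * ripple_slow

    def test_envelope_nonnegative(self, speech_trial_audio):
        _, _, audio, _ = speech_trial_audio
        _, env = A.extract_amplitude_envelope(audio, FS)
        assert env.min() >= 0.0

    def test_impulse_timing_preserved(self):
        # a burst at t0 must keep its envelope maximum within +/-20 ms
        t0 = 2.0
        t = np.arange(0, 4, 1 / FS)
        burst = np.exp(-((t - t0) ** 2) / (2 * 0.05**2)) * np.sin(2 * np.pi * 200 * t)
        tt, env = A.extract_amplitude_envelope(0.5 * burst, FS)
        assert abs(tt[np.argmax(env)] - t0) <= 0.02


class TestZScale:
    def test_mean_zero_sd_one(self, speech_trial_audio):
        _, _, audio, _ = speech_trial_audio
        _, env = A.extract_amplitude_envelope(audio, FS)
        z = A.zscale_per_trial(env)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random(500)
        assert np.allclose(A.zscale_per_trial(x), A.zscale_per_trial(3.7 * x + 11.0))

    def test_gain_artifact_removed(self):
        # same envelope shape at two microphone gains -> identical z tracks
        x = np.abs(np.sin(np.linspace(0, 20, 2000))) + 0.1
        assert np.allclose(A.zscale_per_trial(x), A.zscale_per_trial(0.3 * x))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            A.zscale_per_trial(np.full(100, 2.0))


class TestF0Tracker:
    def test_harmonic_tone_tracked_within_2hz(self):
        t = np.arange(0, 3, 1 / FS)
        x = sum(np.sin(2 * np.pi * 150 * k * t) / k for k in range(1, 6))
        _, f0 = A.extract_f0_autocorr(0.2 * x, FS, "female")
        voiced = np.isfinite(f0)
        assert voiced.mean() > 0.9
        assert np.median(np.abs(f0[voiced] - 150.0)) < 2.0

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        _, f0 = A.extract_f0_autocorr(rng.normal(0, 0.2, int(FS * 3)), FS, "female")
        assert np.isnan(f0).mean() >= 0.95

    def test_out_of_range_tone_never_reports_out_of_range(self):
        t = np.arange(0, 2, 1 / FS)
        _, f0 = A.extract_f0_autocorr(0.3 * np.sin(2 * np.pi * 320 * t), FS, "female")
        finite = f0[np.isfinite(f0)]
        assert np.all(finite >= 100.0)
        assert np.all(finite <= 300.0)

    def test_unknown_sex_raises(self):
        with pytest.raises(ValueError, match="sex"):
            A.extract_f0_autocorr(np.zeros(int(FS)), FS, "unknown")

    def test_range_containment_on_speech(self, speech_trial_audio):
        _, _, audio, _ = speech_trial_audio
        _, f0 = A.extract_f0_autocorr(audio, FS, "female")
        finite = f0[np.isfinite(f0)]
        assert finite.size > 0
        assert finite.min() >= 100.0 and finite.max() <= 300.0


class TestIqrOutlierFilter:
    def test_single_outlier_fixture(self):
        filtered, frac = A.filter_f0_outliers(np.array([0.0, 0.0, 0.0, 0.0, 100.0]))
        assert np.isnan(filtered[-1])
        assert np.isfinite(filtered[:4]).all()
        assert frac == pytest.approx(0.2)

    def test_constant_input_discards_nothing(self):
        filtered, frac = A.filter_f0_outliers(np.full(10, 180.0))
        assert frac == 0.0
        assert np.isfinite(filtered).all()

    def test_asymmetry_of_rule(self):
        # value 1 IQR below Q1 is discarded; the mirrored value 1 IQR above
        # Q3 survives (threshold is 3 IQR above)
        base = np.array([10.0, 11, 12, 13, 14, 15, 16, 17, 18, 19])
        iqr = np.percentile(base, 75) - np.percentile(base, 25)
        low = np.concatenate([base, [np.percentile(base, 25) - 1.5 * iqr]])
        high = np.concatenate([base, [np.percentile(base, 75) + 1.5 * iqr]])
        _, frac_low = A.filter_f0_outliers(low)
        _, frac_high = A.filter_f0_outliers(high)
        assert frac_low > 0.0
        assert frac_high == 0.0

    @settings(deadline=None, max_examples=40)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent_on_separated_outlier_fixtures(self, seed):
        # idempotence holds when outliers are well separated from the bulk
        # (octave errors vs the voiced distribution); for borderline values
        # exactly at the cut a second pass can tighten the quartiles, so the
        # property is asserted on fixtures, not universally
        rng = np.random.default_rng(seed)
        f0 = rng.uniform(180, 220, 400)
        octave = rng.random(400) < 0.05
        f0[octave] = np.where(rng.random(octave.sum()) < 0.5, 400.0, 100.0)
        f0[rng.random(400) < 0.2] = np.nan
        once, _ = A.filter_f0_outliers(f0)
        twice, _ = A.filter_f0_outliers(once)
        assert np.array_equal(np.isnan(once), np.isnan(twice))
        finite = np.isfinite(once)
        assert np.array_equal(once[finite], twice[finite])

    def test_idempotent_on_hand_fixtures(self):
        for fx in ([0.0, 0, 0, 0, 100], [180.0] * 8, [150.0, 160, 170, 180, 420, 430]):
            once, _ = A.filter_f0_outliers(np.asarray(fx))
            twice, _ = A.filter_f0_outliers(once)
            assert np.array_equal(np.isnan(once), np.isnan(twice))

    def test_discard_fraction_few_percent_on_realistic_trials(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f0 = rng.normal(200, 20, 500)
            octave = rng.random(500) < 0.04
            f0[octave] *= np.where(rng.random(octave.sum()) < 0.5, 2.0, 0.5)
            _, frac = A.filter_f0_outliers(f0)
            fracs.append(frac)
        assert 0.005 < np.mean(fracs) < 0.08


class TestIpuDetection:
    def test_continuous_tone_single_interval(self):
        env = np.ones(1000)
        ann = A.detect_ipus_auto(env)
        assert len(ann.intervals) == 1
        assert ann.intervals[0][0] == 0.0

    def test_silence_no_intervals(self):
        ann = A.detect_ipus_auto(np.zeros(1000))
        assert len(ann.intervals) == 0

    def test_generator_iou_above_095(self, speech_trial_audio):
        spec, ipus, audio, _ = speech_trial_audio
        _, env = A.extract_amplitude_envelope(audio, FS)
        ann = A.detect_ipus_auto(env)
        n = int(spec.duration * 100)
        g = np.zeros(n, bool)
        h = np.zeros(n, bool)
        for s, e in ipus:
            g[int(s * 100): int(e * 100)] = True
        for s, e in ann.intervals:
            h[int(s * 100): min(int(e * 100), n)] = True
        iou = (g & h).sum() / (g | h).sum()
        assert iou > 0.95


class TestIntervalAnnotationIO:
    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "iv.txt"
        p.write_text("0.0\t3.4\tipu\n4.0\t7.0\tipu\n")
        ann = A.read_interval_annotation(p)
        assert ann.intervals.shape == (2, 2)
        assert ann.source == "manual"

    def test_reversed_interval_raises_with_line(self, tmp_path):
        p = tmp_path / "iv.txt"
        p.write_text("0.0\t3.4\tipu\n5.0\t4.0\tipu\n")
        with pytest.raises(ValueError, match=":2"):
            A.read_interval_annotation(p)

    def test_overlap_raises(self, tmp_path):
        p = tmp_path / "iv.txt"
        p.write_text("0.0\t3.4\tipu\n3.0\t5.0\tipu\n")
        with pytest.raises(ValueError, match="overlap"):
            A.read_interval_annotation(p)

    def test_textgrid_subset(self, tmp_path):
        tg = """File type = "ooTextFile"
Object class = "TextGrid"
xmin = 0
xmax = 10
tiers? <exists>
size = 1
item []:
    item [1]:
        class = "IntervalTier"
        name = "speech"
        xmin = 0
        xmax = 10
        intervals: size = 3
        intervals [1]:
            xmin = 0.0
            xmax = 1.5
            text = "silence"
        intervals [2]:
            xmin = 1.5
            xmax = 4.9
            text = "ipu"
        intervals [3]:
            xmin = 4.9
            xmax = 10.0
            text = "silence"
"""
        p = tmp_path / "trial.TextGrid"
        p.write_text(tg)
        ann = A.read_interval_annotation(p)
        assert ann.intervals.shape == (1, 2)
        assert ann.intervals[0] == pytest.approx([1.5, 4.9])

    def test_write_read_roundtrip(self, tmp_path):
        ann = A.IPUAnnotation(intervals=np.array([[0.5, 2.0], [3.0, 4.5]]), source="auto")
        p = tmp_path / "out.txt"
        A.write_interval_annotation(p, ann)
        back = A.read_interval_annotation(p)
        assert np.allclose(back.intervals, ann.intervals, atol=1e-4)
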
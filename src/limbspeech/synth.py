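"""Seeded synthetic studies of coupled biking kinematics and narrative-like speech.

Generates, for a configurable roster of participants x conditions x days, the
raw material the analysis pipeline consumes: motion-capture marker tables of a
pedal rotating in the sagittal plane (plus decoy markers), speech audio
organised into interpausal units (IPUs) with pauses, and ground-truth event
tables.  An optional "physical impulse" coupling adds a transient gain bump to
the speech amplitude (and an F0 shift) time-locked to limb acceleration peaks
whose magnitude exceeds a threshold -- the mechanism under test, made concrete
so that every downstream stage has a recovery oracle.

Two output modes exist: full audio synthesis at 44.1 kHz (the format real
recordings arrive in), and a fast track mode that emits the 100 Hz envelope
and F0 tracks directly with realistic noise, for simulation studies where
thousands of trials are needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d

from .kinematics import MarkerSeries

CONDITIONS = ("armBlock", "legMot", "armMot")

#: cycle-duration laws per condition: (pooled mean s, pooled SD s)
CYCLE_DURATION = {"legMot": (1.07, 0.29), "armMot": (1.30, 0.37)}
#: within-trial cycle-duration SD; the rest of the pooled SD is
#: between-participant (steady per-trial cadence, differing riders)
WITHIN_TRIAL_CYCLE_SD = 0.12
#: shared participant cadence SD (drives the arm-leg duration correlation)
SHARED_CADENCE_SD = 0.225
#: arm cycles are faster on day 2 (+/- half of the 0.3 s reported contrast)
ARM_DAY_SHIFT = 0.15
CYCLE_TRUNC = (0.4, 3.5)

#: crank radii (cm) calibrated so acceleration-peak medians land near the
#: reported arm/leg medians (2 and 3.5) with acceleration taken in m/s^2
RADIUS_CM = {"legMot": 8.2, "armMot": 6.9}

IPU_MEAN, IPU_SD = 3.65, 2.28
IPU_DAY2_SHIFT = 0.45
PAUSE_MEAN = 0.6
F0_BASELINE = {"male": 120.0, "female": 210.0}
F0_DAY2_SHIFT = -4.25
F0_DECLINATION = -2.0  # Hz/s within each IPU
SYLLABLE_RATE = 4.0  # Hz, raised-cosine amplitude modulation


@dataclass(frozen=True)
class CouplingParams:
    """Acceleration-peak-locked transient coupling into the speech signal.

    ``env_bump_amplitude`` is a multiplicative gain excess at the peak (0.3
    means the envelope is scaled by up to 1.3), ``f0_bump_amplitude`` an
    additive F0 shift in Hz.  The bump is a Gaussian kernel of SD
    ``bump_width`` seconds centred ``lag`` seconds after each acceleration
    peak whose magnitude is at least ``accel_threshold`` (m/s^2).
    """

    env_bump_amplitude: float = 0.0
    f0_bump_amplitude: float = 0.0
    bump_width: float = 0.04
    accel_threshold: float = 0.0
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.bump_width <= 0:
            raise ValueError("bump_width must be > 0")
        if self.env_bump_amplitude < 0:
            raise ValueError("env_bump_amplitude must be >= 0")
        if self.accel_threshold < 0:
            raise ValueError("accel_threshold must be >= 0")


@dataclass
class TrialSpec:
    """Everything needed to synthesise one trial reproducibly."""

    participant_id: str
    sex: str  # "male" | "female"
    day: int  # 1 | 2
    condition: str  # armBlock | legMot | armMot
    duration: float = 110.0
    cycle_duration_mean: float = 1.07
    cycle_duration_sd: float = 0.29
    ipu_duration_mean: float = IPU_MEAN
    ipu_duration_sd: float = IPU_SD
    pause_duration_mean: float = PAUSE_MEAN
    f0_baseline: float = 210.0
    f0_declination: float = F0_DECLINATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.cycle_duration_mean <= 0:
            raise ValueError("cycle_duration_mean must be > 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex: {self.sex!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Oracle record of what was injected into one trial."""

    true_acc_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_acc_peak_magnitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_cycle_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_ipu_intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    true_f0_track: np.ndarray | None = None  # Hz at 100 Hz, NaN outside IPUs
    true_envelope_modulator: np.ndarray | None = None  # coupling gain at 100 Hz
    coupling: CouplingParams = field(default_factory=CouplingParams)
    pedal_marker_id: str | None = None


# ---------------------------------------------------------------------------
# kinematics generation
# ---------------------------------------------------------------------------

FINE_RATE = 1000.0  # Hz, grid for the analytic phase law and ground truth


def _phase_law(
    durations: np.ndarray, total: float, depth: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rotation phase on a fine grid from per-cycle durations.

    The instantaneous base period P(t) interpolates the drawn cycle durations
    at cycle midpoints (so pedal velocity is continuous across cycles), the
    base phase is psi = integral of 2*pi/P, and effort modulation is locked to
    the revolution: theta = psi + (depth/2)*sin(2*psi), giving two effort
    phases -- hence two positive acceleration maxima -- per cycle.

    Returns (t_fine, theta, dtheta_dt, d2theta_dt2).
    """
    starts = np.concatenate(([0.0], np.cumsum(durations)))
    mids = (starts[:-1] + starts[1:]) / 2.0
    t = np.arange(0.0, total, 1.0 / FINE_RATE)
    P = np.interp(t, mids, durations)
    psid = 2 * np.pi / P
    psi = np.concatenate(([0.0], np.cumsum((psid[1:] + psid[:-1]) / 2.0))) / FINE_RATE
    a = depth / 2.0
    theta = psi + a * np.sin(2 * psi)
    dtheta = psid * (1 + 2 * a * np.cos(2 * psi))
    psidd = np.gradient(psid, 1.0 / FINE_RATE)
    d2theta = psidd * (1 + 2 * a * np.cos(2 * psi)) - 4 * a * psid**2 * np.sin(2 * psi)
    return t, theta, dtheta, d2theta


def _analytic_ground_truth(
    t: np.ndarray,
    theta: np.ndarray,
    dtheta: np.ndarray,
    d2theta: np.ndarray,
    radius_m: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cycle-peak times and positive acceleration-peak events from the phase law."""
    acc = radius_m * (d2theta * np.cos(theta) - dtheta**2 * np.sin(theta))
    is_max = np.zeros(t.size, dtype=bool)
    is_max[1:-1] = (acc[1:-1] > acc[:-2]) & (acc[1:-1] >= acc[2:]) & (acc[1:-1] > 0)
    # refine each maximum with a parabola through its neighbours
    idx = np.flatnonzero(is_max)
    y0, y1, y2 = acc[idx - 1], acc[idx], acc[idx + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    acc_times = t[idx] + shift / FINE_RATE
    acc_mags = y1 - 0.25 * (y0 - y2) * shift
    # position peaks: theta crossing pi/2 (mod 2*pi); theta is monotone
    targets = np.arange(np.pi / 2, theta[-1], 2 * np.pi)
    targets = targets[targets > theta[0]]
    cyc_times = np.interp(targets, theta, t)

    # the piecewise-linear cadence interpolation can create tiny spurious
    # maxima next to true ones, and cadence changes can nearly merge the two
    # effort peaks; enforce a minimum separation of 0.2 cycles (the genuine
    # effort peaks sit ~0.3 cycles apart), keeping the larger peak, and drop
    # negligible maxima
    if acc_times.size:
        keep_mask = acc_mags > 0.1 * np.median(acc_mags)
        acc_times, acc_mags = acc_times[keep_mask], acc_mags[keep_mask]
        med_cycle = float(np.median(np.diff(cyc_times))) if cyc_times.size > 1 else 1.0
        min_sep = 0.2 * med_cycle
        kept_t, kept_m = [], []
        for tt_, mm_ in zip(acc_times, acc_mags):
            if kept_t and tt_ - kept_t[-1] < min_sep:
                if mm_ > kept_m[-1]:
                    kept_t[-1], kept_m[-1] = tt_, mm_
            else:
                kept_t.append(tt_)
                kept_m.append(mm_)
        acc_times = np.asarray(kept_t)
        acc_mags = np.asarray(kept_m)
    return cyc_times, acc_times, acc_mags


def simulate_biking_kinematics(
    spec: TrialSpec,
    rate: float = 200.0,
    rng: np.random.Generator | None = None,
    noise_sd_cm: float = 0.01,
    modulation_depth: float = 0.3,
    radius_cm: float | None = None,
) -> tuple[MarkerSeries, GroundTruth]:
    """Simulate the pedal marker (plus decoys) for one biking trial.

    Vertical position is R*sin(theta(t)) with per-cycle durations drawn from a
    truncated normal on ``CYCLE_TRUNC`` and phase-rate effort modulation.
    Ground-truth cycle-peak and acceleration-peak events come from the
    analytic phase law, not from the sampled signal.
    """
    if rate < 100:
        raise ValueError("rate must be >= 100 Hz")
    if spec.condition == "armBlock":
        raise ValueError("armBlock trials have no kinematics")
    rng = spec.rng() if rng is None else rng
    if radius_cm is None:
        radius_cm = RADIUS_CM.get(spec.condition, 8.2)
    radius_m = radius_cm / 100.0

    # draw cycle durations until the trial is covered
    mean, sd = spec.cycle_duration_mean, spec.cycle_duration_sd
    lo, hi = CYCLE_TRUNC
    n_guess = max(8, int(np.ceil(spec.duration / max(lo, mean - 3 * sd))) + 4)
    if sd > 0:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        durations = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_guess, random_state=rng)
    else:
        durations = np.full(n_guess, mean)
    starts = np.concatenate(([0.0], np.cumsum(durations)))
    if starts[1] > spec.duration:
        raise ValueError("trial too short: duration covers less than one cycle")
    n_cycles = int(np.searchsorted(starts[1:], spec.duration, side="left") + 1)
    durations = durations[:n_cycles]

    t_fine, theta_f, dtheta_f, d2theta_f = _phase_law(
        durations, spec.duration, modulation_depth
    )
    t = np.arange(0.0, spec.duration, 1.0 / rate)
    theta = np.interp(t, t_fine, theta_f)

    z = radius_cm * np.sin(theta)  # vertical, cm
    x = radius_cm * np.cos(theta)  # fore-aft, cm
    x = x + 0.02 * t  # slow horizontal drift of the bike
    y = np.zeros_like(t)  # lateral
    if noise_sd_cm > 0:
        z = z + rng.normal(0, noise_sd_cm, z.shape)
        x = x + rng.normal(0, noise_sd_cm, x.shape)
        y = y + rng.normal(0, noise_sd_cm, y.shape)

    # decoy markers: one stationary, one drifting linearly
    stat = np.stack(
        [
            12.0 + rng.normal(0, noise_sd_cm, t.shape),
            -5.0 + rng.normal(0, noise_sd_cm, t.shape),
            30.0 + rng.normal(0, noise_sd_cm, t.shape),
        ],
        axis=1,
    )
    amp = radius_cm  # drifting marker matches the pedal's vertical amplitude
    drift = np.stack(
        [
            rng.normal(0, noise_sd_cm, t.shape),
            rng.normal(0, noise_sd_cm, t.shape),
            np.linspace(-amp, amp, t.size) + rng.normal(0, noise_sd_cm, t.shape),
        ],
        axis=1,
    )

    ids = ["m1", "m2", "m3"]
    pedal_pos = int(rng.integers(0, 3))
    coords: dict[str, np.ndarray] = {}
    others = [stat, drift]
    j = 0
    for i, mid in enumerate(ids):
        if i == pedal_pos:
            coords[mid] = np.stack([x, y, z], axis=1)
        else:
            coords[mid] = others[j]
            j += 1

    cyc_times, acc_times, acc_mags = _analytic_ground_truth(
        t_fine, theta_f, dtheta_f, d2theta_f, radius_m
    )
    gt = GroundTruth(
        true_acc_peak_times=acc_times,
        true_acc_peak_magnitudes=acc_mags,
        true_cycle_peak_times=cyc_times,
        pedal_marker_id=ids[pedal_pos],
    )
    return MarkerSeries(times=t, coords=coords), gt


# ---------------------------------------------------------------------------
# speech generation
# ---------------------------------------------------------------------------

def simulate_ipu_plan(
    spec: TrialSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Alternating pause/speech intervals tiling [0, duration).

    Speech (IPU) durations follow a gamma matched to the trial's mean/SD;
    pauses a lognormal with the trial's mean.  A ``pause_duration_mean`` of 0
    yields a single IPU covering the whole trial.  Returns an (n, 2) array of
    [start, end) IPU intervals.
    """
    rng = spec.rng() if rng is None else rng
    dur = spec.duration
    if spec.pause_duration_mean <= 0:
        return np.array([[0.0, dur]])
    m, s = spec.ipu_duration_mean, spec.ipu_duration_sd
    shape = (m / s) ** 2 if s > 0 else None
    scale = s**2 / m if s > 0 else None
    # lognormal parameterised to the requested arithmetic mean
    sigma = 0.5
    mu = np.log(spec.pause_duration_mean) - sigma**2 / 2

    ipus = []
    t = float(rng.lognormal(mu, sigma))  # leading pause
    while t < dur:
        ipu = float(rng.gamma(shape, scale)) if shape else m
        ipu = max(ipu, 0.3)
        end = min(t + ipu, dur)
        ipus.append([t, end])
        t = end + float(rng.lognormal(mu, sigma))
    return np.asarray(ipus) if ipus else np.empty((0, 2))


def _coupling_gain(
    t: np.ndarray,
    acc_peak_times: np.ndarray,
    acc_peak_mags: np.ndarray,
    coupling: CouplingParams,
) -> np.ndarray:
    """1 + beta_env * sum of Gaussian kernels at above-threshold peaks."""
    gain = np.ones_like(t)
    if coupling.env_bump_amplitude == 0 or acc_peak_times.size == 0:
        return gain
    w = coupling.bump_width
    sel = acc_peak_mags >= coupling.accel_threshold
    for tp in acc_peak_times[sel]:
        c = tp + coupling.lag
        i0, i1 = np.searchsorted(t, [c - 5 * w, c + 5 * w])
        seg = t[i0:i1]
        gain[i0:i1] += coupling.env_bump_amplitude * np.exp(-((seg - c) ** 2) / (2 * w**2))
    return gain


def _f0_shift(
    t: np.ndarray,
    acc_peak_times: np.ndarray,
    acc_peak_mags: np.ndarray,
    coupling: CouplingParams,
) -> np.ndarray:
    shift = np.zeros_like(t)
    if coupling.f0_bump_amplitude == 0 or acc_peak_times.size == 0:
        return shift
    w = coupling.bump_width
    sel = acc_peak_mags >= coupling.accel_threshold
    for tp in acc_peak_times[sel]:
        c = tp + coupling.lag
        i0, i1 = np.searchsorted(t, [c - 5 * w, c + 5 * w])
        seg = t[i0:i1]
        shift[i0:i1] += coupling.f0_bump_amplitude * np.exp(-((seg - c) ** 2) / (2 * w**2))
    return shift


def _f0_contour(spec: TrialSpec, t: np.ndarray, ipus: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Piecewise F0 with per-IPU declination and slow jitter; NaN outside IPUs."""
    f0 = np.full_like(t, np.nan)
    jitter = gaussian_filter1d(rng.normal(0, 4.0, t.size), max(t.size * 0.002, 2))
    for start, end in ipus:
        m = (t >= start) & (t < end)
        f0[m] = spec.f0_baseline + spec.f0_declination * (t[m] - start) + jitter[m]
    return f0


def _syllabic_modulator(t: np.ndarray, ipus: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Raised-cosine syllabic amplitude modulation (~4 Hz), zero outside IPUs."""
    mod = np.zeros_like(t)
    for start, end in ipus:
        m = (t >= start) & (t < end)
        rate = SYLLABLE_RATE * float(rng.uniform(0.85, 1.15))
        phase = float(rng.uniform(0, 2 * np.pi))
        mod[m] = 0.55 + 0.45 * np.cos(2 * np.pi * rate * (t[m] - start) + phase)
    return mod


def simulate_speech_audio(
    spec: TrialSpec,
    ipus: np.ndarray,
    acc_peak_times: np.ndarray,
    acc_peak_mags: np.ndarray,
    coupling: CouplingParams,
    audio_rate: float = 44100.0,
    rng: np.random.Generator | None = None,
    n_harmonics: int = 8,
    noise_floor_db: float = -50.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesise narrative-like speech audio for one trial.

    Within IPUs the signal is a harmonic source (1/k rolloff) whose F0 carries
    declination and jitter, amplitude-modulated at the syllabic rate and by the
    acceleration-locked coupling gain; outside IPUs a low noise floor remains.
    Returns (audio float array in [-1, 1], ground truth with 100 Hz tracks).
    """
    if not (50.0 < spec.f0_baseline < 400.0):
        raise ValueError("f0_baseline outside (50, 400) Hz")
    rng = spec.rng() if rng is None else rng
    acc_peak_times = np.asarray(acc_peak_times, dtype=float)
    acc_peak_mags = np.asarray(acc_peak_mags, dtype=float)

    n = int(round(spec.duration * audio_rate))
    t = np.arange(n) / audio_rate
    f0 = _f0_contour(spec, t, ipus, rng)
    f0 = f0 + _f0_shift(t, acc_peak_times, acc_peak_mags, coupling)
    syl = _syllabic_modulator(t, ipus, rng)
    gain = _coupling_gain(t, acc_peak_times, acc_peak_mags, coupling)

    voiced = np.isfinite(f0)
    f0_filled = np.where(voiced, f0, 0.0)
    phase = 2 * np.pi * np.cumsum(f0_filled) / audio_rate
    sig = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        sig += np.sin(k * phase) / k
    # smooth IPU onsets/offsets to avoid clicks (10 ms ramps)
    amp = syl * gain * voiced
    amp = gaussian_filter1d(amp, 0.005 * audio_rate)
    sig = sig * amp

    rms = np.sqrt(np.mean(sig[voiced] ** 2)) if voiced.any() else 1.0
    noise = rng.normal(0, rms * 10 ** (noise_floor_db / 20.0), n)
    audio = sig + noise
    peak = np.max(np.abs(audio))
    if peak > 0:
        audio = 0.5 * audio / peak

    # ground-truth tracks at 100 Hz
    t100 = np.arange(0.0, spec.duration, 0.01)
    gt_mod = _coupling_gain(t100, acc_peak_times, acc_peak_mags, coupling)
    gt_f0 = _f0_contour(spec, t100, ipus, np.random.default_rng(0)) * np.nan  # shape only
    # re-evaluate the true contour on the 100 Hz grid (without regenerating jitter,
    # interpolate the audio-rate contour)
    gt_f0 = np.interp(t100, t, np.where(voiced, f0, np.nan))
    out = ~_in_intervals(t100, ipus)
    gt_f0[out] = np.nan
    gt = GroundTruth(
        true_acc_peak_times=acc_peak_times,
        true_acc_peak_magnitudes=acc_peak_mags,
        true_ipu_intervals=np.asarray(ipus, dtype=float).reshape(-1, 2),
        true_f0_track=gt_f0,
        true_envelope_modulator=gt_mod,
        coupling=coupling,
    )
    return audio, gt


def _in_intervals(t: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    mask = np.zeros(t.shape, dtype=bool)
    for start, end in np.asarray(intervals).reshape(-1, 2):
        mask |= (t >= start) & (t < end)
    return mask


def simulate_tracks(
    spec: TrialSpec,
    ipus: np.ndarray,
    acc_peak_times: np.ndarray,
    acc_peak_mags: np.ndarray,
    coupling: CouplingParams,
    rng: np.random.Generator | None = None,
    rate: float = 100.0,
    env_noise_sd: float = 0.12,
    env_noise_rho: float = 0.6,
    f0_noise_sd: float = 1.5,
    f0_dropout: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Directly synthesise the 100 Hz envelope and F0 tracks for one trial.

    Emulates what the extraction chain would recover from the audio: the
    syllabic modulator times the coupling gain plus AR(1) measurement noise
    for the envelope; the true F0 contour plus white tracking error and random
    unvoiced dropouts for F0.  Returns (times, envelope_raw, f0, ground_truth).
    """
    rng = spec.rng() if rng is None else rng
    acc_peak_times = np.asarray(acc_peak_times, dtype=float)
    acc_peak_mags = np.asarray(acc_peak_mags, dtype=float)
    t = np.arange(0.0, spec.duration, 1.0 / rate)
    syl = _syllabic_modulator(t, ipus, rng)
    gain = _coupling_gain(t, acc_peak_times, acc_peak_mags, coupling)
    f0 = _f0_contour(spec, t, ipus, rng)
    f0 = f0 + _f0_shift(t, acc_peak_times, acc_peak_mags, coupling)

    # per-trial microphone gain artifact (removed downstream by z-scaling)
    mic_gain = float(np.exp(rng.normal(0.0, 0.2)))

    # AR(1) measurement noise on the envelope
    from scipy.signal import lfilter

    innov = rng.normal(0.0, env_noise_sd * np.sqrt(1 - env_noise_rho**2), t.size)
    innov[0] = rng.normal(0.0, env_noise_sd)
    ar = lfilter([1.0], [1.0, -env_noise_rho], innov)
    env = mic_gain * np.clip(syl * gain + ar * (syl > 0), 0.0, None)
    env = env + np.abs(rng.normal(0.0, 0.003, t.size))  # silence floor

    f0_meas = f0 + rng.normal(0.0, f0_noise_sd, t.size)
    drop = rng.random(t.size) < f0_dropout
    f0_meas[drop] = np.nan

    gt = GroundTruth(
        true_acc_peak_times=acc_peak_times,
        true_acc_peak_magnitudes=acc_peak_mags,
        true_ipu_intervals=np.asarray(ipus, dtype=float).reshape(-1, 2),
        true_f0_track=f0,
        true_envelope_modulator=gain,
        coupling=coupling,
    )
    return t, env, f0_meas, gt


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Roster and generator settings for a whole synthetic study."""

    n_participants: int = 22
    n_female: int = 16
    days: tuple[int, ...] = (1, 2)
    conditions: tuple[str, ...] = CONDITIONS
    trial_duration: float = 110.0
    coupling: CouplingParams = field(default_factory=CouplingParams)
    mode: str = "audio"  # "audio" | "tracks"
    audio_rate: float = 44100.0
    marker_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.n_female > self.n_participants:
            raise ValueError("n_female exceeds n_participants")
        if self.mode not in ("audio", "tracks"):
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass
class SimulatedTrial:
    spec: TrialSpec
    markers: MarkerSeries | None
    ipus: np.ndarray
    ground_truth: GroundTruth
    audio: np.ndarray | None = None  # audio mode
    track_times: np.ndarray | None = None  # tracks mode
    envelope: np.ndarray | None = None
    f0: np.ndarray | None = None


@dataclass
class StudyBundle:
    config: StudyConfig
    seed: int
    manifest: pd.DataFrame
    trials: dict[str, SimulatedTrial]


def _trial_seed(study_seed: int, participant: int, day: int, condition: str) -> int:
    ss = np.random.SeedSequence([study_seed, participant, day, CONDITIONS.index(condition)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study(
    config: StudyConfig | None = None, seed: int = 0, outdir: str | Path | None = None
) -> StudyBundle:
    """Generate a full study; deterministic given (config, seed).

    armBlock trials carry speech but no kinematics (surrogate pairing happens
    in the analysis).  If ``outdir`` is given, WAV/CSV/interval files and the
    manifest are written there.
    """
    config = config or StudyConfig()
    roster_rng = np.random.default_rng(np.random.SeedSequence([seed, 10_000]))
    rows = []
    trials: dict[str, SimulatedTrial] = {}

    # participant-level latent traits
    shared_cadence = roster_rng.normal(0.0, 1.0, config.n_participants)
    f0_person = roster_rng.normal(0.0, 15.0, config.n_participants)
    cond_specific = {
        c: roster_rng.normal(0.0, 1.0, config.n_participants) for c in ("legMot", "armMot")
    }

    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        sex = "female" if p < config.n_female else "male"
        for day in config.days:
            for cond in config.conditions:
                tseed = _trial_seed(seed, p, day, cond)
                if cond in CYCLE_DURATION:
                    pooled_mean, pooled_sd = CYCLE_DURATION[cond]
                    if cond == "armMot":
                        pooled_mean = pooled_mean + (ARM_DAY_SHIFT if day == 1 else -ARM_DAY_SHIFT)
                    sd_between = np.sqrt(max(pooled_sd**2 - WITHIN_TRIAL_CYCLE_SD**2, 1e-6))
                    spec_sd = np.sqrt(max(sd_between**2 - SHARED_CADENCE_SD**2, 1e-6))
                    mean_p = (
                        pooled_mean
                        + SHARED_CADENCE_SD * shared_cadence[p]
                        + spec_sd * cond_specific[cond][p]
                    )
                    mean_p = float(np.clip(mean_p, 0.55, 2.8))
                    cyc_mean, cyc_sd = mean_p, WITHIN_TRIAL_CYCLE_SD
                else:
                    cyc_mean, cyc_sd = 1.0, 0.0
                spec = TrialSpec(
                    participant_id=pid,
                    sex=sex,
                    day=day,
                    condition=cond,
                    duration=config.trial_duration,
                    cycle_duration_mean=cyc_mean,
                    cycle_duration_sd=cyc_sd,
                    ipu_duration_mean=IPU_MEAN + (IPU_DAY2_SHIFT if day == 2 else 0.0),
                    ipu_duration_sd=IPU_SD,
                    pause_duration_mean=PAUSE_MEAN,
                    f0_baseline=F0_BASELINE[sex] + f0_person[p] + (F0_DAY2_SHIFT if day == 2 else 0.0),
                    seed=tseed,
                )
                rng = spec.rng()
                if cond == "armBlock":
                    markers, kin_gt = None, GroundTruth()
                else:
                    markers, kin_gt = simulate_biking_kinematics(spec, rate=config.marker_rate, rng=rng)
                ipus = simulate_ipu_plan(spec, rng)
                if config.mode == "audio":
                    audio, gt = simulate_speech_audio(
                        spec,
                        ipus,
                        kin_gt.true_acc_peak_times,
                        kin_gt.true_acc_peak_magnitudes,
                        config.coupling,
                        audio_rate=config.audio_rate,
                        rng=rng,
                    )
                    trial = SimulatedTrial(spec, markers, ipus, gt, audio=audio)
                else:
                    tt, env, f0, gt = simulate_tracks(
                        spec,
                        ipus,
                        kin_gt.true_acc_peak_times,
                        kin_gt.true_acc_peak_magnitudes,
                        config.coupling,
                        rng=rng,
                    )
                    trial = SimulatedTrial(
                        spec, markers, ipus, gt, track_times=tt, envelope=env, f0=f0
                    )
                gt = trial.ground_truth
                gt.true_cycle_peak_times = kin_gt.true_cycle_peak_times
                gt.pedal_marker_id = kin_gt.pedal_marker_id
                if cond == "armBlock":
                    gt.true_acc_peak_times = np.empty(0)
                    gt.true_acc_peak_magnitudes = np.empty(0)
                trial_id = f"{pid}_d{day}_{cond}"
                trials[trial_id] = trial
                rows.append(
                    {
                        "trial_id": trial_id,
                        "participant_id": pid,
                        "sex": sex,
                        "day": day,
                        "condition": cond,
                        "seed": tseed,
                        "has_kinematics": cond != "armBlock",
                    }
                )

    manifest = pd.DataFrame(rows)
    bundle = StudyBundle(config=config, seed=seed, manifest=manifest, trials=trials)
    if outdir is not None:
        write_study(bundle, outdir)
    return bundle


def write_study(bundle: StudyBundle, outdir: str | Path) -> pd.DataFrame:
    """Write a StudyBundle to disk in the pipeline's file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = bundle.manifest.copy()
    audio_paths, marker_paths, ann_paths = [], [], []
    for trial_id, trial in bundle.trials.items():
        stem = outdir / trial_id
        if trial.audio is not None:
            wavfile.write(
                str(stem) + ".wav",
                int(bundle.config.audio_rate),
                np.round(trial.audio * 32767).astype(np.int16),
            )
            audio_paths.append(trial_id + ".wav")
        else:
            pd.DataFrame(
                {
                    "time_s": trial.track_times,
                    "envelope_raw": trial.envelope,
                    "f0_hz": trial.f0,
                }
            ).to_csv(str(stem) + "_tracks.csv", index=False)
            audio_paths.append(trial_id + "_tracks.csv")
        if trial.markers is not None:
            frames = []
            for mid, xyz in trial.markers.coords.items():
                frames.append(
                    pd.DataFrame(
                        {
                            "time_s": trial.markers.times,
                            "marker_id": mid,
                            "x_cm": xyz[:, 0],
                            "y_cm": xyz[:, 1],
                            "z_cm": xyz[:, 2],
                        }
                    )
                )
            pd.concat(frames).to_csv(str(stem) + "_markers.csv", index=False, float_format="%.5f")
            marker_paths.append(trial_id + "_markers.csv")
        else:
            marker_paths.append("")
        with open(str(stem) + "_ipus.txt", "w") as fh:
            for start, end in trial.ipus:
                fh.write(f"{start:.4f}\t{end:.4f}\tipu\n")
        ann_paths.append(trial_id + "_ipus.txt")
        gt = trial.ground_truth
        events = pd.DataFrame(
            {
                "event_type": (
                    ["acc_peak"] * gt.true_acc_peak_times.size
                    + ["cycle_peak"] * gt.true_cycle_peak_times.size
                ),
                "time_s": np.concatenate([gt.true_acc_peak_times, gt.true_cycle_peak_times]),
                "magnitude": np.concatenate(
                    [gt.true_acc_peak_magnitudes, np.full(gt.true_cycle_peak_times.size, np.nan)]
                ),
            }
        )
        events.to_csv(str(stem) + "_truth_events.csv", index=False, float_format="%.6f")
        with open(str(stem) + "_truth.json", "w") as fh:
            json.dump(
                {
                    "coupling": asdict(gt.coupling),
                    "pedal_marker_id": gt.pedal_marker_id,
                    "seed": trial.spec.seed,
                },
                fh,
                indent=1,
            )
    manifest["audio_path"] = audio_paths
    manifest["marker_path"] = marker_paths
    manifest["annotation_path"] = ann_paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
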
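"""Acoustic measures at 100 Hz: amplitude envelope, F0, and interpausal units.

The amplitude envelope chain mirrors the standard speech-intensity proxy:
downsample to 11,025 Hz, take the magnitude of the analytic (Hilbert) signal,
low-pass it with a 5 Hz Hanning-window FIR, smooth with a Gaussian-weighted
moving average over 1,000 samples, and resample to 100 Hz.  F0 is tracked by
frame-wise normalised autocorrelation inside sex-specific ranges (50-250 Hz
for males, 100-300 Hz for females) with an asymmetric inter-quartile outlier
filter applied per trial.  Interpausal units (IPUs) -- uninterrupted stretches
of speech between silent pauses -- can be read from annotation files or
detected automatically from the envelope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

TRACK_RATE = 100.0  # Hz
ENVELOPE_RATE = 11025.0  # Hz, intermediate rate for envelope and F0
F0_RANGE = {"male": (50.0, 250.0), "female": (100.0, 300.0)}


@dataclass
class AcousticTracks:
    """Per-trial 100 Hz acoustic measures."""

    times: np.ndarray
    envelope_raw: np.ndarray
    envelope_z: np.ndarray
    f0: np.ndarray  # Hz, NaN where unvoiced/discarded
    sex_range: tuple[float, float]
    meta: dict = field(default_factory=dict)


@dataclass
class IPUAnnotation:
    """Sorted, non-overlapping [start, end) speech intervals."""

    intervals: np.ndarray  # (n, 2) seconds
    source: str  # manual | auto | ground_truth

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size and (np.any(iv[:, 1] <= iv[:, 0]) or np.any(np.diff(iv[:, 0]) < 0)):
            raise ValueError("intervals must be sorted with end > start")
        if iv.shape[0] > 1 and np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("intervals overlap")
        self.intervals = iv


# ---------------------------------------------------------------------------
# amplitude envelope
# ---------------------------------------------------------------------------

def extract_amplitude_envelope(
    samples: np.ndarray,
    rate: float = 44100.0,
    fir_cutoff_hz: float = 5.0,
    gauss_window: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """100 Hz amplitude envelope of a mono speech signal.

    Chain: downsample to 11,025 Hz -> |Hilbert analytic signal| -> Hanning
    FIR low-pass at ``fir_cutoff_hz`` -> Gaussian moving average over
    ``gauss_window`` samples (SD = window/8) -> linear resample to 100 Hz.
    All filters are symmetric, hence zero phase.  Returns (times, envelope).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("audio must be mono")
    n_clipped = np.mean(np.abs(samples) >= 0.999)
    if n_clipped >= 0.01:
        import warnings

        warnings.warn("input audio appears clipped", stacklevel=2)
    if abs(rate - ENVELOPE_RATE) > 1e-6:
        # 44,100 -> 11,025 is an exact factor of 4
        q = rate / ENVELOPE_RATE
        if abs(q - round(q)) > 1e-9:
            raise ValueError(f"cannot downsample {rate} Hz to {ENVELOPE_RATE} Hz")
        samples = signal.resample_poly(samples, 1, int(round(q)))
    fs = ENVELOPE_RATE
    env = np.abs(signal.hilbert(samples))
    ntaps = 2 * int(fs / fir_cutoff_hz) + 1
    fir = signal.firwin(ntaps, fir_cutoff_hz, window="hann", fs=fs)
    env = signal.fftconvolve(env, fir, mode="same")
    g = signal.windows.gaussian(gauss_window, std=gauss_window / 8)
    g = g / g.sum()
    env = signal.fftconvolve(env, g, mode="same")
    env = np.clip(env, 0.0, None)
    t_out = np.arange(0.0, samples.size / fs, 1.0 / TRACK_RATE)
    t_in = np.arange(samples.size) / fs
    return t_out, np.interp(t_out, t_in, env)


def zscale_per_trial(envelope_raw: np.ndarray) -> np.ndarray:
    """Standardise an envelope over the whole trial (mean 0, SD 1)."""
    env = np.asarray(envelope_raw, dtype=float)
    if env.size < 2:
        raise ValueError("need at least 2 samples")
    sd = env.std()
    if sd == 0:
        raise ValueError("degenerate envelope: zero variance")
    return (env - env.mean()) / sd


# ---------------------------------------------------------------------------
# F0
# ---------------------------------------------------------------------------

def extract_f0_autocorr(
    samples: np.ndarray,
    rate: float = 44100.0,
    sex: str = "female",
    f0_range: tuple[float, float] | None = None,
    voicing_threshold: float = 0.45,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    rms_floor_frac: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise autocorrelation F0 at 100 Hz with unvoiced gaps.

    Frames of 40 ms centred every 10 ms; the candidate is the highest peak of
    the normalised autocorrelation whose lag maps inside the sex range,
    refined by parabolic interpolation.  A frame is voiced iff that peak is at
    least ``voicing_threshold`` and the frame RMS is at least
    ``rms_floor_frac`` of the trial RMS.  Returns (times, f0) with NaN for
    unvoiced frames.
    """
    if f0_range is None:
        if sex not in F0_RANGE:
            raise ValueError(f"unknown sex: {sex!r}")
        f0_range = F0_RANGE[sex]
    lo, hi = f0_range
    samples = np.asarray(samples, dtype=float)
    if abs(rate - ENVELOPE_RATE) > 1e-6:
        q = rate / ENVELOPE_RATE
        if abs(q - round(q)) > 1e-9:
            raise ValueError(f"cannot downsample {rate} Hz to {ENVELOPE_RATE} Hz")
        samples = signal.resample_poly(samples, 1, int(round(q)))
    fs = ENVELOPE_RATE
    half = int(round(frame_s * fs / 2))
    frame_len = 2 * half
    lag_min = max(int(np.floor(fs / hi)), 1)
    lag_max = int(np.ceil(fs / lo))
    if lag_max >= frame_len:
        raise ValueError("frame too short for the requested F0 range")

    duration = samples.size / fs
    times = np.arange(0.0, duration, hop_s)
    centers = np.round(times * fs).astype(int)
    valid = (centers - half >= 0) & (centers + half <= samples.size)
    trial_rms = np.sqrt(np.mean(samples**2))

    f0 = np.full(times.size, np.nan)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return times, f0
    frames = np.stack([samples[centers[i] - half : centers[i] + half] for i in idx])
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    nfft = int(2 ** np.ceil(np.log2(2 * frame_len)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : frame_len]
    r0 = ac[:, 0]
    ok = r0 > 0
    acn = np.where(ok[:, None], ac / np.where(r0 == 0, 1, r0)[:, None], 0.0)

    seg = acn[:, lag_min : lag_max + 1]
    best = np.argmax(seg, axis=1) + lag_min
    peak_val = acn[np.arange(acn.shape[0]), best]
    # parabolic refinement of the lag
    can_refine = (best > 0) & (best < frame_len - 1)
    y0 = acn[np.arange(acn.shape[0]), np.clip(best - 1, 0, None)]
    y1 = peak_val
    y2 = acn[np.arange(acn.shape[0]), np.clip(best + 1, None, frame_len - 1)]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    lag = best + np.where(can_refine, np.clip(shift, -0.5, 0.5), 0.0)
    cand = fs / lag
    voiced = ok & (peak_val >= voicing_threshold) & (rms >= rms_floor_frac * trial_rms)
    voiced &= (cand >= lo) & (cand <= hi)
    f0[idx[voiced]] = cand[voiced]
    return times, f0


def filter_f0_outliers(f0: np.ndarray) -> tuple[np.ndarray, float]:
    """Asymmetric inter-quartile outlier filter, per trial.

    Discards values above Q3 + 3*IQR or below Q1 - 1*IQR (quartiles by linear
    interpolation over the non-missing values).  Returns (filtered, fraction
    discarded among non-missing values).
    """
    f0 = np.asarray(f0, dtype=float).copy()
    finite = np.isfinite(f0)
    n = int(finite.sum())
    if n < 4:
        return f0, 0.0
    q1, q3 = np.percentile(f0[finite], [25, 75])
    iqr = q3 - q1
    bad = finite & ((f0 > q3 + 3 * iqr) | (f0 < q1 - 1 * iqr))
    f0[bad] = np.nan
    return f0, float(bad.sum()) / n


# ---------------------------------------------------------------------------
# interpausal units
# ---------------------------------------------------------------------------

def detect_ipus_auto(
    envelope_raw: np.ndarray,
    rate: float = TRACK_RATE,
    threshold_frac: float = 0.1,
    bridge_s: float = 0.25,
    min_dur_s: float = 0.2,
) -> IPUAnnotation:
    """Threshold the envelope to find speech intervals.

    Speech where the envelope exceeds ``threshold_frac`` x its 95th
    percentile; silent gaps shorter than ``bridge_s`` are bridged and
    resulting intervals shorter than ``min_dur_s`` dropped.
    """
    env = np.asarray(envelope_raw, dtype=float)
    theta = threshold_frac * np.percentile(env, 95)
    speech = env > theta
    if not speech.any():
        return IPUAnnotation(intervals=np.empty((0, 2)), source="auto")
    d = np.diff(speech.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if speech[0]:
        starts.insert(0, 0)
    if speech[-1]:
        ends.append(speech.size)
    iv = [[s / rate, e / rate] for s, e in zip(starts, ends)]
    merged = [iv[0]]
    for s, e in iv[1:]:
        if s - merged[-1][1] < bridge_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    merged = [p for p in merged if p[1] - p[0] >= min_dur_s]
    return IPUAnnotation(intervals=np.asarray(merged).reshape(-1, 2), source="auto")


def read_interval_annotation(path: str | Path) -> IPUAnnotation:
    """Read IPU intervals from a tab-separated file or a Praat TextGrid subset.

    The tab-separated dialect is ``start_s<TAB>end_s<TAB>label`` with label
    ``ipu`` marking speech.  For TextGrids, the first IntervalTier is used and
    intervals whose text is ``ipu`` (case-insensitive) are kept.
    """
    path = Path(path)
    text = path.read_text()
    if "IntervalTier" in text or text.lstrip().startswith('File type = "ooTextFile"'):
        intervals = _parse_textgrid(text)
    else:
        intervals = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'start end label'")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric interval bound") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if parts[2].strip().lower() == "ipu":
                intervals.append([start, end])
    intervals.sort()
    for i in range(1, len(intervals)):
        if intervals[i][0] < intervals[i - 1][1]:
            raise ValueError(f"{path}: overlapping intervals near {intervals[i][0]:.3f} s")
    return IPUAnnotation(intervals=np.asarray(intervals).reshape(-1, 2), source="manual")


def _parse_textgrid(text: str) -> list[list[float]]:
    """Minimal IntervalTier parser: xmin/xmax/text triples of the first tier."""
    m = re.search(r'"IntervalTier"(.*?)(?:"IntervalTier"|\Z)', text, flags=re.S)
    if not m:
        raise ValueError("no IntervalTier found in TextGrid")
    body = m.group(1)
    triples = re.findall(
        r"xmin\s*=\s*([0-9.eE+-]+)\s*\n\s*xmax\s*=\s*([0-9.eE+-]+)\s*\n\s*text\s*=\s*\"([^\"]*)\"",
        body,
    )
    out = []
    for xmin, xmax, label in triples:
        if label.strip().lower() == "ipu":
            lo, hi = float(xmin), float(xmax)
            if hi <= lo:
                raise ValueError(f"TextGrid interval with xmax <= xmin at {lo}")
            out.append([lo, hi])
    return out


def write_interval_annotation(path: str | Path, ann: IPUAnnotation) -> None:
    with open(path, "w") as fh:
        for start, end in ann.intervals:
            fh.write(f"{start:.4f}\t{end:.4f}\tipu\n")


# ---------------------------------------------------------------------------
# assembled per-trial extraction
# ---------------------------------------------------------------------------

def extract_tracks(
    samples: np.ndarray,
    rate: float,
    sex: str,
    f0_range: tuple[float, float] | None = None,
    voicing_threshold: float = 0.45,
) -> AcousticTracks:
    """Envelope + z-scaled envelope + IQR-filtered F0 for one trial's audio."""
    t_env, env = extract_amplitude_envelope(samples, rate)
    t_f0, f0 = extract_f0_autocorr(
        samples, rate, sex, f0_range=f0_range, voicing_threshold=voicing_threshold
    )
    n = min(t_env.size, t_f0.size)
    f0_filt, frac = filter_f0_outliers(f0[:n])
    rng = f0_range if f0_range is not None else F0_RANGE[sex]
    return AcousticTracks(
        times=t_env[:n],
        envelope_raw=env[:n],
        envelope_z=zscale_per_trial(env[:n]),
        f0=f0_filt,
        sex_range=rng,
        meta={"f0_fraction_discarded": frac, "quantile_convention": "linear"},
    )


def tracks_from_arrays(
    times: np.ndarray, envelope_raw: np.ndarray, f0: np.ndarray, sex: str
) -> AcousticTracks:
    """Wrap pre-extracted 100 Hz tracks (e.g. the generator's track mode)."""
    f0_filt, frac = filter_f0_outliers(np.asarray(f0, dtype=float))
    return AcousticTracks(
        times=np.asarray(times, dtype=float),
        envelope_raw=np.asarray(envelope_raw, dtype=float),
        envelope_z=zscale_per_trial(envelope_raw),
        f0=f0_filt,
        sex_range=F0_RANGE[sex],
        meta={"f0_fraction_discarded": frac, "quantile_convention": "linear"},
    )
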
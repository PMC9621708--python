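"""Raw marker tables -> rotation angle, acceleration, and cycle/acceleration events.

The processing chain for one biking trial: locate the circularly moving
(pedal) marker among all recorded markers, resample its vertical coordinate to
100 Hz and low-pass it (zero-phase Butterworth, 10 Hz), detect one position
peak per biking cycle, express displacement as a rotation angle via the
arcsine transform, differentiate twice for acceleration, and finally detect
the (typically two) acceleration peaks per cycle.  Acceleration is reported
in m/s^2 (position converted from cm before differentiation) so that peak
magnitudes land on the scale used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

PROCESS_RATE = 100.0  # Hz, analysis rate after resampling
CM_PER_M = 100.0


@dataclass
class MarkerSeries:
    """Uniformly sampled marker coordinates in cm.

    ``coords`` maps marker id -> (n, 3) array of (x fore-aft, y lateral,
    z vertical).
    """

    times: np.ndarray
    coords: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for mid, xyz in self.coords.items():
            if xyz.shape != (self.times.size, 3):
                raise ValueError(f"marker {mid}: coordinate shape mismatch")


@dataclass
class PedalKinematics:
    """Per-trial kinematic series (100 Hz) and events for the pedal marker."""

    times: np.ndarray  # s
    position: np.ndarray  # cm, filtered vertical
    angle: np.ndarray  # degrees in [0, 180]
    acceleration: np.ndarray  # m/s^2
    cycle_peak_times: np.ndarray  # s
    cycle_durations: np.ndarray  # s
    acc_peak_times: np.ndarray  # s (T_accPeak)
    acc_peak_magnitudes: np.ndarray  # m/s^2
    marker_id: str | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def _circle_fit_r2(x: np.ndarray, z: np.ndarray) -> float:
    """Fraction of planar variance explained by a least-squares circle (Kasa fit)."""
    x = x - x.mean()
    z = z - z.mean()
    A = np.column_stack([x, z, np.ones_like(x)])
    b = x**2 + z**2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return 0.0
    cx, cz = sol[0] / 2, sol[1] / 2
    r = np.sqrt(np.clip(sol[2] + cx**2 + cz**2, 0.0, None))
    ri = np.hypot(x - cx, z - cz)
    total = np.sum(x**2 + z**2)
    if total <= 0:
        return 0.0
    return float(max(0.0, 1.0 - np.sum((ri - r) ** 2) / total))


def circularity_score(times: np.ndarray, xyz: np.ndarray) -> float:
    """Circle-fit variance explained x vertical peak-to-peak amplitude."""
    z = xyz[:, 2]
    amp = float(np.ptp(z))
    return _circle_fit_r2(xyz[:, 0], z) * amp


def find_circular_marker(markers: MarkerSeries) -> str:
    """Return the id of the marker moving most circularly in the sagittal plane.

    Raises if no marker has more than 1 cm of vertical amplitude (no pedal in
    view).  The winning and runner-up scores are stored nowhere; callers that
    need them can recompute via :func:`circularity_score`.
    """
    if markers.times[-1] - markers.times[0] < 2.0:
        raise ValueError("need at least 2 s of marker data")
    scores = {
        mid: circularity_score(markers.times, xyz) for mid, xyz in markers.coords.items()
    }
    amps = {mid: float(np.ptp(xyz[:, 2])) for mid, xyz in markers.coords.items()}
    if max(amps.values()) <= 1.0:
        raise ValueError("no circular marker found: no marker exceeds 1 cm vertical amplitude")
    return max(scores, key=scores.get)


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def preprocess_vertical(
    markers: MarkerSeries,
    marker_id: str,
    out_rate: float = PROCESS_RATE,
    cutoff_hz: float = 10.0,
    butter_order: int = 4,
    max_gap_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the vertical coordinate to ``out_rate`` and low-pass it.

    Linear-interpolation resampling onto a uniform grid starting at the first
    input sample, then a zero-phase Butterworth low-pass (applied forward and
    backward, so event timing is preserved).  Returns (times, position_cm).
    """
    t = markers.times
    z = markers.coords[marker_id][:, 2]
    if t[-1] - t[0] < 1.0:
        raise ValueError("need at least 1 s of data")
    gaps = np.diff(t)
    if np.any(gaps > max_gap_s):
        raise ValueError("marker dropout: internal gap exceeds 0.5 s")
    tt = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * out_rate)) + 1) / out_rate
    zz = np.interp(tt, t, z)
    sos = signal.butter(butter_order, cutoff_hz, btype="low", fs=out_rate, output="sos")
    filt = signal.sosfiltfilt(sos, zz)
    return tt, filt


def detect_cycle_peaks(
    times: np.ndarray,
    position: np.ndarray,
    min_prominence_frac: float = 0.3,
    min_separation_s: float = 0.4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One position peak per biking cycle; trims everything before the first.

    Returns (cycle_peak_times, cycle_durations, trimmed_times,
    trimmed_position).  Peaks are local maxima with prominence at least
    ``min_prominence_frac`` of the signal's peak-to-peak amplitude and at
    least ``min_separation_s`` apart.
    """
    rate = 1.0 / float(np.median(np.diff(times)))
    prom = min_prominence_frac * float(np.ptp(position))
    idx, _ = signal.find_peaks(
        position, prominence=prom, distance=max(int(round(min_separation_s * rate)), 1)
    )
    if idx.size < 2:
        raise ValueError("no cycles detected: fewer than 2 position peaks")
    peak_times = times[idx]
    durations = np.diff(peak_times)
    keep = times >= peak_times[0]
    return peak_times, durations, times[keep], position[keep]


def to_rotation_angle(position: np.ndarray) -> np.ndarray:
    """Arcsine transform of vertical displacement to a 0-180 degree rotation angle.

    Centre is the midrange, radius half the peak-to-peak amplitude; values are
    clipped into [-1, 1] before the arcsine so noisy extremes cannot escape
    the domain.
    """
    lo, hi = float(np.min(position)), float(np.max(position))
    radius = (hi - lo) / 2.0
    if radius < 0.5:
        raise ValueError("amplitude too small: radius below 0.5 cm")
    center = (hi + lo) / 2.0
    v = np.clip((position - center) / radius, -1.0, 1.0)
    return np.degrees(np.arcsin(v)) + 90.0


def compute_acceleration(position: np.ndarray, rate: float = PROCESS_RATE) -> np.ndarray:
    """Second derivative by central differences; endpoints copy their neighbours.

    Units follow the input: position in metres gives acceleration in m/s^2.
    """
    if position.size < 3:
        raise ValueError("need at least 3 samples")
    acc = np.empty_like(position, dtype=float)
    acc[1:-1] = (position[2:] - 2 * position[1:-1] + position[:-2]) * rate**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def detect_acceleration_peaks(
    times: np.ndarray,
    acceleration: np.ndarray,
    cycle_peak_times: np.ndarray,
    separation_frac: float = 0.25,
    peak_mode: str = "signed",
) -> tuple[np.ndarray, np.ndarray]:
    """Acceleration-peak events (typically two per cycle) within the cycled span.

    In ``signed`` mode peaks are positive local maxima of the acceleration; in
    ``magnitude`` mode, local maxima of |acceleration|.  Minimum separation is
    ``separation_frac`` x the median cycle duration; events before the first
    or after the last cycle peak are dropped.
    """
    med = float(np.median(np.diff(cycle_peak_times)))
    rate = 1.0 / float(np.median(np.diff(times)))
    dist = max(int(round(separation_frac * med * rate)), 1)
    sig = np.abs(acceleration) if peak_mode == "magnitude" else acceleration
    idx, _ = signal.find_peaks(sig, distance=dist, height=0.0)
    tt = times[idx]
    keep = (tt >= cycle_peak_times[0]) & (tt <= cycle_peak_times[-1])
    return tt[keep], sig[idx][keep]


def process_trial(
    markers: MarkerSeries,
    marker_id: str | None = None,
    cutoff_hz: float = 10.0,
    butter_order: int = 4,
    min_prominence_frac: float = 0.3,
    min_separation_s: float = 0.4,
    peak_mode: str = "signed",
) -> PedalKinematics:
    """Full kinematics chain for one trial's marker table."""
    if marker_id is None:
        marker_id = find_circular_marker(markers)
    tt, pos = preprocess_vertical(
        markers, marker_id, cutoff_hz=cutoff_hz, butter_order=butter_order
    )
    cyc_times, cyc_dur, tt, pos = detect_cycle_peaks(
        tt, pos, min_prominence_frac=min_prominence_frac, min_separation_s=min_separation_s
    )
    angle = to_rotation_angle(pos)
    acc = compute_acceleration(pos / CM_PER_M, rate=PROCESS_RATE)
    acc_times, acc_mags = detect_acceleration_peaks(tt, acc, cyc_times, peak_mode=peak_mode)
    return PedalKinematics(
        times=tt,
        position=pos,
        angle=angle,
        acceleration=acc,
        cycle_peak_times=cyc_times,
        cycle_durations=cyc_dur,
        acc_peak_times=acc_times,
        acc_peak_magnitudes=acc_mags,
        marker_id=marker_id,
        meta={
            "cutoff_hz": cutoff_hz,
            "butter_order": butter_order,
            "min_prominence_frac": min_prominence_frac,
            "min_separation_s": min_separation_s,
            "peak_mode": peak_mode,
        },
    )


# ---------------------------------------------------------------------------
# study-level summaries
# ---------------------------------------------------------------------------

def cycle_duration_stats(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cycle-duration summary per cell and paired arm/leg means.

    ``trials`` needs columns participant_id, day, condition, cycle_duration
    (one row per detected cycle).  Returns (summary, pairs) where ``pairs``
    has one row per (participant, day) with both legMot and armMot means --
    the input to the arm-vs-leg duration correlation test.
    """
    summary = (
        trials.groupby(["participant_id", "day", "condition"])["cycle_duration"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    wide = summary.pivot_table(
        index=["participant_id", "day"], columns="condition", values="mean"
    ).reset_index()
    if "legMot" in wide and "armMot" in wide:
        pairs = wide.dropna(subset=["legMot", "armMot"])[
            ["participant_id", "day", "legMot", "armMot"]
        ]
    else:
        pairs = pd.DataFrame(columns=["participant_id", "day", "legMot", "armMot"])
    return summary, pairs
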
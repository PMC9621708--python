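"""Pair motion with speech, gate events by interpausal units, and build epochs.

Trials with real kinematics (legMot, armMot) are paired with their own
synchronous speech; the static armBlock condition gets a *surrogate* pairing,
in which each armBlock speech trial is matched with a biking signal randomly
drawn from another participant and both streams are truncated to the shorter.
Acceleration peaks are retained only when the full +/-200 ms analysis window
lies inside one interpausal unit.  From the retained peaks, two summaries are
built: 41-sample peak-aligned epochs (one row per event) and 50 ms
peak-window means joined to the peak's acceleration magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import AcousticTracks, IPUAnnotation, TRACK_RATE
from .kinematics import PedalKinematics

EPOCH_HALF_S = 0.2
EPOCH_LEN = 41  # -200 .. +200 ms at 100 Hz


@dataclass
class PairedTrial:
    """One speech stream aligned with one motion stream on a shared 100 Hz grid."""

    speech_trial_id: str
    motion_trial_id: str
    tracks: AcousticTracks
    kinematics: PedalKinematics
    surrogate: bool = False
    donor_participant_id: str | None = None
    common_length: float = 0.0
    meta: dict = field(default_factory=dict)


@dataclass
class EpochSet:
    """Peak-aligned epochs of one acoustic measure."""

    measure: str  # envelope_z | f0
    matrix: np.ndarray  # (n_epochs, 41)
    meta: pd.DataFrame  # participant_id, sex, day, condition, t_acc_peak, acc_peak_magnitude
    times_ms: np.ndarray = field(
        default_factory=lambda: np.arange(-EPOCH_HALF_S * 1000, EPOCH_HALF_S * 1000 + 1, 10)
    )


def _truncate_tracks(tracks: AcousticTracks, n: int) -> AcousticTracks:
    from .acoustics import zscale_per_trial

    return AcousticTracks(
        times=tracks.times[:n],
        envelope_raw=tracks.envelope_raw[:n],
        envelope_z=zscale_per_trial(tracks.envelope_raw[:n]),
        f0=tracks.f0[:n],
        sex_range=tracks.sex_range,
        meta=dict(tracks.meta),
    )


def _truncate_kinematics(kin: PedalKinematics, t_end: float) -> PedalKinematics:
    """Drop samples and events at or beyond absolute time ``t_end``."""
    keep = kin.times < t_end
    ev = kin.acc_peak_times < t_end
    cy = kin.cycle_peak_times < t_end
    return PedalKinematics(
        times=kin.times[keep],
        position=kin.position[keep],
        angle=kin.angle[keep],
        acceleration=kin.acceleration[keep],
        cycle_peak_times=kin.cycle_peak_times[cy],
        cycle_durations=np.diff(kin.cycle_peak_times[cy]),
        acc_peak_times=kin.acc_peak_times[ev],
        acc_peak_magnitudes=kin.acc_peak_magnitudes[ev],
        marker_id=kin.marker_id,
        meta=dict(kin.meta),
    )


def pair_trial(
    speech_trial_id: str,
    tracks: AcousticTracks,
    motion_trial_id: str,
    kinematics: PedalKinematics,
    min_overlap_s: float = 5.0,
) -> PairedTrial:
    """Align one speech and one motion stream; truncate both to the shorter.

    Both streams share the trial's absolute timeline (t = 0 is recording
    start; the kinematic series begins at its first cycle peak but its event
    times stay absolute, so no re-referencing is needed).  For surrogate
    pairings the donor's timeline is aligned at its own start.
    """
    end_speech = tracks.times[-1] + 1 / TRACK_RATE
    end_motion = kinematics.times[-1] + 1 / TRACK_RATE
    common_end = min(end_speech, end_motion)
    overlap = common_end - max(tracks.times[0], kinematics.times[0])
    if overlap < min_overlap_s:
        raise ValueError("insufficient overlap: less than 5 s in common")
    n = int(round((common_end - tracks.times[0]) * TRACK_RATE))
    tr = _truncate_tracks(tracks, min(n, tracks.times.size))
    kin = _truncate_kinematics(kinematics, common_end)
    return PairedTrial(
        speech_trial_id=speech_trial_id,
        motion_trial_id=motion_trial_id,
        tracks=tr,
        kinematics=kin,
        surrogate=False,
        common_length=common_end,
    )


def make_surrogate_pairing(
    speech_trials: list[tuple[str, str, AcousticTracks]],
    motion_pool: list[tuple[str, str, PedalKinematics]],
    rng: np.random.Generator,
    min_overlap_s: float = 5.0,
) -> tuple[list[PairedTrial], pd.DataFrame]:
    """Pair armBlock speech with biking signals from *other* participants.

    ``speech_trials`` holds (trial_id, participant_id, tracks) and
    ``motion_pool`` (trial_id, participant_id, kinematics) from the legMot and
    armMot conditions, all equally eligible.  The donor is drawn uniformly
    from the eligible pool; the longer stream is cut to the shorter.  Returns
    the paired trials plus the seeded speech->donor mapping.
    """
    paired = []
    mapping = []
    for trial_id, pid, tracks in speech_trials:
        eligible = [i for i, (_, dpid, _) in enumerate(motion_pool) if dpid != pid]
        if not eligible:
            raise ValueError(f"no donor available for {trial_id}")
        pick = int(rng.choice(eligible))
        donor_id, donor_pid, kin = motion_pool[pick]
        pt = pair_trial(trial_id, tracks, donor_id, kin, min_overlap_s=min_overlap_s)
        pt.surrogate = True
        pt.donor_participant_id = donor_pid
        paired.append(pt)
        mapping.append({"speech_trial": trial_id, "donor_trial": donor_id})
    return paired, pd.DataFrame(mapping)


def select_peaks_within_ipus(
    acc_peak_times: np.ndarray,
    acc_peak_magnitudes: np.ndarray,
    ipus: IPUAnnotation,
    window_s: float = EPOCH_HALF_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep only peaks whose whole +/-window lies inside a single IPU."""
    if ipus.intervals.size == 0:
        return np.empty(0), np.empty(0)
    keep = np.zeros(acc_peak_times.size, dtype=bool)
    for start, end in ipus.intervals:
        keep |= (acc_peak_times - window_s >= start) & (acc_peak_times + window_s <= end)
    return acc_peak_times[keep], acc_peak_magnitudes[keep]


def extract_peak_epochs(
    paired: PairedTrial,
    peak_times: np.ndarray,
    peak_mags: np.ndarray,
    measure: str = "envelope_z",
    participant_id: str | None = None,
    sex: str | None = None,
    day: int | None = None,
    condition: str | None = None,
    min_voiced_frac: float = 0.5,
) -> EpochSet:
    """41-sample epochs centred on the grid sample nearest each peak.

    Epochs whose window leaves the track are excluded; F0 epochs with fewer
    than ``min_voiced_frac`` non-missing samples are dropped.
    """
    track = getattr(paired.tracks, measure if measure != "f0" else "f0")
    t0 = paired.tracks.times[0]
    half = EPOCH_LEN // 2
    rows, meta = [], []
    for tp, mag in zip(peak_times, peak_mags):
        c = int(round((tp - t0) * TRACK_RATE))
        if c - half < 0 or c + half >= track.size:
            continue
        seg = track[c - half : c + half + 1]
        if measure == "f0" and np.mean(np.isfinite(seg)) < min_voiced_frac:
            continue
        rows.append(seg)
        meta.append(
            {
                "participant_id": participant_id,
                "sex": sex,
                "day": day,
                "condition": condition,
                "t_acc_peak": tp,
                "acc_peak_magnitude": mag,
            }
        )
    matrix = np.asarray(rows).reshape(-1, EPOCH_LEN)
    return EpochSet(measure=measure, matrix=matrix, meta=pd.DataFrame(meta))


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    sets = [s for s in sets if s.matrix.size]
    if not sets:
        return EpochSet(measure="envelope_z", matrix=np.empty((0, EPOCH_LEN)), meta=pd.DataFrame())
    return EpochSet(
        measure=sets[0].measure,
        matrix=np.vstack([s.matrix for s in sets]),
        meta=pd.concat([s.meta for s in sets], ignore_index=True),
    )


def peak_window_mean(
    times: np.ndarray, values: np.ndarray, t_peak: float, width_s: float = 0.05
) -> float:
    """Mean of samples within +/- width/2 of the peak; NaN-aware for F0.

    Returns NaN when the window leaves the track or fewer than half the
    samples are non-missing.
    """
    half = width_s / 2 + 1e-9
    if t_peak - half < times[0] or t_peak + half > times[-1]:
        return np.nan
    # uniform grid: index arithmetic instead of a full-array mask
    dt = times[1] - times[0]
    i0 = int(np.ceil((t_peak - half - times[0]) / dt - 1e-9))
    i1 = int(np.floor((t_peak + half - times[0]) / dt + 1e-9))
    seg = values[max(i0, 0) : i1 + 1]
    if seg.size == 0 or np.mean(np.isfinite(seg)) < 0.5:
        return np.nan
    return float(np.nanmean(seg))


def build_peak_measures(
    paired: PairedTrial,
    peak_times: np.ndarray,
    peak_mags: np.ndarray,
    participant_id: str,
    sex: str,
    day: int,
    condition: str,
    width_s: float = 0.05,
    include_f0: bool = True,
) -> pd.DataFrame:
    """One row per retained acceleration peak: env50 and f050 window means."""
    t = paired.tracks.times
    rows = []
    for tp, mag in zip(peak_times, peak_mags):
        rows.append(
            {
                "participant_id": participant_id,
                "sex": sex,
                "day": day,
                "condition": condition,
                "t_acc_peak": tp,
                "acc_peak_magnitude": mag,
                "env50": peak_window_mean(t, paired.tracks.envelope_z, tp, width_s),
                "f050": peak_window_mean(t, paired.tracks.f0, tp, width_s)
                if include_f0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def average_epochs_by_cell(epochs: EpochSet) -> pd.DataFrame:
    """Sample-wise mean curves per (participant, condition, day) cell.

    Returns a long DataFrame with one row per cell x time sample, columns
    participant_id, sex, condition, day, time_ms, value, n_epochs.  Missing
    F0 samples are averaged over the available epochs only; empty cells are
    omitted.
    """
    if epochs.matrix.size == 0:
        return pd.DataFrame(
            columns=["participant_id", "sex", "condition", "day", "time_ms", "value", "n_epochs"]
        )
    meta = epochs.meta
    out = []
    for (pid, sex, cond, day), grp in meta.groupby(
        ["participant_id", "sex", "condition", "day"], sort=True
    ):
        block = epochs.matrix[grp.index.to_numpy()]
        with np.errstate(invalid="ignore"):
            curve = np.nanmean(block, axis=0)
        out.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "sex": sex,
                    "condition": cond,
                    "day": day,
                    "time_ms": epochs.times_ms,
                    "value": curve,
                    "n_epochs": block.shape[0],
                }
            )
        )
    return pd.concat(out, ignore_index=True)
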
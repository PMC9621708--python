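"""End-to-end study analysis: trials in, epoch curves, models and report out.

The entry point is :func:`analyze_study`, which accepts either an in-memory
:class:`~limbspeech.synth.StudyBundle` or a manifest directory written by the
generator (or by any compatible acquisition pipeline).  Per trial it runs the
kinematics chain and the acoustic extraction, builds the surrogate pairing
for armBlock speech, gates acceleration peaks by interpausal units, extracts
peak-aligned epochs and 50 ms peak-window measures, and fits both statistical
stages.  A trial failing any stage is skipped with a logged reason; the run
continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics, coupling, gam, kinematics, lmm
from .acoustics import AcousticTracks, IPUAnnotation
from .coupling import EpochSet, PairedTrial
from .kinematics import PedalKinematics
from .synth import StudyBundle

log = logging.getLogger("limbspeech")

MOTION_CONDITIONS = ("legMot", "armMot")


@dataclass
class TrialRecord:
    trial_id: str
    participant_id: str
    sex: str
    day: int
    condition: str
    tracks: AcousticTracks | None = None
    kinematics: PedalKinematics | None = None
    ipus: IPUAnnotation | None = None
    error: str | None = None
    counts: dict = field(default_factory=dict)


@dataclass
class StudyResults:
    trials: dict[str, TrialRecord]
    paired: list[PairedTrial]
    surrogate_map: pd.DataFrame
    peak_measures: pd.DataFrame
    epochs: dict[str, EpochSet]  # envelope_z, f0
    cells: dict[str, pd.DataFrame]
    lmm_env: lmm.LmmFit | None = None
    lmm_f0: lmm.LmmFit | None = None
    gam_fits: dict = field(default_factory=dict)
    tests: list = field(default_factory=list)
    cycle_summary: pd.DataFrame | None = None
    duration_correlation: object = None
    skipped: dict = field(default_factory=dict)

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for measure, res in self.tests:
            rows.append(
                {
                    "measure": measure,
                    "test": res.name,
                    "statistic": res.statistic,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "edf": res.edf,
                    "p": res.p_parametric,
                    "p_permutation": res.p_permutation,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-trial processing
# ---------------------------------------------------------------------------

def _process_trials(bundle: StudyBundle, ipu_source: str = "ground_truth") -> dict[str, TrialRecord]:
    records: dict[str, TrialRecord] = {}
    for trial_id, trial in bundle.trials.items():
        row = bundle.manifest[bundle.manifest["trial_id"] == trial_id].iloc[0]
        rec = TrialRecord(
            trial_id=trial_id,
            participant_id=row["participant_id"],
            sex=row["sex"],
            day=int(row["day"]),
            condition=row["condition"],
        )
        try:
            if trial.audio is not None:
                rec.tracks = acoustics.extract_tracks(
                    trial.audio, bundle.config.audio_rate, rec.sex
                )
            else:
                rec.tracks = acoustics.tracks_from_arrays(
                    trial.track_times, trial.envelope, trial.f0, rec.sex
                )
            if ipu_source == "ground_truth":
                rec.ipus = IPUAnnotation(intervals=trial.ipus, source="ground_truth")
            else:
                rec.ipus = acoustics.detect_ipus_auto(rec.tracks.envelope_raw)
            if trial.markers is not None:
                rec.kinematics = kinematics.process_trial(trial.markers)
                rec.counts["n_cycles"] = rec.kinematics.cycle_durations.size
                rec.counts["n_acc_peaks"] = rec.kinematics.acc_peak_times.size
            rec.counts["f0_fraction_discarded"] = rec.tracks.meta.get("f0_fraction_discarded")
        except Exception as exc:  # crash containment: skip trial, keep going
            rec.error = f"{type(exc).__name__}: {exc}"
            log.warning("trial %s skipped: %s", trial_id, rec.error)
        records[trial_id] = rec
    return records


def _pair_all(
    records: dict[str, TrialRecord], seed: int
) -> tuple[list[PairedTrial], pd.DataFrame]:
    paired = []
    speech_only = []
    pool = []
    for rec in records.values():
        if rec.error or rec.tracks is None:
            continue
        if rec.condition in MOTION_CONDITIONS and rec.kinematics is not None:
            paired.append(
                coupling.pair_trial(rec.trial_id, rec.tracks, rec.trial_id, rec.kinematics)
            )
            pool.append((rec.trial_id, rec.participant_id, rec.kinematics))
        elif rec.condition == "armBlock":
            speech_only.append((rec.trial_id, rec.participant_id, rec.tracks))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    if speech_only and pool:
        surr, mapping = coupling.make_surrogate_pairing(speech_only, pool, rng)
        paired.extend(surr)
    else:
        mapping = pd.DataFrame(columns=["speech_trial", "donor_trial"])
    return paired, mapping


# ---------------------------------------------------------------------------
# study-level analysis
# ---------------------------------------------------------------------------

def analyze_study(
    bundle: StudyBundle,
    seed: int = 0,
    ipu_source: str = "ground_truth",
    k: int = 10,
    rho: str | float | None = "toeplitz",
    n_permutations: int = 0,
    fit_lmms: bool = True,
    fit_gams: bool = True,
    fit_f0_models: bool = True,
    structures: tuple[str, ...] = ("by_condition", "difference"),
) -> StudyResults:
    """Run the full analysis on a simulated (or loaded) study bundle."""
    records = _process_trials(bundle, ipu_source=ipu_source)
    paired, mapping = _pair_all(records, seed)

    env_sets, f0_sets, pm_rows = [], [], []
    for pt in paired:
        rec = records[pt.speech_trial_id]
        ipus = rec.ipus
        keep_t, keep_m = coupling.select_peaks_within_ipus(
            pt.kinematics.acc_peak_times,
            pt.kinematics.acc_peak_magnitudes,
            ipus,
        )
        rec.counts["n_peaks_retained"] = keep_t.size
        common = dict(
            participant_id=rec.participant_id,
            sex=rec.sex,
            day=rec.day,
            condition=rec.condition,
        )
        env_sets.append(
            coupling.extract_peak_epochs(pt, keep_t, keep_m, "envelope_z", **common)
        )
        if fit_f0_models:
            f0_sets.append(coupling.extract_peak_epochs(pt, keep_t, keep_m, "f0", **common))
        pm_rows.append(
            coupling.build_peak_measures(
                pt, keep_t, keep_m, rec.participant_id, rec.sex, rec.day, rec.condition,
                include_f0=fit_f0_models,
            )
        )

    epochs = {
        "envelope_z": coupling.concat_epochs(env_sets),
        "f0": coupling.concat_epochs(f0_sets),
    }
    peak_measures = (
        pd.concat(pm_rows, ignore_index=True)
        if pm_rows
        else pd.DataFrame(
            columns=[
                "participant_id",
                "sex",
                "day",
                "condition",
                "t_acc_peak",
                "acc_peak_magnitude",
                "env50",
                "f050",
            ]
        )
    )
    cells = {m: coupling.average_epochs_by_cell(e) for m, e in epochs.items()}

    results = StudyResults(
        trials=records,
        paired=paired,
        surrogate_map=mapping,
        peak_measures=peak_measures,
        epochs=epochs,
        cells=cells,
        skipped={tid: r.error for tid, r in records.items() if r.error},
    )

    # cycle-duration summary + arm/leg correlation
    dur_rows = []
    for rec in records.values():
        if rec.kinematics is not None and rec.error is None:
            for d in rec.kinematics.cycle_durations:
                dur_rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "day": rec.day,
                        "condition": rec.condition,
                        "cycle_duration": d,
                    }
                )
    if dur_rows:
        summary, pairs = kinematics.cycle_duration_stats(pd.DataFrame(dur_rows))
        results.cycle_summary = summary
        if len(pairs) >= 3:
            results.duration_correlation = lmm.correlation_test(
                pairs["armMot"].to_numpy(), pairs["legMot"].to_numpy()
            )

    if fit_lmms and not peak_measures.empty:
        try:
            results.lmm_env = lmm.fit_peak_lmm_env(peak_measures)
        except Exception as exc:
            log.warning("envelope LMM failed: %s", exc)
        if fit_f0_models:
            try:
                results.lmm_f0 = lmm.fit_peak_lmm_f0(peak_measures)
            except Exception as exc:
                log.warning("F0 LMM failed: %s", exc)

    if fit_gams:
        measures = ["envelope_z"] + (["f0"] if fit_f0_models else [])
        for measure in measures:
            cc = cells[measure]
            if cc.empty or cc["condition"].nunique() < 2:
                continue
            try:
                if "by_condition" in structures:
                    fit_bc = gam.fit_factor_smooth_gam(
                        cc, measure=measure, structure="by_condition", k=k, rho=rho
                    )
                    results.gam_fits[(measure, "by_condition")] = fit_bc
                    for cond in fit_bc.conditions:
                        results.tests.append(
                            (measure, gam.test_smooth_nonlinearity(fit_bc, cond, n_permutations))
                        )
                if "difference" in structures:
                    fit_d = gam.fit_factor_smooth_gam(
                        cc, measure=measure, structure="difference", k=k, rho=rho
                    )
                    results.gam_fits[(measure, "difference")] = fit_d
                    for cond in fit_d.conditions:
                        if cond != fit_d.reference:
                            results.tests.append(
                                (measure, gam.test_smooth_difference(fit_d, cond, n_permutations))
                            )
            except Exception as exc:
                log.warning("GAM for %s failed: %s", measure, exc)
    return results


# ---------------------------------------------------------------------------
# disk-backed entry points
# ---------------------------------------------------------------------------

def read_marker_csv(path: str | Path) -> kinematics.MarkerSeries:
    """Read a long- or wide-format marker CSV into a MarkerSeries."""
    df = pd.read_csv(path, comment="#")
    if "marker_id" in df.columns:
        required = {"time_s", "marker_id", "x_cm", "y_cm", "z_cm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        coords = {}
        times = None
        for mid, grp in df.groupby("marker_id", sort=True):
            t = grp["time_s"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif t.size != times.size or not np.allclose(t, times):
                raise ValueError(f"{path}: marker {mid} has a different time base")
            coords[str(mid)] = grp[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
            raise ValueError(f"{path}: non-monotone time at line ~{bad}")
        return kinematics.MarkerSeries(times=times, coords=coords)
    # wide format: time_s plus <marker>_{x,y,z}_cm columns
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing column time_s")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
        raise ValueError(f"{path}: non-monotone time at line ~{bad}")
    ids = sorted(
        {c[: -len("_x_cm")] for c in df.columns if c.endswith("_x_cm")}
    )
    if not ids:
        raise ValueError(f"{path}: no marker coordinate columns found")
    coords = {}
    for mid in ids:
        cols = [f"{mid}_x_cm", f"{mid}_y_cm", f"{mid}_z_cm"]
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"{path}: missing column {c}")
        coords[mid] = df[cols].to_numpy(dtype=float)
    return kinematics.MarkerSeries(times=times, coords=coords)


def load_study(manifest_path: str | Path) -> StudyBundle:
    """Load a study written by ``synth.write_study`` back into a bundle."""
    from scipy.io import wavfile

    from .synth import GroundTruth, SimulatedTrial, StudyConfig, TrialSpec

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError("no trials in manifest")
    trials = {}
    audio_rate = 44100.0
    mode = "audio"
    for _, row in manifest.iterrows():
        spec = TrialSpec(
            participant_id=row["participant_id"],
            sex=row["sex"],
            day=int(row["day"]),
            condition=row["condition"],
            seed=int(row.get("seed", 0)),
        )
        audio = track_times = env = f0 = None
        apath = root / row["audio_path"]
        if not apath.exists():
            raise FileNotFoundError(apath)
        if str(apath).endswith(".wav"):
            rate, data = wavfile.read(apath)
            audio_rate = float(rate)
            audio = data.astype(float) / 32767.0
        else:
            tdf = pd.read_csv(apath)
            track_times = tdf["time_s"].to_numpy(float)
            env = tdf["envelope_raw"].to_numpy(float)
            f0 = tdf["f0_hz"].to_numpy(float)
            mode = "tracks"
        markers = None
        if isinstance(row.get("marker_path"), str) and row["marker_path"]:
            markers = read_marker_csv(root / row["marker_path"])
        ipus = np.empty((0, 2))
        if isinstance(row.get("annotation_path"), str) and row["annotation_path"]:
            ann = acoustics.read_interval_annotation(root / row["annotation_path"])
            ipus = ann.intervals
        trials[row["trial_id"]] = SimulatedTrial(
            spec=spec,
            markers=markers,
            ipus=ipus,
            ground_truth=GroundTruth(),
            audio=audio,
            track_times=track_times,
            envelope=env,
            f0=f0,
        )
    config = StudyConfig(
        n_participants=manifest["participant_id"].nunique(),
        n_female=manifest.loc[manifest["sex"] == "female", "participant_id"].nunique(),
        days=tuple(sorted(manifest["day"].unique())),
        mode=mode,
        audio_rate=audio_rate,
    )
    return StudyBundle(config=config, seed=0, manifest=manifest, trials=trials)


def write_results(results: StudyResults, outdir: str | Path) -> None:
    """Write result tables and a small markdown report with condition curves."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.peak_measures.to_csv(outdir / "peak_measures.csv", index=False)
    for m, cc in results.cells.items():
        cc.to_csv(outdir / f"cells_{m}.csv", index=False)
    results.surrogate_map.to_csv(outdir / "surrogate_map.csv", index=False)
    tf = results.tests_frame()
    tf.to_csv(outdir / "smooth_tests.csv", index=False)
    if results.lmm_env is not None:
        results.lmm_env.terms.to_csv(outdir / "lmm_env_terms.csv", index=False)
    if results.lmm_f0 is not None:
        results.lmm_f0.terms.to_csv(outdir / "lmm_f0_terms.csv", index=False)
    if results.cycle_summary is not None:
        results.cycle_summary.to_csv(outdir / "cycle_summary.csv", index=False)

    lines = ["# Study report", ""]
    if results.skipped:
        lines += ["## Skipped trials", ""]
        lines += [f"- {tid}: {err}" for tid, err in results.skipped.items()]
        lines.append("")
    if results.duration_correlation is not None:
        c = results.duration_correlation
        lines += [
            "## Arm vs leg cycle durations",
            "",
            f"r2 = {c.r2:.3f}, t = {c.statistic:.2f}, df = {int(c.df_den)}, p = {c.p_parametric:.2g}",
            "",
        ]
    if not tf.empty:
        lines += ["## Smooth-term tests", "", tf.to_markdown(index=False), ""]
    (outdir / "report.md").write_text("\n".join(lines))

    try:
        _plot_condition_curves(results, outdir)
    except Exception as exc:
        log.warning("plotting failed: %s", exc)


def _plot_condition_curves(results: StudyResults, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results.cells)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(5 * max(n, 1), 3.5), squeeze=False)
    for ax, (measure, cc) in zip(axes[0], results.cells.items()):
        fit = results.gam_fits.get((measure, "by_condition"))
        for cond, grp in cc.groupby("condition"):
            mean_curve = grp.groupby("time_ms")["value"].mean()
            ax.plot(mean_curve.index, mean_curve.to_numpy(), alpha=0.4, label=f"{cond} (data)")
            if fit is not None:
                pred = fit.condition_curve(cond)
                ax.plot(pred["time_ms"], pred["fit"], lw=2, label=f"{cond} (fit)")
                ax.fill_between(pred["time_ms"], pred["lo"], pred["hi"], alpha=0.15)
        ax.axvline(0.0, ls="--", c="k", lw=0.8)
        ax.set_xlabel("time from acceleration peak (ms)")
        ax.set_ylabel(measure)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "condition_curves.png", dpi=120)
    plt.close(fig)
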
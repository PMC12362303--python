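"""Plain-text table dialects (TSV with JSON sidecars).

Everything the pipeline writes or reads is tab-separated text so outputs can
be inspected and re-consumed by any tool: run series (frame_time_s + one
column per region), 6-parameter motion, BIDS-style events, 10 Hz event
streams, participants, and ground truth (JSON). Floats round-trip exactly
(shortest-repr formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .prep import RunSeries

MOTION_COLUMNS = (
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
)


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}, line 1: missing column(s) {missing}")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees exact float64 round-trip through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if required:
        _require_columns(df, required, path)
    return df


# -- run series ------------------------------------------------------------


def write_run_series(run: RunSeries, path: str | Path) -> Path:
    df = pd.DataFrame(run.values, columns=list(run.regions))
    df.insert(0, "frame_time_s", run.frame_times_s)
    out = write_table(df, path)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "participant_id": run.participant_id,
                "run_index": run.run_index,
                "stage": run.stage,
            },
            indent=2,
        )
    )
    return out


def read_run_series(path: str | Path) -> RunSeries:
    path = Path(path)
    df = read_table(path, required=("frame_time_s",))
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar JSON for {path}")
    meta = json.loads(sidecar.read_text())
    regions = tuple(c for c in df.columns if c != "frame_time_s")
    return RunSeries(
        participant_id=meta["participant_id"],
        run_index=int(meta["run_index"]),
        frame_times_s=df["frame_time_s"].to_numpy(),
        values=df[list(regions)].to_numpy(),
        regions=regions,
        stage=meta.get("stage", "raw"),
    )


# -- motion ----------------------------------------------------------------


def write_motion(params6: np.ndarray, path: str | Path) -> Path:
    if params6.ndim != 2 or params6.shape[1] != 6:
        raise SchemaError("motion table must be frames x 6")
    return write_table(pd.DataFrame(params6, columns=list(MOTION_COLUMNS)), path)


def read_motion(path: str | Path) -> np.ndarray:
    df = read_table(path, required=MOTION_COLUMNS)
    return df[list(MOTION_COLUMNS)].to_numpy()


# -- events ----------------------------------------------------------------


def events_frame(design) -> pd.DataFrame:
    """BIDS-events-style rows (onset, duration, trial_type, ...) for all runs."""
    rows = []
    for _, row in design.episodes.iterrows():
        trial_onset = row["trial_in_run"] * design.layout.trial_duration_s
        for phase, dur in design.layout.phases:
            rows.append(
                {
                    "onset": trial_onset + design.layout.onset_s(phase),
                    "duration": dur,
                    "trial_type": phase,
                    "run": int(row["run"]),
                    "episode_id": int(row["episode"]),
                    "condition": row["condition"],
                }
            )
    return pd.DataFrame(rows)


def read_events(path: str | Path) -> pd.DataFrame:
    return read_table(
        path, required=("onset", "duration", "trial_type", "episode_id", "condition")
    )


# -- event streams ---------------------------------------------------------


def write_stream(stream, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "time_s": stream.time_s,
            "angular_velocity": stream.angular_velocity,
            "gaze_ratio": stream.gaze_ratio,
        }
    )
    return write_table(df, path)


def read_stream(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("time_s", "angular_velocity", "gaze_ratio"))


# -- participants ----------------------------------------------------------


def participants_frame(design, mean_fd: np.ndarray | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant_id": list(design.participant_ids),
            "age": design.ages,
            "group": list(design.groups),
        }
    )
    df["mean_fd"] = mean_fd if mean_fd is not None else np.nan
    return df


def read_participants(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("participant_id", "age", "group"))


# -- whole-simulation round trip -------------------------------------------


def write_simulation(cohort, out_dir: str | Path) -> Path:
    """Serialize a synthetic cohort as TSV tables + JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = cohort.design

    (out / "design.json").write_text(
        json.dumps(
            {
                "tr_s": design.tr_s,
                "n_runs": design.n_runs,
                "trials_per_run": design.trials_per_run,
                "regions": list(design.regions),
                "seed": design.seed,
            },
            indent=2,
        )
    )
    write_table(design.episodes, out / "episodes.tsv")
    write_table(participants_frame(design), out / "participants.tsv")
    write_table(events_frame(design), out / "events.tsv")
    write_table(cohort.behavior.responses, out / "responses.tsv")

    for run in cohort.iter_runs():
        write_run_series(
            run, out / "bold" / f"{run.participant_id}_run-{run.run_index}.tsv"
        )
    for i, pid in enumerate(design.participant_ids):
        for r in range(design.n_runs):
            write_motion(cohort.motion[i, r], out / "motion" / f"{pid}_run-{r}.tsv")
    for stream in cohort.streams:
        write_stream(stream, out / "streams" / f"episode-{stream.episode:02d}.tsv")

    # Observed group gaze ratio at 10 Hz (aggregated from the 250 Hz flags).
    from .events import aggregate_gaze

    rows = []
    for episode, flags in sorted(cohort.gaze.items()):
        ratio = aggregate_gaze(flags)
        t = np.arange(ratio.size) / 10.0
        rows.append(
            pd.DataFrame({"episode": episode, "time_s": t, "gaze_ratio": ratio})
        )
    if rows:
        write_table(pd.concat(rows, ignore_index=True), out / "gaze_ratio.tsv")
    write_ground_truth(cohort.truth, out / "ground_truth.json")
    return out


def load_design(sim_dir: str | Path):
    """Rebuild a StudyDesign from a serialized simulation directory."""
    from .simulate.design import StudyDesign, TrialLayout

    sim = Path(sim_dir)
    meta_path = sim / "design.json"
    if not meta_path.exists():
        raise SchemaError(f"no design.json in {sim}")
    meta = json.loads(meta_path.read_text())
    episodes = read_table(
        sim / "episodes.tsv",
        required=("episode", "condition", "run", "trial_in_run"),
    )
    participants = read_participants(sim / "participants.tsv")
    return StudyDesign(
        participant_ids=tuple(participants["participant_id"]),
        ages=participants["age"].to_numpy(dtype=float),
        groups=tuple(participants["group"]),
        n_runs=int(meta["n_runs"]),
        trials_per_run=int(meta["trials_per_run"]),
        tr_s=float(meta["tr_s"]),
        regions=tuple(meta["regions"]),
        episodes=episodes,
        layout=TrialLayout(),
        seed=int(meta.get("seed", 0)),
    )


def load_runs(dir_path: str | Path) -> list[RunSeries]:
    """All run-series TSVs under a directory (sorted by file name)."""
    d = Path(dir_path)
    paths = sorted(d.glob("*.tsv"))
    if not paths:
        raise SchemaError(f"no run series found under {d}")
    return [read_run_series(p) for p in paths]


def load_motion(sim_dir: str | Path, design) -> np.ndarray:
    sim = Path(sim_dir)
    n_p, n_r = design.n_participants, design.n_runs
    out = np.zeros((n_p, n_r, design.frames_per_run, 6))
    for i, pid in enumerate(design.participant_ids):
        for r in range(n_r):
            out[i, r] = read_motion(sim / "motion" / f"{pid}_run-{r}.tsv")
    return out


def load_gaze_ratio(sim_dir: str | Path) -> dict[int, np.ndarray]:
    path = Path(sim_dir) / "gaze_ratio.tsv"
    if not path.exists():
        return {}
    df = read_table(path, required=("episode", "time_s", "gaze_ratio"))
    return {
        int(e): d.sort_values("time_s")["gaze_ratio"].to_numpy()
        for e, d in df.groupby("episode")
    }


def load_streams(sim_dir: str | Path, design) -> list:
    from .simulate.streams import EpisodeStream

    streams = []
    for _, row in design.episodes.sort_values("episode").iterrows():
        e = int(row["episode"])
        df = read_stream(Path(sim_dir) / "streams" / f"episode-{e:02d}.tsv")
        streams.append(
            EpisodeStream(
                episode=e,
                condition=str(row["condition"]),
                time_s=df["time_s"].to_numpy(),
                angular_velocity=df["angular_velocity"].to_numpy(),
                gaze_ratio=df["gaze_ratio"].to_numpy(),
                turns=pd.DataFrame(columns=["onset_s", "width_s", "amplitude"]),
            )
        )
    return streams


# -- ground truth ----------------------------------------------------------


def write_ground_truth(truth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "mediation_a": truth.mediation_a,
        "mediation_b": truth.mediation_b,
        "mediation_c_prime": truth.mediation_c_prime,
        "motion_gamma": truth.motion_gamma,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "mediator_regions": list(truth.mediator_regions),
        "region_betas": truth.region_betas.to_dict(orient="records"),
        "coupling_w": truth.coupling_w.tolist(),
        "mediator": truth.mediator.tolist(),
        "motion_propensity": truth.motion_propensity.tolist(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
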
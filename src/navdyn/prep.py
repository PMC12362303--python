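"""Run-wise signal conditioning and summary measures.

Raw region series are converted to percent signal change, cleaned by
regressing out 30 confounds (24 motion expansions, framewise displacement,
and 5 discrete-cosine drift terms), and z-scored — each step strictly per
run. Window extraction, baseline-corrected activation, and the spatial-memory
performance score live here too.

Stages move raw -> psc -> cleaned -> zscored only, and degenerate signals
(zero run mean, zero variance) raise instead of propagating NaN.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateSignalError, InvalidConfigError, SchemaError

logger = logging.getLogger(__name__)

STAGES = ("raw", "psc", "cleaned", "zscored")
#: Rotation-to-translation conversion: displacement on a 50 mm sphere.
FD_ROTATION_RADIUS_MM: float = 50.0
N_DCT: int = 5


@dataclass
class RunSeries:
    """One run's frames x regions signal matrix."""

    participant_id: str
    run_index: int
    frame_times_s: np.ndarray
    values: np.ndarray  # frames x regions
    regions: tuple[str, ...]
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.regions):
            raise SchemaError("values must be frames x regions")
        if self.values.shape[0] != self.frame_times_s.size:
            raise SchemaError("frame_times length must match frame count")
        if self.stage not in STAGES:
            raise SchemaError(f"unknown stage {self.stage!r}")

    def _advance(self, values: np.ndarray, stage: str) -> "RunSeries":
        if STAGES.index(stage) != STAGES.index(self.stage) + 1:
            raise SchemaError(f"cannot move from stage {self.stage!r} to {stage!r}")
        return replace(self, values=values, stage=stage)


def percent_signal_change(run: RunSeries) -> RunSeries:
    """y = (x - mean(x)) / mean(x) * 100, mean taken over the whole run."""
    if run.stage != "raw":
        raise SchemaError(f"expected raw stage, got {run.stage!r}")
    means = run.values.mean(axis=0)
    bad = np.abs(means) < 1e-12
    if np.any(bad):
        names = [run.regions[i] for i in np.flatnonzero(bad)]
        raise DegenerateSignalError(f"zero run mean in region(s): {names}")
    values = (run.values - means) / means * 100.0
    return run._advance(values, "psc")


def expand_motion(params6: np.ndarray) -> np.ndarray:
    """24-column motion expansion: params, derivatives, squares, squared derivatives.

    Derivatives are backward differences with the first frame set to 0.
    """
    params6 = np.asarray(params6, dtype=float)
    if params6.ndim != 2 or params6.shape[1] != 6:
        raise SchemaError(f"expected frames x 6 motion parameters, got {params6.shape}")
    if params6.shape[0] < 2:
        raise SchemaError("need at least 2 frames for motion derivatives")
    deriv = np.zeros_like(params6)
    deriv[1:] = np.diff(params6, axis=0)
    return np.hstack([params6, deriv, params6**2, deriv**2])


def framewise_displacement(params6: np.ndarray) -> np.ndarray:
    """Per-frame FD (mm): sum |d translation| + 50 * sum |d rotation|; FD_1 = 0."""
    params6 = np.asarray(params6, dtype=float)
    if params6.ndim != 2 or params6.shape[1] != 6:
        raise SchemaError(f"expected frames x 6 motion parameters, got {params6.shape}")
    d = np.zeros_like(params6)
    d[1:] = np.abs(np.diff(params6, axis=0))
    return d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)


def framewise_displacement_frames(params: np.ndarray) -> np.ndarray:
    """FD for arrays with leading batch dimensions: (..., frames, 6) -> (..., frames)."""
    params = np.asarray(params, dtype=float)
    d = np.zeros_like(params)
    d[..., 1:, :] = np.abs(np.diff(params, axis=-2))
    return d[..., :3].sum(axis=-1) + FD_ROTATION_RADIUS_MM * d[..., 3:].sum(axis=-1)


def mean_fd(params_by_run: np.ndarray) -> float:
    """Participant motion covariate: mean FD over all frames of all runs."""
    fd = framewise_displacement_frames(params_by_run)
    return float(fd.mean())


def dct_basis(n_frames: int, k: int = N_DCT) -> np.ndarray:
    """Lowest k non-constant DCT-II columns: cos(pi*j*(2t+1)/(2n)), j = 1..k.

    Columns are exactly zero-mean and mutually orthogonal.
    """
    if k >= n_frames:
        raise InvalidConfigError(f"k={k} must be smaller than n_frames={n_frames}")
    t = np.arange(n_frames)
    cols = [np.cos(np.pi * j * (2 * t + 1) / (2 * n_frames)) for j in range(1, k + 1)]
    return np.column_stack(cols)


@dataclass
class ConfoundMatrix:
    """30 confound columns: 24 motion expansions + FD + 5 DCT terms."""

    values: np.ndarray
    columns: tuple[str, ...]

    @classmethod
    def build(cls, params6: np.ndarray) -> "ConfoundMatrix":
        motion24 = expand_motion(params6)
        fd = framewise_displacement(params6)[:, None]
        dct = dct_basis(params6.shape[0], N_DCT)
        names = (
            [f"motion_{i + 1}" for i in range(24)]
            + ["framewise_displacement"]
            + [f"dct_{j + 1}" for j in range(N_DCT)]
        )
        return cls(values=np.hstack([motion24, fd, dct]), columns=tuple(names))


def regress_confounds(run: RunSeries, confounds: ConfoundMatrix) -> RunSeries:
    """Residualize every region on the confounds plus an intercept."""
    if run.stage != "psc":
        raise SchemaError(f"expected psc stage, got {run.stage!r}")
    X = confounds.values
    if X.shape[0] != run.values.shape[0]:
        raise SchemaError("confound rows must match frame count")
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(X1)
    if rank < X1.shape[1]:
        logger.warning(
            "confound matrix is rank-deficient (rank %d < %d); "
            "using pseudo-inverse least squares",
            rank,
            X1.shape[1],
        )
    beta, *_ = np.linalg.lstsq(X1, run.values, rcond=None)
    resid = run.values - X1 @ beta
    return run._advance(resid, "cleaned")


def zscore_run(run: RunSeries) -> RunSeries:
    """Per region over the whole run: mean 0, sample SD (n-1) of 1."""
    if run.stage != "cleaned":
        raise SchemaError(f"expected cleaned stage, got {run.stage!r}")
    sd = run.values.std(axis=0, ddof=1)
    bad = sd < 1e-12
    if np.any(bad):
        names = [run.regions[i] for i in np.flatnonzero(bad)]
        raise DegenerateSignalError(f"zero variance in region(s): {names}")
    values = (run.values - run.values.mean(axis=0)) / sd
    return run._advance(values, "zscored")


def condition_run(run: RunSeries, params6: np.ndarray) -> RunSeries:
    """Full run-wise chain raw -> psc -> cleaned -> zscored."""
    psc = percent_signal_change(run)
    cleaned = regress_confounds(psc, ConfoundMatrix.build(params6))
    return zscore_run(cleaned)


@dataclass
class TrialWindows:
    """Frame bookkeeping for one trial's analysis windows."""

    episode: int
    navigation_frames: np.ndarray  # retained frames (26 of 30)
    all_navigation_frames: np.ndarray  # all 30
    baseline_frames: np.ndarray  # 4 frames (2 per fixation phase)


def extract_windows(run: RunSeries, design) -> list[TrialWindows]:
    """Windows for every trial of this run.

    Navigation onsets must fall on a frame boundary; events extending past
    the run raise an alignment error.
    """
    windows = []
    trials = design.episodes[design.episodes["run"] == run.run_index]
    n_frames = run.values.shape[0]
    for _, row in trials.sort_values("trial_in_run").iterrows():
        trial = int(row["trial_in_run"])
        onset_s = trial * design.layout.trial_duration_s + design.layout.onset_s(
            "navigation"
        )
        if abs(onset_s / design.tr_s - round(onset_s / design.tr_s)) > 1e-9:
            raise AlignmentError(
                f"navigation onset {onset_s} s is not aligned to the TR grid"
            )
        nav = design.navigation_frames_in_run(trial)
        if nav[-1] >= n_frames:
            raise AlignmentError("trial events extend past the end of the run")
        windows.append(
            TrialWindows(
                episode=int(row["episode"]),
                navigation_frames=design.retained_frames_in_run(trial),
                all_navigation_frames=nav,
                baseline_frames=design.baseline_frames_in_run(trial),
            )
        )
    return windows


def average_activation(run_psc: RunSeries, windows: list[TrialWindows]) -> pd.DataFrame:
    """Baseline-corrected mean navigation activation per episode x region.

    mean(retained navigation frames) - mean(4 baseline frames), computed on
    the percent-signal series.
    """
    if run_psc.stage not in ("psc", "cleaned"):
        raise SchemaError("activation is computed on a percent-signal series")
    rows = []
    for w in windows:
        if w.baseline_frames.size == 0:
            raise SchemaError("missing baseline frames for a trial")
        nav = run_psc.values[w.navigation_frames].mean(axis=0)
        base = run_psc.values[w.baseline_frames].mean(axis=0)
        act = nav - base
        for k, region in enumerate(run_psc.regions):
            rows.append(
                {
                    "participant_id": run_psc.participant_id,
                    "region": region,
                    "episode": w.episode,
                    "activation": act[k],
                }
            )
    return pd.DataFrame(rows)


def spatial_memory_performance(
    responses: pd.DataFrame, excluded_episodes: tuple[int, ...] = ()
) -> pd.Series:
    """Proportion correct per participant; a missing response scores incorrect.

    ``excluded_episodes`` drops flagged trials from the denominator (e.g. a
    mis-marked map), mirroring the behavioral scoring rule.
    """
    df = responses[~responses["episode"].isin(excluded_episodes)]
    grouped = df.groupby("participant_id", sort=True)
    return grouped.apply(
        lambda d: float((d["correct"] & d["responded"]).sum()) / len(d),
        include_groups=False,
    ).rename("performance")
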
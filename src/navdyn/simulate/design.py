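"""Study design: cohort ages, trial timeline, and episode-to-run assignment.

The timeline mirrors the passive-navigation paradigm: each 102 s trial is
fixation (8 s), overhead map (8 s), 1-minute first-person navigation video,
fixation (8 s), map (4 s), memory question (10 s), and inter-trial padding.
24 episodes — 6 per cue condition (landmark, distal, both, none) in 4
environments — are distributed over 4 runs of 6 trials, balanced across
conditions as evenly as 6-trial runs allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import CohortConfig
from ..errors import InvalidConfigError
from .rng import substream

CONDITIONS: tuple[str, ...] = ("landmark", "distal", "both", "none")
#: Conditions whose episodes contain local landmarks.
LANDMARK_CONDITIONS: tuple[str, ...] = ("landmark", "both")
ENVIRONMENTS: tuple[str, ...] = ("village", "forest", "desert", "city")

NAV_DURATION_S: float = 60.0
#: Frames dropped at the start of the navigation window (hemodynamic delay).
NAV_EXCLUDED_FRAMES: int = 4
#: Baseline frames taken from the tail of each fixation phase.
BASELINE_FRAMES_PER_FIXATION: int = 2


@dataclass(frozen=True)
class TrialLayout:
    """Ordered phases of one trial, in seconds."""

    phases: tuple[tuple[str, float], ...] = (
        ("fixation1", 8.0),
        ("map1", 8.0),
        ("navigation", NAV_DURATION_S),
        ("fixation2", 8.0),
        ("map2", 4.0),
        ("question", 10.0),
        ("iti", 4.0),
    )

    @property
    def trial_duration_s(self) -> float:
        return sum(d for _, d in self.phases)

    def onset_s(self, phase: str) -> float:
        t = 0.0
        for name, dur in self.phases:
            if name == phase:
                return t
            t += dur
        raise KeyError(f"unknown phase: {phase!r}")

    def duration_s(self, phase: str) -> float:
        for name, dur in self.phases:
            if name == phase:
                return dur
        raise KeyError(f"unknown phase: {phase!r}")


@dataclass
class StudyDesign:
    """Complete design of one synthetic study."""

    participant_ids: tuple[str, ...]
    ages: np.ndarray  # years, one per participant
    groups: tuple[str, ...]  # "young" / "old"
    n_runs: int
    trials_per_run: int
    tr_s: float
    regions: tuple[str, ...]
    episodes: pd.DataFrame  # episode, condition, environment, run, trial_in_run, question_type
    layout: TrialLayout = field(default_factory=TrialLayout)
    seed: int = 0

    # -- sizes ------------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.layout.trial_duration_s / self.tr_s))

    @property
    def frames_per_run(self) -> int:
        return self.frames_per_trial * self.trials_per_run

    @property
    def nav_frames(self) -> int:
        """Frames in the navigation window (30 at TR 2 s)."""
        return int(round(NAV_DURATION_S / self.tr_s))

    @property
    def retained_nav_frames(self) -> int:
        """Navigation frames kept for similarity analyses (26 at TR 2 s)."""
        return self.nav_frames - NAV_EXCLUDED_FRAMES

    # -- frame arithmetic --------------------------------------------------
    def run_frame_times(self) -> np.ndarray:
        return np.arange(self.frames_per_run) * self.tr_s

    def trial_start_frame(self, trial_in_run: int) -> int:
        return trial_in_run * self.frames_per_trial

    def phase_frames(self, phase: str, trial_in_run: int) -> np.ndarray:
        """Frame indices (within run) covered by a phase of a trial."""
        onset = self.layout.onset_s(phase)
        dur = self.layout.duration_s(phase)
        start = self.trial_start_frame(trial_in_run) + int(round(onset / self.tr_s))
        return np.arange(start, start + int(round(dur / self.tr_s)))

    def navigation_frames_in_run(self, trial_in_run: int) -> np.ndarray:
        """All navigation frames of a trial (30 at TR 2 s)."""
        return self.phase_frames("navigation", trial_in_run)

    def retained_frames_in_run(self, trial_in_run: int) -> np.ndarray:
        """Navigation frames minus the first 4 (26 at TR 2 s)."""
        return self.navigation_frames_in_run(trial_in_run)[NAV_EXCLUDED_FRAMES:]

    def baseline_frames_in_run(self, trial_in_run: int) -> np.ndarray:
        """Last 2 frames of each of the two fixation phases (4 per trial)."""
        out = []
        for phase in ("fixation1", "fixation2"):
            frames = self.phase_frames(phase, trial_in_run)
            out.append(frames[-BASELINE_FRAMES_PER_FIXATION:])
        return np.concatenate(out)

    def retained_times_in_window(self) -> np.ndarray:
        """Acquisition times of retained frames, relative to navigation onset."""
        return (np.arange(self.nav_frames) * self.tr_s)[NAV_EXCLUDED_FRAMES:]

    def episode_row(self, episode: int) -> pd.Series:
        return self.episodes.loc[self.episodes["episode"] == episode].iloc[0]


def _assign_ages(cfg: CohortConfig, rng: np.random.Generator) -> tuple[np.ndarray, tuple[str, ...]]:
    young = rng.integers(
        int(cfg.young_age_range[0]), int(cfg.young_age_range[1]) + 1, cfg.n_young
    )
    old = rng.integers(
        int(cfg.old_age_range[0]), int(cfg.old_age_range[1]) + 1, cfg.n_old
    )
    ages = np.concatenate([young, old]).astype(float)
    groups = ("young",) * cfg.n_young + ("old",) * cfg.n_old
    return ages, groups


def _assign_episodes(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_ep = cfg.n_episodes
    per_cond = n_ep // len(CONDITIONS)
    conditions = [c for c in CONDITIONS for _ in range(per_cond)]
    environments = [ENVIRONMENTS[i % len(ENVIRONMENTS)] for i in range(n_ep)]
    rng.shuffle(environments)

    # Deal each condition's episodes over runs cyclically (offset per
    # condition) so per-run condition counts differ by at most one.
    runs = np.empty(n_ep, dtype=int)
    pos = 0
    for j, _ in enumerate(CONDITIONS):
        for m in range(per_cond):
            runs[pos] = (j + m) % cfg.n_runs
            pos += 1

    df = pd.DataFrame(
        {
            "episode": np.arange(n_ep),
            "condition": conditions,
            "environment": environments,
            "run": runs,
        }
    )
    # Shuffle trial order within each run.
    order = np.empty(n_ep, dtype=int)
    for r in range(cfg.n_runs):
        idx = df.index[df["run"] == r].to_numpy()
        rng.shuffle(idx)
        order[idx] = np.arange(len(idx))
    df["trial_in_run"] = order
    # Half path, half place memory questions.
    qtypes = np.array(["path", "place"]).repeat(n_ep // 2)
    if len(qtypes) < n_ep:
        qtypes = np.append(qtypes, "path")
    rng.shuffle(qtypes)
    df["question_type"] = qtypes
    return df.sort_values(["run", "trial_in_run"]).reset_index(drop=True)


def generate_design(config: CohortConfig, seed: int = 0) -> StudyDesign:
    """Deterministic study design for a given config and seed."""
    layout = TrialLayout()
    for _, dur in layout.phases:
        if abs(dur / config.tr_s - round(dur / config.tr_s)) > 1e-9:
            raise InvalidConfigError(
                f"phase duration {dur} s is not a multiple of TR {config.tr_s} s"
            )
    rng = substream(seed, "design")
    ages, groups = _assign_ages(config, rng)
    episodes = _assign_episodes(config, rng)
    ids = tuple(f"sub-{i + 1:03d}" for i in range(config.n_participants))
    return StudyDesign(
        participant_ids=ids,
        ages=ages,
        groups=groups,
        n_runs=config.n_runs,
        trials_per_run=config.trials_per_run,
        tr_s=config.tr_s,
        regions=tuple(config.regions),
        episodes=episodes,
        layout=layout,
        seed=seed,
    )
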
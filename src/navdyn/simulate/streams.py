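"""Per-episode 10 Hz event streams: angular velocity and gaze-on-landmark ratio.

Each episode carries 4-8 turns, modelled as half-cosine angular-velocity
bumps 1-3 s wide with onsets at least 2 s apart; the virtual navigator is
stationary during the first and last 2 s of the video. Episodes whose cue
condition includes local landmarks additionally carry a latent
group-gaze-ratio profile with bumps near landmark encounters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ..config import CohortConfig
from .design import LANDMARK_CONDITIONS, NAV_DURATION_S, StudyDesign
from .rng import substream

STREAM_HZ: float = 10.0
N_SAMPLES: int = int(NAV_DURATION_S * STREAM_HZ)  # 600


@dataclass
class EpisodeStream:
    """10 Hz event series over one 60 s navigation episode."""

    episode: int
    condition: str
    time_s: np.ndarray  # 600 samples, bin-start times
    angular_velocity: np.ndarray  # deg/s, >= 0
    gaze_ratio: np.ndarray  # fraction of participants on landmarks, in [0, 1]
    turns: pd.DataFrame  # onset_s, width_s, amplitude

    @property
    def n_turns(self) -> int:
        return len(self.turns)


def _bump(t: np.ndarray, onset: float, width: float, amp: float) -> np.ndarray:
    """Half-cosine (single positive lobe) bump on [onset, onset+width]."""
    x = (t - onset) / width
    out = np.zeros_like(t)
    inside = (x >= 0) & (x <= 1)
    out[inside] = amp * np.sin(np.pi * x[inside])
    return out


def _spaced_onsets(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_gap: float
) -> np.ndarray:
    """n sorted onsets in [lo, hi] with pairwise gaps >= min_gap."""
    slack = (hi - lo) - (n - 1) * min_gap
    if slack < 0:
        raise ValueError("window too short for requested spacing")
    u = np.sort(rng.uniform(0.0, 1.0, n))
    return lo + u * slack + np.arange(n) * min_gap


def _turn_table(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = int(rng.integers(cfg.min_turns, cfg.max_turns + 1))
    w_lo, w_hi = cfg.turn_width_range_s
    widths = rng.uniform(w_lo, w_hi, n)
    margin = cfg.stationary_margin_s
    onsets = _spaced_onsets(
        rng, n, margin, NAV_DURATION_S - margin - w_hi, cfg.stationary_margin_s
    )
    amps = rng.uniform(20.0, 60.0, n)  # deg/s peak angular velocity
    return pd.DataFrame({"onset_s": onsets, "width_s": widths, "amplitude": amps})


def _gaze_profile(cfg: CohortConfig, rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Latent group gaze-on-landmark ratio with bumps at landmark encounters."""
    n_views = int(rng.integers(3, 7))
    margin = cfg.stationary_margin_s
    onsets = _spaced_onsets(rng, n_views, margin, NAV_DURATION_S - margin - 5.0, 4.0)
    ratio = np.zeros_like(t)
    for onset in onsets:
        width = rng.uniform(2.0, 5.0)
        peak = rng.uniform(0.5, 0.9)
        ratio += _bump(t, onset, width, peak)
    # small smooth baseline so the series is tie-free away from clipping
    baseline = 0.05 + 0.03 * gaussian_filter1d(rng.standard_normal(t.size), 8.0)
    return np.clip(ratio + np.clip(baseline, 0.001, None), 0.0, 1.0)


def generate_event_streams(
    design: StudyDesign, config: CohortConfig, seed: int = 0
) -> list[EpisodeStream]:
    """One :class:`EpisodeStream` per episode, deterministic for a seed."""
    rng = substream(seed, "streams")
    t = np.arange(N_SAMPLES) / STREAM_HZ
    streams: list[EpisodeStream] = []
    for _, row in design.episodes.sort_values("episode").iterrows():
        turns = _turn_table(config, rng)
        av = np.zeros_like(t)
        for _, tr in turns.iterrows():
            av += _bump(t, tr["onset_s"], tr["width_s"], tr["amplitude"])
        av[t < config.stationary_margin_s] = 0.0
        av[t >= NAV_DURATION_S - config.stationary_margin_s] = 0.0
        if row["condition"] in LANDMARK_CONDITIONS:
            gaze = _gaze_profile(config, rng, t)
        else:
            gaze = np.zeros_like(t)
        streams.append(
            EpisodeStream(
                episode=int(row["episode"]),
                condition=str(row["condition"]),
                time_s=t.copy(),
                angular_velocity=av,
                gaze_ratio=gaze,
                turns=turns,
            )
        )
    return streams
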
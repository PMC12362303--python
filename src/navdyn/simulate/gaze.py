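"""Synthetic 250 Hz eye-tracking flags for the separate gaze cohort.

A separate group of participants (default n = 42, distinct from the scanned
cohort) views each episode; per-sample on-landmark flags are Bernoulli with
probability tied to the episode's latent group gaze ratio. Episodes without
local landmarks yield all-zero flags.
"""

from __future__ import annotations

import numpy as np

from ..config import CohortConfig
from .design import StudyDesign
from .streams import EpisodeStream, STREAM_HZ
from .rng import substream

GAZE_HZ: float = 250.0
#: 250 Hz samples per 100 ms aggregation bin.
SAMPLES_PER_BIN: int = int(GAZE_HZ / STREAM_HZ)


def generate_gaze(
    design: StudyDesign,
    streams: list[EpisodeStream],
    config: CohortConfig,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Per-episode on-landmark flags, shape (gaze participants, 250 Hz samples)."""
    rng = substream(seed, "gaze")
    n_g = config.n_gaze_participants
    out: dict[int, np.ndarray] = {}
    for stream in streams:
        n_250 = stream.time_s.size * SAMPLES_PER_BIN
        if not np.any(stream.gaze_ratio > 0):
            out[stream.episode] = np.zeros((n_g, n_250), dtype=np.uint8)
            continue
        p = np.clip(
            config.gaze_on_prob_floor
            + config.gaze_on_prob_gain * stream.gaze_ratio,
            0.0,
            1.0,
        )
        p_250 = np.repeat(p, SAMPLES_PER_BIN)
        flags = (rng.random((n_g, n_250)) < p_250).astype(np.uint8)
        out[stream.episode] = flags
    return out
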
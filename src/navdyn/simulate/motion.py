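"""Rigid-body head motion: 6-parameter random walk with occasional spikes.

Each run is a random walk in 3 translations (mm) and 3 rotations (radians),
with per-frame step scale set by the participant's motion propensity so that
the cohort age-to-mean-framewise-displacement correlation is tunable (default
target about 0.49). Step scales are chosen so the expected framewise
displacement equals the participant's FD level.
"""

from __future__ import annotations

import numpy as np

from ..config import CohortConfig
from .design import StudyDesign
from .rng import substream
from .truth import GroundTruth

# E|N(0,1)| = sqrt(2/pi); FD sums 3 translation and 3 (x50) rotation steps.
_FD_PER_STEP_SD = 6.0 * np.sqrt(2.0 / np.pi)

MOTION_COLUMNS: tuple[str, ...] = (
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
)


def fd_levels(truth: GroundTruth, config: CohortConfig) -> np.ndarray:
    """Per-participant expected framewise displacement (mm/frame)."""
    lvl = config.fd_base_mm * (1.0 + config.fd_spread * truth.motion_propensity)
    return np.clip(lvl, 0.1 * config.fd_base_mm, None)


def generate_motion(
    design: StudyDesign,
    truth: GroundTruth,
    config: CohortConfig,
    seed: int = 0,
) -> np.ndarray:
    """Motion parameters, shape (participants, runs, frames, 6).

    Columns follow :data:`MOTION_COLUMNS`. With ``config.motion_enabled``
    False, all parameters are exactly zero (so FD is zero at every frame).
    """
    rng = substream(seed, "motion")
    n_p, n_r, n_f = design.n_participants, design.n_runs, design.frames_per_run
    params = np.zeros((n_p, n_r, n_f, 6))
    if not config.motion_enabled:
        return params

    levels = fd_levels(truth, config)
    for i in range(n_p):
        s_t = levels[i] / _FD_PER_STEP_SD  # translation step sd, mm
        s_r = s_t / 50.0  # rotation step sd, rad (50 mm sphere)
        for r in range(n_r):
            steps = rng.standard_normal((n_f, 6))
            steps[:, :3] *= s_t
            steps[:, 3:] *= s_r
            spikes = rng.random(n_f) < config.motion_spike_prob
            steps[spikes] *= config.motion_spike_scale
            steps[0] = 0.0  # the walk starts at rest
            params[i, r] = np.cumsum(steps, axis=0)
    return params
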
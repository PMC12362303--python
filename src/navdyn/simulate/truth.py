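"""Generative ground truth: coupling weights, event betas, mediation chain.

The participant-level latent mediator M (standardized medial-temporal
coupling) follows M = a*z(age) + sqrt(1-a^2)*eps, the head-motion propensity
follows the same form with the age-motion coefficient gamma, and memory
performance (built in :mod:`.behavior`) loads on M and directly on age. All
latent variables are unit-variance by construction so the standardized
mediation coefficients (a, b, c') are recoverable on their own scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import CohortConfig
from ..regions import MTL_REGIONS, split_label
from .design import StudyDesign
from .rng import substream


@dataclass
class GroundTruth:
    """True generative parameters, stored alongside outputs for recovery tests."""

    region_betas: pd.DataFrame  # region, beta_turn, beta_landmark, lam
    coupling_w: np.ndarray  # participants x regions, in [0, 1]
    mediator: np.ndarray  # latent M per participant (unit variance)
    motion_propensity: np.ndarray  # standardized motion level per participant
    mediation_a: float
    mediation_b: float
    mediation_c_prime: float
    motion_gamma: float
    noise_sd: float
    seed: int
    mediator_regions: tuple[str, ...] = field(default=MTL_REGIONS)

    def w(self, participant_index: int, region_index: int) -> float:
        return float(self.coupling_w[participant_index, region_index])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def generate_ground_truth(
    design: StudyDesign,
    config: CohortConfig,
    seed: int = 0,
    mediator_regions: tuple[str, ...] = MTL_REGIONS,
) -> GroundTruth:
    rng = substream(seed, "truth")
    n_p = design.n_participants
    z_age = _zscore(design.ages)

    a = config.mediation_a
    mediator = a * z_age + np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n_p)

    g = config.motion_gamma
    propensity = g * z_age + np.sqrt(max(0.0, 1.0 - g * g)) * rng.standard_normal(n_p)

    regions = design.regions
    rows = []
    for label in regions:
        name, _ = split_label(label)
        b1, b2 = config.region_betas[name]
        lam = np.sqrt(max(0.0, 1.0 - b1 * b1 - b2 * b2))
        rows.append({"region": label, "beta_turn": b1, "beta_landmark": b2, "lam": lam})
    region_betas = pd.DataFrame(rows)

    w = np.empty((n_p, len(regions)))
    for k, label in enumerate(regions):
        name, _ = split_label(label)
        base = config.coupling_base[name]
        if label in mediator_regions:
            w[:, k] = base + config.coupling_age_scale * mediator
        else:
            w[:, k] = base + config.coupling_noise * rng.standard_normal(n_p)
    if config.coupling_w_fixed is not None:
        w[:] = config.coupling_w_fixed
    np.clip(w, 0.0, 1.0, out=w)

    return GroundTruth(
        region_betas=region_betas,
        coupling_w=w,
        mediator=mediator,
        motion_propensity=propensity,
        mediation_a=config.mediation_a,
        mediation_b=config.mediation_b,
        mediation_c_prime=config.mediation_c_prime,
        motion_gamma=config.motion_gamma,
        noise_sd=config.noise_sd,
        seed=seed,
        mediator_regions=tuple(mediator_regions),
    )
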
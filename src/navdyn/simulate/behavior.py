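"""Trial responses and the latent performance chain.

Latent performance is p_i = b*M_i + c'*z(age_i) + resid, with M_i the
participant's latent medial-temporal coupling (see :mod:`.truth`); the
residual variance is set so p_i has unit variance when the paths allow it.
Trial correctness is Bernoulli with probability affine in p_i, and a small
configurable fraction of trials have no response (scored incorrect
downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import CohortConfig
from .design import StudyDesign
from .rng import substream
from .truth import GroundTruth, _zscore


@dataclass
class BehaviorTable:
    responses: pd.DataFrame  # participant_id, episode, question_type, responded, correct
    performance_latent: np.ndarray  # unit-variance latent score per participant


def generate_behavior(
    design: StudyDesign,
    truth: GroundTruth,
    config: CohortConfig,
    seed: int = 0,
) -> BehaviorTable:
    rng = substream(seed, "behavior")
    n_p = design.n_participants
    z_age = _zscore(design.ages)
    a, b, c_prime = truth.mediation_a, truth.mediation_b, truth.mediation_c_prime

    # var(b*M + c'*X) = b^2 + c'^2 + 2*a*b*c' when M = a*X + sqrt(1-a^2)*e.
    explained = b * b + c_prime * c_prime + 2.0 * a * b * c_prime
    resid_sd = np.sqrt(max(0.0, 1.0 - explained))
    latent = b * truth.mediator + c_prime * z_age + resid_sd * rng.standard_normal(n_p)

    prob = np.clip(
        config.correct_base_prob + config.perf_prob_slope * latent, 0.02, 0.98
    )
    n_e = design.n_episodes
    ep = design.episodes.sort_values("episode")
    responded = rng.random((n_p, n_e)) >= config.missing_response_fraction
    correct = (rng.random((n_p, n_e)) < prob[:, None]) & responded
    responses = pd.DataFrame(
        {
            "participant_id": np.repeat(design.participant_ids, n_e),
            "episode": np.tile(ep["episode"].to_numpy(), n_p),
            "question_type": np.tile(ep["question_type"].to_numpy(), n_p),
            "responded": responded.ravel(),
            "correct": correct.ravel(),
        }
    )
    return BehaviorTable(responses=responses, performance_latent=latent)
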
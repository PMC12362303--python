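"""Configuration dataclasses for the synthetic cohort and the pipeline.

All generative parameters live in :class:`CohortConfig`; everything an
analysis stage needs beyond data lives in :class:`PipelineConfig`. Configs
load from YAML/JSON mappings and reject unknown keys before any stage runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import InvalidConfigError
from .regions import REGION_LABELS, REGION_NAMES

# Per-region baseline canonical-coupling weight w (population level). These
# are tuning constants chosen so region-mean similarity spans roughly the
# 0.02-0.22 band seen in regional intersubject-correlation studies of
# naturalistic viewing, with the visual stream high and the hippocampal
# formation low. Bilateral (same value for L and R).
DEFAULT_COUPLING_BASE: dict[str, float] = {
    "dorsal_visual_area": 0.24,
    "ventral_visual_area": 0.20,
    "early_visual_cortex": 0.21,
    "superior_parietal_lobe": 0.20,
    "middle_temporal_lateral_occipital": 0.18,
    "precuneus_parieto_occipital_sulcus": 0.16,
    "premotor_cortex": 0.14,
    "temporo_parieto_occipital_junction": 0.11,
    "inferior_parietal_lobe": 0.10,
    "dorsolateral_prefrontal": 0.07,
    "paracentral_lobule_midcingulate": 0.08,
    "parahippocampal_region": 0.07,
    "inferior_frontal_cortex": 0.06,
    "lateral_temporal_lobe": 0.05,
    "posterior_opercular_cortex": 0.055,
    "posterior_cingulate_cortex": 0.045,
    "anterior_cingulate_medial_prefrontal": 0.045,
    "auditory_association_area": 0.045,
    "somatosensory_motor_cortex": 0.045,
    "early_auditory_cortex": 0.04,
    "insular_frontal_opercular": 0.04,
    "orbitofrontal_frontopolar": 0.03,
    "hippocampal_formation": 0.04,
}

# Per-region true (beta_turn, beta_landmark) coupling of the canonical signal
# to the HRF-convolved angular-velocity and landmark-viewing regressors.
# Signs follow the field's typical pattern: dorsal-stream/attention regions
# positive for turning, default-mode regions negative, ventral stream positive
# for landmark viewing. Bilateral.
DEFAULT_REGION_BETAS: dict[str, tuple[float, float]] = {
    "dorsal_visual_area": (0.61, 0.0),
    "ventral_visual_area": (0.49, 0.20),
    "early_visual_cortex": (0.36, 0.17),
    "superior_parietal_lobe": (0.61, 0.0),
    "middle_temporal_lateral_occipital": (0.47, 0.11),
    "precuneus_parieto_occipital_sulcus": (0.58, 0.0),
    "premotor_cortex": (0.58, 0.0),
    "temporo_parieto_occipital_junction": (0.33, 0.0),
    "inferior_parietal_lobe": (0.22, 0.0),
    "dorsolateral_prefrontal": (0.13, 0.0),
    "paracentral_lobule_midcingulate": (0.48, 0.0),
    "parahippocampal_region": (0.36, 0.11),
    "inferior_frontal_cortex": (0.24, 0.0),
    "lateral_temporal_lobe": (0.0, 0.0),
    "posterior_opercular_cortex": (-0.09, 0.0),
    "posterior_cingulate_cortex": (-0.16, 0.0),
    "anterior_cingulate_medial_prefrontal": (-0.16, 0.0),
    "auditory_association_area": (0.0, 0.0),
    "somatosensory_motor_cortex": (0.25, 0.0),
    "early_auditory_cortex": (0.0, 0.0),
    "insular_frontal_opercular": (0.10, 0.0),
    "orbitofrontal_frontopolar": (-0.12, 0.0),
    "hippocampal_formation": (0.18, 0.0),
}


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic study.

    The defaults reproduce the study conditions: 76 participants (45 aged
    20-30, 31 aged 50-65), 4 runs of 6 one-minute navigation episodes
    (24 episodes, 6 per cue condition), TR 2 s, 102 s trials, an
    age-correlated head-motion confound, and memory performance linked to
    medial-temporal coupling.
    """

    # Cohort
    n_young: int = 45
    n_old: int = 31
    young_age_range: tuple[float, float] = (20.0, 30.0)
    old_age_range: tuple[float, float] = (50.0, 65.0)
    n_gaze_participants: int = 42

    # Design
    n_runs: int = 4
    trials_per_run: int = 6
    tr_s: float = 2.0
    regions: tuple[str, ...] = REGION_LABELS

    # Event streams (10 Hz, 60 s navigation window)
    min_turns: int = 4
    max_turns: int = 8
    turn_width_range_s: tuple[float, float] = (1.0, 3.0)
    stationary_margin_s: float = 2.0

    # BOLD model
    coupling_base: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING_BASE)
    )
    region_betas: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_BETAS)
    )
    coupling_w_fixed: float | None = None  # override every w[i, k]
    coupling_age_scale: float = 0.05  # MTL w shift per unit latent mediator
    coupling_noise: float = 0.03  # participant scatter of w outside the MTL
    latent_fwhm_s: float = 4.0  # smoothness of the episode-unique latent
    latent_shared: float = 0.0  # cross-region mixing of episode latents
    signal_amplitude_pct: float = 0.8
    noise_sd: float = 1.0  # 0 disables all stochastic signal noise
    baseline_noise_pct: float = 0.3
    drift_amplitude_pct: float = 0.3
    motion_artifact_gain: float = 0.6  # percent signal per mm of FD
    baseline_level: float = 1000.0

    # Motion
    motion_enabled: bool = True
    motion_gamma: float = 0.493  # target age-FD correlation
    fd_base_mm: float = 0.12
    fd_spread: float = 0.35
    motion_spike_prob: float = 0.02
    motion_spike_scale: float = 5.0

    # Behavior / mediation ground truth (standardized scale)
    mediation_a: float = -0.5
    mediation_b: float = 0.5
    mediation_c_prime: float = -0.4
    correct_base_prob: float = 0.70
    perf_prob_slope: float = 0.12
    missing_response_fraction: float = 0.05

    # Gaze simulation
    gaze_on_prob_gain: float = 0.85
    gaze_on_prob_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise InvalidConfigError("need at least 2 participants per age group")
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise InvalidConfigError("n_runs and trials_per_run must be positive")
        if self.n_runs * self.trials_per_run % 4 != 0:
            raise InvalidConfigError(
                "episode count must divide evenly into the 4 cue conditions"
            )
        if self.tr_s <= 0:
            raise InvalidConfigError("tr_s must be positive")
        if not (0 < self.min_turns <= self.max_turns):
            raise InvalidConfigError("turn-count range invalid")
        unknown = [r for r in self.regions if r not in REGION_LABELS]
        if unknown:
            raise InvalidConfigError(f"unknown region labels: {unknown}")
        if self.coupling_w_fixed is not None and not (
            0.0 <= self.coupling_w_fixed <= 1.0
        ):
            raise InvalidConfigError("coupling_w_fixed must lie in [0, 1]")
        for name in REGION_NAMES:
            if name not in self.coupling_base or name not in self.region_betas:
                raise InvalidConfigError(f"missing generative params for {name}")
            b1, b2 = self.region_betas[name]
            if b1 * b1 + b2 * b2 > 1.0:
                raise InvalidConfigError(
                    f"region {name}: beta_turn^2 + beta_landmark^2 must be <= 1"
                )
        if not (0.0 <= self.missing_response_fraction < 1.0):
            raise InvalidConfigError("missing_response_fraction must be in [0, 1)")

    @property
    def n_participants(self) -> int:
        return self.n_young + self.n_old

    @property
    def n_episodes(self) -> int:
        return self.n_runs * self.trials_per_run


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis end to end."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    n_perm: int = 10000
    fdr_alpha: float = 0.05
    seed_region: str = "hippocampal_formation"  # bilateral seed by default
    ics_perm_strategy: str = "relabel"  # or "pairwise_same" / "pairwise_any"
    candidate_filter: bool = True  # gate mediation on a<0, p<0.05
    regressor_sampling: str = "onset"  # or "midpoint"
    run_events: bool = True
    run_isfc: bool = True
    run_seedwise: bool = True
    run_mediation: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise InvalidConfigError("n_perm must be >= 1")
        if not (0 < self.fdr_alpha < 1):
            raise InvalidConfigError("fdr_alpha must lie in (0, 1)")
        if self.ics_perm_strategy not in ("relabel", "pairwise_same", "pairwise_any"):
            raise InvalidConfigError(
                f"unknown ics_perm_strategy: {self.ics_perm_strategy!r}"
            )
        if self.regressor_sampling not in ("onset", "midpoint"):
            raise InvalidConfigError(
                f"unknown regressor_sampling: {self.regressor_sampling!r}"
            )
        if self.seed < 0:
            raise InvalidConfigError("seed must be a non-negative integer")


def _from_mapping(cls: type, data: Mapping[str, Any]) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise InvalidConfigError(f"unknown config keys for {cls.__name__}: {unknown}")
    kwargs = dict(data)
    # tuples survive YAML as lists
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in kwargs[f.name]
            )
    return cls(**kwargs)


def cohort_config_from_dict(data: Mapping[str, Any]) -> CohortConfig:
    return _from_mapping(CohortConfig, data)


def pipeline_config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    data = dict(data)
    cohort = data.pop("cohort", {})
    cfg = _from_mapping(PipelineConfig, {**data, "cohort": None})
    cfg.cohort = cohort_config_from_dict(cohort) if isinstance(cohort, Mapping) else (
        cohort or CohortConfig()
    )
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise InvalidConfigError(f"config root must be a mapping, got {type(data)}")
    return pipeline_config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    """Serializable dict form (used in provenance manifests)."""
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=list))
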
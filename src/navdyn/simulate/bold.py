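"""Region-level BOLD generation.

Canonical dynamics for region k and episode e follow

    g[k,e](t) = beta_turn[k] * z(X_turn) + beta_landmark[k] * z(X_view)
                + lam[k] * latent[k,e](t),

where X_turn is the HRF-convolved angular velocity, X_view the HRF-convolved
binary landmark-viewing mask (top-20% threshold of the latent gaze ratio,
exactly the regressor construction the analysis fits), and latent[k,e] an
episode-unique Gaussian-smoothed noise process (4 s FWHM) that makes episode
decoding non-trivial. g is standardized per region x episode over the
retained frames, so an individual's navigation signal

    w[i,k] * g[k,e] + sqrt(1 - w[i,k]^2) * eps

has population correlation w[i,k] with the canonical signal.

Full runs embed the navigation dynamics into a 102 s trial grid with
phase-specific signal offsets, low-frequency drift, an FD-proportional motion
artifact shared across regions, and a raw-signal baseline so the series
arrives in scanner-like units (percent-change conversion happens downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..config import CohortConfig
from ..errors import SchemaError
from ..events import landmark_mask
from ..hrf import HRFKernel, build_regressor, canonical_hrf
from ..prep import framewise_displacement_frames
from .design import NAV_EXCLUDED_FRAMES, StudyDesign
from .rng import substream
from .streams import EpisodeStream
from .truth import GroundTruth

#: Percent-signal offsets of the non-navigation task phases.
PHASE_OFFSETS_PCT: dict[str, float] = {
    "fixation1": 0.0,
    "map1": 0.4,
    "navigation": 0.5,
    "fixation2": 0.0,
    "map2": 0.4,
    "question": 0.3,
    "iti": 0.0,
}


@dataclass
class CanonicalSignals:
    """Ground-truth canonical dynamics and the regressors that drive them."""

    g: np.ndarray  # regions x episodes x nav_frames, standardized
    x_turn: np.ndarray  # episodes x nav_frames, globally standardized
    x_view: np.ndarray  # episodes x nav_frames, globally standardized
    view_mask: np.ndarray  # episodes x 600, binary landmark-viewing mask

    def retained(self, design: StudyDesign) -> np.ndarray:
        return self.g[:, :, NAV_EXCLUDED_FRAMES:]


def _standardize_concat(x: np.ndarray, retained: slice) -> np.ndarray:
    """Standardize (episodes x frames) using retained-frame concatenation stats."""
    ref = x[:, retained].ravel()
    sd = ref.std(ddof=1)
    if sd == 0:
        return x - ref.mean()
    return (x - ref.mean()) / sd


def canonical_signals(
    design: StudyDesign,
    streams: list[EpisodeStream],
    truth: GroundTruth,
    config: CohortConfig,
    hrf: HRFKernel | None = None,
    seed: int = 0,
) -> CanonicalSignals:
    """Build the canonical signal g for every region x episode."""
    if len(streams) != design.n_episodes:
        raise SchemaError(
            f"{len(streams)} streams for {design.n_episodes} design episodes"
        )
    hrf = hrf or canonical_hrf()
    rng = substream(seed, "bold_canonical")
    n_k, n_e, n_f = len(design.regions), design.n_episodes, design.nav_frames
    frame_times = np.arange(n_f) * design.tr_s
    retained = slice(NAV_EXCLUDED_FRAMES, None)

    x_turn = np.empty((n_e, n_f))
    x_view = np.empty((n_e, n_f))
    masks = np.zeros((n_e, streams[0].time_s.size))
    for stream in sorted(streams, key=lambda s: s.episode):
        e = stream.episode
        x_turn[e] = build_regressor(
            stream.angular_velocity, hrf, frame_times, tr_s=design.tr_s
        )
        if np.any(stream.gaze_ratio > 0):
            masks[e] = landmark_mask(stream.gaze_ratio).astype(float)
        x_view[e] = build_regressor(masks[e], hrf, frame_times, tr_s=design.tr_s)
    x_turn = _standardize_concat(x_turn, retained)
    x_view = _standardize_concat(x_view, retained)

    # Episode-unique smooth latents; optional shared component across regions.
    sigma_frames = config.latent_fwhm_s / 2.355 / design.tr_s
    private = gaussian_filter1d(rng.standard_normal((n_k, n_e, n_f)), sigma_frames, axis=-1)
    s = config.latent_shared
    if s > 0:
        shared = gaussian_filter1d(rng.standard_normal((n_e, n_f)), sigma_frames, axis=-1)
        latent = np.sqrt(1.0 - s * s) * private + s * shared[None, :, :]
    else:
        latent = private
    lat_sd = latent[:, :, retained].std(axis=-1, ddof=1, keepdims=True)
    latent = (latent - latent[:, :, retained].mean(axis=-1, keepdims=True)) / lat_sd

    b1 = truth.region_betas["beta_turn"].to_numpy()[:, None, None]
    b2 = truth.region_betas["beta_landmark"].to_numpy()[:, None, None]
    lam = truth.region_betas["lam"].to_numpy()[:, None, None]
    g = b1 * x_turn[None] + b2 * x_view[None] + lam * latent
    # Unit variance per region over the retained-frame concatenation, so the
    # event betas stay on their own scale in the composed signal and the
    # individual-to-canonical correlation averages to the coupling weight w.
    ref = g[:, :, retained].reshape(g.shape[0], -1)
    g = (g - ref.mean(axis=1)[:, None, None]) / ref.std(axis=1, ddof=1)[:, None, None]
    return CanonicalSignals(g=g, x_turn=x_turn, x_view=x_view, view_mask=masks)


def simulate_segments(
    design: StudyDesign,
    canonical: CanonicalSignals,
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Individual navigation dynamics, shape (participants, regions, episodes, frames).

    Fast path used by tests and by :func:`generate_bold`: mixes the canonical
    signal with unit-variance noise at weight w without embedding into runs.
    """
    n_p = design.n_participants
    n_k, n_e, n_f = canonical.g.shape
    w = truth.coupling_w[:, :, None, None]
    noise_on = 1.0 if config.noise_sd > 0 else 0.0
    eps = rng.standard_normal((n_p, n_k, n_e, n_f)) if noise_on else np.zeros(
        (n_p, n_k, n_e, n_f)
    )
    return w * canonical.g[None] + np.sqrt(1.0 - w * w) * eps


def generate_bold(
    design: StudyDesign,
    streams: list[EpisodeStream],
    truth: GroundTruth,
    config: CohortConfig,
    motion: np.ndarray | None = None,
    hrf: HRFKernel | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, CanonicalSignals]:
    """Raw run series for every participant x run.

    Returns ``(raw, canonical)`` where ``raw`` has shape
    (participants, runs, frames_per_run, regions) in scanner-like units.
    """
    canonical = canonical_signals(design, streams, truth, config, hrf=hrf, seed=seed)
    rng = substream(seed, "bold_noise")
    segments = simulate_segments(design, canonical, truth, config, rng)

    n_p, n_r, n_f = design.n_participants, design.n_runs, design.frames_per_run
    n_k = len(design.regions)
    noise_on = 1.0 if config.noise_sd > 0 else 0.0
    pct = np.zeros((n_p, n_r, n_f, n_k))

    # Phase offsets (identical across regions and participants).
    phase_series = np.zeros(n_f)
    for trial in range(design.trials_per_run):
        for phase, _ in design.layout.phases:
            phase_series[design.phase_frames(phase, trial)] = PHASE_OFFSETS_PCT[phase]
    pct += phase_series[None, None, :, None]

    # Background noise outside the navigation windows.
    if noise_on:
        nav_mask = np.zeros(n_f, dtype=bool)
        for trial in range(design.trials_per_run):
            nav_mask[design.navigation_frames_in_run(trial)] = True
        bg = config.baseline_noise_pct * config.noise_sd * rng.standard_normal(
            (n_p, n_r, n_f, n_k)
        )
        bg[:, :, nav_mask, :] = 0.0
        pct += bg

    # Navigation dynamics.
    amp = config.signal_amplitude_pct
    ep = design.episodes
    for _, row in ep.iterrows():
        r, trial, e = int(row["run"]), int(row["trial_in_run"]), int(row["episode"])
        frames = design.navigation_frames_in_run(trial)
        pct[:, r, frames, :] += amp * np.transpose(segments[:, :, e, :], (0, 2, 1))

    # Low-frequency drift, shared across regions within a run.
    if config.drift_amplitude_pct > 0 and noise_on:
        t = design.run_frame_times()
        for i in range(n_p):
            for r in range(n_r):
                phases = rng.uniform(0, 2 * np.pi, 2)
                amps = rng.uniform(0.5, 1.0, 2)
                drift = config.drift_amplitude_pct * (
                    amps[0] * np.cos(2 * np.pi * t / 120.0 + phases[0])
                    + amps[1] * np.cos(2 * np.pi * t / 80.0 + phases[1])
                )
                pct[i, r] += drift[:, None]

    # FD-proportional artifact shared across regions (motion confound).
    if motion is not None and config.motion_artifact_gain > 0:
        fd = framewise_displacement_frames(motion)  # (n_p, n_r, n_f)
        pct += config.motion_artifact_gain * fd[:, :, :, None]

    raw = config.baseline_level * (1.0 + pct / 100.0)
    return raw, canonical
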
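"""One-call assembly of a complete synthetic study."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ..config import CohortConfig
from ..hrf import HRFKernel, canonical_hrf
from ..prep import RunSeries
from ..regions import MTL_REGIONS
from .behavior import BehaviorTable, generate_behavior
from .bold import CanonicalSignals, generate_bold
from .design import StudyDesign, generate_design
from .gaze import generate_gaze
from .motion import generate_motion
from .streams import EpisodeStream, generate_event_streams
from .truth import GroundTruth, generate_ground_truth


@dataclass
class SyntheticCohort:
    """All generated artifacts of one synthetic study."""

    config: CohortConfig
    seed: int
    design: StudyDesign
    truth: GroundTruth
    streams: list[EpisodeStream]
    motion: np.ndarray  # participants x runs x frames x 6
    gaze: dict[int, np.ndarray]  # episode -> gaze participants x 250 Hz flags
    bold: np.ndarray  # participants x runs x frames x regions, raw units
    canonical: CanonicalSignals
    behavior: BehaviorTable

    def iter_runs(self) -> Iterator[RunSeries]:
        times = self.design.run_frame_times()
        for i, pid in enumerate(self.design.participant_ids):
            for r in range(self.design.n_runs):
                yield RunSeries(
                    participant_id=pid,
                    run_index=r,
                    frame_times_s=times,
                    values=self.bold[i, r],
                    regions=self.design.regions,
                    stage="raw",
                )

    def run(self, participant_index: int, run_index: int) -> RunSeries:
        return RunSeries(
            participant_id=self.design.participant_ids[participant_index],
            run_index=run_index,
            frame_times_s=self.design.run_frame_times(),
            values=self.bold[participant_index, run_index],
            regions=self.design.regions,
            stage="raw",
        )


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    hrf: HRFKernel | None = None,
    mediator_regions: tuple[str, ...] = MTL_REGIONS,
    with_gaze: bool = True,
) -> SyntheticCohort:
    """Generate a full synthetic study from one master seed.

    All randomness flows from named substreams of ``seed``, so the same
    (config, seed) pair reproduces every table byte for byte.
    """
    config = config or CohortConfig()
    design = generate_design(config, seed)
    truth = generate_ground_truth(design, config, seed, mediator_regions)
    streams = generate_event_streams(design, config, seed)
    motion = generate_motion(design, truth, config, seed)
    bold, canonical = generate_bold(
        design, streams, truth, config, motion=motion, hrf=hrf or canonical_hrf(), seed=seed
    )
    gaze = generate_gaze(design, streams, config, seed) if with_gaze else {}
    behavior = generate_behavior(design, truth, config, seed)
    return SyntheticCohort(
        config=config,
        seed=seed,
        design=design,
        truth=truth,
        streams=streams,
        motion=motion,
        gaze=gaze,
        bold=bold,
        canonical=canonical,
        behavior=behavior,
    )
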
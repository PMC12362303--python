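"""Relate canonical dynamics to turning and landmark-viewing events.

Angular velocity and the binary landmark-viewing mask (top 20% of the group
gaze ratio per landmark trial) are convolved with a double-gamma HRF at
10 Hz, sampled at frame times, and regressed against each region's canonical
dynamics concatenated over all 24 episodes (624 frames).
"""

import numpy as np

from navdyn import CohortConfig, build_segment_array, canonical_hrf
from navdyn.events import aggregate_gaze, fit_event_regression, landmark_mask
from navdyn.hrf import build_regressor
from navdyn.pipeline import prep_stage
from navdyn.simulate import generate_cohort
from navdyn.simulate.design import LANDMARK_CONDITIONS, NAV_EXCLUDED_FRAMES

cohort = generate_cohort(CohortConfig(n_young=8, n_old=8), seed=2)
prep = prep_stage(cohort)
segments = build_segment_array(prep.zscored_runs, cohort.design)

hrf = canonical_hrf(dt_s=0.1)
print(f"HRF: double gamma, peak at {hrf.peak_time_s:.1f} s, 32 s support")

frame_times = np.arange(cohort.design.nav_frames) * cohort.design.tr_s
x_turn, x_view = [], []
for stream in sorted(cohort.streams, key=lambda s: s.episode):
    xt = build_regressor(stream.angular_velocity, hrf, frame_times)
    if stream.condition in LANDMARK_CONDITIONS:
        ratio = aggregate_gaze(cohort.gaze[stream.episode])  # 250 Hz -> 10 Hz
        mask = landmark_mask(ratio).astype(float)  # top-20% threshold
    else:
        mask = np.zeros_like(stream.gaze_ratio)
    x_turn.append(xt[NAV_EXCLUDED_FRAMES:])
    x_view.append(build_regressor(mask, hrf, frame_times)[NAV_EXCLUDED_FRAMES:])

canonical = segments.data.mean(axis=0)  # all-participant average dynamics
Y = canonical.transpose(1, 2, 0).reshape(-1, canonical.shape[0])
fit = fit_event_regression(Y, np.concatenate(x_turn), np.concatenate(x_view),
                           segments.regions)

print("\nstrongest turning coupling (standardized beta):")
print(fit.nlargest(4, "beta_turn")[["label", "beta_turn", "p_turn"]]
      .to_string(index=False))
print("\nstrongest landmark-viewing coupling:")
print(fit.nlargest(4, "beta_landmark")[["label", "beta_landmark", "p_landmark"]]
      .to_string(index=False))
print("\n  -> dorsal-stream regions lock to turns; the ventral stream also")
print("     responds to landmark viewing, matching the generative betas")
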
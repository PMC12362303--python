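"""End-to-end orchestration: simulate -> prep -> similarity/decoding ->
event regression -> connectivity -> group statistics.

Each stage is a plain function over in-memory objects; :func:`run_all`
chains them, optionally writing every table as TSV with a provenance
manifest (config hash, seed, package versions). Reruns with the same config
and seed are bit-identical for all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_to_dict
from .errors import StageDependencyError
from .events import aggregate_gaze, fit_event_regression, landmark_mask
from .hrf import build_regressor, canonical_hrf
from .ics import (
    SegmentArray,
    accuracy_by_episode,
    build_segment_array,
    condition_contrast,
    cross_ics,
    decode_episodes,
    decoding_accuracy_by_region,
    decoding_permutation_test,
    ics_permutation_test,
    ics_table,
    mean_ics_by_region,
)
from .isfc import isfc_profile, seedwise_summary
from .prep import (
    ConfoundMatrix,
    average_activation,
    extract_windows,
    framewise_displacement_frames,
    percent_signal_change,
    regress_confounds,
    spatial_memory_performance,
    zscore_run,
)
from .simulate import SyntheticCohort, generate_cohort
from .simulate.design import LANDMARK_CONDITIONS, NAV_EXCLUDED_FRAMES
from .stats import (
    activation_vs_ics_comparison,
    age_regression,
    correlate_with_performance,
    fdr_adjust,
    mediation_scan,
)
from . import io as nio

logger = logging.getLogger(__name__)


@dataclass
class PrepResult:
    zscored_runs: list
    activation: pd.DataFrame  # participants x regions (episode-averaged)
    activation_long: pd.DataFrame
    performance: pd.Series  # per participant
    mean_fd: np.ndarray  # per participant


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SyntheticCohort
    prep: PrepResult
    segments: SegmentArray
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def prep_stage(cohort: SyntheticCohort) -> PrepResult:
    """Run-wise conditioning plus activation, performance and motion summaries."""
    design = cohort.design
    zscored = []
    act_rows = []
    for run in cohort.iter_runs():
        i = design.participant_ids.index(run.participant_id)
        params6 = cohort.motion[i, run.run_index]
        psc = percent_signal_change(run)
        windows = extract_windows(psc, design)
        act_rows.append(average_activation(psc, windows))
        cleaned = regress_confounds(psc, ConfoundMatrix.build(params6))
        zscored.append(zscore_run(cleaned))
    activation_long = pd.concat(act_rows, ignore_index=True)
    activation = (
        activation_long.groupby(["participant_id", "region"], sort=False)["activation"]
        .mean()
        .unstack()
        .reindex(index=list(design.participant_ids), columns=list(design.regions))
    )
    performance = spatial_memory_performance(cohort.behavior.responses).reindex(
        list(design.participant_ids)
    )
    mean_fd = framewise_displacement_frames(cohort.motion).mean(axis=(1, 2))
    return PrepResult(
        zscored_runs=zscored,
        activation=activation,
        activation_long=activation_long,
        performance=performance,
        mean_fd=mean_fd,
    )


def ics_stage(
    result: PipelineResult, n_perm: int, seed: int, strategy: str
) -> None:
    segments = result.segments
    design = result.cohort.design
    C = cross_ics(segments)
    table = ics_table(segments, cross=C)
    summary = mean_ics_by_region(table)
    perm = ics_permutation_test(
        segments, n_perm=n_perm, seed=seed, cross=C, strategy=strategy
    )
    summary = summary.merge(perm[["label", "p_perm"]], on="label")
    summary["p_fdr"] = fdr_adjust(summary["p_perm"].to_numpy())

    decoding = decode_episodes(segments, cross=C)
    acc = decoding_accuracy_by_region(decoding)
    dperm = decoding_permutation_test(segments, n_perm=n_perm, seed=seed + 1, cross=C)
    acc = acc.merge(dperm[["label", "null_mean_accuracy", "p_perm"]], on="label")
    acc["p_fdr"] = fdr_adjust(acc["p_perm"].to_numpy())

    # Landmark vs no-landmark decoding contrast per region (6 vs 6 episodes).
    cond = design.episodes.sort_values("episode")["condition"].to_numpy()
    lm = cond == "landmark"
    none = cond == "none"
    keep = lm | none
    rows = []
    for label in segments.regions:
        ep_acc = accuracy_by_episode(decoding, label)
        t, df, p = condition_contrast(ep_acc[keep], lm[keep])
        rows.append({"label": label, "t": t, "df": df, "p": p})
    result.tables["ics_long"] = table
    result.tables["ics_summary"] = summary
    result.tables["decoding_long"] = decoding
    result.tables["decoding_summary"] = acc
    result.tables["condition_contrast"] = pd.DataFrame(rows)


def events_stage(result: PipelineResult, sampling: str) -> None:
    """Event regression of the all-participant canonical dynamics."""
    cohort = result.cohort
    design = cohort.design
    hrf = canonical_hrf()
    n_f = design.nav_frames
    frame_times = np.arange(n_f) * design.tr_s
    retained = slice(NAV_EXCLUDED_FRAMES, None)

    x_turn, x_view = [], []
    for stream in sorted(cohort.streams, key=lambda s: s.episode):
        xt = build_regressor(
            stream.angular_velocity, hrf, frame_times, sampling=sampling, tr_s=design.tr_s
        )
        if stream.condition in LANDMARK_CONDITIONS and stream.episode in cohort.gaze:
            gaze = cohort.gaze[stream.episode]
            # accept raw 250 Hz flags or an already-aggregated 10 Hz ratio
            ratio = gaze if np.ndim(gaze) == 1 else aggregate_gaze(gaze)
            mask = landmark_mask(ratio).astype(float)
        else:
            mask = np.zeros_like(stream.gaze_ratio)
        xv = build_regressor(mask, hrf, frame_times, sampling=sampling, tr_s=design.tr_s)
        x_turn.append(xt[retained])
        x_view.append(xv[retained])
    X1 = np.concatenate(x_turn)
    X2 = np.concatenate(x_view)

    canonical = result.segments.data.mean(axis=0)  # regions x episodes x frames
    Y = canonical.transpose(1, 2, 0).reshape(-1, canonical.shape[0])
    fit = fit_event_regression(Y, X1, X2, result.segments.regions)
    fit["p_fdr_turn"] = fdr_adjust(fit["p_turn"].to_numpy())
    fit["p_fdr_landmark"] = fdr_adjust(fit["p_landmark"].to_numpy())
    result.tables["event_regression"] = fit


def isfc_stage(result: PipelineResult, seed_region: str, with_seedwise: bool) -> None:
    profile = isfc_profile(result.segments, seed_region)
    corr = correlate_with_performance(
        profile, result.prep.performance.to_numpy(), result.prep.mean_fd
    )
    result.tables["isfc_profile"] = profile.reset_index(names="participant_id")
    result.tables["isfc_performance"] = corr
    if with_seedwise:
        result.tables["isfc_seedwise"] = seedwise_summary(
            result.segments,
            result.prep.performance.to_numpy(),
            result.prep.mean_fd,
        )


def stats_stage(result: PipelineResult, candidate_filter: bool, alpha: float) -> None:
    design = result.cohort.design
    perf = result.prep.performance.to_numpy()
    motion = result.prep.mean_fd
    ages = design.ages

    ics_wide = (
        result.tables["ics_long"]
        .groupby(["participant_id", "region"], sort=False)["z"]
        .mean()
        .unstack()
        .reindex(index=list(design.participant_ids), columns=list(design.regions))
    )
    result.tables["ics_by_participant"] = ics_wide.reset_index(names="participant_id")

    result.tables["performance_vs_measures"] = activation_vs_ics_comparison(
        result.prep.activation, ics_wide, perf, motion
    )

    rows = []
    for label in design.regions:
        res = age_regression(ics_wide[label].to_numpy(), ages, motion)
        rows.append(
            {
                "label": label,
                "coef_age": res.coef_age,
                "p_age": res.p_age,
                "coef_motion": res.coef_motion,
                "vif_age": res.vif_age,
            }
        )
    result.tables["age_regression_ics"] = pd.DataFrame(rows)

    result.tables["mediation_ics"] = mediation_scan(
        ics_wide, ages, perf, motion, candidate_filter=candidate_filter, alpha=alpha
    )
    if "isfc_profile" in result.tables:
        profile = result.tables["isfc_profile"].set_index("participant_id")
        result.tables["mediation_isfc"] = mediation_scan(
            profile, ages, perf, motion, candidate_filter=candidate_filter, alpha=alpha
        )
        rows = []
        for label in profile.columns:
            res = age_regression(profile[label].to_numpy(), ages, motion)
            rows.append({"label": label, "coef_age": res.coef_age, "p_age": res.p_age})
        result.tables["age_regression_isfc"] = pd.DataFrame(rows)

    # Behavioral headline numbers.
    from .stats import partial_pearson, pearson_p

    r_raw = float(np.corrcoef(ages, perf)[0, 1])
    r_partial, p_partial = partial_pearson(ages, perf, motion)
    result.tables["behavior_summary"] = pd.DataFrame(
        [
            {
                "age_performance_r": r_raw,
                "age_performance_p": pearson_p(r_raw, len(ages)),
                "age_performance_r_motion_partialled": r_partial,
                "age_motion_r": float(np.corrcoef(ages, motion)[0, 1]),
                "mean_performance": float(np.mean(perf)),
            }
        ]
    )


def run_all(config: PipelineConfig | None = None, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage; optionally write all tables plus a manifest."""
    config = config or PipelineConfig()
    logger.info("simulating cohort (n=%d)", config.cohort.n_participants)
    cohort = generate_cohort(config.cohort, config.seed, with_gaze=config.run_events)
    logger.info("conditioning runs")
    prep = prep_stage(cohort)
    segments = build_segment_array(prep.zscored_runs, cohort.design)
    result = PipelineResult(config=config, cohort=cohort, prep=prep, segments=segments)

    logger.info("similarity and decoding (n_perm=%d)", config.n_perm)
    ics_stage(result, config.n_perm, config.seed, config.ics_perm_strategy)
    if config.run_events:
        logger.info("event regression")
        events_stage(result, config.regressor_sampling)
    if config.run_isfc:
        logger.info("intersubject functional connectivity")
        isfc_stage(result, config.seed_region, config.run_seedwise)
    logger.info("group statistics")
    stats_stage(result, config.candidate_filter, config.fdr_alpha)

    ptable = nio.participants_frame(cohort.design, prep.mean_fd)
    ptable["performance"] = prep.performance.to_numpy()
    result.tables["participants"] = ptable

    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "results").mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in result.tables.items():
        path = nio.write_table(df, out / "results" / f"{name}.tsv")
        written.append(str(path.relative_to(out)))
    if getattr(result.cohort, "truth", None) is not None:
        nio.write_ground_truth(
            result.cohort.truth, out / "results" / "ground_truth.json"
        )
        written.append("results/ground_truth.json")

    cfg_dict = config_to_dict(result.config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "package": "navdyn",
        "version": __version__,
        "seed": result.config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": sorted(written),
        "versions": _library_versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _library_versions() -> dict[str, str]:
    import pandas
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.version.version,
        "statsmodels": statsmodels.__version__,
    }


def require_outputs(out_dir: str | Path, names: list[str]) -> None:
    """Raise a stage-dependency error naming any missing upstream table."""
    out = Path(out_dir)
    missing = [n for n in names if not (out / "results" / f"{n}.tsv").exists()]
    if missing:
        raise StageDependencyError(
            f"missing upstream outputs in {out}: {missing}"
        )
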
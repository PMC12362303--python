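"""Individual-to-canonical similarity, episode decoding, and permutation tests.

The canonical dynamics of a region during an episode are the frame-wise mean
time course over all participants except the tested one (leave-one-subject-
out). ICS is the Fisher-Z-transformed Pearson correlation between an
individual's retained navigation segment and that template. Decoding
predicts the episode whose template correlates best with the individual
segment; chance is 1/n_episodes (1/24 = 0.041 in the default design).

Both inference procedures are permutation tests: the mean-ICS null pairs a
template with an individual segment from a different, randomly chosen
episode, and the decoding null permutes the episode labels of the templates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidConfigError, SchemaError
from .prep import RunSeries, TrialWindows, extract_windows
from .regions import split_label

#: |r| is clipped here before arctanh so Fisher Z stays finite.
FISHER_CLIP: float = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing arctanh with clipping at |r| = 1 - 1e-7."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


@dataclass
class SegmentArray:
    """Retained navigation segments for a whole cohort.

    ``data`` has shape (participants, regions, episodes, frames); frames are
    the 26 retained navigation frames, z-scored at the run level upstream.
    """

    data: np.ndarray
    participants: tuple[str, ...]
    regions: tuple[str, ...]
    episodes: tuple[int, ...]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def __post_init__(self) -> None:
        n_p, n_k, n_e, _ = self.data.shape
        if (n_p, n_k, n_e) != (
            len(self.participants),
            len(self.regions),
            len(self.episodes),
        ):
            raise SchemaError("segment array labels do not match data shape")
        if not np.all(np.isfinite(self.data)):
            raise SchemaError("segments must be finite")


def build_segment_array(runs: list[RunSeries], design) -> SegmentArray:
    """Collect retained navigation segments from z-scored runs."""
    participants = tuple(dict.fromkeys(r.participant_id for r in runs))
    regions = runs[0].regions
    n_e = design.n_episodes
    data = np.full(
        (len(participants), len(regions), n_e, design.retained_nav_frames), np.nan
    )
    p_index = {p: i for i, p in enumerate(participants)}
    for run in runs:
        if run.stage != "zscored":
            raise SchemaError("segments are extracted from z-scored runs")
        windows: list[TrialWindows] = extract_windows(run, design)
        for w in windows:
            seg = run.values[w.navigation_frames, :].T  # regions x frames
            data[p_index[run.participant_id], :, w.episode, :] = seg
    if np.any(np.isnan(data)):
        raise SchemaError("missing participant x episode segments")
    return SegmentArray(
        data=data,
        participants=participants,
        regions=regions,
        episodes=tuple(range(n_e)),
    )


def canonical_dynamics(segments: np.ndarray, exclude: int) -> np.ndarray:
    """Frame-wise mean over participants except ``exclude``.

    ``segments`` is (participants, frames); needs at least 2 participants.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.shape[0] < 2:
        raise InvalidConfigError("canonical dynamics need at least 2 participants")
    mask = np.ones(segments.shape[0], dtype=bool)
    mask[exclude] = False
    return segments[mask].mean(axis=0)


def _unit_rows(x: np.ndarray) -> np.ndarray:
    """Center and L2-normalize along the last axis (Pearson via dot product)."""
    x = x - x.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise InvalidConfigError("zero-variance segment encountered")
    return x / norm


def ics(individual: np.ndarray, template: np.ndarray) -> tuple[float, float]:
    """Pearson r and Fisher Z between one segment and its canonical template."""
    a = _unit_rows(np.asarray(individual, dtype=float)[None, :])[0]
    b = _unit_rows(np.asarray(template, dtype=float)[None, :])[0]
    r = float(np.clip(a @ b, -1.0, 1.0))
    return r, float(fisher_z(r))


def cross_ics(segments: SegmentArray) -> np.ndarray:
    """All individual x template correlations under leave-one-subject-out.

    Returns C with shape (participants, regions, episode_of_individual,
    episode_of_template): C[i, k, e, f] is the Pearson r between participant
    i's segment of episode e and the template (mean over all others) of
    episode f, in region k.
    """
    S = segments.data
    n_p = S.shape[0]
    if n_p < 2:
        raise InvalidConfigError("need at least 2 participants")
    total = S.sum(axis=0)
    C = np.empty(S.shape[:3] + (S.shape[2],))
    for i in range(n_p):
        template = (total - S[i]) / (n_p - 1)
        a = _unit_rows(S[i])  # k x e x t
        b = _unit_rows(template)  # k x f x t
        C[i] = np.clip(np.einsum("ket,kft->kef", a, b), -1.0, 1.0)
    return C


def ics_table(segments: SegmentArray, cross: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format ICS records: participant, region, episode, r, z."""
    C = cross if cross is not None else cross_ics(segments)
    n_p, n_k, n_e, _ = C.shape
    diag = C[:, :, np.arange(n_e), np.arange(n_e)]  # i x k x e
    idx = pd.MultiIndex.from_product(
        [segments.participants, segments.regions, segments.episodes],
        names=["participant_id", "region", "episode"],
    )
    df = pd.DataFrame(index=idx).reset_index()
    df["r"] = diag.ravel()
    df["z"] = fisher_z(diag).ravel()
    return df


def mean_ics_by_region(table: pd.DataFrame) -> pd.DataFrame:
    """Region summary: mean ICS (Fisher Z) and SE over participants."""
    per_participant = (
        table.groupby(["region", "participant_id"], sort=False)["z"].mean().reset_index()
    )
    out = []
    for region, d in per_participant.groupby("region", sort=False):
        vals = d["z"].to_numpy()
        name, hemi = split_label(region)
        out.append(
            {
                "region": name,
                "hemisphere": hemi,
                "label": region,
                "mean_ics": vals.mean(),
                "se_ics": vals.std(ddof=1) / np.sqrt(vals.size),
            }
        )
    return pd.DataFrame(out)


def decode_episodes(segments: SegmentArray, cross: np.ndarray | None = None) -> pd.DataFrame:
    """Predict each individual segment's episode by maximal ICS.

    Ties go to the lowest episode index and are flagged.
    """
    C = cross if cross is not None else cross_ics(segments)
    n_p, n_k, n_e, _ = C.shape
    pred = C.argmax(axis=3)
    maxval = C.max(axis=3)
    ties = (np.isclose(C, maxval[..., None])).sum(axis=3) > 1
    idx = pd.MultiIndex.from_product(
        [segments.participants, segments.regions, segments.episodes],
        names=["participant_id", "region", "true_episode"],
    )
    df = pd.DataFrame(index=idx).reset_index()
    df["predicted_episode"] = pred.ravel()
    truth = np.broadcast_to(np.arange(n_e), (n_p, n_k, n_e))
    df["correct"] = (pred == truth).ravel()
    df["tie_flag"] = ties.ravel()
    return df


def decoding_accuracy_by_region(decoding: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy and SE (over participants) per region."""
    per_participant = (
        decoding.groupby(["region", "participant_id"], sort=False)["correct"]
        .mean()
        .reset_index()
    )
    rows = []
    for region, d in per_participant.groupby("region", sort=False):
        vals = d["correct"].to_numpy()
        name, hemi = split_label(region)
        rows.append(
            {
                "region": name,
                "hemisphere": hemi,
                "label": region,
                "accuracy": vals.mean(),
                "se_accuracy": vals.std(ddof=1) / np.sqrt(vals.size),
            }
        )
    return pd.DataFrame(rows)


def _check_n_perm(n_perm: int) -> None:
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")


def _loo_mean_z(U: np.ndarray) -> np.ndarray:
    """Mean Fisher-Z leave-one-out similarity per region.

    ``U`` holds centered, unit-norm segments (participants x regions x
    episodes x frames); the correlation of participant i with the mean of
    the others follows from sums, so templates never need materializing.
    """
    V = U.sum(axis=0)  # regions x episodes x frames
    dot = np.einsum("pket,ket->pke", U, V)
    num = dot - 1.0  # u_i . (V - u_i)
    den = np.sqrt(np.maximum((V * V).sum(-1)[None] - 2.0 * dot + 1.0, 1e-24))
    r = np.clip(num / den, -1.0, 1.0)
    return fisher_z(r).mean(axis=(0, 2))  # per region


def ics_permutation_test(
    segments: SegmentArray,
    n_perm: int = 10000,
    seed: int = 0,
    cross: np.ndarray | None = None,
    strategy: str = "relabel",
) -> pd.DataFrame:
    """One-sided permutation p-value for the mean ICS of every region.

    Every null draw correlates each episode's canonical dynamics with an
    individual segment of a different, randomly selected episode. Strategies:

    - ``"relabel"`` (default): each participant's episode labels are permuted
      independently and the leave-one-out templates are rebuilt from the
      relabeled data. Episode relabeling is measure-preserving under the
      null, so the test is calibrated (type-I error ~ alpha).
    - ``"pairwise_same"`` / ``"pairwise_any"``: the original templates are
      re-paired with a randomly drawn different-episode segment of the same
      (or any) participant. Cheaper, but the reused templates omit the
      mutual-reflection covariance of the leave-one-out statistic, which
      makes these variants anticonservative; kept for sensitivity analyses.

    p uses the add-one estimator (1 + #null >= observed) / (1 + n_perm), so
    it is never exactly 0.
    """
    _check_n_perm(n_perm)
    if segments.shape[2] < 2:
        raise InvalidConfigError("permutation needs at least 2 episodes")
    if strategy not in ("relabel", "pairwise_same", "pairwise_any"):
        raise InvalidConfigError(f"unknown strategy {strategy!r}")
    n_p, n_k, n_e, _ = segments.shape
    rng = np.random.default_rng(seed)

    if strategy == "relabel":
        U = _unit_rows(segments.data)
        observed = _loo_mean_z(U)
        null = np.empty((n_perm, n_k))
        for b in range(n_perm):
            # independent episode permutation per participant
            perms = np.argsort(rng.random((n_p, n_e)), axis=1)
            Us = np.take_along_axis(U, perms[:, None, :, None], axis=2)
            null[b] = _loo_mean_z(Us)
    else:
        C = cross if cross is not None else cross_ics(segments)
        Z = fisher_z(C)
        observed = Z[:, :, np.arange(n_e), np.arange(n_e)].mean(axis=(0, 2))
        null = np.empty((n_perm, n_k))
        template_eps = np.broadcast_to(np.arange(n_e), (n_p, n_e))
        region_idx = np.arange(n_k)[None, :, None]
        for b in range(n_perm):
            offset = rng.integers(1, n_e, size=(n_p, n_e))
            seg_eps = (template_eps + offset) % n_e
            if strategy == "pairwise_same":
                part = np.broadcast_to(np.arange(n_p)[:, None], (n_p, n_e))
            else:
                part = rng.integers(0, n_p, size=(n_p, n_e))
            vals = Z[
                part[:, None, :],
                region_idx,
                seg_eps[:, None, :],
                template_eps[:, None, :],
            ]
            null[b] = vals.mean(axis=(0, 2))

    exceed = (null >= observed[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    rows = []
    for k, label in enumerate(segments.regions):
        name, hemi = split_label(label)
        rows.append(
            {
                "region": name,
                "hemisphere": hemi,
                "label": label,
                "mean_ics": observed[k],
                "p_perm": pvals[k],
            }
        )
    return pd.DataFrame(rows)


def decoding_permutation_test(
    segments: SegmentArray,
    n_perm: int = 10000,
    seed: int = 0,
    cross: np.ndarray | None = None,
) -> pd.DataFrame:
    """Permutation p-value for decoding accuracy per region.

    Each null draw permutes the episode labels of the canonical templates
    and re-runs the same argmax decoder; the null accuracy centers on
    1/n_episodes.
    """
    _check_n_perm(n_perm)
    C = cross if cross is not None else cross_ics(segments)
    n_p, n_k, n_e, _ = C.shape
    rng = np.random.default_rng(seed)
    pred = C.argmax(axis=3)  # i x k x e
    truth = np.arange(n_e)[None, None, :]
    observed = (pred == truth).mean(axis=(0, 2))  # per region

    null = np.empty((n_perm, n_k))
    for b in range(n_perm):
        perm = rng.permutation(n_e)
        null[b] = (perm[pred] == truth).mean(axis=(0, 2))
    exceed = (null >= observed[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    rows = []
    for k, label in enumerate(segments.regions):
        name, hemi = split_label(label)
        rows.append(
            {
                "region": name,
                "hemisphere": hemi,
                "label": label,
                "accuracy": observed[k],
                "null_mean_accuracy": null[:, k].mean(),
                "p_perm": pvals[k],
            }
        )
    return pd.DataFrame(rows)


def condition_contrast(
    accuracy_by_episode: np.ndarray, in_group: np.ndarray
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test across episodes.

    ``accuracy_by_episode`` holds participant-averaged decoding accuracy per
    episode; ``in_group`` is a boolean mask splitting episodes into the two
    cue conditions (6 vs 6 by default, giving df = 10).
    """
    acc = np.asarray(accuracy_by_episode, dtype=float)
    mask = np.asarray(in_group, dtype=bool)
    g1, g2 = acc[mask], acc[~mask]
    if g1.size < 2 or g2.size < 2:
        raise InvalidConfigError("each condition group needs at least 2 episodes")
    t, p = sps.ttest_ind(g1, g2, equal_var=True)
    df = g1.size + g2.size - 2
    return float(t), int(df), float(p)


def accuracy_by_episode(decoding: pd.DataFrame, region_label: str) -> np.ndarray:
    """Participant-averaged decoding accuracy per episode for one region."""
    d = decoding[decoding["region"] == region_label]
    acc = d.groupby("true_episode", sort=True)["correct"].mean()
    return acc.to_numpy()
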
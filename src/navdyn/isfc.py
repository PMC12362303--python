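"""Intersubject functional connectivity (ISFC) with a seed region.

ISFC correlates one individual's seed-region dynamics with the
leave-one-subject-out canonical dynamics of each cortical target during the
same episode, Fisher-Z transforms the correlations, and averages the Z values
over episodes. With the (bilateral) hippocampal-formation seed the target
set is the remaining 44 regions. When seed and target coincide, ISFC reduces
exactly to ICS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, SchemaError
from .ics import SegmentArray, _unit_rows, fisher_z
from .regions import bilateral_pair, split_label
from .stats import correlate_with_performance


def resolve_seed(segments: SegmentArray, seed_region: str) -> tuple[list[int], list[int]]:
    """Seed member indices and target indices for a seed name.

    ``seed_region`` may be a bare bilateral name ("hippocampal_formation") or
    a single hemisphere label ("hippocampal_formation_L"). Targets exclude
    both hemispheres of the seed's region.
    """
    labels = segments.regions
    if seed_region in labels:
        members = [labels.index(seed_region)]
        excluded = set(bilateral_pair(seed_region))
    else:
        pair = [f"{seed_region}_L", f"{seed_region}_R"]
        members = [labels.index(p) for p in pair if p in labels]
        if not members:
            raise SchemaError(f"seed region {seed_region!r} not in segment array")
        excluded = set(pair)
    targets = [k for k, lab in enumerate(labels) if lab not in excluded]
    return members, targets


def isfc_records(
    segments: SegmentArray,
    seed_region: str = "hippocampal_formation",
    targets: list[int] | None = None,
) -> pd.DataFrame:
    """Long table of per participant x target x episode ISFC (r and z).

    The individual seed time course is the mean of the seed member regions'
    segments (bilateral average for a bare region name).
    """
    S = segments.data
    n_p = S.shape[0]
    if n_p < 2:
        raise InvalidConfigError("ISFC needs at least 2 participants")
    members, auto_targets = resolve_seed(segments, seed_region)
    t_idx = auto_targets if targets is None else targets
    seed_series = S[:, members].mean(axis=1)  # participants x episodes x frames
    total = S.sum(axis=0)

    rows = []
    for i, pid in enumerate(segments.participants):
        template = (total - S[i]) / (n_p - 1)  # regions x episodes x frames
        a = _unit_rows(seed_series[i])  # episodes x frames
        b = _unit_rows(template[t_idx])  # targets x episodes x frames
        r = np.clip(np.einsum("et,ket->ke", a, b), -1.0, 1.0)
        for j, k in enumerate(t_idx):
            label = segments.regions[k]
            for e_pos, e in enumerate(segments.episodes):
                rows.append(
                    {
                        "participant_id": pid,
                        "seed": seed_region,
                        "target": label,
                        "episode": e,
                        "r": r[j, e_pos],
                        "z": float(fisher_z(r[j, e_pos])),
                    }
                )
    return pd.DataFrame(rows)


def isfc_profile(
    segments: SegmentArray,
    seed_region: str = "hippocampal_formation",
    targets: list[int] | None = None,
) -> pd.DataFrame:
    """Participant x target matrix of episode-averaged Fisher-Z ISFC.

    Averaging happens on the Z scale (variance-stabilized), not on r.
    """
    S = segments.data
    n_p = S.shape[0]
    if n_p < 2:
        raise InvalidConfigError("ISFC needs at least 2 participants")
    members, auto_targets = resolve_seed(segments, seed_region)
    t_idx = auto_targets if targets is None else targets
    seed_series = S[:, members].mean(axis=1)
    total = S.sum(axis=0)
    out = np.empty((n_p, len(t_idx)))
    for i in range(n_p):
        template = (total - S[i]) / (n_p - 1)
        a = _unit_rows(seed_series[i])
        b = _unit_rows(template[t_idx])
        r = np.clip(np.einsum("et,ket->ke", a, b), -1.0, 1.0)
        out[i] = fisher_z(r).mean(axis=1)
    return pd.DataFrame(
        out, index=list(segments.participants), columns=[segments.regions[k] for k in t_idx]
    )


def seedwise_summary(
    segments: SegmentArray,
    performance: np.ndarray,
    motion: np.ndarray,
) -> pd.DataFrame:
    """Mean ISFC-performance correlation per (bilateral) seed region.

    For each seed, each target's episode-averaged ISFC is correlated with
    memory performance after partialling out head motion; the summary is the
    mean r over targets.
    """
    names = sorted({split_label(lab)[0] for lab in segments.regions})
    rows = []
    for name in names:
        profile = isfc_profile(segments, name)
        corr = correlate_with_performance(profile, performance, motion)
        rows.append(
            {
                "seed": name,
                "mean_r": corr["r"].mean(),
                "n_targets": len(corr),
            }
        )
    return pd.DataFrame(rows).sort_values("mean_r", ascending=False).reset_index(drop=True)
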
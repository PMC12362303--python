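"""Event regressors and the canonical-dynamics event regression.

Gaze flags from the eye-tracking cohort are aggregated to a 10 Hz group
on-landmark ratio; landmark-viewing timepoints are the top 20% of that ratio
within each landmark trial. The canonical dynamics of each region,
concatenated over episodes, are regressed on the HRF-convolved angular
velocity (turning) and landmark-viewing mask:

    Y_k = beta_turn * X_turn + beta_landmark * X_view + i + e,

all variables z-scored before fitting (OLS, two-tailed coefficient tests).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateSignalError, SchemaError
from .hrf import HRFKernel, build_regressor, canonical_hrf, convolve_stream  # noqa: F401
from .regions import split_label

#: Within-participant bin threshold before computing the participant ratio.
GAZE_BIN_THRESHOLD: float = 0.5
#: Landmark viewing = ratio above its within-trial 80th percentile.
LANDMARK_PERCENTILE: float = 80.0


def aggregate_gaze(flags: np.ndarray, samples_per_bin: int = 25) -> np.ndarray:
    """Group on-landmark ratio at 10 Hz from per-participant 250 Hz flags.

    Each participant's flags are averaged within consecutive 100 ms bins and
    binarized at 0.5; the returned series is the fraction of participants on
    a landmark in each bin.
    """
    flags = np.asarray(flags)
    if flags.ndim != 2:
        raise SchemaError("flags must be participants x samples")
    n_p, n_s = flags.shape
    if n_p < 1:
        raise SchemaError("need at least one gaze participant")
    if n_s % samples_per_bin:
        raise SchemaError("sample count must divide evenly into bins")
    bins = flags.reshape(n_p, n_s // samples_per_bin, samples_per_bin).mean(axis=2)
    return (bins > GAZE_BIN_THRESHOLD).mean(axis=0)


def landmark_mask(ratio: np.ndarray) -> np.ndarray:
    """Binary 10 Hz landmark-viewing mask for one landmark trial.

    Strict ``>`` against the 80th percentile (linear-interpolation
    definition), so a tie-free 600-sample series marks exactly 120 samples.
    An all-zero ratio on a landmark trial yields an empty mask with a warning.
    """
    ratio = np.asarray(ratio, dtype=float)
    if not np.any(ratio > 0):
        warnings.warn("all-zero gaze ratio on a landmark trial; empty mask")
        return np.zeros_like(ratio, dtype=bool)
    threshold = np.percentile(ratio, LANDMARK_PERCENTILE)
    return ratio > threshold


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd < 1e-15:
        raise DegenerateSignalError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def fit_event_regression(
    canonical: np.ndarray,
    x_turn: np.ndarray,
    x_view: np.ndarray,
    regions: tuple[str, ...],
) -> pd.DataFrame:
    """Per-region OLS of canonical dynamics on the two event regressors.

    ``canonical`` is (frames x regions) with frames the retained navigation
    frames concatenated over all episodes (24 x 26 = 624 in the default
    design). Returns one row per region with coefficients, SEs, two-tailed
    p-values and R^2.
    """
    canonical = np.asarray(canonical, dtype=float)
    if canonical.ndim != 2 or canonical.shape[1] != len(regions):
        raise SchemaError("canonical must be frames x regions")
    if not (canonical.shape[0] == x_turn.size == x_view.size):
        raise SchemaError("regressors must match the concatenated frame count")
    z1, z2 = _zscore(np.asarray(x_turn)), _zscore(np.asarray(x_view))
    r12 = float(np.corrcoef(z1, z2)[0, 1])
    if abs(r12) > 0.999:
        raise DegenerateSignalError(
            f"turn and landmark regressors are collinear (r={r12:.4f})"
        )
    X = sm.add_constant(np.column_stack([z1, z2]))
    rows = []
    for k, label in enumerate(regions):
        fit = sm.OLS(_zscore(canonical[:, k]), X).fit()
        name, hemi = split_label(label)
        rows.append(
            {
                "region": name,
                "hemisphere": hemi,
                "label": label,
                "beta_turn": fit.params[1],
                "se_turn": fit.bse[1],
                "p_turn": fit.pvalues[1],
                "beta_landmark": fit.params[2],
                "se_landmark": fit.bse[2],
                "p_landmark": fit.pvalues[2],
                "intercept": fit.params[0],
                "r_squared": fit.rsquared,
            }
        )
    return pd.DataFrame(rows)
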
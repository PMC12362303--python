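"""Group-level inference: motion-partialled correlations, age regression
with VIF, BH-FDR, and the three-equation mediation with the Sobel test.

Individual-difference correlations regress mean head motion out of both
variables first; the Pearson p-value uses the exact null density of r (via
its t equivalence t = r*sqrt((n-2)/(1-r^2))). The mediation decomposes the
total age effect c on memory into a direct path c' and an indirect path a*b
through a region's coupling measure, with head motion as a confound in all
three standardized OLS equations:

    Y = c X + d1 Z + i1 + e1
    M = a X + d2 Z + i2 + e2
    Y = c' X + b M + d3 Z + i3 + e3

Sobel z = a*b / sqrt(a^2 SE_b^2 + b^2 SE_a^2), two-tailed normal reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError, SchemaError


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise SchemaError("non-finite values in input vector")
    return a


def zscore(x) -> np.ndarray:
    """Sample-SD (n-1) z-score."""
    a = _as1d(x)
    sd = a.std(ddof=1)
    if sd < 1e-15:
        raise InvalidConfigError("cannot z-score a constant vector")
    return (a - a.mean()) / sd


def residualize(x, covariate) -> np.ndarray:
    """OLS residual of x on covariate plus intercept (zero-mean by construction).

    A constant covariate degenerates to centering, with a warning.
    """
    xv, cv = _as1d(x), _as1d(covariate)
    if xv.size != cv.size:
        raise SchemaError("x and covariate must have equal length")
    if xv.size < 3:
        raise InvalidConfigError("residualization needs n >= 3")
    if cv.std(ddof=1) < 1e-15:
        warnings.warn("constant covariate; returning centered x")
        return xv - xv.mean()
    X = np.column_stack([np.ones_like(cv), cv])
    beta, *_ = np.linalg.lstsq(X, xv, rcond=None)
    return xv - X @ beta


def pearson_p(r: float, n: int) -> float:
    """Two-tailed p for a Pearson correlation under the exact null density.

    Uses the t equivalence t = r*sqrt((n-2)/(1-r^2)), which integrates the
    null density f(r) = (1-r^2)^((n-4)/2) / B(1/2, (n-2)/2) exactly.
    """
    if n < 5:
        raise InvalidConfigError("pearson_p requires n >= 5")
    if not -1.0 <= r <= 1.0:
        raise InvalidConfigError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def partial_pearson(x, y, covariate) -> tuple[float, float]:
    """Pearson r and p after regressing the covariate out of both variables.

    p uses n = number of participants in the null density (no df reduction
    for the covariate regression).
    """
    rx, ry = residualize(x, covariate), residualize(y, covariate)
    n = rx.size
    sx, sy = rx.std(ddof=1), ry.std(ddof=1)
    if sx < 1e-15 or sy < 1e-15:
        raise InvalidConfigError("zero variance after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, pearson_p(r, n)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlate_with_performance(
    measure: pd.DataFrame, performance, motion
) -> pd.DataFrame:
    """Motion-partialled correlation of each measure column with performance.

    ``measure`` is participants x regions (or any named measures); BH-FDR is
    applied across the columns.
    """
    perf, mot = _as1d(performance), _as1d(motion)
    if len(measure) != perf.size or perf.size != mot.size:
        raise SchemaError("measure, performance and motion lengths differ")
    if perf.size < 5:
        raise InvalidConfigError("need at least 5 participants")
    rows = []
    for col in measure.columns:
        r, p = partial_pearson(measure[col].to_numpy(), perf, mot)
        rows.append({"measure": col, "r": r, "p": p, "n": perf.size})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out


@dataclass
class AgeRegressionResult:
    """Standardized OLS of a measure on age and motion."""

    coef_age: float
    coef_motion: float
    intercept: float
    se_age: float
    se_motion: float
    p_age: float
    p_motion: float
    vif_age: float
    n: int


def age_regression(measure, age, motion) -> AgeRegressionResult:
    """measure = a*Age + b*Motion + c + e, all variables z-scored.

    The variance inflation factor for age is 1/(1 - R^2) of age regressed
    on motion; with the reported age-motion correlation of 0.493 this gives
    VIF = 1.32.
    """
    m, a, mo = _as1d(measure), _as1d(age), _as1d(motion)
    if not (m.size == a.size == mo.size):
        raise SchemaError("input lengths differ")
    if m.size < 4:
        raise InvalidConfigError("age regression needs n >= 4")
    if a.std(ddof=1) < 1e-15:
        raise InvalidConfigError("age is constant")
    zm, za, zmo = zscore(m), zscore(a), zscore(mo)
    X = sm.add_constant(np.column_stack([za, zmo]))
    fit = sm.OLS(zm, X).fit()
    r_am = float(np.corrcoef(za, zmo)[0, 1])
    vif = 1.0 / (1.0 - r_am * r_am)
    return AgeRegressionResult(
        coef_age=float(fit.params[1]),
        coef_motion=float(fit.params[2]),
        intercept=float(fit.params[0]),
        se_age=float(fit.bse[1]),
        se_motion=float(fit.bse[2]),
        p_age=float(fit.pvalues[1]),
        p_motion=float(fit.pvalues[2]),
        vif_age=float(vif),
        n=m.size,
    )


@dataclass
class MediationResult:
    """Three-equation mediation decomposition with Sobel inference."""

    total_c: float
    direct_c_prime: float
    path_a: float
    path_b: float
    se_a: float
    se_b: float
    indirect: float  # a * b
    sobel_z: float
    sobel_p: float
    confound_d1: float
    confound_d2: float
    confound_d3: float
    p_a: float
    p_total: float
    n: int

    @property
    def decomposition_gap(self) -> float:
        """|c - (c' + a*b)|; identically ~0 for OLS with a shared confound."""
        return abs(self.total_c - (self.direct_c_prime + self.indirect))


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Classic Sobel z and two-tailed normal p for the indirect effect a*b."""
    denom = np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    if denom == 0:
        return 0.0, 1.0
    z = a * b / denom
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def mediation(age, mediator, performance, motion) -> MediationResult:
    """Standardized mediation of the age effect on performance via a mediator.

    X = age, M = mediator (a region's coupling measure), Y = performance,
    Z = head motion; all four z-scored before the three OLS fits.
    """
    x, m, y, z = map(_as1d, (age, mediator, performance, motion))
    n = x.size
    if not (m.size == y.size == z.size == n):
        raise SchemaError("input lengths differ")
    if n <= 5:
        raise InvalidConfigError("mediation needs n > 5")
    zx, zm, zy, zz = zscore(x), zscore(m), zscore(y), zscore(z)

    X1 = sm.add_constant(np.column_stack([zx, zz]))
    fit1 = sm.OLS(zy, X1).fit()  # total effect
    fit2 = sm.OLS(zm, X1).fit()  # age -> mediator
    X3 = sm.add_constant(np.column_stack([zx, zm, zz]))
    fit3 = sm.OLS(zy, X3).fit()  # direct + mediator paths

    a, se_a = float(fit2.params[1]), float(fit2.bse[1])
    b, se_b = float(fit3.params[2]), float(fit3.bse[2])
    z_sobel, p_sobel = sobel_test(a, se_a, b, se_b)
    return MediationResult(
        total_c=float(fit1.params[1]),
        direct_c_prime=float(fit3.params[1]),
        path_a=a,
        path_b=b,
        se_a=se_a,
        se_b=se_b,
        indirect=a * b,
        sobel_z=z_sobel,
        sobel_p=p_sobel,
        confound_d1=float(fit1.params[2]),
        confound_d2=float(fit2.params[2]),
        confound_d3=float(fit3.params[3]),
        p_a=float(fit2.pvalues[1]),
        p_total=float(fit1.pvalues[1]),
        n=n,
    )


def mediation_scan(
    measures: pd.DataFrame,
    age,
    performance,
    motion,
    candidate_filter: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mediation across all measure columns (regions).

    With ``candidate_filter`` (default), only regions whose coupling
    decreases with age (a < 0 with p < alpha in the second equation) are
    tested, mirroring the candidate-region selection rule; the full table is
    returned with a ``candidate`` flag either way.
    """
    rows = []
    for col in measures.columns:
        res = mediation(age, measures[col].to_numpy(), performance, motion)
        candidate = res.path_a < 0 and res.p_a < alpha
        rows.append(
            {
                "measure": col,
                "candidate": candidate,
                "total_c": res.total_c,
                "direct_c_prime": res.direct_c_prime,
                "path_a": res.path_a,
                "p_a": res.p_a,
                "path_b": res.path_b,
                "indirect": res.indirect,
                "sobel_z": res.sobel_z,
                "sobel_p": res.sobel_p,
            }
        )
    out = pd.DataFrame(rows)
    tested = out["candidate"] if candidate_filter else pd.Series(True, index=out.index)
    out["tested"] = tested
    pf = np.full(len(out), np.nan)
    if tested.any():
        pf[tested.to_numpy()] = fdr_adjust(out.loc[tested, "sobel_p"].to_numpy())
    out["sobel_p_fdr"] = pf
    return out


def activation_vs_ics_comparison(
    activation: pd.DataFrame,
    ics_measure: pd.DataFrame,
    performance,
    motion,
) -> pd.DataFrame:
    """Side-by-side motion-partialled correlations for both measures.

    Both inputs are participants x regions with matching columns; the output
    has one row per region with r/p for the dynamics measure (ICS) and the
    time-averaged activation measure.
    """
    if list(activation.columns) != list(ics_measure.columns):
        raise SchemaError("activation and ICS tables must share columns")
    c_ics = correlate_with_performance(ics_measure, performance, motion)
    c_act = correlate_with_performance(activation, performance, motion)
    out = c_ics.rename(columns={"r": "r_ics", "p": "p_ics", "p_fdr": "p_fdr_ics"})
    out["r_activation"] = c_act["r"].to_numpy()
    out["p_activation"] = c_act["p"].to_numpy()
    out["p_fdr_activation"] = c_act["p_fdr"].to_numpy()
    return out
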
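"""Group-level inference: covariate-adjusted GLM contrasts, Benjamini-
Hochberg FDR, partial correlations, subgroup contrasts and summary-statistic
demographic tests.

The group contrast for any feature is the ordinary-least-squares fit of
``y ~ 1 + group + covariates`` (age, gender, education by default; mean
framewise displacement appended for the head-motion validation rerun), with
a two-sided t test on the group coefficient. Families of features are
corrected with the Benjamini-Hochberg step-up procedure at q < 0.05;
temporal state properties are conventionally left uncorrected (per-family
flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_FDR_Q = 0.05


# ---------------------------------------------------------------------------
# GLM group contrasts
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    """Group-effect estimate for one feature."""

    beta: float
    t: float
    df: int
    p: float


def _design_matrix(group, covariates, n):
    group = np.asarray(group, dtype=float)
    if group.shape != (n,):
        raise ValueError("group labels must be one value per subject")
    cols = [np.ones(n), group]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match the number of subjects")
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"cov{j + 1}")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the collinear columns via near-zero R diagonal
        r = np.linalg.qr(x, mode="r")
        bad = [names[j] for j in range(x.shape[1])
               if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return x


def glm_group_test(y, group, covariates=None):
    """OLS group contrast for one feature (or a stack of features).

    ``y`` may be a vector (returns :class:`GLMResult`) or an ``(n, m)``
    matrix of m features fitted jointly column-wise (returns arrays).
    Group is coded numerically (e.g. 0/1); the t statistic tests the group
    coefficient. A feature with zero residual variance gets t = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    ymat = y[:, None] if single else y
    n, m = ymat.shape
    x = _design_matrix(group, covariates, n)
    p_params = x.shape[1]
    if n <= p_params:
        raise ValueError(f"need n > {p_params} subjects, got {n}")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ ymat)
    resid = ymat - x @ beta
    df = n - p_params
    sigma2 = (resid**2).sum(axis=0) / df
    # zero residual variance (at rounding level): degenerate fit, t=0, p=1
    degenerate = sigma2 <= 1e-24 * (1.0 + (ymat**2).mean(axis=0))
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, beta[1] / np.where(se > 0, se, 1.0))
    beta_group = np.where(degenerate, 0.0, beta[1])
    pvals = np.where(degenerate, 1.0, 2.0 * sps.t.sf(np.abs(t), df))
    if single:
        return GLMResult(beta=float(beta_group[0]), t=float(t[0]), df=df,
                         p=float(pvals[0]))
    return beta_group, t, df, pvals


def glm_table(features: pd.DataFrame, group, covariates=None,
              fdr: bool = True, q_threshold: float = DEFAULT_FDR_Q) -> pd.DataFrame:
    """Per-feature GLM contrasts with optional BH correction.

    ``features`` is a subjects-by-features DataFrame; returns a DataFrame
    with columns feature, beta, t, df, p, q, sig. With ``fdr=False`` the raw
    p is thresholded directly (the convention for temporal state properties)
    and q is reported as NaN.
    """
    beta, t, df, p = glm_group_test(features.to_numpy(), group, covariates)
    if fdr:
        q, sig = bh_fdr(p, q_threshold)
    else:
        q = np.full_like(p, np.nan)
        sig = p < q_threshold
    return pd.DataFrame({
        "feature": features.columns,
        "beta": beta,
        "t": t,
        "df": df,
        "p": p,
        "q": q,
        "sig": sig,
    })


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvals, q_threshold: float = DEFAULT_FDR_Q):
    """Step-up BH adjusted q-values and significance mask.

    ``q_(i) = min_{j >= i} m p_(j) / j`` clipped at 1; the mask marks
    q <= threshold. Empty input yields empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= q_threshold


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrelationResult:
    """Covariate-adjusted correlation between two variables."""

    r: float
    df: int
    p: float


def partial_correlation(x, y, covariates=None) -> PartialCorrelationResult:
    """Pearson correlation of OLS residuals after removing covariates.

    With no covariates this reduces to the plain Pearson correlation with
    df = n - 2. The p-value comes from ``t = r sqrt(df / (1 - r^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        z = np.ones((n, 1))
        n_cov = 0
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        n_cov = cov.shape[1]
        z = np.column_stack([np.ones(n), cov])
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError(f"need n > {n_cov + 3} observations, got {n}")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if rx.std() <= 1e-12 * (1.0 + np.abs(x).max()) or \
            ry.std() <= 1e-12 * (1.0 + np.abs(y).max()):
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return PartialCorrelationResult(r=r, df=df, p=0.0)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, df=df, p=p)


# ---------------------------------------------------------------------------
# Summary-statistic demographic tests
# ---------------------------------------------------------------------------

def _check_summary(sd1, n1, sd2, n2):
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")


def welch_t(mean1, sd1, n1, mean2, sd2, n2):
    """Welch two-sample t from summary statistics.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom.
    """
    _check_summary(sd1, n1, sd2, n2)
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def pooled_t(mean1, sd1, n1, mean2, sd2, n2):
    """Classic pooled-variance two-sample t from summary statistics.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2.
    """
    _check_summary(sd1, n1, sd2, n2)
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


def chi_square_2x2(table):
    """Pearson chi-square for a 2x2 count table (no continuity correction).

    Returns ``(chi2, p)`` with df = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("table has a zero margin")
    chi2 = n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / (
        rows[0] * rows[1] * cols[0] * cols[1]
    )
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Subgroup contrasts
# ---------------------------------------------------------------------------

def subgroup_contrast(features: pd.DataFrame, split_values, threshold: float,
                      covariates=None, fdr: bool = True,
                      q_threshold: float = DEFAULT_FDR_Q) -> pd.DataFrame:
    """GLM contrast across a within-group split (e.g. MoCA >= 26, age >= 60).

    Subjects with ``split_values >= threshold`` form the upper subgroup;
    both subgroups must be nonempty.
    """
    split = np.asarray(split_values, dtype=float)
    upper = split >= threshold
    if upper.all() or not upper.any():
        raise ValueError(
            f"split at threshold {threshold} leaves an empty subgroup "
            f"({int(upper.sum())} of {split.size} in the upper subgroup)"
        )
    return glm_table(features, upper.astype(float), covariates,
                     fdr=fdr, q_threshold=q_threshold)
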
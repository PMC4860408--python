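"""Allometry: multivariate regression of shape on log centroid size.

%variance explained is the trace ratio trace(SS_model)/trace(SS_total)
summed over shape variables; significance comes from permutation
(default 9999 rounds, p floored at 1/(n_perm+1)).  Includes the pooled
within-group variant (group means removed from both blocks before a single
common slope is fitted) and a Goodall-style Procrustes ANOVA test for
heterogeneity of allometric slopes among species, with residual
randomization under the reduced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_PERM = 9999


@dataclass
class RegressionResult:
    """One shape-on-size regression: slope vector, %variance, permutation p."""

    coefficients: np.ndarray  # (p,) effect of x on each shape variable
    percent_variance: float
    permutation_p: float
    n: int
    n_permutations: int

    def __repr__(self) -> str:  # compact, Table-4-style
        return (
            f"RegressionResult(n={self.n}, var%={self.percent_variance:.2f}, "
            f"p={self.permutation_p:.4f})"
        )


def _percent_var_perms(
    yc: np.ndarray, xc: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """%variance for each permuted x row-order; perms is (P, n) of indices."""
    ss_tot = (yc**2).sum()
    xp = xc[perms]  # (P, n)
    cross = xp @ yc  # (P, p)
    ss_model = (cross**2).sum(axis=1) / (xc**2).sum()
    return 100.0 * ss_model / ss_tot


def multivariate_regression(
    shape: np.ndarray,
    x: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> RegressionResult:
    """OLS of every shape variable on a single size covariate.

    The p-value counts permutations of ``x`` whose %variance reaches the
    observed one, as (count + 1)/(n_perm + 1).
    """
    y = np.asarray(shape, float)
    x = np.asarray(x, float).ravel()
    n = len(x)
    if y.ndim != 2 or y.shape[0] != n:
        raise ValueError("shape must be (n, p) matching x")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant size covariate")
    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    beta = (xc @ yc) / (xc @ xc)
    ss_tot = (yc**2).sum()
    ss_model = (beta**2).sum() * (xc @ xc)
    pct = 100.0 * ss_model / ss_tot if ss_tot > 0 else 0.0

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    pct_perm = _percent_var_perms(yc, xc, perms)
    count = int(np.sum(pct_perm >= pct - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return RegressionResult(
        coefficients=beta,
        percent_variance=float(pct),
        permutation_p=float(p),
        n=n,
        n_permutations=n_perm,
    )


def pooled_within_group_regression(
    shape: np.ndarray,
    x: np.ndarray,
    groups,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> RegressionResult:
    """Common allometric slope after removing group means from both blocks.

    The permutation test shuffles the size covariate within groups only,
    preserving group structure under the null.
    """
    y = np.asarray(shape, float)
    x = np.asarray(x, float).ravel()
    groups = np.asarray(groups)
    n = len(x)
    codes, uniques = pd.factorize(groups)
    sizes = np.bincount(codes)
    if np.all(sizes < 2):
        raise ValueError("all groups of size 1: no within-group variation")
    # remove group means
    ybar = np.zeros((len(uniques), y.shape[1]))
    xbar = np.zeros(len(uniques))
    np.add.at(ybar, codes, y)
    np.add.at(xbar, codes, x)
    ybar /= sizes[:, None]
    xbar /= sizes
    yw = y - ybar[codes]
    xw = x - xbar[codes]
    if np.allclose(xw, 0):
        raise ValueError("size covariate constant within every group")
    beta = (xw @ yw) / (xw @ xw)
    ss_tot = (yw**2).sum()
    ss_model = (beta**2).sum() * (xw @ xw)
    pct = 100.0 * ss_model / ss_tot if ss_tot > 0 else 0.0

    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    pct_perm = np.empty(n_perm)
    group_members = [np.flatnonzero(codes == g) for g in range(len(uniques))]
    for b in range(n_perm):
        perm = idx.copy()
        for members in group_members:
            perm[members] = rng.permutation(members)
        xp = xw[perm]
        cross = xp @ yw
        pct_perm[b] = 100.0 * (cross**2).sum() / (xp @ xp) / ss_tot
    count = int(np.sum(pct_perm >= pct - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return RegressionResult(
        coefficients=beta,
        percent_variance=float(pct),
        permutation_p=float(p),
        n=n,
        n_permutations=n_perm,
    )


@dataclass
class SlopeTestResult:
    """Interaction test: do groups share one allometric slope?"""

    f_statistic: float
    df1: int
    df2: int
    permutation_p: float
    n_permutations: int


def _design(x: np.ndarray, codes: np.ndarray, g: int, interaction: bool) -> np.ndarray:
    n = len(x)
    cols = [np.ones(n), x]
    for j in range(1, g):  # treatment-coded group indicators
        cols.append((codes == j).astype(float))
    if interaction:
        for j in range(1, g):
            cols.append(x * (codes == j))
    return np.column_stack(cols)


def _residual_maker(design: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(design)
    rank = np.sum(np.abs(np.diag(r)) > np.abs(r).max() * 1e-12)
    q = q[:, :rank]
    return np.eye(design.shape[0]) - q @ q.T


def slope_heterogeneity_test(
    shape: np.ndarray,
    x: np.ndarray,
    groups,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> SlopeTestResult:
    """Procrustes-distance ANOVA for group × size interaction.

    Compares shape ~ x + group + x:group against shape ~ x + group using
    Goodall-style summed sums of squares; F uses trace ratios with
    univariate-style degrees of freedom.  p comes from residual
    randomization under the reduced model (RRPP).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(shape, float)
    x = np.asarray(x, float).ravel()
    codes, uniques = pd.factorize(np.asarray(groups))
    g = len(uniques)
    n = len(x)
    if g < 2:
        raise ValueError("need at least 2 groups")
    yc = y - y.mean(axis=0)
    d_red = _design(x, codes, g, interaction=False)
    d_full = _design(x, codes, g, interaction=True)
    m_red = _residual_maker(d_red)
    m_full = _residual_maker(d_full)
    df1 = g - 1
    df2 = n - 2 * g
    if df2 < 1:
        raise ValueError("not enough observations for the interaction model")

    def f_stat(ymat: np.ndarray) -> float:
        rss_red = (m_red @ ymat).ravel() @ (m_red @ ymat).ravel()
        rss_full = (m_full @ ymat).ravel() @ (m_full @ ymat).ravel()
        if rss_full <= 0:
            return 0.0 if rss_red <= rss_full + 1e-30 else np.inf
        return ((rss_red - rss_full) / df1) / (rss_full / df2)

    f_obs = f_stat(yc)
    fitted_red = yc - m_red @ yc
    resid_red = m_red @ yc
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = fitted_red + resid_red[rng.permutation(n)]
        if f_stat(yp) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SlopeTestResult(
        f_statistic=float(f_obs),
        df1=df1,
        df2=df2,
        permutation_p=float(p),
        n_permutations=n_perm,
    )


def per_species_allometry(
    shape: np.ndarray,
    x: np.ndarray,
    species,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-taxon allometric regressions, one row per species plus 'all'.

    Mirrors the usual N / Var% / P summary table; species with fewer than
    ``min_n`` specimens are skipped with a warning.
    """
    species = np.asarray(species)
    rows = []
    rng = np.random.default_rng(seed)
    labels = ["all"] + sorted(pd.unique(species).tolist())
    for label in labels:
        mask = np.ones(len(species), bool) if label == "all" else species == label
        n = int(mask.sum())
        if n < min_n:
            warnings.warn(f"species {label!r}: n={n} < {min_n}, skipped", stacklevel=2)
            continue
        sub_x = np.asarray(x, float)[mask]
        if np.ptp(sub_x) == 0:
            warnings.warn(f"species {label!r}: constant lnCS, skipped", stacklevel=2)
            continue
        res = multivariate_regression(
            np.asarray(shape, float)[mask],
            sub_x,
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(
            {
                "species": label,
                "N": res.n,
                "percent_variance": res.percent_variance,
                "p": res.permutation_p,
            }
        )
    return pd.DataFrame(rows)
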
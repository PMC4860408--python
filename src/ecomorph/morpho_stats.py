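"""Group-difference tests on shape scores and on log centroid size.

MANOVA uses Pillai's trace computed from the hypothesis and error
cross-product matrices (Type II sums of squares for unbalanced two-way
designs), with the standard F approximation.  Size gets a two-way ANOVA
with interaction (statsmodels, Type II) and all-pairs t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


@dataclass
class ManovaResult:
    term: str
    pillai: float
    F: float
    df1: int
    df2: int
    p: float


def _dummy(codes: np.ndarray, g: int) -> np.ndarray:
    """Treatment-coded indicators, reference level dropped."""
    out = np.zeros((len(codes), g - 1))
    for j in range(1, g):
        out[codes == j, j - 1] = 1.0
    return out


def _proj(design: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(design)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r).max() * 1e-12))
    q = q[:, :rank]
    return q @ q.T


def _rank(design: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(design))


def pillai_f(pillai: float, p: int, df_h: int, df_e: int) -> tuple[float, int, int, float]:
    """F approximation for Pillai's trace V."""
    s = min(p, df_h)
    m = (abs(df_h - p) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = int(s * (2 * m + s + 1))
    df2 = int(s * (2 * nn + s + 1))
    if df2 <= 0 or s - pillai <= 0:
        return np.inf, df1, max(df2, 1), 0.0
    f = (pillai / (s - pillai)) * ((2 * nn + s + 1) / (2 * m + s + 1))
    pval = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, pval


def manova(
    scores: np.ndarray,
    factor_a,
    factor_b=None,
    interaction: bool = False,
) -> list[ManovaResult]:
    """One- or two-way MANOVA via Pillai's trace (Type II SS).

    For each term the hypothesis SSCP is the extra cross-product explained
    when the term enters a model already holding every term that does not
    contain it; the error SSCP comes from the full model.  A singular
    error matrix (too many response variables for the sample) raises with
    a hint to select fewer relative-warp axes.
    """
    y = np.asarray(scores, float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = y.shape
    ca, la = pd.factorize(np.asarray(factor_a))
    terms: dict[str, np.ndarray] = {"factor_a": _dummy(ca, len(la))}
    if factor_b is not None:
        cb, lb = pd.factorize(np.asarray(factor_b))
        terms["factor_b"] = _dummy(cb, len(lb))
        if interaction:
            a_d, b_d = terms["factor_a"], terms["factor_b"]
            inter = np.einsum("ni,nj->nij", a_d, b_d).reshape(n, -1)
            terms["factor_a:factor_b"] = inter
            cells = pd.factorize(list(zip(ca, cb)))[0]
            if np.bincount(cells).min() < 1:
                raise ValueError("empty cell in the interaction design")
    elif interaction:
        raise ValueError("interaction requires two factors")

    intercept = np.ones((n, 1))
    full = np.column_stack([intercept] + list(terms.values()))
    rank_full = _rank(full)
    df_e = n - rank_full
    if df_e <= p:
        raise ValueError(
            f"error df ({df_e}) must exceed the number of response variables "
            f"({p}); select fewer RW axes"
        )
    m_full = np.eye(n) - _proj(full)
    e_mat = y.T @ m_full @ y
    if np.linalg.matrix_rank(e_mat) < p:
        raise ValueError("singular error matrix; select fewer RW axes")

    results = []
    for name, cols in terms.items():
        others = [
            v
            for key, v in terms.items()
            if key != name and name not in key.split(":")
        ] if ":" not in name else [v for key, v in terms.items() if key != name]
        reduced = np.column_stack([intercept] + others)
        with_term = np.column_stack([reduced, cols])
        df_h = _rank(with_term) - _rank(reduced)
        h_mat = y.T @ (_proj(with_term) - _proj(reduced)) @ y
        eigs = np.linalg.eigvals(np.linalg.solve(h_mat + e_mat, h_mat))
        pillai = float(np.real(eigs).sum())
        f, df1, df2, pval = pillai_f(pillai, p, df_h, df_e)
        results.append(ManovaResult(name, pillai, f, df1, df2, pval))
    return results


def pairwise_shape_tests(
    scores: np.ndarray,
    species,
    min_n: int = 2,
) -> pd.DataFrame:
    """All-pairs two-group MANOVA (Pillai) on leading shape axes.

    Returns a square DataFrame with F below the diagonal, p above, and NaN
    on the diagonal or where a pair lacks ``min_n`` specimens per group.
    """
    y = np.asarray(scores, float)
    species = np.asarray(species)
    labels = sorted(pd.unique(species).tolist())
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        mask = (species == a) | (species == b)
        if (species == a).sum() < min_n or (species == b).sum() < min_n:
            continue
        try:
            res = manova(y[mask], species[mask])[0]
        except ValueError:
            continue
        out.loc[b, a] = res.F  # lower triangle: F
        out.loc[a, b] = res.p  # upper triangle: p
    return out


def size_tests(
    lncs: np.ndarray,
    species,
    sex=None,
    equal_var: bool = True,
    correction: str | None = None,
) -> dict:
    """Size ANOVA and pairwise t tests on lnCS.

    Two-way ANOVA with interaction (Type II) when ``sex`` is given,
    otherwise one-way; plus an all-pairs t matrix (t below the diagonal,
    p above).  ``correction`` may name a multiple-testing method
    (``"bonferroni"``, ``"holm"``); raw p by default.
    """
    lncs = np.asarray(lncs, float)
    df = pd.DataFrame({"lncs": lncs, "species": np.asarray(species)})
    if sex is not None:
        df["sex"] = np.asarray(sex)
        keep = df["sex"] != "unknown"
        df = df.loc[keep]
        model = smf.ols("lncs ~ C(species) * C(sex)", data=df).fit()
    else:
        model = smf.ols("lncs ~ C(species)", data=df).fit()
    anova_table = sm.stats.anova_lm(model, typ=2)

    labels = sorted(df["species"].unique().tolist())
    tmat = pd.DataFrame(np.nan, index=labels, columns=labels)
    pvals, pairs = [], []
    for a, b in combinations(labels, 2):
        xa = df.loc[df["species"] == a, "lncs"]
        xb = df.loc[df["species"] == b, "lncs"]
        if len(xa) < 2 or len(xb) < 2:
            continue
        t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
        tmat.loc[b, a] = t
        pairs.append((a, b))
        pvals.append(p)
    if correction and pvals:
        pvals = multipletests(pvals, method=correction)[1]
    for (a, b), p in zip(pairs, pvals):
        tmat.loc[a, b] = p
    return {"anova": anova_table, "pairwise_t": tmat, "n": int(len(df))}
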
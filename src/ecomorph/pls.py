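"""Two-block partial least squares (singular warps).

The singular value decomposition of the cross-covariance matrix between a
centred shape block and a centred (optionally column-standardized)
environmental block yields paired axes maximizing cross-block covariance.
Shape variables share Procrustes units and are only centred; mixed-unit
climate/competition blocks are standardized by default.  Per-dimension
significance comes from permuting the rows of the second block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIOCLIM_NAMES = [f"BIO{i}" for i in range(1, 20)]


@dataclass
class PLSResult:
    """Paired singular vectors, covariation shares and permutation p-values."""

    left_vectors: np.ndarray  # (p, r)
    right_vectors: np.ndarray  # (q, r)
    singular_values: np.ndarray  # (r,) non-increasing
    percent_covariation: np.ndarray  # sums to 100
    score_correlations: np.ndarray  # (r,)
    permutation_p: np.ndarray  # (r,)
    left_scores: np.ndarray  # (n, r)
    right_scores: np.ndarray  # (n, r)
    n: int = 0
    right_names: list = field(default_factory=list)


def _prepare(block: np.ndarray, standardize: bool) -> np.ndarray:
    x = np.asarray(block, float)
    if x.ndim == 1:
        x = x[:, None]
    xc = x - x.mean(axis=0)
    if standardize:
        sd = xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0).tolist()
            raise ValueError(f"constant column(s) in standardized block: {bad}")
        xc = xc / sd
    return xc


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pls(
    blockA: np.ndarray,
    blockB: np.ndarray,
    standardize_A: bool = False,
    standardize_B: bool = True,
    n_perm: int = 999,
    seed: int | None = None,
    right_names: list | None = None,
) -> PLSResult:
    """SVD-based two-block PLS between row-aligned data blocks.

    The permutation test shuffles the rows of block B and counts permuted
    first singular values reaching the observed one for dimension 1 (and
    analogously per dimension), p = (count + 1)/(n_perm + 1).  Each
    dimension is oriented so its largest-|loading| block-B variable loads
    positive.
    """
    a = _prepare(blockA, standardize_A)
    b = _prepare(blockB, standardize_B)
    n = a.shape[0]
    if b.shape[0] != n:
        raise ValueError("blocks must have the same number of rows")
    if n < 3:
        raise ValueError("need at least 3 rows")
    cross = a.T @ b / (n - 1)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    r = min(np.linalg.matrix_rank(cross, tol=1e-12), len(s)) or len(s)
    u, s, v = u[:, :r], s[:r], vt[:r].T
    for j in range(r):  # sign convention on the B side
        imax = np.argmax(np.abs(v[:, j]))
        if v[imax, j] < 0:
            v[:, j] *= -1
            u[:, j] *= -1
    left_scores = a @ u
    right_scores = b @ v
    total = (s**2).sum()
    pct = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    corrs = np.array([_corr(left_scores[:, j], right_scores[:, j]) for j in range(r)])

    rng = np.random.default_rng(seed)
    if total == 0:
        pvals = np.ones(r)
    else:
        exceed = np.zeros(r)
        for _ in range(n_perm):
            bp = b[rng.permutation(n)]
            sp = np.linalg.svd(a.T @ bp / (n - 1), compute_uv=False)
            sp = sp[:r] if len(sp) >= r else np.pad(sp, (0, r - len(sp)))
            exceed += sp >= s - 1e-15
        pvals = (exceed + 1) / (n_perm + 1)
    names = list(right_names) if right_names is not None else []
    return PLSResult(
        left_vectors=u,
        right_vectors=v,
        singular_values=s,
        percent_covariation=pct,
        score_correlations=corrs,
        permutation_p=pvals,
        left_scores=left_scores,
        right_scores=right_scores,
        n=n,
        right_names=names,
    )


def variable_correlations(
    result: PLSResult, blockB: np.ndarray, dimension: int = 0
) -> pd.Series:
    """Pearson correlation of each block-B variable with its SW score.

    The classic loadings profile (e.g. which bioclim variables drive SW1).
    Constant variables get NaN.
    """
    b = np.asarray(blockB, float)
    if b.ndim == 1:
        b = b[:, None]
    score = result.right_scores[:, dimension]
    out = np.full(b.shape[1], np.nan)
    for j in range(b.shape[1]):
        if b[:, j].std() > 0 and score.std() > 0:
            out[j] = np.corrcoef(b[:, j], score)[0, 1]
    names = result.right_names or [f"var{j + 1}" for j in range(b.shape[1])]
    return pd.Series(out, index=names, name=f"SW{dimension + 1}_correlation")


def pls_size(
    lncs: np.ndarray,
    blockB: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    right_names: list | None = None,
) -> PLSResult:
    """Degenerate PLS of a single size variable against a block.

    Produces exactly one pair of vectors; the score correlation plays the
    role of a multiple-correlation-style association between size and the
    block's best linear combination.
    """
    x = np.asarray(lncs, float).ravel()[:, None]
    return pls(
        x,
        blockB,
        standardize_A=False,
        standardize_B=True,
        n_perm=n_perm,
        seed=seed,
        right_names=right_names,
    )
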
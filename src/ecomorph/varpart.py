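"""Variation partitioning of shape or size among named predictor blocks.

Every union of blocks is fitted by (multivariate) least squares; R² is the
trace ratio trace(SS_fit)/trace(SS_total) and the Ezekiel adjustment
1 − (1−R²)(n−1)/(n−q−1) corrects for block width.  Pure and shared
components for up to four blocks follow by inclusion–exclusion on the
adjusted R² of the unions (shared components may legitimately come out
negative).  Pure components can be permutation-tested by residual
randomization of the partial model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


def _as_matrix(block) -> np.ndarray:
    """Numeric design columns; object/categorical columns become indicators."""
    if isinstance(block, pd.Series):
        block = block.to_frame()
    if isinstance(block, pd.DataFrame):
        parts = []
        for col in block.columns:
            s = block[col]
            if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
                parts.append(pd.get_dummies(s, drop_first=True, dtype=float).to_numpy())
            else:
                parts.append(s.to_numpy(dtype=float)[:, None])
        return np.column_stack(parts) if parts else np.empty((len(block), 0))
    x = np.asarray(block)
    if x.dtype.kind in "OUS":
        return pd.get_dummies(pd.Series(x.ravel()), drop_first=True, dtype=float).to_numpy()
    x = np.asarray(x, float)
    return x[:, None] if x.ndim == 1 else x


def _drop_dependent(x: np.ndarray) -> np.ndarray:
    if x.shape[1] == 0:
        return x
    q, r = np.linalg.qr(x - x.mean(axis=0))
    diag = np.abs(np.diag(r))
    keep = np.zeros(x.shape[1], dtype=bool)
    keep[: len(diag)] = diag > (diag.max() if diag.max() > 0 else 1.0) * 1e-10
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} linearly dependent predictor column(s)",
            stacklevel=3,
        )
    return x[:, keep]


def rda_r2(Y: np.ndarray, X) -> tuple[float, float]:
    """Redundancy-analysis R² and Ezekiel-adjusted R² of Y on a block.

    Categorical predictors are expanded to indicators (one level dropped);
    linearly dependent columns are dropped with a warning.
    """
    y = np.asarray(Y, float)
    if y.ndim == 1:
        y = y[:, None]
    x = _drop_dependent(_as_matrix(X))
    n, q = x.shape
    if n <= q + 1:
        raise ValueError(f"n={n} too small for {q} predictor columns")
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    ss_tot = (yc**2).sum()
    if ss_tot == 0:
        return 0.0, 0.0
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    r2 = float((fitted**2).sum() / ss_tot)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
    return r2, float(adj)


@dataclass
class VarpartResult:
    """Pure/shared adjusted-R² components plus the union fits they came from."""

    components: dict[frozenset, float]
    residual: float
    block_names: list[str]
    union_r2: dict[frozenset, float] = field(default_factory=dict)
    union_adj_r2: dict[frozenset, float] = field(default_factory=dict)

    def component(self, *names: str) -> float:
        return self.components[frozenset(names)]

    def pure(self, name: str) -> float:
        return self.components[frozenset([name])]

    def frame(self, drop_negative: bool = False) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.components, key=lambda s: (len(s), sorted(s))):
            val = self.components[subset]
            if drop_negative and val < 0:
                continue
            rows.append({"subset": " & ".join(sorted(subset)), "adj_r2": val})
        rows.append({"subset": "residual", "adj_r2": self.residual})
        return pd.DataFrame(rows)


def _subsets(names: list[str]):
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            yield frozenset(combo)


def variation_partitioning(Y, blocks: dict[str, object]) -> VarpartResult:
    """Partition explained variance among 2–4 named predictor blocks.

    Fits all 2^b − 1 block unions, then solves the inclusion–exclusion
    system so that every union's adjusted R² equals the sum of the
    components it touches.  The residual is 1 − adjR²(all blocks).  The
    exact inclusion–exclusion identity on *unadjusted* R² is verified on
    every run (it holds by construction of the linear solve).
    """
    names = list(blocks)
    if not 1 <= len(names) <= 4:
        raise ValueError("between 1 and 4 blocks supported")
    mats = {name: _as_matrix(blocks[name]) for name in names}
    union_r2: dict[frozenset, float] = {}
    union_adj: dict[frozenset, float] = {}
    subsets = list(_subsets(names))
    for sub in subsets:
        x = np.column_stack([mats[name] for name in sorted(sub)])
        r2, adj = rda_r2(Y, x)
        union_r2[sub] = r2
        union_adj[sub] = adj
    # solve M c = f where M[U, S] = 1 iff S intersects U
    m = np.array(
        [[1.0 if s & u else 0.0 for s in subsets] for u in subsets]
    )
    comp_adj = np.linalg.solve(m, np.array([union_adj[u] for u in subsets]))
    comp_raw = np.linalg.solve(m, np.array([union_r2[u] for u in subsets]))
    full = frozenset(names)
    if not np.isclose(comp_raw.sum(), union_r2[full], atol=1e-8):
        raise AssertionError("inclusion-exclusion identity violated")
    components = dict(zip(subsets, comp_adj.tolist()))
    return VarpartResult(
        components=components,
        residual=1.0 - union_adj[full],
        block_names=names,
        union_r2=union_r2,
        union_adj_r2=union_adj,
    )


def pure_component_test(
    Y,
    blocks: dict[str, object],
    focal: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test of one block's pure (partial) contribution.

    A partial-RDA style test: the focal block is residualized on the other
    blocks, the conditional F statistic is computed, and rows of the
    residualized focal block are permuted (equivalently, residuals of the
    reduced model are randomized).  Returns (F, p).
    """
    y = np.asarray(Y, float)
    if y.ndim == 1:
        y = y[:, None]
    names = list(blocks)
    if focal not in names:
        raise KeyError(focal)
    xf = _drop_dependent(_as_matrix(blocks[focal]))
    others = [
        _drop_dependent(_as_matrix(blocks[nm])) for nm in names if nm != focal
    ]
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    if others:
        xo = np.column_stack(others)
        xo = xo - xo.mean(axis=0)
        qo, _ = np.linalg.qr(xo)
        resid_maker = np.eye(n) - qo @ qo.T
    else:
        resid_maker = np.eye(n)
    y_res = resid_maker @ yc
    x_res = resid_maker @ (xf - xf.mean(axis=0))
    qf, rf = np.linalg.qr(x_res)
    rank_f = int(np.sum(np.abs(np.diag(rf)) > np.abs(rf).max() * 1e-10)) if x_res.size else 0
    qf = qf[:, :rank_f]
    df_resid = n - 1 - (0 if not others else np.linalg.matrix_rank(xo)) - rank_f
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")

    def f_stat(ymat: np.ndarray) -> float:
        fit = qf @ (qf.T @ ymat)
        ss_fit = (fit**2).sum()
        ss_res = ((ymat - fit) ** 2).sum()
        if ss_res <= 0:
            return np.inf
        return (ss_fit / rank_f) / (ss_res / df_resid)

    f_obs = f_stat(y_res)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        # Freedman-Lane: permute the conditioned residuals, then re-project
        # off the conditioning block so permuted and observed data live in
        # the same residual subspace
        yp = resid_maker @ y_res[rng.permutation(n)]
        if f_stat(yp) >= f_obs - 1e-12:
            count += 1
    return float(f_obs), (count + 1) / (n_perm + 1)


def nested_varpart(
    Y,
    species,
    genus_of: dict[str, str],
    genus: str,
    blocks: dict[str, object],
    min_rows: int = 3,
) -> VarpartResult:
    """Variation partitioning restricted to one genus.

    The taxonomy block (species indicators) is included only when the
    genus holds more than one species in the subset; single-species genera
    get size/climate/competition blocks only.
    """
    species = np.asarray(species)
    mask = np.array([genus_of.get(s) == genus for s in species])
    if mask.sum() < min_rows:
        raise ValueError(f"genus {genus!r}: only {int(mask.sum())} rows (< {min_rows})")
    y = np.asarray(Y, float)
    y = y[mask] if y.ndim > 1 else y[mask]
    sub_blocks = {}
    n_species = len(pd.unique(species[mask]))
    for name, block in blocks.items():
        if name == "taxonomy":
            if n_species > 1:
                sub_blocks[name] = np.asarray(block)[mask]
            continue
        b = block
        if isinstance(b, (pd.DataFrame, pd.Series)):
            sub_blocks[name] = b.iloc[mask.nonzero()[0]]
        else:
            sub_blocks[name] = np.asarray(b)[mask]
    return variation_partitioning(y, sub_blocks)
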
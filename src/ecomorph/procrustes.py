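"""Generalized Procrustes analysis and thin-plate-spline shape decomposition.

The pipeline is the classical one for 2-D landmark data: superimposition
(translation, scale, rotation removed; full-Procrustes unit-centroid-size
scaling), projection of the aligned residuals onto the partial-warp +
uniform-component basis derived from the bending-energy matrix of the
consensus (the "weight matrix", 2k−4 columns for k landmarks), and a
principal component analysis of that matrix (relative warps, α = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import SpecimenTable


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from centroid.

    The standard geometric-morphometric size measure; scales linearly with
    the configuration.  A fully degenerate configuration (all landmarks
    coincident) returns 0 with a warning.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 3:
        raise ValueError("configuration must be (k>=3, d)")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks coincide", stacklevel=2)
    return cs


@dataclass
class ShapeSample:
    """GPA output: aligned coordinates, sizes, consensus and metadata.

    ``aligned`` is (n, k, 2) in Procrustes units — every configuration is
    centred at the origin and scaled to unit centroid size.  Original
    centroid sizes (mm) are kept separately; size analyses downstream use
    their natural log (lnCS).
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    metadata: pd.DataFrame
    converged: bool = True

    def __post_init__(self) -> None:
        self.aligned = np.asarray(self.aligned, dtype=float)
        self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)
        if np.any(self.centroid_sizes <= 0):
            raise ValueError("centroid sizes must be positive")

    def __len__(self) -> int:
        return self.aligned.shape[0]

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def lnCS(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    def residuals(self) -> np.ndarray:
        """Flattened Procrustes residuals about the consensus, (n, 2k)."""
        return (self.aligned - self.mean_shape).reshape(self.n, -1)


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centered = config - config.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs == 0:
        raise ValueError("degenerate configuration in GPA")
    return centered / cs, float(cs)


def _optimal_rotation(x: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation R minimizing ||x R − target||_F for centred configurations."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_distance(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """Full Procrustes distance between two configurations.

    Both are centred and scaled to unit centroid size, then optimally
    rotated; the distance is the residual Frobenius norm.
    """
    xa, _ = _center_scale(np.asarray(a, float))
    xb, _ = _center_scale(np.asarray(b, float))
    r = _optimal_rotation(xa, xb, allow_reflection)
    return float(np.linalg.norm(xa @ r - xb))


def gpa(
    table: SpecimenTable,
    allow_reflection: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ShapeSample:
    """Generalized Procrustes analysis of a specimen table.

    Iterates: scale every centred configuration to unit centroid size,
    rotate each onto the current consensus by orthogonal Procrustes,
    recompute the consensus (itself rescaled to unit centroid size each
    round) until its root-mean-square change drops below ``tol``.
    Non-convergence within ``max_iter`` warns and flags the result.
    """
    if len(table) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    raw = table.coords_array()
    n, k, _ = raw.shape
    sizes = np.empty(n)
    x = np.empty_like(raw)
    for i in range(n):
        x[i], sizes[i] = _center_scale(raw[i])

    consensus = x[0].copy()
    converged = False
    for _ in range(max_iter):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus, allow_reflection)
        new_consensus = x.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        # consensus orientation is arbitrary; anchor it to the previous one
        new_consensus = new_consensus @ _optimal_rotation(
            new_consensus, consensus, allow_reflection
        )
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", stacklevel=2
        )
    for i in range(n):  # final alignment to the converged consensus
        x[i] = x[i] @ _optimal_rotation(x[i], consensus, allow_reflection)

    x = _tangent_project(x, consensus)
    return ShapeSample(
        aligned=x,
        centroid_sizes=sizes,
        mean_shape=consensus,
        metadata=table.metadata_frame(),
        converged=converged,
    )


def _tangent_project(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent plane at the consensus.

    The pre-shapes live on the unit sphere; the tangent hyperplane at the
    consensus c is {y : y·c = 1}.  For small shape variation the shift is
    numerically negligible but it makes the residual space exactly linear.
    """
    c = consensus.ravel()
    flat = aligned.reshape(aligned.shape[0], -1)
    dots = flat @ c  # c·c == 1
    projected = flat - np.outer(dots - 1.0, c)
    return projected.reshape(aligned.shape)


def align_sample_to(sample: ShapeSample, reference: np.ndarray) -> ShapeSample:
    """Rigidly rotate a GPA result into a reference orientation.

    GPA fixes orientation only up to a global rotation (it is anchored to
    the starting consensus); comparisons against externally defined shape
    vectors need both in one frame.  Rotates consensus and aligned
    coordinates by the Procrustes rotation onto ``reference``.
    """
    ref, _ = _center_scale(np.asarray(reference, float))
    r = _optimal_rotation(sample.mean_shape, ref, allow_reflection=False)
    return ShapeSample(
        aligned=sample.aligned @ r,
        centroid_sizes=sample.centroid_sizes.copy(),
        mean_shape=sample.mean_shape @ r,
        metadata=sample.metadata,
        converged=sample.converged,
    )


# ---------------------------------------------------------------------------
# thin-plate-spline basis: partial warps + uniform component


@dataclass
class WeightMatrix:
    """Partial-warp + uniform-component scores, (n, 2k−4).

    An orthonormal change of basis of the aligned Procrustes residuals:
    2(k−3) non-affine partial-warp scores followed by 2 affine (uniform)
    scores.  Total variance equals that of the residuals exactly.
    """

    scores: np.ndarray
    basis: np.ndarray  # (2k, 2k−4) orthonormal columns
    bending_eigenvalues: np.ndarray  # (k−3,) positive, ascending
    consensus: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_nonaffine(self) -> int:
        return 2 * len(self.bending_eigenvalues)

    def frame(self) -> pd.DataFrame:
        k3 = len(self.bending_eigenvalues)
        cols = [f"PW{i + 1}{ax}" for i in range(k3) for ax in ("x", "y")]
        cols += ["U1", "U2"]
        return pd.DataFrame(self.scores, columns=cols)


def bending_energy_matrix(consensus: np.ndarray) -> np.ndarray:
    """Bending-energy matrix L_k^{-1} of the thin-plate spline at a reference.

    Built from the TPS kernel U(r) = r² log r² on the consensus landmarks;
    its null space is the affine subspace (spanned by 1, x, y), and its
    k−3 positive-eigenvalue eigenvectors are the principal warps.
    """
    c = np.asarray(consensus, float)
    k = c.shape[0]
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kmat = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    q = np.column_stack([np.ones(k), c])  # (k, 3)
    if np.linalg.matrix_rank(q) < 3:
        raise ValueError("collinear consensus landmarks: bending energy undefined")
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    linv = np.linalg.inv(lmat)
    bend = linv[:k, :k]
    return (bend + bend.T) / 2.0


def _similarity_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k, 4) of translation, scaling and rotation at c."""
    k = consensus.shape[0]
    c = consensus.ravel()
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    scale = c.copy()
    rot = np.column_stack([-consensus[:, 1], consensus[:, 0]]).ravel()
    basis = np.column_stack([tx, ty, scale, rot])
    q, _ = np.linalg.qr(basis)
    return q


def weight_matrix(sample: ShapeSample) -> WeightMatrix:
    """Project aligned residuals onto the partial-warp/uniform basis.

    Principal warps are the positive-eigenvalue eigenvectors of the
    bending-energy matrix of the consensus; each contributes an x and a y
    partial-warp score per specimen (α = 0, i.e. no bending-energy
    reweighting).  The uniform component is the 2-D orthogonal complement
    of the non-affine subspace inside the (2k−4)-dimensional tangent
    space.  The result is an orthonormal basis, so total variance is
    preserved.
    """
    consensus = sample.mean_shape
    k = consensus.shape[0]
    if k < 4:
        raise ValueError("need at least 4 landmarks for a 2k-4 basis")
    bend = bending_energy_matrix(consensus)
    evals, evecs = np.linalg.eigh(bend)
    pos = evals > max(evals.max(), 1.0) * 1e-10
    principal = evecs[:, pos]  # (k, k-3)
    if principal.shape[1] != k - 3:
        raise ValueError(
            f"expected {k - 3} principal warps, got {principal.shape[1]} "
            "(degenerate consensus?)"
        )
    order = np.argsort(evals[pos])
    principal = principal[:, order]
    bend_evals = evals[pos][order]

    # non-affine basis in R^{2k}: each principal warp acting on x and on y
    nonaffine = np.zeros((2 * k, 2 * (k - 3)))
    for j in range(k - 3):
        nonaffine[0::2, 2 * j] = principal[:, j]
        nonaffine[1::2, 2 * j + 1] = principal[:, j]

    sim = _similarity_basis(consensus)
    # uniform component: complete {similarity, non-affine} to a full basis
    known = np.column_stack([sim, nonaffine])
    u, s, _ = np.linalg.svd(known, full_matrices=True)
    null_dim = 2 * k - known.shape[1]
    if null_dim != 2:
        raise ValueError("unexpected tangent-space dimension")
    uniform = u[:, -null_dim:]

    basis = np.column_stack([nonaffine, uniform])
    # reproducible column signs: largest-|loading| entry positive
    for j in range(basis.shape[1]):
        imax = np.argmax(np.abs(basis[:, j]))
        if basis[imax, j] < 0:
            basis[:, j] *= -1

    scores = sample.residuals() @ basis
    return WeightMatrix(
        scores=scores,
        basis=basis,
        bending_eigenvalues=bend_evals,
        consensus=consensus,
        metadata=sample.metadata,
    )


@dataclass
class RWResult:
    """Relative warps: principal components of the weight matrix."""

    scores: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,) non-increasing
    percent_variance: np.ndarray  # sums to 100
    loadings: np.ndarray  # (m, 2k−4) rows are unit eigenvectors

    @property
    def cumulative_percent(self) -> np.ndarray:
        return np.cumsum(self.percent_variance)

    def frame(self) -> pd.DataFrame:
        cols = [f"RW{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, columns=cols)


def relative_warps(wm: WeightMatrix) -> RWResult:
    """Centered PCA of the weight matrix (relative warp analysis, α = 0).

    With α = 0 the scores coincide, up to column sign, with a PCA of the
    raw aligned residuals.  Eigenvector signs are fixed by making each
    column's largest-|loading| entry positive.
    """
    x = wm.scores
    n = x.shape[0]
    if n < 3:
        raise ValueError("relative warps need at least 3 specimens")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = s > s[0] * 1e-12 if s[0] > 0 else slice(0, 0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    eigenvalues = s**2 / (n - 1)
    for j in range(vt.shape[0]):
        imax = np.argmax(np.abs(vt[j]))
        if vt[j, imax] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    total = eigenvalues.sum()
    percent = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return RWResult(
        scores=scores,
        eigenvalues=eigenvalues,
        percent_variance=percent,
        loadings=vt,
    )


def select_rws(rw: RWResult, threshold: float = 95.0) -> int:
    """Smallest number of leading relative warps reaching ``threshold`` %.

    Mirrors the usual practice of feeding MANOVA only the axes that jointly
    explain at least e.g. 95 % of shape variance.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    cum = rw.cumulative_percent
    reached = np.flatnonzero(cum >= threshold - 1e-9)
    if reached.size == 0:
        return len(cum)
    return int(reached[0]) + 1
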
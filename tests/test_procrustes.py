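import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecomorph import (
    LandmarkConfiguration,
    SpecimenTable,
    centroid_size,
    gpa,
    relative_warps,
    select_rws,
    weight_matrix,
)
from ecomorph.procrustes import (
    RWResult,
    ShapeSample,
    procrustes_distance,
)


def _table(coords_list, prefix="s"):
    return SpecimenTable(
        [
            LandmarkConfiguration(specimen_id=f"{prefix}{i}", coords=c, species="sp")
            for i, c in enumerate(coords_list)
        ]
    )


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2))

    @given(c=st.floats(0.01, 100), seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_homogeneity(self, c, seed):
        config = np.random.default_rng(seed).uniform(-5, 5, (7, 2))
        assert centroid_size(c * config) == pytest.approx(
            c * centroid_size(config), rel=1e-9
        )

    def test_matches_defining_sum(self, rng):
        config = rng.uniform(0, 100, (29, 2))
        centroid = config.mean(axis=0)
        brute = np.sqrt(sum(((p - centroid) ** 2).sum() for p in config))
        assert centroid_size(config) == pytest.approx(brute, rel=1e-12)

    def test_degenerate_warns_zero(self):
        with pytest.warns(UserWarning):
            assert centroid_size(np.ones((5, 2))) == 0.0


class TestGPA:
    def test_duplicates_have_zero_distance(self, rng):
        config = rng.uniform(0, 10, (8, 2))
        sample = gpa(_table([config, config.copy(), config.copy()]))
        d = np.linalg.norm(sample.aligned[0] - sample.aligned[1])
        assert d < 1e-10

    def test_similarity_invariance(self, rng):
        config = rng.uniform(0, 10, (8, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = 3.1 * config @ rot + np.array([5.0, -2.0])
        sample = gpa(_table([config, moved]))
        assert np.linalg.norm(sample.aligned[0] - sample.aligned[1]) < 1e-8
        # original centroid sizes survive superimposition
        assert sample.centroid_sizes[1] == pytest.approx(
            3.1 * sample.centroid_sizes[0], rel=1e-9
        )

    def test_pairwise_distance_matches_rotation_grid(self, rng):
        """Procrustes distance equals a brute-force search over rotations."""
        a = rng.uniform(0, 1, (5, 2))
        b = rng.uniform(0, 1, (5, 2))
        d_impl = procrustes_distance(a, b)

        def unit(x):
            x = x - x.mean(axis=0)
            return x / np.sqrt((x**2).sum())

        xa, xb = unit(a), unit(b)
        thetas = np.arange(0.0, 2 * np.pi, 1e-4)
        cos, sin = np.cos(thetas), np.sin(thetas)
        # ||xa R - xb||^2 = 2 - 2 (m11+m22 cosθ + (m21-m12) sinθ) terms
        m = xa.T @ xb
        trace_term = (m[0, 0] + m[1, 1]) * cos + (m[0, 1] - m[1, 0]) * sin
        d_grid = np.sqrt(np.min(2.0 - 2.0 * trace_term))
        assert d_impl == pytest.approx(d_grid, abs=1e-6)

    def test_consensus_is_fixed_point(self, aligned_small):
        """The consensus is the mean of its aligned sample; a re-run only
        moves it at second order (tangent projection leaves configurations
        marginally off the unit sphere, so re-scaling shifts the mean)."""
        m = aligned_small.aligned.mean(axis=0)
        m = m / np.sqrt((m**2).sum())
        assert np.abs(m - aligned_small.mean_shape).max() < 1e-10
        table = _table(list(aligned_small.aligned))
        again = gpa(table, tol=1e-10)
        oriented = _orient(again.mean_shape, aligned_small.mean_shape)
        assert np.abs(oriented - aligned_small.mean_shape).max() < 1e-4

    def test_residual_ssq_invariant_to_order(self, small_study):
        table = small_study.specimens
        s1 = gpa(table)
        rev = SpecimenTable(list(table.configurations[::-1]))
        s2 = gpa(rev)
        assert (s1.residuals() ** 2).sum() == pytest.approx(
            (s2.residuals() ** 2).sum(), rel=1e-6
        )


def _orient(x, target):
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return x @ r


class TestWeightMatrix:
    def test_29_landmarks_give_54_columns(self):
        rng = np.random.default_rng(7)
        base = np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 29, endpoint=False)),
             np.sin(np.linspace(0, 2 * np.pi, 29, endpoint=False))]
        )
        configs = [base + rng.normal(0, 0.01, (29, 2)) for _ in range(6)]
        wm = weight_matrix(gpa(_table(configs)))
        assert wm.scores.shape[1] == 2 * 29 - 4 == 54

    def test_total_variance_preserved(self, aligned_small, wm_small):
        res = aligned_small.residuals()
        assert (wm_small.scores**2).sum() == pytest.approx(
            (res**2).sum(), rel=1e-10
        )

    def test_pure_shear_has_no_nonaffine_energy(self):
        """A uniform shear of the consensus loads only the affine scores."""
        rng = np.random.default_rng(1)
        base = np.column_stack(
            [2 * np.cos(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
             np.sin(np.linspace(0, 2 * np.pi, 12, endpoint=False))]
        )
        shears = np.linspace(-0.05, 0.05, 8)
        configs = []
        for a in shears:
            shear = np.array([[1.0, a], [0.0, 1.0]])
            configs.append(base @ shear.T)
        wm = weight_matrix(gpa(_table(configs), tol=1e-12))
        total = (wm.scores**2).sum()
        nonaffine = (wm.scores[:, : wm.n_nonaffine] ** 2).sum()
        assert nonaffine < 1e-8 * total

    def test_collinear_consensus_rejected(self):
        line = np.column_stack([np.arange(6.0), np.zeros(6)])
        with pytest.raises(ValueError, match="[Cc]ollinear|bending"):
            from ecomorph.procrustes import bending_energy_matrix

            bending_energy_matrix(line)


class TestRelativeWarps:
    def test_percent_variance_sums_to_100(self, wm_small):
        rw = relative_warps(wm_small)
        assert rw.percent_variance.sum() == pytest.approx(100.0)
        assert np.all(np.diff(rw.eigenvalues) <= 1e-12)

    def test_scores_match_pca_of_residuals(self, aligned_small, wm_small):
        """With alpha = 0, RWA equals a PCA of the Procrustes residuals."""
        rw = relative_warps(wm_small)
        res = aligned_small.residuals()
        resc = res - res.mean(axis=0)
        u, s, vt = np.linalg.svd(resc, full_matrices=False)
        direct = u[:, : rw.scores.shape[1]] * s[: rw.scores.shape[1]]
        # columns may differ in sign only
        for j in range(rw.scores.shape[1]):
            diff = min(
                np.abs(rw.scores[:, j] - direct[:, j]).max(),
                np.abs(rw.scores[:, j] + direct[:, j]).max(),
            )
            assert diff < 1e-8

    def test_rank_bound_with_four_specimens(self, rng):
        base = rng.uniform(0, 1, (8, 2))
        configs = [base + rng.normal(0, 0.01, (8, 2)) for _ in range(4)]
        rw = relative_warps(weight_matrix(gpa(_table(configs))))
        assert np.sum(rw.eigenvalues > rw.eigenvalues[0] * 1e-10) <= 3

    def test_scores_columns_orthogonal(self, wm_small):
        rw = relative_warps(wm_small)
        gram = rw.scores.T @ rw.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()


class TestSelectRWs:
    def test_simple_shares(self):
        rw = RWResult(
            scores=np.zeros((5, 3)),
            eigenvalues=np.array([6.0, 3.0, 1.0]),
            percent_variance=np.array([60.0, 30.0, 10.0]),
            loadings=np.eye(3),
        )
        assert select_rws(rw, 95.0) == 3
        assert select_rws(rw, 60.0) == 1
        assert select_rws(rw, 100.0) == 3

    def test_tuned_spectrum_reaches_threshold_at_known_axis(self):
        """A geometric eigen-spectrum calibrated so 25 axes carry 95 %."""
        m = 54
        ratio = 0.887  # chosen so the cumulative share crosses 95% at axis 25
        lam = ratio ** np.arange(m)
        pct = 100 * lam / lam.sum()
        rw = RWResult(
            scores=np.zeros((60, m)),
            eigenvalues=lam,
            percent_variance=pct,
            loadings=np.eye(m),
        )
        expected = int(np.argmax(np.cumsum(pct) >= 95.0)) + 1
        assert expected == 25
        assert select_rws(rw, 95.0) == 25
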
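import numpy as np
import pytest

from eyemorph import morpho
from eyemorph.morpho import LandmarkConfiguration


def _rot(angle):
    return np.array([[np.cos(angle), -np.sin(angle)],
                     [np.sin(angle), np.cos(angle)]])


TRI_A = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
TRI_B = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])


def grid_oracle_distance(a, b, n_steps=200000):
    """Brute-force partial Procrustes distance over a fine rotation grid."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / np.sqrt((a ** 2).sum())
    b = b / np.sqrt((b ** 2).sum())
    thetas = np.linspace(0, 2 * np.pi, n_steps, endpoint=False)
    cos, sin = np.cos(thetas), np.sin(thetas)
    # ||a R(t) - b||^2 = 2 - 2 (cos t * <a,b> + sin t * cross-term)
    dot = (a * b).sum()
    cross = (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]).sum()
    d2 = 2 - 2 * (cos * dot + sin * cross)
    return float(np.sqrt(d2.min()))


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        assert morpho.centroid_size(sq) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_homogeneity(self, rng):
        pts = rng.normal(size=(7, 2))
        assert morpho.centroid_size(2 * pts) == pytest.approx(
            2 * morpho.centroid_size(pts))

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            morpho.centroid_size(np.ones((5, 2)))


class TestProcrustesAlign:
    def test_identical_shapes_distance_zero(self):
        al = morpho.procrustes_align([TRI_A, TRI_A.copy()])
        d = morpho.procrustes_distance(al.procrustes_coords[0],
                                       al.procrustes_coords[1])
        assert d < 1e-12

    def test_similarity_invariance(self):
        moved = 3.0 * TRI_A @ _rot(np.deg2rad(37)).T + np.array([5.0, -2.0])
        al = morpho.procrustes_align([TRI_A, moved])
        d = morpho.procrustes_distance(al.procrustes_coords[0],
                                       al.procrustes_coords[1])
        assert d <= 1e-9

    def test_matches_grid_search_oracle(self):
        al = morpho.procrustes_align([TRI_A, TRI_B])
        d = morpho.procrustes_distance(al.procrustes_coords[0],
                                       al.procrustes_coords[1])
        assert d == pytest.approx(grid_oracle_distance(TRI_A, TRI_B), abs=1e-4)
        # the pairwise superimposing distance agrees too
        assert morpho.procrustes_distance(TRI_A, TRI_B, superimpose=True) == \
            pytest.approx(grid_oracle_distance(TRI_A, TRI_B), abs=1e-4)

    def test_invariant_to_input_transform(self, rng):
        shapes = [rng.normal(size=(10, 2)) for _ in range(4)]
        al1 = morpho.procrustes_align(shapes)
        mangled = list(shapes)
        mangled[2] = 0.3 * mangled[2] @ _rot(1.1).T + rng.normal(size=2)
        al2 = morpho.procrustes_align(mangled)
        d1 = morpho.procrustes_distance(al1.procrustes_coords[0],
                                        al1.procrustes_coords[2])
        d2 = morpho.procrustes_distance(al2.procrustes_coords[0],
                                        al2.procrustes_coords[2])
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_unit_size_and_centering(self, rng):
        shapes = [rng.normal(size=(6, 2)) for _ in range(3)]
        al = morpho.procrustes_align(shapes)
        for row in al.procrustes_coords:
            pts = row.reshape(-1, 2)
            assert np.allclose(pts.mean(axis=0), 0, atol=1e-9)
            assert np.sqrt((pts ** 2).sum()) == pytest.approx(1.0, abs=1e-9)


class TestPcaShapes:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=8)
        scores = rng.normal(size=12)
        x = np.outer(scores, base)
        sub = morpho.pca_shapes(x)
        assert sub.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(sub.variance_fraction[1:] < 1e-12)

    def test_roundtrip_identity(self, rng):
        x = rng.normal(size=(15, 10))
        sub = morpho.pca_shapes(x)
        recon = sub.scores @ sub.basis.T + sub.mean
        assert np.allclose(recon, x, atol=1e-9)

    def test_orthonormal_basis(self, rng):
        sub = morpho.pca_shapes(rng.normal(size=(20, 6)))
        assert np.allclose(sub.basis.T @ sub.basis, np.eye(sub.basis.shape[1]),
                           atol=1e-9)


class TestRemoveNuisance:
    def test_zero_within_variance_identity(self):
        # two groups, all members identical within group
        a = np.tile(np.arange(8.0), (5, 1))
        b = np.tile(np.arange(8.0)[::-1], (5, 1))
        x = np.vstack([a, b])
        groups = ["a"] * 5 + ["b"] * 5
        out = morpho.remove_nuisance_axes(x, groups)
        assert np.allclose(out.coords, x, atol=1e-9)

    def test_residual_orthogonality(self, rng):
        x = rng.normal(size=(30, 8))
        groups = ["a"] * 15 + ["b"] * 15
        out = morpho.remove_nuisance_axes(x, groups, n_steps=1)
        score = out.removed_scores[0]
        inv = np.array([0] * 15 + [1] * 15)
        gmeans = np.stack([out.coords[inv == g].mean(axis=0) for g in (0, 1)])
        within = out.coords - gmeans[inv]
        assert np.allclose(score @ within, 0, atol=1e-9)

    def test_singleton_group_raises(self, rng):
        x = rng.normal(size=(4, 6))
        with pytest.raises(ValueError, match="singleton"):
            morpho.remove_nuisance_axes(x, ["a", "a", "a", "b"])

    def test_planted_pitch_removed(self, two_group_landmarks):
        lm = two_group_landmarks
        al = morpho.procrustes_align(lm.configs)
        out = morpho.remove_nuisance_axes(al, al.groups)
        before = abs(np.corrcoef(al.procrustes_coords @ lm.truth["pitch_vector"],
                                 lm.truth["pitch_scores"])[0, 1])
        after = abs(np.corrcoef(out.coords @ lm.truth["pitch_vector"],
                                lm.truth["pitch_scores"])[0, 1])
        assert before > 0.9
        assert after < 0.2  # desk-scale sample; the tight bound is checked at n=1000

    def test_commutes_with_reordering(self, rng):
        x = rng.normal(size=(20, 6))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        perm = rng.permutation(20)
        out1 = morpho.remove_nuisance_axes(x, groups)
        out2 = morpho.remove_nuisance_axes(x[perm], groups[perm])
        assert np.allclose(out1.coords[perm], out2.coords, atol=1e-8)


class TestReduceBackrotate:
    def test_full_variance_identity(self, rng):
        x = rng.normal(size=(12, 6))
        recon, k, _ = morpho.reduce_backrotate(x, 1.0)
        assert np.allclose(recon, x, atol=1e-9)

    def test_rank2_exact(self, rng):
        basis = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        x = rng.normal(size=(20, 2)) @ basis.T
        recon, k, _ = morpho.reduce_backrotate(x, 0.9)
        assert k == 2
        assert np.allclose(recon, x, atol=1e-9)

    def test_parseval_error_identity(self, rng):
        x = rng.normal(size=(50, 12))
        recon, k, sub = morpho.reduce_backrotate(x, 0.9)
        total = ((x - x.mean(axis=0)) ** 2).sum()
        err = ((x - recon) ** 2).sum()
        captured = sub.variance_fraction[:k].sum()
        assert err / total == pytest.approx(1 - captured, abs=1e-6)

    def test_invalid_target(self, rng):
        with pytest.raises(ValueError):
            morpho.reduce_backrotate(rng.normal(size=(5, 4)), 1.5)


class TestCva:
    @staticmethod
    def _whitened_groups(rng, n, p, delta):
        """Two groups with exactly spherical pooled covariance and a mean
        shift of `delta` along the first coordinate."""
        def whiten(z):
            z = z - z.mean(axis=0)
            cov = z.T @ z / (len(z) - 1)
            l = np.linalg.cholesky(np.linalg.inv(cov))
            return z @ l
        a = whiten(rng.normal(size=(n, p)))
        b = whiten(rng.normal(size=(n, p)))
        b = b + np.eye(p)[0] * delta
        return np.vstack([a, b]), ["a"] * n + ["b"] * n

    def test_closed_form_mahalanobis(self, rng):
        delta = 1.7
        x, groups = self._whitened_groups(rng, 25, 4, delta)
        res = morpho.cva(x, groups, n_perm=99, seed=0)
        assert res.mahalanobis_distances[("a", "b")] == pytest.approx(delta, rel=1e-6)

    def test_affine_invariance(self, rng):
        x, groups = self._whitened_groups(rng, 20, 4, 1.0)
        a = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        res1 = morpho.cva(x, groups, n_perm=49, seed=0)
        res2 = morpho.cva(x @ a, groups, n_perm=49, seed=0)
        assert res1.mahalanobis_distances[("a", "b")] == pytest.approx(
            res2.mahalanobis_distances[("a", "b")], abs=1e-6)

    def test_singular_covariance_raises(self, rng):
        # full-rank data with fewer within-group degrees of freedom than
        # retained dimensions: the pooled covariance cannot be inverted
        wide = rng.normal(size=(6, 30))
        with pytest.raises(np.linalg.LinAlgError, match="reduce"):
            morpho.cva(wide, ["a", "a", "a", "b", "b", "b"], n_perm=9)

    def test_permutation_p_range_and_determinism(self, rng):
        x, groups = self._whitened_groups(rng, 15, 3, 0.2)
        r1 = morpho.cva(x, groups, n_perm=99, seed=5)
        r2 = morpho.cva(x, groups, n_perm=99, seed=5)
        p = r1.p_values[("a", "b")]
        assert 1 / 100 <= p <= 1
        assert p == r2.p_values[("a", "b")]


class TestDfa:
    def test_requires_two_groups(self, rng):
        x = rng.normal(size=(9, 4))
        with pytest.raises(ValueError):
            morpho.dfa(x, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)

    def test_label_swap_flips_scores(self, rng):
        x = rng.normal(size=(20, 4))
        x[10:] += 1.0
        g1 = ["a"] * 10 + ["b"] * 10
        g2 = ["b"] * 10 + ["a"] * 10
        r1 = morpho.dfa(x, g1, n_perm=19, seed=0)
        r2 = morpho.dfa(x, g2, n_perm=19, seed=0)
        assert np.allclose(np.abs(r1.discriminant_scores),
                           np.abs(r2.discriminant_scores), atol=1e-8)
        assert np.allclose(r1.discriminant_scores, -r2.discriminant_scores,
                           atol=1e-8)

    def test_separated_groups_minimum_p(self, rng):
        x = rng.normal(size=(30, 3))
        x[15:, 0] += 20.0
        res = morpho.dfa(x, ["a"] * 15 + ["b"] * 15, n_perm=199, seed=0)
        assert res.p_values[("a", "b")] == pytest.approx(1 / 200)
        assert res.cv_misclassification == 0.0


class TestAllometry:
    def test_perfect_linear_residuals_zero(self, rng):
        cs = rng.uniform(1, 3, 40)
        slopes = rng.normal(size=6)
        x = np.outer(cs, slopes) + 5.0
        fitted, resid, _ = morpho.allometric_decomposition(x, cs)
        assert np.allclose(resid - resid.mean(axis=0), 0, atol=1e-9)

    def test_constant_size_raises(self, rng):
        with pytest.raises(ValueError):
            morpho.allometric_decomposition(rng.normal(size=(5, 4)), np.ones(5))

    def test_planted_vector_recovered(self, rng):
        n, p = 200, 20
        vec = rng.normal(size=p)
        vec /= np.linalg.norm(vec)
        cs = rng.uniform(1, 2, n)
        x = np.outer(cs, vec) + rng.normal(size=(n, p)) * 0.02
        _, _, slopes = morpho.allometric_decomposition(x, cs)
        cos = slopes @ vec / np.linalg.norm(slopes)
        assert cos > 0.95
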
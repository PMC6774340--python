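"""Bray-Curtis oracle equivalence, nMDS behavior, axis conventions, ellipses."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

from noduleco.ordination import (bray_curtis, class_ellipses, classical_mds,
                                 kruskal_stress1, nmds_embed, orient_axes,
                                 _pairwise)


def brute_force_bray(X):
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(X[i][k] - X[j][k]) for k in range(len(X[i])))
            den = sum(X[i][k] + X[j][k] for k in range(len(X[i])))
            D[i, j] = num / den if den > 0 else 0.0
    return D


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert bray_curtis(X)[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert bray_curtis(X)[0, 1] == 1.0

    def test_hand_worked_pair(self):
        X = np.array([[1.0, 2.0, 0.0], [0.0, 2.0, 4.0]])
        assert bray_curtis(X)[0, 1] == pytest.approx(5.0 / 9.0)

    def test_all_zero_pair_convention(self):
        X = np.zeros((3, 4))
        X[0, 0] = 1.0
        with pytest.warns(UserWarning, match="all-zero"):
            D = bray_curtis(X)
        assert D[1, 2] == 0.0

    @settings(max_examples=50, deadline=None)
    @given(arrays(float, (6, 4), elements=st.floats(0, 10)))
    def test_matches_brute_force_double_loop(self, X):
        D = bray_curtis(X)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = brute_force_bray(X)
        assert np.allclose(D, ref, atol=1e-12)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()


class TestNmds:
    def test_collinear_points_embed_with_near_zero_stress(self):
        x = np.linspace(0.0, 9.0, 10)
        D = np.abs(x[:, None] - x[None, :])
        res = nmds_embed(D, restarts=4, rng=np.random.default_rng(1))
        assert res.stress < 0.01
        order = np.argsort(res.coordinates[:, 0])
        assert list(order) in ([*range(10)], [*reversed(range(10))])

    def test_duplicate_objects_coincide(self):
        base = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        D = np.zeros((4, 4))
        D[:3, :3] = base
        D[3, :3] = base[0]          # object 3 duplicates object 0
        D[:3, 3] = base[0]
        res = nmds_embed(D, restarts=8, rng=np.random.default_rng(2))
        gap = np.linalg.norm(res.coordinates[0] - res.coordinates[3])
        span = np.abs(res.coordinates).max()
        assert gap < 0.05 * span

    def test_coordinates_centered_principal_axes(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        D = _pairwise(X)
        res = nmds_embed(D, restarts=4, rng=rng)
        c = res.coordinates
        assert np.allclose(c.mean(axis=0), 0.0, atol=1e-9)
        assert c[:, 0].var() >= c[:, 1].var()
        # principal-axis rotation leaves cross-covariance zero
        assert abs((c[:, 0] * c[:, 1]).sum()) < 1e-6 * (c ** 2).sum()

    def test_embedding_preserves_rank_order_on_structured_gradient(self):
        rng = np.random.default_rng(4)
        grad = np.linspace(0, 1, 30)
        X = np.c_[np.sqrt(1 - grad), np.sqrt(grad)] + rng.normal(
            scale=0.01, size=(30, 2))
        D = bray_curtis(np.abs(X))
        res = nmds_embed(D, restarts=4, rng=rng)
        iu = np.triu_indices(30, 1)
        rs = spearmanr(D[iu], _pairwise(res.coordinates)[iu]).statistic
        assert rs >= 0.95

    def test_classical_mds_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 2))
        D = _pairwise(X)
        Y = classical_mds(D, 2)
        assert np.allclose(_pairwise(Y), D, atol=1e-8)


class TestOrientation:
    def _result(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([1, 2, 3, 4], 5)
        coords = np.c_[labels + rng.normal(scale=0.1, size=20),
                       rng.normal(scale=0.5, size=20)]
        coords -= coords.mean(axis=0)
        from noduleco.ordination import OrdinationResult
        return OrdinationResult(coordinates=coords, stress=0.01,
                                restarts_used=1, converged=True,
                                labels=labels)

    def test_positive_correlation_unchanged(self):
        res = self._result()
        covers = {1: 1.0, 2: 3.0, 3: 6.0, 4: 12.0}
        out = orient_axes(res, covers)
        d2 = out.coordinates[:, 1]
        assert np.allclose(out.coordinates[:, 0], res.coordinates[:, 0])
        assert d2[np.argmax(np.abs(d2))] > 0

    def test_involution_on_negated_input(self):
        from dataclasses import replace
        res = self._result()
        covers = {1: 1.0, 2: 3.0, 3: 6.0, 4: 12.0}
        ref = orient_axes(res, covers)
        neg = replace(res, coordinates=-res.coordinates)
        out = orient_axes(neg, covers)
        assert np.allclose(out.coordinates, ref.coordinates)


class TestEllipses:
    def _result(self, coords, labels):
        from noduleco.ordination import OrdinationResult
        return OrdinationResult(coordinates=coords, stress=0.0,
                                restarts_used=1, converged=True,
                                labels=np.asarray(labels))

    def test_isotropic_cloud_radius(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4000, 2))
        ell = class_ellipses(self._result(pts, np.ones(4000)), 0.95)[0]
        assert ell.semi_axes[0] == pytest.approx(np.sqrt(5.991), rel=0.05)
        assert ell.semi_axes[1] == pytest.approx(np.sqrt(5.991), rel=0.05)

    def test_identical_replicates_zero_area(self):
        pts = np.tile([2.0, -1.0], (5, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            ell = class_ellipses(self._result(pts, np.ones(5)), 0.95)[0]
        assert np.allclose(ell.semi_axes, 0.0)
        assert np.allclose(ell.centroid, [2.0, -1.0])

    def test_area_invariant_under_rotation(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(300, 2)) @ np.diag([2.0, 0.5])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a = class_ellipses(self._result(pts, np.ones(300)), 0.95)[0]
        b = class_ellipses(self._result(pts @ R.T, np.ones(300)), 0.95)[0]
        assert np.prod(a.semi_axes) == pytest.approx(np.prod(b.semi_axes))


def test_stress1_zero_for_perfect_configuration():
    x = np.linspace(0, 5, 8)
    D = np.abs(x[:, None] - x[None, :])
    coords = np.c_[x - x.mean(), np.zeros(8)]
    assert kruskal_stress1(D, coords) < 1e-12
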
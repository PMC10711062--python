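"""Rotation algebra: Procrustes step, block means, oblique transform, OT/OMT."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from meantarget import (
    LoadingMatrix,
    TargetRotation,
    TargetSpec,
    apply_oblique,
    block_mean_loadings,
    build_icm_target,
    condition_kappa,
    oblique_transform,
    omt_rotate,
    orthogonal_target_rotation,
    ot_rotate,
    tucker_congruence,
)
from meantarget.fixtures import (
    balanced_example_ot_pattern,
    balanced_example_ot_phi,
)

from conftest import random_icm_loadings, random_orthogonal


class TestOrthogonalTargetRotation:
    def test_perfect_target_is_fixed_point(self):
        target = build_icm_target(12, 3)
        lam = LoadingMatrix(target.pattern)
        lam1, m = orthogonal_target_rotation(lam, target)
        assert np.allclose(m, np.eye(3), atol=1e-10)
        assert np.allclose(lam1.values, lam.values, atol=1e-10)

    def test_recovers_column_swap(self):
        # 6x2 blocks swapped relative to the target: the optimal orthogonal
        # rotation is the permutation that un-swaps them (confirmed by brute
        # force over rotation angle and axis reflections).
        target = build_icm_target(6, 2)
        lam = LoadingMatrix(target.pattern[:, ::-1])

        def loss(mat):
            return ((lam.values @ mat - target.pattern) ** 2).sum()

        best = None
        for theta in np.linspace(0, 2 * np.pi, 2001):
            c, s = np.cos(theta), np.sin(theta)
            for mat in (
                np.array([[c, -s], [s, c]]),
                np.array([[c, s], [s, -c]]),  # reflection branch
            ):
                if best is None or loss(mat) < loss(best):
                    best = mat
        _, m = orthogonal_target_rotation(lam, target)
        assert np.allclose(m, best, atol=1e-2)
        assert np.allclose(m, np.array([[0.0, 1.0], [1.0, 0.0]]), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_orthogonality_and_invertibility(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            p, q = rng.integers(4, 20), rng.integers(1, 4)
            q = min(p, q)
            lam = LoadingMatrix(rng.standard_normal((p, q)))
            pat = ((rng.random((p, q)) < 0.5) * 1.0)
            if (pat.sum(axis=0) == 0).any():
                continue
            target = TargetSpec(pat)
            lam1, m = orthogonal_target_rotation(lam, target)
            assert np.abs(m.T @ m - np.eye(q)).max() < 1e-10
            assert np.abs(lam1.values @ np.linalg.inv(m) - lam.values).max() < 1e-10


class TestBlockMeanLoadings:
    def test_balanced_example_collapses_to_half_identity(self, balanced_example):
        target = build_icm_target(18, 3)
        l1m = block_mean_loadings(balanced_example, target)
        assert np.allclose(l1m, 0.5 * np.eye(3), atol=1e-12)

    def test_perfect_pattern_gives_identity(self):
        target = build_icm_target(12, 4)
        l1m = block_mean_loadings(LoadingMatrix(target.pattern), target)
        assert np.allclose(l1m, np.eye(4), atol=1e-12)

    def test_hand_computed_weighted_means(self):
        # Block 1 loads (.4,.5,.6) on F1 and (.1,.2,.3) on F2: the
        # salient-weighted means are (.16+.25+.36)/1.5 and (.04+.10+.18)/1.5.
        lam = LoadingMatrix(
            np.array(
                [
                    [0.4, 0.1],
                    [0.5, 0.2],
                    [0.6, 0.3],
                    [0.1, 0.4],
                    [0.2, 0.5],
                    [0.3, 0.6],
                ]
            )
        )
        target = build_icm_target(6, 2)
        l1m = block_mean_loadings(lam, target)
        assert l1m[0, 0] == pytest.approx(0.77 / 1.5)
        assert l1m[0, 1] == pytest.approx(0.32 / 1.5)

    def test_zero_salient_block_raises(self):
        lam = LoadingMatrix(np.array([[0.0, 0.5], [0.0, 0.6], [0.0, 0.4], [0.0, 0.5]]))
        target = build_icm_target(4, 2)
        with pytest.raises(ValueError, match="factor"):
            block_mean_loadings(lam, target)


class TestObliqueTransform:
    def test_scaled_identity(self):
        st = oblique_transform(3.0 * np.eye(4), np.eye(4), ridge=0.0)
        assert np.allclose(st.T, np.eye(4) / 3.0)
        assert np.allclose(st.Tn, np.eye(4))
        assert st.kappa == pytest.approx(1.0)

    def test_matches_explicit_two_by_two_inverse(self):
        source = np.array([[2.0, 0.0], [1.0, 1.0]])
        gram = source.T @ source
        det = gram[0, 0] * gram[1, 1] - gram[0, 1] * gram[1, 0]
        gram_inv = np.array(
            [[gram[1, 1], -gram[0, 1]], [-gram[1, 0], gram[0, 0]]]
        ) / det
        expected = gram_inv @ source.T
        st = oblique_transform(source, np.eye(2), ridge=0.0)
        assert np.allclose(st.T, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_columns_always_unit_norm(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.standard_normal((5, 3))
        st = oblique_transform(src, rng.standard_normal((5, 3)), ridge=0.01)
        assert np.allclose(np.linalg.norm(st.Tn, axis=0), 1.0, atol=1e-10)


class TestApplyOblique:
    def test_identity_transform_is_noop(self, balanced_example):
        st = oblique_transform(np.eye(3), np.eye(3))
        l2, lo, phi = apply_oblique(balanced_example, balanced_example, st)
        assert np.allclose(lo.values, balanced_example.values)
        assert np.allclose(phi, np.eye(3), atol=1e-10)

    def test_common_part_preserved_on_random_input(self):
        rng = np.random.default_rng(42)
        lam_u = random_icm_loadings(rng, q=3, ppq=4)
        target = build_icm_target(12, 3)
        lam1, _ = orthogonal_target_rotation(lam_u, target)
        st = oblique_transform(block_mean_loadings(lam1, target), np.eye(3))
        _, lo, phi = apply_oblique(lam1, lam_u, st)
        common = lam_u.values @ lam_u.values.T
        assert np.abs(lo.values @ phi @ lo.values.T - common).max() < 1e-6


class TestOTRotation:
    def test_balanced_example_two_decimal_values(self, balanced_example):
        res = ot_rotate(balanced_example)
        expected = balanced_example_ot_pattern().values
        assert np.abs(np.round(res.pattern.values, 2) - expected).max() < 1e-12
        assert np.allclose(np.round(res.phi, 2), balanced_example_ot_phi())

    def test_perfect_uncorrelated_icm_unchanged(self):
        target = build_icm_target(12, 3)
        lam = LoadingMatrix(target.pattern * 0.6)
        res = ot_rotate(lam)
        assert np.abs(res.pattern.values - lam.values).max() < 1e-10
        assert np.allclose(res.phi, np.eye(3), atol=1e-10)

    def test_matches_dense_grid_search_oracle(self):
        # Independent oracle for a 2-factor problem: the least-squares
        # transform decouples per target column, so a dense grid over each
        # column of T finds the minimizer of ||Lu T - target||^2; the same
        # normalization and pattern/Phi algebra is then applied by hand.
        rng = np.random.default_rng(7)
        lam = np.kron(np.eye(2), rng.uniform(0.45, 0.7, size=(3, 1)))
        lam[:3, 1] = [0.15, -0.05, 0.1]
        lam[3:, 0] = [0.05, 0.12, -0.08]
        lam_u = LoadingMatrix(lam)
        target = build_icm_target(6, 2)

        def column_loss(j, a, b):
            return ((target.pattern[:, j] - a * lam[:, 0] - b * lam[:, 1]) ** 2).sum()

        t_cols = []
        for j in range(2):
            # coarse joint grid, then shrinking local grids around the optimum
            coarse = np.linspace(-3.0, 3.0, 121)
            losses = [
                (column_loss(j, a, b), a, b) for a in coarse for b in coarse
            ]
            _, a, b = min(losses)
            width = 0.1
            for _ in range(4):
                fine_a = np.linspace(a - width, a + width, 41)
                fine_b = np.linspace(b - width, b + width, 41)
                _, a, b = min(
                    (column_loss(j, fa, fb), fa, fb) for fa in fine_a for fb in fine_b
                )
                width /= 10
            t_cols.append((a, b))
        t = np.array(t_cols).T
        tn = t / np.linalg.norm(t, axis=0)
        lo = lam @ tn @ np.diag(np.sqrt(np.diag(np.linalg.inv(tn.T @ tn))))
        g = np.linalg.inv(lo.T @ lo)
        phi = g @ lo.T @ (lam @ lam.T) @ lo @ g

        res = ot_rotate(lam_u, target)
        assert np.abs(res.pattern.values - lo).max() < 1e-3
        assert np.abs(res.phi[0, 1] - phi[0, 1]) < 1e-3


class TestOMTRotation:
    def test_balanced_example_is_fixed_point(self, balanced_example):
        res = omt_rotate(balanced_example)
        assert np.abs(res.pattern.values - balanced_example.values).max() < 1e-8
        assert np.abs(res.phi - np.eye(3)).max() < 1e-8
        assert np.allclose(res.lambda1m, 0.5 * np.eye(3))

    def test_perfect_icm_is_fixed_point(self):
        target = build_icm_target(9, 3)
        lam = LoadingMatrix(target.pattern * 0.7)
        res = omt_rotate(lam)
        assert np.abs(res.pattern.values - lam.values).max() < 1e-8
        assert np.abs(res.phi - np.eye(3)).max() < 1e-8

    def test_shared_positive_cross_block_gives_positive_phi(self, crossloaded):
        # Two blocks with mutual +0.13 cross-loadings and one clean block:
        # the oblique solution correlates the first two factors positively
        # and leaves the third uncorrelated.
        res = omt_rotate(crossloaded)
        assert res.phi[0, 1] > 0.3
        assert abs(res.phi[0, 2]) < 1e-6
        assert abs(res.phi[1, 2]) < 1e-6

    def test_zero_block_mean_patterns_are_fixed_points(self):
        # Any pattern whose salient-weighted mean cross-loadings vanish is
        # returned unchanged with orthogonal factors.
        rng = np.random.default_rng(3)
        for _ in range(20):
            sal = rng.uniform(0.4, 0.7, size=4)
            lam = np.kron(np.eye(3), sal[:, None])
            for b in range(3):
                block = slice(4 * b, 4 * (b + 1))
                w = lam[block, b]
                basis = np.vstack([w, np.ones(4)])  # salient weights and sums
                proj = basis.T @ np.linalg.solve(basis @ basis.T, basis)
                for k in range(3):
                    if k != b:
                        col = 0.2 * rng.standard_normal(4)
                        # remove the components along the salient weights and
                        # the unit vector: weighted mean and plain sum vanish
                        lam[block, k] = col - proj @ col
            res = omt_rotate(LoadingMatrix(lam))
            assert np.abs(res.pattern.values - lam).max() < 1e-8
            assert np.abs(res.phi - np.eye(3)).max() < 1e-8


class TestPipelineInvariants:
    @pytest.mark.parametrize("method", ["ot", "omt"])
    def test_common_part_preservation(self, method):
        rng = np.random.default_rng(11)
        for _ in range(25):
            lam_u = random_icm_loadings(rng, q=3, ppq=4)
            res = TargetRotation(lam_u, method=method).fit()
            lo, phi = res.pattern.values, res.phi
            common = lam_u.values @ lam_u.values.T
            assert np.abs(lo @ phi @ lo.T - common).max() < 1e-6

    @pytest.mark.parametrize("method", ["ot", "omt"])
    def test_phi_is_a_valid_correlation_matrix(self, method):
        rng = np.random.default_rng(13)
        for _ in range(25):
            lam_u = random_icm_loadings(rng, q=4, ppq=5, noise=0.08)
            res = TargetRotation(lam_u, method=method).fit()
            assert np.allclose(res.phi, res.phi.T)
            assert np.allclose(np.diag(res.phi), 1.0)
            assert np.linalg.eigvalsh(res.phi).min() >= -1e-8

    @pytest.mark.parametrize("method", ["ot", "omt"])
    def test_orthogonal_rotation_equivariance(self, method):
        # Right-multiplying the input by any orthogonal matrix re-orients
        # the unrotated factors only; the oblique solution must not move.
        rng = np.random.default_rng(17)
        lam_u = random_icm_loadings(rng, q=3, ppq=5)
        base = TargetRotation(lam_u, method=method).fit()
        for _ in range(10):
            m = random_orthogonal(rng, 3)
            rotated = LoadingMatrix(lam_u.values @ m)
            res = TargetRotation(rotated, method=method).fit()
            assert np.abs(res.pattern.values - base.pattern.values).max() < 1e-8
            assert np.abs(res.phi - base.phi).max() < 1e-8


class TestCongruenceAndKappa:
    def test_congruence_reference_values(self):
        a = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 1.0]])
        b = np.array([[1.0, -1.0], [1.0, -1.0], [1.0, -1.0]])
        c = tucker_congruence(a, b)
        assert c[0] == pytest.approx(2 / np.sqrt(6))
        assert c[1] == pytest.approx(-1.0)
        assert tucker_congruence(a, a).tolist() == pytest.approx([1.0, 1.0])

    def test_congruence_zero_column_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            tucker_congruence(np.zeros((3, 1)), np.ones((3, 1)))

    def test_kappa_reference_values(self):
        assert condition_kappa(np.eye(5)) == pytest.approx(1.0)
        assert condition_kappa(np.diag([10.0, 0.1])) == pytest.approx(100.0)
        assert condition_kappa(np.zeros((2, 2))) == np.inf

    def test_kappa_matches_eigendecomposition_on_spd(self):
        rng = np.random.default_rng(29)
        a = rng.standard_normal((4, 4))
        spd = a @ a.T + 0.5 * np.eye(4)
        eig = np.linalg.eigvalsh(spd)
        assert condition_kappa(spd) == pytest.approx(eig[-1] / eig[0], rel=1e-10)


def test_summary_mentions_method_and_congruence(balanced_example):
    res = TargetRotation(balanced_example, method="ot").fit()
    text = res.summary()
    assert "OT" in text and "congruence" in text and "x1" in text
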
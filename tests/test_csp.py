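"""CSP, OVR-CSP, log-variance features and the LDA baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_spd, random_zero_mean_epoch
from sfnet.csp import (
    apply_filters,
    class_mean_covariances,
    csp_features,
    epoch_covariance,
    fit_lda,
    predict_lda,
    solve_csp_pair,
    solve_ovr_csp,
)
from sfnet.epochs import EpochSet
from sfnet.toydata import ToySpec, generate


class TestEpochCovariance:
    def test_hand_computed_2x2(self):
        X = np.array([[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(
            epoch_covariance(X), [[0.5, -0.5], [-0.5, 0.5]], atol=1e-15
        )

    def test_unit_trace_and_symmetry(self, rng):
        X = random_zero_mean_epoch(rng, 5, 40)
        R = epoch_covariance(X)
        assert abs(np.trace(R) - 1.0) < 1e-10
        np.testing.assert_allclose(R, R.T, atol=1e-14)
        assert np.linalg.eigvalsh(R)[0] > -1e-12

    def test_zero_epoch_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            epoch_covariance(np.zeros((3, 10)))

    def test_scale_invariance(self, rng):
        X = random_zero_mean_epoch(rng, 3, 30)
        np.testing.assert_allclose(
            epoch_covariance(X), epoch_covariance(7.3 * X), atol=1e-12
        )


class TestClassMeans:
    def test_single_epoch_class_mean_is_its_covariance(self, rng):
        X1 = random_zero_mean_epoch(rng, 3, 20)
        X2 = random_zero_mean_epoch(rng, 3, 20)
        es = EpochSet(epochs=[X1, X2], labels=[1, 2])
        cm = class_mean_covariances(es)
        np.testing.assert_allclose(cm.class_means[0], epoch_covariance(X1))
        np.testing.assert_allclose(cm.class_means[1], epoch_covariance(X2))

    def test_mean_of_identical_epochs_equals_member(self, rng):
        X = random_zero_mean_epoch(rng, 2, 20)
        es = EpochSet(epochs=[X, X.copy(), X.copy()], labels=[1, 1, 1],
                      n_classes=1)
        cm = class_mean_covariances(es)
        np.testing.assert_allclose(cm.class_means[0], epoch_covariance(X))

    def test_monte_carlo_convergence_to_generating_covariance(self):
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        spec = ToySpec(covariances=[sigma], N=2, T=100, K=200, seed=42)
        cm = class_mean_covariances(generate(spec))
        target = sigma / np.trace(sigma)
        assert np.linalg.norm(cm.class_means[0] - target, "fro") < 0.05

    def test_empty_class_rejected(self, rng):
        es = EpochSet(
            epochs=[random_zero_mean_epoch(rng, 2, 10)], labels=[1], n_classes=2
        )
        with pytest.raises(ValueError, match="class 2"):
            class_mean_covariances(es)


class TestCspPair:
    def test_identity_pair_all_unit_eigenvalues(self):
        R = np.eye(3) / 3
        bank = solve_csp_pair(R, R, 1)
        np.testing.assert_allclose(bank.eigenvalues, [1.0, 1.0], atol=1e-10)
        for w in bank.filters:
            assert abs((w @ R @ w) / (w @ R @ w) - 1.0) < 1e-12

    def test_diagonal_closed_form(self):
        R1 = np.diag([2.0, 1.0]) / 3
        R2 = np.diag([1.0, 2.0]) / 3
        bank = solve_csp_pair(R1, R2, 1)
        np.testing.assert_allclose(sorted(bank.eigenvalues), [0.5, 2.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(bank.filters[0]), [1.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(np.abs(bank.filters[1]), [0.0, 1.0], atol=1e-10)

    def test_rayleigh_quotient_equals_eigenvalue(self, rng):
        R1, R2 = random_spd(rng, 4), random_spd(rng, 4)
        bank = solve_csp_pair(R1, R2, 2)
        for w, lam in zip(bank.filters, bank.eigenvalues):
            rq = (w @ R1 @ w) / (w @ R2 @ w)
            assert abs(rq - lam) <= 1e-8 * abs(lam)

    def test_eigenvalue_ordering_largest_block_then_smallest(self, rng):
        R1, R2 = random_spd(rng, 6), random_spd(rng, 6)
        bank = solve_csp_pair(R1, R2, 2)
        lam = bank.eigenvalues
        assert lam[0] >= lam[1]  # descending in the top block
        assert lam[2] <= lam[3]  # ascending in the bottom block
        assert min(lam[0], lam[1]) >= max(lam[2], lam[3])

    def test_max_filter_beats_random_search(self, rng):
        R1, R2 = random_spd(rng, 4), random_spd(rng, 4)
        bank = solve_csp_pair(R1, R2, 2)
        V = rng.standard_normal((10_000, 4))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        rqs = np.einsum("ij,jk,ik->i", V, R1, V) / np.einsum(
            "ij,jk,ik->i", V, R2, V
        )
        assert bank.eigenvalues[0] >= rqs.max()

    def test_filters_unit_norm(self, rng):
        bank = solve_csp_pair(random_spd(rng, 5), random_spd(rng, 5), 2)
        np.testing.assert_allclose(
            np.linalg.norm(bank.filters, axis=1), 1.0, atol=1e-12
        )

    def test_too_many_filters_rejected(self, rng):
        with pytest.raises(ValueError, match="2m"):
            solve_csp_pair(random_spd(rng, 3), random_spd(rng, 3), 2)


class TestOvrCsp:
    def test_two_class_reduction_matches_csp_top_block(self, rng):
        R1, R2 = random_spd(rng, 4), random_spd(rng, 4)
        m = 2
        pair = solve_csp_pair(R1, R2, m)
        ovr = solve_ovr_csp([R1, R2], m)
        top = pair.filters[:m]
        for w in ovr.filters[ovr.source_class == 1]:
            coeffs = np.linalg.lstsq(top.T, w, rcond=None)[0]
            assert np.linalg.norm(top.T @ coeffs - w) < 1e-6

    def test_three_class_diagonal_closed_form(self):
        means = [
            np.diag([4.0, 1.0, 1.0]) / 6,
            np.diag([1.0, 4.0, 1.0]) / 6,
            np.diag([1.0, 1.0, 4.0]) / 6,
        ]
        bank = solve_ovr_csp(means, 1)
        np.testing.assert_allclose(np.abs(bank.filters[0]), [1, 0, 0], atol=1e-10)
        np.testing.assert_allclose(np.abs(bank.filters[1]), [0, 1, 0], atol=1e-10)
        np.testing.assert_allclose(np.abs(bank.filters[2]), [0, 0, 1], atol=1e-10)

    def test_identical_covariances_warn_non_discriminative(self, rng):
        R = random_spd(rng, 3)
        with pytest.warns(UserWarning, match="non-discriminative"):
            bank = solve_ovr_csp([R, R.copy(), R.copy()], 1)
        np.testing.assert_allclose(bank.eigenvalues, 0.5, atol=1e-8)


class TestApplyFiltersAndFeatures:
    def test_single_basis_filter_picks_channel(self, rng):
        from sfnet.csp import SpatialFilterBank

        X = random_zero_mean_epoch(rng, 3, 20)
        bank = SpatialFilterBank(
            filters=np.array([[1.0, 0.0, 0.0]]), eigenvalues=np.array([1.0])
        )
        np.testing.assert_array_equal(apply_filters(bank, X), X[:1])

    def test_orthonormal_bank_preserves_frobenius_norm(self, rng):
        from sfnet.csp import SpatialFilterBank

        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        X = random_zero_mean_epoch(rng, 4, 30)
        bank = SpatialFilterBank(filters=Q, eigenvalues=np.ones(4))
        Z = apply_filters(bank, X)
        assert abs(np.linalg.norm(Z) - np.linalg.norm(X)) < 1e-10

    def test_dimension_mismatch_rejected(self, rng):
        from sfnet.csp import SpatialFilterBank

        bank = SpatialFilterBank(filters=np.ones((1, 3)), eigenvalues=np.ones(1))
        with pytest.raises(ValueError, match="channel count"):
            apply_filters(bank, np.zeros((2, 10)))

    def test_own_csp_bank_orders_class_variances(self):
        from sfnet.toydata import preset_two_class

        es = generate(preset_two_class(seed=11))
        cm = class_mean_covariances(es)
        bank = solve_csp_pair(cm.class_means[0], cm.class_means[1], 1)
        v1 = [apply_filters(bank, X)[0].var() for X in es.epochs]
        v1 = np.array(v1)
        assert v1[es.labels == 1].mean() > v1[es.labels == 2].mean()

    def test_equal_variances_give_log_half(self):
        Z = np.array([[1.0, -1.0, 1.0, -1.0], [-1.0, 1.0, -1.0, 1.0]])
        np.testing.assert_allclose(csp_features(Z), np.log(0.5), atol=1e-12)

    def test_variance_ratio_hand_case(self):
        rng = np.random.default_rng(0)
        z1 = rng.standard_normal(1000)
        Z = np.vstack([np.sqrt(3) * z1, z1])
        f = csp_features(Z)
        np.testing.assert_allclose(f, [np.log(0.75), np.log(0.25)], atol=1e-12)

    def test_zero_variance_row_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            csp_features(np.vstack([np.ones(10), np.zeros(10)]))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31), st.integers(2, 6), st.integers(5, 40))
    def test_features_exponentiate_to_unit_sum(self, seed, m, t):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((m, t))
        assert abs(np.exp(csp_features(Z)).sum() - 1.0) <= 1e-10


class TestLda:
    def test_separated_clouds_classified_perfectly(self, rng):
        x = np.concatenate([rng.normal(-3, 0.3, 50), rng.normal(3, 0.3, 50)])
        y = np.repeat([1, 2], 50)
        model = fit_lda(x[:, None], y)
        assert np.mean(predict_lda(model, x[:, None]) == y) == 1.0

    def test_null_distribution_accuracy_near_chance(self, rng):
        X = rng.standard_normal((400, 3))
        y = rng.integers(1, 3, 400)
        model = fit_lda(X, y)
        acc = np.mean(predict_lda(model, X) == y)
        # binomial 95% band around 0.5 at n=400 is about +-0.05; allow slack
        assert 0.4 < acc < 0.65

    def test_threshold_sits_between_separated_values(self):
        X = np.array([[0.0]] * 5 + [[1.0]] * 5)
        y = np.repeat([1, 2], 5)
        X = X + np.linspace(-0.01, 0.01, 10)[:, None]  # avoid zero scatter
        model = fit_lda(X, y)
        assert predict_lda(model, [[-0.2]])[0] == 1
        assert predict_lda(model, [[1.2]])[0] == 2

    def test_agrees_with_sklearn_reference(self, rng):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        X = rng.standard_normal((120, 4))
        y = rng.integers(1, 4, 120)
        X[y == 2] += 1.5
        X[y == 3] -= 1.5
        ours = predict_lda(fit_lda(X, y), X)
        ref = sklearn_da.LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        assert np.mean(ours == ref.predict(X)) > 0.97

    def test_tiny_class_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="two epochs"):
            fit_lda(X, np.array([1, 1, 2]))


def test_full_pipeline_scale_invariance():
    """Multiplying all epochs by a constant changes no filter or feature."""
    from sfnet.toydata import preset_two_class

    es = generate(preset_two_class(seed=5))
    es_scaled = EpochSet(
        epochs=[13.7 * X for X in es.epochs],
        labels=es.labels,
        n_classes=es.n_classes,
    )
    for data in (es, es_scaled):
        cm = class_mean_covariances(data)
        bank = solve_csp_pair(cm.class_means[0], cm.class_means[1], 1)
        feats = np.array(
            [csp_features(apply_filters(bank, X)) for X in data.epochs]
        )
        if data is es:
            ref_bank, ref_feats = bank, feats
    np.testing.assert_allclose(bank.filters, ref_bank.filters, atol=1e-9)
    np.testing.assert_allclose(feats, ref_feats, atol=1e-9)
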
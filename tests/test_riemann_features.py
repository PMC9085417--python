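"""xDAWN, SPD covariances, Karcher mean, tangent space, PCA chain."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, strategies as st

from ernbci import riemann_features as rf
from ernbci.io_core import ValidationError


def _toy_epochs(rng, n_ep=40, n_ch=12, T=125, evoked_channel=7, amp=5.0):
    evoked = np.zeros((n_ch, T))
    evoked[evoked_channel] = amp * np.sin(np.linspace(0, 3 * np.pi, T))
    eps = rng.standard_normal((n_ep, n_ch, T))
    labels = np.array(["A"] * (n_ep // 2) + ["B"] * (n_ep // 2))
    eps[labels == "A"] += evoked
    return eps, labels, evoked


class TestXdawn:
    def test_recovers_single_channel_evoked_source(self, rng):
        eps, labels, _ = _toy_epochs(rng)
        filters, _ = rf.fit_xdawn(eps, labels, "A")
        e7 = np.zeros(12)
        e7[7] = 1.0
        assert abs(filters[0] @ e7) > 0.99

    def test_matches_generalized_eigendecomposition_oracle(self, rng):
        eps, labels, _ = _toy_epochs(rng, n_ch=3, T=200, evoked_channel=1)
        filters, eigvals = rf.fit_xdawn(eps, labels, "A", n_filters=3)
        evoked = eps[labels == "A"].mean(axis=0)
        s_e = evoked @ evoked.T / evoked.shape[1]
        x = np.concatenate(list(eps), axis=1)
        s_x = x @ x.T / x.shape[1]
        s_x += 1e-9 * np.trace(s_x) / 3 * np.eye(3)
        w = filters[0]
        quotient = (w @ s_e @ w) / (w @ s_x @ w)
        oracle = scipy.linalg.eigh(s_e, s_x, eigvals_only=True)[-1]
        assert abs(quotient - oracle) < 1e-8

    def test_bank_of_five_ordered_filters_per_class(self, rng):
        eps, labels, _ = _toy_epochs(rng, n_ch=32)
        bank = rf.fit_filter_bank(eps, labels, ("A", "B"), n_filters=5)
        for cls in ("A", "B"):
            assert bank.filters[cls].shape == (5, 32)
            assert np.all(np.diff(bank.eigenvalues[cls]) <= 1e-12)
            np.testing.assert_allclose(
                np.linalg.norm(bank.filters[cls], axis=1), 1.0)

    def test_needs_two_epochs_of_target(self, rng):
        eps = rng.normal(size=(3, 4, 50))
        with pytest.raises(ValidationError):
            rf.fit_xdawn(eps, np.array(["A", "B", "B"]), "A")


class TestProjectAugment:
    def test_identity_filters_return_the_data(self, rng):
        data = rng.normal(size=(10, 60))
        bank = rf.SpatialFilterBank(
            {"A": np.eye(10)[:5], "B": np.eye(10)[5:]},
            {"A": np.zeros(5), "B": np.zeros(5)}, ("A", "B"))
        np.testing.assert_allclose(rf.project(data, bank), data)

    def test_zero_epoch_projects_to_zero(self, rng):
        eps, labels, _ = _toy_epochs(rng)
        bank = rf.fit_filter_bank(eps, labels, ("A", "B"))
        assert not rf.project(np.zeros((12, 125)), bank).any()

    def test_augment_shape_and_prototype_rows(self, rng):
        proto = rng.normal(size=(10, 125))
        ep = rng.normal(size=(10, 125))
        aug = rf.augment(ep, proto)
        assert aug.shape == (20, 125)
        np.testing.assert_array_equal(aug[:10], proto)

    def test_augment_length_mismatch(self, rng):
        with pytest.raises(ValidationError):
            rf.augment(rng.normal(size=(10, 100)),
                       rng.normal(size=(10, 125)))


class TestCovariance:
    def test_white_noise_converges_to_identity(self, rng):
        x = rng.standard_normal((20, 100000))
        cov = rf.covariance(x)
        assert np.linalg.norm(cov - np.eye(20), "fro") < 0.05

    def test_duplicated_rows_still_spd(self, rng):
        x = rng.standard_normal((10, 125))
        aug = np.vstack([x, x])               # rank-deficient by construction
        cov = rf.covariance(aug)
        assert cov.shape == (20, 20)
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_batch_equals_reference(self, rng):
        aug = rng.standard_normal((5, 20, 125))
        batch = rf._batch_covariance(aug)
        ref = np.stack([rf.covariance(a) for a in aug])
        np.testing.assert_allclose(batch, ref, atol=1e-12)

    def test_non_finite_rejected(self):
        x = np.zeros((4, 50))
        x[1, 3] = np.inf
        with pytest.raises(ValidationError):
            rf.covariance(x)


def _random_spd(rng, dim=4, scale=1.0):
    a = rng.standard_normal((dim, dim))
    return a @ a.T + scale * np.eye(dim)


class TestRiemannianMean:
    def test_single_matrix_is_its_own_mean(self, rng):
        s = _random_spd(rng)
        np.testing.assert_allclose(rf.riemannian_mean([s]), s)

    def test_commuting_matrices_geometric_mean(self):
        a = np.diag([1.0, 4.0])
        b = np.diag([4.0, 9.0])
        m = rf.riemannian_mean([a, b])
        np.testing.assert_allclose(m, np.diag([2.0, 6.0]), atol=1e-8)

    def test_congruence_equivariance(self, rng):
        mats = [_random_spd(rng) for _ in range(4)]
        a = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        lhs = rf.riemannian_mean([a.T @ s @ a for s in mats])
        rhs = a.T @ rf.riemannian_mean(mats) @ a
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_non_spd_rejected(self, rng):
        with pytest.raises(ValidationError):
            rf.riemannian_mean([np.diag([1.0, -1.0])])

    def test_batch_equals_reference(self, rng):
        mats = np.stack([_random_spd(rng) for _ in range(6)])
        np.testing.assert_allclose(rf._batch_riemannian_mean(mats),
                                   rf.riemannian_mean(list(mats)), atol=1e-10)


class TestTangentSpace:
    def test_reference_maps_to_zero(self, rng):
        s = _random_spd(rng)
        assert np.allclose(rf.tangent_map(s, s), 0.0, atol=1e-10)

    def test_diagonal_log_example(self):
        v = rf.tangent_map(np.diag([np.e ** 2, np.e]), np.eye(2))
        np.testing.assert_allclose(v, [2.0, 0.0, 1.0], atol=1e-12)

    def test_dimension_is_210_for_20x20(self, rng):
        s = _random_spd(rng, dim=20)
        r = _random_spd(rng, dim=20)
        assert rf.tangent_map(s, r).shape == (210,)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_norm_equals_affine_invariant_distance(self, seed):
        rng = np.random.default_rng(seed)
        s, r = _random_spd(rng), _random_spd(rng)
        assert abs(np.linalg.norm(rf.tangent_map(s, r))
                   - rf.riemannian_distance(s, r)) < 1e-8


class TestNormalizationPca:
    def test_l1_example(self):
        np.testing.assert_allclose(rf.l1_normalize([2.0, -2.0]), [0.5, -0.5])

    def test_l1_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            rf.l1_normalize(np.zeros(4))

    def test_pca_recovers_subspace_dimension(self, rng):
        basis = rng.normal(size=(3, 30))
        data = rng.normal(size=(200, 3)) @ basis
        data += 1e-6 * rng.normal(size=data.shape)
        pca = rf.fit_pca(data, retain=0.99)
        assert pca.n_components_ == 3

    def test_retained_variance_at_least_99pct(self, rng):
        data = rng.normal(size=(100, 40)) * np.linspace(5, 0.1, 40)
        pca = rf.fit_pca(data, retain=0.99)
        assert pca.explained_variance_ratio_.sum() >= 0.99


class TestFeatureChain:
    def test_deterministic_given_data(self, rng):
        eps, labels, _ = _toy_epochs(rng, n_ep=20)
        x1 = rf.FeatureChain(classes=("A", "B")).fit_transform(eps, labels)
        x2 = rf.FeatureChain(classes=("A", "B")).fit_transform(eps, labels)
        np.testing.assert_array_equal(x1, x2)

    def test_transform_requires_fit(self, rng):
        with pytest.raises(ValidationError):
            rf.FeatureChain().transform(rng.normal(size=(2, 4, 50)))

    def test_prototype_rows_constant_across_epochs(self, rng):
        eps, labels, _ = _toy_epochs(rng, n_ep=20)
        chain = rf.FeatureChain(classes=("A", "B")).fit(eps, labels)
        assert chain.prototypes.shape == (10, 125)
        for ep in eps[:3]:
            aug = rf.augment(rf.project(ep, chain.bank), chain.prototypes)
            assert aug.shape == (20, 125)
            np.testing.assert_array_equal(aug[:10], chain.prototypes)
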
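"""Hyperbolic MLR head: rewrite equivalence, logits, loss, RSGD."""

import numpy as np
import pytest

from hyperseg import geometry as geo
from hyperseg import head as H
from hyperseg.nn import Tensor

from test_geometry import random_ball_points


def dense_gyroplane_distance(z, p, a, c):
    """Verbatim oracle: materialize the Mobius sum, then apply the
    signed-distance formula."""
    w = geo.mobius_add(p, z, c, project=False)
    inner = (w * a).sum(-1)
    denom = 1.0 - c * (w * w).sum(-1)
    na = np.linalg.norm(a, axis=-1)
    return np.arcsinh(2 * np.sqrt(c) * inner / (denom * na)) / np.sqrt(c)


class TestRewrite:
    def test_flat_coefficients_are_one(self, rng):
        p = rng.normal(size=(4, 3))
        z = rng.normal(size=(4, 3))
        A, B = H.rewrite_coefficients(p, z, 0.0)
        assert np.all(A == 1.0) and np.all(B == 1.0)

    def test_zero_z_identity_consistency(self, rng):
        p = random_ball_points(rng, 6, 4, 1.0)
        z = np.zeros_like(p)
        A, B = H.rewrite_coefficients(p, z, 1.0)
        recon = A[..., None] * p + B[..., None] * z
        assert np.abs(recon - geo.mobius_add(p, z, 1.0)).max() < 1e-12

    @pytest.mark.parametrize("c", (0.2, 1.0, 5.0))
    def test_reconstructs_mobius_add(self, c):
        rng = np.random.default_rng(int(c * 10))
        p = random_ball_points(rng, 300, 8, c)
        z = random_ball_points(rng, 300, 8, c)
        A, B = H.rewrite_coefficients(p, z, c)
        recon = A[..., None] * p + B[..., None] * z
        direct = geo.mobius_add(p, z, c, project=False)
        rel = np.abs(recon - direct).max() / max(np.abs(direct).max(), 1e-12)
        assert rel < 1e-6

    @pytest.mark.parametrize("c", (0.2, 1.0, 5.0))
    def test_gyro_inner_matches_oracle(self, c):
        rng = np.random.default_rng(int(10 * c) + 1)
        p = random_ball_points(rng, 1000, 6, c)
        z = random_ball_points(rng, 1000, 6, c)
        a = rng.normal(size=(1000, 6))
        got = H.gyro_inner(p, z, a, c)
        want = (geo.mobius_add(p, z, c, project=False) * a).sum(-1)
        rel = np.abs(got - want).max() / np.abs(want).max()
        assert rel < 1e-5

    def test_gyro_inner_zero_normal(self, rng):
        p = random_ball_points(rng, 5, 4, 1.0)
        z = random_ball_points(rng, 5, 4, 1.0)
        assert np.all(H.gyro_inner(p, z, np.zeros_like(p), 1.0) == 0.0)

    @pytest.mark.parametrize("c", (0.2, 1.0, 5.0))
    def test_gyro_sq_norm_matches_oracle(self, c):
        rng = np.random.default_rng(int(10 * c) + 2)
        p = random_ball_points(rng, 1000, 6, c)
        z = random_ball_points(rng, 1000, 6, c)
        got = H.gyro_sq_norm(p, z, c)
        want = (geo.mobius_add(p, z, c, project=False) ** 2).sum(-1)
        assert np.abs(got - want).max() / np.abs(want).max() < 1e-5

    def test_gyro_sq_norm_inverse_pair(self, rng):
        p = random_ball_points(rng, 50, 4, 1.0)
        assert np.abs(H.gyro_sq_norm(p, -p, 1.0)).max() < 1e-9

    def test_gyro_sq_norm_zero_z(self, rng):
        p = random_ball_points(rng, 10, 4, 1.0)
        got = H.gyro_sq_norm(p, np.zeros_like(p), 1.0)
        assert np.abs(got - (p * p).sum(-1)).max() < 1e-12


class TestGyroplaneDistance:
    def test_point_on_plane_is_zero(self, rng):
        c = 1.0
        p = random_ball_points(rng, 1, 4, c)[0]
        z = random_ball_points(rng, 1, 4, c)[0]
        w = geo.mobius_add(p, z, c, project=False)
        # construct a normal orthogonal to the Mobius sum
        a = rng.normal(size=4)
        a -= (a @ w) / (w @ w) * w
        assert abs(H.gyroplane_distance(z, p, a, c)) < 1e-9

    def test_normal_scale_invariance_and_sign(self, rng):
        c = 0.5
        p = random_ball_points(rng, 20, 5, c)
        z = random_ball_points(rng, 20, 5, c)
        a = rng.normal(size=(20, 5))
        d = H.gyroplane_distance(z, p, a, c)
        assert np.abs(H.gyroplane_distance(z, p, 7.3 * a, c) - d).max() < 1e-9
        assert np.abs(H.gyroplane_distance(z, p, -a, c) + d).max() < 1e-12

    def test_matches_dense_oracle(self, rng):
        c = 1.0
        p = random_ball_points(rng, 500, 8, c)
        z = random_ball_points(rng, 500, 8, c)
        a = rng.normal(size=(500, 8))
        got = H.gyroplane_distance(z, p, a, c)
        want = dense_gyroplane_distance(z, p, a, c)
        assert np.abs(got - want).max() / np.abs(want).max() < 1e-5

    def test_flat_curvature_raises(self, rng):
        with pytest.raises(ValueError):
            H.gyroplane_distance(np.zeros(3), np.zeros(3),
                                 np.ones(3), 0.0)

    def test_zero_normal_raises(self, rng):
        z = random_ball_points(rng, 1, 3, 1.0)[0]
        with pytest.raises(ValueError):
            H.gyroplane_distance(z, np.zeros(3), np.zeros(3), 1.0)


def make_bank(c, dim=8, classes=5, seed=5, **kw):
    return H.GyroplaneBank(classes, dim, c, np.random.default_rng(seed), **kw)


class TestLogits:
    def test_euclidean_limit(self, rng):
        bank = make_bank(1e-9)
        bank.offsets.data = rng.normal(0, 0.05, bank.offsets.data.shape)
        f = rng.normal(0, 0.3, (40, 8))
        got = H.hyperbolic_logits(f, bank)
        z = f  # exp_map0 is ~identity at this curvature and scale
        want = 4 * (z @ bank.normals.data.T -
                    (bank.offsets.data * bank.normals.data).sum(-1))
        assert np.abs(got - want).max() / np.abs(want).max() < 1e-4

    def test_flat_branch_equals_affine_classifier(self, rng):
        bank = make_bank(0.0)
        bank.offsets.data = rng.normal(0, 0.3, bank.offsets.data.shape)
        f = rng.normal(0, 1.0, (7, 3, 8))
        got = H.hyperbolic_logits(f, bank)
        want = 4 * (f @ bank.normals.data.T -
                    (bank.offsets.data * bank.normals.data).sum(-1))
        assert np.all(got == want)

    def test_antisymmetric_pair(self, rng):
        bank = make_bank(1.0, classes=2)
        bank.offsets.data[1] = bank.offsets.data[0]
        bank.normals.data[1] = -bank.normals.data[0]
        f = rng.normal(0, 0.4, (30, 8))
        logits = H.hyperbolic_logits(f, bank)
        assert np.all(logits[:, 0] == -logits[:, 1])

    def test_curvature_continuity_at_zero(self, rng):
        f = rng.uniform(-1, 1, (100, 8))
        bank0 = make_bank(0.0)
        bank_eps = make_bank(1e-6)
        bank_eps.offsets.data = bank0.offsets.data.copy()
        bank_eps.normals.data = bank0.normals.data.copy()
        gap = np.abs(H.hyperbolic_logits(f, bank0) -
                     H.hyperbolic_logits(f, bank_eps)).max()
        assert gap <= 1e-3

    def test_memory_rewrite_never_allocates_pair_by_dim(self, rng):
        bank = make_bank(1.0, dim=16, classes=7)
        f = rng.normal(0, 0.3, (50, 16))
        log = []
        H.hyperbolic_logits(f, bank, shape_log=log)
        assert log, "shape log must record per-pair intermediates"
        for shape in log:
            assert len(shape) <= 2
            assert shape not in {(50, 7, 16)}, "materialized Mobius sum"


class TestLoss:
    def test_uniform_logits_give_log_c(self, rng):
        logits = np.zeros((4, 4, 6))
        labels = rng.integers(0, 6, (4, 4))
        assert H.segmentation_loss(logits, labels) == \
            pytest.approx(np.log(6), abs=1e-12)

    def test_confident_correct_goes_to_zero(self, rng):
        labels = rng.integers(0, 3, (5, 5))
        logits = np.full((5, 5, 3), -50.0)
        for i in range(5):
            for j in range(5):
                logits[i, j, labels[i, j]] = 50.0
        assert H.segmentation_loss(logits, labels) < 1e-8

    def test_hand_example(self):
        logits = np.array([[[2.0, 0.0], [0.0, 1.0]],
                           [[1.0, 1.0], [3.0, -1.0]]])
        labels = np.array([[0, 1], [0, 1]])
        # independent scalar softmax-CE
        want = np.mean([
            -np.log(np.exp(2) / (np.exp(2) + 1)),
            -np.log(np.exp(1) / (np.exp(1) + 1)),
            -np.log(0.5),
            -np.log(np.exp(-1) / (np.exp(3) + np.exp(-1)))])
        assert H.segmentation_loss(logits, labels) == pytest.approx(want, abs=1e-12)

    def test_ignore_index(self):
        logits = np.zeros((2, 2, 3))
        labels = np.array([[0, 255], [255, 255]])
        assert H.segmentation_loss(logits, labels) == \
            pytest.approx(np.log(3))
        with pytest.raises(ValueError):
            H.segmentation_loss(logits, np.full((2, 2), 255))

    def test_tensor_path_matches_numpy(self, rng):
        logits = rng.normal(size=(3, 4, 5))
        labels = rng.integers(0, 5, (3, 4))
        t = H.segmentation_loss(Tensor(logits, requires_grad=True), labels)
        assert float(t.data) == pytest.approx(
            H.segmentation_loss(logits, labels), abs=1e-12)


class TestRSGD:
    def test_zero_gradient_no_change(self):
        bank = make_bank(1.0)
        before = {k: v.copy() for k, v in bank.state_dict().items()}
        H.rsgd_step(bank, lr=0.1)
        after = bank.state_dict()
        assert all(np.all(before[k] == after[k]) for k in before)

    def test_flat_branch_metric_factor_four(self):
        bank = make_bank(0.0, dim=3, classes=2)
        g = np.ones_like(bank.offsets.data)
        bank.offsets.grad = g.copy()
        p0 = bank.offsets.data.copy()
        H.rsgd_step(bank, lr=0.4)
        assert np.allclose(bank.offsets.data, p0 - 0.4 * g / 4.0)

    def test_scalar_oracle_curved(self):
        bank = make_bank(1.0, dim=1, classes=2)
        bank.offsets.data[:] = [[0.3], [0.0]]
        bank.offsets.grad = np.array([[2.0], [0.0]])
        H.rsgd_step(bank, lr=0.1)
        lam = 2.0 / (1.0 - 0.09)
        v = -0.1 * 2.0 / lam ** 2
        second = np.tanh(lam * abs(v) / 2) * np.sign(v)
        want = (0.3 + second) / (1 + 0.3 * second)
        assert bank.offsets.data[0, 0] == pytest.approx(want, abs=1e-12)
        assert bank.offsets.data[1, 0] == 0.0

    def test_nonfinite_gradient_skipped_with_warning(self):
        bank = make_bank(1.0)
        bank.offsets.grad = np.full_like(bank.offsets.data, np.nan)
        p0 = bank.offsets.data.copy()
        with pytest.warns(RuntimeWarning):
            H.rsgd_step(bank, lr=0.1)
        assert np.all(bank.offsets.data == p0)

    def test_offsets_stay_contained(self):
        bank = make_bank(1.0, dim=2, classes=2)
        for _ in range(50):
            bank.offsets.grad = np.full_like(bank.offsets.data, -100.0)
            H.rsgd_step(bank, lr=1.0)
        assert np.linalg.norm(bank.offsets.data, axis=-1).max() <= 1.0 - 1e-3


class TestSeparableRecovery:
    def test_head_learns_wrapped_clusters(self):
        """RSGD on the bank alone separates two wrapped Gaussian clusters."""
        rng = np.random.default_rng(123)
        mu = np.zeros(8)
        mu[0] = 1.2
        f = np.concatenate([rng.normal(+mu, 0.25, (300, 8)),
                            rng.normal(-mu, 0.25, (300, 8))])
        labels = np.repeat([0, 1], 300)
        bank = make_bank(1.0, dim=8, classes=2, seed=9)
        opt = H.RiemannianSGD(bank)
        for _ in range(200):
            logits = H.hyperbolic_logits(Tensor(f), bank)
            loss = H.segmentation_loss(logits, labels)
            bank.zero_grad()
            loss.backward()
            opt.step(0.5)
        pred = H.hyperbolic_logits(f, bank).argmax(-1)
        assert (pred == labels).mean() >= 0.95
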
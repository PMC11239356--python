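"""GAN surface: range mapping, architecture shapes, loss oracles,
schedule handling, and seeded training reproducibility."""

import numpy as np
import pytest

from stainlab import gan
from stainlab.gan import Pix2PixTranslator


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        x = np.array([0.0, 0.5, 1.0])
        assert np.allclose(gan.normalize_input(x), [-0.5, 0.0, 0.5])

    def test_inverse_round_trip(self):
        x = np.random.default_rng(0).uniform(0, 1, (4, 8, 8, 3))
        assert np.allclose(gan.rescale_output(gan.normalize_input(x)), x)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gan.normalize_input(np.array([1.5]))


class TestArchitectures:
    def test_scaled_discriminator_score_map_6x6(self):
        d = gan.build_discriminator(64, 8, seed=0, dtype=np.float32)
        out = d.forward(np.zeros((2, 6, 64, 64), np.float32))
        assert out.shape == (2, 1, 6, 6)

    def test_generator_output_shape_and_range(self):
        g = gan.build_generator(64, 8, seed=0, dtype=np.float32)
        x = np.random.default_rng(1).uniform(-0.5, 0.5, (2, 3, 64, 64)).astype(np.float32)
        y = g.forward(x)
        assert y.shape == x.shape
        assert y.min() > -0.5 and y.max() < 0.5

    def test_generator_requires_power_of_two(self):
        with pytest.raises(ValueError):
            gan.build_generator(100, 8)

    def test_unet_backward_shape(self):
        g = gan.build_generator(32, 4, seed=2)
        x = np.random.default_rng(2).normal(size=(2, 3, 32, 32))
        y = g.forward(x)
        dx = g.backward(np.ones_like(y))
        assert dx.shape == x.shape


class TestLosses:
    def test_l1_examples(self):
        a = np.zeros((4, 4))
        assert gan.loss_l1(a, a) == 0.0
        assert gan.loss_l1(np.full((4, 4), 0.5), a) == pytest.approx(0.5)

    def test_l1_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        total = sum(abs(a[i, j] - b[i, j]) for i in range(6) for j in range(6))
        assert gan.loss_l1(a, b) == pytest.approx(total / 36, abs=1e-12)

    def test_iou_identical_and_disjoint(self):
        a = np.zeros((8, 8))
        a[:4] = 1
        b = np.zeros((8, 8))
        b[4:] = 1
        assert gan.loss_iou(a, a) == pytest.approx(0.0, abs=1e-5)
        assert gan.loss_iou(a, b) == pytest.approx(1.0, abs=1e-5)

    def test_iou_set_counting(self):
        a = np.zeros(8)
        b = np.zeros(8)
        a[[0, 1]] = 1
        b[[1, 2]] = 1  # areas 2 and 2, intersection 1, union 3
        assert gan.loss_iou(a, b) == pytest.approx(2.0 / 3.0, abs=1e-5)

    def test_iou_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((5, 5)), rng.random((5, 5))
        assert gan.loss_iou(a, b) == pytest.approx(gan.loss_iou(b, a))
        assert 0.0 <= gan.loss_iou(a, b) <= 1.0

    def test_iou_rejects_negative(self):
        with pytest.raises(ValueError):
            gan.loss_iou(np.array([-0.1]), np.array([0.5]))

    def test_bce_uniform_half_is_ln2(self):
        s = np.full((30, 30), 0.5)
        assert gan.loss_adversarial(s, "ones") == pytest.approx(np.log(2), abs=1e-6)
        assert gan.loss_adversarial(s, "zeros") == pytest.approx(np.log(2), abs=1e-6)

    def test_bce_limit_toward_zero_loss(self):
        s = np.full((4, 4), 1 - 1e-9)
        assert gan.loss_adversarial(s, "ones") < 1e-6

    def test_bce_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0.05, 0.95, (6, 6))
        oracle = -sum(np.log(s[i, j]) for i in range(6) for j in range(6)) / 36
        assert gan.loss_adversarial(s, "ones") == pytest.approx(oracle, abs=1e-10)

    def test_bce_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            gan.loss_adversarial(np.array([0.0, 0.5]), "ones")

    def test_iou_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(6)
        a, b = rng.uniform(0.1, 0.9, (4, 4)), rng.uniform(0.1, 0.9, (4, 4))
        g = gan._iou_grad(a, b)
        eps = 1e-7
        for i in range(4):
            for j in range(4):
                a[i, j] += eps
                up = gan.loss_iou(a, b)
                a[i, j] -= 2 * eps
                dn = gan.loss_iou(a, b)
                a[i, j] += eps
                assert (up - dn) / (2 * eps) == pytest.approx(g[i, j], abs=1e-6)


class TestSchedule:
    def test_paper_schedule_values(self):
        sched = ((300, 100.0), (150, 250.0))
        assert gan._schedule_lambda(sched, 1) == 100.0
        assert gan._schedule_lambda(sched, 300) == 100.0
        assert gan._schedule_lambda(sched, 301) == 250.0
        assert gan._schedule_lambda(sched, 450) == 250.0


def _tiny_data(n=12, size=32, seed=0):
    rng = np.random.default_rng(seed)
    Y = rng.uniform(0, 1, (n, size, size, 3))
    X = Y.copy()
    X[..., 0] = 0.0
    return X, Y


class TestTraining:
    def test_smoke_run_reports_finite_losses(self):
        X, Y = _tiny_data()
        b = gan.build_gan(32, 4, 4, seed=0, dtype=np.float32)
        b, hist = gan.train(b, X, Y, schedule=((2, 100.0),), batch_size=6)
        assert len(hist) == 2
        for h in hist:
            assert all(np.isfinite([h.loss1, h.loss2, h.loss3, h.loss4]))
            assert h.loss1 >= 0 and h.loss2 >= 0

    def test_objective_composition(self):
        X, Y = _tiny_data()
        b = gan.build_gan(32, 4, 4, seed=0, dtype=np.float32)
        _, hist = gan.train(b, X, Y, schedule=((2, 100.0),), batch_size=6)
        for h in hist:
            assert h.gen_total == pytest.approx(h.loss3 + 100.0 * h.loss1 + h.lambda_iou * h.loss2)

    def test_batch_clamp_warning(self):
        X, Y = _tiny_data(n=4)
        b = gan.build_gan(32, 4, 4, seed=0, dtype=np.float32)
        with pytest.warns(UserWarning, match="clamp"):
            gan.train(b, X, Y, schedule=((1, 100.0),), batch_size=350)

    def test_seeded_training_reproducible(self):
        X, Y = _tiny_data()
        hists = []
        for _ in range(2):
            b = gan.build_gan(32, 4, 4, seed=3, dtype=np.float64)
            _, h = gan.train(
                b, X, Y, schedule=((2, 100.0),), batch_size=6, rng=np.random.default_rng(3)
            )
            hists.append([(r.loss1, r.loss2, r.loss3, r.loss4) for r in h])
        assert hists[0] == hists[1]

    def test_l1_decreases_with_training(self):
        """The generator learns: final-epoch L1 below first-epoch L1 on a
        structured toy task (R channel = shifted copy of G channel)."""
        rng = np.random.default_rng(7)
        Y = rng.uniform(0, 1, (30, 32, 32, 3))
        Y[..., 0] = Y[..., 1]
        X = Y.copy()
        X[..., 0] = 0.0
        b = gan.build_gan(32, 8, 8, seed=1, dtype=np.float32)
        _, hist = gan.train(b, X, Y, schedule=((15, 100.0),), batch_size=10)
        assert hist[-1].loss1 < hist[0].loss1

    def test_infer_deterministic_and_bounded(self):
        X, Y = _tiny_data()
        b = gan.build_gan(32, 4, 4, seed=0, dtype=np.float32)
        out1 = gan.infer(b, X)
        out2 = gan.infer(b, X)
        assert np.array_equal(out1, out2)
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        assert out1.shape == X.shape

    def test_infer_warns_on_nonzero_red(self):
        X, Y = _tiny_data()
        b = gan.build_gan(32, 4, 4, seed=0, dtype=np.float32)
        with pytest.warns(UserWarning, match="R channel"):
            gan.infer(b, Y)


class TestEstimator:
    def test_sklearn_get_set_params(self):
        est = Pix2PixTranslator(patch_size=16, gen_filters=4)
        params = est.get_params()
        assert params["patch_size"] == 16
        est.set_params(gen_filters=8)
        assert est.gen_filters == 8

    def test_fit_predict_contract(self):
        X, Y = _tiny_data()
        est = Pix2PixTranslator(
            patch_size=32, gen_filters=4, disc_filters=4, schedule=((2, 100.0),), batch_size=6
        )
        est.fit(X, Y)
        assert est.n_epochs_ == 2 and len(est.history_) == 2
        pred = est.predict(X)
        assert pred.shape == X.shape

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            Pix2PixTranslator(patch_size=16).predict(np.zeros((1, 16, 16, 3)))

    def test_shape_validation(self):
        est = Pix2PixTranslator(patch_size=16)
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 8, 8, 3)), np.zeros((2, 8, 8, 3)))


class TestSaveLoad:
    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        X, Y = _tiny_data()
        est = Pix2PixTranslator(
            patch_size=32, gen_filters=4, disc_filters=4, schedule=((1, 100.0),), batch_size=6
        ).fit(X, Y)
        pred = est.predict(X)
        est.save(tmp_path / "m")
        back = Pix2PixTranslator.load(tmp_path / "m")
        assert back.n_epochs_ == est.n_epochs_
        assert np.allclose(back.predict(X), pred)
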
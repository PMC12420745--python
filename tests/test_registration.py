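"""Quadrature, loss contracts, and small end-to-end fits."""

import numpy as np
import pytest

import nodereg as nr
from nodereg import fixtures as fx
from nodereg.fields import smoothed


class TestQuadrature:
    def test_single_element_weights_sum_to_measure(self):
        q = nr.build_quadrature([(0, 1), (0, 1)], (1, 1), 2)
        assert q.flat_points().shape == (4, 2)
        assert q.flat_weights().sum() == pytest.approx(1.0, abs=1e-10)

    def test_domain_measure_200x200(self):
        q = nr.build_quadrature([(-1, 1), (-1, 1)], (200, 200), 2)
        assert q.flat_weights().sum() == pytest.approx(4.0, abs=1e-9)

    def test_cubic_exactness(self):
        q = nr.build_quadrature([(0, 1)], (1,), 2)
        x, w = q.flat_points()[:, 0], q.flat_weights()
        assert (w * x ** 2).sum() == pytest.approx(1 / 3, abs=1e-14)
        assert (w * x ** 3).sum() == pytest.approx(1 / 4, abs=1e-14)

    def test_points_inside_domain(self):
        q = nr.build_quadrature([(-2, 3), (0, 1)], (7, 5), 2)
        p = q.flat_points()
        assert p[:, 0].min() > -2 and p[:, 0].max() < 3
        assert p[:, 1].min() > 0 and p[:, 1].max() < 1

    def test_invalid_elements_rejected(self):
        with pytest.raises(ValueError):
            nr.build_quadrature([(0, 1)], (0,), 2)


class TestPredictorLoss:
    @pytest.fixture()
    def setup(self, disc_field):
        q = nr.build_quadrature([(-1, 1), (-1, 1)], (30, 30), 2)
        net = nr.VelocityNetwork.create(2, (10, 10, 10),
                                        np.random.default_rng(0))
        return disc_field, q, nr.FlowMap(net)

    def test_identical_images_identity_map_zero_loss(self, setup):
        f, q, fm = setup
        cfg = nr.PredictorConfig(beta=1 / 6000)
        out = nr.predictor_loss(fm, f, f, q.flat_points(),
                                q.flat_weights(), cfg)
        assert out["mismatch"] == pytest.approx(0.0, abs=1e-12)
        assert out["reg"] == pytest.approx(0.0, abs=1e-12)

    def test_beta_zero_total_equals_mismatch(self, setup, disc_field):
        f, q, fm = setup
        shifted = fx.make_pair(fx.ShapeSpec.disc(0.5),
                               fx.translation([0.3, 0.0]), resolution=101,
                               frame=[(-1, 1), (-1, 1)])["S2"]
        cfg = nr.PredictorConfig(beta=0.0)
        out = nr.predictor_loss(fm, f, shifted, q.flat_points(),
                                q.flat_weights(), cfg)
        assert out["total"] == out["mismatch"] > 0

    def test_disjoint_indicators_mismatch_is_two_areas(self):
        # two disjoint unit squares: every body point of either image
        # mismatches, so the integral is the sum of both areas
        n = 121
        ax = np.linspace(-1.5, 1.5, n)
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        sq1 = ((X > -1.2) & (X < -0.2) & (np.abs(Y) < 0.5)).astype(float)
        sq2 = ((X > 0.2) & (X < 1.2) & (np.abs(Y) < 0.5)).astype(float)
        sp = (ax[1] - ax[0],) * 2
        f1 = nr.build_field(sq1, (-1.5, -1.5), sp, 0.5)
        f2 = nr.build_field(sq2, (-1.5, -1.5), sp, 0.5)
        q = nr.build_quadrature([(-1.5, 1.5), (-1.5, 1.5)], (150, 150), 2)
        fm = nr.FlowMap(nr.VelocityNetwork.create(
            2, (8, 8, 8), np.random.default_rng(0)))
        out = nr.predictor_loss(fm, f1, f2, q.flat_points(),
                                q.flat_weights(), nr.PredictorConfig(beta=0))
        # nominal value 2 x unit-square area, up to one-pixel edge ramps
        assert out["mismatch"] == pytest.approx(2.0, rel=0.08)
        # exhaustive fine-grid Riemann oracle on the same fields
        gx = np.linspace(-1.5, 1.5, 901)
        cell = (gx[1] - gx[0]) ** 2
        centers = np.stack(np.meshgrid(
            (gx[:-1] + gx[1:]) / 2, (gx[:-1] + gx[1:]) / 2,
            indexing="ij"), axis=-1).reshape(-1, 2)
        brute = cell * ((nr.sample(f1, centers)
                         - nr.sample(f2, centers)) ** 2).sum()
        assert out["mismatch"] == pytest.approx(brute, rel=0.01)


class TestSmallFits:
    @pytest.fixture(scope="class")
    def translation_fit(self):
        pair = fx.disc_translation(resolution=96, shift=(0.2, 0.0))
        S1s, S2s = smoothed(pair["S1"], 1.0), smoothed(pair["S2"], 1.0)
        quad = nr.build_quadrature(pair["frame"], (48, 48), 2)
        cfg = nr.PredictorConfig(beta=1 / 6000, epochs=500,
                                 batch_elements=400, learning_rate=1e-3,
                                 seed=3, hidden=(20, 20, 20),
                                 eval_elements=400, eval_every=100)
        res = nr.fit_predictor(S1s, S2s, quad, cfg)
        return pair, quad, res

    def test_self_registration_is_near_perfect(self, disc_field):
        quad = nr.build_quadrature([(-1, 1), (-1, 1)], (40, 40), 2)
        cfg = nr.PredictorConfig(beta=1 / 6000, epochs=60,
                                 batch_elements=300, learning_rate=3e-4,
                                 seed=1, hidden=(16, 16, 16), eval_every=30)
        res = nr.fit_predictor(disc_field, disc_field, quad, cfg)
        assert res.dice_predictor >= 0.99
        pts = quad.flat_points()[::10]
        disp = res.predictor.forward(pts) - pts
        assert np.abs(disp).max() <= disc_field.spacing.max()

    def test_translation_recovered(self, translation_fit):
        pair, quad, res = translation_fit
        S1 = pair["S1"]
        pts = quad.flat_points()
        body = nr.sample(S1, pts) >= 0.5
        disp = res.predictor.forward(pts[body]) - pts[body]
        assert np.abs(disp.mean(axis=0) - [0.2, 0.0]).max() <= 0.02
        assert res.dice_predictor > 0.9

    def test_loss_traces_have_epoch_length(self, translation_fit):
        _, _, res = translation_fit
        assert len(res.traces["mismatch"]) == 500
        assert len(res.traces["total"]) == 500

    def test_seed_reproducibility(self, disc_field):
        quad = nr.build_quadrature([(-1, 1), (-1, 1)], (30, 30), 2)
        cfg = nr.PredictorConfig(beta=0.0, epochs=30, batch_elements=200,
                                 learning_rate=3e-4, seed=9,
                                 hidden=(12, 12, 12), eval_every=30)
        r1 = nr.fit_predictor(disc_field, disc_field, quad, cfg)
        r2 = nr.fit_predictor(disc_field, disc_field, quad, cfg)
        assert r1.traces["total"] == r2.traces["total"]


class TestCorrector:
    @pytest.fixture(scope="class")
    def radial_fit(self):
        """Radial inflation pair, predictor then gated corrector."""
        shape = fx.ShapeSpec.disc(0.6)
        pair = fx.make_pair(shape, fx.radial_inflation(0.15, 0.5),
                            resolution=96, frame=[(-1.1, 1.1), (-1.1, 1.1)])
        S1s, S2s = smoothed(pair["S1"], 1.0), smoothed(pair["S2"], 1.0)
        quad = nr.build_quadrature(pair["frame"], (48, 48), 2)
        pcfg = nr.PredictorConfig(beta=1 / 6000, epochs=450,
                                  batch_elements=400, learning_rate=1e-3,
                                  seed=5, hidden=(20, 20, 20),
                                  eval_elements=400)
        pred = nr.fit_predictor(S1s, S2s, quad, pcfg)
        pred.dice_predictor = nr.whole_domain_dice(
            pair["S1"], pair["S2"], pred.predictor.inverse)
        ccfg = nr.CorrectorConfig(epochs=300, batch_elements=300,
                                  learning_rate=1e-3, seed=6,
                                  hidden=(20, 20, 20), eval_elements=300,
                                  boundary_max_points=600)
        corr = nr.fit_corrector(pred, pair["S1"], pair["S2"], quad, ccfg)
        return pair, quad, pred, corr

    def test_zero_corrector_on_identity_predictor_zero_energy(self, disc_field):
        quad = nr.build_quadrature([(-1, 1), (-1, 1)], (20, 20), 2)
        ident = nr.FlowMap(nr.VelocityNetwork.create(
            2, (8, 8, 8), np.random.default_rng(0)))
        pi = nr.corrector_loss(ident, ident, disc_field, quad.flat_points(),
                               quad.flat_weights(), nr.Material("stvk"))
        assert pi == pytest.approx(0.0, abs=1e-8)

    def test_pure_growth_compensates_uniform_stretch(self, disc_field):
        # F = 2I absorbed exactly by theta = 2
        quad = nr.build_quadrature([(-1, 1), (-1, 1)], (15, 15), 2)
        stretch = fx.affine_stretch(2.0 * np.eye(2))
        ident = nr.FlowMap(nr.VelocityNetwork.create(
            2, (8, 8, 8), np.random.default_rng(0)))

        class _AffineFlow:
            def forward(self, x):
                return stretch.map(np.asarray(x, dtype=np.float64))

        growth = nr.GrowthModel(kappa=np.log(2.0), mode="growth", t=1.0)
        pi = nr.corrector_loss(ident, _AffineFlow(), disc_field,
                               quad.flat_points(), quad.flat_weights(),
                               nr.Material("stvk"), growth=growth)
        assert pi == pytest.approx(0.0, abs=1e-6)

    def test_corrector_preserves_dice_and_lowers_energy(self, radial_fit):
        pair, quad, pred, corr = radial_fit
        assert abs(corr.dice_corrector - pred.dice_predictor) <= 0.01
        assert corr.energy_corrector <= corr.energy_predictor + 1e-9

    def test_energy_trace_decreases_overall(self, radial_fit):
        _, _, _, corr = radial_fit
        e = corr.traces["energy"]
        assert e[-1] < e[0]

    def test_gate_keeps_transported_boundary_fixed(self, radial_fit):
        _, _, _, corr = radial_fit
        cloud = corr.corrector.gate.cloud.points
        moved = corr.corrector.forward(cloud)
        assert np.abs(moved - cloud).max() < 1e-12
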
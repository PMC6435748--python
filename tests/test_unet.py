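"""Network contracts, loss-weighting oracles, training and inference."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from myelinquant import (PhantomSpec, TrainConfig, UNetConfig, WeightParams,
                         build_model, generate_phantom, infer_cell,
                         infer_well, spatial_weight_map, train,
                         weighted_loss)
from myelinquant.candidates import (CandidateCell, CandidateParams,
                                    build_training_set)
from myelinquant.unet import UNetSegmenter, _as_arrays
from myelinquant import _nn

TINY = UNetConfig(depth=2, kernel_px=3, filters_down=(3, 4))
SMALL = UNetConfig(depth=3, kernel_px=5, filters_down=(4, 6, 8))


def expected_parameter_count(cfg: UNetConfig) -> int:
    """Layer-wise closed-form count, written independently of the builder:
    every convolution holds kernel^2 * c_in * c_out + c_out parameters."""
    k2 = cfg.kernel_px ** 2
    fd = list(cfg.filters_down)
    fu = fd[::-1]
    total = 0
    c_in = cfg.in_channels
    for f in fd:                       # down arm
        total += k2 * c_in * f + f
        c_in = f
    c_in = fd[-1]
    for i, f in enumerate(fu):         # up arm with skip concatenation
        total += k2 * c_in * f + f
        c_in = f + (fd[cfg.depth - 2 - i] if i < cfg.depth - 1 else 0)
    total += 1 * fu[-1] * cfg.n_classes + cfg.n_classes  # 1x1 softmax head
    return total


class TestModelContracts:
    def test_output_shape_and_softmax_sum(self, rng):
        model = build_model(seed=0)
        x = rng.random((2, 3, 64, 64))
        p = model.predict_proba(x)
        assert p.shape == (2, 2, 64, 64)
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-5

    @pytest.mark.parametrize("cfg", [TINY, SMALL, UNetConfig()],
                             ids=["tiny", "small", "default"])
    def test_parameter_count_closed_form(self, cfg):
        assert build_model(cfg).count_parameters() \
            == expected_parameter_count(cfg)

    def test_zero_input_spatially_constant(self):
        model = build_model(seed=3)
        p = model.predict_proba(np.zeros((1, 3, 64, 64)))
        assert float(p[0, 1].std()) < 1e-6

    def test_indivisible_input_padded_internally(self, rng):
        model = build_model(SMALL, seed=0)
        p = model.predict_proba(rng.random((1, 3, 50, 70)))
        assert p.shape == (1, 2, 50, 70)

    def test_wrong_channel_count_rejected(self):
        model = build_model(TINY)
        with pytest.raises(ValueError, match="expected"):
            model.forward_logits(np.zeros((1, 5, 16, 16)))

    def test_gradients_match_finite_differences(self):
        model = build_model(TINY, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.random((2, 3, 8, 8))
        y = rng.random((2, 8, 8)) > 0.7
        w = 1.0 + rng.random((2, 8, 8))

        def loss_and_grads():
            cache = {}
            probs = _nn.softmax_channels(model.forward_logits(x, cache))
            m = w * np.where(y, 5.0, 1.0)
            p_true = np.where(y, probs[:, 1], probs[:, 0])
            loss = float(np.mean(m * -np.log(np.clip(p_true, 1e-12, None))))
            onehot = np.stack([~y, y], axis=1).astype(float)
            dlog = m[:, None] * (probs - onehot) / y[0].size / len(x)
            return loss, model.backward(dlog, cache)

        _, grads = loss_and_grads()
        check_rng = np.random.default_rng(2)
        for p, g in zip(model.parameters(), grads):
            idx = tuple(check_rng.integers(0, s) for s in p.shape)
            eps, old = 1e-6, p[idx]
            p[idx] = old + eps
            lp, _ = loss_and_grads()
            p[idx] = old - eps
            lm, _ = loss_and_grads()
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-9)


class TestSpatialWeightMap:
    def test_point_values_of_decay_formula(self):
        truth = np.zeros((16, 16), dtype=bool)
        truth[8, 8] = True
        wp = WeightParams(f=4.0, b=0.0, spatial_mode="exponent")
        w = spatial_weight_map(truth, wp)
        assert w[8, 8] == pytest.approx(np.e)           # D = 0
        assert w[8, 12] == pytest.approx(1.0)           # D = f
        assert w[4, 4] == pytest.approx(np.exp(1 - 4 / 4.0))  # chebyshev

    def test_matches_brute_force_chebyshev(self, rng):
        for _ in range(10):
            truth = rng.random((24, 24)) > 0.9
            if not truth.any():
                continue
            w = spatial_weight_map(truth, WeightParams(
                f=5.0, b=0.0, spatial_mode="exponent"))
            ty, tx = np.nonzero(truth)
            for y in range(0, 24, 5):
                for x in range(0, 24, 5):
                    d = np.max(np.abs([ty - y, tx - x]), axis=0).min()
                    assert w[y, x] == pytest.approx(np.exp(1 - d / 5.0))

    def test_monotone_decay_along_ray(self):
        truth = np.zeros((64, 64), dtype=bool)
        truth[32, 2] = True
        w = spatial_weight_map(truth, WeightParams(
            f=6.0, b=0.0, spatial_mode="exponent"))
        ray = w[32, 2:]
        assert np.all(np.diff(ray) < 0)

    def test_additive_floor_keeps_weights_positive(self):
        truth = np.zeros((32, 32), dtype=bool)
        truth[5, 5] = True
        w = spatial_weight_map(truth, WeightParams(
            f=3.0, b=0.25, spatial_mode="additive_floor"))
        assert w.min() > 0.25
        assert w[5, 5] == pytest.approx(np.e + 0.25)

    def test_empty_truth_uniform_tiny(self):
        w = spatial_weight_map(np.zeros((20, 30), dtype=bool),
                               WeightParams(f=6.0, b=0.0,
                                            spatial_mode="exponent"))
        assert np.allclose(w, w.flat[0])
        assert w.flat[0] == pytest.approx(np.exp(1 - 30 / 6.0))


class TestWeightedLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        truth = rng.random((16, 16)) > 0.8
        pred = np.where(truth, 1.0 - 1e-12, 1e-12)
        assert weighted_loss(pred, truth, class_weight=10.0) <= 1e-6

    def test_uniform_half_is_ln2(self):
        pred = np.full((8, 8), 0.5)
        truth = np.zeros((8, 8), dtype=bool)
        assert weighted_loss(pred, truth) == pytest.approx(np.log(2))

    def test_class_weight_scales_mispredicted_truth(self, rng):
        truth = rng.random((12, 12)) > 0.7
        pred = np.clip(rng.random((12, 12)), 0.05, 0.95)
        l1 = weighted_loss(pred, truth, class_weight=5.0)
        l2 = weighted_loss(pred, truth, class_weight=10.0)
        assert l2 > l1
        # direct recomputation oracle
        ce = -np.where(truth, np.log(pred), np.log1p(-pred))
        manual = float(np.mean(np.where(truth, 10.0, 1.0) * ce))
        assert l2 == pytest.approx(manual, rel=1e-9)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            weighted_loss(np.full((4, 4), 1.5), np.zeros((4, 4), bool))


def _toy_dataset(n=16, size=32, seed=0):
    """Bright vertical bars as sheaths; channel 1 marks the center bar."""
    rngl = np.random.default_rng(seed)
    X = np.zeros((n, 3, size, size), dtype=np.float32)
    Y = np.zeros((n, size, size), dtype=np.float32)
    for i in range(n):
        x0 = int(rngl.integers(6, size - 10))
        X[i, 0, 4:size - 4, x0:x0 + 3] = 1.0
        X[i, 1, 14:18, x0:x0 + 3] = 1.0
        X[i, 0] += rngl.normal(0, 0.05, (size, size)).astype(np.float32)
        Y[i, 4:size - 4, x0:x0 + 3] = 1.0
    return X, Y


class TestTraining:
    def test_loss_descends_and_log_monotone(self):
        X, Y = _toy_dataset()
        model = build_model(SMALL, seed=0)
        cfg = TrainConfig(steps=60, batch_size=4, learning_rate=3e-3,
                          seed=0, val_every=20)
        model, log = train(model, (X[:12], Y[:12]), (X[12:], Y[12:]), cfg,
                           WeightParams())
        steps = [r["step"] for r in log.records]
        assert steps == sorted(steps)
        assert log.records[-1]["train_loss"] < log.records[0]["train_loss"]
        assert log.records[-1]["val_pooled_JI"] > 0.2

    def test_identical_seeds_identical_logs(self):
        X, Y = _toy_dataset()
        logs = []
        for _ in range(2):
            model = build_model(TINY, seed=5)
            cfg = TrainConfig(steps=20, batch_size=2, learning_rate=1e-3,
                              seed=5, val_every=10)
            _, log = train(model, (X[:8], Y[:8]), (X[8:], Y[8:]), cfg,
                           WeightParams())
            logs.append(log.records)
        assert logs[0] == logs[1]

    def test_rotation_augment_changes_trajectory_not_determinism(self):
        X, Y = _toy_dataset()
        records = []
        for _ in range(2):
            model = build_model(TINY, seed=2)
            cfg = TrainConfig(steps=10, batch_size=2, learning_rate=1e-3,
                              seed=2, val_every=10,
                              rotate_augment="random_angle")
            _, log = train(model, (X[:8], Y[:8]), (X[8:], Y[8:]), cfg,
                           WeightParams())
            records.append(log.records)
        assert records[0] == records[1]

    def test_empty_sets_rejected(self):
        X, Y = _toy_dataset(4)
        model = build_model(TINY)
        with pytest.raises(ValueError):
            train(model, (X[:0], Y[:0]), (X, Y), TrainConfig(steps=5,
                                                             val_every=5))

    def test_as_arrays_accepts_pairs(self):
        X, Y = _toy_dataset(4)
        pairs = list(zip(X, Y))
        X2, Y2 = _as_arrays(pairs)
        np.testing.assert_allclose(X2, X)


class TestInference:
    def test_threshold_boundaries(self, rng):
        model = build_model(SMALL, seed=0)
        x = rng.random((3, 64, 64)).astype(np.float32)
        assert infer_cell(model, x, threshold=0.0).all()
        assert not infer_cell(model, x, threshold=1.0 + 1e-9).any()

    def test_mask_size_monotone_in_threshold(self, rng):
        model = build_model(SMALL, seed=0)
        x = rng.random((3, 64, 64)).astype(np.float32)
        counts = [infer_cell(model, x, t).sum()
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_zero_candidates_empty_result(self, compact_phantom):
        img, _ = compact_phantom
        model = build_model(SMALL, seed=0)
        assert infer_well(model, img, [], crop_size_px=64) == []

    def test_perfect_stub_reproduces_truth(self, compact_phantom):
        img, truth = compact_phantom

        def perfect_model(masked_input):
            oy, ox = masked_input.offset
            h, w = img.shape
            out = np.zeros((256, 256))
            sy = slice(max(oy, 0), min(oy + 256, h))
            sx = slice(max(ox, 0), min(ox + 256, w))
            out[sy.start - oy:sy.stop - oy, sx.start - ox:sx.stop - ox] = \
                truth.sheaths.raster[sy, sx] == masked_input.cell_id
            return out

        candidates = [
            CandidateCell(int(lbl), ndi.center_of_mass(
                truth.nuclei.raster == lbl),
                truth.nuclei.raster == lbl)
            for lbl in truth.nuclei.labels]
        cells = infer_well(perfect_model, img, candidates,
                           crop_size_px=256)
        rebuilt = np.zeros(img.shape, dtype=bool)
        for c in cells:
            rebuilt |= c.sheath_mask
            np.testing.assert_array_equal(
                c.sheath_mask, truth.sheaths.raster == c.cell_id)
        np.testing.assert_array_equal(rebuilt, truth.sheaths.raster > 0)

    def test_border_candidate_mask_confined_to_image(self):
        spec = PhantomSpec(height_px=128, width_px=128, n_cells=1,
                           p_ensheathing=1.0, seed=13)
        img, truth = generate_phantom(spec)

        def all_ones(masked_input):
            return np.ones((256, 256))

        lbl = int(truth.nuclei.labels[0])
        cand = CandidateCell(lbl, ndi.center_of_mass(
            truth.nuclei.raster == lbl), truth.nuclei.raster == lbl)
        cells = infer_well(all_ones, img, [cand], crop_size_px=256)
        assert cells[0].pixel_indices.size == 128 * 128


class TestEstimatorWrapper:
    def test_fit_predict_shapes_and_params(self):
        X, Y = _toy_dataset(n=20)
        est = UNetSegmenter(depth=3, filters_down=(4, 6, 8), steps=30,
                            batch_size=4, learning_rate=3e-3, seed=0,
                            val_every=15)
        assert est.get_params()["depth"] == 3
        est.fit(X, Y)
        masks = est.predict(X[:2])
        assert masks.shape == (2, 32, 32) and masks.dtype == bool
        assert est.log_.records
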
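"""Reconstructor architecture, training loop and inference contracts."""

from dataclasses import replace

import numpy as np
import pytest

import pgrecon as pg
from pgrecon.model import _batch_loss_and_grad
from pgrecon.physics import boundary_mask

FAST_TRAIN = pg.TrainConfig(max_epochs=8, patience=20, allow_override=True)

SMALL = pg.ScenarioConfig(n_train=16, n_val=8, n_test=8, grid=pg.GridSpec(32, 32))


@pytest.fixture(scope="module")
def small_ds():
    return pg.generate_scenario("modality", SMALL, seed=11)


class TestBuildModel:
    def test_same_seed_identical_parameters(self):
        a = pg.build_model(seed=42)
        b = pg.build_model(seed=42)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_different_seed_differs(self):
        a = pg.build_model(seed=0)
        b = pg.build_model(seed=1)
        assert any(
            not np.array_equal(pa, pb)
            for pa, pb in zip(a.parameters(), b.parameters())
        )

    def test_forward_preserves_shape(self):
        model = pg.build_model(seed=0)
        out = model.forward(np.zeros((3, 1, 64, 64), dtype=np.float32))
        assert out.shape == (3, 1, 64, 64)

    def test_param_count_matches_layerwise_arithmetic(self):
        # conv stack for depth 7, widths (16, 32, 64), 3x3 kernels, concat
        # skips doubling the decoder-side input widths:
        # 1->16, 16->32, 32->64, 64->32, (32+32)->16, (16+16)->16, 16->1
        expected = sum(
            ci * co * 9 + co
            for ci, co in [(1, 16), (16, 32), (32, 64), (64, 32), (64, 16), (32, 16), (16, 1)]
        )
        assert pg.build_model(seed=0).param_count() == expected

    def test_skip_variants_share_encoder_shapes(self):
        plain = pg.build_model(pg.ModelConfig(skip_mode="none"), seed=0)
        cat = pg.build_model(pg.ModelConfig(skip_mode="concat"), seed=0)
        x = np.zeros((2, 1, 32, 32), dtype=np.float32)
        assert plain.forward(x).shape == cat.forward(x).shape

    @pytest.mark.parametrize("depth,n_convs", [(6, 6), (7, 7), (8, 8)])
    def test_depth_controls_conv_count(self, depth, n_convs):
        model = pg.build_model(pg.ModelConfig(depth=depth), seed=0)
        convs = [l for l in model.layers if hasattr(l, "W")]
        assert len(convs) == n_convs

    def test_depth_outside_range_rejected_without_override(self):
        with pytest.raises(ValueError):
            pg.ModelConfig(depth=5)
        pg.ModelConfig(depth=5, allow_depth_override=True)  # explicit override ok


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        import pgrecon.model as M

        old = M._DTYPE
        M._DTYPE = np.float64
        try:
            model = pg.build_model(seed=3)
            rng = np.random.default_rng(1)
            x = rng.normal(size=(2, 1, 8, 8))
            y = rng.normal(size=(2, 1, 8, 8))
            bm = boundary_mask((8, 8)).astype(float)
            w = pg.LossWeights(1.0, 0.3, 0.2)
            rs = pg.ResidualSpec()

            def loss():
                p = model.forward(x, train=True)
                return _batch_loss_and_grad(p, y, w, rs, 2 / 7, bm)

            terms, g = loss()
            model.backward(g)
            ana = [gr.copy() for gr in model.gradients()]
            rngi = np.random.default_rng(0)
            for p, a in zip(model.parameters(), ana):
                for _ in range(3):
                    idx = tuple(rngi.integers(0, s) for s in p.shape)
                    eps = 1e-6
                    orig = p[idx]
                    p[idx] = orig + eps
                    lp = loss()[0]["total"]
                    p[idx] = orig - eps
                    lm = loss()[0]["total"]
                    p[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    assert num == pytest.approx(a[idx], rel=1e-4, abs=1e-9)
        finally:
            M._DTYPE = old


class TestTrain:
    def test_single_pair_overfit_drives_data_loss_down(self):
        # the residual input skip starts the loss at the noise floor, so the
        # memorisation capacity of the conv stack is probed without it
        grid = pg.GridSpec(32, 32)
        clean = pg.gaussian_field(grid, alpha=15.0).values
        noisy = pg.add_gaussian_noise(clean, pg.NoiseSpec(0.05, seed=0))
        ds = pg.ScenarioDataset(
            "modality",
            np.stack([clean, clean]),
            np.stack([noisy, noisy]),
            [{}, {}],
            np.array([0]),
            np.array([1]),
            np.array([], dtype=int),
            0,
            grid,
        )
        model = pg.build_model(pg.ModelConfig(input_skip=False), seed=0)
        tcfg = pg.TrainConfig(
            max_epochs=200, patience=500, batch_size=1, allow_override=True
        )
        res = pg.train(
            model, ds, pg.LossWeights(1.0, 0.0, 0.0), tcfg
        )
        assert res.log[-1]["train_data"] < 1e-3

    def test_validation_loss_decreases_across_seeds(self, small_ds):
        for seed in (0, 1, 2):
            model = pg.build_model(seed=seed)
            res = pg.train(
                model, small_ds, pg.LossWeights(), replace(FAST_TRAIN, seed=seed)
            )
            assert res.log[-1]["val_total"] < res.log[0]["val_total"]

    def test_training_reproducible_under_fixed_seed(self, small_ds):
        logs = []
        for _ in range(2):
            model = pg.build_model(seed=5)
            res = pg.train(
                model,
                small_ds,
                pg.LossWeights(),
                replace(FAST_TRAIN, max_epochs=3),
            )
            logs.append(res.log)
        assert logs[0] == logs[1]

    def test_first_step_data_term_identical_with_and_without_physics(self, small_ds):
        # the ablation differs only through the loss: same seed, same first batch
        rows = []
        for w in (pg.LossWeights(), pg.LossWeights(1.0, 0.0, 0.0)):
            model = pg.build_model(seed=7)
            res = pg.train(model, small_ds, w, replace(FAST_TRAIN, max_epochs=1))
            rows.append(res.log[0]["train_data"])
        assert rows[0] == pytest.approx(rows[1], rel=2e-2)

    def test_empty_split_rejected(self, small_ds):
        ds = replace(small_ds) if False else small_ds
        import dataclasses

        bad = dataclasses.replace(ds, val_idx=np.array([], dtype=int))
        with pytest.raises(ValueError):
            pg.train(pg.build_model(seed=0), bad, pg.LossWeights(), FAST_TRAIN)


class TestTrainConfigGuards:
    def test_out_of_range_values_need_override(self):
        with pytest.raises(ValueError):
            pg.TrainConfig(batch_size=4)
        with pytest.raises(ValueError):
            pg.TrainConfig(max_epochs=50)
        with pytest.raises(ValueError):
            pg.TrainConfig(learning_rate=1e-3)
        pg.TrainConfig(max_epochs=50, batch_size=4, allow_override=True)


class TestPredict:
    def test_deterministic(self, small_ds):
        model = pg.build_model(seed=0)
        x = small_ds.noisy[:4]
        np.testing.assert_array_equal(pg.predict(model, x), pg.predict(model, x))

    def test_batch_equals_per_sample(self, small_ds):
        model = pg.build_model(seed=0)
        x = small_ds.noisy[:5]
        batched = pg.predict(model, x)
        singles = np.stack([pg.predict(model, xi) for xi in x])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_outputs_finite(self, small_ds):
        model = pg.build_model(seed=0)
        out = pg.predict(model, small_ds.noisy[:3])
        assert np.all(np.isfinite(out))

    def test_rejects_bad_side_length(self):
        model = pg.build_model(seed=0)
        with pytest.raises(ValueError):
            pg.predict(model, np.zeros((30, 30)))


def test_checkpoint_round_trip(tmp_path, small_ds):
    model = pg.build_model(seed=9)
    path = tmp_path / "ckpt.npz"
    pg.save_checkpoint(model, path, extra={"note": "test"})
    back = pg.load_checkpoint(path)
    x = small_ds.noisy[:2]
    np.testing.assert_array_equal(pg.predict(model, x), pg.predict(back, x))
    assert back.config == model.config


def test_training_log_is_line_delimited_json(tmp_path, small_ds):
    import json

    model = pg.build_model(seed=0)
    res = pg.train(
        model, small_ds, pg.LossWeights(), replace(FAST_TRAIN, max_epochs=2)
    )
    path = tmp_path / "log.jsonl"
    pg.write_training_log(res.log, path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == len(res.log)
    row = json.loads(lines[0])
    assert {"epoch", "train_total", "train_data", "train_physics",
            "train_boundary", "val_total"} <= set(row)
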
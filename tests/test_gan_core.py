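"""Depth codec, adversarial/L1 losses, training regimes and their contracts."""

import copy

import numpy as np
import pytest
from scipy.optimize import brentq

from colodepth.gan_core import (
    DepthCodec,
    DiscriminatorSpec,
    GeneratorSpec,
    Pix2PixTrainer,
    TrainBatch,
    TrainingConfig,
    combined_generator_objective,
    load_checkpoint,
    loss_cgan,
    loss_l1,
    save_checkpoint,
    split_dataset,
)
from colodepth.nn import sigmoid


@pytest.fixture
def codec():
    return DepthCodec(d_max=20.0)


def _tiny_trainer(seed=0, mode="standard", size=8, **cfg_kw):
    cfg = TrainingConfig(
        epochs=1, batch_size=4, seed=seed, mode=mode, **cfg_kw
    )
    return Pix2PixTrainer(
        GeneratorSpec(n_levels=2, base_channels=4),
        DiscriminatorSpec(n_layers=1, base_channels=4),
        cfg,
        DepthCodec(),
    )


def _tiny_batch(seed=0, n=3, size=8, n_reals=0):
    rng = np.random.default_rng(seed)
    pairs = [
        (rng.uniform(0, 1, (size, size, 3)), rng.uniform(0.5, 19.5, (size, size)))
        for _ in range(n)
    ]
    reals = [rng.uniform(0, 1, (size, size, 3)) for _ in range(n_reals)]
    return TrainBatch(pairs=pairs, reals=reals)


# ---------------------------------------------------------------------------
# Depth codec
# ---------------------------------------------------------------------------


class TestDepthCodec:
    def test_bounds(self, codec):
        assert codec.encode(0.0) == pytest.approx(-1.0, abs=1e-12)
        assert codec.encode(20.0) == pytest.approx(1.0, abs=1e-12)
        assert codec.decode(-1.0) == pytest.approx(0.0, abs=1e-12)

    def test_log_formula_value(self, codec):
        assert codec.encode(np.e - 1.0) == pytest.approx(
            2.0 / np.log(21.0) - 1.0, abs=1e-12
        )

    def test_round_trip_grid(self, codec):
        d = np.linspace(0.0, 20.0, 1000)
        assert np.max(np.abs(codec.decode(codec.encode(d)) - d)) < 1e-6

    def test_strictly_increasing(self, codec):
        d = np.linspace(0.0, 20.0, 500)
        assert np.all(np.diff(codec.encode(d)) > 0)

    def test_midpoint_against_root_finding(self, codec):
        """decode(0) agrees with numerically inverting encode."""
        root = brentq(lambda d: codec.encode(d) - 0.0, 0.0, 20.0, xtol=1e-12)
        assert codec.decode(0.0) == pytest.approx(root, abs=1e-9)
        assert codec.decode(0.0) == pytest.approx(np.exp(np.log(21.0) / 2) - 1, abs=1e-9)

    def test_out_of_range_rejected(self, codec):
        with pytest.raises(ValueError):
            codec.encode(21.0)
        with pytest.raises(ValueError):
            codec.encode(-0.5)
        with pytest.raises(ValueError):
            codec.decode(1.5)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


class TestLosses:
    def test_cgan_uninformative_discriminator(self):
        assert loss_cgan([0.5, 0.5], [0.5, 0.5]) == pytest.approx(
            -2.0 * np.log(2.0), abs=1e-12
        )

    def test_cgan_perfect_discriminator_limit(self):
        val = loss_cgan([1 - 1e-9], [1e-9])
        assert -1e-6 < val < 0.0

    def test_cgan_hand_summed_batch(self):
        d_real = [0.9, 0.6, 0.7]
        d_fake = [0.2, 0.4, 0.1]
        expected = (
            np.log(1 - 0.2) + np.log(1 - 0.4) + np.log(1 - 0.1)
        ) / 3 + (np.log(0.9) + np.log(0.6) + np.log(0.7)) / 3
        assert loss_cgan(d_real, d_fake) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_cgan_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            loss_cgan([bad], [0.5])

    def test_l1_identity_and_constant(self):
        x = np.random.default_rng(0).normal(0, 1, (4, 4))
        assert loss_l1(x, x) == 0.0
        assert loss_l1(x + 0.1, x) == pytest.approx(0.1, abs=1e-12)

    def test_l1_brute_force(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, (4, 4))
        x = rng.normal(0, 1, (4, 4))
        brute = sum(abs(y[i, j] - x[i, j]) for i in range(4) for j in range(4)) / 16
        assert loss_l1(y, x) == pytest.approx(brute, abs=1e-12)

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_l1(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_combined_objective(self):
        assert combined_generator_objective(0.7, 0.01, 200.0) == pytest.approx(2.7)
        assert combined_generator_objective(0.7, 0.5, 0.0) == pytest.approx(0.7)
        # linearity in the L1 term
        vals = [combined_generator_objective(0.0, l1, 50.0) for l1 in (0.1, 0.2, 0.3)]
        assert np.allclose(np.diff(vals), 5.0)


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------


class TestForwardPasses:
    def test_generator_seeded_determinism(self):
        tr = _tiny_trainer()
        c = np.random.default_rng(2).uniform(0, 1, (8, 8, 3))
        y1 = tr.generator_forward(c, noise_seed=5)
        y2 = tr.generator_forward(c, noise_seed=5)
        y3 = tr.generator_forward(c, noise_seed=6)
        assert np.array_equal(y1, y2)
        assert not np.array_equal(y1, y3)  # dropout noise z differs
        assert y1.shape == (8, 8)
        assert y1.min() >= -1.0 and y1.max() <= 1.0

    def test_generator_rejects_bad_size(self):
        tr = _tiny_trainer()
        with pytest.raises(ValueError):
            tr.generator_forward(np.zeros((7, 7, 3)))

    def test_discriminator_zero_head_gives_half(self):
        tr = _tiny_trainer()
        tr.D.head.params["W"][...] = 0.0
        tr.D.head.params["b"][...] = 0.0
        c = np.random.default_rng(3).uniform(0, 1, (8, 8, 3))
        m = np.random.default_rng(4).uniform(-1, 1, (8, 8))
        assert tr.discriminator_forward(c, m) == 0.5

    def test_discriminator_output_in_open_interval(self):
        tr = _tiny_trainer()
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = tr.discriminator_forward(
                rng.uniform(0, 1, (8, 8, 3)), rng.uniform(-1, 1, (8, 8))
            )
            assert 0.0 < p < 1.0

    def test_mean_patch_aggregation_oracle(self):
        """p equals the hand-computed mean of per-patch logit sigmoids."""
        tr = _tiny_trainer()
        rng = np.random.default_rng(6)
        c = rng.uniform(0, 1, (8, 8, 3))
        m = rng.uniform(-1, 1, (8, 8))
        p = tr.discriminator_forward(c, m)
        x = np.concatenate(
            [2.0 * np.moveaxis(c, -1, 0)[None] - 1.0, m[None, None]], axis=1
        )
        h = tr.D.convs[0].forward(x)
        h = np.where(h >= 0, h, 0.2 * h)
        logits = tr.D.head.forward(h)
        assert p == pytest.approx(float(np.mean(sigmoid(logits))), abs=1e-12)

    def test_misaligned_inputs_rejected(self):
        tr = _tiny_trainer()
        with pytest.raises(ValueError):
            tr.discriminator_forward(np.zeros((8, 8, 3)), np.zeros((4, 4)))

    def test_predict_range_and_determinism(self):
        tr = _tiny_trainer()
        c = np.random.default_rng(7).uniform(0, 1, (8, 8, 3))
        d1 = tr.predict(c, noise_seed=3)
        d2 = tr.predict(c, noise_seed=3)
        assert np.array_equal(d1, d2)
        assert d1.min() >= 0.0 and d1.max() <= 20.0

    def test_inference_speed_256(self):
        """One 256x256 prediction stays under a second on a single CPU."""
        import time

        tr = Pix2PixTrainer(
            GeneratorSpec(n_levels=3, base_channels=8),
            DiscriminatorSpec(),
            TrainingConfig(seed=0),
            DepthCodec(),
        )
        c = np.random.default_rng(8).uniform(0, 1, (256, 256, 3))
        tr.predict(c)  # warm-up
        t0 = time.perf_counter()
        tr.predict(c)
        assert time.perf_counter() - t0 < 1.0


# ---------------------------------------------------------------------------
# Training steps
# ---------------------------------------------------------------------------


class TestTrainSteps:
    def test_empty_batch_rejected(self):
        tr = _tiny_trainer()
        with pytest.raises(ValueError):
            tr.train_step_standard(TrainBatch(pairs=[]))

    def test_standard_rejects_reals(self):
        tr = _tiny_trainer()
        with pytest.raises(ValueError):
            tr.train_step_standard(_tiny_batch(n_reals=1))

    def test_real_with_depth_map_rejected(self):
        """A 'real' element carrying ground truth violates the contract."""
        tr = _tiny_trainer(mode="extended")
        batch = _tiny_batch()
        batch.reals = [(np.zeros((8, 8, 3)), np.zeros((8, 8)))]
        with pytest.raises(TypeError):
            tr.train_step_extended(batch)

    def test_parameter_isolation_between_players(self):
        """Disabling one optimizer leaves that player's parameters bit-identical."""
        base = _tiny_trainer(seed=11)
        batch = _tiny_batch(seed=11)

        tr = copy.deepcopy(base)
        tr.optG.step = lambda: None  # freeze the generator update
        g_before = tr.G.state_dict()
        d_before = tr.D.state_dict()
        tr.train_step_standard(batch, rng=np.random.default_rng(0))
        assert all(np.array_equal(g_before[k], v) for k, v in tr.G.state_dict().items())
        assert any(
            not np.array_equal(d_before[k], v) for k, v in tr.D.state_dict().items()
        )

        tr = copy.deepcopy(base)
        tr.optD.step = lambda: None  # freeze the discriminator update
        d_before = tr.D.state_dict()
        tr.train_step_standard(batch, rng=np.random.default_rng(0))
        assert all(np.array_equal(d_before[k], v) for k, v in tr.D.state_dict().items())

    def test_extended_with_no_reals_equals_standard(self):
        a = _tiny_trainer(seed=21)
        b = _tiny_trainer(seed=21)
        batch = _tiny_batch(seed=21)
        a.train_step_standard(batch, rng=np.random.default_rng(1))
        b.train_step_extended(_tiny_batch(seed=21), rng=np.random.default_rng(1))
        for k, v in a.G.state_dict().items():
            assert np.array_equal(v, b.G.state_dict()[k])
        for k, v in a.D.state_dict().items():
            assert np.array_equal(v, b.D.state_dict()[k])

    def test_lambda_zero_ignores_labels(self):
        """With lambda=0 (and D frozen so labels cannot act through the
        discriminator update) the generator update is label-independent:
        the L1 influence is gone."""
        a = _tiny_trainer(seed=31, lambda_l1=0.0)
        b = _tiny_trainer(seed=31, lambda_l1=0.0)
        a.optD.step = lambda: None
        b.optD.step = lambda: None
        ba = _tiny_batch(seed=31)
        bb = _tiny_batch(seed=31)
        for i, (c, _) in enumerate(bb.pairs):
            bb.pairs[i] = (c, np.full_like(bb.pairs[i][1], 7.0))  # different labels
        a.train_step_standard(ba, rng=np.random.default_rng(2))
        b.train_step_standard(bb, rng=np.random.default_rng(2))
        for k, v in a.G.state_dict().items():
            assert np.array_equal(v, b.G.state_dict()[k])

    def test_discriminative_mode_is_pure_regression(self):
        """No adversarial influence: D untouched, G update independent of D init."""
        a = _tiny_trainer(seed=41, mode="discriminative")
        b = _tiny_trainer(seed=41, mode="discriminative")
        b.D = _tiny_trainer(seed=99).D  # a completely different discriminator
        d_before = a.D.state_dict()
        batch = _tiny_batch(seed=41)
        la = a._step(_tiny_batch(seed=41), np.random.default_rng(3))
        lb = b._step(_tiny_batch(seed=41), np.random.default_rng(3))
        assert la.g_adv == 0.0 and la.d_loss == 0.0
        assert all(np.array_equal(d_before[k], v) for k, v in a.D.state_dict().items())
        for k, v in a.G.state_dict().items():
            assert np.array_equal(v, b.G.state_dict()[k])

    def test_l1_term_blind_to_real_images(self):
        """Finite differences: perturbing a real image moves the adversarial
        term but leaves the L1 term exactly unchanged (the domain-adaptation
        mechanism: unlabeled frames join the cGAN loss only)."""
        tr = _tiny_trainer(mode="extended")
        batch = _tiny_batch(seed=51, n=2, n_reals=1)

        def terms(reals):
            c_all = [p[0] for p in batch.pairs] + reals
            y = np.stack(
                [tr.generator_forward(c, noise_seed=7) for c in c_all]
            )
            x_enc = np.stack([tr.codec.encode(p[1]) for p in batch.pairs])
            l1 = loss_l1(y[:2], x_enc)
            p_fake = np.array(
                [tr.discriminator_forward(c, m) for c, m in zip(c_all, y)]
            )
            return l1, float(np.mean(np.log(p_fake)))

        l1_0, adv_0 = terms(batch.reals)
        bumped = [batch.reals[0] + 0.05]
        bumped[0][bumped[0] > 1] = 1.0
        l1_1, adv_1 = terms(bumped)
        assert l1_1 == l1_0  # exactly zero change
        assert adv_1 != adv_0


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------


class TestSplitDataset:
    @pytest.mark.parametrize(
        "n,expected", [(10, (6, 1, 3)), (100, (60, 10, 30)), (17, None)]
    )
    def test_proportions_and_partition(self, n, expected):
        rows = [{"i": i} for i in range(n)]
        out = split_dataset(rows, seed=3)
        counts = {
            s: sum(1 for r in out if r["split"] == s) for s in ("train", "val", "test")
        }
        if expected:
            assert (counts["train"], counts["val"], counts["test"]) == expected
        assert sum(counts.values()) == n  # disjoint cover
        assert {r["i"] for r in out} == set(range(n))

    def test_deterministic(self):
        rows = [{"i": i} for i in range(30)]
        a = split_dataset(rows, seed=9)
        b = split_dataset(rows, seed=9)
        assert a == b

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            split_dataset([{}, {}])


# ---------------------------------------------------------------------------
# Training loop and checkpointing
# ---------------------------------------------------------------------------


class TestTrainingLoop:
    def test_zero_epochs_leaves_params(self, toy_pairs_32):
        pairs, _, _ = toy_pairs_32
        tr = _tiny_trainer()
        before = tr.G.state_dict()
        tr.fit(pairs[:4], epochs=0)
        assert all(np.array_equal(before[k], v) for k, v in tr.G.state_dict().items())

    def test_config_defaults_match_published_recipe(self):
        cfg = TrainingConfig()
        assert cfg.lambda_l1 == 200.0
        assert cfg.lr == 2e-4
        assert cfg.epochs == 300
        assert cfg.batch_size == 20
        assert cfg.reals_per_batch == 1
        assert cfg.split_ratios == (6, 1, 3)

    def test_extended_requires_real_pool(self, toy_pairs_32):
        pairs, _, _ = toy_pairs_32
        tr = _tiny_trainer(mode="extended")
        with pytest.raises(ValueError):
            tr.fit(pairs[:4], reals=[], epochs=1)

    def test_training_reduces_train_l1(self, toy_pairs_32):
        """A short toy run drives the train L1 term below its first epoch."""
        pairs, _, _ = toy_pairs_32
        cfg = TrainingConfig(epochs=10, batch_size=8, seed=0, mode="standard")
        tr = Pix2PixTrainer(
            GeneratorSpec(n_levels=3, base_channels=8),
            DiscriminatorSpec(n_layers=2),
            cfg,
            DepthCodec(),
        )
        report = tr.fit(pairs[:12], epochs=10)
        assert report.l1_term[-1] < report.l1_term[0]
        assert all(np.isfinite(report.g_loss))
        assert all(np.isfinite(report.d_loss))

    def test_checkpoint_round_trip(self, tmp_path):
        tr = _tiny_trainer(seed=61)
        tr.fit(_tiny_batch(seed=61, n=4).pairs, epochs=1)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, tr)
        tr2 = load_checkpoint(path)
        c = np.random.default_rng(62).uniform(0, 1, (8, 8, 3))
        assert np.array_equal(tr.predict(c, noise_seed=1), tr2.predict(c, noise_seed=1))
        assert tr2.config == tr.config
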
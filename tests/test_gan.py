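"""Patch sampling, augmentation, losses, schedules, training and inference."""

import numpy as np
import pytest
from scipy import stats

from refless4dflow.gan import (DiscriminatorConfig, GeneratorConfig,
                               PatchDiscriminator, ReferencePredictor,
                               TrainConfig, TrainingSubject, UNet3D,
                               _forward_tiled, augment, discriminator_loss,
                               encoding_set_to_arrays, generator_loss,
                               load_checkpoint, lr_schedule, predict_reference,
                               sample_patch, save_checkpoint)
from refless4dflow.phantom import PhantomConfig, generate_phantom, simulate_encodings


def _subject(shape=(16, 16, 16), T=2, seed=0):
    rng = np.random.default_rng(seed)
    return TrainingSubject(inputs=rng.normal(size=(6, T) + shape),
                           target=rng.normal(size=(2, T) + shape))


def _toy_sets(n=2, grid=(32, 32, 32), T=3):
    cfgs = [PhantomConfig(grid_shape=grid, n_timeframes=T, noise_sd=0.0,
                          background_poly_order=2, background_amplitude_rad=0.2,
                          seed=s) for s in range(1, n + 1)]
    gts = [generate_phantom(c) for c in cfgs]
    return gts, [simulate_encodings(g, c) for g, c in zip(gts, cfgs)]


class TestSamplePatch:
    def test_full_size_patch_origin_zero(self):
        sub = _subject()
        rng = np.random.default_rng(0)
        x, y, w = sample_patch(sub, (16, 16, 16), rng)
        assert x.shape == (6, 16, 16, 16)
        assert y.shape == (2, 16, 16, 16)
        # origin forced to (0,0,0): the patch equals a whole timeframe
        assert any(np.array_equal(x, sub.inputs[:, t])
                   for t in range(sub.inputs.shape[1]))

    def test_reproducible_with_fixed_rng(self):
        sub = _subject()
        x1, y1, _ = sample_patch(sub, (8, 8, 8), np.random.default_rng(42))
        x2, y2, _ = sample_patch(sub, (8, 8, 8), np.random.default_rng(42))
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)

    def test_patch_larger_than_volume_errors(self):
        with pytest.raises(ValueError, match="patch"):
            sample_patch(_subject(), (32, 8, 8), np.random.default_rng(0))

    def test_origin_distribution_uniform(self):
        """Chi-square test of spatial-origin uniformity at alpha = 0.01:
        10^4 draws of 64^3 patches from a 128^3 volume."""
        shape, patch, n_draws = (128, 128, 128), (64, 64, 64), 10_000
        coords = np.arange(np.prod(shape), dtype=np.float64).reshape(shape)
        inputs = np.zeros((6, 1) + shape, dtype=np.float32)
        inputs[0, 0] = coords            # first corner value encodes the origin
        sub = TrainingSubject(inputs=inputs,
                              target=np.zeros((2, 1) + shape, dtype=np.float32))
        rng = np.random.default_rng(7)
        n_pos = shape[0] - patch[0] + 1          # 65 positions per axis
        counts = np.zeros((3, n_pos), dtype=int)
        for _ in range(n_draws):
            x, _, _ = sample_patch(sub, patch, rng)
            flat = int(x[0, 0, 0, 0])
            org = np.unravel_index(flat, shape)
            for ax, o in enumerate(org):
                counts[ax, o] += 1
        for ax in range(3):
            chi2 = ((counts[ax] - n_draws / n_pos) ** 2 / (n_draws / n_pos)).sum()
            p = stats.chi2.sf(chi2, df=n_pos - 1)
            assert p > 0.01


class TestAugment:
    def test_zero_probabilities_identity(self):
        vol = np.random.default_rng(0).normal(size=(8, 8, 8, 8))
        out = augment(vol, np.random.default_rng(1), p_flip=0.0, p_rotate=0.0,
                      p_zoom=0.0)
        assert np.array_equal(out, vol)

    def test_double_flip_identity(self):
        vol = np.random.default_rng(0).normal(size=(8, 6, 6, 6))
        once = augment(vol, np.random.default_rng(3), p_flip=1.0, p_rotate=0.0,
                       p_zoom=0.0)
        twice = augment(once, np.random.default_rng(3), p_flip=1.0, p_rotate=0.0,
                        p_zoom=0.0)
        assert np.allclose(twice, vol)

    def test_trivial_zoom_and_rotation_identity(self):
        vol = np.random.default_rng(0).normal(size=(8, 6, 6, 6))
        out = augment(vol, np.random.default_rng(2), p_flip=0.0, p_rotate=1.0,
                      p_zoom=1.0, max_angle_deg=0.0, zoom_range=(1.0, 1.0))
        assert np.abs(out - vol).max() < 1e-6

    def test_channels_transform_identically(self):
        rng = np.random.default_rng(4)
        vol = np.stack([rng.normal(size=(10, 10, 10))] * 5)
        out = augment(vol, np.random.default_rng(5))
        for c in range(1, 5):
            assert np.array_equal(out[c], out[0])


class TestLosses:
    def test_generator_loss_bce_at_zero_logit(self):
        pred = np.zeros((1, 2, 4, 4, 4))
        val = generator_loss(pred, pred, disc_logits_on_fake=np.zeros((1, 1, 2, 2, 2)))
        assert val == pytest.approx(np.log(2.0))

    def test_generator_loss_weighted_hand_examples(self):
        pred = np.array([1.0, 3.0])
        tgt = np.zeros(2)
        assert generator_loss(pred, tgt, weights=np.array([1.0, 1.0]),
                              mode="velocity_weighted") == pytest.approx(2.0)
        assert generator_loss(pred, tgt, weights=np.array([3.0, 1.0]),
                              mode="velocity_weighted") == pytest.approx(1.5)

    def test_discriminator_loss_closed_forms(self):
        z0 = np.zeros(10)
        assert discriminator_loss(z0, z0) == pytest.approx(np.log(2.0))
        z1 = np.ones(10)
        expected = 0.5 * (np.logaddexp(0, -1.0) + np.logaddexp(0, 1.0))
        assert discriminator_loss(z1, z1) == pytest.approx(expected)
        assert expected == pytest.approx(0.8133, abs=1e-4)

    def test_discriminator_perfect_limit(self):
        big = np.full(10, 50.0)
        assert discriminator_loss(big, -big) < 1e-20


class TestSchedule:
    def test_constant_then_linear_decay(self):
        cfg = TrainConfig(epochs=200, lr_constant_epochs=100, lr=0.002)
        assert lr_schedule(0, cfg) == 0.002
        assert lr_schedule(100, cfg) == 0.002
        assert lr_schedule(150, cfg) == pytest.approx(0.001)
        assert lr_schedule(199, cfg) <= 0.002 / 100 + 1e-12   # within one step of 0
        assert lr_schedule(200, cfg) == 0.0


class _ConstModel:
    """Inference stub: constant 2-channel output, U-Net-compatible surface."""

    depth = 1

    def __init__(self, value):
        self.value = value

    def forward(self, x):
        return np.full((x.shape[0], 2) + x.shape[2:], self.value)


class TestPredictReference:
    def test_empty_ensemble_errors(self):
        with pytest.raises(ValueError, match="empty"):
            predict_reference([], np.zeros((6, 1, 8, 8, 8)))

    def test_constant_models_average(self):
        inputs = np.zeros((6, 2, 8, 8, 8))
        out = predict_reference([_ConstModel(1.0), _ConstModel(3.0)], inputs)
        assert np.allclose(out, 2.0)

    def test_identical_models_equal_single(self):
        rng = np.random.default_rng(0)
        m = UNet3D(GeneratorConfig(depth=2, base_channels=4), rng=rng)
        inputs = rng.normal(size=(6, 1, 8, 8, 8))
        single = predict_reference([m], inputs)
        triple = predict_reference([m, m, m], inputs)
        assert np.allclose(single, triple)

    def test_tiled_matches_untiled_in_interior(self):
        rng = np.random.default_rng(3)
        m = UNet3D(GeneratorConfig(depth=2, base_channels=4), rng=rng)
        vol = rng.normal(size=(6, 48, 32, 32))
        full = m.forward(vol[None])[0]
        tiled = _forward_tiled(m, vol, tile=(32, 32, 32), overlap=8)
        interior = np.abs(full - tiled)[:, 8:-8]
        assert interior.max() <= 1e-5


class TestTraining:
    def test_toy_training_reduces_dev_mae(self):
        _, sets = _toy_sets(n=2, grid=(32, 32, 32), T=3)
        est = ReferencePredictor(mode="adversarial", depth=2, base_channels=4,
                                 disc_layers=2, disc_channels=4,
                                 patch_size=(16, 16, 16), batch_size=2,
                                 epochs=20, lr_constant_epochs=10,
                                 dev_interval=20, folds=1, seed=0)
        est.fit(sets)
        h = est.history_[0]
        assert h["dev_mae"][-1] < h["dev_mae"][0]

    def test_same_seed_identical_history(self):
        _, sets = _toy_sets(n=2, grid=(32, 32, 32), T=2)
        histories = []
        for _ in range(2):
            est = ReferencePredictor(mode="velocity_weighted", depth=2,
                                     base_channels=4, patch_size=(16, 16, 16),
                                     batch_size=2, epochs=5, lr_constant_epochs=2,
                                     dev_interval=5, folds=1, seed=123)
            est.fit(sets)
            histories.append(est.history_[0]["gen_loss"])
        assert histories[0] == histories[1]

    def test_nan_loss_aborts_with_epoch(self):
        _, sets = _toy_sets(n=1, grid=(32, 32, 32), T=2)
        est = ReferencePredictor(mode="velocity_weighted", depth=2,
                                 base_channels=4, patch_size=(16, 16, 16),
                                 batch_size=1, epochs=10, lr_constant_epochs=5,
                                 lr=1e18, folds=1, seed=0)
        with pytest.raises(RuntimeError, match="epoch"):
            est.fit(sets)

    def test_folds_partition_and_ensemble(self):
        _, sets = _toy_sets(n=3, grid=(32, 32, 32), T=2)
        est = ReferencePredictor(mode="velocity_weighted", depth=2,
                                 base_channels=4, patch_size=(16, 16, 16),
                                 batch_size=2, epochs=2, lr_constant_epochs=1,
                                 folds=3, seed=0)
        est.fit(sets)
        assert len(est.models_) == 3
        pred = est.predict(sets[0])
        assert pred.shape == (2, 2, 32, 32, 32)

    def test_sklearn_params_roundtrip(self):
        est = ReferencePredictor(epochs=7, seed=9)
        params = est.get_params()
        est2 = ReferencePredictor(**params)
        assert est2.get_params() == params
        est2.set_params(epochs=11)
        assert est2.epochs == 11

    def test_adversarial_touches_discriminator_weighted_does_not(self):
        _, sets = _toy_sets(n=1, grid=(32, 32, 32), T=2)
        kwargs = dict(depth=2, base_channels=4, patch_size=(16, 16, 16),
                      batch_size=1, epochs=2, lr_constant_epochs=1, folds=1,
                      seed=0)
        adv = ReferencePredictor(mode="adversarial", **kwargs).fit(sets)
        assert not np.isnan(adv.history_[0]["disc_loss"]).any()
        wtd = ReferencePredictor(mode="velocity_weighted", **kwargs).fit(sets)
        assert np.isnan(wtd.history_[0]["disc_loss"]).all()


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        models = [UNet3D(GeneratorConfig(depth=2, base_channels=4), rng=rng)
                  for _ in range(2)]
        p = tmp_path / "ck.npz"
        save_checkpoint(p, models, seed=5, extra={"mode": "adversarial"})
        loaded, meta = load_checkpoint(p)
        assert meta["seed"] == 5 and meta["n_folds"] == 2
        x = rng.normal(size=(1, 6, 8, 8, 8))
        for a, b in zip(models, loaded):
            assert np.allclose(a.forward(x), b.forward(x))


class TestConfigs:
    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            TrainConfig(mode="bogus")

    def test_epochs_vs_constant(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, lr_constant_epochs=20)

    def test_generator_full_scale_defaults(self):
        cfg = GeneratorConfig()
        assert cfg.depth == 5
        tc = TrainConfig()
        assert tc.patch_size == (64, 64, 32) and tc.batch_size == 8
        assert tc.epochs == 2500 and tc.lr == 0.002
        assert DiscriminatorConfig().n_layers == 4

    def test_encoding_set_to_arrays_channel_order(self, noiseless_encodings):
        from refless4dflow.recon import normalize_and_centralize

        pre = normalize_and_centralize(noiseless_encodings)
        inputs, target = encoding_set_to_arrays(pre)
        assert np.array_equal(inputs[0], pre.real[1])
        assert np.array_equal(inputs[1], pre.imag[1])
        assert np.array_equal(inputs[4], pre.real[3])
        assert np.array_equal(target[1], pre.imag[0])
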
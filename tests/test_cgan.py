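"""cGAN: losses, labels, architecture, training behaviour, LOOCV splits."""
import numpy as np
import pandas as pd
import pytest

from leafseq import cgan
from leafseq.preprocessing import DoseMap2D, TrainingSet


def toy_pairs(n=4, size=32, seed=0):
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame({
        "patient": [f"P{i % 2}" for i in range(n)],
        "fraction": [1 + i % 2 for i in range(n)],
        "beam": list(range(n)), "angle": [5.0] * n,
        "scale": [1.0] * n, "mu_scale": [1.0] * n, "n_segments": [1] * n})
    return TrainingSet(rng.random((n, size, size, 1)).astype(np.float32),
                       rng.random((n, size, size, 6)).astype(np.float32),
                       meta)


class TestLosses:
    def test_perfect_discriminator_with_hard_labels_has_zero_loss(self):
        real = np.ones((2, 1, 4, 4))
        fake = np.zeros((2, 1, 4, 4))
        loss = cgan.cgan_loss(real - 1e-9, fake + 1e-9)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_discriminator_scores_log2_per_term(self):
        half = np.full((2, 1, 4, 4), 0.5)
        assert cgan.cgan_loss(half, half) == pytest.approx(2 * np.log(2))
        assert cgan.binary_cross_entropy(half, np.ones_like(half)) == \
            pytest.approx(np.log(2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cgan.binary_cross_entropy(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_bce_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.05, 0.95, (2, 2))
        labels = rng.uniform(0.0, 1.2, (2, 2))
        grad = cgan.binary_cross_entropy_grad(scores, labels)
        eps = 1e-6
        for i in np.ndindex(scores.shape):
            sp = scores.copy(); sp[i] += eps
            sm = scores.copy(); sm[i] -= eps
            fd = (cgan.binary_cross_entropy(sp, labels)
                  - cgan.binary_cross_entropy(sm, labels)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4)

    def test_logits_form_matches_score_form(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(0, 2, (3, 5))
        labels = rng.uniform(0, 1.2, (3, 5))
        loss, _ = cgan._bce_logits(logits, labels)
        scores = 1.0 / (1.0 + np.exp(-logits))
        assert loss == pytest.approx(
            cgan.binary_cross_entropy(scores, labels), rel=1e-6)

    def test_generator_objective(self):
        assert cgan.generator_objective(0.7, 0.1, 0.0) == pytest.approx(0.7)
        assert cgan.generator_objective(0.7, 0.0, 100.0) == pytest.approx(0.7)
        base = cgan.generator_objective(0.5, 0.2, 50.0)
        doubled = cgan.generator_objective(0.5, 0.2, 100.0)
        assert doubled - 0.5 == pytest.approx(2 * (base - 0.5))


class TestLabels:
    def test_ranges_and_flips(self, rng):
        cfg = cgan.TrainConfig(label_flip=0.0)
        real = cgan.make_labels(rng, (64, 1, 4, 4), "real", cfg)
        fake = cgan.make_labels(rng, (64, 1, 4, 4), "fake", cfg)
        assert real.min() >= 0.8 and real.max() <= 1.2
        assert fake.min() >= 0.0 and fake.max() <= 0.2

    def test_flip_frequency_binomial(self, rng):
        cfg = cgan.TrainConfig(label_flip=0.05)
        n = 10_000
        flips = 0
        labels = cgan.make_labels(rng, (n, 1), "real", cfg)
        flips = int((labels < 0.5).sum())
        sigma = np.sqrt(n * 0.05 * 0.95)
        assert abs(flips - n * 0.05) < 3 * sigma

    def test_flip_probability_validated(self):
        with pytest.raises(ValueError, match="flip"):
            cgan.TrainConfig(label_flip=0.7)


class TestArchitecture:
    def test_generator_output_shape_and_determinism(self):
        cfg = cgan.TrainConfig(image_size=64, gen_filters=4, disc_filters=4,
                               seed=5)
        model = cgan.build_model(cfg)
        dm = DoseMap2D(np.random.default_rng(0).random((64, 64)), 1.0)
        dm.pixels /= dm.pixels.max()
        s1 = cgan.predict(model, dm)
        s2 = cgan.predict(model, dm)
        assert s1.channels.shape == (64, 64, 6)
        assert np.array_equal(s1.channels, s2.channels)
        assert s1.channels.min() >= 0.0

    def test_unnormalized_input_rejected(self):
        cfg = cgan.TrainConfig(image_size=64, gen_filters=4, disc_filters=4)
        model = cgan.build_model(cfg)
        with pytest.raises(ValueError, match="normalize"):
            cgan.predict(model, DoseMap2D(np.full((64, 64), 2.0), 1.0))

    def test_discriminator_emits_patch_grid(self):
        cfg = cgan.TrainConfig(image_size=64, gen_filters=4, disc_filters=4)
        model = cgan.build_model(cfg)
        x = np.zeros((1, 7, 64, 64), dtype=np.float32)
        out = model.discriminator.forward(x, train=False, rng=None)
        assert out.ndim == 4 and out.shape[2] > 1 and out.shape[3] > 1


class TestTraining:
    def test_smoke_one_epoch(self):
        pairs = toy_pairs()
        cfg = cgan.TrainConfig(epochs=1, image_size=32, gen_filters=4,
                               disc_filters=4, n_down=5, seed=0)
        model = cgan.train(pairs, None, cfg)
        assert len(model.history) == 1
        assert np.isfinite(model.history[["d_loss", "g_loss"]]).all().all()

    def test_loss_history_length_equals_epochs(self):
        pairs = toy_pairs()
        cfg = cgan.TrainConfig(epochs=3, image_size=32, gen_filters=4,
                               disc_filters=4, n_down=5, seed=0)
        model = cgan.train(pairs, None, cfg)
        assert len(model.history) == 3

    def test_training_is_seed_reproducible(self):
        pairs = toy_pairs()
        cfg = cgan.TrainConfig(epochs=2, image_size=32, gen_filters=4,
                               disc_filters=4, n_down=5, seed=9)
        m1 = cgan.train(pairs, None, cfg)
        m2 = cgan.train(pairs, None, cfg)
        for p1, p2 in zip(m1.generator.params(), m2.generator.params()):
            assert np.array_equal(p1.value, p2.value)
        assert m1.history.equals(m2.history)

    def test_empty_training_set_rejected(self):
        pairs = toy_pairs()
        split = cgan.CohortSplit("P0", np.array([], dtype=int),
                                 np.arange(4))
        with pytest.raises(cgan.TrainingError, match="empty"):
            cgan.train(pairs, split, cgan.TrainConfig(image_size=32))

    def test_memorizes_small_training_set(self, machine):
        """Overfit oracle: with the L1 term dominating, a small model
        must reproduce ten training targets almost exactly."""
        from leafseq import preprocessing as pp
        from leafseq import simulation as sim
        from leafseq.core import Grid3
        half = 31 * 5.0 / 2.0
        grid = Grid3((32, 32, 32), (5.0,) * 3, (-half,) * 3)
        cohort = sim.sample_cohort(17, machine, n_patients=1, n_fractions=1,
                                   grid_spec=grid)
        pairs = pp.build_training_pairs(cohort, shape=(32, 32))
        pairs = pairs.subset(np.arange(10))
        cfg = cgan.TrainConfig(epochs=120, image_size=32, gen_filters=8,
                               disc_filters=8, n_down=5, seed=2)
        model = cgan.train(pairs, None, cfg)
        maes = []
        for i in range(10):
            st = cgan.predict(model, DoseMap2D(pairs.inputs[i, :, :, 0], 1.0))
            maes.append(np.abs(st.channels - pairs.targets[i]).mean())
        assert np.mean(maes) < 0.05

    def test_checkpoint_roundtrip(self, tmp_path):
        pairs = toy_pairs()
        cfg = cgan.TrainConfig(epochs=1, image_size=32, gen_filters=4,
                               disc_filters=4, n_down=5, seed=0)
        model = cgan.train(pairs, None, cfg)
        model.save(tmp_path / "ckpt")
        back = cgan.TrainedModel.load(tmp_path / "ckpt")
        dm = DoseMap2D(pairs.inputs[0, :, :, 0], 1.0)
        assert np.array_equal(cgan.predict(model, dm).channels,
                              cgan.predict(back, dm).channels)


class TestLoocvSplits:
    def make_meta(self, n_patients=10, n_fractions=5, n_beams=11):
        rows = []
        for p in range(n_patients):
            for f in range(1, n_fractions + 1):
                for b in range(n_beams):
                    rows.append({"patient": f"P{p:02d}", "fraction": f,
                                 "beam": b})
        return pd.DataFrame(rows)

    def test_one_split_per_patient_with_44_test_beams(self):
        meta = self.make_meta()
        splits = cgan.make_loocv_splits(meta)
        assert len(splits) == 10
        for s in splits:
            assert s.test_idx.size == 44
            held = meta.iloc[s.test_idx]
            assert set(held["patient"]) == {s.held_out_patient}
            assert s.retained_fraction not in set(held["fraction"])

    def test_train_and_test_partition_cohort(self):
        meta = self.make_meta(n_patients=3)
        for s in cgan.make_loocv_splits(meta):
            joint = np.concatenate([s.train_idx, s.test_idx])
            assert np.array_equal(np.sort(joint), np.arange(len(meta)))

    def test_single_fraction_patient_rejected(self):
        meta = self.make_meta(n_patients=2, n_fractions=1)
        with pytest.raises(cgan.TrainingError, match="fraction"):
            cgan.make_loocv_splits(meta)
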
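"""Surrogate forecasting network: construction, rollout, training, metrics."""

import numpy as np
import pytest
from scipy.stats import wilcoxon

from epmodkit.surrogate import (SurrogateConfig, aggregate_mse, build,
                                crossvalidate, evaluate, load_checkpoint,
                                save_checkpoint, train)


class TestConfig:
    def test_default_architecture_matches_reference(self):
        cfg = SurrogateConfig()
        assert cfg.encoder_channels == (64, 32, 32)
        assert cfg.lstm_channels == 32
        assert cfg.decoder_channels[:2] == (32, 64)
        assert cfg.k_out == 11
        assert cfg.latent_size == 8  # 64 / 2^3

    @pytest.mark.parametrize("bad", [dict(kt=8), dict(kb=4), dict(kt=0),
                                     dict(frame_size=20)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SurrogateConfig(**bad)


class TestBuildAndRollout:
    def test_same_seed_gives_identical_weights(self, tiny_surrogate_config):
        a = build(tiny_surrogate_config, 5)
        b = build(tiny_surrogate_config, 5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_rollout_shape_and_finiteness_untrained(self, tiny_surrogate_config):
        model = build(tiny_surrogate_config, 0)
        x = np.random.default_rng(0).standard_normal((3, 16, 16))
        out = model.predict_rollout(x)
        assert out.shape == (tiny_surrogate_config.k_out, 16, 16)
        assert np.all(np.isfinite(out))

    def test_wrong_input_count_rejected(self, tiny_surrogate_config):
        model = build(tiny_surrogate_config, 0)
        with pytest.raises(ValueError, match="expected"):
            model.predict_rollout(np.zeros((2, 16, 16)))

    def test_zero_sequence_rolls_out_to_zero_after_training(self,
                                                            tiny_surrogate_config):
        model = build(tiny_surrogate_config, 1)
        sims = np.zeros((2, 8, 16, 16))
        train(model, sims, tiny_surrogate_config, rng=1)
        out = model.predict_rollout(sims[0][:3])
        assert float(np.mean(out**2)) < 1e-6


class TestTraining:
    def test_loss_decreases_on_toy_archive(self, tiny_surrogate_config, toy_sims):
        model = build(tiny_surrogate_config, 2)
        cfg = tiny_surrogate_config
        train(model, toy_sims, cfg, rng=2)
        assert model.train_log[-1]["train_mse"] < model.train_log[0]["train_mse"]

    def test_seeded_training_reproducible(self, tiny_surrogate_config, toy_sims):
        logs = []
        for _ in range(2):
            m = build(tiny_surrogate_config, 3)
            train(m, toy_sims, tiny_surrogate_config, rng=3)
            logs.append([l["train_mse"] for l in m.train_log])
        np.testing.assert_array_equal(logs[0], logs[1])

    def test_short_archive_rejected(self, tiny_surrogate_config):
        model = build(tiny_surrogate_config, 0)
        with pytest.raises(ValueError, match="frames"):
            train(model, np.zeros((4, 5, 16, 16)), tiny_surrogate_config)

    def test_checkpoint_round_trip(self, tiny_surrogate_config, toy_sims,
                                   tmp_path):
        model = build(tiny_surrogate_config, 4)
        train(model, toy_sims[:4], tiny_surrogate_config, rng=4)
        path = str(tmp_path / "m.npz")
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        x = toy_sims[0][:3]
        np.testing.assert_allclose(clone.predict_rollout(x),
                                   model.predict_rollout(x))


class TestEvaluate:
    def test_perfect_predictions_give_zero_errors(self, tiny_surrogate_config,
                                                  toy_sims):
        # a static sequence makes the last-input baseline exact
        static = np.repeat(toy_sims[:5, :1], 8, axis=1)
        model = build(tiny_surrogate_config, 0)
        m = evaluate(model, static)
        np.testing.assert_allclose(m.baseline_mse_per_sim, 0.0, atol=1e-30)

    def test_signed_rank_convention_is_two_sided_exact(self):
        # 20 pairs, one side strictly better (distinct margins so the exact
        # null enumeration applies) -> p = 2 * 2^-20
        x = np.arange(1.0, 21.0)
        p = wilcoxon(x, x + np.linspace(0.5, 1.5, 20),
                     alternative="two-sided").pvalue
        assert p == pytest.approx(2 * 2.0**-20, rel=1e-9)

    def test_empty_test_set_rejected(self, tiny_surrogate_config):
        model = build(tiny_surrogate_config, 0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, np.zeros((0, 8, 16, 16)))

    def test_nmse_zero_for_exact_prediction(self, tiny_surrogate_config,
                                            toy_sims):
        model = build(tiny_surrogate_config, 0)
        m = evaluate(model, toy_sims)
        assert np.all(np.isfinite(m.nmse_per_step))
        assert np.all(m.nmse_per_step >= 0)


class TestCrossValidation:
    def test_each_simulation_in_exactly_one_test_fold(self,
                                                      tiny_surrogate_config,
                                                      toy_sims):
        cfg = tiny_surrogate_config
        results, folds = crossvalidate(toy_sims[:10], cfg, rng=0)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(10))
        agg = aggregate_mse(results, folds)
        manual = sum(r.mse * len(f) for r, f in zip(results, folds)) / 10
        assert agg == pytest.approx(manual)

    def test_more_folds_than_sims_rejected(self, tiny_surrogate_config,
                                           toy_sims):
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(toy_sims[:3], tiny_surrogate_config)
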
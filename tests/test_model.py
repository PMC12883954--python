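"""FAT-Net architecture contracts, training loop, attention extraction."""


import numpy as np
import pytest

from fatnet import nn
from fatnet.datasets import SampleSet, build_samples
from fatnet.model import (FATNet, FATNetModule, FATNetResults, FatNetConfig,
                          penalized_loss)
from fatnet.score import score_cohort


def tiny_config(**over):
    base = dict(T=16, d_ts=2, d_ds=6, h=16, n_heads=4, batch_size=8,
                max_epochs=3, patience=2, ffn_dims=(32, 32), head_dim=16)
    base.update(over)
    return FatNetConfig(**base)


def toy_samples(rng, n=48, T=16, d_ds=6, split="train", linear_target=False):
    X_ts = rng.normal(size=(n, T, 2))
    X_ts[:, :, 1] = (X_ts[:, :, 1] > 0).astype(float)
    X_ds = rng.normal(size=(n, d_ds))
    y = X_ds[:, 0] - 0.5 * X_ds[:, 1] if linear_target else rng.normal(size=n)
    pids = np.array([f"{split}-{i % 6}" for i in range(n)])
    return SampleSet(X_ts=X_ts, X_ds=X_ds, y=y, participant_id=pids,
                     day_index=np.arange(n), feature_names=list("abcdef"),
                     split=split)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,match", [
        (dict(h=15), "even"),
        (dict(h=16, n_heads=3), "divide"),
        (dict(T=2), "kernel"),
        (dict(conv_dropout=1.0), "conv_dropout"),
        (dict(lr=0.0), "lr"),
        (dict(conv_filters=(8, 8)), "align"),
    ])
    def test_invalid(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            FatNetConfig(**kwargs)


class TestShapes:
    @pytest.mark.parametrize("T,d_ds,h,n_heads", [
        (8, 4, 8, 2), (16, 6, 16, 4), (24, 19, 32, 4)])
    def test_shape_contract(self, rng, T, d_ds, h, n_heads):
        cfg = FatNetConfig(T=T, d_ds=d_ds, h=h, n_heads=n_heads,
                           ffn_dims=(16, 16), head_dim=8)
        m = FATNetModule(cfg, rng)
        m.eval()
        B = 3
        x_ts = nn.Tensor(rng.normal(size=(B, T, 2)).astype(np.float32))
        h0 = m.conv_stack(x_ts)
        assert h0.shape == (B, T, cfg.conv_filters[-1])
        h_ts = m.temporal_encode(h0)
        assert h_ts.shape == (B, T, h)
        v_ts, u = m.self_attention_pool(h_ts)
        assert v_ts.shape == (B, h) and u.shape == (B, T, h)
        x_ds = nn.Tensor(rng.normal(size=(B, d_ds)).astype(np.float32))
        v_ds, tokens = m.summary_encode(x_ds)
        assert v_ds.shape == (B, h) and tokens.shape == (B, d_ds, h)
        f = m.cross_modal_fuse(v_ts, v_ds, u, tokens)
        assert f.shape == (B, 2 * h)
        y = m.predict_head(f)
        assert y.shape == (B,)

    def test_forward_finite_on_zero_input(self, rng):
        m = FATNetModule(tiny_config(), rng)
        m.eval()
        out = m(np.zeros((2, 16, 2)), np.zeros((2, 6)))
        assert np.all(np.isfinite(out.data))


class TestAttentionProperties:
    def test_rows_stochastic_everywhere(self, rng):
        m = FATNetModule(tiny_config(), rng)
        m.eval()
        m(rng.normal(size=(2, 16, 2)), rng.normal(size=(2, 6)))
        maps = m.attention_maps()
        assert np.allclose(maps.self_attention.sum(axis=-1), 1.0, atol=1e-5)
        assert np.allclose(maps.cross_attention.sum(axis=-1), 1.0, atol=1e-5)
        assert maps.summary_attention.sum() == pytest.approx(1.0, abs=1e-5)
        assert maps.self_attention.min() >= 0

    def test_single_step_attention_is_one(self, rng):
        """T=1 keys: every attention weight is exactly 1."""
        cfg = tiny_config()
        m = FATNetModule(cfg, rng)
        m.eval()
        h_ts = nn.Tensor(rng.normal(size=(2, 1, cfg.h)).astype(np.float32))
        v, u = m.self_attention_pool(h_ts)
        assert np.allclose(m.self_attn.last_weights, 1.0)
        assert np.allclose(v.data, u.data[:, 0, :])

    def test_mean_pool_of_constant_rows(self, rng):
        cfg = tiny_config()
        m = FATNetModule(cfg, rng)
        m.eval()
        row = rng.normal(size=(1, 1, cfg.h)).astype(np.float32)
        h_ts = nn.Tensor(np.repeat(row, 5, axis=1))
        v, u = m.self_attention_pool(h_ts)
        assert np.allclose(v.data, u.data[:, 0, :], atol=1e-5)

    def test_token_locality(self, rng):
        """Doubling one summary feature rescales only its token row."""
        cfg = tiny_config()
        m = FATNetModule(cfg, rng)
        m.eval()
        x = rng.normal(size=(1, cfg.d_ds)).astype(np.float32)
        _, tok1 = m.summary_encode(nn.Tensor(x.copy()))
        x2 = x.copy()
        x2[0, 2] *= 2.0
        _, tok2 = m.summary_encode(nn.Tensor(x2))
        diff = np.abs(tok1.data - tok2.data).sum(axis=-1)[0]
        assert diff[2] > 0
        assert np.allclose(np.delete(diff, 2), 0.0, atol=1e-7)


class TestHeadAndLoss:
    def test_zero_weights_give_bias(self, rng):
        m = FATNetModule(tiny_config(), rng)
        m.eval()
        m.head2.W.data[:] = 0.0
        m.head2.b.data[:] = 1.75
        out = m(rng.normal(size=(4, 16, 2)), rng.normal(size=(4, 6)))
        assert np.allclose(out.data, 1.75, atol=1e-6)

    def test_penalized_loss_values(self):
        y = np.array([1.0, 2.0])
        assert penalized_loss(y, y) == 0.0
        assert penalized_loss(y + 1.0, y) == pytest.approx(1.0)
        theta = [nn.Tensor(np.full(100, 1.0), requires_grad=True)]
        assert penalized_loss(y, y, theta, 1e-5) == pytest.approx(1e-3)
        with pytest.raises(ValueError):
            penalized_loss(np.array([]), np.array([]))

    def test_eval_determinism(self, rng):
        m = FATNetModule(tiny_config(), rng)
        m.eval()
        X_ts, X_ds = rng.normal(size=(3, 16, 2)), rng.normal(size=(3, 6))
        assert np.array_equal(m(X_ts, X_ds).data, m(X_ts, X_ds).data)


class TestTraining:
    def test_learnability_on_linear_target(self, rng):
        """Noiseless linear-in-summaries target: val MAE falls below the
        untrained baseline within the epoch budget."""
        train = toy_samples(rng, n=96, split="train", linear_target=True)
        val = toy_samples(rng, n=32, split="val", linear_target=True)
        cfg = tiny_config(max_epochs=30, patience=30, lr=3e-3)
        model = FATNet(train, val, cfg)
        res = model.fit(seed=0)
        untrained = np.mean(np.abs(val.y - train.y.mean()))
        assert res.val_mae < untrained * 0.8

    def test_seed_reproducibility_and_variation(self, rng):
        train = toy_samples(rng, n=32, split="train")
        val = toy_samples(rng, n=16, split="val")
        cfg = tiny_config(max_epochs=2)
        r1 = FATNet(train, val, cfg).fit(seed=1)
        r1b = FATNet(train, val, cfg).fit(seed=1)
        r2 = FATNet(train, val, cfg).fit(seed=2)
        assert r1.history["train_mse"].tolist() == r1b.history["train_mse"].tolist()
        assert r1.history["train_mse"].tolist() != r2.history["train_mse"].tolist()
        assert np.isfinite(r1.history["train_mse"]).all()

    def test_early_stopping_contract(self, rng):
        """Pure-noise target: patience exhausts before max_epochs."""
        train = toy_samples(rng, n=40, split="train")
        val = toy_samples(rng, n=16, split="val")
        cfg = tiny_config(max_epochs=50, patience=3, lr=3e-3)
        res = FATNet(train, val, cfg).fit(seed=0)
        assert res.n_epochs < cfg.max_epochs
        assert res.best_epoch < res.n_epochs - 1

    def test_leakage_guard_on_shared_participants(self, rng):
        train = toy_samples(rng, n=24, split="train")
        val = toy_samples(rng, n=12, split="train")  # same id prefix
        with pytest.raises(ValueError, match="span train and val"):
            FATNet(train, val, tiny_config())

    def test_empty_split_rejected(self, rng):
        s = toy_samples(rng, n=8)
        with pytest.raises(ValueError, match="non-empty"):
            FATNet(s.subset(np.array([], dtype=int)), s, tiny_config())


class TestResultsObject:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        train = toy_samples(rng, n=32, split="train")
        val = toy_samples(rng, n=16, split="val")
        return FATNet(train, val, tiny_config()).fit(seed=0), val

    def test_summary_mentions_key_facts(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "val MAE" in text and "AdamW" in text
        assert f"{res.module.n_parameters():,}" in text

    def test_predict_shape_and_determinism(self, fitted):
        res, val = fitted
        p1, p2 = res.predict(val), res.predict(val)
        assert p1.shape == (len(val),)
        assert np.array_equal(p1, p2)

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        res, val = fitted
        path = tmp_path / "model.ckpt"
        res.save(path)
        back = FATNetResults.load(path)
        assert np.allclose(back.predict(val), res.predict(val), atol=1e-7)
        assert back.config == res.config

    def test_attention_export_files(self, fitted, tmp_path):
        res, val = fitted
        maps = res.extract_attention(val, 0)
        maps.export(tmp_path, "s0")
        assert (tmp_path / "self_attn_s0.csv").exists()
        assert (tmp_path / "cross_attn_s0.csv").exists()


class TestPairBuilder:
    def test_next_day_alignment(self, small_cohort):
        from fatnet.preprocessing import refine_cohort
        refined, engineered, _ = refine_cohort(small_cohort)
        scores, _ = score_cohort(engineered)
        samples = build_samples(refined, engineered, scores)
        smap = scores.set_index(["participant_id", "day_index"])["equal_weight"]
        last_day = refined.daily.groupby("participant_id")["day_index"].max()
        for i in range(len(samples)):
            pid, day = samples.participant_id[i], samples.day_index[i]
            # target is exactly the next day's score of the same participant
            assert samples.y[i] == smap.loc[(pid, day + 1)]
            assert day < last_day[pid]  # last day never used as input
        # every sample's input minutes come from its own day
        assert len(samples) == len(refined.daily) - refined.daily[
            "participant_id"].nunique()

    def test_first_day_never_a_target_of_previous_participant(self, small_cohort):
        from fatnet.preprocessing import refine_cohort
        refined, engineered, _ = refine_cohort(small_cohort)
        scores, _ = score_cohort(engineered)
        samples = build_samples(refined, engineered, scores)
        assert (samples.day_index >= 0).all()
        # pairing never crosses participants: ids of inputs must exist with day+1
        keys = set(zip(refined.daily["participant_id"], refined.daily["day_index"]))
        for pid, day in zip(samples.participant_id, samples.day_index):
            assert (pid, day + 1) in keys
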
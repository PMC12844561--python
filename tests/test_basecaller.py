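import numpy as np
import pytest

import porecall as pc
from porecall._nn import warmup_cosine_lr
from porecall.basecaller import BasecallerNetwork, encode_target


@pytest.fixture(scope="module")
def tiny_net():
    cfg = pc.BasecallConfig.tiny(chunk_len=600)
    return cfg, BasecallerNetwork(cfg, seed=0)


class TestConfig:
    def test_frame_arithmetic(self):
        cfg = pc.BasecallConfig(chunk_len=6000, cumulative_stride=5)
        assert cfg.n_frames == 1200

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            pc.BasecallConfig(chunk_len=6001, cumulative_stride=5)
        with pytest.raises(ValueError):
            pc.BasecallConfig(n_classes=4)
        with pytest.raises(ValueError):
            pc.BasecallConfig(direction_mode="forwards")


class TestForward:
    def test_rows_sum_to_one(self, tiny_net, rng):
        cfg, net = tiny_net
        x = rng.normal(size=(600,)).astype(np.float32)
        call = pc.forward(x, net)
        assert call.probs.shape == (120, 5)
        assert np.allclose(call.probs.sum(axis=1), 1.0, atol=1e-5)
        assert (call.probs >= 0).all()

    def test_batch_order_independence(self, tiny_net, rng):
        cfg, net = tiny_net
        x = rng.normal(size=(4, 600)).astype(np.float32)
        a = net.forward(x, train=False)
        b = net.forward(x[::-1].copy(), train=False)
        assert np.allclose(a[:, 0, :], b[:, 3, :], atol=1e-6)

    def test_reverse_mode_runs_and_differs(self, rng):
        cfg = pc.BasecallConfig.tiny(chunk_len=600)
        bi = BasecallerNetwork(cfg, seed=0)
        cfg_rev = pc.BasecallConfig(
            chunk_len=600, conv_channels=cfg.conv_channels,
            conv_kernels=cfg.conv_kernels, cumulative_stride=5,
            lstm_layers=cfg.lstm_layers, lstm_hidden=cfg.lstm_hidden,
            direction_mode="reverse")
        rev = BasecallerNetwork(cfg_rev, seed=0)
        x = rng.normal(size=(1, 600)).astype(np.float32)
        assert rev.forward(x, train=False).shape == (120, 1, 5)
        assert not np.allclose(rev.forward(x, train=False),
                               bi.forward(x, train=False))

    def test_length_must_divide_stride(self, tiny_net, rng):
        cfg, net = tiny_net
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(1, 601)).astype(np.float32))

    def test_translation_consistency_on_periodic_input(self, tiny_net):
        """Shifting a periodic input by one stride shifts the argmax frame
        pattern (edge frames excluded)."""
        cfg, net = tiny_net
        base = np.tile(np.repeat([1.5, -1.5, 0.5, -0.5], 5), 600)[:600]
        shifted = np.roll(base, cfg.cumulative_stride)
        a = net.forward(base[None, :].astype(np.float32), train=False)
        b = net.forward(shifted[None, :].astype(np.float32), train=False)
        pa = a[:, 0, :].argmax(axis=1)
        pb = b[:, 0, :].argmax(axis=1)
        assert (pa[5:-5] == pb[6:-4]).mean() > 0.9


class TestSchedule:
    def test_warmup_endpoints(self):
        assert warmup_cosine_lr(0, 100, 10, 1e-3) == 0.0
        assert warmup_cosine_lr(10, 100, 10, 1e-3) == pytest.approx(1e-3)
        assert warmup_cosine_lr(100, 100, 10, 1e-3) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_monotone_decay_after_warmup(self):
        lrs = [warmup_cosine_lr(s, 100, 10, 1e-3) for s in range(10, 101)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestTraining:
    def _dataset(self, pore_model, n_reads=12, chunk_len=600):
        params = pc.SimParams(seed=5, open_pore_len=(100, 200))
        ref = pc.random_reference(4000, seed=6)
        reads, truths = pc.simulate_run(ref, n_reads, pore_model, params,
                                        read_len_range=(200, 400))
        return pc.make_basecall_training_set(reads, truths,
                                             chunk_len=chunk_len, overlap=100)[:2]

    def test_loss_halves_on_small_noise_free_set(self, pore_model):
        """Overfit sanity: training loss drops by >= 50% within 30 epochs on
        ~50 small chunks."""
        params = pc.SimParams(seed=5, noise_sd_pA=0.0, open_pore_len=(50, 80))
        ref = pc.random_reference(4000, seed=6)
        reads, truths = pc.simulate_run(ref, 25, pore_model, params,
                                        read_len_range=(150, 250))
        chunks, targets, frames = pc.make_basecall_training_set(
            reads, truths, chunk_len=600, overlap=100)
        chunks, targets = chunks[:50], targets[:50]
        cfg = pc.BasecallConfig.tiny(chunk_len=600)
        res = pc.BasecallerModel(chunks, targets, cfg).fit(
            pc.TrainConfig(batch_size=4, epochs=30, seed=0, lr=8e-3,
                           val_fraction=0.1))
        first = res.history[0]["train_loss"]
        last = min(h["train_loss"] for h in res.history)
        assert last <= 0.5 * first

    def test_same_seed_reproduces_epoch_losses(self, pore_model):
        chunks, targets = self._dataset(pore_model)
        tc = pc.TrainConfig(batch_size=8, epochs=1, seed=3)
        r1 = pc.BasecallerModel(chunks, targets,
                                pc.BasecallConfig.tiny(600)).fit(tc)
        r2 = pc.BasecallerModel(chunks, targets,
                                pc.BasecallConfig.tiny(600)).fit(tc)
        assert r1.history[0]["train_loss"] == r2.history[0]["train_loss"]

    def test_infeasible_examples_skipped_not_fatal(self, pore_model, rng):
        chunks = rng.normal(size=(6, 600)).astype(np.float32)
        targets = ["ACGT" * 10] * 5 + ["A" * 200]  # last is infeasible (120 frames)
        res = pc.BasecallerModel(
            chunks, targets, pc.BasecallConfig.tiny(600)
        ).fit(pc.TrainConfig(batch_size=6, epochs=1, seed=0, val_fraction=0.0))
        assert res.n_skipped >= 1

    def test_group_weighted_sampling_validates_lengths(self, pore_model):
        chunks, targets = self._dataset(pore_model)
        groups = np.zeros(len(chunks), dtype=int)
        groups[: len(chunks) // 2] = 1
        tc = pc.TrainConfig(batch_size=8, epochs=1, seed=0,
                            group_weights=(4.0, 2.0))
        res = pc.BasecallerModel(chunks, targets, pc.BasecallConfig.tiny(600),
                                 groups=groups).fit(tc)
        assert len(res.history) == 1
        with pytest.raises(ValueError):
            pc.BasecallerModel(
                chunks, targets, pc.BasecallConfig.tiny(600), groups=groups
            ).fit(pc.TrainConfig(epochs=1, group_weights=(1.0, 2.0, 3.0)))

    def test_checkpoint_round_trip_preserves_predictions(self, pore_model,
                                                         tmp_path):
        chunks, targets = self._dataset(pore_model)
        res = pc.BasecallerModel(chunks, targets,
                                 pc.BasecallConfig.tiny(600)).fit(
            pc.TrainConfig(batch_size=8, epochs=1, seed=0))
        path = tmp_path / "bc.npz"
        res.save(path)
        back = pc.BasecallerResults.load(path)
        a = res.predict(chunks[:3])
        b = back.predict(chunks[:3])
        for ca, cb in zip(a, b):
            assert np.allclose(ca.probs, cb.probs, atol=1e-6)


class TestEncodeTarget:
    def test_round_trip(self):
        assert encode_target("ACGT").tolist() == [1, 2, 3, 4]
        with pytest.raises(ValueError):
            encode_target("ACGN")
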
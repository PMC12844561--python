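import numpy as np
import pytest

import porecall as pc
from porecall.methcaller import MethNetwork, balance_classes, _stack_features


def synth_features(n, shift, rng, noise=1.0):
    """Toy features: signal-stats mean column carries a +-shift at the
    window center for positive labels."""
    feats, labels = [], []
    for i in range(n):
        y = int(rng.random() < 0.5)
        onehot = np.zeros((21, 4))
        bases = rng.integers(0, 4, size=21)
        bases[10], bases[11] = 1, 2  # CpG at the center
        onehot[np.arange(21), bases] = 1.0
        stats = np.zeros((21, 4))
        stats[:, 0] = rng.normal(0, noise, 21)
        stats[:, 1] = np.abs(rng.normal(1, .1, 21))
        stats[:, 2] = stats[:, 0]
        stats[:, 3] = rng.integers(5, 15, 21)
        if y:
            stats[8:13, 0] += shift
            stats[8:13, 2] += shift
        feats.append(pc.MethFeature("r", 10, onehot, stats))
        labels.append(y)
    return feats, np.array(labels)


class TestExtractFeatures:
    def test_noise_free_truth_spans_recover_pore_levels(self, pore_model):
        params = pc.SimParams(seed=2, noise_sd_pA=0.0, dwell_dispersion=0.0,
                              open_pore_len=100)
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        seq = seq[:25] + "CG" + seq[27:]
        raw, truth = pc.simulate_read(seq, None, pore_model, params)
        norm = pc.mad_normalize(raw.signal[100:], trim_start=100)
        spans = truth.base_spans - 100
        feats, skipped = pc.extract_features(seq, spans, norm.samples,
                                             positions=[25])
        assert skipped == 0 and len(feats) == 1
        f = feats[0]
        padded = "AA" + seq + "AA"
        for i, p in enumerate(range(15, 36)):
            level = pore_model.mean_level(padded[p : p + 5])
            want = (level - norm.median_pA) / norm.mad_pA
            assert f.signal_stats[i, 0] == pytest.approx(want, abs=1e-5)
            assert f.signal_stats[i, 1] == pytest.approx(0.0, abs=1e-5)
            assert f.signal_stats[i, 2] == pytest.approx(want, abs=1e-5)
            assert f.signal_stats[i, 3] == 10

    def test_window_truncation_skips_edge_sites(self):
        seq = "AAAAACGAAAAAAAAAAAAAAACGAAAAAAAAAAA"
        spans = np.stack([np.arange(len(seq)) * 10,
                          np.arange(1, len(seq) + 1) * 10], axis=1)
        samples = np.zeros(len(seq) * 10)
        feats, skipped = pc.extract_features(seq, spans, samples)
        assert skipped == 1  # site at position 5: window would truncate
        assert [f.position for f in feats] == [22]

    def test_every_feature_is_centered_on_cg(self, small_run):
        _, reads, truths, params = small_run
        raw, truth = reads[0], truths[0]
        norm_start = truth.base_spans[0, 0]
        samples = raw.signal[norm_start:]
        feats, _ = pc.extract_features(truth.sequence,
                                       truth.base_spans - norm_start, samples)
        for f in feats:
            assert truth.sequence[f.position : f.position + 2] == "CG"
            assert f.seq_onehot.sum(axis=1).tolist() == [1.0] * 21
            assert (f.signal_stats[:, 3] >= 1).all()

    def test_non_cpg_position_rejected(self):
        with pytest.raises(ValueError):
            pc.extract_features("A" * 30, np.zeros((30, 2)), np.zeros(10),
                                positions=[15])


class TestMethForward:
    def test_probabilities_sum_to_one_and_attention_normalized(self, rng):
        net = MethNetwork(pc.MethConfig(), seed=1)
        feats, _ = synth_features(4, 1.0, rng)
        x_seq, x_sig = _stack_features(feats)
        logits, alpha = net.forward(x_seq, x_sig, train=False)
        from porecall._nn import softmax
        p = softmax(logits, axis=-1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert np.allclose(alpha.sum(axis=0), 1.0, atol=1e-5)
        assert (alpha >= 0).all()
        p_um, p_m = pc.meth_forward(feats[0], net)
        assert p_um + p_m == pytest.approx(1.0, abs=1e-5)

    def test_signal_branch_is_live(self, rng):
        net = MethNetwork(pc.MethConfig(), seed=2)
        feats, _ = synth_features(1, 0.0, rng)
        p1 = pc.meth_forward(feats[0], net)
        feats[0].signal_stats[:, 0] += 2.0
        p2 = pc.meth_forward(feats[0], net)
        assert p1 != p2

    def test_deterministic_given_weights(self, rng):
        net = MethNetwork(pc.MethConfig(), seed=3)
        feats, _ = synth_features(1, 1.0, rng)
        assert pc.meth_forward(feats[0], net) == pc.meth_forward(feats[0], net)


class TestTraining:
    def test_balance_rule_downsamples_majority(self, rng):
        labels = np.array([1] * 300 + [0] * 100)
        idx = balance_classes(labels, rng)
        assert (labels[idx] == 1).sum() == 100
        assert (labels[idx] == 0).sum() == 100

    def test_single_class_rejected(self, rng):
        feats, _ = synth_features(10, 1.0, rng)
        with pytest.raises(ValueError):
            pc.MethylationModel(feats, np.ones(10, dtype=int)).fit()

    def test_separable_task_reaches_high_auc(self, rng):
        feats, labels = synth_features(600, 3.0, rng)
        res = pc.train_meth(feats, labels,
                            train_config=pc.MethTrainConfig(epochs=4, seed=0))
        assert res.test_metrics["auc_roc"] >= 0.95

    def test_null_task_auc_near_half(self, rng):
        aucs = []
        for seed in range(3):
            feats, labels = synth_features(400, 0.0, rng)
            res = pc.train_meth(
                feats, labels,
                train_config=pc.MethTrainConfig(epochs=2, seed=seed))
            aucs.append(res.test_metrics["auc_roc"])
        assert 0.3 <= float(np.mean(aucs)) <= 0.7

    def test_lr_decay_schedules(self, rng):
        """Linear mode ramps the rate down to 0.4x the initial value over
        the epochs; exponential mode multiplies by 0.4 each epoch."""
        feats, labels = synth_features(60, 2.0, rng)
        res = pc.train_meth(feats, labels,
                            train_config=pc.MethTrainConfig(epochs=3, seed=0))
        lrs = [h["lr"] for h in res.history]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[1] == pytest.approx(0.7e-3)
        assert lrs[2] == pytest.approx(0.4e-3)

        res = pc.train_meth(
            feats, labels,
            train_config=pc.MethTrainConfig(epochs=3, seed=0,
                                            decay_mode="exponential"))
        lrs = [h["lr"] for h in res.history]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[1] == pytest.approx(0.4e-3)
        assert lrs[2] == pytest.approx(0.16e-3)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        feats, labels = synth_features(80, 2.0, rng)
        res = pc.train_meth(feats, labels,
                            train_config=pc.MethTrainConfig(epochs=1, seed=0))
        path = tmp_path / "meth.npz"
        res.save(path)
        back = pc.MethylationResults.load(path)
        a = res.predict_proba(feats[:5])
        b = back.predict_proba(feats[:5])
        assert np.allclose(a, b)


class TestCallReadSites:
    def _trained(self, rng):
        feats, labels = synth_features(200, 3.0, rng)
        return pc.train_meth(feats, labels,
                             train_config=pc.MethTrainConfig(epochs=2, seed=0))

    def test_read_without_cg_yields_no_calls(self, rng):
        res = self._trained(rng)
        seq = "AT" * 20
        spans = np.stack([np.arange(40) * 5, np.arange(1, 41) * 5], axis=1)
        assert pc.call_read_sites(seq, spans, np.zeros(200), res) == []

    def test_calls_are_deterministic_and_threshold_strict(self, rng):
        res = self._trained(rng)
        seq = "A" * 12 + "CG" + "A" * 12
        spans = np.stack([np.arange(26) * 5, np.arange(1, 27) * 5], axis=1)
        samples = rng.normal(size=26 * 5)
        a = pc.call_read_sites(seq, spans, samples, res)
        b = pc.call_read_sites(seq, spans, samples, res)
        assert len(a) == 1
        assert (a[0].p_m, a[0].p_um) == (b[0].p_m, b[0].p_um)
        # threshold strictness: p_m exactly at threshold is unmethylated
        c = pc.call_read_sites(seq, spans, samples, res,
                               threshold=a[0].p_m)[0]
        assert c.label == 0
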
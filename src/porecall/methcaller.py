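"""Per-read CpG 5mC classification.

For every CpG whose 21-base window fits inside the read, two feature blocks
are extracted: one-hot encodings of the window sequence, and per-base summary
statistics of the normalized signal (mean, sd, median of the base's samples,
and its dwell).  Two BiLSTM branches process the blocks independently; their
per-position outputs are concatenated, an additive attention layer produces
normalized position weights and a context vector, a further BiLSTM summarises
the fused sequence, and two linear layers with a 2-way softmax emit the
unmethylated/methylated probabilities (P_um, P_m).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import Adam, BiLSTM, Linear, Parameter, ReLU, log_softmax, softmax
from ._nn.layers import _uniform
from .sim import cpg_positions

WINDOW_FLANK = 10  # 21-base window: c-10 .. c+10
N_SIGNAL_FEATURES = 4
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass
class MethFeature:
    """Features of one candidate CpG site in one read."""

    read_id: str
    position: int  # read coordinate of the CpG cytosine
    seq_onehot: np.ndarray  # (21, 4)
    signal_stats: np.ndarray  # (21, 4): mean, sd, median, dwell (samples)


@dataclass
class MethCall:
    """Per-read methylation probability at one CpG site."""

    read_id: str
    position: int
    p_um: float
    p_m: float
    label: int = 0  # binary call, strict p_m > threshold
    ref: str | None = None
    ref_pos: int | None = None
    strand: str = "+"


def extract_features(
    sequence: str,
    base_spans: np.ndarray,
    normalized_samples: np.ndarray,
    positions=None,
    read_id: str = "",
) -> tuple[list[MethFeature], int]:
    """Feature extraction around CpG sites of a read.

    ``base_spans`` maps base i to its half-open [start, end) span in
    ``normalized_samples`` (truth spans on synthetic reads, or decoder
    frames x stride on called reads).  ``positions`` defaults to every CG
    cytosine in ``sequence``.  Sites whose 21-base window would truncate at
    a read end are skipped; returns (features, n_skipped).
    """
    spans = np.asarray(base_spans)
    if spans.shape[0] != len(sequence):
        raise ValueError("base_spans length != sequence length")
    if positions is None:
        positions = cpg_positions(sequence)
    x = np.asarray(normalized_samples, dtype=np.float64)

    feats: list[MethFeature] = []
    skipped = 0
    for c in positions:
        c = int(c)
        if sequence[c : c + 2] != "CG":
            raise ValueError(f"position {c} is not the C of a CG")
        lo, hi = c - WINDOW_FLANK, c + WINDOW_FLANK
        if lo < 0 or hi >= len(sequence):
            skipped += 1
            continue
        window = sequence[lo : hi + 1]
        onehot = np.zeros((2 * WINDOW_FLANK + 1, 4))
        for i, b in enumerate(window):
            onehot[i, _BASE_INDEX[b]] = 1.0
        stats = np.zeros((2 * WINDOW_FLANK + 1, N_SIGNAL_FEATURES))
        for i, p in enumerate(range(lo, hi + 1)):
            s, e = int(spans[p, 0]), int(spans[p, 1])
            seg = x[s:e]
            stats[i] = (seg.mean(), seg.std(), np.median(seg), e - s)
        feats.append(MethFeature(read_id, c, onehot, stats))
    return feats, skipped


# =====================================================================
@dataclass
class MethConfig:
    hidden: int = 16
    attn_dim: int = 16
    mlp_hidden: int = 32
    window: int = 2 * WINDOW_FLANK + 1

    def __post_init__(self) -> None:
        if self.window != 2 * WINDOW_FLANK + 1:
            raise ValueError("window is fixed at 21 bases")


@dataclass
class MethTrainConfig:
    """Adam at lr 0.001 with a linear decay to ``lr_decay`` x the initial
    rate over the epochs (decay_mode="exponential" instead multiplies the
    rate by ``lr_decay`` each epoch)."""

    lr: float = 1e-3
    lr_decay: float = 0.4
    decay_mode: str = "linear"  # or "exponential"
    epochs: int = 12
    batch_size: int = 64
    clip_grad_norm: float = 1.0  # global-norm clip; 0 disables
    test_fraction: float = 0.1
    seed: int = 0

    def epoch_lr(self, epoch: int) -> float:
        if self.decay_mode == "exponential":
            return self.lr * self.lr_decay**epoch
        frac = epoch / max(self.epochs - 1, 1)
        return self.lr * (1.0 - (1.0 - self.lr_decay) * frac)


class MethNetwork:
    def __init__(self, config: MethConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden
        self.branch_seq = BiLSTM(4, h, rng)
        self.branch_sig = BiLSTM(N_SIGNAL_FEATURES, h, rng)
        d = 4 * h  # concatenated branch outputs per position
        self.Wa = Parameter(_uniform(rng, (d, config.attn_dim), d))
        self.ba = Parameter(np.zeros(config.attn_dim, dtype=np.float32))
        self.v = Parameter(_uniform(rng, (config.attn_dim,), config.attn_dim))
        self.post = BiLSTM(d, h, rng)
        self.fc1 = Linear(d + 2 * h, config.mlp_hidden, rng)
        self.act = ReLU()
        self.fc2 = Linear(config.mlp_hidden, 2, rng)

    def params(self):
        out = []
        for layer in (self.branch_seq, self.branch_sig, self.post, self.fc1,
                      self.fc2):
            out += layer.params()
        return out + [self.Wa, self.ba, self.v]

    # -------------------------------------------------------------- fwd
    def forward(self, x_seq: np.ndarray, x_sig: np.ndarray,
                train: bool = True):
        """x_seq (B,21,4), x_sig (B,21,4) -> (logits (B,2), attn (T,B))."""
        xa = np.ascontiguousarray(x_seq.transpose(1, 0, 2), dtype=np.float32)
        xb = np.ascontiguousarray(x_sig.transpose(1, 0, 2), dtype=np.float32)
        ha = self.branch_seq.forward(xa, train)
        hb = self.branch_sig.forward(xb, train)
        a = np.concatenate([ha, hb], axis=-1)  # (T,B,4h)

        u = np.tanh(a @ self.Wa.value + self.ba.value)  # (T,B,m)
        e = u @ self.v.value  # (T,B)
        alpha = softmax(e, axis=0)
        ctx = np.einsum("tb,tbd->bd", alpha, a)

        h2 = self.post.forward(a, train)  # (T,B,2h)
        h = self.config.hidden
        summary = np.concatenate([h2[-1, :, :h], h2[0, :, h:]], axis=-1)

        z = np.concatenate([ctx, summary], axis=-1)
        out = self.fc2.forward(self.act.forward(self.fc1.forward(z, train),
                                                train), train)
        self._cache = (a, u, alpha)
        return out, alpha

    def backward(self, dlogits: np.ndarray) -> None:
        a, u, alpha = self._cache
        h = self.config.hidden
        dz = self.fc1.backward(self.act.backward(self.fc2.backward(dlogits)))
        d = a.shape[-1]
        dctx, dsum = dz[:, :d], dz[:, d:]

        dh2 = np.zeros((a.shape[0], a.shape[1], 2 * h), dtype=np.float32)
        dh2[-1, :, :h] = dsum[:, :h]
        dh2[0, :, h:] = dsum[:, h:]
        da = self.post.backward(dh2)

        # attention backward
        dalpha = np.einsum("bd,tbd->tb", dctx, a)
        da = da + alpha[:, :, None] * dctx[None, :, :]
        de = alpha * (dalpha - (alpha * dalpha).sum(axis=0, keepdims=True))
        du = de[:, :, None] * self.v.value
        self.v.grad += (u * de[:, :, None]).sum(axis=(0, 1))
        dpre = (du * (1.0 - u * u)).astype(np.float32)
        T, B, m = dpre.shape
        self.Wa.grad += a.reshape(T * B, -1).T @ dpre.reshape(T * B, m)
        self.ba.grad += dpre.sum(axis=(0, 1))
        da = da + dpre @ self.Wa.value.T

        self.branch_seq.backward(da[..., : 2 * h])
        self.branch_sig.backward(da[..., 2 * h :])


def _stack_features(features: list[MethFeature]):
    x_seq = np.stack([f.seq_onehot for f in features]).astype(np.float32)
    x_sig = np.stack([f.signal_stats for f in features]).astype(np.float32)
    # dwell is on a different scale from the normalized-signal statistics
    x_sig[:, :, 3] = np.log1p(x_sig[:, :, 3])
    return x_seq, x_sig


def meth_forward(feature: MethFeature, network: MethNetwork):
    """(p_um, p_m) for one feature; also exposes the attention weights as
    ``meth_forward.last_attention`` for inspection."""
    x_seq, x_sig = _stack_features([feature])
    logits, alpha = network.forward(x_seq, x_sig, train=False)
    p = softmax(logits, axis=-1)[0]
    meth_forward.last_attention = alpha[:, 0]
    return float(p[0]), float(p[1])


def balance_classes(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices achieving a 1:1 class ratio by downsampling the majority."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required to balance")
    n = min(len(pos), len(neg))
    pos = rng.choice(pos, size=n, replace=False)
    neg = rng.choice(neg, size=n, replace=False)
    return np.sort(np.concatenate([pos, neg]))


class MethylationModel:
    """5mC classifier ready to fit to labeled MethFeatures."""

    def __init__(self, features: list[MethFeature], labels,
                 config: MethConfig | None = None):
        self.features = features
        self.labels = np.asarray(labels, dtype=np.int64)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        self.config = config or MethConfig()

    def fit(self, train_config: MethTrainConfig | None = None,
            verbose: bool = False) -> "MethylationResults":
        tc = train_config or MethTrainConfig()
        rng = np.random.default_rng(tc.seed)
        keep = balance_classes(self.labels, rng)
        x_seq, x_sig = _stack_features([self.features[i] for i in keep])
        y = self.labels[keep]

        perm = rng.permutation(len(y))
        n_test = max(1, int(round(tc.test_fraction * len(y))))
        test_idx, train_idx = perm[:n_test], perm[n_test:]

        net = MethNetwork(self.config, seed=tc.seed)
        opt = Adam(net.params(), lr=tc.lr)
        history = []
        for epoch in range(tc.epochs):
            lr = tc.epoch_lr(epoch)
            order = rng.permutation(train_idx)
            total, count = 0.0, 0
            for start in range(0, len(order), tc.batch_size):
                b = order[start : start + tc.batch_size]
                logits, _ = net.forward(x_seq[b], x_sig[b], train=True)
                logp = log_softmax(logits, axis=-1)
                loss = -logp[np.arange(len(b)), y[b]].mean()
                dlogits = softmax(logits, axis=-1)
                dlogits[np.arange(len(b)), y[b]] -= 1.0
                opt.zero_grad()
                net.backward((dlogits / len(b)).astype(np.float32))
                if tc.clip_grad_norm:
                    total = sum(
                        float(np.sum(p.grad.astype(np.float64) ** 2))
                        for p in net.params()
                    )
                    norm = np.sqrt(total)
                    if norm > tc.clip_grad_norm:
                        scale = np.float32(tc.clip_grad_norm / norm)
                        for p in net.params():
                            p.grad *= scale
                opt.step(lr)
                total += float(loss) * len(b)
                count += len(b)
            history.append({"epoch": epoch, "train_loss": total / count,
                            "lr": lr})
            if verbose:
                print(f"epoch {epoch}  loss {total / count:.4f}  lr {lr:.2e}")

        results = MethylationResults(net, self.config, tc, history)
        results.test_metrics = results._evaluate(
            x_seq[test_idx], x_sig[test_idx], y[test_idx]
        )
        return results


class MethylationResults:
    """Fitted methylation classifier with held-out test metrics."""

    def __init__(self, network: MethNetwork, config: MethConfig,
                 train_config, history):
        self.network = network
        self.config = config
        self.train_config = train_config
        self.history = history
        self.test_metrics: dict | None = None

    def predict_proba(self, features: list[MethFeature],
                      batch_size: int = 256) -> np.ndarray:
        """(n, 2) array of (P_um, P_m)."""
        x_seq, x_sig = _stack_features(features)
        out = []
        for start in range(0, len(features), batch_size):
            logits, _ = self.network.forward(
                x_seq[start : start + batch_size],
                x_sig[start : start + batch_size],
                train=False,
            )
            out.append(softmax(logits, axis=-1))
        return np.concatenate(out, axis=0)

    def _evaluate(self, x_seq, x_sig, y) -> dict:
        from .evalmetrics import prf1, roc_pr

        logits, _ = self.network.forward(x_seq, x_sig, train=False)
        p_m = softmax(logits, axis=-1)[:, 1]
        pred = (p_m > 0.5).astype(int)
        metrics = {"n_test": int(len(y))}
        if len(np.unique(y)) == 2:
            auc_roc, auc_pr, _ = roc_pr(y, p_m)
            metrics["auc_roc"] = auc_roc
            metrics["auc_pr"] = auc_pr
        if pred.sum() > 0:
            precision, recall, f1 = prf1(y, pred)
            metrics.update(precision=precision, recall=recall, f1=f1)
        return metrics

    def summary(self) -> str:
        lines = [
            "Methylation classifier fit summary",
            "=" * 54,
            f"branch hidden        : {self.config.hidden}",
            f"attention dim        : {self.config.attn_dim}",
            f"parameters           : "
            f"{sum(p.value.size for p in self.network.params())}",
            f"epochs run           : {len(self.history)}",
        ]
        if self.history:
            lines.append(
                f"train loss           : {self.history[0]['train_loss']:.4f}"
                f" -> {self.history[-1]['train_loss']:.4f}"
            )
        if self.test_metrics:
            for k, v in self.test_metrics.items():
                lines.append(f"test {k:<15} : "
                             f"{v:.4f}" if isinstance(v, float) else
                             f"test {k:<15} : {v}")
        return "\n".join(lines)

    # ---------------------------------------------------------------- IO
    def save(self, path) -> None:
        meta = {
            "format_version": CHECKPOINT_SCHEMA_VERSION,
            "kind": "methcaller",
            "config": asdict(self.config),
            "history": self.history,
            "test_metrics": self.test_metrics,
        }
        arrays = {
            f"param_{i:04d}": p.value for i, p in enumerate(self.network.params())
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "MethylationResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != CHECKPOINT_SCHEMA_VERSION:
                raise ValueError("unsupported checkpoint version")
            config = MethConfig(**meta["config"])
            net = MethNetwork(config, seed=0)
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"param_{i:04d}"]
            res = cls(net, config, None, meta["history"])
            res.test_metrics = meta.get("test_metrics")
            return res


def train_meth(features, labels, config: MethConfig | None = None,
               train_config: MethTrainConfig | None = None,
               verbose: bool = False) -> MethylationResults:
    """Functional wrapper: balance, split, fit, and report test metrics."""
    return MethylationModel(features, labels, config=config).fit(
        train_config, verbose=verbose
    )


def call_read_sites(
    sequence: str,
    base_spans: np.ndarray,
    normalized_samples: np.ndarray,
    results: MethylationResults,
    threshold: float = 0.5,
    read_id: str = "",
) -> list[MethCall]:
    """One MethCall per CpG of the read whose window fits; ``label`` on each
    call uses strict p_m > threshold."""
    feats, _ = extract_features(sequence, base_spans, normalized_samples,
                                read_id=read_id)
    if not feats:
        return []
    proba = results.predict_proba(feats)
    return [
        MethCall(read_id, f.position, float(p[0]), float(p[1]),
                 label=int(p[1] > threshold))
        for f, p in zip(feats, proba)
    ]
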
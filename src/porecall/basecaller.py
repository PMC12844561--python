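"""The basecalling network and its training loop.

Architecture: five 1-D convolutional layers (each with batch normalization
and ReLU; the last carries the temporal downsampling stride) followed by five
recurrent layers — bidirectional LSTMs by default, with a reverse-direction
single-LSTM mode also available — and a linear head producing per-frame
probabilities over {blank, A, C, G, T}.  Training minimises the CTC loss with
AdamW under a linear warm-up / cosine decay schedule.

The model surface follows the fit/results idiom: ``BasecallerModel(chunks,
targets, config).fit(train_config)`` returns a ``BasecallerResults`` holding
the trained weights, the per-epoch history, and prediction/IO methods.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import (
    AdamW,
    BatchNorm1d,
    BiLSTM,
    Conv1d,
    Linear,
    LSTM,
    ReLU,
    ctc_loss_grad,
    log_softmax,
    softmax,
    warmup_cosine_lr,
)

#: CTC class order: index 0 is the blank, 1..4 are the bases.
CLASS_BASES = "ACGT"
BASE_TO_CLASS = {b: i + 1 for i, b in enumerate(CLASS_BASES)}

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass
class BasecallConfig:
    """Architecture hyper-parameters.

    ``cumulative_stride`` is the total temporal downsampling of the conv
    stack (applied in the final conv layer), so a chunk of L samples yields
    L / cumulative_stride output frames.
    """

    chunk_len: int = 6000
    conv_channels: tuple[int, ...] = (16, 16, 32, 32, 64)
    conv_kernels: tuple[int, ...] = (5, 5, 5, 5, 5)
    cumulative_stride: int = 5
    lstm_layers: int = 5
    lstm_hidden: int = 96
    direction_mode: str = "bidirectional"  # or "reverse"
    residual: bool = True  # skip connections where layer widths match
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.n_classes != 5:
            raise ValueError("n_classes must be 5 (blank + ACGT)")
        if self.chunk_len % self.cumulative_stride:
            raise ValueError("chunk_len must be divisible by cumulative_stride")
        if len(self.conv_channels) != len(self.conv_kernels):
            raise ValueError("conv_channels and conv_kernels length mismatch")
        if self.direction_mode not in ("bidirectional", "reverse"):
            raise ValueError("direction_mode must be 'bidirectional' or 'reverse'")

    @property
    def n_frames(self) -> int:
        return self.chunk_len // self.cumulative_stride

    @classmethod
    def tiny(cls, chunk_len: int = 6000) -> "BasecallConfig":
        """Desk-scale preset used for CPU training runs."""
        return cls(
            chunk_len=chunk_len,
            conv_channels=(8, 16, 32, 32, 32),
            conv_kernels=(5, 5, 5, 5, 5),
            cumulative_stride=5,
            lstm_layers=5,
            lstm_hidden=32,
        )


@dataclass
class TrainConfig:
    """Optimisation settings: AdamW, initial lr after warm-up 0.001, linear
    warm-up followed by cosine decay.  ``group_weights`` optionally biases
    example sampling across dataset groups (e.g. species), by relative
    weight.

    ``pretrain_epochs`` > 0 prepends an alignment-bootstrap phase: frame-wise
    cross-entropy against a single valid CTC path derived from the known
    base->signal spans (first frame of each base labeled with the base, all
    other frames blank).  This is an upper bound of the CTC loss restricted
    to one alignment; the subsequent CTC epochs relax it to the full
    path-sum.  It requires frame targets (available for simulator-derived
    training sets) and shortens CPU training dramatically."""

    batch_size: int = 32
    lr: float = 1e-3
    epochs: int = 20
    pretrain_epochs: int = 0
    warmup_frac: float = 0.05
    weight_decay: float = 0.01
    clip_grad_norm: float = 1.0  # global-norm clip; 0 disables
    val_fraction: float = 0.1
    seed: int = 0
    group_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 <= self.warmup_frac < 1:
            raise ValueError("warmup_frac in [0, 1)")


@dataclass
class ChunkCall:
    """Per-frame class probabilities for one chunk (rows sum to 1)."""

    read_id: str
    probs: np.ndarray  # (T', 5), order (blank, A, C, G, T)
    signal_offset: int


def encode_target(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_TO_CLASS[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"target contains non-ACGT symbol {exc}") from None


def ctc_loss(probs: np.ndarray, target) -> float:
    """-log P(target | probs) summed over all CTC alignments, in nats.

    ``probs`` is a (T', 5) row-stochastic matrix; ``target`` a base string or
    an array of classes in 1..4.  Infeasible targets return +inf.
    """
    if isinstance(target, str):
        target = encode_target(target)
    logp = np.log(np.clip(np.asarray(probs, dtype=np.float64), 1e-300, None))
    loss, _ = ctc_loss_grad(logp, np.asarray(target, dtype=np.int64))
    return float(loss)


class BasecallerNetwork:
    """Stateless-forward network; holds parameters and layer caches."""

    def __init__(self, config: BasecallConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.conv_stack = []
        c_in = 1
        n_conv = len(config.conv_channels)
        for i, (c_out, k) in enumerate(zip(config.conv_channels, config.conv_kernels)):
            stride = config.cumulative_stride if i == n_conv - 1 else 1
            self.conv_stack += [
                Conv1d(c_in, c_out, k, stride, rng),
                BatchNorm1d(c_out),
                ReLU(),
            ]
            c_in = c_out
        self.rnn_stack = []
        n_in = c_in
        for _ in range(config.lstm_layers):
            if config.direction_mode == "bidirectional":
                layer = BiLSTM(n_in, config.lstm_hidden, rng)
                n_in = 2 * config.lstm_hidden
            else:
                layer = LSTM(n_in, config.lstm_hidden, rng, reverse=True)
                n_in = config.lstm_hidden
            self.rnn_stack.append(layer)
        self.head = Linear(n_in, config.n_classes, rng)

    def params(self):
        out = []
        for layer in self.conv_stack + self.rnn_stack + [self.head]:
            out += layer.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (B, L) -> logits (L / stride, B, 5).

        The conv and recurrent stacks are length-agnostic; any L divisible
        by the cumulative stride is accepted (training and inference chunk
        lengths may differ)."""
        if x.shape[1] % self.config.cumulative_stride:
            raise ValueError(
                f"chunk length {x.shape[1]} not divisible by stride "
                f"{self.config.cumulative_stride}"
            )
        h = np.ascontiguousarray(x, dtype=np.float32)[:, :, None]  # (B,L,1)
        for layer in self.conv_stack:
            h = layer.forward(h, train)
        h = np.ascontiguousarray(h.transpose(1, 0, 2))  # (T', B, C)
        self._skipped = []
        for layer in self.rnn_stack:
            out = layer.forward(h, train)
            skip = self.config.residual and out.shape == h.shape
            self._skipped.append(skip)
            h = out + h if skip else out
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        for layer, skip in zip(reversed(self.rnn_stack),
                               reversed(self._skipped)):
            d_in = layer.backward(d)
            d = d_in + d if skip else d_in
        d = np.ascontiguousarray(d.transpose(1, 0, 2))  # (B, T', C)
        for layer in reversed(self.conv_stack):
            d = layer.backward(d)

    # ------------------------------------------------------------- weights
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    def get_bn_state(self):
        return [
            (l.running_mean.copy(), l.running_var.copy())
            for l in self.conv_stack
            if isinstance(l, BatchNorm1d)
        ]

    def set_bn_state(self, state) -> None:
        bns = [l for l in self.conv_stack if isinstance(l, BatchNorm1d)]
        for l, (m, v) in zip(bns, state, strict=True):
            l.running_mean[...] = m
            l.running_var[...] = v


def forward(chunk_samples: np.ndarray, network: BasecallerNetwork,
            signal_offset: int = 0, read_id: str = "") -> ChunkCall:
    """Run one chunk through the network and return its probability matrix."""
    logits = network.forward(np.asarray(chunk_samples)[None, :], train=False)
    return ChunkCall(read_id, softmax(logits[:, 0, :], axis=-1), signal_offset)


class BasecallerModel:
    """Basecaller ready to fit to a set of (chunk, target) examples.

    Parameters
    ----------
    chunks : (N, chunk_len) array of normalized signal chunks.
    targets : length-N list of class arrays (1..4) or base strings.
    config : architecture; defaults to ``BasecallConfig()``.
    groups : optional length-N integer group label per example (e.g.
        species), used with ``TrainConfig.group_weights``.
    """

    def __init__(self, chunks, targets, config: BasecallConfig | None = None,
                 groups=None, frame_targets=None):
        self.chunks = np.asarray(chunks, dtype=np.float32)
        if self.chunks.ndim != 2:
            raise ValueError("chunks must be a 2-D (N, chunk_len) array")
        self.targets = [
            encode_target(t) if isinstance(t, str) else np.asarray(t, np.int64)
            for t in targets
        ]
        if len(self.targets) != len(self.chunks):
            raise ValueError("chunks and targets length mismatch")
        if len(self.targets) == 0:
            raise ValueError("empty training set")
        self.config = config or BasecallConfig(chunk_len=self.chunks.shape[1])
        self.groups = None if groups is None else np.asarray(groups)
        self.frame_targets = None
        if frame_targets is not None:
            if len(frame_targets) != len(self.chunks):
                raise ValueError("frame_targets length mismatch")
            self.frame_targets = np.asarray(frame_targets, dtype=np.int64)

    def fit(self, train_config: TrainConfig | None = None,
            verbose: bool = False) -> "BasecallerResults":
        tc = train_config or TrainConfig()
        rng = np.random.default_rng(tc.seed)
        net = BasecallerNetwork(self.config, seed=tc.seed)
        opt = AdamW(net.params(), lr=tc.lr, weight_decay=tc.weight_decay)

        n = len(self.chunks)
        perm = rng.permutation(n)
        n_val = max(1, int(round(tc.val_fraction * n))) if n > 1 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = perm, perm[:0]

        if tc.pretrain_epochs > 0 and self.frame_targets is None:
            raise ValueError("pretrain_epochs > 0 requires frame_targets")
        self._train_config_clip = tc.clip_grad_norm
        steps_per_epoch = math.ceil(len(train_idx) / tc.batch_size)
        total_epochs = tc.epochs + tc.pretrain_epochs
        total_steps = total_epochs * steps_per_epoch
        warmup_steps = int(round(tc.warmup_frac * total_steps))

        history = []
        best = (np.inf, net.get_weights(), net.get_bn_state())
        step = 0
        n_skipped = 0
        for epoch in range(total_epochs):
            bootstrap = epoch < tc.pretrain_epochs
            order = self._epoch_order(train_idx, rng, tc)
            epoch_loss, epoch_items = 0.0, 0
            for start in range(0, len(order), tc.batch_size):
                batch = order[start : start + tc.batch_size]
                lr = warmup_cosine_lr(step, total_steps, warmup_steps, tc.lr)
                if bootstrap:
                    loss, skipped = self._step_framewise(net, opt, batch, lr)
                else:
                    loss, skipped = self._step(net, opt, batch, lr)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (loss={loss}) at epoch {epoch}, "
                        f"step {step}"
                    )
                epoch_loss += loss * (len(batch) - skipped)
                epoch_items += len(batch) - skipped
                n_skipped += skipped
                step += 1
            val_loss = self._eval_loss(net, val_idx) if len(val_idx) else np.nan
            rec = {
                "epoch": epoch,
                "phase": "bootstrap" if bootstrap else "ctc",
                "train_loss": epoch_loss / max(epoch_items, 1),
                "val_loss": val_loss,
                "lr": lr,
            }
            history.append(rec)
            if verbose:
                print(
                    f"epoch {epoch:3d} [{rec['phase']}]  "
                    f"train {rec['train_loss']:.4f}  "
                    f"val {val_loss:.4f}  lr {lr:.2e}"
                )
            # validation is always the CTC loss, so bootstrap and CTC epochs
            # compete for the checkpoint on the same scale
            score = val_loss if np.isfinite(val_loss) else rec["train_loss"]
            if score < best[0]:
                best = (score, net.get_weights(), net.get_bn_state())
        net.set_weights(best[1])
        net.set_bn_state(best[2])
        return BasecallerResults(net, self.config, tc, history,
                                 n_skipped=n_skipped)

    # ------------------------------------------------------------------
    def _epoch_order(self, train_idx, rng, tc):
        if tc.group_weights is None or self.groups is None:
            return rng.permutation(train_idx)
        groups = self.groups[train_idx]
        uniq = np.unique(groups)
        w = np.asarray(tc.group_weights, dtype=float)
        if len(w) != len(uniq):
            raise ValueError("group_weights length != number of groups")
        per_example = np.zeros(len(train_idx))
        for g, wg in zip(uniq, w):
            mask = groups == g
            per_example[mask] = wg / mask.sum()
        per_example /= per_example.sum()
        return rng.choice(train_idx, size=len(train_idx), p=per_example)

    def _step(self, net, opt, batch, lr):
        x = self.chunks[batch]
        logits = net.forward(x, train=True)  # (T', B, 5)
        logp = log_softmax(logits.astype(np.float64), axis=-1)
        probs = np.exp(logp)
        dlogits = np.zeros_like(logits, dtype=np.float64)
        total, skipped = 0.0, 0
        for j, idx in enumerate(batch):
            loss, gamma = ctc_loss_grad(logp[:, j, :], self.targets[idx])
            if not np.isfinite(loss):
                skipped += 1  # infeasible target for this chunk; leave grad 0
                continue
            dlogits[:, j, :] = probs[:, j, :] - gamma
            total += loss
        n_eff = max(len(batch) - skipped, 1)
        opt.zero_grad()
        net.backward((dlogits / n_eff).astype(np.float32))
        self._clip(net)
        opt.step(lr)
        return total / n_eff, skipped

    def _clip(self, net) -> None:
        limit = self._train_config_clip
        if not limit:
            return
        total = 0.0
        params = net.params()
        for p in params:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
        norm = np.sqrt(total)
        if norm > limit:
            scale = np.float32(limit / norm)
            for p in params:
                p.grad *= scale

    def _step_framewise(self, net, opt, batch, lr):
        """Cross-entropy against the span-derived CTC path (bootstrap)."""
        x = self.chunks[batch]
        yt = self.frame_targets[batch].T  # (T', B)
        logits = net.forward(x, train=True)
        logp = log_softmax(logits.astype(np.float64), axis=-1)
        nll = -np.take_along_axis(logp, yt[:, :, None], axis=2)[:, :, 0]
        loss = float(nll.sum()) / len(batch)  # per-chunk sum, CTC-like scale
        dlogits = np.exp(logp)
        np.put_along_axis(
            dlogits, yt[:, :, None],
            np.take_along_axis(dlogits, yt[:, :, None], axis=2) - 1.0, axis=2,
        )
        opt.zero_grad()
        net.backward((dlogits / len(batch)).astype(np.float32))
        self._clip(net)
        opt.step(lr)
        return loss, 0

    def _eval_loss(self, net, idx):
        total, count = 0.0, 0
        for start in range(0, len(idx), 32):
            batch = idx[start : start + 32]
            logits = net.forward(self.chunks[batch], train=False)
            logp = log_softmax(logits.astype(np.float64), axis=-1)
            for j, i in enumerate(batch):
                loss, _ = ctc_loss_grad(logp[:, j, :], self.targets[i])
                if np.isfinite(loss):
                    total += loss
                    count += 1
        return total / max(count, 1)


class BasecallerResults:
    """Fitted basecaller: weights, training history, prediction and IO."""

    def __init__(self, network: BasecallerNetwork, config: BasecallConfig,
                 train_config: TrainConfig | None, history: list[dict],
                 n_skipped: int = 0):
        self.network = network
        self.config = config
        self.train_config = train_config
        self.history = history
        self.n_skipped = n_skipped

    # ------------------------------------------------------------ predict
    def predict(self, chunks, read_ids=None, signal_offsets=None,
                batch_size: int = 32) -> list[ChunkCall]:
        """Probability matrices for a batch of chunks (N, chunk_len)."""
        x = np.asarray(chunks, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        n = len(x)
        read_ids = read_ids or [""] * n
        signal_offsets = signal_offsets if signal_offsets is not None else [0] * n
        calls = []
        for start in range(0, n, batch_size):
            logits = self.network.forward(x[start : start + batch_size], train=False)
            p = softmax(logits, axis=-1)
            for j in range(logits.shape[1]):
                i = start + j
                calls.append(ChunkCall(read_ids[i], p[:, j, :], signal_offsets[i]))
        return calls

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(p.value.size for p in self.network.params())
        lines = [
            "Basecaller fit summary",
            "=" * 54,
            f"conv channels        : {cfg.conv_channels}",
            f"recurrent layers     : {cfg.lstm_layers} x {cfg.direction_mode} "
            f"(hidden {cfg.lstm_hidden})",
            f"frames per chunk     : {cfg.n_frames} "
            f"(chunk {cfg.chunk_len} / stride {cfg.cumulative_stride})",
            f"parameters           : {n_params}",
            f"epochs run           : {len(self.history)}",
            f"infeasible examples  : {self.n_skipped} (skipped)",
        ]
        if self.history:
            first, last = self.history[0], self.history[-1]
            best = min(h["val_loss"] for h in self.history)
            lines += [
                f"train loss           : {first['train_loss']:.4f} -> "
                f"{last['train_loss']:.4f}",
                f"best val loss        : {best:.4f}",
            ]
        return "\n".join(lines)

    # ---------------------------------------------------------------- IO
    def save(self, path) -> None:
        """Single-archive checkpoint: config JSON + weight arrays."""
        meta = {
            "format_version": CHECKPOINT_SCHEMA_VERSION,
            "kind": "basecaller",
            "config": asdict(self.config),
            "history": self.history,
            "n_skipped": self.n_skipped,
        }
        arrays = {
            f"param_{i:04d}": p.value for i, p in enumerate(self.network.params())
        }
        for i, (m, v) in enumerate(self.network.get_bn_state()):
            arrays[f"bn_mean_{i:02d}"] = m
            arrays[f"bn_var_{i:02d}"] = v
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "BasecallerResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != CHECKPOINT_SCHEMA_VERSION:
                raise ValueError("unsupported checkpoint version")
            config = BasecallConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["config"].items()
            })
            net = BasecallerNetwork(config, seed=0)
            weights = [
                data[f"param_{i:04d}"] for i in range(len(net.params()))
            ]
            net.set_weights(weights)
            n_bn = len(net.get_bn_state())
            net.set_bn_state([
                (data[f"bn_mean_{i:02d}"], data[f"bn_var_{i:02d}"])
                for i in range(n_bn)
            ])
            return cls(net, config, None, meta["history"],
                       n_skipped=meta.get("n_skipped", 0))


def train(chunks, targets, train_config: TrainConfig | None = None,
          config: BasecallConfig | None = None, groups=None,
          verbose: bool = False) -> BasecallerResults:
    """Functional wrapper: fit a basecaller on (chunk, target) examples."""
    return BasecallerModel(chunks, targets, config=config, groups=groups).fit(
        train_config, verbose=verbose
    )
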
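"""Residual CNN + batch-normalized BiLSTM basecalling network with CTC.

Architecture: the normalized raw signal passes through a stack of residual
convolution blocks (stride 1, zero padding, no conv bias, batch
normalization after every convolution), then through stacked bidirectional
LSTM layers whose recurrent and input pre-activations are batch-normalized
separately, and finally through a fully connected layer with a softmax
over the five CTC symbols (A, C, G, T, blank).  The default configuration
is five conv blocks of 256 channels with a 1x3 kernel and three BiLSTM
layers of 200 hidden units.

Training minimizes the CTC loss with Adam (initial learning rate 0.001)
over shuffled mini-batches of uniform-length labeled segments, alternating
round-robin among the per-length pools (default lengths 200/400/1000).

The BN-LSTM gates are

    (f, i, o, g) = BN(W_h h_{t-1}; gamma_h, 0) + BN(W_x x_t; gamma_x, 0) + b
    c_t = sigmoid(f) * c_{t-1} + sigmoid(i) * tanh(g)
    h_t = sigmoid(o) * tanh(BN(c_t; gamma_c, beta_c))

with the shifts of the recurrent and input BN fixed at zero (they would be
redundant with the cell bias b).  BN statistics are shared across time:
training normalizes each term by its current mini-batch statistics while
accumulating one set of running statistics per term, which inference then
uses, making inference deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, batch_norm, concat, conv1d
from .sim import ALPHABET, BASES, BLANK

__all__ = [
    "NetworkConfig",
    "BnLstmParams",
    "Network",
    "ModelCheckpoint",
    "bn_lstm_step",
    "ctc_loss",
    "train",
]

CHECKPOINT_FORMAT = 1


@dataclass
class NetworkConfig:
    n_conv_layers: int = 5
    conv_channels: int = 256
    conv_kernel: int = 3
    n_rnn_layers: int = 3
    rnn_hidden: int = 200
    alphabet_size: int = 5
    bn_epsilon: float = 1e-5
    learning_rate: float = 0.001
    segment_lengths: tuple[int, ...] = (200, 400, 1000)
    batch_size: int = 8

    def __post_init__(self) -> None:
        if self.alphabet_size != 5:
            raise ValueError("alphabet is fixed to {A,C,G,T,blank}")
        for name in ("n_conv_layers", "conv_channels", "conv_kernel",
                     "n_rnn_layers", "rnn_hidden", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        self.segment_lengths = tuple(self.segment_lengths)


class BnLstmParams:
    """Parameters of one LSTM direction with recurrent batch normalization.

    The recurrent-term and input-term BN shifts (beta_h, beta_x) are
    identically zero and not trainable; only the gains (gamma_h, gamma_x)
    and the cell-state BN (gamma_c, beta_c) are learned alongside W_h, W_x
    and the bias b.
    """

    beta_h = 0.0  # fixed, non-trainable
    beta_x = 0.0

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 eps: float = 1e-5):
        H = hidden
        self.hidden = H
        self.eps = eps
        glorot = np.sqrt(6.0 / (input_size + 4 * H))
        self.W_x = Tensor(rng.uniform(-glorot, glorot, (input_size, 4 * H)),
                          requires_grad=True)
        self.W_h = Tensor(_orthogonal_gates(H, rng), requires_grad=True)
        self.b = Tensor(np.zeros(4 * H), requires_grad=True)
        # gain 0.1 keeps tanh/sigmoid pre-activations out of saturation early on
        self.gamma_h = Tensor(np.full(4 * H, 0.1), requires_grad=True)
        self.gamma_x = Tensor(np.full(4 * H, 0.1), requires_grad=True)
        self.gamma_c = Tensor(np.full(H, 0.1), requires_grad=True)
        self.beta_c = Tensor(np.zeros(H), requires_grad=True)
        self.run_h: dict = {}
        self.run_x: dict = {}
        self.run_c: dict = {}

    def trainables(self) -> dict[str, Tensor]:
        return {"W_x": self.W_x, "W_h": self.W_h, "b": self.b,
                "gamma_h": self.gamma_h, "gamma_x": self.gamma_x,
                "gamma_c": self.gamma_c, "beta_c": self.beta_c}


def _orthogonal_gates(H: int, rng: np.random.Generator) -> np.ndarray:
    """(H, 4H) recurrent weight: one orthogonal block per gate."""
    blocks = []
    for _ in range(4):
        a = rng.standard_normal((H, H))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


def bn_lstm_step(x_t, h_prev, c_prev, params: BnLstmParams, *,
                 training: bool = False):
    """One batch-normalized LSTM step.

    Accepts Tensors (graph-building, used by the training loop) or plain
    arrays (returns plain arrays).  In inference mode the BN terms use the
    running statistics stored on ``params`` (identity when those are
    mean 0 / var 1 and the gains are 1).
    """
    plain = not isinstance(x_t, Tensor)
    if plain:
        x_t, h_prev, c_prev = Tensor(x_t), Tensor(h_prev), Tensor(c_prev)
    p = params
    axes = (0,)  # statistics over the batch dimension
    rec = batch_norm(h_prev @ p.W_h, p.gamma_h, None, p.run_h, axes=axes,
                     training=training, eps=p.eps)
    inp = batch_norm(x_t @ p.W_x, p.gamma_x, None, p.run_x, axes=axes,
                     training=training, eps=p.eps)
    gates = rec + inp + p.b
    H = p.hidden
    f, i, o, g = (gates[:, :H], gates[:, H:2 * H],
                  gates[:, 2 * H:3 * H], gates[:, 3 * H:])
    c_t = f.sigmoid() * c_prev + i.sigmoid() * g.tanh()
    cn = batch_norm(c_t, p.gamma_c, p.beta_c, p.run_c, axes=axes,
                    training=training, eps=p.eps)
    h_t = o.sigmoid() * cn.tanh()
    if plain:
        return h_t.data, c_t.data
    return h_t, c_t


class _ConvBlock:
    """Residual block: 1x1 reshaping branch + (1x1 -> ReLU -> 1x3 -> ReLU -> 1x1)
    branch, elementwise add, ReLU; BN after every convolution; no conv bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, eps: float):
        self.kernel = kernel
        self.eps = eps

        def he(k, cin, cout):
            return Tensor(rng.standard_normal((k * cin, cout))
                          * np.sqrt(2.0 / (k * cin)), requires_grad=True)

        self.W_skip = he(1, c_in, c_out)
        self.W_a = he(1, c_in, c_out)
        self.W_b = he(kernel, c_out, c_out)
        self.W_c = he(1, c_out, c_out)
        self.bn = []
        for _ in range(4):
            self.bn.append({
                "gamma": Tensor(np.ones(c_out), requires_grad=True),
                "beta": Tensor(np.zeros(c_out), requires_grad=True),
                "run": {},
            })

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        def bn(i, t):
            return batch_norm(t, self.bn[i]["gamma"], self.bn[i]["beta"],
                              self.bn[i]["run"], axes=(0, 1),
                              training=training, eps=self.eps)

        skip = bn(0, conv1d(x, self.W_skip, 1))
        y = bn(1, conv1d(x, self.W_a, 1)).relu()
        y = bn(2, conv1d(y, self.W_b, self.kernel)).relu()
        y = bn(3, conv1d(y, self.W_c, 1))
        return (skip + y).relu()

    def trainables(self) -> dict[str, Tensor]:
        out = {"W_skip": self.W_skip, "W_a": self.W_a,
               "W_b": self.W_b, "W_c": self.W_c}
        for i, b in enumerate(self.bn):
            out[f"bn{i}_gamma"] = b["gamma"]
            out[f"bn{i}_beta"] = b["beta"]
        return out


class Network:
    """The full basecalling network (see module docstring)."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.conv_blocks = []
        c_in = 1
        for _ in range(cfg.n_conv_layers):
            self.conv_blocks.append(
                _ConvBlock(c_in, cfg.conv_channels, cfg.conv_kernel, rng,
                           cfg.bn_epsilon))
            c_in = cfg.conv_channels
        self.rnn_layers: list[tuple[BnLstmParams, BnLstmParams]] = []
        in_size = cfg.conv_channels
        for _ in range(cfg.n_rnn_layers):
            fwd = BnLstmParams(in_size, cfg.rnn_hidden, rng, cfg.bn_epsilon)
            bwd = BnLstmParams(in_size, cfg.rnn_hidden, rng, cfg.bn_epsilon)
            self.rnn_layers.append((fwd, bwd))
            in_size = 2 * cfg.rnn_hidden
        glorot = np.sqrt(6.0 / (in_size + cfg.alphabet_size))
        # the FC layer carries no bias: the softmax argument is W_j . H_i
        self.W_fc = Tensor(rng.uniform(-glorot, glorot,
                                       (in_size, cfg.alphabet_size)),
                           requires_grad=True)

    # ---- parameters -----------------------------------------------------

    def trainables(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {"fc/W": self.W_fc}
        for i, blk in enumerate(self.conv_blocks):
            for name, t in blk.trainables().items():
                out[f"conv{i}/{name}"] = t
        for i, (fwd, bwd) in enumerate(self.rnn_layers):
            for name, t in fwd.trainables().items():
                out[f"rnn{i}/fwd/{name}"] = t
            for name, t in bwd.trainables().items():
                out[f"rnn{i}/bwd/{name}"] = t
        return out

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.trainables().values())

    def _running_stats(self) -> dict[str, dict]:
        out: dict[str, dict] = {}
        for i, blk in enumerate(self.conv_blocks):
            for j, b in enumerate(blk.bn):
                out[f"conv{i}/bn{j}"] = b["run"]
        for i, (fwd, bwd) in enumerate(self.rnn_layers):
            for d, p in (("fwd", fwd), ("bwd", bwd)):
                out[f"rnn{i}/{d}/run_h"] = p.run_h
                out[f"rnn{i}/{d}/run_x"] = p.run_x
                out[f"rnn{i}/{d}/run_c"] = p.run_c
        return out

    # ---- forward --------------------------------------------------------

    def _lstm_direction(self, x: Tensor, params: BnLstmParams, reverse: bool,
                        training: bool) -> list[Tensor]:
        B, T, _ = x.shape
        H = params.hidden
        # the input-term projection + BN is time-independent: do it in one shot,
        # with statistics over (batch, time) in training mode
        flat = x.reshape(B * T, x.shape[2])
        inp = batch_norm(flat @ params.W_x, params.gamma_x, None, params.run_x,
                         axes=(0,), training=training, eps=params.eps)
        inp = inp.reshape(B, T, 4 * H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        out: list[Tensor | None] = [None] * T
        for t in steps:
            rec = batch_norm(h @ params.W_h, params.gamma_h, None,
                             params.run_h, axes=(0,), training=training,
                             eps=params.eps)
            gates = rec + inp[:, t] + params.b
            f, i, o, g = (gates[:, :H], gates[:, H:2 * H],
                          gates[:, 2 * H:3 * H], gates[:, 3 * H:])
            c = f.sigmoid() * c + i.sigmoid() * g.tanh()
            cn = batch_norm(c, params.gamma_c, params.beta_c, params.run_c,
                            axes=(0,), training=training, eps=params.eps)
            h = o.sigmoid() * cn.tanh()
            out[t] = h
        return out  # type: ignore[return-value]

    def forward(self, windows: np.ndarray, *, training: bool = False) -> Tensor:
        """Map (B, T) normalized signal windows to (B, T, 5) logits."""
        windows = np.asarray(windows, dtype=float)
        if windows.ndim == 1:
            windows = windows[None, :]
        if windows.ndim != 2 or windows.shape[1] < 1:
            raise ValueError("input must be (B, T) with T >= 1")
        B, T = windows.shape
        x = Tensor(windows[:, :, None])
        for blk in self.conv_blocks:
            x = blk(x, training)
        for fwd, bwd in self.rnn_layers:
            hf = self._lstm_direction(x, fwd, False, training)
            hb = self._lstm_direction(x, bwd, True, training)
            # concat forward/backward states per timestep, stack to (B, T, 2H)
            per_t = [concat([hf[t], hb[t]], axis=1).reshape(B, 1, -1)
                     for t in range(T)]
            x = concat(per_t, axis=1)
        flat = x.reshape(B * T, x.shape[2])
        logits = (flat @ self.W_fc).reshape(B, T, self.config.alphabet_size)
        return logits

    def predict(self, windows: np.ndarray,
                starts: Sequence[int] | None = None) -> np.ndarray:
        """Inference: (B, T) windows -> (B, T, 5) probability matrices.

        ``starts`` (window offsets) is accepted for interface compatibility
        with oracle models and ignored: the network is translation
        invariant.
        """
        logits = self.forward(windows, training=False).data
        return _softmax(logits)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


# ---- CTC ---------------------------------------------------------------

NEG_INF = -np.inf


def _expand_label(indices: Sequence[int]) -> np.ndarray:
    """Blank-augmented label: [-, y1, -, y2, ..., -] as symbol indices."""
    ext = np.full(2 * len(indices) + 1, BLANK, dtype=int)
    ext[1::2] = indices
    return ext


def required_length(label: str) -> int:
    """Minimum number of timesteps needed to emit ``label``.

    Each base needs one step, and each repeated adjacent base needs one
    separating blank.
    """
    reps = sum(1 for a, b in zip(label, label[1:]) if a == b)
    return len(label) + reps


def label_to_indices(label: str) -> list[int]:
    try:
        return [BASES.index(b) for b in label]
    except ValueError:
        raise ValueError(f"label {label!r} must be over {{A,C,G,T}}")


def _ctc_alpha_beta(logp: np.ndarray, ext: np.ndarray):
    """Forward/backward lattice variables in log space.

    ``logp`` is (T, 5) log probabilities, ``ext`` the blank-augmented
    label.  Returns (alpha, beta, log_total).
    """
    T, S = logp.shape[0], len(ext)
    # transitions: stay, step, and skip (only onto a base differing from s-2)
    can_skip = np.zeros(S, dtype=bool)
    can_skip[2:] = (ext[2:] != BLANK) & (ext[2:] != ext[:-2])

    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = logp[0, ext[0]]
    if S > 1:
        alpha[0, 1] = logp[0, ext[1]]
    for t in range(1, T):
        prev = alpha[t - 1]
        stay = prev
        step = np.full(S, NEG_INF)
        step[1:] = prev[:-1]
        skip = np.full(S, NEG_INF)
        skip[2:] = prev[:-2]
        skip = np.where(can_skip, skip, NEG_INF)
        alpha[t] = _logsumexp3(stay, step, skip) + logp[t, ext]

    beta = np.full((T, S), NEG_INF)
    beta[T - 1, S - 1] = 0.0
    if S > 1:
        beta[T - 1, S - 2] = 0.0
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1] + logp[t + 1, ext]
        stay = nxt
        step = np.full(S, NEG_INF)
        step[:-1] = nxt[1:]
        skip = np.full(S, NEG_INF)
        skip[:-2] = np.where(can_skip[2:], nxt[2:], NEG_INF)
        beta[t] = _logsumexp3(stay, step, skip)

    tail = alpha[T - 1, S - 1]
    if S > 1:
        tail = np.logaddexp(tail, alpha[T - 1, S - 2])
    return alpha, beta, tail


def _logsumexp3(a, b, c):
    m = np.maximum(np.maximum(a, b), c)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = safe + np.log(
            np.exp(a - safe) + np.exp(b - safe) + np.exp(c - safe))
    return np.where(np.isfinite(m), out, NEG_INF)


def ctc_loss(probs: np.ndarray, label: str) -> float:
    """-log P(label | probs): CTC loss of one probability matrix.

    ``probs`` is a T x 5 row-stochastic matrix in the fixed symbol order
    (A, C, G, T, blank); the probability of the label sums over every
    blank-augmented alignment that collapses to it.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 5:
        raise ValueError("probs must be T x 5")
    T = probs.shape[0]
    indices = label_to_indices(label)
    need = required_length(label)
    if T < need:
        raise ValueError(
            f"label {label!r} needs >= {need} timesteps, got {T} "
            "(infinite loss)")
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    _, _, log_total = _ctc_alpha_beta(logp, _expand_label(indices))
    return float(-log_total)


def ctc_loss_grad(logits: np.ndarray, labels: Sequence[Sequence[int]]):
    """Batch CTC loss and its gradient with respect to the logits.

    ``logits`` is (B, T, 5).  Returns (mean loss, dloss/dlogits) where the
    per-sample gradient is softmax(logits) minus the CTC symbol posterior.
    """
    B, T, _ = logits.shape
    logp = _log_softmax(logits)
    grad = np.exp(logp).copy()  # softmax term
    total = 0.0
    for b, indices in enumerate(labels):
        ext = _expand_label(indices)
        alpha, beta, log_total = _ctc_alpha_beta(logp[b], ext)
        total += -log_total
        occ = alpha + beta - log_total  # log posterior over lattice states
        gamma = np.full((T, 5), NEG_INF)
        for sym in range(5):
            cols = np.where(ext == sym)[0]
            if len(cols):
                gamma[:, sym] = _logsumexp_rows(occ[:, cols])
        grad[b] -= np.exp(gamma)
    return total / B, grad / B


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = safe + np.log(np.exp(x - safe[:, None]).sum(axis=1))
    return np.where(np.isfinite(m), out, NEG_INF)


# ---- training ----------------------------------------------------------


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


@dataclass
class ModelCheckpoint:
    network: Network
    epochs: int = 0
    seed: int = 0
    loss_curve: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for name, t in self.network.trainables().items():
            arrays["param:" + name] = t.data
        for name, run in self.network._running_stats().items():
            for key, val in run.items():
                arrays[f"stat:{name}:{key}"] = np.asarray(val)
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(self.network.config),
            "epochs": self.epochs,
            "seed": self.seed,
            "loss_curve": self.loss_curve,
            "net_seed": self.network.seed,
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ModelCheckpoint":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"]).decode())
            if meta["format"] != CHECKPOINT_FORMAT:
                raise ValueError(f"unsupported checkpoint format {meta['format']}")
            cfg = meta["config"]
            cfg["segment_lengths"] = tuple(cfg["segment_lengths"])
            net = Network(NetworkConfig(**cfg), seed=meta["net_seed"])
            params = net.trainables()
            stats = net._running_stats()
            for key in npz.files:
                if key.startswith("param:"):
                    params[key[6:]].data[...] = npz[key]
                elif key.startswith("stat:"):
                    _, name, stat_key = key.split(":", 2)
                    stats[name][stat_key] = npz[key]
        return cls(network=net, epochs=meta["epochs"], seed=meta["seed"],
                   loss_curve=list(meta["loss_curve"]))


def train(dataset, config: NetworkConfig | None = None, *, epochs: int = 1,
          seed: int = 0, network: Network | None = None,
          log=None) -> ModelCheckpoint:
    """Train a network on labeled segments with shuffled mini-batch CTC.

    ``dataset`` is a sequence of labeled segments (anything with ``signal``
    and ``label`` attributes) whose lengths are all in
    ``config.segment_lengths``.  Each mini-batch holds segments of a single
    length; the per-length pools are visited round-robin ("in
    alternation").  Pools are reshuffled every epoch.  Returns a checkpoint
    with the per-epoch mean CTC loss curve.  Fully reproducible per seed.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    config = config or NetworkConfig()
    pools: dict[int, list] = {}
    for seg in dataset:
        L = len(seg.signal)
        if L not in config.segment_lengths:
            raise ValueError(
                f"segment length {L} not in configured lengths "
                f"{config.segment_lengths}")
        pools.setdefault(L, []).append(seg)
    net = network or Network(config, seed=seed)
    opt = Adam(net.trainables(), lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    curve: list[float] = []
    for epoch in range(epochs):
        batches: list[list] = []
        per_length: list[list[list]] = []
        for L in sorted(pools):
            pool = pools[L]
            order = rng.permutation(len(pool))
            shuffled = [pool[i] for i in order]
            per_length.append(
                [shuffled[i:i + config.batch_size]
                 for i in range(0, len(shuffled), config.batch_size)])
        # round-robin alternation among the per-length batch queues
        while any(per_length):
            for queue in per_length:
                if queue:
                    batches.append(queue.pop(0))
        losses = []
        for batch in batches:
            x = np.stack([np.asarray(seg.signal, dtype=float)
                          for seg in batch])
            labels = [label_to_indices(seg.label) for seg in batch]
            logits = net.forward(x, training=True)
            loss, grad = ctc_loss_grad(logits.data, labels)
            logits.backward(grad)
            opt.step()
            losses.append(loss)
        curve.append(float(np.mean(losses)) if losses else float("nan"))
        if log is not None:
            log(f"epoch {epoch + 1}/{epochs}: mean CTC loss {curve[-1]:.4f}")
    return ModelCheckpoint(network=net, epochs=epochs, seed=seed,
                           loss_curve=curve)
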
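"""Attention-extended spatial-temporal graph convolutional score regressor.

The network maps a normalized skeleton sequence (T frames x 11 markers x
3 coordinates) to a continuous movement-quality score.  Architecture:

1. temporal lift: the raw sequence is concatenated channel-wise with its
   temporal convolution (kernel Gamma_u), doubling the channels;
2. three spatial-temporal blocks; each block computes per-partition
   self-attention maps S_k with a ConvLSTM (1x1 convolutional gates over
   the marker axis), modulates the partition adjacency Ahat_k = A_k + I
   elementwise by S_k, degree-normalizes, and applies the graph
   convolution G = sigma(sum_k phi(Ahat_k o S_k) Z W_k); the result goes
   through three parallel temporal convolutions with distinct kernels
   whose outputs are concatenated, plus a 1x1 residual;
3. a stacked LSTM (output dims 80, 40, 40, 80, dropout between layers)
   reads the flattened node features over time; its output features are
   mean-pooled over time and fed to a fully-connected scalar head.

Training minimizes mean squared error on a 0-100 score scale with the
adaptive-moment (Adam) optimizer.  Everything is seeded and runs in
double precision on the CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, Tensor, concat, stack
from .skeleton import build_limb_graph

__all__ = [
    "NetConfig", "GraphSpec", "AssessmentNet", "build_network", "train",
    "predict", "joint_importance",
]


@dataclass(frozen=True)
class NetConfig:
    """Hyper-parameters of the assessment network."""

    num_blocks: int = 3
    lift_kernel: int = 9
    temporal_kernels: Tuple[int, int, int] = (3, 5, 7)
    gcn_channels: int = 18
    tcn_channels: int = 6              # per temporal kernel; 3x6 concat = 18
    attention_hidden: int = 6
    lstm_dims: Tuple[int, ...] = (80, 40, 40, 80)
    dropout: float = 0.25
    learning_rate: float = 0.1         # nominal default; see train()
    batch_size: int = 4
    attention_frozen: bool = False     # ablation: S_k fixed to ones

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.temporal_kernels + (self.lift_kernel,)):
            raise ValueError("temporal kernels must be odd")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


class GraphSpec:
    """Partition adjacencies and degree normalizers of the limb graph.

    Partitions follow A_0 = I (self) and A_1 = A (neighbors); each is
    augmented as Ahat_k = A_k + I and degree-normalized symmetrically,
    phi(M) = D^{-1/2} M D^{-1/2} with D the degree matrix of Ahat_k.
    """

    def __init__(self, adjacency: Optional[np.ndarray] = None):
        a = (np.asarray(adjacency, float) if adjacency is not None
             else build_limb_graph().adjacency)
        n = a.shape[0]
        self.n_nodes = n
        self.partitions = [np.eye(n), a]
        self.a_hat = [p + np.eye(n) for p in self.partitions]
        self.d_inv_sqrt = [1.0 / np.sqrt(m.sum(axis=1)) for m in self.a_hat]

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)


# --- parameterized layers ------------------------------------------------

class _Layer:
    def params(self) -> List[Tensor]:
        raise NotImplementedError


def _glorot(rng, shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    s = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class TemporalConv(_Layer):
    """1-D convolution along the frame axis, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        self.kernel = kernel
        self.w = Tensor(_glorot(rng, (kernel, c_in, c_out)) / kernel,
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, T, N, C); output (B, T, N, c_out)
        b_, t_, n_, _ = x.shape
        half = self.kernel // 2
        pad = Tensor(np.zeros((b_, half, n_, x.shape[3])))
        xp = concat([pad, x, pad], axis=1)
        out = None
        for tau in range(self.kernel):
            term = xp[:, tau:tau + t_] @ self.w[tau]
            out = term if out is None else out + term
        return out + self.b

    def params(self):
        return [self.w, self.b]


class ConvLSTMAttention(_Layer):
    """ConvLSTM (1x1 gates over nodes) producing per-frame attention maps.

    Gate equations follow the standard i/f/o/g ConvLSTM recurrence; the
    hidden state h_t (nodes x hidden) is reduced to an (N x N) map by a
    learned linear projection of its flattened entries, squashed by tanh
    so map entries lie in (-1, 1).
    """

    def __init__(self, c_in: int, hidden: int, n_nodes: int, rng):
        self.hidden = hidden
        self.n_nodes = n_nodes
        self.wq = Tensor(_glorot(rng, (c_in, hidden)), requires_grad=True)
        # gates i, f, o, g fused into one weight block each for W, U
        self.w = Tensor(_glorot(rng, (hidden, 4 * hidden)),
                        requires_grad=True)
        self.u = Tensor(_glorot(rng, (hidden, 4 * hidden)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)
        self.proj = Tensor(_glorot(rng, (n_nodes * hidden,
                                         n_nodes * n_nodes)),
                           requires_grad=True)

    def __call__(self, z: Tensor) -> Tensor:
        # z: (B, T, N, C) -> S: (B, T, N, N)
        b_, t_, n_, _ = z.shape
        d = self.hidden
        h = Tensor(np.zeros((b_, n_, d)))
        c = Tensor(np.zeros((b_, n_, d)))
        maps = []
        qw_all = (z @ self.wq) @ self.w + self.b   # (B, T, N, 4H)
        for t in range(t_):
            gates = qw_all[:, t] + h @ self.u
            i = gates[:, :, :d].sigmoid()
            f = gates[:, :, d:2 * d].sigmoid()
            o = gates[:, :, 2 * d:3 * d].sigmoid()
            g = gates[:, :, 3 * d:].tanh()
            c = f * c + i * g
            h = o * c.tanh()
            s = (h.reshape(b_, n_ * d) @ self.proj).tanh()
            maps.append(s.reshape(b_, n_, n_))
        return stack(maps, axis=1)

    def params(self):
        return [self.wq, self.w, self.u, self.b, self.proj]


class AttentionGCN(_Layer):
    """Graph convolution modulated elementwise by attention maps."""

    def __init__(self, c_in: int, c_out: int, graph: GraphSpec, rng):
        self.graph = graph
        self.w = [Tensor(_glorot(rng, (c_in, c_out)), requires_grad=True)
                  for _ in range(graph.n_partitions)]
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, z: Tensor, s_maps: Sequence[Optional[Tensor]]
                 ) -> Tensor:
        out = None
        for k in range(self.graph.n_partitions):
            a_hat = self.graph.a_hat[k]
            dis = self.graph.d_inv_sqrt[k]
            scale = dis[:, None] * dis[None, :]
            if s_maps[k] is None:            # frozen attention: S = 1
                mod = Tensor(a_hat * scale)
            else:
                mod = s_maps[k] * Tensor(a_hat * scale)
            term = mod @ z @ self.w[k]
            out = term if out is None else out + term
        return (out + self.b).relu()

    def params(self):
        return self.w + [self.b]


class STGCNBlock(_Layer):
    """Attention-GCN -> three parallel temporal convs -> residual."""

    def __init__(self, c_in: int, config: NetConfig, graph: GraphSpec, rng):
        self.attention = [ConvLSTMAttention(c_in, config.attention_hidden,
                                            graph.n_nodes, rng)
                          for _ in range(graph.n_partitions)]
        self.gcn = AttentionGCN(c_in, config.gcn_channels, graph, rng)
        self.tcn = [TemporalConv(config.gcn_channels, config.tcn_channels,
                                 k, rng) for k in config.temporal_kernels]
        c_out = config.tcn_channels * len(config.temporal_kernels)
        self.res = Tensor(_glorot(rng, (c_in, c_out)), requires_grad=True)
        self.frozen = config.attention_frozen
        self.c_out = c_out

    def __call__(self, z: Tensor, collect: Optional[list] = None) -> Tensor:
        if self.frozen:
            s_maps = [None] * len(self.attention)
        else:
            s_maps = [att(z) for att in self.attention]
        if collect is not None and not self.frozen:
            collect.extend(s.data for s in s_maps)
        g = self.gcn(z, s_maps)
        t = concat([tc(g) for tc in self.tcn], axis=-1)
        return (t + z @ self.res).relu()

    def params(self):
        p = []
        for a in self.attention:
            p += a.params()
        p += self.gcn.params()
        for t in self.tcn:
            p += t.params()
        return p + [self.res]


class LSTMLayer(_Layer):
    """Single LSTM layer; forget bias starts at +1 so early training
    preserves cell memory, and input weights carry a gain of 2 to keep
    feature variance alive through the stacked layers."""

    def __init__(self, d_in: int, d_out: int, rng):
        self.d_out = d_out
        self.w = Tensor(2.0 * _glorot(rng, (d_in, 4 * d_out)),
                        requires_grad=True)
        self.u = Tensor(_glorot(rng, (d_out, 4 * d_out)), requires_grad=True)
        b = np.zeros(4 * d_out)
        b[d_out:2 * d_out] = 1.0     # forget gate
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, T, D) -> outputs (B, T, d_out)
        b_, t_, _ = x.shape
        h = Tensor(np.zeros((b_, self.d_out)))
        c = Tensor(np.zeros((b_, self.d_out)))
        outs = []
        xw = x @ self.w
        d = self.d_out
        for t in range(t_):
            gates = xw[:, t] + h @ self.u + self.b
            i = gates[:, :d].sigmoid()
            f = gates[:, d:2 * d].sigmoid()
            g = gates[:, 2 * d:3 * d].tanh()
            o = gates[:, 3 * d:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return stack(outs, axis=1)

    def params(self):
        return [self.w, self.u, self.b]


class AssessmentNet:
    """The full score-regression network (see module docstring)."""

    def __init__(self, config: NetConfig, seed: int = 0,
                 graph: Optional[GraphSpec] = None):
        self.config = config
        self.graph = graph or GraphSpec()
        rng = np.random.default_rng(seed)
        n = self.graph.n_nodes
        c_in = 3
        self.lift = TemporalConv(c_in, c_in, config.lift_kernel, rng)
        self.blocks = []
        c = 2 * c_in
        for _ in range(config.num_blocks):
            blk = STGCNBlock(c, config, self.graph, rng)
            self.blocks.append(blk)
            c = blk.c_out
        dims = config.lstm_dims
        self.lstm = []
        d = n * c
        for d_out in dims:
            self.lstm.append(LSTMLayer(d, d_out, rng))
            d = d_out
        self.fc_w = Tensor(_glorot(rng, (d, 1)), requires_grad=True)
        self.fc_b = Tensor(np.array([50.0]), requires_grad=True)

    def params(self) -> List[Tensor]:
        p = self.lift.params()
        for blk in self.blocks:
            p += blk.params()
        for l in self.lstm:
            p += l.params()
        return p + [self.fc_w, self.fc_b]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None,
                collect_attention: Optional[list] = None) -> Tensor:
        """Scores for a batch: (B, T, N, 3) -> (B,)."""
        v = Tensor(np.asarray(x, float))
        if v.ndim != 4:
            raise ValueError("input must be (batch, frames, nodes, 3)")
        if v.shape[1] < self.config.lift_kernel:
            raise ValueError(
                f"sequence length {v.shape[1]} shorter than the lift "
                f"kernel {self.config.lift_kernel}")
        z = concat([v, self.lift(v)], axis=-1)
        for blk in self.blocks:
            z = blk(z, collect=collect_attention)
        b_, t_, n_, c_ = z.shape
        seq = z.reshape(b_, t_, n_ * c_)
        for li, layer in enumerate(self.lstm):
            seq = layer(seq)
            if training and self.config.dropout > 0 and li < len(self.lstm) - 1:
                mask = (rng.random(seq.shape) >= self.config.dropout)
                seq = seq * Tensor(mask / (1.0 - self.config.dropout))
        pooled = seq.mean(axis=1)      # temporal mean of LSTM features
        return (pooled @ self.fc_w + self.fc_b).reshape(b_)


def build_network(config: Optional[NetConfig] = None,
                  seed: int = 0) -> AssessmentNet:
    return AssessmentNet(config or NetConfig(), seed=seed)


def train(model: AssessmentNet, x: np.ndarray, y: np.ndarray,
          epochs: int = 100, lr: Optional[float] = None,
          seed: int = 0, verbose: bool = False,
          stop_below: Optional[float] = None,
          clip_norm: float = 5.0) -> List[float]:
    """Fit by minimizing mean squared error with Adam; returns history.

    ``lr`` defaults to the config's nominal learning rate.  A non-finite
    loss (the nominal 0.1 rate diverges on this architecture) raises
    immediately rather than silently returning garbage weights.
    ``stop_below`` ends training early once the epoch MSE drops under
    the given value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape[0] == 0:
        raise ValueError("empty dataset")
    if x.shape[0] != y.shape[0]:
        raise ValueError("inputs and labels differ in length")
    lr = lr if lr is not None else model.config.learning_rate
    opt = Adam(model.params(), lr=lr)
    rng = np.random.default_rng(seed)
    bs = model.config.batch_size
    history: List[float] = []
    for epoch in range(epochs):
        order = rng.permutation(x.shape[0])
        total, count = 0.0, 0
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            pred = model.forward(x[idx], training=True, rng=rng)
            err = pred - Tensor(y[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            if clip_norm > 0:     # recurrent nets spike; clip global norm
                total = math.sqrt(sum(
                    float(np.sum(p.grad**2)) for p in opt.params
                    if p.grad is not None))
                if total > clip_norm:
                    scale = clip_norm / total
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        epoch_loss = total / count
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch} "
                f"with learning rate {lr}")
        history.append(epoch_loss)
        if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
            print(f"epoch {epoch:4d}  mse {epoch_loss:10.3f}")
        if stop_below is not None and epoch_loss < stop_below:
            break
    return history


def predict(model: AssessmentNet, x: np.ndarray) -> np.ndarray:
    """Scores for one sequence (T, N, 3) or a batch (B, T, N, 3)."""
    x = np.asarray(x, float)
    single = x.ndim == 3
    if single:
        x = x[None]
    out = model.forward(x, training=False).data
    return out[0] if single else out


def joint_importance(model: AssessmentNet,
                     groups: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Per-action node importance from the attention maps.

    For each action group (B, T, N, 3), the absolute attention maps are
    averaged over time, partitions, batch and map columns/rows to one
    value per node, then min-max scaled to [0, 1] across the nodes.
    """
    out: Dict[str, np.ndarray] = {}
    for action, x in groups.items():
        x = np.asarray(x, float)
        if x.ndim == 3:
            x = x[None]
        maps: list = []
        model.forward(x, training=False, collect_attention=maps)
        if not maps:
            raise ValueError("model has frozen attention; no maps to rank")
        acc = np.zeros(model.graph.n_nodes)
        for s in maps:                     # (B, T, N, N)
            a = np.abs(s)
            acc += a.mean(axis=(0, 1, 3)) + a.mean(axis=(0, 1, 2))
        lo, hi = acc.min(), acc.max()
        out[action] = (acc - lo) / (hi - lo) if hi > lo else np.zeros_like(acc)
    return out
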
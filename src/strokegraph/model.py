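"""Five-block Chebyshev spectral GCN for lesion-node classification.

Architecture: five stacked graph-convolution blocks, each

    ChebConv(K) -> BatchNorm -> LeakyReLU -> BatchNorm,

with channel widths 16 -> 16 -> 16 -> 16 -> 16 -> 2, followed by dropout
(training only) and a per-node softmax over the two classes (lesion /
non-lesion).  A ChebConv layer computes

    S = sum_k T_k(L~) X theta_k + b,

where T_k is the Chebyshev polynomial of the rescaled graph Laplacian L~,
theta is an (order, in, out) coefficient tensor and b a bias -- so a layer
holds order*in*out + out parameters and each batch-norm 2 per channel.

Everything -- forward, backward, batch-norm statistics, dropout, the
cross-entropy loss and the Adadelta/SGD optimizers -- is implemented
directly on numpy arrays; gradients are exact (verified against finite
differences in the test suite) and all randomness flows from a single
numpy Generator, so seeded training runs are bit-reproducible.

Batch normalization operates over the node axis of the single graph being
processed (one graph per optimization step) and keeps running statistics
for evaluation mode; on a single-node graph it degrades to the identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigurationError, InputError
from .graphs import RegionGraph
from .spectral import cheb_basis_apply, scaled_laplacian

__all__ = [
    "ChebLayerParams",
    "ModelConfig",
    "TrainConfig",
    "ChebGCN",
    "cheb_conv_forward",
    "parameter_count",
    "train",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    """Network shape: five blocks, widths 16..16 then 2, Chebyshev order 3."""

    n_blocks: int = 5
    dims: tuple[int, ...] = (16, 16, 16, 16, 16, 2)
    cheb_orders: tuple[int, ...] = (3, 3, 3, 3, 3)
    leaky_relu_slope: float = 0.01
    dropout_rate: float = 0.3
    double_batchnorm: bool = True

    def validate(self) -> None:
        if len(self.dims) != self.n_blocks + 1:
            raise ConfigurationError("dims must have n_blocks + 1 entries")
        if len(self.cheb_orders) != self.n_blocks:
            raise ConfigurationError("cheb_orders must have n_blocks entries")
        if any(o < 1 for o in self.cheb_orders):
            raise ConfigurationError("Chebyshev orders must be >= 1")
        if self.dims[-1] != 2:
            raise ConfigurationError("final dimension must be 2 (lesion / non-lesion)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults follow the tuned values of the method: Adadelta with
    cross-entropy loss, weight decay 6e-4, 150 epochs.  ``learning_rate``
    carries its conventional meaning for the gradient-descent family
    ("sgd"); Adadelta in its original formulation is learning-rate free --
    its step size is the ratio of accumulated update and gradient RMS --
    and is scaled only by ``adadelta_step_scale`` (canonical value 1.0).
    Setting ``learning_rate`` to 0 disables parameter updates for every
    optimizer.
    """

    optimizer: str = "adadelta"
    loss: str = "cross_entropy"
    learning_rate: float = 0.0001
    weight_decay: float = 6e-4
    epochs: int = 150
    seed: int = 0
    adadelta_rho: float = 0.9
    adadelta_eps: float = 1e-6
    adadelta_step_scale: float = 1.0
    class_weighting: bool = False

    def validate(self) -> None:
        if self.optimizer not in ("adadelta", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")


@dataclass
class ChebLayerParams:
    """Coefficient tensor (order, in, out) plus bias of one ChebConv layer."""

    theta: np.ndarray
    bias: np.ndarray

    @property
    def order(self) -> int:
        return self.theta.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.theta.size + self.bias.size

    @classmethod
    def initialize(cls, order: int, in_dim: int, out_dim: int,
                   rng: np.random.Generator) -> "ChebLayerParams":
        # Glorot-style scale over the order*in fan-in.
        scale = np.sqrt(2.0 / (order * in_dim + out_dim))
        theta = rng.standard_normal((order, in_dim, out_dim)) * scale
        return cls(theta=theta, bias=np.zeros(out_dim))


class _BatchNorm:
    """Per-channel batch normalization over the node axis."""

    def __init__(self, n_channels: int):
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def forward(self, x: np.ndarray, train: bool):
        if train and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (x - mu) * inv_std
            self.running_mean = ((1 - _BN_MOMENTUM) * self.running_mean
                                 + _BN_MOMENTUM * mu)
            self.running_var = ((1 - _BN_MOMENTUM) * self.running_var
                                + _BN_MOMENTUM * var)
            cache = ("batch", xhat, inv_std)
            return self.gamma * xhat + self.beta, cache
        if train:  # single node: normalization undefined, fall back to identity
            return x, ("identity",)
        inv_std = 1.0 / np.sqrt(self.running_var + _BN_EPS)
        xhat = (x - self.running_mean) * inv_std
        return self.gamma * xhat + self.beta, ("running", inv_std)

    def backward(self, dout: np.ndarray, cache):
        mode = cache[0]
        if mode == "identity":
            return dout, np.zeros_like(self.gamma), np.zeros_like(self.beta)
        if mode == "running":
            inv_std = cache[1]
            return dout * self.gamma * inv_std, None, None
        _, xhat, inv_std = cache
        n = dout.shape[0]
        dgamma = (dout * xhat).sum(axis=0)
        dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        dx = (inv_std / n) * (n * dxhat - dxhat.sum(axis=0)
                              - xhat * (dxhat * xhat).sum(axis=0))
        return dx, dgamma, dbeta


def _conv_forward(Lt: np.ndarray, X: np.ndarray, params: ChebLayerParams):
    if X.shape[1] != params.theta.shape[1]:
        raise InputError(
            f"feature dim {X.shape[1]} != layer in_dim {params.theta.shape[1]}")
    txs = cheb_basis_apply(Lt, X, params.order)
    out = params.bias + sum(tx @ params.theta[k] for k, tx in enumerate(txs))
    return out, txs


def _conv_backward(Lt: np.ndarray, dS: np.ndarray, params: ChebLayerParams,
                   txs, need_dx: bool):
    order = params.order
    dtheta = np.stack([txs[k].T @ dS for k in range(order)])
    dbias = dS.sum(axis=0)
    dX = None
    if need_dx:
        in_dim = params.theta.shape[1]
        # T_k is symmetric, so d/dX of T_k X theta_k is T_k (dS theta_k^T).
        stacked = np.concatenate([dS @ params.theta[k].T for k in range(order)],
                                 axis=1)
        basis = cheb_basis_apply(Lt, stacked, order)
        dX = np.zeros((dS.shape[0], in_dim))
        for k in range(order):
            dX += basis[k][:, k * in_dim:(k + 1) * in_dim]
    return dtheta, dbias, dX


def cheb_conv_forward(graph, X: np.ndarray, params: ChebLayerParams) -> np.ndarray:
    """One Chebyshev graph convolution: sum_k T_k(L~) X theta_k + bias.

    ``graph`` may be a :class:`RegionGraph` (its rescaled symmetric-normalized
    Laplacian is built on the fly) or a precomputed L~ matrix.
    """
    Lt = (scaled_laplacian(graph.adjacency)
          if isinstance(graph, RegionGraph) else np.asarray(graph, dtype=np.float64))
    out, _ = _conv_forward(Lt, np.asarray(X, dtype=np.float64), params)
    return out


class ChebGCN:
    """The five-block Chebyshev GCN node classifier."""

    def __init__(self, cfg: ModelConfig | None = None,
                 rng: int | np.random.Generator = 0):
        self.cfg = cfg or ModelConfig()
        self.cfg.validate()
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.convs: list[ChebLayerParams] = []
        self.bn1: list[_BatchNorm] = []
        self.bn2: list[_BatchNorm | None] = []
        for b in range(self.cfg.n_blocks):
            in_d, out_d = self.cfg.dims[b], self.cfg.dims[b + 1]
            self.convs.append(ChebLayerParams.initialize(
                self.cfg.cheb_orders[b], in_d, out_d, rng))
            self.bn1.append(_BatchNorm(out_d))
            self.bn2.append(_BatchNorm(out_d) if self.cfg.double_batchnorm else None)

    # -- parameter bookkeeping -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        """Trainable arrays in a fixed order (conv theta/bias, bn gamma/beta)."""
        params = []
        for b in range(self.cfg.n_blocks):
            params += [self.convs[b].theta, self.convs[b].bias,
                       self.bn1[b].gamma, self.bn1[b].beta]
            if self.bn2[b] is not None:
                params += [self.bn2[b].gamma, self.bn2[b].beta]
        return params

    def decay_mask(self) -> list[bool]:
        """True for arrays that receive weight decay (conv coefficients only)."""
        mask = []
        for b in range(self.cfg.n_blocks):
            mask += [True, False, False, False]
            if self.bn2[b] is not None:
                mask += [False, False]
        return mask

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward ----------------------------------------------------

    def block_forward(self, Lt: np.ndarray, X: np.ndarray, block: int,
                      train: bool = False):
        """ChebConv -> BN -> LeakyReLU -> BN of one block, with cache."""
        s, txs = _conv_forward(Lt, X, self.convs[block])
        h1, c1 = self.bn1[block].forward(s, train)
        neg = h1 < 0
        h2 = np.where(neg, self.cfg.leaky_relu_slope * h1, h1)
        if self.bn2[block] is not None:
            h3, c2 = self.bn2[block].forward(h2, train)
        else:
            h3, c2 = h2, None
        return h3, (X, txs, c1, neg, c2)

    def forward(self, Lt: np.ndarray, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Full forward pass; returns (probs, caches) -- each row sums to 1."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.cfg.dims[0]:
            raise InputError(
                f"feature dim {X.shape[1]} != model input dim {self.cfg.dims[0]}")
        h = X
        caches = []
        for b in range(self.cfg.n_blocks):
            h, cache = self.block_forward(Lt, h, b, train)
            caches.append(cache)
        if train and self.cfg.dropout_rate > 0:
            if rng is None:
                raise ConfigurationError("training forward pass needs an rng for dropout")
            keep = (rng.random(h.shape) >= self.cfg.dropout_rate)
            h = h * keep / (1.0 - self.cfg.dropout_rate)
            drop_cache = keep
        else:
            drop_cache = None
        z = h - h.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (caches, drop_cache)

    def predict_graph(self, graph: RegionGraph, Lt: np.ndarray | None = None):
        """Eval-mode class probabilities and hard labels for one graph."""
        if Lt is None:
            Lt = scaled_laplacian(graph.adjacency)
        probs, _ = self.forward(Lt, graph.features, train=False)
        return probs, probs.argmax(axis=1)

    def loss_and_grads(self, Lt: np.ndarray, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None,
                       train: bool = True,
                       class_weights: np.ndarray | None = None):
        """Mean per-node cross-entropy and exact gradients for all parameters."""
        y = np.asarray(y, dtype=np.int64)
        probs, (caches, drop_cache) = self.forward(Lt, X, train=train, rng=rng)
        n = probs.shape[0]
        w = (class_weights[y] if class_weights is not None
             else np.ones(n))
        wsum = w.sum()
        loss = float(-(w * np.log(probs[np.arange(n), y] + 1e-12)).sum() / wsum)

        dz = probs.copy()
        dz[np.arange(n), y] -= 1.0
        dz *= (w / wsum)[:, None]
        if drop_cache is not None:
            dz = dz * drop_cache / (1.0 - self.cfg.dropout_rate)

        grads = [None] * len(self.parameters())
        gi = len(grads)
        dh = dz
        for b in reversed(range(self.cfg.n_blocks)):
            _, txs, c1, neg, c2 = caches[b]
            if self.bn2[b] is not None:
                gi -= 2
                dh, dg2, db2 = self.bn2[b].backward(dh, c2)
                grads[gi], grads[gi + 1] = dg2, db2
            dh = np.where(neg, self.cfg.leaky_relu_slope * dh, dh)
            gi -= 4
            dh, dg1, db1 = self.bn1[b].backward(dh, c1)
            grads[gi + 2], grads[gi + 3] = dg1, db1
            dtheta, dbias, dh = _conv_backward(Lt, dh, self.convs[b], txs,
                                               need_dx=(b > 0))
            grads[gi], grads[gi + 1] = dtheta, dbias
        return loss, grads

    # -- checkpointing ---------------------------------------------------------

    def save(self, path: str) -> None:
        """JSON checkpoint embedding the model config and all arrays."""
        state = {
            "config": asdict(self.cfg),
            "blocks": [],
        }
        for b in range(self.cfg.n_blocks):
            blk = {
                "theta": self.convs[b].theta.tolist(),
                "bias": self.convs[b].bias.tolist(),
                "bn1": _bn_state(self.bn1[b]),
            }
            if self.bn2[b] is not None:
                blk["bn2"] = _bn_state(self.bn2[b])
            state["blocks"].append(blk)
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def load(cls, path: str) -> "ChebGCN":
        with open(path) as fh:
            state = json.load(fh)
        c = state["config"]
        cfg = ModelConfig(n_blocks=c["n_blocks"], dims=tuple(c["dims"]),
                          cheb_orders=tuple(c["cheb_orders"]),
                          leaky_relu_slope=c["leaky_relu_slope"],
                          dropout_rate=c["dropout_rate"],
                          double_batchnorm=c["double_batchnorm"])
        model = cls(cfg, rng=0)
        for b, blk in enumerate(state["blocks"]):
            model.convs[b].theta = np.array(blk["theta"], dtype=np.float64)
            model.convs[b].bias = np.array(blk["bias"], dtype=np.float64)
            _bn_restore(model.bn1[b], blk["bn1"])
            if "bn2" in blk:
                _bn_restore(model.bn2[b], blk["bn2"])
        return model


def _bn_state(bn: _BatchNorm) -> dict:
    return {k: getattr(bn, k).tolist()
            for k in ("gamma", "beta", "running_mean", "running_var")}


def _bn_restore(bn: _BatchNorm, state: dict) -> None:
    for k, v in state.items():
        setattr(bn, k, np.array(v, dtype=np.float64))


def parameter_count(cfg: ModelConfig | None = None) -> int:
    """Closed-form trainable-parameter count: sum of O_k*in*out + out per conv
    plus 2 (scale, shift) per batch-norm channel."""
    cfg = cfg or ModelConfig()
    cfg.validate()
    total = 0
    for b in range(cfg.n_blocks):
        in_d, out_d = cfg.dims[b], cfg.dims[b + 1]
        total += cfg.cheb_orders[b] * in_d * out_d + out_d
        total += 2 * out_d
        if cfg.double_batchnorm:
            total += 2 * out_d
    return total


# -- optimizers ----------------------------------------------------------------


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class _Adadelta:
    """Original accumulated-RMS-ratio method; step scale 1.0 is canonical."""

    def __init__(self, rho: float, eps: float, scale: float):
        self.rho, self.eps, self.scale = rho, eps, scale
        self.eg = None
        self.ed = None

    def step(self, params, grads):
        if self.eg is None:
            self.eg = [np.zeros_like(p) for p in params]
            self.ed = [np.zeros_like(p) for p in params]
        for p, g, eg, ed in zip(params, grads, self.eg, self.ed):
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt((ed + self.eps) / (eg + self.eps)) * g
            ed *= self.rho
            ed += (1 - self.rho) * dx * dx
            p += self.scale * dx


def train(graphs: list[RegionGraph], cfg: ModelConfig | None = None,
          tcfg: TrainConfig | None = None,
          scaled_laplacians: list[np.ndarray] | None = None):
    """Train a :class:`ChebGCN` on labelled region graphs.

    One optimization step per graph per epoch, in a seeded shuffled order;
    weight decay applies to the Chebyshev coefficient tensors.  Returns the
    trained model and the per-epoch mean loss history.
    """
    cfg = cfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    cfg.validate()
    tcfg.validate()
    if not graphs:
        raise InputError("empty training set")
    all_labels = np.concatenate([g.node_labels for g in graphs])
    if len(np.unique(all_labels)) < 2:
        warnings.warn("training labels contain a single class; proceeding anyway",
                      stacklevel=2)
    rng = np.random.default_rng(tcfg.seed)
    model = ChebGCN(cfg, rng)
    if scaled_laplacians is None:
        scaled_laplacians = [scaled_laplacian(g.adjacency) for g in graphs]
    params = model.parameters()
    decay = model.decay_mask()
    if tcfg.optimizer == "sgd":
        opt = _SGD(tcfg.learning_rate)
    else:
        opt = _Adadelta(tcfg.adadelta_rho, tcfg.adadelta_eps,
                        tcfg.adadelta_step_scale)
    class_weights = None
    if tcfg.class_weighting:
        freq = np.bincount(all_labels, minlength=2).astype(np.float64)
        freq = np.maximum(freq, 1.0)
        class_weights = freq.sum() / (2.0 * freq)

    update = tcfg.learning_rate != 0.0  # lr == 0 disables updates entirely
    history = []
    for _ in range(tcfg.epochs):
        order = rng.permutation(len(graphs))
        epoch_losses = []
        for idx in order:
            g = graphs[idx]
            loss, grads = model.loss_and_grads(
                scaled_laplacians[idx], g.features, g.node_labels, rng=rng,
                class_weights=class_weights)
            if update:
                if tcfg.weight_decay:
                    for p, gr, d in zip(params, grads, decay):
                        if d:
                            gr += tcfg.weight_decay * p
                opt.step(params, grads)
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return model, history
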
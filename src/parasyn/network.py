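"""Two-layer feedforward network with parallel synapses.

Architecture: ``d_in`` inputs connect to ``d_hidden`` hidden units through
ordinary linear synapses; each hidden unit connects to each of the ``d_out``
output units through ``M`` parallel sigmoidal synapses sharing the hidden
unit's activity (``M = 0`` selects the linear comparison network).  Hidden
pre-activations are batch-normalized and passed through a Softplus
nonlinearity; training minimizes softmax cross-entropy.

Every hidden-to-output aggregate transmission function is constrained to be
monotonically increasing (excitatory): parallel-synapse slopes are projected
to be nonnegative after every optimizer step, and in the linear comparison
network the hidden-to-output weights are clamped nonnegative, so that the two
network types face the same constraint.

Learnable parameters, counting hidden and output biases, total
``(d_in + 1) d_hidden + (3 M d_hidden + 1) d_out`` for the parallel-synapse
network and ``(d_in + 1) d_hidden + (d_hidden + 1) d_out`` for the linear
one; batch-normalization scale/shift parameters are accounted separately.

Implemented directly in numpy with explicit gradients and an Adam optimizer.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit, softmax

__all__ = [
    "NetworkSpec",
    "NetTrainConfig",
    "parameter_count",
    "parameter_count_with_batchnorm",
    "ParallelSynapseNetwork",
    "train_network",
    "make_synthetic_images",
    "read_idx",
    "load_images_csv",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the two-layer network; ``M = 0`` means linear synapses."""

    d_in: int = 784
    d_hidden: int = 20
    d_out: int = 10
    M: int = 3
    constrain_positive: bool = True

    def __post_init__(self) -> None:
        if min(self.d_in, self.d_hidden, self.d_out) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if self.M < 0:
            raise ValueError("M must be >= 0")

    @property
    def linear(self) -> bool:
        return self.M == 0


def parameter_count(spec: NetworkSpec) -> int:
    """Learnable parameters including biases (batch-norm excluded).

    ``(d_in+1) d_hidden + (3 M d_hidden + 1) d_out`` with parallel synapses;
    the linear network replaces the second term by ``(d_hidden + 1) d_out``.
    """
    first = (spec.d_in + 1) * spec.d_hidden
    if spec.linear:
        return first + (spec.d_hidden + 1) * spec.d_out
    return first + (3 * spec.M * spec.d_hidden + 1) * spec.d_out


def parameter_count_with_batchnorm(spec: NetworkSpec) -> int:
    """As :func:`parameter_count` plus the 2·d_hidden batch-norm scale/shifts."""
    return parameter_count(spec) + 2 * spec.d_hidden


@dataclass
class NetTrainConfig:
    epochs: int = 50
    batch_size: int = 128
    lr: float = 1e-3
    bn_momentum: float = 0.9
    seed: int = 0


class ParallelSynapseNetwork:
    """The network's parameters, forward pass, gradients and optimizer."""

    BN_EPS = 1e-5

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d_in, d_h, d_out, M = spec.d_in, spec.d_hidden, spec.d_out, spec.M
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_h))
        self.b1 = np.zeros(d_h)
        self.gamma = np.ones(d_h)
        self.beta = np.zeros(d_h)
        self.running_mean = np.zeros(d_h)
        self.running_var = np.ones(d_h)
        self.b2 = np.zeros(d_out)
        if spec.linear:
            self.W2 = np.abs(rng.normal(0.0, np.sqrt(1.0 / d_h), size=(d_h, d_out)))
        else:
            # Hidden activities after BN + Softplus mostly fall in [0, ~2.5];
            # spread initial thresholds over that range.
            self.A = rng.normal(0.0, 0.3, size=(d_h, d_out, M))
            self.S = np.full((d_h, d_out, M), 2.0)
            self.T = rng.uniform(0.0, 2.5, size=(d_h, d_out, M))
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # --- parameter bookkeeping -------------------------------------------
    def _learnable(self) -> list[str]:
        base = ["W1", "b1", "b2"]
        base += ["W2"] if self.spec.linear else ["A", "S", "T"]
        return base

    def n_parameters(self, include_batchnorm: bool = False) -> int:
        """Actual count of allocated learnable scalars (self-consistency check
        for :func:`parameter_count`)."""
        n = sum(getattr(self, name).size for name in self._learnable())
        if include_batchnorm:
            n += self.gamma.size + self.beta.size
        return n

    # --- forward ----------------------------------------------------------
    def hidden_activity(self, X: np.ndarray, training: bool = False,
                        bn_momentum: float = 0.9) -> tuple[np.ndarray, dict]:
        pre = X @ self.W1 + self.b1
        if training:
            mu = pre.mean(axis=0)
            var = pre.var(axis=0)
            self.running_mean = bn_momentum * self.running_mean + (1 - bn_momentum) * mu
            self.running_var = bn_momentum * self.running_var + (1 - bn_momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
        xhat = (pre - mu) * inv_std
        bn = self.gamma * xhat + self.beta
        act = np.logaddexp(0.0, bn)  # Softplus
        cache = {"X": X, "xhat": xhat, "inv_std": inv_std, "bn": bn, "act": act}
        return act, cache

    def output_preactivation(self, act: np.ndarray) -> np.ndarray:
        if self.spec.linear:
            return act @ self.W2 + self.b2
        u = self.S[None] * (act[:, :, None, None] - self.T[None])
        contrib = (self.A[None] ** 2) * expit(u)
        return contrib.sum(axis=(1, 3)) + self.b2

    def forward(self, X: np.ndarray, training: bool = False,
                bn_momentum: float = 0.9) -> np.ndarray:
        """Logits for a batch of inputs, shape (n, d_out)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.d_in:
            raise ValueError(f"expected inputs of shape (n, {self.spec.d_in})")
        act, _ = self.hidden_activity(X, training=training, bn_momentum=bn_momentum)
        return self.output_preactivation(act)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).argmax(axis=1)

    def pair_aggregate(self, hidden: int, out: int, grid: np.ndarray) -> np.ndarray:
        """Aggregate hidden->output transmission for one pair on a grid."""
        if self.spec.linear:
            return self.W2[hidden, out] * np.asarray(grid)
        u = self.S[hidden, out][None, :] * (np.asarray(grid)[:, None] - self.T[hidden, out][None, :])
        return ((self.A[hidden, out][None, :] ** 2) * expit(u)).sum(axis=1)

    # --- backward + optimizer --------------------------------------------
    def _loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                        bn_momentum: float) -> tuple[float, dict[str, np.ndarray]]:
        n = X.shape[0]
        act, cache = self.hidden_activity(X, training=True, bn_momentum=bn_momentum)
        logits = self.output_preactivation(act)
        probs = softmax(logits, axis=1)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-300).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads: dict[str, np.ndarray] = {"b2": dlogits.sum(axis=0)}
        if self.spec.linear:
            grads["W2"] = act.T @ dlogits
            dact = dlogits @ self.W2.T
        else:
            d = act[:, :, None, None] - self.T[None]
            sig = expit(self.S[None] * d)
            core = (self.A[None] ** 2) * sig * (1.0 - sig)
            dl = dlogits[:, None, :, None]
            grads["A"] = (dl * 2.0 * self.A[None] * sig).sum(axis=0)
            grads["S"] = (dl * core * d).sum(axis=0)
            grads["T"] = (-dl * core * self.S[None]).sum(axis=0)
            dact = (dl * core * self.S[None]).sum(axis=(2, 3))

        dbn = dact * expit(cache["bn"])  # Softplus'
        grads["gamma"] = (dbn * cache["xhat"]).sum(axis=0)
        grads["beta"] = dbn.sum(axis=0)
        dxhat = dbn * self.gamma
        xhat = cache["xhat"]
        dpre = (cache["inv_std"] / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        grads["W1"] = cache["X"].T @ dpre
        grads["b1"] = dpre.sum(axis=0)
        return loss, grads

    def adam_step(self, grads: dict[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            p = getattr(self, name)
            m, v = self._adam_state.get(name, (np.zeros_like(p), np.zeros_like(p)))
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g**2
            self._adam_state[name] = (m, v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            setattr(self, name, p - lr * mhat / (np.sqrt(vhat) + eps))
        self._project()

    def _project(self) -> None:
        """Enforce monotone (excitatory) hidden-to-output transmission."""
        if self.spec.linear:
            if self.spec.constrain_positive:
                np.clip(self.W2, 0.0, None, out=self.W2)
        else:
            np.clip(self.S, 0.0, None, out=self.S)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == y).mean())


def train_network(
    spec: NetworkSpec,
    train_data: tuple[np.ndarray, np.ndarray],
    config: NetTrainConfig | None = None,
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ParallelSynapseNetwork, list[float]]:
    """Minibatch Adam training with per-step monotonicity projection.

    Returns the trained network and the per-epoch accuracy trace on
    ``val_data`` (or on the training data when no validation set is given).
    """
    cfg = config or NetTrainConfig()
    X, y = np.asarray(train_data[0], dtype=float), np.asarray(train_data[1], dtype=int)
    net = ParallelSynapseNetwork(spec, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    eval_X, eval_y = val_data if val_data is not None else (X, y)
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue  # batch norm needs at least two samples
            _, grads = net._loss_and_grads(X[idx], y[idx], cfg.bn_momentum)
            net.adam_step(grads, cfg.lr)
        trace.append(net.accuracy(eval_X, eval_y))
    return net, trace


def make_synthetic_images(
    n_samples: int, side: int = 4, n_classes: int = 2, noise: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Small synthetic image-classification fixture (synthetic stand-in for
    real digit data, used by tests and the ``--synthetic`` CLI path).

    Each class has a fixed bright-region template on a ``side x side`` grid
    (class 0: top rows, class 1: bottom rows, further classes: random but
    fixed masks); samples are the template plus Gaussian pixel noise, clipped
    to [0, 1].  Linearly separable by construction for small noise.
    """
    rng = np.random.default_rng(seed)
    d = side * side
    templates = np.zeros((n_classes, d))
    templates[0].reshape(side, side)[: side // 2, :] = 1.0
    if n_classes > 1:
        templates[1].reshape(side, side)[side // 2:, :] = 1.0
    template_rng = np.random.default_rng(12345)
    for k in range(2, n_classes):
        templates[k] = (template_rng.random(d) < 0.5).astype(float)
    y = rng.integers(0, n_classes, size=n_samples)
    X = templates[y] + rng.normal(0.0, noise, size=(n_samples, d))
    return np.clip(X, 0.0, 1.0), y


_IDX_DTYPES = {
    0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
    0x0D: ">f4", 0x0E: ">f8",
}


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX-format array (the standard digit-image container)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4 or raw[0] != 0 or raw[1] != 0:
        raise ValueError("not an IDX file")
    dtype = _IDX_DTYPES.get(raw[2])
    if dtype is None:
        raise ValueError(f"unsupported IDX type code 0x{raw[2]:02x}")
    ndim = raw[3]
    dims = struct.unpack(f">{ndim}I", raw[4:4 + 4 * ndim])
    data = np.frombuffer(raw[4 + 4 * ndim:], dtype=dtype)
    return data.reshape(dims)


def load_images_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """CSV fallback reader: first column 'label', remaining columns pixels
    in [0, 255] or [0, 1]."""
    import pandas as pd

    df = pd.read_csv(path)
    y = df.iloc[:, 0].to_numpy(dtype=int)
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if X.size and X.max() > 1.0:
        X = X / 255.0
    return X, y
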
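"""Restricted parallel-synapse neuron: M sigmoidal synapses per axon.

Model
-----
A single neuron receives ``N`` axonal inputs; each axon makes ``M`` parallel
synaptic contacts.  Synapse ``(i, j)`` transmits a sigmoidal current

    h_ij(x) = a_ij^2 / (1 + exp(-s_ij (x - t_ij)))

with amplitude ``a^2`` (squared so it stays nonnegative), slope ``s >= 0``
(excitatory synapses respond monotonically), and threshold ``t`` (the input at
which the response rises fastest).  Currents add linearly at the soma — there
are no dendritic nonlinearities — so the total current for pattern ``x`` is
``z = sum_ij h_ij(x_i)`` and the prediction is ``sign(z - theta)`` with somatic
threshold ``theta`` (``sign(0)`` resolves to -1 by convention).

Training minimizes the hinge loss ``L = sum_mu max(0, eps - (z_mu - theta) y_mu)``
by synchronous full-batch gradient descent restricted to the margin-violation
set, with a periodic "resurrection" heuristic that revives synapses whose
amplitude has collapsed (their gradients all vanish with the amplitude).

An equivalent hyperbolic-tangent parameterization
``h'(x) = a'^2 tanh(s'(x - t'))`` is provided; it is centered around zero,
which eases learning of ``theta``, and maps exactly onto the sigmoid form via
``a^2 = 2 a'^2, s = 2 s', t = t', theta = theta' + sum a'^2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import _fastloop
from .patterns import PatternSet

__all__ = [
    "SynapseParams",
    "RestrictedNeuron",
    "TrainConfig",
    "TrainReport",
    "sigmoid_transmission",
    "tanh_form_transmission",
    "convert_tanh_to_sigmoid",
    "total_current",
    "predict",
    "hinge_loss",
    "margin_violation_set",
    "gradient_step",
    "resurrect_dead_synapses",
    "train_restricted",
    "initialize_neuron",
    "RestrictedNeuronModel",
    "RestrictedNeuronResults",
]


@dataclass(frozen=True)
class SynapseParams:
    """Parameters of one sigmoidal synapse: amplitude root, slope, threshold."""

    a: float
    s: float
    t: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("slope s must be nonnegative (monotone transmission)")


def sigmoid_transmission(p: SynapseParams, x):
    """Transmission current of one synapse, ``a^2 * logistic(s (x - t))``.

    Bounded in ``[0, a^2]``; equals ``a^2 / 2`` at ``x = t``.
    """
    return p.a**2 * expit(p.s * (np.asarray(x, dtype=float) - p.t))


def tanh_form_transmission(p: SynapseParams, x):
    """Transmission in the centered form, ``a'^2 * tanh(s'(x - t'))``.

    Identical to ``2 a'^2 logistic(2 s'(x - t')) - a'^2``; antisymmetric about
    ``x = t'`` and bounded in ``[-a'^2, a'^2]``.
    """
    return p.a**2 * np.tanh(p.s * (np.asarray(x, dtype=float) - p.t))


@dataclass
class RestrictedNeuron:
    """Parameter grid of an N-axon, M-synapse-per-axon neuron.

    ``a``, ``s``, ``t`` are (N, M) arrays; ``theta`` is the somatic threshold.
    ``parameterization`` records which functional form the parameters live in:
    ``"sigmoid"`` (nonnegative transmissions) or ``"tanh"`` (centered).
    """

    a: np.ndarray
    s: np.ndarray
    t: np.ndarray
    theta: float
    parameterization: str = "sigmoid"

    def __post_init__(self) -> None:
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.s = np.atleast_2d(np.asarray(self.s, dtype=float))
        self.t = np.atleast_2d(np.asarray(self.t, dtype=float))
        if not (self.a.shape == self.s.shape == self.t.shape):
            raise ValueError("a, s, t must share the (N, M) shape")
        if self.parameterization not in ("sigmoid", "tanh"):
            raise ValueError("parameterization must be 'sigmoid' or 'tanh'")
        if (self.s < 0).any():
            raise ValueError("slopes must be nonnegative")

    @property
    def num_axons(self) -> int:
        return self.a.shape[0]

    @property
    def synapses_per_axon(self) -> int:
        return self.a.shape[1]

    def copy(self) -> "RestrictedNeuron":
        return RestrictedNeuron(
            a=self.a.copy(), s=self.s.copy(), t=self.t.copy(),
            theta=float(self.theta), parameterization=self.parameterization,
        )

    def synapse_currents(self, X: np.ndarray) -> np.ndarray:
        """Per-synapse currents, shape (P, N, M), for inputs X of shape (P, N)."""
        u = self.s[None, :, :] * (X[:, :, None] - self.t[None, :, :])
        if self.parameterization == "sigmoid":
            return self.a[None, :, :] ** 2 * expit(u)
        return self.a[None, :, :] ** 2 * np.tanh(u)

    def total_current(self, x) -> np.ndarray | float:
        """Somatic current ``z``; accepts one pattern (N,) or a batch (P, N)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = x[None, :] if single else x
        if X.shape[1] != self.num_axons:
            raise ValueError(
                f"input has {X.shape[1]} axons, neuron expects {self.num_axons}"
            )
        z = self.synapse_currents(X).sum(axis=(1, 2))
        return float(z[0]) if single else z

    def predict(self, x) -> np.ndarray | int:
        """Classify: +1 iff ``z - theta > 0``, else -1 (ties go to -1)."""
        z = self.total_current(x)
        pred = np.where(np.asarray(z) - self.theta > 0, 1, -1)
        return int(pred) if np.isscalar(z) else pred

    def aggregate_axon_values(self, axon: int, grid: np.ndarray) -> np.ndarray:
        """Aggregate transmission of one axon, ``sum_j h_ij``, on a grid."""
        u = self.s[axon][None, :] * (np.asarray(grid)[:, None] - self.t[axon][None, :])
        f = expit(u) if self.parameterization == "sigmoid" else np.tanh(u)
        return (self.a[axon][None, :] ** 2 * f).sum(axis=1)

    # --- persistence ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "num_axons": self.num_axons,
            "synapses_per_axon": self.synapses_per_axon,
            "theta": self.theta,
            "parameterization": self.parameterization,
            "a": self.a.tolist(),
            "s": self.s.tolist(),
            "t": self.t.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RestrictedNeuron":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            a=np.array(d["a"]), s=np.array(d["s"]), t=np.array(d["t"]),
            theta=float(d["theta"]), parameterization=d["parameterization"],
        )


def total_current(neuron: RestrictedNeuron, x):
    return neuron.total_current(x)


def predict(neuron: RestrictedNeuron, x):
    return neuron.predict(x)


def convert_tanh_to_sigmoid(neuron: RestrictedNeuron) -> RestrictedNeuron:
    """Map a tanh-form neuron to the equivalent sigmoid-form neuron.

    From ``tanh(u) = 2 sigma(2u) - 1``, each synapse satisfies
    ``a'^2 tanh(s'(x - t')) = 2 a'^2 sigma(2 s'(x - t')) - a'^2``, so the
    mapping ``a^2 = 2 a'^2``, ``s = 2 s'``, ``t = t'`` together with
    ``theta = theta' + sum_ij a'_ij^2`` preserves the margin ``z - theta``
    (hence every prediction) exactly.
    """
    if neuron.parameterization != "tanh":
        raise ValueError("expected a tanh-form neuron")
    return RestrictedNeuron(
        a=np.sqrt(2.0) * np.abs(neuron.a),
        s=2.0 * neuron.s,
        t=neuron.t.copy(),
        theta=float(neuron.theta) + float((neuron.a**2).sum()),
        parameterization="sigmoid",
    )


@dataclass
class TrainConfig:
    """Hyperparameters of hinge-loss gradient training.

    ``margin`` is the hinge margin epsilon (0.1 during training).  The four
    learning rates are deliberately *per parameter family*: the summed
    amplitude/threshold gradients grow with the number of patterns P while
    slope gradients are intrinsically small (they carry a factor
    ``a^2 (1 - tanh^2)`` that vanishes off-threshold), so a single shared
    rate either stalls the slopes or blows up the amplitudes.  Rates left at
    ``None`` are resolved at fit time to the scaled defaults

        lr_a = 0.06 / P,  lr_s = 4.5,  lr_t = 0.18 / P,  lr_theta = 0.015 / P

    which keep the per-epoch parameter motion roughly P-independent.  The
    step size is further modulated by ``1/sqrt(1 + (epoch mod cycle)/tau)``
    — a square-root annealing schedule with warm restarts that lets early
    epochs reorganize the synapses and late epochs settle the last few
    margin violations.  ``patience`` stops a run whose best error count has
    not improved for that many epochs (0 disables).  The resurrection redraw
    distribution is an equal mixture of Beta(b1, b2) and Beta(b2, b1) —
    U-shaped on [0, 1], dense near the edges of the input range like the
    learned threshold distribution.
    """

    margin: float = 0.1
    lr_a: float | None = None
    lr_s: float | None = None
    lr_t: float | None = None
    lr_theta: float | None = None
    max_epochs: int = 40000
    anneal_tau: float = 2000.0
    anneal_cycle: int = 20000
    patience: int = 15000
    resurrection_floor: float = 0.01
    resurrection_check_every: int = 500
    resurrection_beta: tuple[float, float] = (0.5, 3.0)
    parameterization: str = "tanh"
    init_a_std: float = 0.3
    init_slope: float = 10.0
    seed: int = 0

    # reference scales for the auto-resolved rates
    _AUTO = {"lr_a": 0.06, "lr_s": 4.5, "lr_t": 0.18, "lr_theta": 0.015}

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        for name in ("lr_a", "lr_s", "lr_t", "lr_theta"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resurrection_floor <= 0:
            raise ValueError("resurrection_floor must be positive")
        if self.max_epochs < 1 or self.resurrection_check_every < 1:
            raise ValueError("epoch counts must be positive")
        if self.anneal_tau <= 0 or self.anneal_cycle < 1 or self.patience < 0:
            raise ValueError("invalid annealing/patience settings")

    def resolved_rates(self, num_patterns: int) -> tuple[float, float, float, float]:
        """Concrete (lr_a, lr_s, lr_t, lr_theta) for a P-pattern problem."""
        P = max(int(num_patterns), 1)
        out = []
        for name, scale in self._AUTO.items():
            v = getattr(self, name)
            if v is None:
                v = scale if name == "lr_s" else scale / P
            out.append(float(v))
        return tuple(out)


@dataclass
class TrainReport:
    success: bool
    epochs: int
    final_loss: float
    final_errors: int
    resurrections: int


def hinge_loss(neuron: RestrictedNeuron, data: PatternSet, margin: float) -> float:
    """Hinge loss ``sum_mu max(0, eps - (z_mu - theta) y_mu)``."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    if len(data) == 0:
        return 0.0
    m = (neuron.total_current(data.inputs) - neuron.theta) * data.labels
    return float(np.maximum(0.0, margin - m).sum())


def margin_violation_set(neuron: RestrictedNeuron, data: PatternSet, margin: float) -> np.ndarray:
    """Indices mu with ``eps - (z_mu - theta) y_mu > 0`` (strict)."""
    if len(data) == 0:
        return np.array([], dtype=int)
    m = (neuron.total_current(data.inputs) - neuron.theta) * data.labels
    return np.flatnonzero(margin - m > 0)


def _grad_sums(neuron: RestrictedNeuron, X: np.ndarray, y: np.ndarray):
    """Summed update directions over the given (violating) patterns.

    Returns (da, ds, dt, dtheta_sum) such that gradient descent on the hinge
    loss is ``a += lr_a * da`` etc. and ``theta -= lr_theta * dtheta_sum``.
    """
    a2 = neuron.a[None, :, :] ** 2
    d = X[:, :, None] - neuron.t[None, :, :]
    u = neuron.s[None, :, :] * d
    yv = y[:, None, None].astype(float)
    if neuron.parameterization == "sigmoid":
        S = expit(u)
        da = (yv * 2.0 * neuron.a[None, :, :] * S).sum(axis=0)
        core = a2 * S * (1.0 - S)
    else:
        T = np.tanh(u)
        da = (yv * 2.0 * neuron.a[None, :, :] * T).sum(axis=0)
        core = a2 * (1.0 - T**2)
    ds = (yv * core * d).sum(axis=0)
    dt = -(yv * core * neuron.s[None, :, :]).sum(axis=0)
    return da, ds, dt, float(y.sum())


def gradient_step(neuron: RestrictedNeuron, data: PatternSet, cfg: TrainConfig) -> RestrictedNeuron:
    """One synchronous full-batch update over the margin-violation set.

    All four parameter families move along the exact negative gradient of the
    hinge loss, computed from the pre-update parameters; afterwards slopes are
    projected back to ``s >= 0``.  An empty violation set leaves the neuron
    unchanged.
    """
    out = neuron.copy()
    omega = margin_violation_set(neuron, data, cfg.margin)
    if omega.size == 0:
        return out
    lr_a, lr_s, lr_t, lr_theta = cfg.resolved_rates(len(data))
    da, ds, dt, dth = _grad_sums(neuron, data.inputs[omega], data.labels[omega])
    out.a += lr_a * da
    out.s += lr_s * ds
    out.t += lr_t * dt
    out.theta -= lr_theta * dth
    np.clip(out.s, 0.0, None, out=out.s)
    return out


def _effective_amplitude(neuron: RestrictedNeuron) -> np.ndarray:
    """Amplitude on the sigmoid scale: a^2, or 2 a'^2 in the tanh form."""
    amp = neuron.a**2
    return 2.0 * amp if neuron.parameterization == "tanh" else amp


def _draw_edge_thresholds(rng: np.random.Generator, size: int, beta: tuple[float, float]) -> np.ndarray:
    """U-shaped threshold redraws: equal mixture of Beta(b1,b2) and Beta(b2,b1)."""
    b1, b2 = beta
    lo = rng.beta(b1, b2, size=size)
    hi = rng.beta(b2, b1, size=size)
    pick = rng.random(size) < 0.5
    return np.where(pick, lo, hi)


def resurrect_dead_synapses(
    neuron: RestrictedNeuron, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[RestrictedNeuron, int]:
    """Revive synapses whose amplitude collapsed below the floor.

    A synapse with (sigmoid-scale) amplitude below ``resurrection_floor`` has
    vanishing gradients on all of its parameters, so it can never recover on
    its own.  Its amplitude is raised to exactly the floor and its threshold
    redrawn from the edge-weighted distribution; slopes and live synapses are
    untouched.
    """
    out = neuron.copy()
    dead = _effective_amplitude(neuron) < cfg.resurrection_floor
    count = int(dead.sum())
    if count:
        floor_a = (
            np.sqrt(cfg.resurrection_floor / 2.0)
            if neuron.parameterization == "tanh"
            else np.sqrt(cfg.resurrection_floor)
        )
        out.a[dead] = floor_a
        out.t[dead] = _draw_edge_thresholds(rng, count, cfg.resurrection_beta)
    return out, count


def initialize_neuron(
    num_axons: int, synapses_per_axon: int, cfg: TrainConfig, rng: np.random.Generator
) -> RestrictedNeuron:
    """Seeded default initialization: a ~ N(0, std), s fixed, t ~ U(0,1), theta=0."""
    shape = (num_axons, synapses_per_axon)
    return RestrictedNeuron(
        a=rng.normal(0.0, cfg.init_a_std, size=shape),
        s=np.full(shape, float(cfg.init_slope)),
        t=rng.uniform(0.0, 1.0, size=shape),
        theta=0.0,
        parameterization=cfg.parameterization,
    )


def train_restricted(
    data: PatternSet,
    num_axons: int,
    synapses_per_axon: int,
    cfg: TrainConfig | None = None,
    neuron: RestrictedNeuron | None = None,
) -> tuple[RestrictedNeuron, TrainReport]:
    """Train a restricted neuron until all patterns are classified or the
    epoch budget runs out.

    Success means zero sign errors on the training set (patterns correct by
    less than the hinge margin still count as correctly classified).  Failure
    to converge is reported, not raised.
    """
    cfg = cfg or TrainConfig()
    if data.num_patterns and data.num_axons != num_axons:
        raise ValueError("data dimensionality does not match num_axons")
    rng = np.random.default_rng(cfg.seed)
    if neuron is None:
        neuron = initialize_neuron(num_axons, synapses_per_axon, cfg, rng)
    else:
        neuron = neuron.copy()

    if len(data) == 0:
        return neuron, TrainReport(True, 0, 0.0, 0, 0)

    X, y = data.inputs, data.labels
    lr_a, lr_s, lr_t, lr_theta = cfg.resolved_rates(len(y))

    if neuron.parameterization == "tanh" and _fastloop.HAVE_NUMBA:
        n_checks = cfg.max_epochs // cfg.resurrection_check_every + 1
        pool_size = min(max(n_checks * neuron.a.size, 1), 200_000)
        res_pool = _draw_edge_thresholds(rng, pool_size, cfg.resurrection_beta)
        theta, status, epochs_run, resurrections = _fastloop.train_loop_tanh(
            np.ascontiguousarray(X), y.astype(np.float64),
            neuron.a, neuron.s, neuron.t, float(neuron.theta),
            lr_a, lr_s, lr_t, lr_theta, cfg.margin, cfg.max_epochs,
            cfg.resurrection_check_every, cfg.resurrection_floor, res_pool,
            float(cfg.anneal_tau), int(cfg.anneal_cycle), int(cfg.patience),
        )
        neuron.theta = float(theta)
        if status == -1:
            return neuron, TrainReport(False, epochs_run, float("inf"),
                                       len(y), resurrections)
        with np.errstate(over="ignore", invalid="ignore"):
            m = (neuron.total_current(X) - neuron.theta) * y
            errors = int((m <= 0).sum())
            loss = float(np.maximum(0.0, cfg.margin - m).sum())
        return neuron, TrainReport(errors == 0, epochs_run, loss, errors,
                                   resurrections)

    resurrections = 0
    epochs_run = 0
    best_errors = len(y) + 1
    best_epoch = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for epoch in range(cfg.max_epochs):
            z = neuron.total_current(X)
            if not np.isfinite(z).all():
                # diverged (runaway amplitudes): an honest failure, not success
                return neuron, TrainReport(False, epochs_run, float("inf"),
                                           len(y), resurrections)
            m = (z - neuron.theta) * y
            errors = int((m <= 0).sum())  # ties predict -1, so m == 0 is an error
            if errors == 0:
                loss = float(np.maximum(0.0, cfg.margin - m).sum())
                return neuron, TrainReport(True, epochs_run, loss, 0, resurrections)
            if errors < best_errors:
                best_errors, best_epoch = errors, epoch
            elif cfg.patience and epoch - best_epoch >= cfg.patience:
                break
            decay = 1.0 / np.sqrt(1.0 + (epoch % cfg.anneal_cycle) / cfg.anneal_tau)
            omega = np.flatnonzero(cfg.margin - m > 0)
            da, ds, dt, dth = _grad_sums(neuron, X[omega], y[omega])
            neuron.a += decay * lr_a * da
            neuron.s += decay * lr_s * ds
            neuron.t += decay * lr_t * dt
            neuron.theta -= decay * lr_theta * dth
            np.clip(neuron.s, 0.0, None, out=neuron.s)
            epochs_run = epoch + 1
            if epochs_run % cfg.resurrection_check_every == 0:
                neuron, n_res = resurrect_dead_synapses(neuron, cfg, rng)
                resurrections += n_res

        z = neuron.total_current(X)
        if not np.isfinite(z).all():
            return neuron, TrainReport(False, epochs_run, float("inf"),
                                       len(y), resurrections)
        m = (z - neuron.theta) * y
        errors = int((m <= 0).sum())
        loss = float(np.maximum(0.0, cfg.margin - m).sum())
    return neuron, TrainReport(errors == 0, epochs_run, loss, errors, resurrections)


class RestrictedNeuronModel:
    """Restricted parallel-synapse neuron fitted to a :class:`PatternSet`.

    Examples
    --------
    >>> from parasyn.patterns import make_fixture
    >>> model = RestrictedNeuronModel(make_fixture("sep2"), synapses_per_axon=1)
    >>> res = model.fit()
    >>> bool(res.converged)
    True
    """

    def __init__(self, data: PatternSet, synapses_per_axon: int, config: TrainConfig | None = None):
        self.data = data
        self.synapses_per_axon = int(synapses_per_axon)
        self.config = config or TrainConfig()

    def fit(self, **overrides) -> "RestrictedNeuronResults":
        cfg = replace(self.config, **overrides) if overrides else self.config
        neuron, report = train_restricted(
            self.data, self.data.num_axons, self.synapses_per_axon, cfg
        )
        return RestrictedNeuronResults(self, neuron, report, cfg)


@dataclass
class RestrictedNeuronResults:
    model: RestrictedNeuronModel
    neuron: RestrictedNeuron
    report: TrainReport
    config: TrainConfig

    @property
    def converged(self) -> bool:
        return self.report.success

    def predict(self, x):
        return self.neuron.predict(x)

    def as_sigmoid(self) -> RestrictedNeuron:
        if self.neuron.parameterization == "tanh":
            return convert_tanh_to_sigmoid(self.neuron)
        return self.neuron

    def summary(self) -> str:
        n, m = self.neuron.num_axons, self.neuron.synapses_per_axon
        r = self.report
        lines = [
            "Restricted parallel-synapse neuron",
            "==================================",
            f"axons (N):            {n}",
            f"synapses/axon (M):    {m}",
            f"patterns (P):         {self.model.data.num_patterns}",
            f"parameterization:     {self.neuron.parameterization}",
            f"converged:            {r.success}",
            f"epochs:               {r.epochs}",
            f"final hinge loss:     {r.final_loss:.6g}",
            f"training errors:      {r.final_errors}",
            f"resurrected synapses: {r.resurrections}",
            f"theta:                {self.neuron.theta:.6g}",
        ]
        return "\n".join(lines)
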
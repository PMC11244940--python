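"""Unrestricted parallel-synapse neuron: monotone staircase aggregates.

In the limit of unlimited parallel synapses per axon, each axon's aggregate
transmission function becomes an arbitrary nondecreasing staircase: on a
dataset of ``P`` points it can take at most ``P`` values ``I_alpha`` (alpha
indexing the data points by ascending input on that axon), with nonnegative
step sizes ``rho_beta^2`` and the smallest value pinned to ``I_1 = 0``.

Training decomposes over axons.  Each axon minimizes the regularized,
importance-weighted objective

    C = - sum_alpha y_alpha w_alpha I_alpha + lambda * sum_alpha I_alpha^2

over nondecreasing ``I`` with ``I_1 = 0``: labels pull their point's function
value up (+1) or down (-1), weights ``w`` mark hard points, and the L2 term
keeps somatic currents realistic.  The exact minimizer is found by the
*envelope method*: treat ``y_alpha w_alpha`` as the steps of a random walk;
the staircase takes steps exactly where the convex envelope of the cumulative
walk touches it, and each touching segment's value is its mean slope over
``2 lambda`` (clipped at zero).  This is, equivalently, a weighted isotonic
regression of ``y w / (2 lambda)`` — the stationarity conditions of the two
problems coincide.

An outer loop alternates exact per-axon solves with importance reweighting:
every misclassified point's weight is incremented by one, until all points
are classified or an iteration budget is exhausted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .patterns import PatternSet

__all__ = [
    "StaircaseAxon",
    "UnrestrictedNeuron",
    "SolverConfig",
    "UnrestrictedReport",
    "envelope_solve",
    "evaluate_axon",
    "optimal_threshold",
    "train_unrestricted",
    "count_effective_synapses",
    "UnrestrictedNeuronModel",
    "UnrestrictedNeuronResults",
]


@dataclass(frozen=True)
class StaircaseAxon:
    """One axon's staircase aggregate: sorted knots and nondecreasing values.

    ``values[0]`` is pinned to 0; ``steps`` are the nonnegative increments
    ``rho_beta^2`` between consecutive knots.
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.shape != values.shape or knots.ndim != 1:
            raise ValueError("knots and values must be matching 1-D arrays")
        if knots.size:
            if (np.diff(knots) <= 0).any():
                raise ValueError("knots must be strictly ascending")
            if abs(values[0]) > 1e-12:
                raise ValueError("first staircase value must be 0")
            if (np.diff(values) < -1e-12).any():
                raise ValueError("staircase values must be nondecreasing")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    @property
    def steps(self) -> np.ndarray:
        """Step sizes rho_beta^2 between consecutive knots (length K-1)."""
        return np.diff(self.values)


def _isotonic_segments(targets: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted nondecreasing isotonic fit via the envelope construction.

    Equivalent to pool-adjacent-violators: scanning the cumulative
    weight/target walk, segments whose mean slopes would decrease are merged,
    which is exactly taking the greatest convex minorant of the walk; the
    returned values are the segment slopes, nondecreasing by construction.
    """
    sums: list[float] = []
    cnts: list[float] = []
    bounds: list[int] = []
    for k in range(targets.size):
        s, c = targets[k] * weights[k], weights[k]
        while sums and sums[-1] / cnts[-1] >= s / c:
            s += sums.pop()
            c += cnts.pop()
            bounds.pop()
        sums.append(s)
        cnts.append(c)
        bounds.append(k + 1)
    out = np.empty(targets.size)
    start = 0
    for s, c, end in zip(sums, cnts, bounds):
        out[start:end] = s / c
        start = end
    return out


def envelope_solve(
    labels_sorted: np.ndarray,
    weights_sorted: np.ndarray,
    lam: float,
    counts: np.ndarray | None = None,
) -> np.ndarray:
    """Exact minimizer of the per-axon staircase objective.

    Parameters
    ----------
    labels_sorted, weights_sorted : arrays of length P
        Labels in {-1, +1} and positive importance weights, ordered by
        ascending input value on this axon.  With *counts* given, entry k is
        instead the summed label-weight product of the ``counts[k]`` points
        tied at knot k (tied inputs must share one function value).
    lam : float
        Positive L2 regularization coefficient.

    Returns
    -------
    ndarray of length P with ``I[0] = 0``, nondecreasing and nonnegative; the
    unique minimizer of ``-sum y w I + lam sum I^2`` over that cone.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = np.asarray(labels_sorted, dtype=float)
    if y.size == 0:
        return np.array([])
    if counts is None:
        w = np.asarray(weights_sorted, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        yw = y * w
        counts = np.ones_like(yw)
    else:
        yw = y  # already summed per knot
        counts = np.asarray(counts, dtype=float)
    values = np.zeros(yw.size)
    if yw.size > 1:
        targets = yw[1:] / (2.0 * lam * counts[1:])
        fit = _isotonic_segments(targets, counts[1:])
        values[1:] = np.maximum(fit, 0.0)
    return values


def evaluate_axon(axon: StaircaseAxon, x) -> np.ndarray | float:
    """Staircase value at arbitrary input: right-continuous, left-constant.

    Below the first knot the aggregate is 0; above the last knot it stays at
    the last value.
    """
    x = np.asarray(x, dtype=float)
    idx = np.searchsorted(axon.knots, x, side="right") - 1
    padded = np.concatenate(([0.0], axon.values))
    out = padded[idx + 1]
    return float(out) if x.ndim == 0 else out


@dataclass
class UnrestrictedNeuron:
    """N staircase axons plus a somatic threshold.

    ``permutations[i]`` maps sorted order alpha back to pattern order mu for
    axon i (it is the argsort of the training inputs on that axon).
    """

    axons: list[StaircaseAxon]
    theta: float
    permutations: list[np.ndarray] | None = None

    @property
    def num_axons(self) -> int:
        return len(self.axons)

    def total_current(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = x[None, :] if single else x
        if X.shape[1] != self.num_axons:
            raise ValueError("input dimensionality mismatch")
        z = np.zeros(X.shape[0])
        for i, axon in enumerate(self.axons):
            z += evaluate_axon(axon, X[:, i])
        return float(z[0]) if single else z

    def predict(self, x) -> np.ndarray | int:
        z = self.total_current(x)
        pred = np.where(np.asarray(z) - self.theta > 0, 1, -1)
        return int(pred) if np.isscalar(z) else pred

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "theta": self.theta,
            "axons": [
                {"knots": ax.knots.tolist(), "values": ax.values.tolist()}
                for ax in self.axons
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "UnrestrictedNeuron":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        axons = [
            StaircaseAxon(np.array(a["knots"]), np.array(a["values"]))
            for a in d["axons"]
        ]
        return cls(axons=axons, theta=float(d["theta"]))


def optimal_threshold(z: np.ndarray, y: np.ndarray) -> float:
    """Exact 1-D split of the currents minimizing training errors.

    Scans all cuts of the sorted currents; returns the midpoint of the best
    gap (ties broken toward fewer false positives, i.e. the larger
    threshold).  Predictions use ``sign(z - theta)`` with ties counted as -1.
    """
    order = np.argsort(z, kind="stable")
    zs, ys = z[order], y[order]
    P = zs.size
    cum_pos = np.concatenate(([0], np.cumsum(ys == 1)))
    cum_neg = np.concatenate(([0], np.cumsum(ys == -1)))
    total_neg = cum_neg[-1]
    # k = number of lowest-current points predicted -1; valid cuts fall in
    # gaps between distinct current values (or outside the range).
    ks = np.flatnonzero(
        np.concatenate(([True], zs[1:] > zs[:-1], [True]))
    )
    errors = cum_pos[ks] + (total_neg - cum_neg[ks])
    best = errors.min()
    k = int(ks[np.flatnonzero(errors == best)[-1]])  # largest k: fewer FP
    if k == 0:
        return float(zs[0] - 1.0)
    if k == P:
        return float(zs[-1])
    return float(0.5 * (zs[k - 1] + zs[k]))


@dataclass
class SolverConfig:
    """Outer-loop settings for the unrestricted model.

    ``lam=None`` defaults to ``1/(2P)`` at fit time so that typical staircase
    values are order one.  The solver itself is deterministic; ``seed`` is
    recorded for provenance only.
    """

    lam: float | None = None
    max_outer_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be positive")


@dataclass
class UnrestrictedReport:
    success: bool
    iterations: int
    final_errors: int
    weight_histogram: dict[int, int]


def train_unrestricted(
    data: PatternSet, cfg: SolverConfig | None = None
) -> tuple[UnrestrictedNeuron, UnrestrictedReport, np.ndarray]:
    """Iterative envelope solve + importance reweighting.

    Each outer iteration re-solves every axon's staircase exactly for the
    current weights, sets the somatic threshold by the optimal 1-D split of
    the total currents, and increments the weight of every misclassified
    point by one.  Stops at zero errors or the iteration budget.

    Returns the neuron, a report, and the final importance weights (in
    pattern order).
    """
    cfg = cfg or SolverConfig()
    X, y = data.inputs, data.labels
    P, N = X.shape
    lam = cfg.lam if cfg.lam is not None else 1.0 / (2.0 * max(P, 1))

    # Per-axon knot structure (tied inputs share a knot and a value).
    knots_list, inv_list, counts_list, perms = [], [], [], []
    for i in range(N):
        knots, inv = np.unique(X[:, i], return_inverse=True)
        knots_list.append(knots)
        inv_list.append(inv)
        counts_list.append(np.bincount(inv).astype(float))
        perms.append(np.argsort(X[:, i], kind="stable"))

    w = np.ones(P)
    neuron = None
    errors = P
    iters = 0
    for it in range(cfg.max_outer_iterations):
        iters = it + 1
        z = np.zeros(P)
        axons = []
        for i in range(N):
            yw_knot = np.bincount(inv_list[i], weights=y * w)
            vals = envelope_solve(yw_knot, None, lam, counts=counts_list[i])
            axons.append(StaircaseAxon(knots_list[i], vals))
            z += vals[inv_list[i]]
        theta = optimal_threshold(z, y)
        neuron = UnrestrictedNeuron(axons=axons, theta=theta, permutations=perms)
        pred = np.where(z - theta > 0, 1, -1)
        mis = pred != y
        errors = int(mis.sum())
        if errors == 0:
            break
        w[mis] += 1.0

    hist_vals, hist_counts = np.unique(w.astype(int), return_counts=True)
    report = UnrestrictedReport(
        success=errors == 0,
        iterations=iters,
        final_errors=errors,
        weight_histogram=dict(zip(hist_vals.tolist(), hist_counts.tolist())),
    )
    return neuron, report, w


def count_effective_synapses(neuron: UnrestrictedNeuron) -> np.ndarray:
    """Effective parallel synapses per axon.

    A staircase step counts as an effective synapse when its size strictly
    exceeds 1/1000 of the maximum step size across the whole neuron.  An
    all-zero neuron has no effective synapses.
    """
    all_steps = [ax.steps for ax in neuron.axons]
    max_step = max((s.max() if s.size else 0.0) for s in all_steps) if all_steps else 0.0
    if max_step <= 0.0:
        return np.zeros(len(neuron.axons), dtype=int)
    thr = max_step / 1000.0
    return np.array([int((s > thr).sum()) for s in all_steps])


class UnrestrictedNeuronModel:
    """Unrestricted (staircase) neuron fitted to a :class:`PatternSet`."""

    def __init__(self, data: PatternSet, config: SolverConfig | None = None):
        self.data = data
        self.config = config or SolverConfig()

    def fit(self, **overrides) -> "UnrestrictedNeuronResults":
        cfg = replace(self.config, **overrides) if overrides else self.config
        neuron, report, weights = train_unrestricted(self.data, cfg)
        return UnrestrictedNeuronResults(self, neuron, report, weights, cfg)


@dataclass
class UnrestrictedNeuronResults:
    model: UnrestrictedNeuronModel
    neuron: UnrestrictedNeuron
    report: UnrestrictedReport
    weights: np.ndarray
    config: SolverConfig

    @property
    def converged(self) -> bool:
        return self.report.success

    def predict(self, x):
        return self.neuron.predict(x)

    def effective_synapse_counts(self) -> np.ndarray:
        return count_effective_synapses(self.neuron)

    def summary(self) -> str:
        counts = self.effective_synapse_counts()
        r = self.report
        lines = [
            "Unrestricted parallel-synapse neuron",
            "====================================",
            f"axons (N):              {self.neuron.num_axons}",
            f"patterns (P):           {self.model.data.num_patterns}",
            f"converged:              {r.success}",
            f"outer iterations:       {r.iterations}",
            f"training errors:        {r.final_errors}",
            f"theta:                  {self.neuron.theta:.6g}",
            f"effective synapses/axon: mean {counts.mean():.2f}, max {counts.max()}",
        ]
        return "\n".join(lines)
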
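"""Classification-capacity measurement protocol.

Capacity is defined through random-pattern classification: for a model with
``N`` input axons, the critical problem size ``P*`` is the number of random
patterns the model classifies perfectly with 50% probability, and the
capacity is the normalized load ``P*/N``.

The protocol: run repeated independent training trials over a grid of
problem sizes ``P`` (fresh random dataset per trial, derived seeds), fit a
two-parameter logistic curve to the per-trial Bernoulli success outcomes as
a function of load ``P/N`` by maximum likelihood (slope constrained so the
curve decreases with load), and interpolate the load at which the fitted
success probability crosses 0.5.  Confidence intervals come from a
nonparametric bootstrap that resamples trials with replacement within each
``P`` stratum and refits the logistic curve per resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .patterns import PatternSet, generate_patterns
from .perceptron import is_linearly_separable
from .restricted import TrainConfig, train_restricted
from .unrestricted import SolverConfig, train_unrestricted

__all__ = [
    "TrialRecord",
    "CapacityResult",
    "DegenerateFitError",
    "run_trials",
    "fit_capacity",
    "bootstrap_capacity",
    "estimate_capacity",
    "records_to_csv",
    "records_from_csv",
    "CapacityExperiment",
]

MODEL_KINDS = ("restricted", "unrestricted", "perceptron")


class DegenerateFitError(RuntimeError):
    """Raised when the success outcomes cannot pin down a 50% crossing."""


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one training trial on one fresh random dataset."""

    model_kind: str
    N: int
    M: int | None
    P: int
    seed: int
    success: bool
    iters: int


@dataclass
class CapacityResult:
    """Success-rate curve and interpolated capacity with bootstrap CI."""

    load_grid: np.ndarray
    success_rates: np.ndarray
    pstar_over_N: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0

    def summary(self) -> str:
        lines = [
            "Capacity estimate",
            "=================",
            f"P*/N:        {self.pstar_over_N:.4f}",
        ]
        if self.ci_low is not None:
            lines.append(
                f"bootstrap CI: [{self.ci_low:.4f}, {self.ci_high:.4f}]"
                f"  ({self.n_bootstrap} resamples)"
            )
        lines.append("load    success rate")
        for load, rate in zip(self.load_grid, self.success_rates):
            lines.append(f"{load:6.3f}  {rate:12.3f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "load_grid": np.asarray(self.load_grid).tolist(),
            "success_rates": np.asarray(self.success_rates).tolist(),
            "pstar_over_N": self.pstar_over_N,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _trial_seed(base_seed: int, P: int, rep: int) -> int:
    """Deterministic, well-separated per-trial seed below 2^31."""
    ss = np.random.SeedSequence([int(base_seed), int(P), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_one(model_kind: str, data: PatternSet, M: int | None, seed: int,
             restricted_config: TrainConfig | None,
             solver_config: SolverConfig | None) -> tuple[bool, int]:
    if model_kind == "perceptron":
        return is_linearly_separable(data, with_bias=True), 0
    if model_kind == "restricted":
        cfg = replace(restricted_config or TrainConfig(), seed=seed)
        _, report = train_restricted(data, data.num_axons, M, cfg)
        return report.success, report.epochs
    if model_kind == "unrestricted":
        cfg = replace(solver_config or SolverConfig(), seed=seed)
        _, report, _ = train_unrestricted(data, cfg)
        return report.success, report.iterations
    raise ValueError(f"unknown model_kind {model_kind!r}; expected {MODEL_KINDS}")


def run_trials(
    model_kind: str,
    N: int,
    M: int | None,
    P_grid,
    trials_per_P: int,
    base_seed: int,
    restricted_config: TrainConfig | None = None,
    solver_config: SolverConfig | None = None,
    progress: bool = False,
) -> list[TrialRecord]:
    """Run independent training trials across a grid of problem sizes.

    Every trial regenerates a fresh random dataset from its own derived seed
    (recorded in the :class:`TrialRecord`), so a record list is exactly
    reproducible from ``base_seed``.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}; expected {MODEL_KINDS}")
    records: list[TrialRecord] = []
    for P in P_grid:
        P = int(P)
        if P < 1:
            raise ValueError("all P values must be >= 1")
        for rep in range(int(trials_per_P)):
            seed = _trial_seed(base_seed, P, rep)
            data = generate_patterns(P, N, seed)
            success, iters = _run_one(
                model_kind, data, M, seed, restricted_config, solver_config
            )
            records.append(TrialRecord(model_kind, N, M, P, seed, success, iters))
            if progress:
                print(f"  P={P} trial {rep + 1}/{trials_per_P}: "
                      f"{'success' if success else 'fail'} ({iters} iters)",
                      flush=True)
    return records


def _negloglik(params: np.ndarray, loads: np.ndarray, outcomes: np.ndarray) -> float:
    c, log_k = params
    m = np.exp(np.clip(log_k, -20, 20)) * (loads - c)
    # success prob = expit(-m): decreasing in load by construction
    return float(np.where(outcomes, np.logaddexp(0.0, m), np.logaddexp(0.0, -m)).sum())


def fit_capacity(records: list[TrialRecord]) -> CapacityResult:
    """Maximum-likelihood logistic interpolation of the 50% crossing.

    Fits ``p(success) = 1 / (1 + exp(k (load - c)))`` with ``k > 0`` on the
    per-trial outcomes; ``c`` is directly the capacity estimate P*/N.
    """
    if not records:
        raise DegenerateFitError("no trial records")
    loads = np.array([r.P / r.N for r in records], dtype=float)
    outcomes = np.array([r.success for r in records], dtype=bool)
    if np.unique([r.P for r in records]).size < 2:
        raise DegenerateFitError("need trials at >= 2 distinct P values")
    if outcomes.all() or (~outcomes).all():
        raise DegenerateFitError(
            "all trials succeeded or all failed; widen the P grid to bracket "
            "the 50% success transition"
        )

    grid = np.unique(loads)
    rates = np.array([outcomes[loads == g].mean() for g in grid])

    above = grid[rates > 0.5]
    below = grid[rates <= 0.5]
    if above.size and below.size:
        c0 = 0.5 * (above.max() + below.min())
    else:
        c0 = float(np.average(grid, weights=np.ones_like(grid)))
    spread = max(grid.max() - grid.min(), 1e-3)
    best = None
    for log_k0 in (np.log(4.0 / spread), np.log(20.0 / spread)):
        res = minimize(
            _negloglik, x0=np.array([c0, log_k0]), args=(loads, outcomes),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    pstar = float(best.x[0])
    return CapacityResult(load_grid=grid, success_rates=rates, pstar_over_N=pstar)


def bootstrap_capacity(
    records: list[TrialRecord], n_bootstrap: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for P*/N (2.5–97.5), stratified by P.

    Resamples trials with replacement within each P stratum (preserving the
    per-P trial counts), refits the logistic curve per resample, and returns
    the percentile interval.  Degenerate resamples are skipped; more than 50%
    degenerate is an error.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    strata: dict[int, list[TrialRecord]] = {}
    for r in records:
        strata.setdefault(r.P, []).append(r)
    estimates = []
    degenerate = 0
    for _ in range(n_bootstrap):
        resample: list[TrialRecord] = []
        for P in sorted(strata):
            pool = strata[P]
            idx = rng.integers(0, len(pool), size=len(pool))
            resample.extend(pool[i] for i in idx)
        try:
            estimates.append(fit_capacity(resample).pstar_over_N)
        except DegenerateFitError:
            degenerate += 1
    if degenerate > n_bootstrap / 2:
        raise DegenerateFitError(
            f"{degenerate}/{n_bootstrap} bootstrap resamples were degenerate"
        )
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


def estimate_capacity(
    model_kind: str,
    N: int,
    M: int | None = None,
    P_grid=None,
    trials_per_P: int = 5,
    base_seed: int = 0,
    n_bootstrap: int = 100,
    probe_trials: int = 3,
    refine_points: int = 5,
    max_probe_load: float = 64.0,
    restricted_config: TrainConfig | None = None,
    solver_config: SolverConfig | None = None,
    progress: bool = False,
) -> tuple[CapacityResult, list[TrialRecord]]:
    """End-to-end capacity estimate with optional adaptive grid selection.

    With ``P_grid=None``, a coarse doubling scan over loads 1, 2, 4, ...
    brackets the 50% success crossing with a few probe trials per level, and
    a ``refine_points``-point grid across the bracket is then run at the full
    ``trials_per_P``.  The logistic fit uses only the refined-grid records.
    """
    if P_grid is None:
        load = 1.0
        lower = None
        upper = None
        while load <= max_probe_load:
            P = max(int(round(load * N)), 1)
            recs = run_trials(model_kind, N, M, [P], probe_trials,
                              base_seed + 1_000_003, restricted_config,
                              solver_config, progress=progress)
            rate = np.mean([r.success for r in recs])
            if rate > 0.5:
                lower = load
            else:
                upper = load
                break
            load *= 2.0
        if upper is None:
            raise DegenerateFitError(
                f"success rate still above 0.5 at load {max_probe_load}"
            )
        if lower is None:
            lower, upper = upper / 2.0, upper
        loads = np.linspace(lower, upper, refine_points)
        P_grid = sorted({max(int(round(l * N)), 1) for l in loads})
    records = run_trials(model_kind, N, M, P_grid, trials_per_P, base_seed,
                         restricted_config, solver_config, progress=progress)
    result = fit_capacity(records)
    if n_bootstrap:
        lo, hi = bootstrap_capacity(records, n_bootstrap, seed=base_seed + 17)
        result.ci_low, result.ci_high, result.n_bootstrap = lo, hi, n_bootstrap
    return result, records


def records_to_csv(records: list[TrialRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        m = None if pd.isna(row.M) else int(row.M)
        out.append(TrialRecord(str(row.model_kind), int(row.N), m, int(row.P),
                               int(row.seed), bool(row.success), int(row.iters)))
    return out


class CapacityExperiment:
    """Capacity-measurement experiment for one model configuration.

    ``fit()`` runs the trials (adaptive grid when none is given), the
    logistic interpolation and the bootstrap, returning a
    :class:`CapacityResult`; the trial records are kept on the experiment.
    """

    def __init__(self, model_kind: str, N: int, M: int | None = None,
                 restricted_config: TrainConfig | None = None,
                 solver_config: SolverConfig | None = None):
        if model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {model_kind!r}")
        self.model_kind = model_kind
        self.N = int(N)
        self.M = None if M is None else int(M)
        self.restricted_config = restricted_config
        self.solver_config = solver_config
        self.records: list[TrialRecord] | None = None

    def fit(self, P_grid=None, trials_per_P: int = 5, seed: int = 0,
            n_bootstrap: int = 100, progress: bool = False) -> CapacityResult:
        result, records = estimate_capacity(
            self.model_kind, self.N, self.M, P_grid=P_grid,
            trials_per_P=trials_per_P, base_seed=seed, n_bootstrap=n_bootstrap,
            restricted_config=self.restricted_config,
            solver_config=self.solver_config, progress=progress,
        )
        self.records = records
        return result
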
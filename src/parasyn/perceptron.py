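"""Linear-synapse (Perceptron) baseline.

The comparison point for the parallel-synapse models is the classical
Perceptron: a linear threshold unit whose capacity on random patterns is
governed by Cover's function-counting theorem.  For ``P`` points in general
position in ``D`` dimensions (homogeneous separators), the fraction of the
``2^P`` labelings that are linearly separable is

    C(P, D) = 2^(1-P) * sum_{k=0}^{D-1} binom(P-1, k)

which equals 1 for ``P <= D`` and exactly 1/2 at ``P = 2D``, giving the
asymptotic capacity ``P*/N -> 2``.  Empirical separability of a concrete
dataset is decided exactly by linear-program feasibility with unit margin.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import linprog

from .patterns import PatternSet

__all__ = ["cover_fraction", "is_linearly_separable"]


def cover_fraction(P: int, D: int) -> float:
    """Probability that P random points in D dimensions are separable.

    Evaluated in exact rational arithmetic before conversion to float;
    ``cover_fraction(2 * D, D)`` is exactly 0.5 and ``P <= D`` gives 1.0.
    """
    if P < 1 or D < 1:
        raise ValueError("P and D must be positive")
    if P <= D:
        return 1.0
    total = sum(Fraction(comb(P - 1, k)) for k in range(D))
    return float(total * Fraction(2) / Fraction(2) ** P)


def is_linearly_separable(data: PatternSet, with_bias: bool = True) -> bool:
    """Decide strict linear separability by margin-1 LP feasibility.

    Looks for ``(w, b)`` with ``y_mu (w . x_mu + b) >= 1`` for every pattern;
    the unit margin makes strict separation scale-invariant and avoids the
    zero-vector degeneracy.  Raises if the LP solver fails outright rather
    than silently reporting inseparable.
    """
    X = data.inputs
    y = data.labels.astype(float)
    feats = np.hstack([X, np.ones((X.shape[0], 1))]) if with_bias else X
    A_ub = -y[:, None] * feats
    b_ub = -np.ones(X.shape[0])
    res = linprog(
        c=np.zeros(feats.shape[1]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * feats.shape[1],
        method="highs",
    )
    if res.status == 0:
        return True
    if res.status == 2:  # infeasible
        return False
    raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")
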
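"""Random binary-classification pattern sets.

The capacity benchmark used throughout this package is the classification of
random patterns: ``P`` activity patterns over ``N`` presynaptic axons, with
each axonal activity drawn i.i.d. from Uniform(0, 1) and binary labels drawn
with equal probability from {-1, +1}.  A model's capacity is the largest
``P/N`` it can classify perfectly with 50% probability.

This module owns the :class:`PatternSet` container, the seeded generator for
the benchmark, a handful of fixed hand-written fixtures used in tests and
docs, and lossless CSV persistence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatternSet",
    "generate_patterns",
    "make_fixture",
    "save_patterns",
    "load_patterns",
]


@dataclass(frozen=True)
class PatternSet:
    """A set of input patterns with binary labels.

    Parameters
    ----------
    inputs : ndarray of shape (P, N)
        Axonal activities; every entry must lie in the closed interval [0, 1].
    labels : ndarray of shape (P,)
        Class labels in {-1, +1}.
    seed : int or None
        Record of the generator seed that produced this set (None for
        hand-written fixtures).
    """

    inputs: np.ndarray
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if inputs.ndim != 2:
            raise ValueError("inputs must be a 2-D (P, N) array")
        if labels.shape != (inputs.shape[0],):
            raise ValueError("labels must be 1-D with one entry per pattern")
        if inputs.size and (inputs.min() < 0.0 or inputs.max() > 1.0):
            raise ValueError("all inputs must lie in [0, 1]")
        if labels.size and not np.isin(labels, (-1, 1)).all():
            raise ValueError("labels must be -1 or +1")
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "labels", labels)

    @property
    def num_patterns(self) -> int:
        return self.inputs.shape[0]

    @property
    def num_axons(self) -> int:
        return self.inputs.shape[1]

    def __len__(self) -> int:
        return self.num_patterns


def generate_patterns(num_patterns: int, num_axons: int, seed: int) -> PatternSet:
    """Draw a random classification problem.

    Inputs are i.i.d. Uniform(0, 1); labels are i.i.d. uniform on {-1, +1}.
    A fresh ``numpy.random.Generator`` is built from *seed* on every call, so
    identical arguments give bit-identical output and no global state is
    touched.
    """
    if num_patterns < 1 or num_axons < 1:
        raise ValueError("num_patterns and num_axons must be >= 1")
    rng = np.random.default_rng(seed)
    inputs = rng.uniform(0.0, 1.0, size=(num_patterns, num_axons))
    labels = rng.choice(np.array([-1, 1]), size=num_patterns)
    return PatternSet(inputs=inputs, labels=labels, seed=seed)


# Hand-written fixtures.  "xor4" uses generic (non-corner) points on purpose:
# any model whose total current is an axon-wise sum satisfies
# z(0,0) + z(1,1) = z(1,0) + z(0,1), so the exact-corner XOR is unsolvable by
# construction; generic points with an XOR-like labeling are not linearly
# separable yet are solvable by the parallel-synapse models.
_FIXTURES: dict[str, tuple[list[list[float]], list[int]]] = {
    "xor4": (
        [[0.9, 0.2], [0.1, 0.1], [0.8, 0.8], [0.2, 0.9]],
        [1, -1, -1, 1],
    ),
    "sep2": (
        [[0.8], [0.2]],
        [1, -1],
    ),
    # Illustrative 4-point 2-D toy with mixed labels (random-looking points).
    "fig2_toy": (
        [[0.24, 0.71], [0.62, 0.33], [0.85, 0.88], [0.15, 0.22]],
        [1, -1, 1, -1],
    ),
}


def make_fixture(name: str) -> PatternSet:
    """Return one of the fixed, hard-coded pattern sets used in tests/docs."""
    try:
        inputs, labels = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    return PatternSet(inputs=np.array(inputs), labels=np.array(labels), seed=None)


def save_patterns(data: PatternSet, inputs_path: str | Path, labels_path: str | Path) -> None:
    """Write a PatternSet as an inputs CSV (x1..xN) and a labels CSV (y).

    Round-trips losslessly: floats are written with 17 significant digits.
    """
    n = data.num_axons
    df = pd.DataFrame(data.inputs, columns=[f"x{i + 1}" for i in range(n)])
    df.to_csv(inputs_path, index=False, float_format="%.17g")
    pd.DataFrame({"y": data.labels}).to_csv(labels_path, index=False)


def load_patterns(inputs_path: str | Path, labels_path: str | Path) -> PatternSet:
    """Read back a PatternSet written by :func:`save_patterns`."""
    inputs = pd.read_csv(inputs_path, float_precision="round_trip").to_numpy(dtype=float)
    labels = pd.read_csv(labels_path)["y"].to_numpy(dtype=int)
    return PatternSet(inputs=inputs, labels=labels, seed=None)
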
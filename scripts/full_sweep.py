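#!/usr/bin/env python
"""Offline capacity sweeps over N (and M) for all three models.

This reproduces the full capacity-versus-axon-count curves (restricted
neurons at several M, the unrestricted neuron, and the Perceptron baseline)
with the >=5-trials-per-P protocol and 100-resample bootstrap.  At the larger
N values this runs for hours; it is not part of the test suite.

Example:
    python scripts/full_sweep.py --models perceptron unrestricted \
        --N 10 20 50 100 --trials 5 --out scratch/sweep.csv
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from parasyn.capacity import estimate_capacity


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--models", nargs="+", default=["perceptron"],
                    choices=["perceptron", "restricted", "unrestricted"])
    ap.add_argument("--N", nargs="+", type=int, default=[10, 20, 50])
    ap.add_argument("--M", nargs="+", type=int, default=[2, 3, 5],
                    help="synapse counts for the restricted model")
    ap.add_argument("--trials", type=int, default=5)
    ap.add_argument("--bootstrap", type=int, default=100)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("scratch/sweep.csv"))
    args = ap.parse_args(argv)

    rows = []
    for model in args.models:
        m_values = args.M if model == "restricted" else [None]
        for M in m_values:
            for N in args.N:
                label = f"{model}" + (f" M={M}" if M else "") + f" N={N}"
                print(f"== {label}", file=sys.stderr)
                result, _ = estimate_capacity(
                    model, N, M, trials_per_P=args.trials,
                    base_seed=args.seed, n_bootstrap=args.bootstrap,
                    progress=True,
                )
                rows.append({
                    "model": model, "M": M, "N": N,
                    "pstar_over_N": result.pstar_over_N,
                    "ci_low": result.ci_low, "ci_high": result.ci_high,
                })
                print(result.summary(), file=sys.stderr)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
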
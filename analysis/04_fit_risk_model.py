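#!/usr/bin/env python
"""Fit the prospect-theory risk model (lambda, gamma, tau) per subject by MLE."""

import argparse
from pathlib import Path

import pandas as pd

from relapsekit import decision, pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/fits.csv")
    ap.add_argument("--starts", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    choices = pd.read_csv(Path(args.data) / "choices.csv")
    qc: dict = {}
    fits = pipeline.fit_decision_stage(
        choices, decision.FitConfig(n_starts=args.starts, seed=args.seed), qc
    )
    fits.to_csv(args.out, index=False)
    print(f"fitted {len(fits)} subjects -> {args.out}")
    print(f"lambda median {fits['lambda'].median():.3f}, "
          f"gamma median {fits['gamma'].median():.3f}; "
          f"{len(qc['fit_not_converged'])} non-converged, "
          f"{len(qc['catch_failures'])} catch-QC failures")


if __name__ == "__main__":
    main()
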
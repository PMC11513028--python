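#!/usr/bin/env python
"""Validate the trained surrogates: R^2/SOSE/RE, parity data, importance.

Emits the metric table (rows = targets, train/test columns), the tidy
per-case parity/residual file for plotting, and permutation-importance
scores identifying which elements drive each prediction.
"""

import argparse
from pathlib import Path

import pandas as pd

from gwhazard.pipeline import reports_for
from gwhazard.surrogate import SurrogateModel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--truth", type=Path,
                    default=Path("results/01_simulate/truth.csv"))
    ap.add_argument("--models", type=Path, default=Path("results/05_surrogates"))
    ap.add_argument("--out", type=Path, default=Path("results/06_validation"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    truth = pd.read_csv(args.truth)
    models = [SurrogateModel.load(p) for p in sorted(args.models.glob("*.json"))]
    args.out.mkdir(parents=True, exist_ok=True)
    summary, parity, imp = reports_for(models, truth, args.seed)
    summary.to_csv(args.out / "fit_report.csv", index=False)
    parity.to_csv(args.out / "parity.csv", index=False)
    imp.to_csv(args.out / "importance.csv", index=False)

    print(summary[["family", "target", "r2_train", "r2_test",
                   "sose_train", "sose_test"]].round(4).to_string(index=False))
    top = (imp.sort_values("importance", ascending=False)
              .groupby(["model", "target"]).head(2))
    print("\nmost influential inputs per model:")
    print(top.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
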
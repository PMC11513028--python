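#!/usr/bin/env python
"""Train RBF and MLP surrogates on the study dataset's ground truth.

One network per target, with the family-specific train/test fractions
(pollution indices 75/25 RBF and 70/30 MLP; HI 75/25 and 85/15; CR 80/20
and 70/30) and automatic hidden-unit selection.  Models are serialized as
JSON for exact reload.
"""

import argparse
from pathlib import Path

import pandas as pd

from gwhazard.pipeline import TARGET_FAMILIES, train_family


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--truth", type=Path,
                    default=Path("results/01_simulate/truth.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/05_surrogates"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    truth = pd.read_csv(args.truth)
    args.out.mkdir(parents=True, exist_ok=True)
    for kind in ("rbf", "mlp"):
        for family in TARGET_FAMILIES:
            for model in train_family(truth, family, kind, args.seed):
                name = f"{kind}_{family}_{'_'.join(model.output_names)}.json"
                model.save(args.out / name)
                print(f"{name}: {model.hidden_units} hidden units, "
                      f"test SOSE {model.metadata['test_sose']:.3e}")


if __name__ == "__main__":
    main()
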
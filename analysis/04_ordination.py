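#!/usr/bin/env python
"""PCA ordination of the three systems' ordinal ratings, overall and per
food group: which classification 'dimensions' point the same way?

The loading-arrow angle between two systems quantifies biplot closeness:
small angles mean the systems rank the basket along the same axis. Reads
scratch/classified.csv; writes results/ordination.json."""

import json
from pathlib import Path

import pandas as pd

from nutrilabel import concordance as cc

ROOT = Path(__file__).resolve().parents[1]


def main():
    df = pd.read_csv(ROOT / "scratch" / "classified.csv", index_col="food_id")
    results = {}
    for stratum in ["all", *sorted(df["group"].unique())]:
        sub = df if stratum == "all" else df[df["group"] == stratum]
        try:
            X = cc.ordinal_encode(sub[["nutriscore", "nova", "fop"]],
                                  stratum=stratum)
        except ValueError as e:
            print(f"{stratum}: skipped ({e})")
            continue
        res = cc.run_pca(X, stratum=stratum)
        results[stratum] = res.to_dict()
        ang = res.angles_deg
        print(f"{stratum:14s} PC1 {res.explained_variance[0]:.0%}  "
              f"NS-FoP {ang['nutriscore|fop']:5.1f} deg   "
              f"NS-NOVA {ang['nutriscore|nova']:5.1f} deg   "
              f"NOVA-FoP {ang['nova|fop']:5.1f} deg")
    (ROOT / "results" / "ordination.json").write_text(
        json.dumps(results, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
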
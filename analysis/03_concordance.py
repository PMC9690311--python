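#!/usr/bin/env python
"""Concordance layer over the classified basket: per-group distribution
tables, the three pairwise cross-tabulations with row percentages, and the
recommended/not-recommended agreement (directional shares, percent
agreement, Cohen's kappa).

Reads scratch/classified.csv (run 02 first); writes the tables under
results/."""

import json
from pathlib import Path

import pandas as pd

from nutrilabel import concordance as cc

ROOT = Path(__file__).resolve().parents[1]


def main():
    df = pd.read_csv(ROOT / "scratch" / "classified.csv", index_col="food_id")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    rows = []
    for system in ("nutriscore", "nova", "fop"):
        for stratum in ["all", *sorted(df["group"].unique())]:
            sub = df if stratum == "all" else df[df["group"] == stratum]
            t = cc.tabulate_distribution(sub[system], system, group=stratum)
            rows += [{"system": system, "stratum": stratum, "category": c,
                      "count": t.counts[c], "pct": t.pct[c]} for c in t.counts]
    pd.DataFrame(rows).to_csv(out / "distributions.csv", index=False)

    for a, b in [("nutriscore", "nova"), ("nutriscore", "fop"), ("nova", "fop")]:
        ct = cc.cross_tabulate(df[a], df[b], a, b)
        ct.counts.to_csv(out / f"crosstab_{a}_x_{b}_counts.csv")
        ct.row_pct.to_csv(out / f"crosstab_{a}_x_{b}_rowpct.csv")
        diag = ct.row_pct.iloc[0, 0]
        print(f"{a} x {b}: grand total {ct.grand_total}; "
              f"top-left row% {diag}")

    maps = cc.DEFAULT_RECOMMENDATION_MAPS
    agreement = {}
    for a, b in [("nutriscore", "nova"), ("nutriscore", "fop"), ("nova", "fop")]:
        s = cc.recommendation_agreement(df[a], df[b], maps[a], maps[b])
        agreement[f"{a}|{b}"] = s.__dict__
        print(f"{a} vs {b}: recommended-under-{a} also recommended-under-{b} "
              f"= {s.share_recommended_a_also_b:.1f}%, kappa = {s.kappa:.2f}")
    (out / "agreement.json").write_text(
        json.dumps(agreement, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
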
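#!/usr/bin/env python
"""Classify the synthetic basket under all three systems (Nutri-Score with
the special-category variants, the NOVA marker ladder, and composition-only
warning-label counting) and report the whole-basket category shares.

Reads scratch/basket.csv (run 01 first); writes the per-food verdict table
with full rationale to scratch/classified.csv."""

from pathlib import Path

from nutrilabel.model import read_food_table
from nutrilabel.nova import load_vocabulary
from nutrilabel.pipeline import classify_basket

ROOT = Path(__file__).resolve().parents[1]


def main():
    vocab = load_vocabulary()
    records, issues = read_food_table(ROOT / "scratch" / "basket.csv",
                                      vocabulary=vocab)
    fatal = sum(1 for i in issues if i.is_fatal)
    print(f"read {len(records)} foods ({fatal} excluded)")
    df = classify_basket(records, vocab=vocab, gate=False, variant="auto")
    df.to_csv(ROOT / "scratch" / "classified.csv")
    for system in ("nutriscore", "nova", "fop"):
        shares = (df[system].value_counts(normalize=True)
                  .sort_index().mul(100).round(1))
        print(f"{system:11s}: " + "  ".join(
            f"{cat}={pct}%" for cat, pct in shares.items()))
    print(f"wrote {len(df)} verdicts -> scratch/classified.csv")


if __name__ == "__main__":
    main()
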
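# nutrilabel

Deterministic implementations of three front-of-pack food classification
systems over a shared food-record model, plus the concordance analysis used
to quantify how much — and where — they disagree:

* **Nutri-Score** (2017 general-food algorithm): a continuous nutrient-profile
  score mapped to the letters A–E. Negative points N ∈ [0, 40] accrue from
  energy (kJ), sugars, saturated fat and sodium (0–10 each, earned by strictly
  exceeding fixed thresholds); positive points P ∈ [0, 15] from
  fruit/vegetable/nut/legume content (FVNL, 0–5), fibre (0–5) and protein
  (0–5). The score is `N − P` with the balance rule: if `N ≥ 11` and the FVNL
  component is not maximal, protein is dropped from P. Bands: A [−15, −1],
  B [0, 2], C [3, 10], D [11, 18], E [19, 40]. Cheeses always count protein;
  added fats score saturated fat as the ratio 100·sat/total fat; beverages use
  their own energy/sugar/FVNL scales with water rated A.
* **NOVA** (degree of processing, classes 1–4): implemented as an auditable
  rule ladder over closed-vocabulary ingredient-marker tags — any
  ultra-processing marker ⇒ 4; a single processed culinary substance ⇒ 2; any
  processing marker ⇒ 3; otherwise 1 — replacing the expert judgement used in
  field studies with a reproducible, versioned rule engine.
* **Chilean FoP warning labels** (Law 20.606): a food carries one black
  "high in" stamp per critical element whose declared content per 100 g/mL
  strictly exceeds the legal limit for its physical state — solids
  275 kcal / 400 mg sodium / 10 g sugars / 4 g saturated fat, liquids
  70 / 100 / 5 / 3 — for 0–4 stamps in total. The law's added-ingredient
  scope is available as an optional gate.

The concordance layer reproduces the analytic toolkit of basket surveys:
category distributions by food group, pairwise cross-tabulations with
half-up row percentages, recommended/not-recommended agreement (directional
shares, percent agreement, Cohen's κ), and a PCA ordination of the ordinal
ratings whose loading-arrow angles quantify biplot closeness between
systems.

Because the 736-food Chilean basic-basket survey dataset that motivates the
package is not publicly deposited, `nutrilabel.basket` generates synthetic
baskets with the survey's structure: five food groups at the surveyed sizes
(198 cereals, 109 dairy, 139 protein foods, 100 oils/fats, 190
sugars/others), an archetype library of ~70 label-level product templates,
and an L1-minimising mixture calibration against published per-group
category distributions. `nutrilabel.reference` ships the published
contingency counts as inputs for arithmetic reproduction.

Audience: nutrition-policy researchers and epidemiologists comparing
nutrient-profiling schemes, and anyone needing a reproducible, testable
implementation of these three classifiers.

## Worked example

```python
from nutrilabel import (NutrientPanel, FoodRecord, compute_nutriscore,
                        count_warnings, classify_nova, load_vocabulary)

panel = NutrientPanel(energy_kcal=390, sugars_g=25, saturated_fat_g=1.5,
                      total_fat_g=2.5, sodium_mg=460, fibre_g=4,
                      protein_g=6, fvnl_pct=0)
cereal = FoodRecord(food_id="x1", name="sweetened breakfast cereal",
                    group="cereals", state="solid", panel=panel,
                    added_sugar=True, added_sodium=True,
                    markers=frozenset({"colouring", "flavouring"}))

ns = compute_nutriscore(panel)
print(ns.n_total, ns.p_total, ns.final_score, ns.category)
# 15 7 11 D        (protein dropped by the balance rule: N>=11, FVNL<5)
fop = count_warnings(cereal)
print(fop.n_labels, sorted(fop.labels))
# 3 ['high_calories', 'high_sodium', 'high_sugars']
print(classify_nova(cereal, load_vocabulary()).nova)
# 4
```

So one supermarket cereal is simultaneously "low nutritional quality" (D),
ultra-processed (NOVA 4) and triple-stamped — while a sweetener-reformulated
yogurt can be B, NOVA 4 and stamp-free, which is exactly the kind of
between-system discrepancy the concordance layer measures.

The full pipeline, on a synthetic basket:

```bash
nutrilabel all --seed 1 --sigma 0.1 --out-dir results/run1
```

or step by step through the analysis drivers:

```bash
python analysis/01_simulate_basket.py   # calibrate mixture, generate 736 foods
python analysis/02_classify.py          # three verdicts per food + rationale
python analysis/03_concordance.py       # distributions, cross-tabs, agreement
python analysis/04_ordination.py        # per-group PCA, loading-arrow angles
python analysis/05_reproduce_published_tables.py
```

Driver 04 prints, for the whole basket, a Nutri-Score↔FoP loading angle of
~3° against Nutri-Score↔NOVA of ~57°: the two nutrient-threshold systems
rank foods along nearly the same axis, while the processing-based system
points elsewhere.

## Layout

* `src/nutrilabel/` — the library: `model` (food records + CSV io),
  `nutriscore`, `nova`, `fop` (the three classifiers), `concordance`
  (distributions, cross-tabs, agreement, PCA), `basket` (synthetic
  generator + calibration), `reference` (published tables as inputs),
  `pipeline` and `cli`.
* `analysis/` — numbered narrative drivers writing under `results/`.
* `tests/` — pytest suite, including dual-route oracle checks and the
  acceptance surface.
* `docs/methods.md` — the methods note: models, assumptions, parameter
  choices, generator scope and limitations.
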
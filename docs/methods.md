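# Methods

## Scope and data model

All computation operates on `FoodRecord`s: a food identity, one of five
basket groups (cereals/potatoes/fresh pulses; dairy; fish/meat/eggs/dried
pulses; oils and fats; sugars and others), a physical state (solid or
liquid) and a `NutrientPanel` of declared composition per 100 g (solids) or
100 mL (liquids) *as sold* — the convention of Chilean labels. Energy is
carried in both kcal and kJ; when only kcal is declared, kJ is derived as
4.184 × kcal, and a declared kJ value more than 2% away from that product
is a fatal inconsistency. Sodium is stored as mg of sodium; a `salt_g`
column, when present, is converted at 400 mg sodium per g of salt. A
missing FVNL fraction defaults to 0 with a warning (conservative: it can
only withhold positive points); missing fibre or protein is fatal, because
no classifier output is meaningful without them — records with any fatal
issue are excluded and reported rather than imputed, mirroring how survey
pipelines drop incomplete labels. Liquids are assumed to be declared
per 100 mL directly; no serving-size renormalisation is attempted.

## Nutri-Score

The scorer implements the 2017 general-food algorithm of the official
French calculator. Point tables (value must *strictly* exceed a threshold
to earn the next point):

* energy (kJ): 335, 670, …, 3350 (0–10 pts);
* sugars (g): 4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45;
* saturated fat (g): 1, 2, …, 10;
* sodium (mg): 90, 180, …, 900;
* FVNL (%): 0 pts ≤ 40, 1 > 40, 2 > 60, 5 > 80;
* fibre (g): 0.9, 1.9, 2.8, 3.7, 4.7 (0–5 pts);
* protein (g): 1.6, 3.2, 4.8, 6.4, 8.0.

Balance rule: with N the negative and P the positive total, the score is
N − P unless N ≥ 11 and the FVNL component is below its maximum, in which
case protein is excluded (score = N − fibre − FVNL). Variants, selected by
the record's `special_category`: **cheese** always counts protein;
**added fats** replace the saturated-fat grams table by the percentage
100 × saturated/total fat with thresholds 10, 16, 22, …, 64; **beverages**
use energy thresholds 0, 30, …, 270 kJ, sugar thresholds 0, 1.5, …, 13.5 g
and an FVNL scale of 2/4/10 points, with their own bands (B ≤ 1, C 2–5,
D 6–9, E ≥ 10) and plain water — an all-zero panel — rated A by
definition. Milk and milk-based drinks are treated as general foods unless
explicitly tagged `beverage`; the choice is exposed because survey practice
varies. All point tables are integral, so scores are exact integers and no
rounding is involved. General-food bands are closed intervals:
A [−15, −1], B [0, 2], C [3, 10], D [11, 18], E [19, 40]; scores outside
[−15, 40] are rejected rather than clamped.

## NOVA rule ladder

Field studies assign NOVA by expert reading of ingredient statements. To
make that reproducible, each record carries marker tags from a closed,
hash-versioned vocabulary (`data/vocabulary.yaml`) split into three
disjoint sets: *ultra-processing markers* (cosmetic additives and refined
industrial ingredients: colourings, flavourings, emulsifiers, thickeners,
non-caloric sweeteners, hydrogenated oils, protein isolates,
maltodextrin, …), *processing markers* (salting, sugaring, oiling,
canning, fermentation, smoking, curing) and *culinary substances* (oils,
butter, lard, sugar, salt, starch, honey). The ladder fires in fixed
order: any ultra-processing marker ⇒ NOVA 4; else a culinary-substance tag
⇒ NOVA 2 (the tag is applied, by data-authoring convention, only when the
product essentially *is* that single substance — the CSV carries no full
ingredient list to count); else any processing marker ⇒ NOVA 3; else
NOVA 1. Unknown tags are errors, never silently ignored. The shipped
vocabulary is an editorial operationalisation of NOVA guidance, shipped as
data precisely so users can align it with any revision; every result
carries the fired rule, the evidence tags and the vocabulary hash.

## Warning labels

A stamp is earned when the declared value strictly exceeds the legal limit
for the record's state (equality earns nothing; the opposite convention
would be a one-line change). The statutory scope — only foods with *added*
sugars, saturated fat or sodium are stamped — is implemented as an optional
gate (`gate=True`: the sugar/fat/sodium stamps require the matching
`added_*` flag and the calorie stamp requires any of them). The default is
`gate=False`, composition-only stamping, which is what can be recomputed
from a nutrition panel alone; the gate matters in practice (pure oils and
cheeses are stamp-free in shops despite exceeding limits) and is the main
reason published FoP distributions cannot be fully reproduced from
composition data, see Limitations.

## Concordance analysis

Distribution tables report counts and percentages (half-up, integer for
headline distributions, one decimal for cross-tab cells). Cross-tabs are
built with pandas and carry raw counts, marginals and half-up row
percentages; conservation (marginals = distribution counts, transpose
symmetry, grand total = classified rows) is asserted in tests.
Recommendation agreement collapses categories via configurable maps
(default: Nutri-Score A/B recommended, C neutral, D/E not; NOVA 4 not
recommended; any stamp not recommended) and reports directional shares,
percent agreement and unweighted Cohen's κ over foods non-neutral under
both systems (κ defined as 1 for perfect agreement when chance agreement
is degenerate at 1, else 0).

The ordination encodes the three verdicts ordinally (A–E → 1–5, NOVA 1–4,
stamps 0–4 → 1–5; larger is always less favourable), standardizes columns
(ddof = 1; a zero-variance column in a stratum is an error naming the
stratum) and eigendecomposes the resulting 3 × 3 correlation matrix. The
first two components are returned with a deterministic sign convention
(each component's largest-magnitude loading is positive). Between-system
angles are computed on *biplot arrows* — eigenvectors scaled by the square
root of their eigenvalue — so the cosine of an angle is the correlation
between the two systems as represented in the retained plane and
degenerate components contribute nothing; with three perfectly correlated
systems all angles are exactly 0°. The unscaled orthonormal loadings are
also exposed.

## Synthetic basket generator

The generator emulates the *structure* of the surveyed Chilean basket, not
any real product: five groups at the surveyed sizes (198/109/139/100/190,
n = 736), an archetype library of ~70 synthetic label-level templates
(plain staples, breads, sweetened cereals, cheeses, deli meats, pure fats,
soft drinks, confectionery, sweetener-reformulated products, …), and
independent multiplicative lognormal noise (default σ = 0.1, a typical
between-brand spread for declared values) on each nutrient, truncated so
saturated ≤ total fat and FVNL ≤ 100, with kJ rederived from the noised
kcal. Each archetype's zero-noise panel classifies exactly to its declared
(Nutri-Score band, NOVA class, stamp count) profile; a test re-derives all
of them.

Mixture weights per group are calibrated by linear programming: minimise
the summed L1 distance between the zero-noise classified distribution and
target distributions for one or more systems, over the simplex of
archetype weights (SciPy HiGHS). Targets put on categories no archetype in
the group can reach raise an error listing them. Record counts are
allocated by largest-remainder quotas, so a calibrated mixture regenerated
at zero noise reproduces an achievable target *exactly*; the seeded
generator consumes draws in a documented order (groups in canonical order,
archetypes in quota order, records sequentially, nutrients in canonical
order), making baskets bit-reproducible across platforms.

Default targets are the published per-group category distributions, with
two corrections where the published sugars-group vectors do not sum to
~100 (NOVA 3 taken as 8 not 18, FoP 2 as 9 not 19, both back-computed from
the published contingency marginals), and with the oils/fats FoP target
excluded from calibration: under composition-only stamping a pure fat
always exceeds the energy limit, so the published 50% stamp-free share of
that group — a consequence of the statute's added-ingredient scope — is
unreachable by construction.

Noise stability: for mixtures of archetypes whose baselines sit well
inside their score bands and legal limits, every category share of all
three systems stays within 5 percentage points of the zero-noise shares in
≥ 95% of 200 seeds at σ = 0.1 (tested). This guarantee deliberately
excludes the boundary-straddling "reformulated just-under-the-limit"
templates: σ = 0.1 moves roughly 40% of their draws across a limit, which
is faithful to how such products behave, not a generator defect.

## What passing tests do and do not show

The synthetic basket reproduces the surveyed group sizes, calibrated
marginal category distributions and the qualitative ordination geometry
(Nutri-Score and the warning labels nearly collinear, NOVA pointing
elsewhere). It does not reproduce brand-level composition, the survey's
joint (three-way) category structure beyond what the marginal calibration
induces, price or availability structure, or rater disagreement. Arithmetic
reproduction of the published percentages runs on the published counts
themselves and is exact up to the tables' own printing conventions.

## Numerical choices

* Threshold comparisons are strict (`value > threshold`) everywhere, for
  points and stamps alike; ties earn nothing.
* Percentages use decimal half-up rounding (`round_half_up`), not banker's
  rounding. The published tables truncate 25 of 65 cross-tab cells (always
  exactly 0.1 below half-up); tests therefore pin exact equality only where
  truncation and half-up coincide, and printed precision (±0.1) elsewhere.
* The calibration LP renormalises weights and clips at 0 to absorb solver
  epsilon; quota ties break by library order.
* κ with degenerate chance agreement: 1 if observed agreement is perfect,
  else 0.
* PCA eigenvalues are clipped at 0 (the correlation matrix is PSD up to
  rounding); eigenvalue ties make the within-subspace loadings
  solver-determined but the sign convention still fixes the output.

## Known limitations

* The FoP added-ingredient gate cannot be inferred from composition; the
  `added_*` flags are input data. Published stamp distributions for fat-
  and cheese-heavy groups are reproducible only with the gate on.
* The NOVA vocabulary is an editorial choice; NOVA's own boundaries are
  contested, and the ladder is only as good as the marker tagging.
* The 2023-revised Nutri-Score algorithm is out of scope; so are free-text
  ingredient parsing, inferential statistics on the cross-tabs, and
  correspondence analysis.
* Archetype baselines are plausible synthetic label values, not
  measurements; no nutrient summary statistics of the original survey were
  published to fit against.
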
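"""Synthetic Chilean-basket generator.

The surveyed 736-food basket is not publicly deposited, so this module
fabricates baskets with the same *structure*: the five food groups at their
surveyed sizes (198 cereals, 109 dairy, 139 protein foods, 100 oils/fats,
190 sugars/others), per-group nutrient heterogeneity, and marker/flag
patterns that make the three classifiers disagree the way real products do.

Each food is an instance of an *archetype* — a plausible label-level product
template (plain potatoes, sweetened breakfast cereal, diet soft drink, ...)
shipped as data in ``data/archetypes.yaml`` — with independent multiplicative
lognormal noise on every nutrient, truncated so saturated fat never exceeds
total fat and FVNL never exceeds 100%. At zero noise an archetype reproduces
its intended (Nutri-Score band, NOVA class, warning-label count) exactly.

Archetype mixture weights per group can be calibrated against target
category distributions (e.g. the published per-group percentages) by L1-
minimising linear programming over the archetypes' zero-noise profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import linprog

from . import reference
from .fop import count_warnings
from .model import GROUPS, FoodRecord, NutrientPanel, NUTRIENT_FIELDS
from .nova import MarkerVocabulary, classify_nova, load_vocabulary
from .nutriscore import compute_nutriscore

_GROUP_PREFIX = {
    "cereals": "CER", "dairy": "DAI", "protein_foods": "PRO",
    "oils_fats": "OIL", "sugars_others": "SUG",
}


class InfeasibleTargetError(ValueError):
    """A calibration target puts mass on categories no archetype can reach."""

    def __init__(self, unreachable: dict):
        self.unreachable = unreachable
        msg = "; ".join(f"{s}: {sorted(map(str, cats))}" for s, cats in unreachable.items())
        super().__init__(f"unreachable target categories — {msg}")


@dataclass(frozen=True)
class Archetype:
    """A product template with the classification profile it is built to hit."""

    name: str
    group: str
    state: str
    panel: NutrientPanel
    markers: frozenset[str]
    added_sugar: bool
    added_sat_fat: bool
    added_sodium: bool
    special_category: str
    intended_profile: tuple  # (nutriscore band, nova class, fop label count)

    def record(self, food_id: str | None = None, panel: NutrientPanel | None = None) -> FoodRecord:
        return FoodRecord(
            food_id=food_id or self.name, name=self.name.replace("_", " "),
            group=self.group, state=self.state, panel=panel or self.panel,
            added_sugar=self.added_sugar, added_sat_fat=self.added_sat_fat,
            added_sodium=self.added_sodium, markers=self.markers,
            special_category=self.special_category)


@dataclass
class BasketConfig:
    """Generator conditions: the surveyed group sizes, calibrated weights,
    lognormal nutrient noise sigma and a seed."""

    group_sizes: dict = field(default_factory=lambda: dict(reference.GROUP_SIZES))
    weights: dict | None = None  # group -> {archetype name: weight}; None = calibrate
    seed: int = 0
    sigma: float = 0.1

    def __post_init__(self):
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s) in group_sizes: {sorted(unknown)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes.values())


def load_archetypes(path=None) -> list[Archetype]:
    """Load the archetype library (the packaged default when path is None)."""
    if path is None:
        text = resources.files("nutrilabel.data").joinpath("archetypes.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    out = []
    for raw in yaml.safe_load(text):
        ip = raw["intended_profile"]
        out.append(Archetype(
            name=raw["name"], group=raw["group"], state=raw["state"],
            panel=NutrientPanel(**raw["panel"]),
            markers=frozenset(raw.get("markers") or []),
            added_sugar=bool(raw.get("added", {}).get("sugar", 0)),
            added_sat_fat=bool(raw.get("added", {}).get("sat_fat", 0)),
            added_sodium=bool(raw.get("added", {}).get("sodium", 0)),
            special_category=raw.get("special_category", "none"),
            intended_profile=(ip["nutriscore"], int(ip["nova"]), int(ip["fop"])),
        ))
    names = [a.name for a in out]
    if len(names) != len(set(names)):
        raise ValueError("duplicate archetype names in library")
    return out


def archetype_profile(arch: Archetype, vocab: MarkerVocabulary | None = None,
                      gate: bool = False) -> tuple:
    """Classify the zero-noise baseline: (Nutri-Score band, NOVA, label count)."""
    vocab = vocab or load_vocabulary()
    rec = arch.record()
    ns = compute_nutriscore(rec.panel, rec.special_category).category
    nova = classify_nova(rec, vocab).nova
    fop = count_warnings(rec, gate=gate).n_labels
    return (ns, nova, fop)


def _largest_remainder(weights: dict[str, float], n: int) -> dict[str, int]:
    names = list(weights)
    quotas = np.array([weights[k] for k in names], dtype=float)
    quotas = quotas / quotas.sum() * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # distribute the remainder by largest fractional part, ties by order
    order = np.argsort(-(quotas - counts), kind="stable")
    for j in order[:short]:
        counts[j] += 1
    return {k: int(c) for k, c in zip(names, counts)}


def calibrate_mixture(targets: dict, group: str,
                      library: list[Archetype] | None = None,
                      vocab: MarkerVocabulary | None = None,
                      gate: bool = False) -> tuple[dict[str, float], float]:
    """Weights over the group's archetypes minimising the summed L1 distance
    between the zero-noise classified distribution and the targets.

    ``targets`` maps system name ("nutriscore" | "nova" | "fop") to a
    category->share distribution; one or several systems may be given.
    Raises :class:`InfeasibleTargetError` when a targeted category is
    reachable by no archetype of the group.
    """
    library = library if library is not None else load_archetypes()
    vocab = vocab or load_vocabulary()
    archs = [a for a in library if a.group == group]
    if not archs:
        raise ValueError(f"no archetypes for group {group!r}")
    sys_index = {"nutriscore": 0, "nova": 1, "fop": 2}
    unknown = set(targets) - set(sys_index)
    if unknown:
        raise ValueError(f"unknown system(s) in targets: {sorted(unknown)}")
    profiles = [archetype_profile(a, vocab, gate=gate) for a in archs]

    unreachable = {}
    for system, dist in targets.items():
        reachable = {p[sys_index[system]] for p in profiles}
        bad = {c for c, share in dist.items() if share > 0 and c not in reachable}
        if bad:
            unreachable[system] = bad
    if unreachable:
        raise InfeasibleTargetError(unreachable)

    # LP: minimise sum of slacks e_{s,c} >= |A w - t| with w on the simplex
    rows = []  # (system, category, target, indicator vector)
    for system, dist in targets.items():
        for cat, share in dist.items():
            ind = np.array([1.0 if p[sys_index[system]] == cat else 0.0
                            for p in profiles])
            rows.append((share, ind))
    J, K = len(archs), len(rows)
    c = np.concatenate([np.zeros(J), np.ones(K)])
    A_ub, b_ub = [], []
    for k, (t, ind) in enumerate(rows):
        e = np.zeros(K); e[k] = 1.0
        A_ub.append(np.concatenate([ind, -e])); b_ub.append(t)
        A_ub.append(np.concatenate([-ind, -e])); b_ub.append(-t)
    A_eq = [np.concatenate([np.ones(J), np.zeros(K)])]
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  A_eq=np.array(A_eq), b_eq=[1.0],
                  bounds=[(0, None)] * (J + K), method="highs")
    if not res.success:  # pragma: no cover - LP above is always feasible
        raise RuntimeError(f"calibration LP failed: {res.message}")
    w = np.clip(res.x[:J], 0.0, None)
    w = w / w.sum()
    distance = float(res.x[J:].sum())
    return ({a.name: float(wi) for a, wi in zip(archs, w)}, distance)


def default_weights(library: list[Archetype] | None = None,
                    vocab: MarkerVocabulary | None = None) -> dict:
    """Per-group weights calibrated to the published per-group distributions.

    The oils/fats FoP target is excluded from its calibration: under
    composition-only stamping (the package default) pure fats always exceed
    the energy limit, so the published 50% stamp-free share — a consequence
    of the law's added-ingredient scope — is unreachable by construction.
    """
    library = library if library is not None else load_archetypes()
    vocab = vocab or load_vocabulary()
    out = {}
    for group in GROUPS:
        targets = reference.normalized_targets(group)
        if group == "oils_fats":
            targets = {s: d for s, d in targets.items() if s != "fop"}
        out[group], _ = calibrate_mixture(targets, group, library, vocab)
    return out


def generate_basket(config: BasketConfig,
                    library: list[Archetype] | None = None,
                    vocab: MarkerVocabulary | None = None) -> list[FoodRecord]:
    """Generate a fully reproducible synthetic basket.

    Per group (canonical order) archetype counts are fixed by largest-
    remainder quotas on the weights, then each record's nutrients are
    multiplied by iid lognormal(0, sigma) factors drawn from a single
    seeded generator in document order (groups, then archetypes, then
    records, then the canonical nutrient order).
    """
    library = library if library is not None else load_archetypes()
    weights = config.weights if config.weights is not None else default_weights(library, vocab)
    rng = np.random.default_rng(config.seed)
    by_group: dict[str, list[Archetype]] = {g: [] for g in GROUPS}
    by_name = {a.name: a for a in library}
    records: list[FoodRecord] = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        gw = weights.get(group)
        if not gw:
            raise ValueError(f"no mixture weights for group {group!r}")
        unknown = set(gw) - set(by_name)
        if unknown:
            raise ValueError(f"weights name unknown archetype(s): {sorted(unknown)}")
        counts = _largest_remainder(gw, n)
        idx = 0
        for name, count in counts.items():
            arch = by_name[name]
            if arch.group != group:
                raise ValueError(f"archetype {name!r} is not in group {group!r}")
            for _ in range(count):
                idx += 1
                if config.sigma > 0:
                    factors = dict(zip(
                        NUTRIENT_FIELDS,
                        rng.lognormal(0.0, config.sigma, size=len(NUTRIENT_FIELDS))))
                    panel = arch.panel.scaled(factors)
                else:
                    panel = arch.panel.scaled({})
                records.append(arch.record(
                    food_id=f"{_GROUP_PREFIX[group]}{idx:04d}", panel=panel))
    return records
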
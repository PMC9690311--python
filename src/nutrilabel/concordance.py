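"""Concordance analysis between classification systems.

Given per-food category labels from the three systems (Nutri-Score A-E,
NOVA 1-4, FoP warning-label counts 0-4) this module produces the analytic
layer of the study design: frequency distributions by food group, pairwise
cross-tabulations with row percentages, recommended/not-recommended
agreement (directional shares, percent agreement, Cohen's kappa), and a
PCA ordination of ordinal-encoded ratings whose loading-vector angles
quantify how close the systems' verdict geometries are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

NUTRISCORE_CATEGORIES = ["A", "B", "C", "D", "E"]
NOVA_CATEGORIES = [1, 2, 3, 4]
FOP_CATEGORIES = [0, 1, 2, 3, 4]

SYSTEM_CATEGORIES = {
    "nutriscore": NUTRISCORE_CATEGORIES,
    "nova": NOVA_CATEGORIES,
    "fop": FOP_CATEGORIES,
}

#: default recommended/neutral/not mappings: Nutri-Score A/B recommended and
#: D/E not; NOVA 4 (ultra-processed) not recommended; any warning label not.
DEFAULT_RECOMMENDATION_MAPS = {
    "nutriscore": {"A": "recommended", "B": "recommended", "C": "neutral",
                   "D": "not_recommended", "E": "not_recommended"},
    "nova": {1: "recommended", 2: "recommended", 3: "recommended",
             4: "not_recommended"},
    "fop": {0: "recommended", 1: "not_recommended", 2: "not_recommended",
            3: "not_recommended", 4: "not_recommended"},
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of printed survey tables,
    where banker's rounding would be surprising)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DistributionTable:
    """Category counts and percentages for one system in one stratum."""

    system: str
    group: str
    counts: dict
    pct: dict
    n: int
    decimals: int


@dataclass(frozen=True)
class CrossTab:
    """Counts and row percentages crossing two systems, with marginals."""

    row_system: str
    col_system: str
    counts: pd.DataFrame
    row_pct: pd.DataFrame
    row_marginals: pd.Series
    col_marginals: pd.Series
    grand_total: int


@dataclass(frozen=True)
class AgreementSummary:
    share_recommended_a_also_b: float  # percent, directional
    share_recommended_b_also_a: float
    percent_agreement: float  # on foods non-neutral under both systems
    kappa: float
    n_non_neutral: int


@dataclass(frozen=True)
class OrdinationResult:
    """Two-component PCA of the standardized ordinal rating matrix."""

    stratum: str
    encoded: np.ndarray  # foods x 3, standardized
    loadings: np.ndarray  # 3 systems x 2 components (orthonormal columns)
    scores: np.ndarray  # foods x 2
    explained_variance: np.ndarray  # fraction per component, all 3
    angles_deg: dict  # "sysA|sysB" -> angle between 2-D loading vectors

    def to_dict(self, include_scores: bool = False) -> dict:
        out = {
            "stratum": self.stratum,
            "systems": list(SYSTEM_CATEGORIES),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "angles_deg": self.angles_deg,
        }
        if include_scores:
            out["scores"] = self.scores.tolist()
        return out


def tabulate_distribution(labels, system: str, group: str = "all",
                          categories=None, decimals: int = 0) -> DistributionTable:
    """Counts and rounded percentages of each category in a stratum.

    ``decimals=0`` reproduces headline integer percentages; ``decimals=1``
    the one-decimal convention of cross-tab cells. Empty strata are errors.
    """
    labels = pd.Series(list(labels))
    n = len(labels)
    if n == 0:
        raise ValueError(f"empty stratum: system={system!r}, group={group!r}")
    if categories is None:
        categories = SYSTEM_CATEGORIES[system]
    unknown = set(labels) - set(categories)
    if unknown:
        raise ValueError(f"labels outside category set: {sorted(map(str, unknown))}")
    counts = {c: int((labels == c).sum()) for c in categories}
    pct = {c: round_half_up(100.0 * counts[c] / n, decimals) for c in categories}
    return DistributionTable(system=system, group=group, counts=counts,
                             pct=pct, n=n, decimals=decimals)


def cross_tabulate(row_labels: pd.Series, col_labels: pd.Series,
                   row_system: str = "row", col_system: str = "col",
                   row_categories=None, col_categories=None) -> CrossTab:
    """Cross-tabulate two aligned label vectors (indexed by food_id).

    Row percentages are 100 x cell / row-marginal, rounded half-up to one
    decimal; rows with zero marginal report 0 throughout.
    """
    row_labels, col_labels = pd.Series(row_labels), pd.Series(col_labels)
    if set(row_labels.index) != set(col_labels.index):
        raise ValueError("row and column label vectors cover different food_id sets")
    col_labels = col_labels.reindex(row_labels.index)
    if row_categories is None:
        row_categories = SYSTEM_CATEGORIES.get(row_system, sorted(row_labels.unique()))
    if col_categories is None:
        col_categories = SYSTEM_CATEGORIES.get(col_system, sorted(col_labels.unique()))
    counts = (pd.crosstab(row_labels, col_labels)
              .reindex(index=row_categories, columns=col_categories, fill_value=0)
              .astype(int))
    counts.index.name, counts.columns.name = row_system, col_system
    row_marg = counts.sum(axis=1)
    col_marg = counts.sum(axis=0)
    denom = row_marg.replace(0, 1)
    row_pct = (100.0 * counts.div(denom, axis=0)).map(lambda v: round_half_up(v, 1))
    return CrossTab(row_system=row_system, col_system=col_system,
                    counts=counts, row_pct=row_pct,
                    row_marginals=row_marg, col_marginals=col_marg,
                    grand_total=int(counts.values.sum()))


def _to_binary(labels: pd.Series, mapping: dict, name: str) -> pd.Series:
    missing = set(labels.unique()) - set(mapping)
    if missing:
        raise KeyError(
            f"category(ies) absent from {name} mapping: {sorted(map(str, missing))}")
    return labels.map(mapping)


def recommendation_agreement(labels_a: pd.Series, labels_b: pd.Series,
                             mapping_a: dict, mapping_b: dict) -> AgreementSummary:
    """Agreement of two systems after collapsing categories to
    recommended / not_recommended / neutral.

    Directional shares condition on being recommended under one system;
    percent agreement and unweighted Cohen's kappa are computed over foods
    non-neutral under both. With degenerate chance agreement (pe = 1) kappa
    is 1 for perfect observed agreement and 0 otherwise.
    """
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("label vectors cover different food_id sets")
    labels_b = labels_b.reindex(labels_a.index)
    a = _to_binary(labels_a, mapping_a, "system A")
    b = _to_binary(labels_b, mapping_b, "system B")

    def directional(x, y):
        rec = x == "recommended"
        if rec.sum() == 0:
            return float("nan")
        return 100.0 * float((y[rec] == "recommended").mean())

    keep = (a != "neutral") & (b != "neutral")
    ak, bk = a[keep], b[keep]
    n = len(ak)
    if n == 0:
        po, kappa = float("nan"), float("nan")
    else:
        po = float((ak == bk).mean())
        pe = sum(float((ak == c).mean()) * float((bk == c).mean())
                 for c in ("recommended", "not_recommended"))
        if math.isclose(pe, 1.0):
            kappa = 1.0 if math.isclose(po, 1.0) else 0.0
        else:
            kappa = (po - pe) / (1 - pe)
    return AgreementSummary(
        share_recommended_a_also_b=directional(a, b),
        share_recommended_b_also_a=directional(b, a),
        percent_agreement=100.0 * po if not math.isnan(po) else po,
        kappa=kappa, n_non_neutral=n)


_NS_CODE = {c: i + 1 for i, c in enumerate(NUTRISCORE_CATEGORIES)}


def ordinal_encode(labels: pd.DataFrame, stratum: str = "all",
                   standardize: bool = True) -> np.ndarray:
    """Encode the three systems' labels as ordinal severity codes.

    Nutri-Score A..E -> 1..5, NOVA 1..4 -> 1..4, FoP 0..4 labels -> 1..5;
    higher always means less favourable. Columns are standardized to zero
    mean and unit variance (ddof=1) unless ``standardize=False``; a
    zero-variance column in the stratum is an error.
    """
    required = ("nutriscore", "nova", "fop")
    missing = [c for c in required if c not in labels.columns]
    if missing:
        raise ValueError(f"missing system column(s): {missing}")
    X = np.column_stack([
        labels["nutriscore"].map(_NS_CODE).to_numpy(dtype=float),
        labels["nova"].astype(int).to_numpy(dtype=float),
        labels["fop"].astype(int).to_numpy(dtype=float) + 1.0,
    ])
    if np.isnan(X).any():
        raise ValueError("unencodable label present (check category values)")
    if not standardize:
        return X
    sd = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(3)
    for j, name in enumerate(required):
        if sd[j] == 0:
            raise ValueError(
                f"zero-variance column {name!r} in stratum {stratum!r}; "
                "PCA on constant ratings is undefined")
    return (X - X.mean(axis=0)) / sd


def run_pca(encoded: np.ndarray, stratum: str = "all") -> OrdinationResult:
    """Eigendecompose the 3x3 correlation matrix of the standardized codes.

    Returns the first two components with a fixed sign convention (each
    component's largest-magnitude loading is positive) so the ordination is
    unique, plus the pairwise angles between the systems' 2-D loading
    vectors — the quantitative counterpart of biplot arrow closeness.
    """
    X = np.asarray(encoded, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("encoded matrix must be foods x 3 systems")
    n = X.shape[0]
    if n < X.shape[1]:
        raise ValueError(f"need at least 3 foods, got {n}")
    corr = X.T @ X / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(3):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    loadings = eigvecs[:, :2]
    scores = X @ loadings
    explained = eigvals / eigvals.sum()

    # biplot arrows scale eigenvectors by sqrt(eigenvalue): the cosine of the
    # angle between two variables' arrows is then their correlation as
    # approximated in the retained plane, and degenerate components vanish
    arrows = loadings * np.sqrt(eigvals[:2])
    systems = list(SYSTEM_CATEGORIES)
    angles = {}
    for i in range(3):
        for j in range(i + 1, 3):
            u, v = arrows[i], arrows[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0 or nv == 0:
                ang = float("nan")
            else:
                ang = math.degrees(math.acos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))
            angles[f"{systems[i]}|{systems[j]}"] = ang
    return OrdinationResult(stratum=stratum, encoded=X, loadings=loadings,
                            scores=scores, explained_variance=explained,
                            angles_deg=angles)
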
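"""Published reference tables from the 736-item Chilean market-basket survey.

The survey classified 736 supermarket foods belonging to the Chilean basic
food basket under Nutri-Score, NOVA and the Chilean FoP warning labels and
printed (i) pairwise contingency counts between the three systems and
(ii) per-group category percentage distributions. Those printed numbers are
*inputs* here: the contingency counts feed the arithmetic-reproduction
checks (recomputing the printed row percentages through the concordance
module), and the percentage distributions are the calibration targets the
synthetic basket generator aims at.

Two caption percentages in the published per-group distributions are
internally inconsistent (the sugars-group NOVA and FoP vectors do not sum
to ~100); the calibration targets below correct them (NOVA 3: 8 not 18;
FoP 2: 9 not 19) by back-computation from the contingency-table marginals.
"""

from __future__ import annotations

import pandas as pd

#: foods per group as surveyed (sums to 736)
GROUP_SIZES = {
    "cereals": 198,
    "dairy": 109,
    "protein_foods": 139,
    "oils_fats": 100,
    "sugars_others": 190,
}
N_TOTAL = 736

#: Nutri-Score (rows A-E) x NOVA (cols 1-4) contingency counts
CROSSTAB_NUTRISCORE_NOVA = {
    "A": [107, 3, 50, 37],
    "B": [17, 3, 15, 83],
    "C": [7, 39, 16, 67],
    "D": [4, 40, 25, 96],
    "E": [8, 4, 3, 112],
}

#: Nutri-Score (rows A-E) x FoP label count (cols 0-4)
CROSSTAB_NUTRISCORE_FOP = {
    "A": [187, 8, 1, 1, 0],
    "B": [101, 12, 4, 1, 0],
    "C": [82, 21, 17, 9, 0],
    "D": [39, 28, 36, 62, 0],
    "E": [12, 4, 9, 98, 4],
}

#: NOVA (rows 1-4) x FoP label count (cols 0-4)
CROSSTAB_NOVA_FOP = {
    1: [143, 0, 0, 0, 0],
    2: [69, 0, 12, 8, 0],
    3: [78, 18, 4, 9, 0],
    4: [131, 55, 51, 154, 4],
}

#: printed row percentages, in the same layout, for comparison in tests
PRINTED_ROW_PCT_NUTRISCORE_NOVA = {
    "A": [54.3, 1.5, 25.3, 18.7],
    "B": [14.4, 2.5, 12.7, 70.3],
    "C": [5.4, 30.2, 12.4, 51.9],
    "D": [2.4, 24.2, 15.1, 58.1],
    "E": [6.2, 3.1, 2.3, 88.1],
}
PRINTED_ROW_PCT_NUTRISCORE_FOP = {
    "A": [94.9, 4.0, 0.5, 0.5, 0.0],
    "B": [85.5, 10.1, 3.3, 0.8, 0.0],
    "C": [63.5, 16.2, 13.1, 6.9, 0.0],
    "D": [23.6, 16.9, 21.8, 37.5, 0.0],
    "E": [9.4, 3.1, 7.0, 77.1, 3.1],
}
PRINTED_ROW_PCT_NOVA_FOP = {
    1: [100.0, 0.0, 0.0, 0.0, 0.0],
    2: [77.5, 0.0, 13.4, 8.9, 0.0],
    3: [71.5, 16.5, 3.6, 8.2, 0.0],
    4: [33.2, 13.9, 12.9, 38.9, 1.0],
}

#: published per-group category distributions (percent), used as the
#: generator's calibration targets; see module docstring for the two
#: corrected sugars-group entries.
GROUP_DISTRIBUTION_PCT = {
    "cereals": {
        "nutriscore": {"A": 46, "B": 7, "C": 13, "D": 15, "E": 19},
        "nova": {1: 25, 2: 0, 3: 10, 4: 65},
        "fop": {0: 49, 1: 13, 2: 7, 3: 29, 4: 2},
    },
    "dairy": {
        "nutriscore": {"A": 11, "B": 47, "C": 7, "D": 19, "E": 16},
        "nova": {1: 14, 2: 0, 3: 31, 4: 55},
        "fop": {0: 75, 1: 18, 2: 6, 3: 0, 4: 1},
    },
    "protein_foods": {
        "nutriscore": {"A": 60, "B": 7, "C": 6, "D": 25, "E": 4},
        "nova": {1: 48, 2: 2, 3: 25, 4: 25},
        "fop": {0: 71, 1: 14, 2: 6, 3: 9, 4: 0},
    },
    "oils_fats": {
        "nutriscore": {"A": 4, "B": 5, "C": 51, "D": 36, "E": 4},
        "nova": {1: 0, 2: 64, 3: 6, 4: 30},
        "fop": {0: 50, 1: 2, 2: 21, 3: 27, 4: 0},
    },
    "sugars_others": {
        "nutriscore": {"A": 4, "B": 20, "C": 18, "D": 25, "E": 33},
        "nova": {1: 6, 2: 11, 3: 8, 4: 75},
        "fop": {0: 49, 1: 3, 2: 9, 3: 38, 4: 0},
    },
}

#: headline whole-basket distributions (percent) and counts
ALL_FOODS_PCT = {
    "nutriscore": {"A": 27, "B": 16, "C": 18, "D": 22, "E": 17},
    "nova": {1: 19, 2: 12, 3: 15, 4: 54},
    "fop": {0: 57, 1: 10, 2: 9, 3: 23, 4: 1},
}


def normalized_targets(group: str) -> dict:
    """Per-group calibration targets as proper distributions (shares sum 1)."""
    out = {}
    for system, pct in GROUP_DISTRIBUTION_PCT[group].items():
        total = float(sum(pct.values()))
        out[system] = {c: v / total for c, v in pct.items()}
    return out


def expand_crosstab(counts: dict, prefix: str = "f") -> tuple[pd.Series, pd.Series]:
    """Expand a contingency-count table into aligned per-food label vectors
    (synthetic food ids) suitable for :func:`concordance.cross_tabulate`."""
    rows, cols, ids = [], [], []
    k = 0
    for r, row in counts.items():
        for c, n in zip(_columns_of(counts), row):
            for _ in range(n):
                ids.append(f"{prefix}{k:04d}")
                rows.append(r)
                cols.append(c)
                k += 1
    return (pd.Series(rows, index=ids), pd.Series(cols, index=ids))


def _columns_of(counts: dict) -> list:
    width = len(next(iter(counts.values())))
    if width == 4:
        return [1, 2, 3, 4]  # NOVA columns
    return [0, 1, 2, 3, 4]  # FoP columns
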
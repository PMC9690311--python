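"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's lookup machinery: every point table
is scanned linearly with explicit if-chains, and the whole score is
assembled in one flat function, so agreement with the package is a genuine
dual-route check rather than the same code called twice.
"""


def linear_points(value, thresholds):
    pts = 0
    for t in thresholds:
        if value > t:
            pts += 1
    return pts


def brute_force_nutriscore(panel, special_category="none"):
    """Flat re-implementation of the 2017 scoring; returns (score, category)."""
    beverage = special_category == "beverage"

    if beverage:
        energy_pts = linear_points(panel.energy_kj,
                                   [0, 30, 60, 90, 120, 150, 180, 210, 240, 270])
        sugar_pts = linear_points(panel.sugars_g,
                                  [0, 1.5, 3, 4.5, 6, 7.5, 9, 10.5, 12, 13.5])
    else:
        energy_pts = linear_points(panel.energy_kj,
                                   [335, 670, 1005, 1340, 1675, 2010, 2345,
                                    2680, 3015, 3350])
        sugar_pts = linear_points(panel.sugars_g,
                                  [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45])
    if special_category == "added_fat":
        ratio = 0.0
        if panel.total_fat_g > 0:
            ratio = 100.0 * panel.saturated_fat_g / panel.total_fat_g
        sat_pts = linear_points(ratio, [10, 16, 22, 28, 34, 40, 46, 52, 58, 64])
    else:
        sat_pts = linear_points(panel.saturated_fat_g,
                                [1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
    sodium_pts = linear_points(panel.sodium_mg,
                               [90, 180, 270, 360, 450, 540, 630, 720, 810, 900])

    fvnl = panel.fvnl_pct
    if beverage:
        fvnl_pts = 10 if fvnl > 80 else 4 if fvnl > 60 else 2 if fvnl > 40 else 0
    else:
        fvnl_pts = 5 if fvnl > 80 else 2 if fvnl > 60 else 1 if fvnl > 40 else 0
    fibre_pts = linear_points(panel.fibre_g, [0.9, 1.9, 2.8, 3.7, 4.7])
    protein_pts = linear_points(panel.protein_g, [1.6, 3.2, 4.8, 6.4, 8.0])

    n = energy_pts + sugar_pts + sat_pts + sodium_pts
    fvnl_max = 10 if beverage else 5
    if special_category == "cheese" or n < 11 or fvnl_pts == fvnl_max:
        score = n - (fvnl_pts + fibre_pts + protein_pts)
    else:
        score = n - (fvnl_pts + fibre_pts)

    if beverage:
        if (panel.energy_kcal == 0 and panel.sugars_g == 0
                and panel.total_fat_g == 0 and panel.sodium_mg == 0):
            cat = "A"
        elif score <= 1:
            cat = "B"
        elif score <= 5:
            cat = "C"
        elif score <= 9:
            cat = "D"
        else:
            cat = "E"
    else:
        if score <= -1:
            cat = "A"
        elif score <= 2:
            cat = "B"
        elif score <= 10:
            cat = "C"
        elif score <= 18:
            cat = "D"
        else:
            cat = "E"
    return score, cat
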
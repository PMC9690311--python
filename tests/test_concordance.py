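import math

import numpy as np
import pandas as pd
import pytest

from nutrilabel import concordance as cc
from nutrilabel import reference


def series(values, prefix="f"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (54.305, 1, 54.3), (18.78, 1, 18.8), (0.05, 1, 0.1), (26.8, 0, 27.0),
        (22.4, 0, 22.0), (2.5, 0, 3.0),
    ])
    def test_half_up(self, x, nd, expected):
        assert cc.round_half_up(x, nd) == expected


class TestDistribution:
    def test_degenerate_stratum_is_100_percent(self):
        t = cc.tabulate_distribution(series(["A"] * 4), "nutriscore")
        assert t.pct["A"] == 100.0
        assert all(t.pct[c] == 0.0 for c in "BCDE")

    def test_headline_nutriscore_share(self):
        labels = (["A"] * 197 + ["B"] * 118 + ["C"] * 129 + ["D"] * 165
                  + ["E"] * 127)
        t = cc.tabulate_distribution(series(labels), "nutriscore")
        assert t.n == 736
        assert t.pct["A"] == 27.0  # 197/736 = 26.77 -> 27
        assert t.pct["D"] == 22.0

    def test_headline_nova_share(self):
        labels = [1] * 143 + [2] * 89 + [3] * 109 + [4] * 395
        t = cc.tabulate_distribution(series(labels), "nova")
        assert t.pct[4] == 54.0
        assert t.pct[1] == 19.0

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="empty stratum"):
            cc.tabulate_distribution(series([]), "nova")

    def test_counts_sum_to_n(self):
        t = cc.tabulate_distribution(series(["A", "C", "C", "E"]), "nutriscore")
        assert sum(t.counts.values()) == t.n == 4


class TestCrossTab:
    def test_system_crossed_with_itself_is_diagonal(self):
        labels = series(["A", "B", "B", "E"])
        ct = cc.cross_tabulate(labels, labels, "nutriscore", "nutriscore")
        counts = ct.counts.to_numpy()
        assert counts.sum() == np.trace(counts)
        for cat, n in zip("ABCDE", np.diag(counts)):
            if n:
                assert ct.row_pct.loc[cat, cat] == 100.0

    def test_published_nutriscore_nova_row_a(self):
        rows, cols = reference.expand_crosstab(reference.CROSSTAB_NUTRISCORE_NOVA)
        ct = cc.cross_tabulate(rows, cols, "nutriscore", "nova")
        assert ct.counts.loc["A"].tolist() == [107, 3, 50, 37]
        assert ct.row_marginals["A"] == 197
        # half-up from the printed counts: 107/197, 3/197, 50/197, 37/197
        assert ct.row_pct.loc["A"].tolist() == [54.3, 1.5, 25.4, 18.8]

    def test_published_nova_fop_row_1_is_all_label_free(self):
        rows, cols = reference.expand_crosstab(reference.CROSSTAB_NOVA_FOP)
        ct = cc.cross_tabulate(rows, cols, "nova", "fop")
        assert ct.row_pct.loc[1].tolist() == [100.0, 0.0, 0.0, 0.0, 0.0]

    def test_transpose_symmetry(self):
        rows, cols = reference.expand_crosstab(reference.CROSSTAB_NUTRISCORE_FOP)
        ab = cc.cross_tabulate(rows, cols, "nutriscore", "fop")
        ba = cc.cross_tabulate(cols, rows, "fop", "nutriscore")
        assert (ab.counts.to_numpy() == ba.counts.to_numpy().T).all()

    def test_marginals_reproduce_distribution_counts(self):
        rows, cols = reference.expand_crosstab(reference.CROSSTAB_NUTRISCORE_NOVA)
        ct = cc.cross_tabulate(rows, cols, "nutriscore", "nova")
        dist = cc.tabulate_distribution(rows, "nutriscore")
        assert ct.row_marginals.to_dict() == dist.counts
        assert ct.grand_total == dist.n

    def test_row_percent_rows_sum_to_about_100(self):
        rows, cols = reference.expand_crosstab(reference.CROSSTAB_NOVA_FOP)
        ct = cc.cross_tabulate(rows, cols, "nova", "fop")
        sums = ct.row_pct.sum(axis=1)
        assert ((sums >= 99.5) & (sums <= 100.5)).all()

    def test_mismatched_food_ids_rejected(self):
        a = series(["A", "B"])
        b = series([1, 2], prefix="g")
        with pytest.raises(ValueError, match="different food_id"):
            cc.cross_tabulate(a, b)


class TestAgreement:
    MAPS = cc.DEFAULT_RECOMMENDATION_MAPS

    def test_identical_vectors_agree_perfectly(self):
        labels = series([1, 1, 4, 4, 2])
        s = cc.recommendation_agreement(labels, labels,
                                        self.MAPS["nova"], self.MAPS["nova"])
        assert s.share_recommended_a_also_b == 100.0
        assert s.percent_agreement == 100.0
        assert s.kappa == 1.0

    def test_nova1_foods_all_label_free(self):
        rows, cols = reference.expand_crosstab(reference.CROSSTAB_NOVA_FOP)
        nova1 = rows[rows == 1]
        fop1 = cols[nova1.index]
        assert (fop1 == 0).mean() == 1.0  # directional share = 100%
        s = cc.recommendation_agreement(rows, cols, self.MAPS["nova"],
                                        self.MAPS["fop"])
        assert 0 <= s.share_recommended_a_also_b <= 100
        assert -1 <= s.kappa <= 1

    def test_independence_gives_kappa_zero(self):
        a = series([1, 1, 4, 4])
        b = series([0, 1, 0, 1])
        s = cc.recommendation_agreement(a, b, self.MAPS["nova"], self.MAPS["fop"])
        assert s.kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_matches_sklearn_on_random_labels(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        a = series(rng.choice([1, 2, 3, 4], size=200).tolist())
        b = series(rng.choice([0, 1, 2, 3, 4], size=200).tolist())
        s = cc.recommendation_agreement(a, b, self.MAPS["nova"], self.MAPS["fop"])
        ra = a.map(self.MAPS["nova"])
        rb = b.map(self.MAPS["fop"])
        expected = sklearn.cohen_kappa_score(ra, rb)
        assert s.kappa == pytest.approx(expected, abs=1e-12)

    def test_unmapped_category_rejected(self):
        a = series(["A", "F"])
        b = series([0, 1])
        with pytest.raises(KeyError, match="F"):
            cc.recommendation_agreement(a, b, self.MAPS["nutriscore"],
                                        self.MAPS["fop"])


def frame(ns, nova, fop):
    idx = [f"f{i}" for i in range(len(ns))]
    return pd.DataFrame({"nutriscore": ns, "nova": nova, "fop": fop}, index=idx)


class TestOrdinalEncode:
    def test_best_and_worst_codes(self):
        df = frame(["A", "E"], [1, 4], [0, 4])
        X = cc.ordinal_encode(df, standardize=False)
        assert X[0].tolist() == [1.0, 1.0, 1.0]
        assert X[1].tolist() == [5.0, 4.0, 5.0]

    def test_standardized_columns_have_zero_mean_unit_variance(self):
        df = frame(["A", "C", "E", "B"], [1, 2, 4, 3], [0, 2, 4, 1])
        X = cc.ordinal_encode(df)
        assert np.allclose(X.mean(axis=0), 0)
        assert np.allclose(X.std(axis=0, ddof=1), 1)

    def test_constant_column_rejected_naming_stratum(self):
        df = frame(["A", "B"], [4, 4], [0, 1])
        with pytest.raises(ValueError, match="dairy"):
            cc.ordinal_encode(df, stratum="dairy")


class TestRunPCA:
    def test_three_perfectly_correlated_columns(self):
        base = np.array([1.0, 2, 3, 4, 5])
        x = (base - base.mean()) / base.std(ddof=1)
        X = np.column_stack([x, x, x])
        res = cc.run_pca(X)
        assert np.allclose(res.explained_variance, [1.0, 0.0, 0.0], atol=1e-12)
        assert all(math.isclose(a, 0.0, abs_tol=1e-6)
                   for a in res.angles_deg.values())

    def test_two_identical_plus_one_independent_column(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        a = (a - a.mean()) / a.std(ddof=1)
        b = b - (b @ a) / (a @ a) * a  # make the third column exactly uncorrelated
        b = (b - b.mean()) / b.std(ddof=1)
        # exact 2-block correlation structure: PC1 explains 2/3
        X = np.column_stack([a, a, b])
        res = cc.run_pca(X)
        assert res.explained_variance[0] == pytest.approx(2 / 3, abs=1e-9)

    def test_loadings_match_sklearn_pca(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(11)
        raw = rng.normal(size=(100, 3)) @ rng.normal(size=(3, 3))
        X = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        res = cc.run_pca(X)
        sk = sklearn_pca.PCA(n_components=2).fit(X)
        for k in range(2):
            ours = res.loadings[:, k]
            theirs = sk.components_[k]
            theirs = theirs * np.sign(theirs[np.argmax(np.abs(theirs))])
            # sklearn normalizes by n, we by n-1; directions must agree
            assert np.allclose(ours, theirs, atol=1e-8)

    def test_result_invariant_to_food_ordering(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(60, 3))
        X = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        res1 = cc.run_pca(X)
        perm = rng.permutation(60)
        Xp = X[perm]
        Xp = (Xp - Xp.mean(axis=0)) / Xp.std(axis=0, ddof=1)
        res2 = cc.run_pca(Xp)
        assert np.allclose(res1.loadings, res2.loadings, atol=1e-10)
        assert np.allclose(res1.explained_variance, res2.explained_variance)

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(9)
        raw = rng.normal(size=(50, 3))
        X = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        res = cc.run_pca(X)
        assert res.explained_variance.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance) <= 1e-12).all()

    def test_fewer_foods_than_columns_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            cc.run_pca(np.zeros((2, 3)))
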
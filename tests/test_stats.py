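"""Rank-based statistics: KW, Dunn, letters, Spearman, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from uavpheno.errors import (DataIntegrityError, DegenerateInputError,
                             InsufficientDataError, InvalidParameterError)
from uavpheno.stats import (compact_letters, dunn_bonferroni, kruskal_wallis,
                            pca_traits, shapiro_normality, significance_stars,
                            spearman_matrix, spearman_pair, trait_stats_report)


class TestShapiro:
    def test_calibrated_under_the_null(self):
        """Standard-normal samples rarely fail the screen."""
        hits = sum(shapiro_normality(np.random.default_rng(s).normal(size=500))[1]
                   > 0.01 for s in range(200))
        assert hits >= 190

    def test_detects_skewed_alternative(self):
        hits = sum(shapiro_normality(np.random.default_rng(s).exponential(size=500))[1]
                   < 0.05 for s in range(200))
        assert hits >= 190

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            shapiro_normality([2.0] * 10)
        with pytest.raises(InsufficientDataError):
            shapiro_normality([1.0, 2.0])


def _oracle_kw(groups):
    """From-scratch Kruskal-Wallis: rank by sorting, average ties by hand."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[k] = avg
        i = j + 1
    rank_sums = {}
    sizes = {}
    for (v, gi), r in zip(pooled, ranks):
        rank_sums[gi] = rank_sums.get(gi, 0.0) + r
        sizes[gi] = sizes.get(gi, 0) + 1
    h = 12.0 / (n * (n + 1)) * sum(rank_sums[g] ** 2 / sizes[g]
                                   for g in rank_sums) - 3 * (n + 1)
    # tie correction
    tie = 0.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        t = j - i + 1
        tie += t ** 3 - t
        i = j + 1
    return h / (1 - tie / (n ** 3 - n))


class TestKruskalWallis:
    def test_hand_computable_example(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(sps.chi2.sf(7.2, 2), rel=1e-12)

    def test_identical_groups(self):
        h, df, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_ties_match_independent_oracle_and_scipy(self):
        gen = np.random.default_rng(12)
        groups = [np.round(gen.normal(size=8), 1) for _ in range(4)]
        h, df, p = kruskal_wallis(groups)
        assert h == pytest.approx(_oracle_kw(groups), rel=1e-12)
        h_scipy, p_scipy = sps.kruskal(*groups)
        assert h == pytest.approx(h_scipy, rel=1e-10)
        assert p == pytest.approx(p_scipy, rel=1e-9)

    def test_invariant_under_monotone_transform(self):
        gen = np.random.default_rng(3)
        groups = [gen.normal(loc=m, size=6) for m in (0, 0.5, 1.0)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(InvalidParameterError):
            kruskal_wallis([[1, 2]])
        with pytest.raises(InvalidParameterError):
            kruskal_wallis([[1, 2], []])

    def test_chi_square_tail_conservative_at_three_reps(self):
        """With many groups of only 3 replicates (the trial's design) the
        chi-square approximation to the rank statistic is conservative: the
        null rejection rate stays below the nominal 5 % level rather than
        matching it. The test documents this known small-sample property."""
        gen = np.random.default_rng(161803)
        n_reps = 800
        rejections = sum(kruskal_wallis(list(gen.normal(size=(20, 3))))[2] < 0.05
                         for _ in range(n_reps))
        rate = rejections / n_reps
        assert 0.005 < rate < 0.05


def _oracle_dunn_z(groups, i, j):
    """Independent mean-rank z for one pair."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mr = [ranks[bounds[k]:bounds[k + 1]].mean() for k in range(len(groups))]
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    var = (n * (n + 1) / 12 - tie / (12 * (n - 1)))
    se = np.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
    return (mr[i] - mr[j]) / se


class TestDunn:
    def test_identical_groups_z_zero(self):
        table = dunn_bonferroni([[1, 2, 3], [1, 2, 3]], labels=["a", "b"])
        row = table.iloc[0]
        assert row["z"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_adj"] == 1.0

    def test_bonferroni_caps_at_one(self):
        gen = np.random.default_rng(0)
        groups = [gen.normal(size=3) for _ in range(20)]  # 190 comparisons
        table = dunn_bonferroni(groups)
        assert len(table) == 190
        assert (table["p_adj"] <= 1.0).all()
        # any pair with p_raw >= 1/190 is capped exactly at 1
        capped = table[table["p_raw"] * 190 >= 1.0]
        assert (capped["p_adj"] == 1.0).all()
        uncapped = table[table["p_raw"] * 190 < 1.0]
        assert np.allclose(uncapped["p_adj"], uncapped["p_raw"] * 190)

    def test_z_matches_independent_oracle(self):
        gen = np.random.default_rng(21)
        groups = [gen.normal(loc=m, size=7) for m in (0.0, 0.8, 1.6)]
        table = dunn_bonferroni(groups, labels=["g0", "g1", "g2"])
        for (i, j), row in zip(itertools.combinations(range(3), 2),
                               table.itertuples()):
            assert row.z == pytest.approx(_oracle_dunn_z(groups, i, j), rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            dunn_bonferroni([[1.0], []])


def _contract_holds(sig, letters):
    for (a, b), s in sig.items():
        shared = set(letters[a]) & set(letters[b])
        if s and shared:
            return False
        if not s and not shared:
            return False
    return True


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        sig = {(a, b): False for a, b in itertools.combinations("ABC", 2)}
        assert compact_letters(sig, list("ABC")) == {"A": "a", "B": "a", "C": "a"}

    def test_all_pairs_significant(self):
        sig = {(a, b): True for a, b in itertools.combinations("ABC", 2)}
        assert compact_letters(sig, list("ABC")) == {"A": "a", "B": "b", "C": "c"}

    def test_chain_pattern(self):
        sig = {("A", "B"): False, ("B", "C"): False, ("A", "C"): True}
        assert compact_letters(sig, list("ABC")) == {"A": "a", "B": "ab", "C": "b"}

    def test_asymmetric_relation_rejected(self):
        sig = {("A", "B"): True, ("B", "A"): False, ("A", "C"): False,
               ("B", "C"): False}
        with pytest.raises(DataIntegrityError):
            compact_letters(sig, list("ABC"))

    @pytest.mark.parametrize("n_groups", [3, 4, 5])
    def test_share_iff_nonsignificant_exhaustive(self, n_groups):
        """Every possible pairwise significance pattern satisfies the
        contract: a pair shares a letter iff it is not significant."""
        names = [chr(ord("A") + i) for i in range(n_groups)]
        pairs = list(itertools.combinations(names, 2))
        for bits in itertools.product([False, True], repeat=len(pairs)):
            sig = dict(zip(pairs, bits))
            letters = compact_letters(sig, names)
            assert _contract_holds(sig, letters), (sig, letters)


class TestSpearman:
    def test_perfect_reversal(self):
        rho, p, n = spearman_pair([1, 2, 3], [3, 2, 1])
        assert rho == -1.0 and n == 3

    def test_matches_no_ties_closed_form(self):
        gen = np.random.default_rng(30)
        x = gen.permutation(50).astype(float)
        y = gen.permutation(50).astype(float)
        rho, _, n = spearman_pair(x, y)
        d = sps.rankdata(x) - sps.rankdata(y)
        closed = 1 - 6 * np.sum(d ** 2) / (n * (n ** 2 - 1))
        assert rho == pytest.approx(closed, abs=1e-12)

    def test_matrix_structure_and_pairwise_complete(self):
        gen = np.random.default_rng(4)
        df = pd.DataFrame({"a": gen.normal(size=30), "b": gen.normal(size=30),
                           "c": gen.normal(size=30)})
        df.loc[:4, "b"] = np.nan
        corr = spearman_matrix(df, ["a", "b", "c"])
        assert np.allclose(np.diag(corr.rho), 1.0)
        assert np.allclose(corr.rho, corr.rho.T, equal_nan=True)
        assert corr.n.loc["a", "b"] == 25
        assert corr.n.loc["a", "c"] == 30
        ref = sps.spearmanr(df["a"][5:], df["b"][5:])
        assert corr.rho.loc["a", "b"] == pytest.approx(ref.statistic, rel=1e-10)
        assert corr.p.loc["a", "b"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_column_yields_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
        corr = spearman_matrix(df, ["a", "b"])
        assert np.isnan(corr.rho.loc["a", "b"])


class TestPCA:
    def test_two_perfectly_correlated_variables(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["y"] = 2 * df["x"] + 1
        res = pca_traits(df, ["x", "y"], abs_exr=False)
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_matches_independent_eigendecomposition(self):
        gen = np.random.default_rng(11)
        df = pd.DataFrame(gen.normal(size=(40, 6)),
                          columns=list("abcdef"))
        res = pca_traits(df, list("abcdef"), abs_exr=False)
        # oracle: SVD of the standardized data matrix
        z = (df - df.mean()) / df.std(ddof=1)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        eigvals = s ** 2 / (len(df) - 1)
        explained = 100 * eigvals / eigvals.sum()
        assert np.allclose(res.explained_pct, explained, atol=1e-9)
        load_oracle = vt.T
        for j in range(6):
            pivot = np.argmax(np.abs(load_oracle[:, j]))
            if load_oracle[pivot, j] < 0:
                load_oracle[:, j] = -load_oracle[:, j]
        assert np.allclose(res.loadings.to_numpy(), load_oracle, atol=1e-9)

    def test_loadings_orthonormal_and_variance_sums_to_100(self, default_traits):
        cols = ["sur_cm2", "eph_mm", "sd_mm", "nn", "exg", "exr"]
        res = pca_traits(default_traits, cols)
        lo = res.loadings.to_numpy()
        assert np.allclose(lo.T @ lo, np.eye(lo.shape[1]), atol=1e-9)
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(res.explained_pct) <= 1e-9).all()

    def test_explained_invariant_to_variable_permutation(self):
        gen = np.random.default_rng(13)
        df = pd.DataFrame(gen.normal(size=(30, 4)), columns=list("wxyz"))
        a = pca_traits(df, list("wxyz"), abs_exr=False).explained_pct
        b = pca_traits(df, list("zyxw"), abs_exr=False).explained_pct
        assert np.allclose(a, b, atol=1e-9)

    def test_abs_exr_equals_negation_when_all_negative(self):
        gen = np.random.default_rng(14)
        df = pd.DataFrame({"exr": -np.abs(gen.normal(size=25)) - 0.1,
                           "other": gen.normal(size=25)})
        res_abs = pca_traits(df, ["exr", "other"], abs_exr=True)
        df_neg = df.assign(exr=-df["exr"])
        res_neg = pca_traits(df_neg, ["exr", "other"], abs_exr=False)
        assert np.allclose(res_abs.explained_pct, res_neg.explained_pct, atol=1e-12)
        assert np.allclose(np.abs(res_abs.loadings.to_numpy()),
                           np.abs(res_neg.loadings.to_numpy()), atol=1e-12)

    def test_constant_variable_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5],
                           "c": [2.0, 1, 4, 3]})
        res = pca_traits(df, ["a", "b", "c"], abs_exr=False)
        assert res.variables == ("a", "c")


class TestReport:
    def test_stars(self):
        assert significance_stars(0.2) == "NS"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"

    def test_full_report_structure(self, default_traits):
        report = trait_stats_report(default_traits)
        assert {"kw_tests", "letters", "spearman_set1", "spearman_set2",
                "pca_loadings", "pca_variance"} <= set(report)
        kw = report["kw_tests"]
        # entry and replicate tests for every trait and both sets
        assert set(kw["source"]) == {"entry", "rep"}
        assert set(kw["set"]) == {1, 2}
        # letters satisfy the share-iff-nonsignificant contract against dunn
        letters = report["letters"]
        dunn = report["dunn_pairs"]
        for (set_id, trait), sub in dunn.groupby(["set", "trait"]):
            lmap = letters[(letters["set"] == set_id)
                           & (letters["trait"] == trait)]
            lmap = dict(zip(lmap["entry"], lmap["letters"]))
            sig = {(r.group_i, r.group_j): bool(r.p_adj < 0.05)
                   for r in sub.itertuples()}
            assert _contract_holds(sig, lmap)
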
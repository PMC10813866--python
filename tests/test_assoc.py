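"""z-scoring, Spearman, redundancy filter, FDR, cross-modal and KS stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radiopathomics.assoc import (_filter_from_corr, correlation_filter,
                                  cross_correlation, endpoint_correlation,
                                  ks_compare, spearman, spearman_matrix, zscore)
from radiopathomics.synthetic import SyntheticCohortSpec, generate_cohort

from oracles import (bh_qvalues_bruteforce, ks_statistic_bruteforce,
                     spearman_bruteforce)


class TestZscore:
    def test_transforms_to_zero_mean_unit_sd(self):
        out = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.isclose(out["a"].mean(), 0)
        assert np.isclose(out["a"].std(ddof=1), 1)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = zscore(df)
        assert list(out.columns) == ["a"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(2, 3, (20, 4)), columns=list("abcd"))
        once = zscore(df)
        pd.testing.assert_frame_equal(zscore(once), once)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            zscore(pd.DataFrame({"a": [1.0]}))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(-2, 2, 15)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        """x=[1..5], y=[3,1,4,1,5]: rho = 4/sqrt(95) by hand ranking."""
        x = [1, 2, 3, 4, 5]
        y = [3, 1, 4, 1, 5]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(4 / np.sqrt(95))
        assert rho == pytest.approx(spearman_bruteforce(x, y))
        assert 0 < p < 1

    def test_constant_vector_returns_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 99999))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho0 = spearman(x, y)[0]
        assert spearman(np.exp(x), y)[0] == pytest.approx(rho0)
        assert spearman(x, 3 * y + 1)[0] == pytest.approx(rho0)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(20, 2)), columns=list("uv"))
        M = spearman_matrix(X, Y)
        for a in X.columns:
            for b in Y.columns:
                assert M.loc[a, b] == pytest.approx(spearman(X[a], Y[b])[0])


class TestCorrelationFilter:
    def test_hand_derived_elimination_order(self):
        """|r(A,B)|=0.95, |r(A,C)|=0.92, |r(B,C)|=0.1: the (A,B) pair is
        examined first; A has the higher mean |r| (0.935 vs 0.525) and is
        eliminated; B and C survive."""
        corr = pd.DataFrame(
            [[1.0, 0.95, 0.92], [0.95, 1.0, 0.10], [0.92, 0.10, 1.0]],
            index=list("ABC"), columns=list("ABC"))
        assert _filter_from_corr(corr, 0.9) == ["B", "C"]

    def test_exact_duplicate_column(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        df = pd.DataFrame({"A": a, "B": a, "C": rng.normal(size=30)})
        kept = correlation_filter(df, threshold=0.9)
        assert "C" in kept
        assert len([c for c in kept if c in ("A", "B")]) == 1

    def test_nothing_removed_below_threshold(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        assert correlation_filter(df, threshold=1.0) == list("abcd")

    def test_postcondition_no_retained_pair_above_threshold(self):
        from radiopathomics.experiments import filter_postcondition_sweep

        assert filter_postcondition_sweep(n_tables=5, seed=0)["violations"] == 0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=(30, 2))
        x = latent @ rng.uniform(-1, 1, (2, 12)) + 0.1 * rng.normal(size=(30, 12))
        df = pd.DataFrame(x, columns=[f"c{j}" for j in range(12)])
        assert correlation_filter(df) == correlation_filter(df)


class TestCrossCorrelation:
    def test_identical_column_across_modalities(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=30)
        path = {"S1": pd.DataFrame({"p1": base, "p2": rng.normal(size=30)},
                                   index=[f"P{i}" for i in range(30)])}
        rad = pd.DataFrame({"r1": base}, index=[f"P{i}" for i in range(30)])
        res = cross_correlation(path, rad)
        assert res.matrices["S1"].loc["p1", "r1"] == pytest.approx(1.0)

    def test_sign_counts_are_complete(self):
        rng = np.random.default_rng(6)
        idx = [f"P{i}" for i in range(25)]
        path = {"S1": pd.DataFrame(rng.normal(size=(25, 6)), index=idx,
                                   columns=[f"p{j}" for j in range(6)])}
        rad = pd.DataFrame(rng.normal(size=(25, 9)), index=idx,
                           columns=[f"r{j}" for j in range(9)])
        res = cross_correlation(path, rad)
        row = res.sign_counts.iloc[0]
        assert row["positive"] + row["negative"] + row["zero"] == 6 * 9

    def test_null_tables_calibrated(self):
        """Independent noise: ~5% of |rho| exceed the 5% critical value."""
        rng = np.random.default_rng(7)
        n = 200
        idx = [f"P{i}" for i in range(n)]
        path = {"S1": pd.DataFrame(rng.normal(size=(n, 30)), index=idx,
                                   columns=[f"p{j}" for j in range(30)])}
        rad = pd.DataFrame(rng.normal(size=(n, 30)), index=idx,
                           columns=[f"r{j}" for j in range(30)])
        res = cross_correlation(path, rad)
        crit = 1.96 / np.sqrt(n - 1)
        frac = (res.matrices["S1"].abs() > crit).to_numpy().mean()
        assert 0.02 < frac < 0.09

    def test_too_few_shared_patients(self):
        path = {"S1": pd.DataFrame({"p": [1.0, 2.0]}, index=["A", "B"])}
        rad = pd.DataFrame({"r": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="shared"):
            cross_correlation(path, rad)


class TestEndpointCorrelation:
    def test_endpoint_equal_to_feature(self):
        rng = np.random.default_rng(8)
        idx = [f"P{i}" for i in range(20)]
        feats = pd.DataFrame(rng.normal(size=(20, 5)), index=idx,
                             columns=[f"f{j}" for j in range(5)])
        ep = feats["f2"].rename("os_months")
        res = endpoint_correlation(feats, ep)
        t = res.table.set_index("feature")
        assert t.loc["f2", "rho"] == pytest.approx(1.0)
        assert t.loc["f2", "q"] == t["q"].min()

    def test_bh_qvalues_match_step_up_formula(self):
        """BH on p=[0.01,0.02,0.03,0.5] -> q=[0.04,0.04,0.04,0.5]."""
        pvals = [0.01, 0.02, 0.03, 0.5]
        from statsmodels.stats.multitest import multipletests

        q = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        np.testing.assert_allclose(q, bh_qvalues_bruteforce(pvals))

    def test_null_cohort_has_no_discoveries(self):
        """Null synthetic cohort: essentially no q < 0.05 findings."""
        spec = SyntheticCohortSpec(n_patients=60, cd8_slope=0.0,
                                   radiomics_loading_range=(0.0, 0.0),
                                   n_radiomics_features=100, seed=13)
        cohort = generate_cohort(spec, make_images=False)
        res = endpoint_correlation(cohort.radiomics, cohort.clinical["cd8_pct"])
        assert (res.table["q"] < 0.05).mean() <= 0.02

    def test_sign_counts(self):
        idx = [f"P{i}" for i in range(10)]
        x = np.arange(10.0)
        feats = pd.DataFrame({"up": x, "down": -x}, index=idx)
        res = endpoint_correlation(feats, pd.Series(x, index=idx, name="os"))
        assert res.n_positive == 1 and res.n_negative == 1

    def test_missing_endpoint_handled_pairwise(self):
        idx = [f"P{i}" for i in range(10)]
        feats = pd.DataFrame({"f": np.arange(10.0)}, index=idx)
        ep = pd.Series(np.arange(10.0), index=idx, name="os")
        ep.iloc[:3] = np.nan
        res = endpoint_correlation(feats, ep)
        assert res.table["n"].iloc[0] == 7
        with pytest.raises(ValueError):
            endpoint_correlation(feats, pd.Series(np.nan, index=idx, name="os"))


class TestKSCompare:
    def test_identical_samples(self):
        r = ks_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        r = ks_compare([0.0, 0.1, 0.2], [5.0, 5.1, 5.2])
        assert r.statistic == 1.0

    def test_shifted_triplets_match_ecdf_sweep(self):
        a = [0.1, 0.2, 0.3]
        b = [0.2, 0.3, 0.4]
        r = ks_compare(a, b)
        assert r.statistic == pytest.approx(1 / 3)
        assert r.statistic == pytest.approx(ks_statistic_bruteforce(a, b))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 99999))
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=15)
        b = rng.normal(0.5, 1.2, size=20)
        r_ab = ks_compare(a, b)
        r_ba = ks_compare(b, a)
        assert r_ab.statistic == pytest.approx(r_ba.statistic)
        assert r_ab.pvalue == pytest.approx(r_ba.pvalue)
        r_t = ks_compare(np.exp(a), np.exp(b))  # common monotone transform
        assert r_t.statistic == pytest.approx(r_ab.statistic)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([0.1], [0.2, 0.3])
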
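import itertools

import numpy as np
import pandas as pd
import pytest

from panomicnet.association import (
    cluster_heatmap_order,
    cumulative_incidence_curve,
    kendall_screen,
    quartile_logistic,
    snp_association,
)


def _tau_b_oracle(x, y):
    """Brute-force tie-corrected Kendall tau over all pairs."""
    conc = disc = tx = ty = 0
    for (i, j) in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = len(x) * (len(x) - 1) / 2
    return (conc - disc) / np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


class TestKendallScreen:
    def test_perfect_agreement(self):
        x = np.arange(10, dtype=float)
        taus, ps, kept = kendall_screen(
            pd.DataFrame({"b": x}), pd.DataFrame({"o": x})
        )
        assert taus.loc["b", "o"] == pytest.approx(1.0)
        assert ps.loc["b", "o"] < 0.05
        assert kept == ["b"]

    def test_perfect_reversal(self):
        x = np.arange(10, dtype=float)
        taus, _, _ = kendall_screen(pd.DataFrame({"b": x}), pd.DataFrame({"o": -x}))
        assert taus.loc["b", "o"] == pytest.approx(-1.0)

    def test_tau_b_matches_all_pairs_oracle_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])
        taus, _, _ = kendall_screen(pd.DataFrame({"b": x}), pd.DataFrame({"o": y}))
        assert taus.loc["b", "o"] == pytest.approx(_tau_b_oracle(x, y), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        t1, _, _ = kendall_screen(pd.DataFrame({"a": x}), pd.DataFrame({"b": y}))
        t2, _, _ = kendall_screen(pd.DataFrame({"b": y}), pd.DataFrame({"a": x}))
        assert t1.loc["a", "b"] == pytest.approx(t2.loc["b", "a"], abs=1e-15)

    def test_constant_column_flagged_excluded(self):
        x = np.arange(12, dtype=float)
        taus, ps, kept = kendall_screen(
            pd.DataFrame({"flat": np.ones(12), "b": x}), pd.DataFrame({"o": x})
        )
        assert np.isnan(taus.loc["flat", "o"])
        assert kept == ["b"]


class TestClusterHeatmapOrder:
    def test_identical_rows_merge_first(self):
        tau = pd.DataFrame(
            [[1.0, 0.2, 0.9], [1.0, 0.2, 0.9], [0.1, 0.8, 0.0]],
            index=["r1", "r2", "r3"],
            columns=["c1", "c2", "c3"],
        )
        row_order, _, row_link, _ = cluster_heatmap_order(tau)
        # first merge joins the two identical rows at distance 0
        assert set(row_link[0, :2].astype(int)) == {0, 1}
        assert row_link[0, 2] == pytest.approx(0.0)
        assert row_order.index("r1") + 1 == row_order.index("r2") or (
            row_order.index("r2") + 1 == row_order.index("r1")
        )

    def test_three_row_average_linkage_merge_order(self):
        # profiles chosen so rows 0 and 1 correlate perfectly and row 2
        # anti-correlates: average linkage must join {0,1} first, then add 2
        tau = pd.DataFrame(
            [[0.9, 0.1, 0.5], [0.8, 0.0, 0.4], [0.1, 0.9, 0.5]],
            index=list("abc"),
            columns=list("xyz"),
        )
        _, _, link, _ = cluster_heatmap_order(tau)
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[1, 2] >= link[0, 2]

    def test_row_permutation_consistency(self):
        rng = np.random.default_rng(1)
        tau = pd.DataFrame(rng.uniform(-1, 1, size=(5, 4)), index=list("abcde"))
        order1, _, _, _ = cluster_heatmap_order(tau)
        perm = ["c", "a", "e", "b", "d"]
        order2, _, _, _ = cluster_heatmap_order(tau.loc[perm])
        assert set(order1) == set(order2)

    def test_non_finite_rejected(self):
        tau = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            cluster_heatmap_order(tau)


def _balanced_bins_data():
    """200 patients in 4 exact bins of 50; case counts 10/40, 15/35, 20/30, 40/10."""
    x = np.arange(1, 201, dtype=float)
    cases = np.zeros(200)
    for b, n_cases in enumerate([10, 15, 20, 40]):
        cases[b * 50 : b * 50 + n_cases] = 1
    return x, cases


class TestQuartileLogistic:
    def test_null_biomarker_ors_cover_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=4000)
        y = rng.binomial(1, 0.5, 4000).astype(float)
        tab = quartile_logistic(x, y)
        for b in ("Q2", "Q3", "Q4"):
            assert tab.loc[b, "ci_lower"] < 1.0 < tab.loc[b, "ci_upper"]

    def test_closed_form_2x2_odds_ratio(self):
        x, cases = _balanced_bins_data()
        tab = quartile_logistic(x, cases)
        assert tab.loc["Q4", "OR"] == pytest.approx((40 / 10) / (10 / 40), abs=1e-6)
        assert list(tab.loc[["Q1", "Q2", "Q3", "Q4"], "n"]) == [50, 50, 50, 50]
        assert "trend" in tab.index and tab.loc["trend", "p"] < 0.05

    def test_two_bins_agree_with_2x2(self):
        x, cases = _balanced_bins_data()
        tab = quartile_logistic(x, cases, n_bins=2)
        # low bin: 25 cases / 100; high bin: 60 cases / 100
        expected = (60 / 40) / (25 / 75)
        assert tab.loc["Q2", "OR"] == pytest.approx(expected, abs=1e-6)

    def test_covariate_adjustment_accepts_columns(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.normal(size=n)
        age = rng.normal(50, 10, n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.8 * x)))).astype(float)
        cov = pd.DataFrame({"age": age, "sex": rng.integers(0, 2, n)})
        tab = quartile_logistic(x, y, covariates=cov)
        assert tab.loc["Q4", "OR"] > 1.0

    def test_simulated_q4_gap_coverage(self):
        # true Q4-vs-Q1 log-odds gap 1.04 built directly on bin membership
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(4000 + s)
            x = rng.normal(size=2000)
            bins = np.searchsorted(np.quantile(x, [0.25, 0.5, 0.75]), x, side="left")
            lp = -0.5 + (1.04 / 3.0) * bins
            y = rng.binomial(1, 1 / (1 + np.exp(-lp))).astype(float)
            tab = quartile_logistic(x, y)
            if tab.loc["Q4", "ci_lower"] <= np.exp(1.04) <= tab.loc["Q4", "ci_upper"]:
                hits += 1
        assert hits >= 45

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            quartile_logistic(np.arange(64, dtype=float), np.arange(64, dtype=float))


class TestSnpAssociation:
    def test_outcome_equals_genotype(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, 200).astype(float)
        res = snp_association(g, g + 0.0)
        assert res.estimate == pytest.approx(1.0, abs=1e-8)
        assert res.p < 1e-10
        assert res.ci_lower <= res.estimate <= res.ci_upper

    def test_permuted_genotype_is_null(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.3, 500).astype(float)
        y = 0.5 * g + rng.normal(size=500)
        g_perm = rng.permutation(g)
        res = snp_association(g_perm, y)
        assert abs(res.estimate) < 3 * res.se

    def test_binary_outcome_reports_or_and_lnse(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, 800).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.4 * g)))).astype(float)
        res = snp_association(g, y)
        assert res.kind == "OR" and res.estimate > 0
        assert res.ci_lower == pytest.approx(
            res.estimate * np.exp(-1.959963984540054 * res.se), rel=1e-9
        )

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            snp_association(np.zeros(100), np.random.default_rng(8).normal(size=100))


class TestCumulativeIncidence:
    def test_all_cases_constant_one(self):
        out = cumulative_incidence_curve([1.0, 2.0, 3.0], [1, 1, 1])
        assert (out["cumulative_incidence"] == 1.0).all()

    def test_worked_six_patient_example(self):
        out = cumulative_incidence_curve(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [0, 0, 0, 1, 1, 1]
        )
        assert np.allclose(out["cumulative_incidence"], [0, 0, 0, 0.25, 0.4, 0.5])

    def test_final_point_equals_prevalence(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = rng.binomial(1, 0.3, 200)
        out = cumulative_incidence_curve(x, y)
        assert out["cumulative_incidence"].iloc[-1] == pytest.approx(y.mean())

    def test_subset_filter_excludes_patients(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1, 0, 1, 0])
        keep = np.array([True, True, False, False])
        out = cumulative_incidence_curve(x, y, subset_filter=keep)
        assert out.shape[0] == 2
        assert out["cumulative_incidence"].iloc[-1] == pytest.approx(0.5)
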
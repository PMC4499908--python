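"""Random gene groups, monotone quantile curves, chi-square reference
selection and FDR adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import genepart as gp
from genepart.data import DataError
from genepart.mapping import MarkerGeneIndex
from genepart.nulldist import _best_candidate, fit_threshold_curve

from _oracles import bh_reference


def toy_index(sizes, n_markers=None):
    """Index whose genes carry disjoint consecutive marker runs of the
    given sizes."""
    gene_markers, marker_genes, start = {}, [], 0
    for k, size in enumerate(sizes):
        gid = f"g{k}"
        gene_markers[gid] = np.arange(start, start + size)
        marker_genes += [(gid,)] * size
        start += size
    total = n_markers or start
    marker_genes += [()] * (total - start)
    return MarkerGeneIndex(gene_markers, marker_genes, flank=0, n_markers=total)


class _ScriptedRNG:
    """Stands in for a Generator: fixed target and gene order."""

    def __init__(self, target, order):
        self._target, self._order = target, order

    def integers(self, low, high):
        return self._target

    def permutation(self, n):
        return np.asarray(self._order)


class TestRandomGeneGroup:
    def test_stops_at_first_gene_reaching_target(self):
        idx = toy_index([30, 40, 25], n_markers=200)
        fs = gp.sample_random_gene_group(_ScriptedRNG(50, [0, 1, 2]), idx, max_target=100)
        assert fs.genes == ("g0", "g1")
        assert fs.m_S == 70
        assert not fs.exhausted

    def test_stopping_is_minimal(self):
        idx = toy_index([30, 40, 25], n_markers=200)
        fs = gp.sample_random_gene_group(_ScriptedRNG(90, [2, 0, 1]), idx, max_target=100)
        without_last = fs.m_S - idx.gene_markers[fs.genes[-1]].size
        assert without_last < fs.target <= fs.m_S

    def test_exhaustion_returns_full_union(self):
        idx = toy_index([10, 10], n_markers=100)
        fs = gp.sample_random_gene_group(_ScriptedRNG(99, [0, 1]), idx, max_target=100)
        assert fs.exhausted and fs.m_S == 20

    def test_target_distribution_uniform(self, small_dataset):
        idx = small_dataset["index"]
        rng = np.random.default_rng(123)
        targets = np.array(
            [gp.sample_random_gene_group(rng, idx, max_target=300).target for _ in range(10_000)]
        )
        # targets are uniform integers on {1..300}
        p = stats.kstest(targets, stats.randint(1, 301).cdf).pvalue
        assert p > 0.01

    def test_focal_flag_set_from_sampled_genes(self, small_dataset):
        idx = small_dataset["index"]
        focal = gp.focal_region_genes(small_dataset["focal"], small_dataset["genes"])
        rng = np.random.default_rng(5)
        flags, hits = [], []
        for _ in range(50):
            fs = gp.sample_random_gene_group(rng, idx, 200, focal_genes=focal)
            flags.append(fs.contains_focal)
            hits.append(bool(set(fs.genes) & focal))
        assert flags == hits


@pytest.fixture(scope="module")
def small_null(small_dataset):
    d = small_dataset
    y = d["pheno"].trait_frame("sim_trait")["value"].to_numpy()
    w = gp.center_scale(d["geno"])
    df, simple = gp.build_null_distribution(y, w, d["index"], 40, seed=99)
    return d, y, w, df, simple


class TestNullDistribution:
    def test_reproducible_bit_for_bit(self, small_null):
        d, y, w, df, _ = small_null
        df2, _ = gp.build_null_distribution(y, w, d["index"], 40, seed=99)
        pd.testing.assert_frame_equal(df, df2)

    def test_few_exclusions_under_null(self, small_null):
        _, _, _, df, _ = small_null
        assert df["excluded"].mean() <= 0.02

    def test_rows_complete(self, small_null):
        _, _, _, df, _ = small_null
        ok = df.loc[~df["excluded"]]
        assert np.isfinite(ok[["h2_set", "lr", "raw_lr"]].to_numpy()).all()
        assert (ok["m_S"] >= 1).all()


class TestThresholdCurve:
    @staticmethod
    def _null_frame(x, y, focal=None):
        return pd.DataFrame(
            {
                "m_S": x,
                "lr": y,
                "h2_set": y,
                "contains_focal": focal if focal is not None else np.zeros(len(x), bool),
                "excluded": np.zeros(len(x), bool),
            }
        )

    def test_median_curve_reproduces_exact_line(self):
        x = np.linspace(10, 500, 200)
        y = 0.5 + 0.01 * x
        curve = fit_threshold_curve(self._null_frame(x, y), "lr", tau=0.5, lam=1e-6)
        assert np.max(np.abs(curve(x) - y)) < 1e-6

    def test_in_sample_coverage_near_tau(self):
        rng = np.random.default_rng(8)
        x = rng.integers(1, 1000, size=800).astype(float)
        y = 0.2 + 0.002 * x + rng.gamma(2.0, 0.5 + 0.001 * x)
        curve = fit_threshold_curve(self._null_frame(x, y), "lr", tau=0.95)
        cov = float(np.mean(y <= curve(x)))
        assert 0.93 <= cov <= 0.97

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(9)
        x = rng.integers(1, 500, size=300).astype(float)
        y = rng.exponential(1.0 + 0.01 * x)
        curve = fit_threshold_curve(self._null_frame(x, y), "lr", tau=0.95)
        grid = np.linspace(x.min(), x.max(), 200)
        assert np.all(np.diff(curve(grid)) >= -1e-9)

    def test_degenerate_constant_statistic(self):
        x = np.arange(1, 101, dtype=float)
        curve = fit_threshold_curve(self._null_frame(x, np.full(100, 3.3)), "lr", tau=0.95)
        assert curve(50) == pytest.approx(3.3)

    def test_clamped_outside_fitted_range(self):
        x = np.linspace(100, 200, 100)
        curve = fit_threshold_curve(self._null_frame(x, 0.01 * x), "lr", tau=0.5, lam=1e-6)
        assert curve(10) == pytest.approx(curve(100))
        assert curve(1e6) == pytest.approx(curve(200))

    def test_focal_stratification_selects_rows(self):
        rng = np.random.default_rng(10)
        x = rng.integers(1, 500, size=400).astype(float)
        focal = np.arange(400) % 2 == 0
        y = np.where(focal, 10.0, 1.0)
        df = self._null_frame(x, y, focal)
        hi = fit_threshold_curve(df, "lr", tau=0.5, stratum="focal")
        lo = fit_threshold_curve(df, "lr", tau=0.5, stratum="non_focal")
        assert hi(250) == pytest.approx(10.0, abs=1e-6)
        assert lo(250) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_samples_rejected(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(DataError, match="need >="):
            fit_threshold_curve(self._null_frame(x, x), "lr", tau=0.95)


class TestEvaluateCriteria:
    def _curves(self):
        x = np.linspace(1, 100, 60)
        df = TestThresholdCurve._null_frame(x, np.full(60, 2.0))
        lr_c = fit_threshold_curve(df, "lr", tau=0.95)
        h2_c = fit_threshold_curve(df, "h2_set", tau=0.95)
        return lr_c, h2_c

    def test_boundary_is_inclusive(self):
        lr_c, h2_c = self._curves()
        assert gp.evaluate_criteria(2.0, 2.0, 50, lr_c, h2_c) == (True, True)

    def test_partial_pass(self):
        lr_c, h2_c = self._curves()
        assert gp.evaluate_criteria(1.9, 2.5, 50, lr_c, h2_c) == (False, True)

    def test_failed_fit_gives_na(self):
        lr_c, h2_c = self._curves()
        out = gp.evaluate_criteria(5.0, 5.0, 50, lr_c, h2_c, qc_flags={"negative_lr"})
        assert out == (None, None)


class TestChi2Selection:
    def test_recovers_df1_and_df2(self):
        rng = np.random.default_rng(0)
        assert gp.select_chi2_df(rng.chisquare(1, 1000)).selected == "chi2_df1"
        assert gp.select_chi2_df(rng.chisquare(2, 1000)).selected == "chi2_df2"

    def test_recovers_mixture(self):
        rng = np.random.default_rng(1)
        draws = np.where(rng.random(4000) < 0.5, rng.chisquare(1, 4000), rng.chisquare(2, 4000))
        assert gp.select_chi2_df(draws).selected == "mixture"

    def test_tie_breaks_toward_lowest_df(self):
        assert _best_candidate({"chi2_df1": 0.1, "chi2_df2": 0.1, "mixture": 0.1}) == "chi2_df1"
        assert _best_candidate({"chi2_df1": 0.2, "chi2_df2": 0.1, "mixture": 0.1 + 1e-13}) == "chi2_df2"

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            gp.select_chi2_df(np.zeros(500))

    def test_sf_maps_zero_lr_to_one(self):
        sel = gp.select_chi2_df(np.random.default_rng(3).chisquare(1, 500))
        assert sel.sf(0.0) == 1.0


class TestPathwayPvalues:
    def _sel(self):
        return gp.DfSelection(ks={"chi2_df1": 0.0, "chi2_df2": 1.0, "mixture": 1.0}, selected="chi2_df1")

    def test_bh_worked_example(self):
        sel = self._sel()
        lrs = stats.chi2.isf([0.01, 0.02, 0.03, 0.04], 1)
        out = gp.pathway_pvalues(pd.Series(lrs, index=list("abcd")), sel)
        np.testing.assert_allclose(out["q_value"], [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_test_q_equals_p(self):
        out = gp.pathway_pvalues(pd.Series([3.0], index=["a"]), self._sel())
        assert out["q_value"].iloc[0] == pytest.approx(out["p_value"].iloc[0])

    def test_q_monotone_in_sorted_p_and_capped(self):
        rng = np.random.default_rng(2)
        lrs = rng.chisquare(1, 40)
        out = gp.pathway_pvalues(pd.Series(lrs, index=[f"p{i}" for i in range(40)]), self._sel())
        df = out.sort_values("p_value")
        assert (np.diff(df["q_value"]) >= -1e-12).all()
        assert (df["q_value"] <= 1.0).all()
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()

    @given(st.integers(0, 2**31 - 1), st.integers(1, 60))
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_reference_implementation(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        sel = self._sel()
        lrs = stats.chi2.isf(p, 1)
        out = gp.pathway_pvalues(pd.Series(lrs, index=[f"x{i}" for i in range(m)]), sel)
        np.testing.assert_allclose(out["q_value"], bh_reference(out["p_value"].to_numpy()), atol=1e-10)
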
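"""Rank-sum and Spearman statistics, sweep layout, significance report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracle
from plinet.stats import (
    rank_sum_test,
    results_frame,
    run_comparisons,
    significance_report,
    spearman_corr,
)
from plinet.types import CohortTable, MEASURE_NAMES


class TestRankSum:
    def test_separated_groups_exact_p(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_groups_p_near_one(self):
        r = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert r.p > 0.9

    def test_missing_values_dropped(self):
        r = rank_sum_test([1.0, np.nan, 2, 3], [4, 5, np.nan, 6])
        assert r.n_used == 6
        assert r.p == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([np.nan], [1, 2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_exact_p_equals_enumeration(self, data):
        # tie-free random integer samples with n_a + n_b <= 10
        na = data.draw(st.integers(2, 5))
        nb = data.draw(st.integers(2, 10 - na))
        pool = data.draw(st.lists(st.integers(0, 10 ** 6), min_size=na + nb,
                                  max_size=na + nb, unique=True))
        a, b = pool[:na], pool[na:]
        r = rank_sum_test(a, b)
        assert r.p == pytest.approx(oracle.exact_ranksum_p(a, b))

    def test_null_type_I_error_calibrated(self):
        # group sizes of the study design (15 vs 7)
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.standard_normal(15)
            b = rng.standard_normal(7)
            hits += rank_sum_test(a, b).significant
        assert 0.03 <= hits / n_rep <= 0.07


class TestSpearman:
    def test_monotone_increase_is_one(self):
        r = spearman_corr([1, 2, 3, 4], [10, 20, 25, 90])
        assert r.rho == pytest.approx(1.0)

    def test_monotone_decrease_is_minus_one(self):
        r = spearman_corr([1, 2, 3, 4], [5, 4, 3, -10])
        assert r.rho == pytest.approx(-1.0)

    def test_tied_ranks_hand_example(self):
        # ranks {1,2,3} vs {1.5,1.5,3} -> rho = sqrt(3)/2
        r = spearman_corr([1, 2, 3], [1, 1, 2])
        assert r.rho == pytest.approx(np.sqrt(3) / 2)

    def test_pairwise_deletion(self):
        r = spearman_corr([1, 2, np.nan, 4, 5], [2, np.nan, 3, 8, 10])
        assert r.n_used == 3
        assert r.rho == pytest.approx(1.0)

    def test_constant_input_flagged_undefined(self):
        r = spearman_corr([1, 1, 1], [2, 5, 3])
        assert np.isnan(r.rho) and not r.significant

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman_corr([1, 2], [3, 4])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-100, 100), min_size=5, max_size=12,
                    unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        rng = np.random.default_rng(7)
        ys = rng.normal(size=len(xs))
        base = spearman_corr(xs, ys).rho
        transformed = spearman_corr(np.exp(np.asarray(xs) / 100), ys).rho
        assert transformed == pytest.approx(base)

    def test_power_at_planted_rho(self):
        # planted rho = 0.8 at the study's n = 22 is detected essentially always
        rng = np.random.default_rng(11)
        r_pearson = 2 * np.sin(np.pi * 0.8 / 6)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.standard_normal(22)
            y = r_pearson * x + np.sqrt(1 - r_pearson ** 2) * \
                rng.standard_normal(22)
            hits += spearman_corr(x, y).significant
        assert hits / n_rep >= 0.95


def _long_measures(rng, ids, bands=("theta", "alpha1", "alpha2")):
    rows = []
    for sid in ids:
        for band in bands:
            for name in MEASURE_NAMES:
                rows.append({"id": sid, "band": band, "measure": name,
                             "value": rng.uniform(0, 1)})
    return pd.DataFrame(rows)


def _cohort(rng, n_a=15, n_b=7):
    rows = []
    for k in range(n_a + n_b):
        rows.append({
            "id": f"S{k:03d}",
            "group": "agPPA" if k < n_a else "PPAOS",
            "age": rng.uniform(55, 85),
            "disease_duration": rng.uniform(1, 8),
            "MoCA": rng.uniform(10, 30),
            "MDS_UPDRS_III": rng.uniform(0, 40),
            "ASRS3": rng.uniform(5, 45),
            "WAB_AQ": rng.uniform(60, 100),
        })
    return CohortTable(pd.DataFrame(rows))


class TestRunComparisons:
    def test_grid_size_counts(self, rng):
        ct = _cohort(rng)
        long = _long_measures(rng, ct.ids)
        results = run_comparisons(long, ct)
        corr = [r for r in results if r.kind == "spearman"]
        group = [r for r in results if r.kind == "rank_sum"]
        assert len(corr) == 9 * 3 * 6 == 162
        assert len(group) == 9

    def test_all_missing_covariate_skipped_not_fatal(self, rng):
        ct = _cohort(rng)
        ct.df["WAB_AQ"] = np.nan
        long = _long_measures(rng, ct.ids)
        results = run_comparisons(long, ct)
        assert not any(r.covariate == "WAB_AQ" for r in results)
        assert len([r for r in results if r.kind == "spearman"]) == 135

    def test_unknown_covariate_rejected(self, rng):
        ct = _cohort(rng)
        with pytest.raises(KeyError, match="bogus"):
            run_comparisons(_long_measures(rng, ct.ids), ct,
                            covariates=["bogus"])

    def test_band_collapse_mean_uses_one_value_per_subject(self, rng):
        ct = _cohort(rng)
        long = _long_measures(rng, ct.ids)
        results = run_comparisons(long, ct)
        group = [r for r in results if r.kind == "rank_sum"]
        assert all(r.n_used == len(ct) for r in group)


class TestSignificanceReport:
    def _results(self, rng, ps):
        ct = _cohort(rng, 3, 3)
        out = []
        for k, p in enumerate(ps):
            r = spearman_corr([1, 2, 3, 4], [2, 1, 4, 3],
                              measure=MEASURE_NAMES[k], band="theta",
                              covariate="age")
            r.p = p
            out.append(r)
        return out

    def test_just_below_alpha_marked(self, rng, tmp_path):
        grid = significance_report(self._results(rng, [0.049]),
                                   tmp_path / "r.tsv")
        assert grid.iloc[0, 0].endswith("*")

    def test_exact_alpha_not_marked(self, rng):
        grid = significance_report(self._results(rng, [0.05]))
        assert not grid.iloc[0, 0].endswith("*")

    def test_empty_results_give_empty_grid(self, tmp_path):
        grid = significance_report([], tmp_path / "r.tsv")
        assert grid.empty
        assert (tmp_path / "r.tsv").exists()

    def test_results_frame_columns(self, rng):
        df = results_frame(self._results(rng, [0.01, 0.2]))
        assert list(df.columns) == ["kind", "measure", "band", "covariate",
                                    "n_used", "statistic", "rho", "p",
                                    "significant"]
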
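"""Bridged SILAC ratios, median centering, and volcano filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mtornet.phospho import (
    DesignSpec,
    VolcanoAnalysis,
    compute_ratios,
    localization_filter,
    median_center,
    volcano_filter,
    volcano_records,
)
from mtornet.synthetic import generate_phospho_table


class TestDesign:
    def test_published_design_ratio_counts(self, silac_design):
        assert silac_design.n_ratio_combinations(5) == 9
        assert silac_design.n_ratio_combinations(10) == 6
        assert silac_design.n_ratio_combinations(15) == 6

    def test_bridge_required_everywhere(self):
        with pytest.raises(ValueError, match="bridge"):
            DesignSpec(experiments={"E1": {"L": 0, "M": 5, "H": 10}})

    @settings(max_examples=30, deadline=None)
    @given(
        n_with_t=st.integers(min_value=0, max_value=4),
        n_with_0=st.integers(min_value=0, max_value=4),
    )
    def test_combination_count_formula(self, n_with_t, n_with_0):
        # brute-force oracle over arbitrary designs: #exps with t x #exps with 0
        exps = {}
        for i in range(n_with_t):
            exps[f"T{i}"] = {"L": 5, "M": 99, "H": 30}
        for i in range(n_with_0):
            exps[f"Z{i}"] = {"L": 0, "M": 98, "H": 30}
        exps["pad"] = {"L": 97, "M": 96, "H": 30}
        design = DesignSpec(experiments=exps)
        table = pd.DataFrame({
            design.intensity_column(e, t): [2.0]
            for e in exps for t in exps[e].values()
        })
        ratios = compute_ratios(table, design, 5)
        assert ratios.shape[1] == n_with_t * n_with_0


class TestComputeRatios:
    def test_bridge_cancels_within_one_experiment(self):
        design = DesignSpec(experiments={"E1": {"L": 0, "M": 5, "H": 30}})
        table = pd.DataFrame({
            "Intensity L E1": [4.0], "Intensity M E1": [12.0],
            "Intensity H E1": [7.0],
        })
        ratios = compute_ratios(table, design, 5)
        assert ratios.shape == (1, 1)
        assert ratios.iloc[0, 0] == pytest.approx(np.log2(12.0 / 4.0))

    def test_missing_terms_drop_single_combinations(self, silac_design):
        table = generate_phospho_table(n_sites=20, n_regulated=0, seed=2,
                                       missing_rate=0.0)
        table.loc[0, "Intensity L Exp1"] = 0.0  # 0 min of Exp1 missing
        ratios = compute_ratios(table, silac_design, 5)
        row = ratios.iloc[0]
        dropped = [c for c in ratios.columns if c.endswith("/Exp1")]
        assert row[dropped].isna().all()
        assert row.drop(dropped).notna().all()

    def test_invalid_time_point(self, phospho_table, silac_design):
        with pytest.raises(ValueError):
            compute_ratios(phospho_table, silac_design, 30)


class TestMedianCenter:
    def test_shifts_by_column_median(self):
        cols = pd.DataFrame({"a": [0.1, 0.3, 0.5], "b": [1.0, 2.0, 6.0]})
        centered = median_center(cols)
        assert np.allclose(centered["a"], [-0.2, 0.0, 0.2])
        assert centered["b"].median() == 0.0

    def test_post_condition_zero_median(self, phospho_table, silac_design):
        ratios = compute_ratios(localization_filter(phospho_table),
                                silac_design, 5)
        centered = median_center(ratios)
        assert np.allclose(centered.median(skipna=True), 0.0, atol=1e-12)

    def test_empty_column_warns(self):
        cols = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="empty"):
            median_center(cols)


class TestLocalizationFilter:
    @pytest.mark.parametrize("prob,kept", [(0.75, False), (0.76, True),
                                           (0.5, False), (1.0, True)])
    def test_strict_cutoff(self, prob, kept):
        table = pd.DataFrame({"Localization prob": [prob], "x": [1]})
        assert (len(localization_filter(table)) == 1) is kept

    def test_empty_table(self):
        table = pd.DataFrame({"Localization prob": []})
        assert len(localization_filter(table)) == 0


def _records(site, time, values):
    values = np.asarray(values, float)
    n = len(values)
    mean = values.mean()
    if n >= 2 and values.std(ddof=1) > 0:
        t = mean / (values.std(ddof=1) / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), df=n - 1)
    else:
        p = np.nan
    return {"site": site, "time": time, "n_ratios": n, "mean_log2fc": mean,
            "fold_change": 2.0 ** mean, "p_value": p}


class TestVolcanoFilter:
    def test_strong_consistent_site_regulated_at_twofold(self):
        # hand-rolled t-test oracle: log2 ratios (1.0, 1.0, 1.1)
        vals = np.array([1.0, 1.0, 1.1])
        rec = pd.DataFrame([_records("s1", 5, vals)])
        assert rec["fold_change"].iloc[0] >= 2.0
        t_oracle = vals.mean() / (vals.std(ddof=1) / np.sqrt(3))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=2)
        assert p_oracle < 0.05
        assert volcano_filter(rec, 2.0, 0.05) == {"s1"}

    def test_fold_change_without_significance_not_regulated(self):
        # mean ~1.54-fold but too variable for the t-test at alpha 0.05
        vals = np.array([1.8, -0.4, 0.45])
        rec = pd.DataFrame([_records("cJun_S73", 15, vals)])
        assert 2.0 ** vals.mean() == pytest.approx(1.54, abs=0.02)
        assert volcano_filter(rec, 1.5, 0.05) == set()

    def test_single_ratio_excluded(self):
        rec = pd.DataFrame([_records("solo", 5, [3.0])])
        assert volcano_filter(rec, 1.5, 0.05) == set()

    def test_cutoff_validation(self):
        rec = pd.DataFrame([_records("s", 5, [1.0, 1.0, 1.0])])
        with pytest.raises(ValueError):
            volcano_filter(rec, 0.9, 0.05)
        with pytest.raises(ValueError):
            volcano_filter(rec, 2.0, 1.5)


class TestPipeline:
    def test_nested_cutoffs(self, phospho_table, silac_design):
        res = VolcanoAnalysis(phospho_table, silac_design).fit()
        assert res.regulated_2_0 <= res.regulated_1_5

    def test_deterministic(self, phospho_table, silac_design):
        a = VolcanoAnalysis(phospho_table, silac_design).fit()
        b = VolcanoAnalysis(phospho_table, silac_design).fit()
        assert a.regulated_1_5 == b.regulated_1_5
        assert a.records.equals(b.records)

    def test_planted_effects_recovered(self, silac_design):
        table = generate_phospho_table(
            n_sites=200, n_regulated=12, effect_log2fc=1.5, seed=9,
            noise_cv=0.03, missing_rate=0.0, contaminant_fraction=0.0,
        )
        res = VolcanoAnalysis(table, silac_design).fit()
        planted = set(table.index[table["Regulated truth"] == 1])
        # 2^1.5 ~ 2.8-fold planted effects must clear the twofold filter
        assert planted <= res.regulated_2_0

    def test_type_one_error_controlled_on_null_table(self, silac_design):
        null = generate_phospho_table(n_sites=500, n_regulated=0, seed=5)
        res = VolcanoAnalysis(null, silac_design).fit()
        n = res.n_sites_tested
        rate = len(res.regulated_1_5) / n
        # binomial Monte-Carlo slack around alpha
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
        assert len(res.regulated_2_0) / n <= 0.05

    def test_contaminants_never_tested(self, phospho_table, silac_design):
        res = VolcanoAnalysis(phospho_table, silac_design,
                              site_column=None).fit()
        contaminated = set(
            phospho_table.index[phospho_table["Localization prob"] <= 0.75]
        )
        assert not (res.regulated_1_5 & contaminated)
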
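"""Stagewise AIC selection: accept rule, enumeration combinatorics, workflow."""

from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtornet.estimate import FitConfig
from mtornet.network import candidate_sites
from mtornet.select import (
    SelectionConfig,
    accept_rule,
    enumerate_candidates,
    published_enumeration_counts,
    run_selection,
)
from mtornet.synthetic import TRUTH_PARAMS, SynthConfig, generate_timecourses


class TestAcceptRule:
    @pytest.mark.parametrize("aic_new,prev_best,expected", [
        (953.0, 1415.0, True),    # threshold 0.99 * 1415 = 1400.85
        (1402.0, 1415.0, False),  # above the 1% boundary
        (943.0, 953.0, True),     # threshold 943.47
        (944.0, 953.0, False),
        (790.0, 798.0, True),     # threshold 790.02
        (791.0, 798.0, False),
    ])
    def test_published_boundaries(self, aic_new, prev_best, expected):
        assert accept_rule(aic_new, prev_best, 0.01) is expected

    def test_threshold_is_exactly_one_minus_fraction(self):
        assert accept_rule(99.0, 100.0, 0.01)
        assert not accept_rule(99.0 + 1e-9, 100.0, 0.01)


class TestEnumeration:
    def test_stage2_one_model_per_site(self, base_simple):
        sites = [c.id for c in candidate_sites(base_simple)]
        cands = enumerate_candidates(2, [], sites)
        assert len(cands) == 12
        assert all(len(c) == 1 for c in cands)

    def test_stage3_pairs_of_surviving_components(self, base_simple):
        sites = [c.id for c in candidate_sites(base_simple)]
        survivors = [frozenset({s}) for s in sites[:9]]
        cands = enumerate_candidates(3, survivors, sites)
        assert len(cands) == 36  # C(9, 2)
        assert all(len(c) == 2 for c in cands)

    def test_stage4_unions_of_accepted_triples(self):
        triples = [frozenset({"IRS_p", x}) for x in
                   ["A", "B", "C", "D", "E", "F", "G"]]
        cands = enumerate_candidates(4, triples, [])
        # brute-force oracle: deduplicated three-component pairwise unions
        oracle = {a | b for a, b in combinations(triples, 2) if len(a | b) == 3}
        assert len(cands) == 21
        assert set(cands) == oracle

    def test_empty_survivors_halt_selection(self):
        assert enumerate_candidates(3, [], ["x"]) == []
        assert enumerate_candidates(4, [], ["x"]) == []

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=2, max_value=12))
    def test_stage3_count_identity(self, n_survivors):
        sites = [f"s{i}" for i in range(12)]
        survivors = [frozenset({s}) for s in sites[:n_survivors]]
        cands = enumerate_candidates(3, survivors, sites)
        oracle = len(list(combinations(range(n_survivors), 2)))
        assert len(cands) == oracle

    def test_published_survivor_pattern_gives_seventy(self):
        counts = published_enumeration_counts()
        assert counts == {"single": 1, "double": 12, "triple": 36,
                          "quadruple": 21, "total": 70}


def _fast_selection_config(candidates, improvement=0.01, seed=0):
    frozen = tuple(
        (p, v) for p, v in TRUTH_PARAMS.items() if not p.startswith("k_aa_")
    )
    return SelectionConfig(
        improvement_fraction=improvement,
        fit_config=FitConfig(n_starts=2, seed=seed, frozen=frozen),
        candidate_ids=candidates,
    )


class TestRunSelection:
    def test_impossible_improvement_stops_at_stage_one(self, base_extended,
                                                       noisy_dataset):
        config = _fast_selection_config(("IRS_p", "AMPK_pT172"), improvement=1.0)
        result = run_selection(base_extended, noisy_dataset, config)
        assert result.best_inputs == frozenset()
        assert result.survivors.get(2) == []
        assert set(result.table["stage"]) == {1, 2}

    def test_recovers_planted_inputs(self, base_extended, truth):
        dataset = generate_timecourses(truth, SynthConfig(seed=23))
        config = _fast_selection_config(
            ("IRS_p", "AMPK_pT172", "mTORC2_pS2481", "TSC_pS1387")
        )
        result = run_selection(base_extended, dataset, config)
        assert result.best_inputs == frozenset(
            {"IRS_p", "AMPK_pT172", "mTORC2_pS2481"}
        )
        # stage-n entries carry exactly n-1 extra inputs
        for _, row in result.table.iterrows():
            assert len(row["inputs"]) == row["stage"] - 1

    def test_reproducible_at_fixed_seed(self, base_extended, noisy_dataset):
        config = _fast_selection_config(("IRS_p", "AMPK_pT172"), seed=3)
        a = run_selection(base_extended, noisy_dataset, config)
        b = run_selection(base_extended, noisy_dataset, config)
        assert a.table["aic"].tolist() == b.table["aic"].tolist()
        assert a.best_inputs == b.best_inputs

    def test_table_serialization(self, base_extended, noisy_dataset, tmp_path):
        config = _fast_selection_config(("IRS_p",), improvement=1.0)
        result = run_selection(base_extended, noisy_dataset, config)
        out = tmp_path / "sel.tsv"
        result.to_tsv(out)
        text = out.read_text()
        assert text.startswith("stage\t")
        assert "IRS_p" in text
        assert "total_evaluated" in result.to_json()
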
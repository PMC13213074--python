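"""MM/GBSA aggregation, score filtering, ranking and lead selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinasecv import datasets
from kinasecv.screening import (
    aggregate_mmgbsa,
    binding_free_energy,
    filter_above_reference,
    rank_by,
    select_multicriteria,
    validate_energy_table,
)

finite = st.floats(-200, 200, allow_nan=False)


class TestBindingFreeEnergy:
    def test_bound_minus_free(self):
        assert binding_free_energy(-100, -60, -30) == pytest.approx(-10.0)

    def test_no_binding_identity(self):
        assert binding_free_energy(-90, -60, -30) == 0.0

    @given(finite, finite, finite)
    def test_matches_hand_formula(self, c, p, l):
        assert binding_free_energy(c, p, l) == pytest.approx(c - p - l)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            binding_free_energy(np.nan, 0, 0)


class TestAggregate:
    def test_all_zero_components(self):
        df = pd.DataFrame({"compound": ["X"], "VDW": [0.0], "EEL": [0.0],
                           "EGB": [0.0], "ESURF": [0.0]})
        row = aggregate_mmgbsa(df).iloc[0]
        assert row["dG_gas"] == row["dG_solv"] == row["dG_total"] == 0.0

    @pytest.mark.parametrize("compound,gas,solv,total", [
        ("C11596", -87.99, 37.23, -50.76),
        ("C7831", -102.23, 52.31, -49.92),
    ])
    def test_published_component_sums(self, compound, gas, solv, total):
        agg = aggregate_mmgbsa(datasets.load_mmgbsa_components())
        row = agg.set_index("compound").loc[compound]
        assert row["dG_gas"] == pytest.approx(gas, abs=1e-9)
        assert row["dG_solv"] == pytest.approx(solv, abs=1e-9)
        assert row["dG_total"] == pytest.approx(total, abs=1e-9)

    def test_gas_plus_solv_equals_total_exactly(self):
        agg = aggregate_mmgbsa(datasets.load_mmgbsa_components())
        np.testing.assert_array_equal(agg["dG_gas"] + agg["dG_solv"],
                                      agg["dG_total"])

    def test_per_frame_rows_give_sd(self, rng):
        frames = pd.DataFrame({
            "compound": ["X"] * 100,
            "VDW": rng.normal(-60, 2, 100),
            "EEL": rng.normal(-20, 2, 100),
            "EGB": rng.normal(45, 2, 100),
            "ESURF": rng.normal(-8, 0.5, 100),
        })
        row = aggregate_mmgbsa(frames).iloc[0]
        totals = frames[["VDW", "EEL", "EGB", "ESURF"]].sum(axis=1)
        assert row["sd"] == pytest.approx(totals.std(ddof=1))
        assert row["dG_total"] == pytest.approx(totals.mean())

    def test_summary_rows_have_nan_sd(self):
        agg = aggregate_mmgbsa(datasets.load_mmgbsa_components())
        assert agg["sd"].isna().all()

    def test_missing_component_named(self):
        df = pd.DataFrame({"compound": ["X"], "VDW": [1.0], "EEL": [1.0],
                           "EGB": [1.0]})
        with pytest.raises(ValueError, match="ESURF"):
            aggregate_mmgbsa(df)

    def test_empty_table_rejected(self):
        df = pd.DataFrame(columns=["compound", "VDW", "EEL", "EGB", "ESURF"])
        with pytest.raises(ValueError, match="empty"):
            aggregate_mmgbsa(df)


class TestValidation:
    def test_inconsistent_published_rows_flagged(self):
        report = validate_energy_table(datasets.load_mmgbsa_table())
        flagged = set(report.loc[~report["consistent"], "compound"])
        # two published rows disagree with their own component sums by
        # more than component-rounding can explain
        assert flagged == {"C4481", "C19017"}

    def test_corrupted_total_detected(self):
        table = datasets.load_mmgbsa_table().copy()
        table.loc[table["compound"] == "C11596", "dG_total"] = -40.0
        report = validate_energy_table(table).set_index("compound")
        assert not report.loc["C11596", "consistent"]


class TestFilter:
    def test_all_candidates_beat_reference(self):
        scores = datasets.load_candidate_scores()
        kept = filter_above_reference(scores, "EAI001", "ml_score")
        assert len(kept) == 10
        assert "EAI001" not in kept

    def test_reference_at_maximum_keeps_nothing(self):
        scores = datasets.load_candidate_scores()
        assert filter_above_reference(scores, 9.61, "ml_score") == []

    def test_reference_below_all_keeps_everything(self):
        scores = datasets.load_candidate_scores()
        assert len(filter_above_reference(scores, 0.0, "ml_score")) == 11

    def test_lower_is_better_direction(self):
        scores = datasets.load_candidate_scores()
        kept = filter_above_reference(scores, "EAI001", "docking_score")
        assert kept == []  # the reference has the best (lowest) docking score

    def test_unknown_reference_errors(self):
        with pytest.raises(ValueError, match="matched 0"):
            filter_above_reference(datasets.load_candidate_scores(),
                                   "NOPE", "ml_score")


class TestRankBy:
    def test_distinct_values_ascending(self):
        np.testing.assert_array_equal(rank_by([3, 1, 2], "asc"), [3, 1, 2])

    def test_stable_tie_policy_uses_input_order(self):
        np.testing.assert_array_equal(rank_by([5, 5, 7], "asc"), [1, 2, 3])

    def test_competition_tie_policy(self):
        np.testing.assert_array_equal(
            rank_by([5, 5, 7], "asc", ties="competition"), [1, 1, 3])

    def test_published_totals_reproduce_consensus_column(self):
        agg = aggregate_mmgbsa(datasets.load_mmgbsa_components())
        ranks = dict(zip(agg["compound"], rank_by(agg["dG_total"], "asc")))
        consensus = datasets.load_consensus_ranks().set_index("compound")
        for compound, expected in consensus["mmgbsa_rank"].items():
            assert ranks[compound] == expected

    def test_tied_ml_scores_get_listing_order_ranks(self):
        scores = datasets.load_candidate_scores()
        ranks = dict(zip(scores["compound"], rank_by(scores["ml_score"], "desc")))
        consensus = datasets.load_consensus_ranks().set_index("compound")
        for compound, expected in consensus["ml_score_rank"].items():
            assert ranks[compound] == expected

    def test_docking_scores_reproduce_consensus_column(self):
        scores = datasets.load_candidate_scores()
        ranks = dict(zip(scores["compound"], rank_by(scores["docking_score"], "asc")))
        consensus = datasets.load_consensus_ranks().set_index("compound")
        for compound, expected in consensus["docking_rank"].items():
            assert ranks[compound] == expected

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                    max_size=30, unique=True))
    def test_bijection_and_idempotence_for_distinct_values(self, values):
        ranks = rank_by(values, "asc")
        assert sorted(ranks) == list(range(1, len(values) + 1))
        np.testing.assert_array_equal(rank_by(ranks.astype(float), "asc"), ranks)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rank_by([1.0, np.nan], "asc")


class TestSelection:
    def test_published_matrix_gives_lead_set(self):
        selected = select_multicriteria(datasets.load_consensus_ranks(),
                                        top_k=5, min_criteria=3)
        assert set(selected) == {"C4481", "C11596", "C7806", "C7831", "C4049"}

    def test_min_criteria_zero_rejected(self):
        with pytest.raises(ValueError, match="min_criteria"):
            select_multicriteria(datasets.load_consensus_ranks(),
                                 top_k=5, min_criteria=0)

    def test_loosest_rule_selects_everything(self):
        ranks = datasets.load_consensus_ranks()
        selected = select_multicriteria(ranks, top_k=len(ranks), min_criteria=1)
        assert selected == ranks["compound"].tolist()

    def test_missing_rank_named(self):
        ranks = datasets.load_consensus_ranks().copy()
        ranks.loc[0, "docking_rank"] = np.nan
        with pytest.raises(ValueError, match="C4481"):
            select_multicriteria(ranks, top_k=5, min_criteria=3)

    @given(st.integers(0, 500))
    def test_matches_brute_force_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 8), rng.integers(2, 5)
        ranks = pd.DataFrame(
            {f"crit{j}": rng.permutation(n) + 1 for j in range(m)},
            index=[f"cpd{i}" for i in range(n)])
        top_k = int(rng.integers(1, n + 1))
        min_c = int(rng.integers(1, m + 1))
        expected = [
            c for c in ranks.index
            if sum(ranks.loc[c, f"crit{j}"] <= top_k for j in range(m)) >= min_c
        ]
        assert select_multicriteria(ranks, top_k=top_k, min_criteria=min_c) == expected

    def test_monotone_in_parameters(self):
        ranks = datasets.load_consensus_ranks()
        s_base = set(select_multicriteria(ranks, top_k=5, min_criteria=3))
        assert set(select_multicriteria(ranks, top_k=5, min_criteria=4)) <= s_base
        assert set(select_multicriteria(ranks, top_k=4, min_criteria=3)) <= s_base
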
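"""Multi-criterion development sizes, binary and time-to-event."""

import pytest
from hypothesis import given, settings, strategies as st

from cpmsize import (
    develop_binary,
    develop_scenario,
    develop_survival,
    epp_from_n,
    person_time_rate,
)

from oracles import oracle_final_n_binary, oracle_final_n_survival


class TestBinary:
    def test_balanced_half_prevalence_case(self):
        res = develop_binary(30, 0.5, r2_nagelkerke=0.3)
        assert res.criterion_sizes == {
            "shrinkage": 1043,
            "optimism": 690,
            "risk_precision": 385,
        }
        assert res.final_n == 1043
        assert res.epp == 17.38
        assert res.dominating_criterion == "shrinkage"

    def test_weaker_anticipated_fit_needs_more_data(self):
        res = develop_binary(30, 0.5, r2_nagelkerke=0.15)
        assert res.final_n == 2247
        assert res.epp == 37.45

    def test_half_the_predictors(self):
        assert develop_binary(15, 0.5, r2_nagelkerke=0.3).final_n == 522

    def test_expected_events_is_n_times_prevalence(self):
        res = develop_binary(30, 0.307)
        assert res.expected_events == pytest.approx(res.final_n * 0.307)

    def test_shrinkage_unsatisfiable_when_r2_exceeds_target(self):
        with pytest.raises(ValueError, match="shrinkage criterion unsatisfiable"):
            develop_binary(30, 0.5, r2_nagelkerke=0.95, shrinkage_target=0.6)

    @given(phi=st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=60, deadline=None)
    def test_prevalence_symmetry(self, phi):
        a = develop_binary(30, phi)
        b = develop_binary(30, 1 - phi)
        assert a.criterion_sizes == b.criterion_sizes

    @given(
        p=st.integers(min_value=2, max_value=60),
        phi=st.floats(min_value=0.05, max_value=0.95),
        r2n=st.floats(min_value=0.05, max_value=0.6),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_independent_search_oracle(self, p, phi, r2n):
        assert develop_binary(p, phi, r2_nagelkerke=r2n).final_n == oracle_final_n_binary(
            p, phi, r2_nagelkerke=r2n
        )

    def test_monotone_in_predictors_and_fit(self):
        sizes_p = [develop_binary(p, 0.3).final_n for p in range(2, 42, 4)]
        assert all(b >= a for a, b in zip(sizes_p, sizes_p[1:]))
        sizes_r = [develop_binary(30, 0.3, r2_nagelkerke=r).final_n
                   for r in (0.1, 0.2, 0.3, 0.5, 0.7)]
        assert all(b < a for a, b in zip(sizes_r, sizes_r[1:]))


class TestSurvival:
    def test_registry_scenarios_match_independent_oracle(self, by_id, survival_reference):
        pinned = survival_reference["final_n"]
        for sid, expected in pinned.items():
            assert develop_scenario(by_id[sid]).final_n == expected

    def test_fresh_oracle_agrees_with_pinned_values(self, by_id, survival_reference):
        for sid, expected in survival_reference["final_n"].items():
            sc = by_id[sid]
            rate = person_time_rate(
                sc.prevalence, sc.median_time_to_event, sc.median_follow_up
            ).rate
            assert oracle_final_n_survival(
                30, rate, sc.prediction_timepoint, sc.study_follow_up
            ) == expected

    def test_sizes_near_published_case_study(self, by_id):
        published = {
            "nb_death_tte": 1397,
            "hr_nb_relapse_tte": 1060,
            "dipg_death_tte": 1273,
            "dipg_prog_tte": 1130,
        }
        for sid, printed in published.items():
            n = develop_scenario(by_id[sid]).final_n
            assert abs(n - printed) / printed <= 0.01

    def test_slack_risk_margin_leaves_shrinkage_dominant(self):
        # a cumulative-risk half-width can never exceed 0.5, so a margin
        # above that is met at n = 1
        res = develop_survival(30, 0.0063, 24, 24, risk_margin=0.51)
        assert res.criterion_sizes["risk_precision"] == 1
        assert res.final_n == res.criterion_sizes["shrinkage"]

    def test_risk_precision_tightens_with_margin(self):
        loose = develop_survival(30, 0.0063, 24, 24, risk_margin=0.05)
        tight = develop_survival(30, 0.0063, 24, 24, risk_margin=0.01)
        assert (
            tight.criterion_sizes["risk_precision"]
            > loose.criterion_sizes["risk_precision"]
        )

    def test_expected_events_uses_mean_follow_up(self):
        res = develop_survival(30, 0.0063, 24, 24)
        assert res.expected_events == pytest.approx(res.final_n * 0.0063 * 24)

    def test_scarce_events_warning(self):
        # vanishingly rare outcome: even the shrinkage-driven n expects < 1 event
        res = develop_survival(1, 4e-10, 24, 24, risk_margin=0.51)
        assert res.expected_events < 1
        assert any("expected event" in w for w in res.warnings)

    def test_printed_rate_mode(self, by_id):
        full = develop_scenario(by_id["nb_death_tte"])
        printed = develop_scenario(by_id["nb_death_tte"], round_rate_dp=4)
        # both modes exist and give close but not necessarily equal sizes
        assert abs(printed.final_n - full.final_n) / full.final_n < 0.01


class TestEpp:
    @pytest.mark.parametrize(
        "n, phi, p, expected",
        [(1043, 0.5, 30, 17.38), (2247, 0.5, 30, 37.45)],
    )
    def test_published_epp_values(self, n, phi, p, expected):
        assert epp_from_n(n, phi, p) == expected

    def test_linear_in_n(self):
        assert epp_from_n(1200, 0.5, 30) == 2 * epp_from_n(600, 0.5, 30)
        assert epp_from_n(2086, 0.5, 30) == pytest.approx(
            2 * epp_from_n(1043, 0.5, 30), abs=0.011  # 2-dp rounding of each side
        )

    def test_rounding_is_half_up(self):
        # 100 * 0.305 / 61 = 0.5 exactly at the third decimal: 0.50
        assert epp_from_n(405, 0.5, 30) == 6.75
        assert epp_from_n(3, 0.5, 4) == 0.38  # 0.375 rounds up, not to even
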
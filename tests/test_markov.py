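"""Markov engine: transition construction, rewards, cohort evolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dkdcea.markov import (State, build_transition_model, default_allocation,
                           effective_exit_probability, run_cohort, state_cost,
                           state_utility, validate_allocation)
from dkdcea.params import EARLY_STAGES, ConfigError
from dkdcea.tree import PATHWAYS, build_pathway_mix

ZERO_EXITS = {f"exit_{k}": 0.0 for k in
              ("g1", "g2", "g3a", "g3b", "g4", "g5", "dialysis", "post_kt")}


class TestEffectiveExit:
    def test_true_positive_hazard_applies_when_above_cap(self, base):
        # G2: HR 0.60 exceeds 1/RR = 0.5035, so the care effect is used
        assert effective_exit_probability("g2", "TP", base) == pytest.approx(
            0.088 * 1.986 * 0.60)

    def test_cap_binds_when_care_effect_exceeds_inverse_rr(self, base):
        # G1: HR 0.37 < 1/1.671, so TP exit is capped at the TN exit rate
        assert effective_exit_probability("g1", "TP", base) == pytest.approx(
            0.110, abs=1e-12)

    def test_no_effect_limit(self, base):
        flat = base.replace(rr_pdkf_g3a=1.0, hr_comp_tp_g3a=1.0,
                            hr_comp_fp=1.0)
        for p in PATHWAYS:
            assert effective_exit_probability("g3a", p, flat) == \
                pytest.approx(0.105)

    def test_false_negative_scales_by_relative_risk(self, base):
        assert effective_exit_probability("g3b", "FN", base) == pytest.approx(
            0.150 * 1.315)

    @given(st.floats(0.0, 1.0), st.floats(1.0, 3.0),
           st.floats(0.01, 1.0), st.floats(0.5, 1.0))
    @settings(derandomize=True, deadline=None)
    def test_cap_rule_orders_pathways(self, base, r, rr, hr, hr_fp):
        """TN exit <= TP exit <= FN exit for every admissible input."""
        inputs = base.replace(exit_g2=r, rr_pdkf_g2=rr, hr_comp_tp_g2=hr,
                              hr_comp_fp=hr_fp)
        tn = effective_exit_probability("g2", "TN", inputs)
        tp = effective_exit_probability("g2", "TP", inputs)
        fn = effective_exit_probability("g2", "FN", inputs)
        assert tn - 1e-12 <= tp <= fn + 1e-12


class TestTransitionModel:
    def test_rows_are_stochastic(self, base):
        model = build_transition_model(base)
        for p in PATHWAYS:
            P = model.matrix(p)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all() and (P <= 1).all()

    def test_death_is_absorbing(self, base):
        P = build_transition_model(base).matrix("TP")
        expected = np.zeros(len(State))
        expected[State.DEATH] = 1.0
        assert (P[State.DEATH] == expected).all()

    def test_advanced_states_identical_across_pathways(self, base):
        """From G4 onward the PDKF label and care assignment stop mattering."""
        model = build_transition_model(base)
        ref = model.matrix("TN")
        for p in ("TP", "FN", "FP"):
            P = model.matrix(p)
            for s in (State.G4, State.G5, State.DIALYSIS, State.KT,
                      State.POST_KT):
                assert (P[s] == ref[s]).all()

    def test_transient_transplant_empties_in_one_cycle(self, base):
        P = build_transition_model(base).matrix("TN")
        assert P[State.KT, State.KT] == 0.0
        assert P[State.KT, State.DEATH] == pytest.approx(0.049)
        assert P[State.KT, State.POST_KT] == pytest.approx(0.951)

    def test_stage_exit_splits_between_progression_and_death(self, base):
        P = build_transition_model(base).matrix("TN")
        d = base.settings.death_share
        assert P[State.G3A, State.G3A] == pytest.approx(1 - 0.105)
        assert P[State.G3A, State.G3B] == pytest.approx(0.105 * (1 - d))
        assert P[State.G3A, State.DEATH] == pytest.approx(0.105 * d)

    def test_regressive_allocation_rejected(self, base):
        alloc = default_allocation(base)
        alloc[State.G2] = {State.G1: 0.5, State.DEATH: 0.5}
        with pytest.raises(ConfigError, match="not more severe"):
            validate_allocation(alloc)

    def test_allocation_rows_must_be_simplex(self, base):
        alloc = default_allocation(base)
        alloc[State.G1] = {State.G2: 0.7, State.DEATH: 0.2}
        with pytest.raises(ConfigError, match="sums to"):
            validate_allocation(alloc)


class TestRewards:
    def test_state_utility_examples(self, base):
        assert state_utility(State.G3A, 65, base) == pytest.approx(
            0.944 - 0.0007 * 65 - 0.200)
        assert state_utility(State.DIALYSIS, 67, base) == pytest.approx(
            0.944 - 0.0007 * 67 - 0.530)
        assert state_utility(State.DEATH, 80, base) == 0.0

    def test_utility_floors_at_zero(self, base):
        heavy = base.replace(disutility_dialysis=0.944)
        assert state_utility(State.DIALYSIS, 90, heavy) == 0.0

    def test_state_cost_includes_care_addon_for_treated_pathways(self, base):
        assert state_cost(State.G3A, "TP", base) == pytest.approx(
            34284 + 2655 + 143)
        assert state_cost(State.G3A, "TN", base) == pytest.approx(34284)
        assert state_cost(State.DEATH, "TP", base) == 0.0

    def test_care_addon_ceases_in_advanced_stages(self, base):
        assert state_cost(State.G4, "TP", base) == state_cost(
            State.G4, "TN", base)

    def test_transient_transplant_cycle_is_blended(self, base):
        expected = 0.25 * 71958 + 0.75 * 79632
        assert state_cost(State.KT, "TN", base) == pytest.approx(expected)


class TestRunCohort:
    def test_occupancy_conserved_every_cycle(self, base):
        for arm in ("AIKD", "SoC"):
            res = run_cohort(build_pathway_mix(base, arm), base)
            assert np.allclose(res.occupancy.sum(axis=1), 1.0, atol=1e-10)

    def test_stationary_cohort_matches_closed_form(self, base):
        """With zero transition rates and a degenerate tree (everyone TP in
        G3a) the engine must reproduce the geometric-discounting closed form."""
        inputs = base.replace(
            stage_share_g1=0.0, stage_share_g2=0.0, stage_share_g3a=1.0,
            stage_share_g3b=0.0, pdkf_prevalence_g3a=1.0,
            aikd_sensitivity=1.0, aikd_specificity=1.0, **ZERO_EXITS)
        res = run_cohort(build_pathway_mix(inputs, "AIKD"), inputs)
        disc = [(1.03) ** (-t) for t in range(1, 6)]
        u = [0.944 - 0.0007 * (65 + t) - 0.200 for t in range(5)]
        c = 34284 + 2655 + 143
        assert res.disc_qaly == pytest.approx(
            sum(d * ut for d, ut in zip(disc, u)), abs=1e-12)
        assert res.disc_cost == pytest.approx(
            1050 + c * sum(disc), abs=1e-9)

    def test_discounting_reduces_totals(self, base):
        undisc = base.replace(discount_rate=0.0)
        for arm in ("AIKD", "SoC"):
            mix_d = build_pathway_mix(base, arm)
            mix_u = build_pathway_mix(undisc, arm)
            r_d = run_cohort(mix_d, base)
            r_u = run_cohort(mix_u, undisc)
            assert r_u.disc_cost > r_d.disc_cost
            assert r_u.disc_qaly > r_d.disc_qaly
            # undiscounted accruals are identical: discounting only rescales
            assert np.allclose(r_u.cycle_cost, r_d.cycle_cost)

    def test_equalized_arms_coincide(self, base):
        same = base.replace(soc_sensitivity=0.51, soc_specificity=0.93,
                            cost_test=0.0)
        aikd = run_cohort(build_pathway_mix(same, "AIKD"), same)
        soc = run_cohort(build_pathway_mix(same, "SoC"), same)
        assert aikd.disc_cost == pytest.approx(soc.disc_cost, abs=1e-9)
        assert aikd.disc_qaly == pytest.approx(soc.disc_qaly, abs=1e-12)

    def test_half_cycle_correction_averages_boundary_occupancy(self, base):
        alt = base.replace()
        alt.settings.half_cycle_correction = True
        res_hc = run_cohort(build_pathway_mix(alt, "SoC"), alt)
        res = run_cohort(build_pathway_mix(base, "SoC"), base)
        # deaths during the cycle now shave accruals
        assert res_hc.disc_qaly < res.disc_qaly
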
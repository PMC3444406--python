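"""Diffusion drivers: failure, non-compliance, uptake, and their composition."""

from dataclasses import replace

import numpy as np
import pytest

from diffcea.diffusion import (
    UPTAKE_PROGRAM,
    DiffusionDrivers,
    ScenarioTrajectory,
    apply_failure,
    apply_noncompliance,
    apply_uptake,
    default_trajectory,
    evaluate_scenario,
    per_tested_increments,
    scenario_table,
)
from diffcea.health_model import ModelValidationError
from diffcea.synthetic_params import ParameterSet, with_paths
from diffcea.test_strategy import (
    DEFAULT_POLICY,
    classify,
    group_outcome,
    joint_classification,
    strategy_expected_outcomes,
)


def drv(failure=0.0, chgl=0.0, clgh=0.0, uptake=1.0, year="x"):
    return DiffusionDrivers(
        year=year,
        failure=failure,
        noncompliance_chgl=chgl,
        noncompliance_clgh=clgh,
        uptake=uptake,
    )


class TestDrivers:
    def test_total_noncompliance_is_additive(self):
        d = drv(chgl=0.15, clgh=0.20)
        assert d.total_noncompliance == pytest.approx(0.35)

    def test_from_total_preserves_anchor_split(self):
        d = DiffusionDrivers.from_total_noncompliance("2010", 0.2, 0.26, 0.5)
        assert d.noncompliance_chgl / d.noncompliance_clgh == pytest.approx(0.15 / 0.20)
        assert d.total_noncompliance == pytest.approx(0.26)

    def test_bounds_validated(self):
        with pytest.raises(ModelValidationError):
            drv(failure=1.2)

    def test_default_trajectory_reproduces_packaged_values(self, trajectory):
        got = {
            p.year: (p.failure, round(p.total_noncompliance, 10), p.uptake)
            for p in trajectory
        }
        assert got == {
            "2005": (0.27, 0.35, 0.03),
            "2010": (0.20, 0.26, 0.50),
            "2020": (0.08, 0.08, 0.92),
        }

    def test_alternative_2020_failure_preset(self):
        traj = default_trajectory(failure_2020=0.14)
        assert traj.points[2].failure == 0.14

    def test_years_must_increase(self):
        with pytest.raises(ModelValidationError, match="increasing"):
            ScenarioTrajectory(points=(drv(year="2010"), drv(year="2005")))


class TestApplyFailure:
    def test_zero_failure_is_identity(self, params):
        out = apply_failure((10.0, 5000.0), (9.0, 4000.0), drv(failure=0.0),
                            params.signature)
        assert out == (10.0, 5000.0)

    def test_full_failure_reverts_to_guideline_plus_partial_cost(self, params):
        test = replace(params.signature, unit_cost=1000.0)
        out = apply_failure((10.0, 5000.0), (9.0, 4000.0), drv(failure=1.0), test)
        assert out[0] == pytest.approx(9.0)
        assert out[1] == pytest.approx(4000.0 + 100.0)

    def test_expected_test_cost_mixture(self, params):
        # cost component: 0.73 x 1000 + 0.27 x 100 = 757
        test = replace(params.signature, unit_cost=1000.0)
        sig = (0.0, 1000.0)  # isolate the test-cost component
        gl = (0.0, 0.0)
        out = apply_failure(sig, gl, drv(failure=0.27), test)
        assert out[1] == pytest.approx(757.0)


@pytest.fixture(scope="module")
def joint(params):
    return joint_classification(
        params.profile, params.guideline, params.signature,
        params.concordance_adjustment,
    )


class TestApplyNoncompliance:

    def test_zero_rates_equal_pure_signature_strategy(self, params, settings, joint):
        got = apply_noncompliance(joint, drv(), params, settings)
        shares = classify(params.profile, params.signature)
        want = strategy_expected_outcomes(shares, params, settings,
                                          test=params.signature)
        assert got == pytest.approx(want)

    def test_full_reversion_recovers_guideline_effects(self, params, settings, joint):
        got = apply_noncompliance(joint, drv(chgl=1.0, clgh=1.0), params, settings)
        shares = classify(params.profile, params.guideline)
        want = strategy_expected_outcomes(shares, params, settings)
        assert got[0] == pytest.approx(want[0])
        assert got[1] == pytest.approx(want[1] + params.signature.unit_cost)

    def test_matches_eight_cell_enumeration(self, params, settings, joint):
        # independent oracle: explicit weighted enumeration over all cells
        rates = {(1, 0): 0.15, (0, 1): 0.20}
        got = apply_noncompliance(joint, drv(chgl=0.15, clgh=0.20), params, settings)
        calls = ("low", "high")
        q = c = 0.0
        for g in (0, 1):
            for s in (0, 1):
                nc = rates.get((g, s), 0.0)
                for t in (0, 1):
                    w = joint.cells[g, s, t]
                    truth = "high" if t else "low"
                    oq_s, oc_s = group_outcome(
                        params, settings, truth, DEFAULT_POLICY.treatment(calls[s]))
                    oq_g, oc_g = group_outcome(
                        params, settings, truth, DEFAULT_POLICY.treatment(calls[g]))
                    q += w * ((1 - nc) * oq_s + nc * oq_g)
                    c += w * ((1 - nc) * oc_s + nc * oc_g)
        c += params.signature.unit_cost
        assert got == pytest.approx((q, c), rel=1e-12)

    def test_requires_joint_classification(self, params, settings):
        with pytest.raises(ModelValidationError, match="joint"):
            apply_noncompliance(None, drv(), params, settings)


class TestApplyUptake:
    def test_no_diffusion_limit(self):
        assert apply_uptake((10.0, 9000.0), (9.0, 4000.0), drv(uptake=0.0)) == (0.0, 0.0)

    def test_full_uptake_identity(self):
        de, dc = apply_uptake((10.0, 9000.0), (9.0, 4000.0), drv(uptake=1.0))
        assert (de, dc) == (1.0, 5000.0)

    def test_published_uptake_scaling(self):
        # per-tested dE = 0.1184 scales to the two published uptake rows
        tested, guideline = (0.1184, 0.0), (0.0, 0.0)
        de50, _ = apply_uptake(tested, guideline, drv(uptake=0.50))
        de92, _ = apply_uptake(tested, guideline, drv(uptake=0.92))
        assert de50 == pytest.approx(0.0592, abs=5e-5)
        assert de92 == pytest.approx(0.1089, abs=5e-5)

    def test_exact_linearity_in_uptake(self, params, settings, drivers_by_year):
        detail = per_tested_increments(params, drivers_by_year["2010"], settings)
        pts = []
        for u in (0.2, 0.5, 0.9):
            d = replace(drivers_by_year["2010"], uptake=u)
            pts.append(apply_uptake(detail["tested"], detail["guideline"], d))
        (e1, c1), (e2, c2), (e3, c3) = pts
        assert e2 / e1 == pytest.approx(0.5 / 0.2, rel=1e-12)
        assert e3 / e1 == pytest.approx(0.9 / 0.2, rel=1e-12)
        assert c2 / c1 == pytest.approx(0.5 / 0.2, rel=1e-12)
        assert c3 / c1 == pytest.approx(0.9 / 0.2, rel=1e-12)

    def test_program_mode_charges_testing_to_whole_population(self):
        tested, guideline = (1.0, 2_000.0), (0.9, 0.0)
        comp = 2_500.0  # expected testing cost per tested patient
        de, dc = apply_uptake(tested, guideline, drv(uptake=0.4),
                              mode=UPTAKE_PROGRAM, test_cost_component=comp)
        assert de == pytest.approx(0.4 * 0.1)
        assert dc == pytest.approx(comp + 0.4 * (2_000.0 - 0.0 - comp))

    def test_program_mode_requires_component(self):
        with pytest.raises(ModelValidationError, match="test_cost_component"):
            apply_uptake((1.0, 1.0), (0.0, 0.0), drv(), mode=UPTAKE_PROGRAM)


class TestEvaluateScenario:
    def test_identical_strategies_cost_test_price_only(self, settings):
        base = ParameterSet()
        ps = with_paths(
            base,
            {
                "guideline.sensitivity": 1.0,
                "guideline.specificity": 1.0,
                "signature.sensitivity": 1.0,
                "signature.specificity": 1.0,
            },
        )
        res = evaluate_scenario(ps, drv(uptake=1.0), settings)
        assert res.delta_effects == pytest.approx(0.0, abs=1e-12)
        assert res.delta_costs == pytest.approx(ps.signature.unit_cost)

    def test_full_failure_and_full_noncompliance_each_collapse_effects(
        self, params, settings
    ):
        for d in (drv(failure=1.0), drv(chgl=1.0, clgh=1.0)):
            res = evaluate_scenario(params, d, settings)
            assert res.delta_effects == pytest.approx(0.0, abs=1e-12)
            assert res.delta_costs > 0  # residual test costs remain

    def test_monotone_improvement_in_failure_and_compliance(self, params, settings):
        base = evaluate_scenario(params, drv(failure=0.3, chgl=0.1, clgh=0.15), settings)
        assert base.delta_effects > 0
        better_f = evaluate_scenario(params, drv(failure=0.1, chgl=0.1, clgh=0.15), settings)
        better_nc = evaluate_scenario(params, drv(failure=0.3, chgl=0.0, clgh=0.05), settings)
        assert better_f.delta_effects >= base.delta_effects
        assert better_nc.delta_effects >= base.delta_effects

    def test_composition_order_is_not_commutative(self, params, settings):
        # canonical order: non-compliance within delivered results, then
        # failure mixing.  Applying non-compliance to the failure-mixed
        # outcomes (failed tests reaching a compliance decision) differs.
        d = drv(failure=0.27, chgl=0.15, clgh=0.20, uptake=1.0)
        canonical = evaluate_scenario(params, d, settings)

        joint = joint_classification(
            params.profile, params.guideline, params.signature,
            params.concordance_adjustment,
        )
        shares_g = classify(params.profile, params.guideline)
        gl = strategy_expected_outcomes(shares_g, params, settings)
        shares_s = classify(params.profile, params.signature)
        sig = strategy_expected_outcomes(shares_s, params, settings,
                                         test=params.signature)
        mixed = apply_failure(sig, gl, d, params.signature)
        nc_w = joint.discordant_chgl * d.noncompliance_chgl + \
            joint.discordant_clgh * d.noncompliance_clgh
        shuffled = ((1 - nc_w) * mixed[0] + nc_w * gl[0],
                    (1 - nc_w) * mixed[1] + nc_w * (gl[1] + params.signature.unit_cost))
        de_alt = shuffled[0] - gl[0]
        assert de_alt != pytest.approx(canonical.delta_effects, rel=1e-6)


class TestScenarioTable:
    def test_single_year_trajectory_has_four_rows(self, params, settings):
        traj = ScenarioTrajectory(points=(drv(failure=0.1, chgl=0.05, clgh=0.05,
                                              uptake=0.5, year="2010"),))
        table = scenario_table(params, traj, settings)
        assert len(table) == 4
        assert sorted(table["scenario"]) == ["combined", "failure", "noncompliance", "uptake"]

    def test_default_trajectory_layout(self, params, settings, trajectory):
        table = scenario_table(params, trajectory, settings)
        counts = table["scenario"].value_counts().to_dict()
        assert len(table) == 10
        assert counts == {"start": 1, "failure": 2, "noncompliance": 2,
                          "uptake": 2, "combined": 3}

    def test_constant_trajectory_gives_identical_rows(self, params, settings):
        base = drv(failure=0.27, chgl=0.15, clgh=0.20, uptake=0.03, year="2005")
        traj = ScenarioTrajectory(points=(
            base, replace(base, year="2010"), replace(base, year="2020")))
        table = scenario_table(params, traj, settings)
        assert table["delta_effects"].nunique() == 1
        assert table["delta_costs"].nunique() == 1
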
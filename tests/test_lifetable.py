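import math

import numpy as np
import pytest

import oracles
from agestage.cohort import Cohort, IndividualRecord
from agestage.lifetable import (
    LifeTable,
    NoReproductionError,
    age_stage_counts,
    analyze,
    build_schedule,
    derived_rates,
    life_expectancy,
    renewal_residual,
    survival_rates,
    transition_probabilities,
)
from agestage.simulate import generate_cohort
from conftest import mini_config


def single_female(lay_age: int = 3, eggs: int = 8) -> Cohort:
    """One female alive through `lay_age`, laying all eggs on that day."""
    stages = ("egg", "larva", "pupa") + ("female",) * (lay_age - 2)
    egg_row = [0] * len(stages)
    egg_row[lay_age] = eggs
    return Cohort(
        (IndividualRecord("f", stages, tuple(egg_row)),), label="single"
    )


class TestCountsAndSchedule:
    def test_toy_counts(self, toy_cohort):
        counts = age_stage_counts(toy_cohort)
        assert counts[0].tolist() == [4, 0, 0, 0, 0]
        assert counts[4].tolist() == [0, 0, 1, 2, 0]

    def test_single_egg_dying_at_zero(self):
        cohort = Cohort((IndividualRecord("a", ("egg",), (0,)),), "dead")
        assert age_stage_counts(cohort).tolist() == [[1, 0, 0, 0, 0]]

    def test_survival_matrix(self, toy_cohort):
        s = survival_rates(age_stage_counts(toy_cohort), toy_cohort.n)
        assert s[0, 0] == 1.0
        assert s[4, 3] == 0.5
        assert (s.sum(axis=1) <= 1.0 + 1e-12).all()
        with pytest.raises(ValueError):
            survival_rates(age_stage_counts(toy_cohort), 0)

    def test_toy_schedule(self, toy_cohort):
        s = survival_rates(age_stage_counts(toy_cohort), toy_cohort.n)
        sched = build_schedule(toy_cohort, s)
        assert sched.l_x.tolist() == [1, 1, 1, 0.75, 0.75, 0.75, 0.5]
        assert sched.m_x[4] == pytest.approx(1.0)
        assert sched.m_x[5] == pytest.approx(4 / 3)
        assert sched.m_x[6] == pytest.approx(1.0)
        assert np.array_equal(sched.lm_x, sched.l_x * sched.m_x)

    def test_no_oviposition_schedule_is_zero(self):
        inds = tuple(
            IndividualRecord(f"m{i}", ("egg", "larva", "pupa", "male"), (0,) * 4)
            for i in range(4)
        )
        cohort = Cohort(inds, "males")
        s = survival_rates(age_stage_counts(cohort), cohort.n)
        sched = build_schedule(cohort, s)
        assert (sched.m_x == 0).all() and (sched.lm_x == 0).all()


class TestDemographicParams:
    def test_toy_R0(self, toy_cohort):
        res = analyze(toy_cohort)
        assert res.params.R0 == 2.25  # 9 eggs / 4 individuals, exactly

    def test_single_spike_closed_form(self):
        res = analyze(single_female(lay_age=3, eggs=8))
        assert res.params.R0 == 8.0
        assert res.params.r == pytest.approx(math.log(8) / 4, abs=1e-10)

    def test_R0_of_one_gives_r_zero(self):
        cohort = Cohort((IndividualRecord("f", ("egg", "female"), (0, 1)),), "unit")
        res = analyze(cohort)
        assert res.params.R0 == 1.0
        assert res.params.r == pytest.approx(0.0, abs=1e-12)
        assert res.params.lambda_ == pytest.approx(1.0, abs=1e-12)
        # generation-time limit: the single egg arrives at age 1 (x+1 = 2)
        assert res.params.T == pytest.approx(2.0)

    def test_toy_r_matches_independent_oracle(self, toy_cohort):
        res = analyze(toy_cohort)
        r_oracle = oracles.oracle_r(res.schedule.lm_x)
        assert res.params.r == pytest.approx(r_oracle, abs=1e-10)
        assert res.params.r == pytest.approx(0.1386, abs=2e-4)
        assert abs(renewal_residual(res.params.r, res.schedule.lm_x)) < 1e-10

    def test_derived_rates_printed_rounding(self):
        # lambda = exp(r) reproduces the published pairings at 4 decimals
        assert round(derived_rates(0.0152, 16.67)[0], 4) == 1.0153
        assert round(derived_rates(0.0027, 1.69)[0], 4) == 1.0027

    def test_r_zero_limit(self):
        lam, T = derived_rates(0.0, 2.0, analyze(single_female()).schedule)
        assert lam == 1.0
        assert T > 0  # falls back to the cohort generation time

    def test_no_reproduction_raises(self):
        cohort = Cohort((IndividualRecord("a", ("egg",), (0,)),), "dead")
        with pytest.raises(NoReproductionError, match="no reproduction"):
            analyze(cohort)
        res = LifeTable(cohort).fit(require_reproduction=False)
        assert res.params.R0 == 0.0 and math.isnan(res.params.r)


class TestTransitions:
    def test_toy_larva_age2(self, toy_cohort):
        model = transition_probabilities(toy_cohort)
        assert model.p_grow(2, 1) == 0.5
        assert model.p_stay(2, 1) == 0.25
        assert model.p_die(2, 1) == pytest.approx(0.25)

    def test_terminal_age_dies(self, toy_cohort):
        model = transition_probabilities(toy_cohort)
        x_max = toy_cohort.x_max
        for j in range(5):
            if model.at_risk[x_max, j]:
                assert model.p_die(x_max, j) == 1.0

    def test_sole_survivor_stays(self):
        cohort = Cohort((IndividualRecord("a", ("egg", "egg", "larva"), (0, 0, 0)),), "c")
        model = transition_probabilities(cohort)
        assert model.p_stay(0, 0) == 1.0
        assert model.p_grow(1, 0) == 1.0


class TestExpectancyAndValue:
    def test_e01_is_mean_lifespan(self, toy_cohort):
        res = analyze(toy_cohort)
        assert res.e_xj[0, 0] == pytest.approx(5.75, abs=1e-12)
        assert res.e_xj[0, 0] == pytest.approx(oracles.mean_lifespan(toy_cohort), abs=1e-9)

    def test_terminal_e_is_one(self, toy_cohort):
        res = analyze(toy_cohort)
        x_max = toy_cohort.x_max
        observed = res.transitions.at_risk[x_max] > 0
        assert np.allclose(res.e_xj[x_max][observed], 1.0)

    def test_deterministic_chain(self):
        cohort = Cohort((IndividualRecord("a", ("egg",) * 5, (0,) * 5),), "chain")
        e = life_expectancy(transition_probabilities(cohort))
        # k further guaranteed days alive -> e = k + 1
        assert np.allclose(e[:, 0], [5, 4, 3, 2, 1])

    def test_single_female_terminal_reproduction(self):
        res = analyze(single_female(lay_age=3, eggs=8))
        assert res.v_xj[3, 3] == pytest.approx(8.0)

    def test_male_column_has_zero_value(self, toy_cohort):
        res = analyze(toy_cohort)
        male = res.v_xj[:, 4]
        assert np.nansum(male) == 0.0

    def test_weighted_value_identity(self, toy_cohort):
        # sum_j s_0j v_0j = e^r sum_x e^{-r(x+1)} lm_x = lambda
        res = analyze(toy_cohort)
        lhs = np.nansum(res.survival[0] * np.nan_to_num(res.v_xj[0]))
        x1 = np.arange(1, len(res.schedule.lm_x) + 1)
        rhs = math.exp(res.params.r) * float(
            np.exp(-res.params.r * x1) @ res.schedule.lm_x
        )
        assert lhs == pytest.approx(rhs, rel=1e-10)
        assert lhs == pytest.approx(res.params.lambda_, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_recursions_match_forward_summation(self, seed):
        """Backward-recursion e_xj and v_xj equal the explicit forward
        s'-matrix summation on small cohorts."""
        cohort = generate_cohort(mini_config(), n=8, seed=seed)
        res = LifeTable(cohort).fit(require_reproduction=False)
        r = res.params.r
        for x in range(cohort.x_max + 1):
            for j, stage in enumerate(("egg", "larva", "pupa", "female", "male")):
                if res.transitions.at_risk[x, j] == 0:
                    assert math.isnan(res.e_xj[x, j])
                    continue
                assert res.e_xj[x, j] == pytest.approx(
                    oracles.forward_life_expectancy(cohort, x, stage), abs=1e-9
                )
                if res.v_xj is not None:
                    assert res.v_xj[x, j] == pytest.approx(
                        oracles.forward_reproductive_value(cohort, x, stage, r),
                        abs=1e-9,
                    )


class TestInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_schedule_and_parameter_invariants(self, seed):
        cohort = generate_cohort(mini_config(), n=60, seed=100 + seed)
        res = LifeTable(cohort).fit(require_reproduction=False)
        sched = res.schedule
        assert (np.diff(sched.l_x) <= 1e-12).all()  # l_x non-increasing
        assert np.array_equal(res.survival.sum(axis=1), sched.l_x)
        # R0 identity: (females/n) * mean eggs per female, machine precision
        females = cohort.females
        if females:
            identity = (len(females) / cohort.n) * np.mean(
                [f.total_eggs for f in females]
            )
            assert res.params.R0 == pytest.approx(identity, abs=1e-12)
        if res.params.R0 > 0:
            assert abs(renewal_residual(res.params.r, sched.lm_x)) < 1e-10
            assert res.params.lambda_ == pytest.approx(
                math.exp(res.params.r), abs=1e-15
            )
            assert (res.params.R0 > 1) == (res.params.r > 0) == (res.params.lambda_ > 1)
        assert res.e_xj[0, 0] == pytest.approx(oracles.mean_lifespan(cohort), abs=1e-9)
        # e >= 1 wherever observed
        observed = res.transitions.at_risk > 0
        assert (res.e_xj[observed] >= 1.0 - 1e-12).all()


class TestResultsSurface:
    def test_summary_mentions_parameters(self, toy_cohort):
        text = analyze(toy_cohort).summary()
        assert "R0" in text and "lambda" in text and "n = 4" in text

    def test_save_writes_expected_files(self, toy_cohort, tmp_path):
        written = analyze(toy_cohort).save(tmp_path, seed=1)
        names = {p.name for p in written}
        assert names == {
            "sxj.tsv", "exj.tsv", "vxj.tsv", "schedule.tsv", "traits.tsv", "params.json"
        }
        import json

        params = json.loads((tmp_path / "params.json").read_text())
        assert params["R0"] == 2.25
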
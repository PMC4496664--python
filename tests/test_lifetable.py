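"""Life table schedules, demographic parameters, e_xj and v_xj matrices.

Expected values for the two-individual toy cohort are derived by hand (and,
for the intrinsic rate, from the polynomial root of the renewal equation
computed independently with np.roots in the ``toy_r`` fixture).
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from agestage import (
    Cohort,
    CohortError,
    IndividualRecord,
    StageSchema,
    compute_fecundity_schedules,
    compute_survival_schedule,
    conditional_survival,
    demographic_params,
    finite_rate,
    life_expectancy,
    mean_generation_time,
    net_reproductive_rate,
    r0_consistency,
    reproduction_stats,
    reproductive_value,
    simulate_cohort,
    solve_intrinsic_rate,
    stage_duration_stats,
    table1_presets,
)


@pytest.fixture
def toy_schedules(toy_cohort):
    surv = compute_survival_schedule(toy_cohort)
    fec = compute_fecundity_schedules(toy_cohort, surv)
    return surv, fec


class TestSchedules:
    def test_toy_survival_matrix(self, toy_schedules):
        surv, _ = toy_schedules
        expected = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 0.5]])
        np.testing.assert_allclose(surv.s, expected)
        np.testing.assert_allclose(surv.l, [1.0, 1.0, 0.5])

    def test_toy_fecundity_schedules(self, toy_schedules):
        _, fec = toy_schedules
        assert fec.f[1, 1] == 2.0 and fec.f[2, 1] == 1.0
        np.testing.assert_allclose(fec.m_x, [0.0, 1.0, 1.0])
        np.testing.assert_allclose(fec.phi, [0.0, 1.0, 0.5])

    def test_immortal_individual_keeps_l_at_one(self, toy_schema):
        c = Cohort(
            schema=toy_schema,
            records=[IndividualRecord("a", [("egg", 0)] * 6)],
        )
        surv = compute_survival_schedule(c)
        np.testing.assert_allclose(surv.l, np.ones(6))

    def test_phi_equals_l_times_m(self, toy_schedules):
        surv, fec = toy_schedules
        ok = surv.l > 0
        np.testing.assert_allclose(fec.phi[ok], (surv.l * fec.m_x)[ok])

    def test_no_eggs_gives_zero_schedules(self, toy_schema):
        c = Cohort(
            schema=toy_schema,
            records=[IndividualRecord("a", [("egg", 0), ("female_adult", 0)])],
        )
        surv = compute_survival_schedule(c)
        fec = compute_fecundity_schedules(c, surv)
        assert fec.f.sum() == 0 and fec.phi.sum() == 0

    def test_empty_cohort_raises(self, toy_schema):
        with pytest.raises(CohortError):
            compute_survival_schedule(Cohort(schema=toy_schema, records=[]))


class TestParameters:
    def test_toy_r0(self, toy_schedules):
        assert net_reproductive_rate(toy_schedules[1]) == pytest.approx(1.5)

    def test_toy_intrinsic_rate_matches_polynomial_root(self, toy_schedules, toy_r):
        r = solve_intrinsic_rate(toy_schedules[1])
        assert r == pytest.approx(toy_r, abs=1e-9)
        assert r == pytest.approx(0.17520, abs=5e-6)

    def test_intrinsic_rate_matches_brentq_oracle_on_synthetic(self):
        c = simulate_cohort(table1_presets("batatas"), n=150, seed=5)
        surv = compute_survival_schedule(c)
        fec = compute_fecundity_schedules(c, surv)
        r = solve_intrinsic_rate(fec)
        ages1 = np.arange(1, fec.phi.size + 1)
        f = lambda rr: np.sum(np.exp(-rr * ages1) * fec.phi) - 1.0
        assert r == pytest.approx(brentq(f, -1, 1, xtol=1e-13), abs=1e-9)

    def test_residual_below_tolerance(self, toy_schedules):
        fec = toy_schedules[1]
        r = solve_intrinsic_rate(fec)
        ages1 = np.arange(1, fec.phi.size + 1)
        assert abs(np.sum(np.exp(-r * ages1) * fec.phi) - 1.0) < 1e-10

    def test_unit_r0_gives_zero_rate(self, toy_schema):
        # one individual laying exactly one egg: R0 = 1 => r = 0
        c = Cohort(
            schema=toy_schema,
            records=[IndividualRecord("a", [("egg", 0), ("female_adult", 1)])],
        )
        surv = compute_survival_schedule(c)
        fec = compute_fecundity_schedules(c, surv)
        assert solve_intrinsic_rate(fec) == pytest.approx(0.0, abs=1e-9)

    def test_no_reproduction_has_no_solution(self, toy_schema):
        c = Cohort(schema=toy_schema, records=[IndividualRecord("a", [("egg", 0)])])
        surv = compute_survival_schedule(c)
        fec = compute_fecundity_schedules(c, surv)
        with pytest.raises(ValueError):
            solve_intrinsic_rate(fec)

    def test_finite_rate(self, toy_r):
        assert finite_rate(0.0) == 1.0
        assert finite_rate(toy_r) == pytest.approx(np.exp(toy_r))

    def test_generation_time(self, toy_r):
        assert mean_generation_time(1.5, toy_r) == pytest.approx(
            np.log(1.5) / toy_r
        )
        # r ~ 0 limit: cohort generation time sum (x+1) phi / R0
        phi = np.array([0.0, 1.0, 0.0])
        assert mean_generation_time(1.0, 0.0, phi=phi) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            mean_generation_time(0.0, 0.1)

    def test_r0_consistency_identity(self):
        assert r0_consistency(90.91, 90, 150) == pytest.approx(54.546)
        assert r0_consistency(68.57, 83, 150) == pytest.approx(37.9421, abs=1e-4)
        assert r0_consistency(10.0, 0, 150) == 0.0
        with pytest.raises(ValueError):
            r0_consistency(1.0, 1, 0)

    def test_demographic_params_toy(self, toy_cohort, toy_r):
        p = demographic_params(toy_cohort)
        assert p.R0 == pytest.approx(1.5)
        assert p.r == pytest.approx(toy_r, abs=1e-9)
        assert p.lam == pytest.approx(np.exp(toy_r), abs=1e-9)
        assert (p.F, p.n_female, p.n) == (3.0, 1, 2)


class TestConditionalSurvival:
    def test_origin_at_female_adult(self, toy_cohort):
        cs = conditional_survival(toy_cohort, 1, "female_adult")
        assert cs.s_prime[1, 1] == 1.0
        assert cs.s_prime[2, 1] == 1.0  # the only occupant survives to age 2

    def test_origin_at_birth_recovers_lx(self, toy_cohort):
        surv = compute_survival_schedule(toy_cohort)
        cs = conditional_survival(toy_cohort, 0, 0)
        np.testing.assert_allclose(cs.s_prime.sum(axis=1), surv.l)

    def test_undefined_origin_raises(self, toy_cohort):
        with pytest.raises(CohortError):
            conditional_survival(toy_cohort, 2, "egg")  # s_2,egg = 0


class TestExpectancyAndValue:
    def test_toy_life_expectancy(self, toy_cohort):
        e = life_expectancy(toy_cohort).e
        assert e[0, 0] == pytest.approx(2.5)  # sum of l_x
        assert e[1, 1] == pytest.approx(2.0)
        assert np.isnan(e[2, 0])  # no egg survives to age 2

    def test_expectancy_at_birth_is_mean_days_alive(self, toy_cohort):
        e = life_expectancy(toy_cohort).e
        mean_days = np.mean([len(r.days) for r in toy_cohort.records])
        assert e[0, 0] == pytest.approx(mean_days, abs=1e-9)

    def test_final_day_expectancy_is_one(self, toy_cohort):
        e = life_expectancy(toy_cohort).e
        assert e[2, 1] == pytest.approx(1.0)

    def test_toy_reproductive_values(self, toy_cohort, toy_r):
        surv = compute_survival_schedule(toy_cohort)
        fec = compute_fecundity_schedules(toy_cohort, surv)
        v = reproductive_value(toy_cohort, fec, toy_r).v
        assert v[0, 0] == pytest.approx(np.exp(toy_r), abs=1e-9)  # v01 = lambda
        assert v[1, 1] == pytest.approx(2 + np.exp(-toy_r), abs=1e-9)
        assert v[1, 0] == 0.0  # ind2's path: no reproduction reachable

    def test_value_matches_through_cell_convention(self, toy_cohort, toy_r):
        # independent route: v_xj = exp(r(x+1))/s_xj * sum_i exp(-r(i+1))
        #                      * sum_y s''_iy f_iy with s'' = s_xj * s'
        surv = compute_survival_schedule(toy_cohort)
        fec = compute_fecundity_schedules(toy_cohort, surv)
        v = reproductive_value(toy_cohort, fec, toy_r).v
        A = surv.s.shape[0] - 1
        for x in range(A + 1):
            for j in range(surv.s.shape[1]):
                if surv.s[x, j] == 0:
                    continue
                sp = conditional_survival(toy_cohort, x, j).s_prime
                s_dd = surv.s[x, j] * sp
                total = sum(
                    np.exp(-toy_r * (i + 1)) * (s_dd[i] * fec.f[i]).sum()
                    for i in range(x, A + 1)
                )
                expected = np.exp(toy_r * (x + 1)) / surv.s[x, j] * total
                assert v[x, j] == pytest.approx(expected, abs=1e-9)


class TestIndividualStats:
    def test_toy_reproduction_stats(self, toy_cohort):
        rs = reproduction_stats(toy_cohort)
        row = rs.females.iloc[0]
        assert row["apop"] == 0 and row["tpop"] == 1
        assert row["oviposition_days"] == 2 and row["fecundity"] == 3
        assert rs.F == 3.0 and rs.female_longevity_mean == 2.0

    def test_no_females_reports_missing(self, toy_schema):
        c = Cohort(
            schema=toy_schema,
            records=[IndividualRecord("a", [("egg", 0), ("egg", 0)])],
        )
        rs = reproduction_stats(c)
        assert rs.n_female == 0 and np.isnan(rs.F)

    def test_tpop_minus_apop_is_emergence_age(self):
        c = simulate_cohort(table1_presets("batatas"), n=60, seed=2)
        f = reproduction_stats(c).females.dropna(subset=["first_egg_age"])
        assert (f["tpop"] - f["apop"] == f["emergence_age"]).all()

    def test_toy_stage_durations_exclude_noncompleters(self, toy_cohort):
        d = stage_duration_stats(toy_cohort)
        assert d.loc["egg", "n"] == 1 and d.loc["egg", "mean"] == 1.0

    def test_identical_durations_give_that_mean(self, toy_schema):
        c = Cohort(
            schema=toy_schema,
            records=[
                IndividualRecord(f"i{k}", [("egg", 0)] * 3 + [("female_adult", 0)])
                for k in range(4)
            ],
        )
        d = stage_duration_stats(c)
        assert d.loc["egg", "mean"] == 3.0 and d.loc["egg", "n"] == 4

    def test_synthetic_batatas_larval_duration_recovers_table_mean(self):
        c = simulate_cohort(table1_presets("batatas"), n=150, seed=7)
        d = stage_duration_stats(c)
        assert d.loc["larva", "mean"] == pytest.approx(37.08, abs=3 * 0.22)
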
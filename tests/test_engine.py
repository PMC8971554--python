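"""Microsimulation engine: cycle probabilities, trajectories, population runs."""

import math

import numpy as np
import pytest

from osteosim import DEN_ZOL, NO_TREATMENT, ZOL_MONO
from osteosim.economics import summarize_trajectory
from osteosim.engine import (IndividualState, annual_event_probabilities,
                             mortality_probability, run_strategy,
                             simulate_individual, simulate_population)
from osteosim.treatment import TreatmentStatus

from helpers import make_ps


def _state(ps, age=65, **kw):
    st = IndividualState(age=age, treatment=TreatmentStatus.start(NO_TREATMENT))
    for k, v in kw.items():
        setattr(st, k, v)
    return st


class TestAnnualEventProbabilities:
    def test_null_hazards_mean_certain_no_event(self):
        ps = make_ps()
        probs = annual_event_probabilities(ps, _state(ps))
        assert probs["none"] == 1.0
        assert all(probs[s] == 0.0 for s in ("hip", "clinical_vertebral",
                                             "wrist", "other"))

    def test_single_hazard_closed_form(self):
        ps = make_ps(incidence={"hip": 0.01, "clinical_vertebral": 0.0,
                                "wrist": 0.0, "other": 0.0})
        probs = annual_event_probabilities(ps, _state(ps))
        assert probs["hip"] == pytest.approx(-math.expm1(-0.01))
        assert probs["none"] == pytest.approx(math.exp(-0.01))

    def test_equal_hazards_split_equally(self):
        ps = make_ps(incidence={"hip": 0.02, "clinical_vertebral": 0.02,
                                "wrist": 0.0, "other": 0.0})
        probs = annual_event_probabilities(ps, _state(ps))
        assert probs["hip"] == pytest.approx(probs["clinical_vertebral"])
        total = sum(v for k, v in probs.items() if k != "none")
        assert total == pytest.approx(-math.expm1(-0.04))
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_hip_hazard_forced_zero_at_cap(self):
        ps = make_ps(incidence={"hip": 0.5, "clinical_vertebral": 0.0,
                                "wrist": 0.0, "other": 0.0})
        probs = annual_event_probabilities(ps, _state(ps, hip_count=2))
        assert probs["hip"] == 0.0
        assert probs["none"] == 1.0

    def test_age_outside_grid_errors(self):
        ps = make_ps(max_age=90)
        with pytest.raises(KeyError, match="incidence grid"):
            annual_event_probabilities(ps, _state(ps, age=95))


class TestMortalityProbability:
    def test_no_hip_history_is_background(self):
        ps = make_ps(mortality=0.02)
        assert mortality_probability(ps, _state(ps)) == 0.02

    def test_unit_excess_rr_is_background(self):
        ps = make_ps(mortality=0.02, short_rr=1.0, long_rr=1.0)
        st = _state(ps, hip_count=1, years_since_hip=0)
        assert mortality_probability(ps, st) == pytest.approx(0.02)

    def test_zero_attributable_fraction_is_background(self):
        ps = make_ps(mortality=0.02, short_rr=5.0, af=0.0)
        st = _state(ps, hip_count=1, years_since_hip=0)
        assert mortality_probability(ps, st) == pytest.approx(0.02)

    def test_short_term_formula(self):
        ps = make_ps(mortality=0.02, short_rr=3.0, af=0.25)
        st = _state(ps, hip_count=1, years_since_hip=0)
        assert mortality_probability(ps, st) == pytest.approx(0.03)

    def test_long_term_after_first_year_and_cap(self):
        ps = make_ps(mortality=0.02, short_rr=3.0, long_rr=2.0, af=0.25)
        st = _state(ps, hip_count=1, years_since_hip=4)
        assert mortality_probability(ps, st) == pytest.approx(0.02 * 1.25)
        ps2 = make_ps(mortality=0.9, short_rr=10.0, af=1.0)
        st2 = _state(ps2, hip_count=1, years_since_hip=0)
        assert mortality_probability(ps2, st2) == 1.0


class TestTrajectories:
    def test_certain_death_gives_one_cycle(self):
        ps = make_ps(mortality=1.0)
        recs = simulate_individual(ps, NO_TREATMENT, 65, np.random.default_rng(0))
        assert len(recs) == 1
        assert recs[0].event == "death"
        assert recs[0].utility == 0.0

    def test_null_process_runs_to_max_age(self):
        ps = make_ps(mortality=0.0, max_age=105)
        recs = simulate_individual(ps, NO_TREATMENT, 65, np.random.default_rng(0))
        assert len(recs) == 105 - 65 + 1
        assert all(r.event == "none" for r in recs)

    def test_hip_cap_under_stress_incidence(self):
        ps = make_ps(mortality=0.0,
                     incidence={"hip": 5.0, "clinical_vertebral": 0.0,
                                "wrist": 0.0, "other": 0.0})
        rng = np.random.default_rng(1)
        for _ in range(50):
            recs = simulate_individual(ps, NO_TREATMENT, 65, rng)
            assert sum(r.event == "hip" for r in recs) <= 2

    def test_event_log_csv(self, ps, tmp_path):
        from osteosim.engine import write_event_log
        recs = simulate_individual(ps, DEN_ZOL, 65, np.random.default_rng(9))
        path = tmp_path / "log.csv"
        write_event_log(recs, 65, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "cycle,age,event,cost,utility"
        assert len(lines) == len(recs) + 1

    def test_dead_accrue_nothing_and_length_bounded(self, ps):
        rng = np.random.default_rng(5)
        T = ps.analysis.max_age - 65 + 1
        for _ in range(30):
            recs = simulate_individual(ps, DEN_ZOL, 65, rng)
            assert len(recs) <= T


class TestPopulationRuns:
    def test_seeded_determinism(self, ps):
        a = run_strategy(ps, DEN_ZOL, 65, 500, 99)
        b = run_strategy(ps, DEN_ZOL, 65, 500, 99)
        assert a == b

    def test_scalar_and_vectorized_paths_identical(self, ps):
        """Two independent implementations of the same trajectory law."""
        n = 150
        rng = np.random.default_rng(42)
        scal = [summarize_trajectory(simulate_individual(ps, DEN_ZOL, 65, rng),
                                     ps.analysis.discount_rate_costs,
                                     ps.analysis.discount_rate_effects)
                for _ in range(n)]
        pop = simulate_population(ps, DEN_ZOL, 65, n,
                                  np.random.default_rng(42))
        assert np.array_equal(np.array([s[0] for s in scal]), pop.cost)
        assert np.array_equal(np.array([s[1] for s in scal]), pop.qalys)
        assert np.array_equal(np.array([s[2] for s in scal]), pop.fractures)

    def test_null_efficacy_with_crn_gives_identical_fractures(self):
        ps = make_ps(mortality=0.03, rr_den=1.0, rr_zol=1.0,
                     persistence=(0.8, 0.7, 0.6),
                     incidence={"hip": 0.01, "clinical_vertebral": 0.02,
                                "wrist": 0.005, "other": 0.01})
        pops = [simulate_population(ps, s, 65, 2000, np.random.default_rng(7))
                for s in (NO_TREATMENT, DEN_ZOL, ZOL_MONO)]
        assert np.array_equal(pops[0].fractures, pops[1].fractures)
        assert np.array_equal(pops[0].fractures, pops[2].fractures)

    def test_lower_rr_never_increases_fractures_elementwise(self):
        """Exact CRN coupling (no cap/mortality feedback confounds)."""
        kw = dict(mortality=0.03, persistence=(0.9, 0.8, 0.7), short_rr=1.0,
                  long_rr=1.0,
                  incidence={"hip": 0.0, "clinical_vertebral": 0.03,
                             "wrist": 0.01, "other": 0.02})
        weak = make_ps(rr_den=0.9, rr_zol=0.9, **kw)
        strong = make_ps(rr_den=0.5, rr_zol=0.5, **kw)
        pw = simulate_population(weak, DEN_ZOL, 65, 5000, np.random.default_rng(11))
        pstr = simulate_population(strong, DEN_ZOL, 65, 5000, np.random.default_rng(11))
        assert np.all(pstr.fractures <= pw.fractures)
        assert pstr.fractures.sum() < pw.fractures.sum()

    def test_mean_fractures_decrease_with_stronger_efficacy(self, ps):
        strong = ps.copy()
        for drug in strong.treatment_efficacy:
            for site, rr in strong.treatment_efficacy[drug].items():
                rr.point *= 0.6
                rr.low *= 0.6
        a = run_strategy(ps, DEN_ZOL, 65, 20000, 13)
        b = run_strategy(strong, DEN_ZOL, 65, 20000, 13)
        assert b.mean_fractures < a.mean_fractures

    def test_undiscounted_unit_utility_qalys_are_life_years(self):
        ps = make_ps(mortality=0.04, discount=0.0, baseline_utility=1.0,
                     fy_hip=1.0, fy_vert=1.0, sub_hip=1.0, sub_vert=1.0,
                     dis_wrist=0.0, dis_other=0.0, short_rr=1.0, long_rr=1.0,
                     incidence={"hip": 0.01, "clinical_vertebral": 0.02,
                                "wrist": 0.005, "other": 0.01})
        pop = simulate_population(ps, NO_TREATMENT, 65, 3000,
                                  np.random.default_rng(2))
        T = ps.analysis.max_age - 65 + 1
        assert np.array_equal(pop.qalys, np.round(pop.qalys))   # whole years
        assert pop.qalys.max() <= T

    def test_horizon_truncates_accrual_without_changing_draws(self, ps):
        full = simulate_population(ps, DEN_ZOL, 65, 1000, np.random.default_rng(4))
        trunc = simulate_population(ps, DEN_ZOL, 65, 1000,
                                    np.random.default_rng(4), horizon=10)
        assert np.all(trunc.qalys <= full.qalys)
        assert np.all(trunc.fractures <= full.fractures)
        assert np.array_equal(trunc.reached_max_age, full.reached_max_age)

    def test_invalid_inputs(self, ps):
        with pytest.raises(ValueError):
            run_strategy(ps, DEN_ZOL, 65, 0, 1)
        with pytest.raises(KeyError):
            run_strategy(ps, DEN_ZOL, 20, 10, 1)
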
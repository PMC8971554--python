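"""One-way scenarios, PSA sampling, and acceptability curves."""

import math

import numpy as np
import pytest

from osteosim import DEN_ZOL, ZOL_MONO, run_strategy
from osteosim.params import (OverrideItem, ParameterOverride, PsaDistribution,
                             to_dict, validate_parameter_set)
from osteosim.sensitivity import (DSAScenario, PSASample, ceac, psa_streams,
                                  run_one_way, run_psa, sample_psa_parameters,
                                  one_way_presets)
from osteosim.uncertainty import (beta_from_mean_sd, lognormal_from_bounds,
                                  sample_distribution)

EXPECTED_LABELS = [
    "No residual effect", "10-years time horizon",
    "DEN persistence rate 10% higher", "ZOL persistence rate 10% higher",
    "Discount rates: 0", "Discount rates: 0.05",
    "Fracture costs 30% higher", "Fracture costs 30% lower",
    "Excess mortality 50% higher", "Excess mortality 0%",
]


def test_scenario_presets_are_the_canonical_ten():
    assert [s.label for s in one_way_presets()] == EXPECTED_LABELS


def test_identity_scenario_reproduces_base_case(ps):
    scen = [DSAScenario("base", ParameterOverride("base", []))]
    df = run_one_way(ps, scen, DEN_ZOL, ZOL_MONO, 65, 1000, 21)
    ri = run_strategy(ps, DEN_ZOL, 65, 1000, 21)
    rc = run_strategy(ps, ZOL_MONO, 65, 1000, 21)
    row = df.iloc[0]
    assert row.cost_intervention == ri.mean_cost
    assert row.qalys_comparator == rc.mean_qalys
    assert row.delta_cost == pytest.approx(ri.mean_cost - rc.mean_cost)


def test_zero_discount_raises_per_strategy_qalys(ps):
    scen = [DSAScenario("base", ParameterOverride("base", [])),
            next(s for s in one_way_presets() if s.label == "Discount rates: 0")]
    df = run_one_way(ps, scen, DEN_ZOL, ZOL_MONO, 65, 2000, 22)
    base, r0 = df.iloc[0], df.iloc[1]
    assert r0.qalys_intervention > base.qalys_intervention
    assert r0.qalys_comparator > base.qalys_comparator


def test_removing_residual_effect_lowers_each_strategys_qalys(ps):
    scen = [DSAScenario("base", ParameterOverride("base", [])),
            next(s for s in one_way_presets() if s.label == "No residual effect")]
    df = run_one_way(ps, scen, DEN_ZOL, ZOL_MONO, 65, 5000, 23)
    base, nores = df.iloc[0], df.iloc[1]
    assert nores.qalys_intervention < base.qalys_intervention
    assert nores.qalys_comparator < base.qalys_comparator


def test_rows_satisfy_icer_identity(ps):
    df = run_one_way(ps, one_way_presets(), DEN_ZOL, ZOL_MONO, 65, 1000, 24)
    for _, row in df.iterrows():
        if row.icer_code == "ratio":
            assert row.icer * row.delta_qalys == pytest.approx(row.delta_cost,
                                                               rel=1e-9)


def test_override_error_carries_scenario_label(ps):
    bad = DSAScenario("broken knob", ParameterOverride(
        "broken knob", [OverrideItem("costs.nonexistent", scale=2.0)]))
    with pytest.raises(Exception, match="broken knob"):
        run_one_way(ps, [bad], DEN_ZOL, ZOL_MONO, 65, 50, 1)


def test_duplicate_labels_rejected(ps):
    s = DSAScenario("dup", ParameterOverride("dup", []))
    with pytest.raises(ValueError):
        run_one_way(ps, [s, s], DEN_ZOL, ZOL_MONO, 65, 50, 1)


class TestPSASampling:
    def test_empty_spec_returns_input_unchanged(self, ps):
        bare = ps.copy()
        bare.psa_spec = {}
        assert sample_psa_parameters(bare, np.random.default_rng(0)) is bare

    def test_sampled_sets_validate_and_differ(self, ps):
        rng = np.random.default_rng(1)
        drawn = sample_psa_parameters(ps, rng)
        assert validate_parameter_set(drawn) == []
        assert to_dict(drawn) != to_dict(ps)

    def test_beta_moment_matching(self):
        d = beta_from_mean_sd(0.84, 0.04)
        rng = np.random.default_rng(2)
        draws = np.array([sample_distribution(d, rng) for _ in range(10000)])
        assert abs(draws.mean() - 0.84) < 3 * 0.04 / math.sqrt(10000)
        assert np.all((draws > 0) & (draws < 1))

    def test_lognormal_bounds_envelope(self):
        """Fitted to 95% bounds (0.4, 0.9): nearly all draws in (0.3, 1.1)."""
        d = lognormal_from_bounds(0.6, 0.4, 0.9)
        rng = np.random.default_rng(3)
        draws = np.array([sample_distribution(d, rng) for _ in range(4000)])
        inside = np.mean((draws > 0.3) & (draws < 1.1))
        assert inside >= 0.95


class TestRunPSA:
    def test_seed_reproducibility(self, ps):
        a = run_psa(ps, [DEN_ZOL, ZOL_MONO], 80, 4, 300, 5)
        b = run_psa(ps, [DEN_ZOL, ZOL_MONO], 80, 4, 300, 5)
        assert a == b

    def test_zero_width_collapses_to_base_case(self, ps):
        frozen = ps.copy()
        frozen.psa_spec = {}
        for drug, site_map in ps.treatment_efficacy.items():
            for site, rr in site_map.items():
                frozen.psa_spec[f"treatment_efficacy.{drug}.{site}.point"] = \
                    PsaDistribution("beta", {"mean": rr.point, "sd": 0.0})
        samples = run_psa(frozen, [DEN_ZOL, ZOL_MONO], 80, 2, 400, 9)
        for j, s in enumerate(samples):
            sim_ss = psa_streams(9, j)[1]
            for strat in (DEN_ZOL, ZOL_MONO):
                ref = run_strategy(ps, strat, 80, 400, sim_ss)
                assert s.outcomes[strat.name] == (ref.mean_cost, ref.mean_qalys)


class TestCEAC:
    @staticmethod
    def _samples(pairs):
        return [PSASample(i, "x", {"I": (ci, qi), "C": (cc, qc)})
                for i, (ci, qi, cc, qc) in enumerate(pairs)]

    def test_probability_matches_brute_force_count(self, ps):
        samples = run_psa(ps, [DEN_ZOL, ZOL_MONO], 80, 30, 300, 7)
        grid = [0, 10504, 31512, 60000]
        points = ceac(samples, "DEN/ZOL", "ZOL mono", grid)
        for pt in points:
            count = sum(
                1 for s in samples
                if pt.wtp * (s.outcomes["DEN/ZOL"][1] - s.outcomes["ZOL mono"][1])
                - (s.outcomes["DEN/ZOL"][0] - s.outcomes["ZOL mono"][0]) > 0)
            assert pt.probability == count / len(samples)

    def test_dominant_samples_probability_one_everywhere(self):
        samples = self._samples([(50.0, 2.0, 100.0, 1.0)] * 10)
        for pt in ceac(samples, "I", "C", [0, 1000, 1e6]):
            assert pt.probability == 1.0

    def test_wtp_exactly_at_icer_counts_as_not_cost_effective(self):
        samples = self._samples([(200.0, 2.5, 100.0, 2.0)])  # ICER exactly 200
        (pt,) = ceac(samples, "I", "C", [200.0])
        assert pt.probability == 0.0

    def test_nondecreasing_in_wtp_when_all_gains_positive(self):
        rng = np.random.default_rng(4)
        pairs = [(100 + 50 * rng.random(), 1.0 + 0.01 * rng.random(), 100.0, 1.0)
                 for _ in range(50)]
        probs = [p.probability
                 for p in ceac(self._samples(pairs), "I", "C",
                               list(np.linspace(0, 20000, 21)))]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_degenerate_psa_gives_step_function_at_base_icer(self, ps):
        frozen = ps.copy()
        frozen.psa_spec = {"utilities.subsequent_multiplier.hip": PsaDistribution(
            "beta", {"mean": ps.utilities.subsequent_multiplier["hip"], "sd": 0.0})}
        samples = run_psa(frozen, [DEN_ZOL, ZOL_MONO], 80, 1, 2000, 13)
        (s,) = samples
        dc = s.outcomes["DEN/ZOL"][0] - s.outcomes["ZOL mono"][0]
        de = s.outcomes["DEN/ZOL"][1] - s.outcomes["ZOL mono"][1]
        icer = dc / de
        pts = ceac(samples, "DEN/ZOL", "ZOL mono",
                   [icer * 0.9, icer * 1.1])
        assert [p.probability for p in pts] == [0.0, 1.0]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ceac([], "I", "C", [1000.0])
        with pytest.raises(ValueError):
            ceac(self._samples([(1.0, 1.0, 0.0, 0.0)]), "I", "C", [])
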
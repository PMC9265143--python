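"""Deterministic/probabilistic sensitivity analyses and threshold search."""

import numpy as np
import pytest

import telestroke_cea as tcea
from telestroke_cea.config import ConfigError, ModelConfig, set_param
from telestroke_cea.economics import evaluate, net_monetary_benefit
from telestroke_cea.uncertainty import (
    DSASpec,
    ParamDist,
    PSADistributions,
    default_psa_distributions,
    draw_psa_config,
    per_person_program_cost,
    point_mass_distributions,
    run_one_way_dsa,
    run_psa,
    threshold_population,
    threshold_population_scan,
)


@pytest.fixture(scope="module")
def fast_cfg(base_cfg):
    """Short-horizon variant to keep repeated model runs cheap."""
    d = base_cfg.to_dict()
    d["settings"]["horizon_years"] = 5
    return ModelConfig.from_dict(d)


class TestOneWayDSA:
    def test_degenerate_spec_has_zero_range(self, fast_cfg):
        base = 40_689.0
        spec = DSASpec("costs.nursing_home", low=base, high=base, base=base)
        df = run_one_way_dsa(fast_cfg, [spec])
        assert df.loc[0, "nmb_range"] == 0.0

    def test_case_fatality_alternative_produces_finite_row(self, base_cfg):
        spec = DSASpec("transition.p_death_after_recur", low=0.11, high=0.1783, base=0.1783)
        df = run_one_way_dsa(base_cfg, [spec])
        assert np.isfinite(df.loc[0, "nmb_range"]) and df.loc[0, "nmb_range"] > 0

    def test_ordering_matches_independent_recompute(self, fast_cfg):
        specs = [
            DSASpec("costs.nursing_home", 32_551.2, 48_826.8, 40_689.0),
            DSASpec("utilities.mRS0", 0.6688, 1.0, 0.836),
            DSASpec("transition.p_recur_later", 0.01608, 0.02412, 0.0201),
        ]
        df = run_one_way_dsa(fast_cfg, specs)
        wtp = fast_cfg.settings.wtp
        ranges = {}
        for spec in specs:  # brute-force endpoint recompute
            nmb = [
                net_monetary_benefit(evaluate(set_param(fast_cfg, spec.path, v), "societal")[2], wtp)
                for v in (spec.low, spec.high)
            ]
            ranges[spec.path] = abs(nmb[1] - nmb[0])
        expected_order = sorted(ranges, key=ranges.get, reverse=True)
        assert list(df["parameter"]) == expected_order

    def test_unknown_path_rejected(self, fast_cfg):
        with pytest.raises(ConfigError):
            run_one_way_dsa(fast_cfg, [DSASpec("transition.nonexistent", 0.0, 1.0, 0.5)])

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ConfigError):
            DSASpec("costs.nursing_home", low=2.0, high=1.0, base=1.5)


class TestPSADraws:
    def test_point_mass_returns_config_unchanged(self, base_cfg):
        sampled = draw_psa_config(base_cfg, point_mass_distributions(base_cfg), seed=5)
        assert sampled == base_cfg

    def test_dirichlet_draw_lies_on_simplex(self, base_cfg):
        sampled = draw_psa_config(base_cfg, default_psa_distributions(base_cfg), seed=11)
        vec = sampled.baselines["intervention"].mrs_day365
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(vec >= 0)
        assert tcea.validate_config(sampled) == []

    def test_fixed_seed_reproducible(self, base_cfg):
        dists = default_psa_distributions(base_cfg)
        assert draw_psa_config(base_cfg, dists, seed=7) == draw_psa_config(base_cfg, dists, seed=7)

    def test_beta_sampler_matches_moments(self, base_cfg):
        dists = default_psa_distributions(base_cfg)
        entry = next(e for e in dists.entries if e.path == "transition.p_recur_year1")
        assert entry.family == "beta"
        a, b = entry.params
        mean = a / (a + b)
        assert mean == pytest.approx(0.0649, rel=1e-9)
        draws = np.random.default_rng(0).beta(a, b, size=10_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se


class TestRunPSA:
    def test_point_mass_pairs_equal_base_case(self, fast_cfg):
        _, _, base_ce = evaluate(fast_cfg, "societal")
        out = run_psa(fast_cfg, dists=point_mass_distributions(fast_cfg), n_draws=4, seed=2)
        assert np.all(out.draws[:, 0] == base_ce.delta_cost)
        assert np.all(out.draws[:, 1] == base_ce.delta_qaly)

    def test_seed_reproducibility(self, fast_cfg):
        a = run_psa(fast_cfg, n_draws=20, seed=9)
        b = run_psa(fast_cfg, n_draws=20, seed=9)
        assert np.array_equal(a.draws, b.draws)
        assert a.prob_dominant == b.prob_dominant
        assert a.ceac.equals(b.ceac)

    def test_ceac_bounded_and_consistent_with_dominance(self, fast_cfg):
        out = run_psa(fast_cfg, n_draws=50, seed=3)
        probs = out.ceac["probability"].to_numpy()
        assert np.all((probs >= 0) & (probs <= 1))
        assert 50_000.0 in set(out.ceac["wtp"])
        # at unbounded willingness-to-pay every dominant draw is cost-effective
        assert probs[-1] >= out.prob_dominant


class TestThreshold:
    def test_per_person_cost_sharing(self):
        assert per_person_program_cost(1_762_892.0, 67) == pytest.approx(26_311.82, abs=0.01)

    def test_bisection_equals_linear_scan(self, fast_cfg):
        # small implementation total so the threshold sits in scan range
        total = 2_000_000.0
        n_bis, per_person = threshold_population(fast_cfg, total, n_max=5_000)
        n_scan = threshold_population_scan(fast_cfg, total, n_max=5_000)
        assert n_bis == n_scan is not None
        assert per_person == pytest.approx(total / n_bis)

    def test_doubling_total_cost_never_lowers_threshold(self, fast_cfg):
        n1, _ = threshold_population(fast_cfg, 2_000_000.0, n_max=5_000)
        n2, _ = threshold_population(fast_cfg, 4_000_000.0, n_max=5_000)
        assert n2 >= n1

    def test_never_cost_effective_reports_no_threshold(self, base_cfg):
        # make the intervention strictly worse: same outcomes, positive program cost
        d = base_cfg.to_dict()
        d["baselines"]["intervention"] = dict(d["baselines"]["control"])
        cfg = ModelConfig.from_dict(d)
        n_min, per_person = threshold_population(cfg, 1_000_000.0, n_max=100)
        assert n_min is None and per_person is None
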
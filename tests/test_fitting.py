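import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidflux.engine import SimulationConfig, run
from acidflux.fitting import (
    FitResult,
    ModelVariant,
    Observation,
    aic,
    fit,
    generate_synthetic_observations,
    relative_noise_sd,
    rss,
    select_model,
)

QUICK = SimulationConfig(duration=48.0, dt=0.5, phosphate_gL=0.05)
RECOVERY = SimulationConfig(duration=144.0, dt=0.5, phosphate_gL=0.05)
RECOVERY_PH7 = SimulationConfig(duration=96.0, dt=0.5, initial_ph=7.0)
VARIABLES = ["biomass", "glucose", "phosphate", "citrate"]


@pytest.fixture(scope="module")
def quick_traj(toy_net_module, params_module):
    return run(toy_net_module, params_module, QUICK)


@pytest.fixture(scope="module")
def toy_net_module():
    from acidflux.network import make_toy_network

    return make_toy_network()


@pytest.fixture(scope="module")
def params_module():
    from acidflux.kinetics import KineticParameters

    return KineticParameters()


class TestObservation:
    def test_validation(self):
        with pytest.raises(ValueError):
            Observation(time_h=-1.0, variable="biomass", value=1.0)
        with pytest.raises(ValueError):
            Observation(time_h=1.0, variable="biomass", value=-1.0)
        with pytest.raises(ValueError, match="unknown variable"):
            Observation(time_h=1.0, variable="ethanol", value=1.0)


class TestRss:
    def test_zero_for_on_trajectory_points(self, quick_traj, toy_net_module, params_module):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK, {v: 0.0 for v in VARIABLES}, seed=0
        )
        assert rss(quick_traj, obs) == pytest.approx(0.0, abs=1e-16)

    def test_unit_offset_unit_weight(self, quick_traj):
        t = float(quick_traj.times[10])
        truth = quick_traj.variable("biomass")[10]
        obs = [Observation(time_h=t, variable="biomass", value=truth + 1.0)]
        assert rss(quick_traj, obs, weights={"biomass": 1.0}) == pytest.approx(1.0)

    def test_replicates_add(self, quick_traj):
        t = float(quick_traj.times[10])
        one = [Observation(t, "biomass", 0.0)]
        two = one * 2
        w = {"biomass": 1.0}
        assert rss(quick_traj, two, w) == pytest.approx(2 * rss(quick_traj, one, w))

    def test_outside_range_rejected(self, quick_traj):
        with pytest.raises(ValueError, match="outside simulated range"):
            rss(quick_traj, [Observation(1e4, "biomass", 1.0)])


class TestAic:
    def test_ln1_case(self):
        assert aic(2, 10, 10.0) == pytest.approx(4.0, abs=1e-15)

    def test_delta_two_per_parameter(self):
        assert aic(8, 50, 3.0) - aic(5, 50, 3.0) == pytest.approx(6.0, abs=1e-12)

    def test_algebraic_inversion(self):
        # choose RSS so that a k=8, n=84 fit scores exactly 300
        rss_value = 84.0 * math.exp((300.0 - 16.0) / 84.0)
        assert aic(8, 84, rss_value) == pytest.approx(300.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aic(1, 0, 1.0)
        with pytest.raises(ValueError):
            aic(1, 10, 0.0)

    @given(
        k=st.integers(min_value=0, max_value=50),
        n=st.integers(min_value=1, max_value=10000),
        rss_value=st.floats(min_value=1e-12, max_value=1e12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_closed_form(self, k, n, rss_value):
        assert aic(k, n, rss_value) == 2 * k + n * math.log(rss_value / n)


class TestFit:
    def test_empty_free_params_echoes_base(self, toy_net_module, params_module):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK, {"biomass": 0.0}, seed=0
        )
        result = fit(toy_net_module, params_module, {}, obs, QUICK)
        assert result.k == 0
        assert result.parameters == {}
        assert result.rss == pytest.approx(0.0, abs=1e-16)

    def test_unknown_parameter_rejected(self, toy_net_module, params_module):
        obs = [Observation(24.0, "biomass", 1.0)]
        with pytest.raises(ValueError, match="unknown fittable"):
            fit(toy_net_module, params_module, {"bogus": (0, 1)}, obs, QUICK)

    def test_inert_parameter_costs_exactly_two_aic(self, toy_net_module, params_module):
        # no xylose in the run, so the xylose Vmax has zero influence
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK,
            {"biomass": 0.001, "glucose": 0.01}, seed=1,
        )
        base = fit(toy_net_module, params_module, {}, obs, QUICK)
        inert = fit(
            toy_net_module, params_module, {"v_X2_max": (0.05, 1.0)}, obs, QUICK,
            n_starts=1, max_evaluations=20,
        )
        assert inert.rss == pytest.approx(base.rss, rel=1e-12)
        assert inert.aic - base.aic == pytest.approx(2.0, abs=1e-9)

    def test_invariant_to_observation_order(self, toy_net_module, params_module):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK,
            {"biomass": 0.01, "phosphate": 0.001}, seed=2,
        )
        shuffled = obs.copy()
        random.Random(99).shuffle(shuffled)
        a = fit(toy_net_module, params_module, {"v_Pe_max": (0.016, 0.4)}, obs,
                QUICK, seed=5, n_starts=1, max_evaluations=25)
        b = fit(toy_net_module, params_module, {"v_Pe_max": (0.016, 0.4)}, shuffled,
                QUICK, seed=5, n_starts=1, max_evaluations=25)
        assert a.parameters == b.parameters
        assert a.rss == pytest.approx(b.rss, rel=1e-12)

    def test_deterministic_given_seed(self, toy_net_module, params_module):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK, {"phosphate": 0.002}, seed=3
        )
        kwargs = dict(seed=7, n_starts=2, max_evaluations=30)
        a = fit(toy_net_module, params_module, {"K_Pe": (0.007, 0.17)}, obs, QUICK, **kwargs)
        b = fit(toy_net_module, params_module, {"K_Pe": (0.007, 0.17)}, obs, QUICK, **kwargs)
        assert a.parameters == b.parameters

    @pytest.mark.parametrize(
        "name,truth,config,variables",
        [
            ("v_Pe_max", 0.08, RECOVERY, VARIABLES),
            ("K_Pe", 0.0333, RECOVERY, VARIABLES),
            ("v_CIT", 0.12, RECOVERY, VARIABLES),
            ("GOX_conc", 0.1, RECOVERY_PH7, VARIABLES + ["gluconate"]),
        ],
    )
    def test_noiseless_recovery_within_one_percent(
        self, toy_net_module, params_module, name, truth, config, variables
    ):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, config,
            {v: 0.0 for v in variables}, seed=0, sample_every_h=12.0,
        )
        result = fit(
            toy_net_module, params_module, {name: (0.2 * truth, 5 * truth)},
            obs, config, seed=0, n_starts=1, max_evaluations=120,
        )
        assert result.parameters[name] == pytest.approx(truth, rel=0.01)


class TestSyntheticObservations:
    def test_zero_noise_on_trajectory(self, toy_net_module, params_module, quick_traj):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK, {"glucose": 0.0}, seed=0
        )
        times = quick_traj.times
        series = quick_traj.variable("glucose")
        for o in obs:
            assert o.value == pytest.approx(float(np.interp(o.time_h, times, series)))

    def test_seed_reproducibility(self, toy_net_module, params_module):
        kwargs = dict(noise_sd={"biomass": 0.1}, seed=11)
        a = generate_synthetic_observations(toy_net_module, params_module, QUICK, **kwargs)
        b = generate_synthetic_observations(toy_net_module, params_module, QUICK, **kwargs)
        assert [(o.time_h, o.value) for o in a] == [(o.time_h, o.value) for o in b]

    def test_count_by_construction(self, toy_net_module, params_module):
        # 18 h offset + 150 h duration -> day samples 24,48,...,168: 7 days
        config = SimulationConfig(duration=150.0, dt=0.5, phosphate_gL=0.05)
        obs = generate_synthetic_observations(
            toy_net_module, params_module, config,
            {"biomass": 0.0, "glucose": 0.0, "citrate": 0.0}, seed=0,
        )
        assert len(obs) == 7 * 3

    def test_values_floored_at_zero(self, toy_net_module, params_module):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK, {"citrate": 50.0}, seed=4
        )
        assert all(o.value >= 0.0 for o in obs)

    def test_negative_noise_rejected(self, toy_net_module, params_module):
        with pytest.raises(ValueError):
            generate_synthetic_observations(
                toy_net_module, params_module, QUICK, {"biomass": -1.0}, seed=0
            )


class TestSelectModel:
    def test_needs_two_candidates(self, toy_net_module, params_module):
        obs = [Observation(24.0, "biomass", 1.0)]
        with pytest.raises(ValueError):
            select_model([ModelVariant("only")], toy_net_module, params_module,
                         obs, QUICK)

    def test_identical_variants_tie_stably(self, toy_net_module, params_module):
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK, {"biomass": 0.01}, seed=0
        )
        candidates = [ModelVariant("first"), ModelVariant("second")]
        ranking = select_model(candidates, toy_net_module, params_module, obs, QUICK)
        assert [r.variant for r in ranking] == ["first", "second"]
        assert ranking[0].aic == ranking[1].aic

    def test_nested_variant_bookkeeping(self, toy_net_module, params_module):
        # nested ladder: 5 base kinetic parameters, then +nucleic acid,
        # +phospholipid, +both, +both-and-citrate-cap => k = 5,6,6,7,8
        obs = generate_synthetic_observations(
            toy_net_module, params_module, QUICK, {"biomass": 0.02}, seed=0
        )
        base5 = {
            "v_Pe_max": (0.02, 0.4), "K_Pe": (0.01, 0.1), "v_P_max": (2e-4, 4e-3),
            "K_P": (0.02, 0.4), "GOX_conc": (0.02, 0.5),
        }
        nucleic = {"nucleic_acid_scale": (0.5, 2.0)}
        lipid = {"phospholipid_scale": (0.5, 2.0)}
        cap = {"v_CIT": (0.024, 0.6)}
        candidates = [
            ModelVariant("none", base5),
            ModelVariant("nucleic", {**base5, **nucleic}),
            ModelVariant("phospholipid", {**base5, **lipid}),
            ModelVariant("both", {**base5, **nucleic, **lipid}),
            ModelVariant("both+cap", {**base5, **nucleic, **lipid, **cap}),
        ]
        ranking = select_model(
            candidates, toy_net_module, params_module, obs, QUICK,
            n_starts=1, max_evaluations=10,
        )
        ks = {r.variant: r.k for r in ranking}
        assert ks == {"none": 5, "nucleic": 6, "phospholipid": 6, "both": 7,
                      "both+cap": 8}
        aics = [r.aic for r in ranking]
        assert aics == sorted(aics)

    def test_recovers_generating_cap_variant(self, toy_net_module, params_module):
        sd = relative_noise_sd(toy_net_module, params_module, RECOVERY, VARIABLES, 0.02)
        obs = generate_synthetic_observations(
            toy_net_module, params_module, RECOVERY, sd, seed=42
        )
        candidates = [
            ModelVariant("no_cap", overrides={"v_CIT": 1000.0}),
            ModelVariant("with_cap", free_params={"v_CIT": (0.024, 0.6)}),
        ]
        ranking = select_model(
            candidates, toy_net_module, params_module, obs, RECOVERY,
            seed=42, n_starts=1, max_evaluations=60,
        )
        assert ranking[0].variant == "with_cap"
        assert ranking[0].aic < ranking[1].aic
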
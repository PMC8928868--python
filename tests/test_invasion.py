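"""Multi-strain dynamics, invasion fitness, ESS, phase-dependent invasion."""

import numpy as np
import pytest

from phenocycle import (
    ModelParams,
    SeasonState,
    StrainTraits,
    MultiStrainState,
    EquilibriumError,
    within_season_multistrain,
    multistrain_season_map,
    invasion_fitness,
    selection_gradient,
    ess_tau,
    phase_dependent_invasion,
    resident_environment,
    end_of_season,
    endemic_fixed_point,
    parasite_free_fixed_point,
)

STABLE_TAU = 3.5  # outside the cycling window at T=4, t_l=1


@pytest.fixture(scope="module")
def stable_params(ref_params):
    return ref_params.replace(tau=STABLE_TAU)


@pytest.fixture(scope="module")
def stable_env(stable_params):
    return endemic_fixed_point(stable_params)


class TestMultiStrain:
    def test_single_strain_reduces_to_core_solver(self, ref_params, ref_state):
        state = MultiStrainState(
            ref_state.s_hat, [(StrainTraits.from_params(ref_params), ref_state.v_hat)]
        )
        s_multi, v2_multi = within_season_multistrain(ref_params, state)
        s_core, v2_core = end_of_season(ref_params, ref_state)
        assert s_multi == pytest.approx(s_core, rel=1e-10)
        assert v2_multi[0] == pytest.approx(v2_core, rel=1e-10)

    def test_identical_strains_split_additively(self, ref_params, ref_state):
        tr = StrainTraits.from_params(ref_params)
        x = 0.3 * ref_state.v_hat
        split = MultiStrainState(
            ref_state.s_hat, [(tr, x), (StrainTraits.from_params(ref_params), ref_state.v_hat - x)]
        )
        s_split, v2_split = within_season_multistrain(ref_params, split)
        s_one, v2_one = end_of_season(ref_params, ref_state)
        assert s_split == pytest.approx(s_one, rel=1e-10)
        assert sum(v2_split) == pytest.approx(v2_one, rel=1e-10)

    def test_tau_beyond_season_yields_no_progeny(self, ref_params, ref_state):
        state = MultiStrainState(
            ref_state.s_hat,
            [(StrainTraits.from_params(ref_params, tau_m=ref_params.T + 0.5), ref_state.v_hat)],
        )
        _, v2 = within_season_multistrain(ref_params, state)
        assert v2[0] == 0.0

    def test_map_prunes_strains_below_extinction_threshold(self, stable_params, stable_env):
        weak = StrainTraits.from_params(stable_params, tau_m=3.95)  # nearly no release
        state = MultiStrainState(
            stable_env.s_hat,
            [(StrainTraits.from_params(stable_params), stable_env.v_hat), (weak, 5.0)],
        )
        nxt = multistrain_season_map(stable_params, state)
        assert len(nxt.strains) == 1
        assert nxt.strains[0][0].tau_m == STABLE_TAU


class TestInvasionFitness:
    def test_neutral_mutant_has_unit_fitness(self, stable_params, stable_env):
        f = invasion_fitness(stable_env, StrainTraits.from_params(stable_params), stable_params)
        assert f == pytest.approx(1.0, abs=1e-3)

    def test_mutant_at_resident_equilibrium_grows_by_factor_one(
        self, stable_params, stable_env
    ):
        # simulation route: a single mutant particle with resident traits
        state = MultiStrainState(
            stable_env.s_hat,
            [
                (StrainTraits.from_params(stable_params), stable_env.v_hat),
                (StrainTraits.from_params(stable_params), 1.0),
            ],
        )
        _, v2 = within_season_multistrain(stable_params, state)
        assert v2[1] == pytest.approx(1.0, abs=1e-3)

    def test_tau_beyond_season_has_zero_fitness(self, stable_params, stable_env):
        mut = StrainTraits.from_params(stable_params, tau_m=stable_params.T + 1.0)
        assert invasion_fitness(stable_env, mut, stable_params) == 0.0

    @pytest.mark.parametrize("tau_m", [2.0, 2.6, 2.9, 3.0, 3.2, 3.7])
    def test_quadrature_matches_multistrain_simulator(self, stable_params, stable_env, tau_m):
        """The closed-form quadrature and the two-strain simulator are two
        independent computations of the mutant's seasonal growth."""
        mut = StrainTraits.from_params(stable_params, tau_m=tau_m)
        f_quad = invasion_fitness(stable_env, mut, stable_params, check=False)
        state = MultiStrainState(
            stable_env.s_hat,
            [(StrainTraits.from_params(stable_params), stable_env.v_hat), (mut, 1.0)],
        )
        _, v2 = within_season_multistrain(stable_params, state)
        assert f_quad == pytest.approx(v2[1], rel=1e-3)

    def test_continuity_at_emergence_regime_boundary(self, stable_params, stable_env):
        b = stable_params.T - stable_params.t_l
        lo = invasion_fitness(
            stable_env, StrainTraits.from_params(stable_params, tau_m=b - 1e-6),
            stable_params, check=False,
        )
        hi = invasion_fitness(
            stable_env, StrainTraits.from_params(stable_params, tau_m=b + 1e-6),
            stable_params, check=False,
        )
        assert hi == pytest.approx(lo, rel=1e-4)

    def test_rejects_non_equilibrium_resident(self, ref_params):
        with pytest.raises(EquilibriumError, match="cycling"):
            invasion_fitness(
                SeasonState(1e4, 1e4), StrainTraits.from_params(ref_params), ref_params
            )


class TestSelectionAndESS:
    def test_gradient_points_toward_optimum(self, ref_params):
        # tau* ~ 2.98 at T=4, t_l=1: selection is directional on either side
        assert selection_gradient(ref_params, 2.6) > 0
        assert selection_gradient(ref_params, 3.4) < 0

    def test_ess_lies_inside_cycling_window(self, ref_params):
        tau_star = ess_tau(ref_params)
        assert 2.75 < tau_star < 3.26

    def test_fitness_profile_concave_at_ess(self, ref_params):
        tau_star = ess_tau(ref_params)
        p = ref_params.replace(tau=tau_star)
        env = resident_environment(p)
        f = lambda tm: invasion_fitness(
            env, StrainTraits.from_params(p, tau_m=tm), p, check=False
        )
        h = 0.05
        assert f(tau_star + h) + f(tau_star - h) - 2 * f(tau_star) < 0

    def test_more_synchronous_emergence_delays_optimal_kill_time(self, ref_params):
        late = ess_tau(ref_params.replace(t_l=0.5))
        base = ess_tau(ref_params)
        assert late > base

    def test_constant_cohort_environment_has_similar_optimum(self, ref_params):
        hc = parasite_free_fixed_point(ref_params).s_hat
        tau_star = ess_tau(ref_params, host_constant=hc)
        assert 2.75 < tau_star < 3.26


@pytest.fixture(scope="module")
def sweep(ref_params):
    return phase_dependent_invasion(
        ref_params, resident_tau=2.8, mutant_tau=2.81,
        intro_seasons=range(800, 812), horizon=250,
    )


class TestPhaseDependentInvasion:
    def test_both_outcomes_occur_within_one_sweep(self, sweep):
        outcomes = {r.outcome for r in sweep}
        assert outcomes == {"invaded", "extinct"}

    def test_invasion_happens_at_low_resident_density(self, sweep):
        invaded = [r.v_hat_at_intro for r in sweep if r.outcome == "invaded"]
        extinct = [r.v_hat_at_intro for r in sweep if r.outcome == "extinct"]
        assert max(invaded) < np.median(extinct)

    def test_neutral_mutant_never_invades(self, ref_params):
        res = phase_dependent_invasion(
            ref_params, resident_tau=2.8, mutant_tau=2.8,
            intro_seasons=range(800, 806), horizon=150,
        )
        assert all(r.outcome == "extinct" for r in res)
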
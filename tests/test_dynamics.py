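"""Season-map iteration, attractor classification, stability analysis."""

import numpy as np
import pytest

from phenocycle import (
    ModelParams,
    SeasonState,
    iterate_seasons,
    classify_dynamics,
    bifurcation_scan,
    phase_boundary,
    parasite_free_fixed_point,
    endemic_fixed_point,
    map_jacobian_stability,
)
from phenocycle.dynamics import MultiSeasonSeries, FixedPointError


class TestIteration:
    def test_parasite_free_run_stays_parasite_free(self, ref_params):
        series = iterate_seasons(ref_params, SeasonState(1e4, 0.0), 300)
        assert np.all(series.v_hat_series == 0.0)
        # converges to the host-only fixed point
        fp = parasite_free_fixed_point(ref_params)
        assert series.s_hat_series[-1] == pytest.approx(fp.s_hat, rel=1e-6)

    def test_extinction_threshold_is_absorbing(self, ref_params):
        # a parasite inoculum too small to persist is zeroed and stays zero
        p = ref_params.replace(tau=3.9)  # near-zero progeny release
        series = iterate_seasons(p, SeasonState(1e4, 1e2), 200)
        assert series.v_hat_series[-1] == 0.0
        zero_from = np.nonzero(series.v_hat_series == 0.0)[0][0]
        assert np.all(series.v_hat_series[zero_from:] == 0.0)

    def test_cycling_run_oscillates(self, cycling_series):
        w = cycling_series.v_hat_series[801:]
        assert (w.max() - w.min()) / w.mean() > 0.1

    def test_high_tau_converges_to_fixed_point(self, ref_params):
        series = iterate_seasons(ref_params.replace(tau=3.5), SeasonState(1e4, 1e2), 900)
        c = classify_dynamics(series)
        assert c.label == "endemic_equilibrium"


class TestClassification:
    def test_constant_series_is_equilibrium(self, ref_params):
        series = MultiSeasonSeries(
            params=ref_params,
            initial=SeasonState(10.0, 5.0),
            s_hat_series=np.full(901, 10.0),
            v_hat_series=np.full(901, 5.0),
        )
        c = classify_dynamics(series)
        assert c.label == "endemic_equilibrium"
        assert c.relative_amplitude == 0.0

    def test_cycling_classification_with_period_and_lag(self, cycling_series):
        c = classify_dynamics(cycling_series)
        assert c.label == "cycling"
        assert c.period_estimate >= 4.0
        assert 2.0 <= c.host_parasite_peak_lag <= 3.0

    def test_classification_insensitive_to_initial_condition(self, ref_params):
        # an order of magnitude around the default in each coordinate
        # (inocula that cannot clear the unit extinction threshold on the
        # initial transient are genuinely parasite-free, not tested here)
        labels = set()
        for s0, v0 in [(1e4, 1e2), (1e5, 1e3), (1e4, 1e3), (1e5, 1e2), (3e4, 3e2)]:
            series = iterate_seasons(ref_params, SeasonState(s0, v0), 900)
            labels.add(classify_dynamics(series).label)
        assert labels == {"cycling"}

    def test_classification_invariant_to_longer_burn_in(self, ref_params):
        series = iterate_seasons(ref_params, SeasonState(1e4, 1e2), 1700)
        assert classify_dynamics(series, 800, 100).label == "cycling"
        assert classify_dynamics(series, 1600, 100).label == "cycling"
        series2 = iterate_seasons(ref_params.replace(tau=3.5), SeasonState(1e4, 1e2), 1700)
        assert classify_dynamics(series2, 800, 100).label == "endemic_equilibrium"
        assert classify_dynamics(series2, 1600, 100).label == "endemic_equilibrium"

    def test_window_validation(self, cycling_series):
        with pytest.raises(ValueError):
            classify_dynamics(cycling_series, burn_in=850, window=100)


class TestBifurcationScan:
    def test_non_cycling_tau_outside_window(self, ref_params):
        scan = bifurcation_scan(ref_params, [2.6, 3.0, 3.4], burn_in=800, window=100)
        assert scan.labels == ["endemic_equilibrium", "cycling", "endemic_equilibrium"]

    def test_near_season_length_tau_never_cycles(self, ref_params):
        scan = bifurcation_scan(ref_params, [3.9], burn_in=400, window=100)
        assert scan.labels[0] in ("parasite_free", "endemic_equilibrium")

    def test_empty_grid_rejected(self, ref_params):
        with pytest.raises(ValueError):
            bifurcation_scan(ref_params, [])


class TestFixedPointsAndStability:
    def test_endemic_fixed_point_is_fixed(self, ref_params):
        from phenocycle import season_map

        fp = endemic_fixed_point(ref_params.replace(tau=3.5))
        nxt = season_map(ref_params.replace(tau=3.5), fp)
        assert nxt.s_hat == pytest.approx(fp.s_hat, rel=1e-8)
        assert nxt.v_hat == pytest.approx(fp.v_hat, rel=1e-8)

    def test_stable_regime_has_modulus_below_one(self, ref_params):
        p = ref_params.replace(tau=3.5)
        eig = map_jacobian_stability(p, endemic_fixed_point(p))
        assert np.max(np.abs(eig)) < 1.0

    def test_cycling_regime_has_modulus_above_one(self, ref_params):
        p = ref_params.replace(tau=3.0)
        eig = map_jacobian_stability(p, endemic_fixed_point(p))
        assert np.max(np.abs(eig)) > 1.0

    def test_neimark_sacker_pair_is_complex_at_onset(self, ref_params):
        # just inside the cycling window the unstable pair is complex conjugate
        p = ref_params.replace(tau=2.85)
        eig = map_jacobian_stability(p, endemic_fixed_point(p))
        assert abs(eig[0].imag) > 0
        assert eig[0] == pytest.approx(np.conj(eig[1]))

    def test_modulus_crossing_matches_amplitude_boundary(self, ref_params):
        # eigenvalue modulus crosses 1 between tau=2.7 (stable) and 2.8 (cycling)
        mods = {}
        for tau in (2.7, 2.8):
            p = ref_params.replace(tau=tau)
            mods[tau] = np.max(np.abs(map_jacobian_stability(p, endemic_fixed_point(p))))
        assert mods[2.7] < 1.0 < mods[2.8]

    def test_parasite_free_point_unstable_under_fit_parasite(self, ref_params):
        fp = parasite_free_fixed_point(ref_params)
        eig = map_jacobian_stability(ref_params, fp)
        assert np.max(np.abs(eig)) > 1.0

    def test_jacobian_requires_fixed_point(self, ref_params):
        with pytest.raises(FixedPointError):
            map_jacobian_stability(ref_params, SeasonState(123.0, 456.0))


class TestDirectionalEffects:
    """Single-parameter displacements from a cycling reference point.

    Longer seasons, longer emergence windows, higher host mortality, and
    faster environmental decay all suppress cycling; stronger transmission,
    larger burst size, and higher host fecundity preserve it.
    """

    REF = dict(T=4.0, t_l=1.0, tau=3.0)

    def _label(self, **changes):
        p = ModelParams(**{**self.REF, **changes})
        series = iterate_seasons(p, SeasonState(1e4, 1e2), 900)
        return classify_dynamics(series).label

    def test_reference_point_cycles(self):
        assert self._label() == "cycling"

    @pytest.mark.parametrize(
        "changes", [dict(T=4.5), dict(t_l=2.0), dict(mu=0.4), dict(delta=2.6)]
    )
    def test_suppressing_directions(self, changes):
        assert self._label(**changes) == "endemic_equilibrium"

    @pytest.mark.parametrize(
        "changes", [dict(alpha=5e-7), dict(beta=300.0), dict(sigma=750.0)]
    )
    def test_promoting_directions(self, changes):
        assert self._label(**changes) == "cycling"


class TestPhaseBoundary:
    def test_short_season_cycles_long_season_stable(self, ref_params):
        from phenocycle import ess_tau

        provider = lambda T, t_l: ess_tau(ref_params.replace(T=T, t_l=t_l))
        grid = phase_boundary([4.0, 6.0], [1.0], ref_params, provider)
        assert grid[0, 0] == "cycling"
        assert grid[1, 0] == "stable"

    def test_failed_cells_marked_undetermined(self, ref_params):
        def provider(T, t_l):
            raise RuntimeError("no ESS")

        grid = phase_boundary([4.0], [1.0, 2.0], ref_params, provider)
        assert set(grid.ravel()) == {"undetermined"}

    def test_invalid_cells_when_emergence_exceeds_season(self, ref_params):
        grid = phase_boundary([2.0], [3.0], ref_params, lambda T, t_l: 1.0)
        assert grid[0, 0] == "invalid"
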
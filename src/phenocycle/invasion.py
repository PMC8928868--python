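"""Mutant invasion dynamics, invasion fitness, and the ESS virulence solver.

A rare mutant parasite introduced at unit density into a resident-at-
equilibrium environment invades iff its end-of-season progeny density
``v2m(T)`` is at least the single particle it started from.  ``v2m(T)`` is
available two independent ways here:

* :func:`invasion_fitness` evaluates the closed-form expression by nested
  adaptive Gauss-Kronrod quadrature (the host density under the combined
  resident + single-mutant-particle force of infection, integrated against
  the mutant's delayed-release kernel); the expression changes analytic form
  at ``tau_m = T - t_l`` (whether the release integral ends inside the host
  emergence window), which the quadrature handles as a panel boundary, so the
  value is continuous there;
* :func:`within_season_multistrain` runs the full multi-strain season solver
  (shared panel quadrature engine) with the mutant as a second strain.

The agreement of the two routes is a core correctness property of the
package.  The ESS ``tau*`` is the virulence at which the selection gradient
(finite difference of invasion fitness in ``tau_m`` at the resident value)
vanishes with negative curvature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.integrate
import scipy.optimize

from .params import ModelParams, SeasonState
from .season import solve_season, season_map, host_recruitment
from .dynamics import (
    endemic_fixed_point,
    iterate_seasons,
    FixedPointError,
    DEFAULT_INITIAL,
    EXTINCTION_THRESHOLD,
)

__all__ = [
    "StrainTraits",
    "MultiStrainState",
    "EquilibriumError",
    "within_season_multistrain",
    "multistrain_season_map",
    "invasion_fitness",
    "selection_gradient",
    "ess_tau",
    "phase_dependent_invasion",
    "resident_environment",
]


class EquilibriumError(RuntimeError):
    """The supplied resident state is not an equilibrium of the season map."""


@dataclass(frozen=True)
class StrainTraits:
    """Trait set of one parasite strain (host parameters are shared)."""

    alpha_m: float
    beta_m: float
    delta_m: float
    tau_m: float

    def __post_init__(self) -> None:
        for name in ("alpha_m", "beta_m", "delta_m", "tau_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_params(cls, params: ModelParams, tau_m: float | None = None) -> "StrainTraits":
        """Resident traits, optionally with a substituted virulence delay."""
        return cls(
            alpha_m=params.alpha,
            beta_m=params.beta,
            delta_m=params.delta,
            tau_m=params.tau if tau_m is None else tau_m,
        )


@dataclass
class MultiStrainState:
    """Host cohort plus any number of parasite strains at a season start."""

    s_hat: float
    strains: list[tuple[StrainTraits, float]]  # (traits, v_hat)

    def __post_init__(self) -> None:
        if self.s_hat < 0:
            raise ValueError("s_hat must be >= 0")
        for _, v in self.strains:
            if v < 0:
                raise ValueError("strain densities must be >= 0")


def within_season_multistrain(
    params: ModelParams, state: MultiStrainState
) -> tuple[float, list[float]]:
    """End-of-season ``(s(T), [v2_i(T)])`` with all strains depleting the host.

    Each strain's free parasites decay at its own ``delta_i``; its progeny
    release uses its own ``tau_i``, ``beta_i`` and survival factor
    ``exp(-mu tau_i)``; the strains interact only through the shared host.
    """
    p = params
    strain_spec = [(tr.alpha_m, v, tr.delta_m) for tr, v in state.strains]
    a_times = sorted({p.T - tr.tau_m for tr, _ in state.strains if tr.tau_m < p.T})
    s_T, a_vals = solve_season(
        state.s_hat, p.mu, p.T, p.t_l, strain_spec, s_times=[p.T], a_times=a_times
    )
    a_lookup = dict(zip(a_times, a_vals))
    v2 = []
    for tr, v_hat in state.strains:
        if tr.tau_m >= p.T or v_hat == 0.0:
            v2.append(0.0)
            continue
        fac = (
            tr.alpha_m
            * tr.beta_m
            * np.exp(-p.mu * tr.tau_m)
            * np.exp(-tr.delta_m * (p.T - tr.tau_m))
        )
        v2.append(float(fac * v_hat * a_lookup[p.T - tr.tau_m]))
    return float(s_T[0]), v2


def multistrain_season_map(
    params: ModelParams,
    state: MultiStrainState,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    host_constant: float | None = None,
) -> MultiStrainState:
    """One between-season step of the multi-strain system.

    Strains whose next-season density falls below ``extinction_threshold``
    are pruned.  With ``host_constant`` set, the emerging cohort is held fixed
    at that value (demographic feedback disabled) instead of following
    Beverton-Holt recruitment.
    """
    s_T, v2 = within_season_multistrain(params, state)
    s_next = host_constant if host_constant is not None else host_recruitment(s_T, params)
    survivors = [
        (tr, v) for (tr, _), v in zip(state.strains, v2) if v >= extinction_threshold
    ]
    return MultiStrainState(s_hat=float(s_next), strains=survivors)


# ---------------------------------------------------------------------------
# invasion fitness by nested adaptive quadrature (independent of solve_season)


def _check_equilibrium(
    resident_env: SeasonState, params: ModelParams, host_constant: float | None, rtol: float = 1e-6
) -> None:
    st = season_map(params, resident_env)
    s_next = host_constant if host_constant is not None else st.s_hat
    ok_s = abs(s_next - resident_env.s_hat) <= rtol * max(resident_env.s_hat, 1.0)
    ok_v = abs(st.v_hat - resident_env.v_hat) <= rtol * max(resident_env.v_hat, 1.0)
    if not (ok_s and ok_v):
        raise EquilibriumError(
            "resident state is not an equilibrium of the season map "
            "(cycling regime; use simulation)"
        )


def invasion_fitness(
    resident_env: SeasonState,
    mutant: StrainTraits,
    params: ModelParams,
    host_constant: float | None = None,
    check: bool = True,
    epsabs: float = 1e-10,
    epsrel: float = 1e-8,
) -> float:
    """End-of-season progeny ``v2m(T)`` of one mutant particle (``v1m(0)=1``).

    ``resident_env`` must be an equilibrium ``(s_hat*, v_hat*)``; the host
    dynamics include both the resident force of infection and the (small)
    term from the mutant particle itself.  Invasion requires a value >= 1.
    """
    p = params
    if check:
        _check_equilibrium(resident_env, p, host_constant)
    if mutant.tau_m >= p.T:
        return 0.0
    s_hat, v_hat = resident_env.s_hat, resident_env.v_hat
    am, dm = mutant.alpha_m, mutant.delta_m
    a, d = p.alpha, p.delta

    def phi(u: float) -> float:
        out = p.mu * u + (am / dm) * (1.0 - np.exp(-dm * u))
        if v_hat > 0:
            out += (a * v_hat / d) * (1.0 - np.exp(-d * u))
        return out

    if p.t_l > 0.0:

        def s_of(y: float) -> float:
            if y <= 0.0:
                return 0.0
            phy = phi(y)
            val, _ = scipy.integrate.quad(
                lambda u: np.exp(phi(u) - phy), 0.0, min(y, p.t_l),
                epsabs=epsabs, epsrel=epsrel, limit=200,
            )
            return s_hat / p.t_l * val

    else:

        def s_of(y: float) -> float:
            return s_hat * np.exp(-phi(y))

    t_end = p.T - mutant.tau_m
    kink = [p.t_l] if 0.0 < p.t_l < t_end else []
    A, _ = scipy.integrate.quad(
        s_of, 0.0, t_end, points=kink or None, epsabs=epsabs, epsrel=epsrel, limit=200
    )
    fac = am * mutant.beta_m * np.exp(-p.mu * mutant.tau_m) * np.exp(-dm * t_end)
    return float(fac * A)


def resident_environment(
    params: ModelParams, host_constant: float | None = None
) -> SeasonState:
    """Equilibrium ``(s_hat*, v_hat*)`` of the resident-only system.

    With ``host_constant`` the host cohort is fixed and only the 1-D parasite
    equilibrium is solved; otherwise the full 2-D (possibly unstable)
    coexistence fixed point is located.
    """
    if host_constant is None:
        return endemic_fixed_point(params)

    def growth(log_v: float) -> float:
        st = season_map(params, SeasonState(host_constant, float(np.exp(log_v))))
        return np.log(st.v_hat) - log_v

    lo, hi = 0.0, 5.0
    while growth(hi) > 0 and hi < 25:  # e^25 is far above any physical density
        hi += 5.0
    if growth(lo) < 0:
        raise FixedPointError("parasite cannot persist on the constant host cohort")
    log_v = scipy.optimize.brentq(growth, lo, hi, xtol=1e-10)
    return SeasonState(host_constant, float(np.exp(log_v)))


def selection_gradient(
    params: ModelParams,
    tau_r: float,
    resident_env: SeasonState | None = None,
    dtau: float = 1e-3,
    host_constant: float | None = None,
) -> float:
    """Central-difference derivative of invasion fitness in ``tau_m`` at the
    resident value (positive: selection for longer incubation delays)."""
    p = params.replace(tau=tau_r)
    if resident_env is None:
        resident_env = resident_environment(p, host_constant)
    f = lambda tm: invasion_fitness(
        resident_env, StrainTraits.from_params(p, tau_m=tm), p,
        host_constant=host_constant, check=False,
    )
    return (f(tau_r + dtau) - f(tau_r - dtau)) / (2.0 * dtau)


def ess_tau(
    params: ModelParams,
    bracket: tuple[float, float] | None = None,
    xtol: float = 1e-3,
    dtau: float = 1e-3,
    host_constant: float | None = None,
    coarse_points: int = 13,
) -> float:
    """Optimal (uninvadable) virulence delay ``tau*`` for one environment.

    Finds the zero of the selection gradient, recomputing the resident
    equilibrium at every candidate ``tau``; the curvature condition (local
    concavity of the fitness profile) is verified at the root.  Raises if the
    gradient has no sign change on the bracket ("no interior ESS").
    """
    p = params
    lo, hi = bracket if bracket is not None else (0.25 * p.T, p.T - 0.05)

    def grad(tau: float) -> float | None:
        try:
            return selection_gradient(p, tau, dtau=dtau, host_constant=host_constant)
        except FixedPointError:
            return None

    taus = np.linspace(lo, hi, coarse_points)
    vals = [grad(t) for t in taus]
    root = None
    for (t1, g1), (t2, g2) in zip(zip(taus, vals), zip(taus[1:], vals[1:])):
        if g1 is None or g2 is None:
            continue
        if g1 > 0 and g2 < 0:
            root = scipy.optimize.brentq(grad, t1, t2, xtol=xtol)
            break
    if root is None:
        raise FixedPointError(f"no interior ESS: selection gradient has no +/- sign change on ({lo}, {hi})")
    # second-order condition: fitness locally concave around tau*
    env = resident_environment(p.replace(tau=root), host_constant)
    f = lambda tm: invasion_fitness(
        env, StrainTraits.from_params(p, tau_m=tm), p.replace(tau=root),
        host_constant=host_constant, check=False,
    )
    h = 10 * dtau
    if not f(root + h) + f(root - h) - 2.0 * f(root) < 0:
        raise FixedPointError(f"gradient zero at tau={root} is not a fitness maximum")
    return float(root)


# ---------------------------------------------------------------------------
# phase-dependent invasion on the cycling attractor


@dataclass(frozen=True)
class InvasionTrialResult:
    """Outcome of introducing one mutant at one phase of the resident cycle."""

    intro_season: int
    s_hat_at_intro: float
    v_hat_at_intro: float
    outcome: str  # invaded | extinct
    mutant_series: np.ndarray


def phase_dependent_invasion(
    params: ModelParams,
    resident_tau: float,
    mutant_tau: float,
    intro_seasons: Sequence[int],
    burn_in: int = 800,
    horizon: int = 300,
    persist: int = 50,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> list[InvasionTrialResult]:
    """Introduce the same mutant at different phases of the resident cycle.

    The resident runs alone for ``burn_in`` seasons to reach its attractor;
    at each requested season (indexed from the start of the run) a single
    mutant particle is added and the two-strain system is simulated for
    ``horizon`` further seasons.  The mutant has *invaded* if it is alive for
    the final ``persist`` consecutive seasons and ends above its introduction
    density; otherwise it is *extinct* (pruning below the threshold kills it
    immediately).
    """
    p = params.replace(tau=resident_tau)
    need = max(intro_seasons)
    base = iterate_seasons(p, DEFAULT_INITIAL, need)
    res_tr = StrainTraits.from_params(p)
    mut_tr = StrainTraits.from_params(p, tau_m=mutant_tau)
    results = []
    for n0 in intro_seasons:
        if n0 < burn_in:
            raise ValueError(f"introduction season {n0} is before burn-in {burn_in}")
        s0 = float(base.s_hat_series[n0])
        v0 = float(base.v_hat_series[n0])
        state = MultiStrainState(s_hat=s0, strains=[(res_tr, v0), (mut_tr, 1.0)])
        mut = np.zeros(horizon + 1)
        mut[0] = 1.0
        for k in range(1, horizon + 1):
            state = multistrain_season_map(p, state, extinction_threshold)
            dens = {id(tr): v for tr, v in state.strains}
            mut[k] = dens.get(id(mut_tr), 0.0)
            if mut[k] == 0.0 and not any(tr is mut_tr for tr, _ in state.strains):
                break
        alive_tail = np.all(mut[horizon - persist + 1 : horizon + 1] >= extinction_threshold)
        outcome = "invaded" if alive_tail and mut[horizon] > 1.0 else "extinct"
        results.append(
            InvasionTrialResult(
                intro_season=int(n0),
                s_hat_at_intro=s0,
                v_hat_at_intro=v0,
                outcome=outcome,
                mutant_series=mut,
            )
        )
    return results
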
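"""Semi-analytic solution of the within-season transmission dynamics.

Within one season of length ``T`` the single-strain dynamics are the delay
system::

    ds/dt  = s_hat * g(t, t_l) - mu * s - alpha * s * v1
    dv1/dt = -delta * v1
    dv2/dt = alpha * beta * exp(-mu*tau) * s(t-tau) * v1(t-tau) - delta * v2

with ``s(0) = 0``, ``v1(0) = v_hat``, ``v2(t) = 0`` for ``t <= tau``, and
``g`` the uniform emergence density on ``[0, t_l]``.  Removal of free
parasites through transmission is neglected, so ``v1`` is pure exponential
decay and the system collapses to closed forms plus quadrature:

* ``v1(t) = v_hat * exp(-delta * t)`` exactly;
* ``s`` follows from the integrating factor ``exp(Phi(t))`` with
  ``Phi(t) = mu*t + sum_i (alpha_i v_hat_i / delta_i) (1 - exp(-delta_i t))``
  (the sum runs over all strains sharing the host),
  giving ``s(t) = (s_hat/t_l) * int_0^{min(t, t_l)} exp(Phi(u) - Phi(t)) du``;
* in the progeny quadrature the two decay factors cancel,
  ``exp(-delta (t-x)) * v1(x - tau) = v_hat * exp(-delta (t - tau))``, so
  ``v2(t) = alpha*beta*exp(-mu*tau) * v_hat * exp(-delta*(t-tau)) * A(t-tau)``
  with ``A(y) = int_0^y s`` (zero for ``t < tau``).

The quadratures are evaluated with composite Gauss-Legendre panels whose
boundaries adapt to the slope of ``Phi`` (so the integrand varies by a bounded
factor per panel) and always include the kink at ``t = t_l``.  All exponents
are taken as differences, which keeps the scheme overflow-free even at the
very large parasite densities reached on the cycling attractor.

An independent method-of-steps integrator lives in :mod:`phenocycle.oracle`
and shares no code with this module.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .params import ModelParams, SeasonState, WithinSeasonTrajectory

__all__ = [
    "NumericalFailure",
    "emergence_rate",
    "solve_season",
    "within_season",
    "end_of_season",
    "season_map",
    "infection_free_survivors",
]


class NumericalFailure(RuntimeError):
    """A within-season quantity became non-finite."""


# 12-point Gauss-Legendre nodes/weights on [-1, 1]; exact through degree 23.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(12)


def emergence_rate(t: float, params: ModelParams) -> float:
    """Per-capita host emergence rate g(t, t_l) at season-local time ``t``.

    Uniform on ``[0, t_l]`` (density ``1/t_l``), zero on ``(t_l, T]``.
    Raises ``ValueError`` outside ``[0, T]``.  For ``t_l = 0`` the emergence
    is an atom at ``t = 0`` and this density view is degenerate (inf at 0).
    """
    if t < 0 or t > params.T:
        raise ValueError(f"t={t!r} outside the season [0, {params.T!r}]")
    if params.t_l == 0:
        return np.inf if t == 0 else 0.0
    return 1.0 / params.t_l if t <= params.t_l else 0.0


def _build_knots(
    mu: float,
    alpha_v: np.ndarray,
    deltas: np.ndarray,
    T: float,
    t_l: float,
    eval_times: Sequence[float],
    dphi_max: float,
    du_max: float,
) -> np.ndarray:
    """Panel boundaries on [0, T]: eval times, the kink at t_l, and refinement
    so Phi (whose slope mu + sum alpha_i v_hat_i exp(-delta_i u) is
    decreasing) changes by at most ``dphi_max`` per panel."""
    # refuse pathological refinement up front (total Phi rise bounds the
    # slope-driven panel count); reachable densities keep this tiny
    est_panels = (mu * T + float(np.sum(alpha_v / np.maximum(deltas, 1e-300)))) / dphi_max
    if est_panels > 2e5:
        raise NumericalFailure(
            f"within-season force of infection too large to resolve "
            f"(sum alpha_i*v_hat_i = {float(np.sum(alpha_v)):.3g})"
        )
    base = {0.0, T}
    if 0.0 < t_l < T:
        base.add(t_l)
    for t in eval_times:
        if 0.0 < t < T:
            base.add(float(t))
    anchors = sorted(base)
    knots = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        knots.append(a)
        u = a
        while True:
            slope = mu + float(np.sum(alpha_v * np.exp(-deltas * u)))
            du = min(du_max, dphi_max / slope) if slope > 0 else du_max
            if u + du >= b - 1e-12:
                break
            u += du
            knots.append(u)
    knots.append(T)
    return np.asarray(knots)


def solve_season(
    s_hat: float,
    mu: float,
    T: float,
    t_l: float,
    strains: Sequence[tuple[float, float, float]],
    s_times: Sequence[float] = (),
    a_times: Sequence[float] = (),
    dphi_max: float = 1.0,
    du_max: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Host density ``s`` and its running integral ``A`` at requested times.

    Parameters
    ----------
    strains
        Sequence of ``(alpha_i, v_hat_i, delta_i)`` for every parasite strain
        sharing the host (their transmission terms all deplete ``s``).
    s_times, a_times
        Times in ``[0, T]`` at which to return ``s`` and ``A = int_0^t s``.

    This is the shared quadrature engine behind :func:`within_season`, the
    season map, and the multi-strain invasion dynamics.
    """
    s_times = np.asarray(s_times, dtype=float)
    a_times = np.asarray(a_times, dtype=float)
    if s_times.size and (s_times.min() < 0 or s_times.max() > T + 1e-12):
        raise ValueError("s_times outside [0, T]")
    if a_times.size and (a_times.min() < 0 or a_times.max() > T + 1e-12):
        raise ValueError("a_times outside [0, T]")
    if s_hat == 0.0:
        return np.zeros_like(s_times), np.zeros_like(a_times)

    alphas = np.array([st[0] for st in strains], dtype=float)
    v_hats = np.array([st[1] for st in strains], dtype=float)
    deltas = np.array([st[2] for st in strains], dtype=float)
    alpha_v = alphas * v_hats
    coef = np.divide(alpha_v, deltas, out=np.zeros_like(alpha_v), where=deltas > 0)

    def phi(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return mu * u + np.einsum(
            "i,i...->...", coef, 1.0 - np.exp(-np.multiply.outer(deltas, u))
        )

    eval_all = np.concatenate([s_times, a_times])
    knots = _build_knots(mu, alpha_v, deltas, T, min(t_l, T), eval_all, dphi_max, du_max)
    a, b = knots[:-1], knots[1:]
    half = 0.5 * (b - a)
    nodes = 0.5 * (a + b)[:, None] + half[:, None] * _GL_X  # (K, 12)

    phi_knots = phi(knots)
    phi_nodes = phi(nodes)

    tl_eff = min(t_l, T)
    if tl_eff > 0.0:
        emer = b <= tl_eff + 1e-12  # emergence panels (t_l is a knot)
        # log of panel masses int_a^b exp(Phi), referenced to Phi(b)
        mass = half[emer] * np.sum(
            _GL_W * np.exp(phi_nodes[emer] - phi_knots[1:][emer, None]), axis=1
        )
        log_p = phi_knots[1:][emer] + np.log(mass)
        # cumulative logE at knots, capped at t_l
        log_e = np.full(knots.size, -np.inf)
        acc = -np.inf
        j = 1
        for k in range(a.size):
            if emer[k]:
                acc = np.logaddexp(acc, log_p[j - 1]) if np.isfinite(acc) else log_p[j - 1]
                j += 1  # consume next mass (emergence panels are a prefix)
            log_e[k + 1] = acc
        # within-panel partial integrals at GL nodes for emergence panels:
        # int_a^{y_q} exp(Phi(z) - Phi(y_q)) dz  via nested 12-pt GL
        ya = nodes[emer] - a[emer][:, None]  # (Ke, 12) node offsets
        z = a[emer][:, None, None] + 0.5 * ya[:, :, None] * (_GL_X + 1.0)  # (Ke,12,12)
        partial = 0.5 * ya * np.sum(_GL_W * np.exp(phi(z) - phi_nodes[emer][:, :, None]), axis=2)
        log_c = np.log(s_hat / t_l)
        # s at emergence-panel nodes: carried mass from earlier panels + partial
        carried = np.exp(log_c + log_e[:-1][emer, None] - phi_nodes[emer])
        s_nodes_emer = carried + np.exp(log_c) * partial
        log_e_end = log_e[np.searchsorted(knots, tl_eff)]
        log_s_scale = log_c + log_e_end  # s(y) = exp(log_s_scale - Phi(y)) past t_l
    else:
        emer = np.zeros(a.size, dtype=bool)
        log_e = np.full(knots.size, 0.0)  # unused sentinel
        s_nodes_emer = np.empty((0, _GL_X.size))
        log_s_scale = np.log(s_hat)

    # s at nodes of decay panels (a >= t_l): pure exp(-Phi) profile
    s_nodes = np.empty_like(phi_nodes)
    s_nodes[emer] = s_nodes_emer
    s_nodes[~emer] = np.exp(log_s_scale - phi_nodes[~emer])

    # s at knots
    s_knots = np.empty(knots.size)
    s_knots[0] = 0.0 if tl_eff > 0.0 else s_hat
    past = knots[1:] >= tl_eff - 1e-12
    if tl_eff > 0.0:
        s_knots[1:][~past] = np.exp(np.log(s_hat / t_l) + log_e[1:][~past] - phi_knots[1:][~past])
        # knots at/after t_l use the capped mass
        s_knots[1:][past] = np.exp(log_s_scale - phi_knots[1:][past])
    else:
        s_knots[1:] = np.exp(log_s_scale - phi_knots[1:])

    # cumulative A at knots
    panel_s_int = half * np.sum(_GL_W * s_nodes, axis=1)
    a_knots = np.concatenate([[0.0], np.cumsum(panel_s_int)])

    if not (np.all(np.isfinite(s_knots)) and np.all(np.isfinite(a_knots))):
        raise NumericalFailure(
            "non-finite host density in within-season solve "
            f"(s_hat={s_hat!r}, strains={list(strains)!r})"
        )

    idx_s = np.searchsorted(knots, np.clip(s_times, 0.0, T))
    idx_a = np.searchsorted(knots, np.clip(a_times, 0.0, T))
    return s_knots[idx_s], a_knots[idx_a]


def _progeny_factor(alpha: float, beta: float, mu: float, tau: float, delta: float, t: float) -> float:
    """alpha*beta*exp(-mu*tau)*exp(-delta*(t-tau)): multiplies v_hat * A(t-tau)."""
    return alpha * beta * np.exp(-mu * tau) * np.exp(-delta * (t - tau))


def within_season(
    params: ModelParams, state: SeasonState, n_grid: int = 201
) -> WithinSeasonTrajectory:
    """Solve one season and return the trajectory on an ``n_grid``-point grid.

    ``v1`` is the closed-form decay, ``s`` the integrating-factor quadrature,
    and ``v2`` the progeny quadrature (zero before ``tau``).
    """
    p = params
    t = np.linspace(0.0, p.T, n_grid)
    a_needed = t[t >= p.tau] - p.tau
    s_vals, a_vals = solve_season(
        state.s_hat, p.mu, p.T, p.t_l,
        [(p.alpha, state.v_hat, p.delta)],
        s_times=t, a_times=a_needed,
    )
    v1 = state.v_hat * np.exp(-p.delta * t)
    v2 = np.zeros_like(t)
    mask = t >= p.tau
    if mask.any():
        fac = p.alpha * p.beta * np.exp(-p.mu * p.tau) * np.exp(-p.delta * (t[mask] - p.tau))
        v2[mask] = fac * state.v_hat * a_vals
    if not np.all(np.isfinite(v2)):
        raise NumericalFailure(f"non-finite progeny density v2 (params={p!r}, state={state!r})")
    return WithinSeasonTrajectory(t_grid=t, s=s_vals, v1=v1, v2=v2, params=p)


def end_of_season(params: ModelParams, state: SeasonState) -> tuple[float, float]:
    """``(s(T), v2(T))`` for one season; ``v2(T) = 0`` whenever ``tau >= T``."""
    p = params
    if state.v_hat == 0.0:
        s_T, _ = solve_season(state.s_hat, p.mu, p.T, p.t_l, [(p.alpha, 0.0, p.delta)], s_times=[p.T])
        return float(s_T[0]), 0.0
    if p.tau >= p.T:
        s_T, _ = solve_season(
            state.s_hat, p.mu, p.T, p.t_l, [(p.alpha, state.v_hat, p.delta)], s_times=[p.T]
        )
        return float(s_T[0]), 0.0
    s_T, a_val = solve_season(
        state.s_hat, p.mu, p.T, p.t_l,
        [(p.alpha, state.v_hat, p.delta)],
        s_times=[p.T], a_times=[p.T - p.tau],
    )
    v2_T = _progeny_factor(p.alpha, p.beta, p.mu, p.tau, p.delta, p.T) * state.v_hat * float(a_val[0])
    if not np.isfinite(v2_T):
        raise NumericalFailure(f"non-finite v2(T) (params={p!r}, state={state!r})")
    return float(s_T[0]), v2_T


def host_recruitment(s_T: float, params: ModelParams) -> float:
    """Beverton-Holt recruitment: next-season cohort from survivors ``s(T)``."""
    return params.sigma * s_T / (1.0 + params.rho * s_T)


def season_map(params: ModelParams, state: SeasonState) -> SeasonState:
    """One application of the between-season map.

    ``s_hat(n+1) = sigma s(T) / (1 + rho s(T))`` and ``v_hat(n+1) = v2(T)``.
    """
    s_T, v2_T = end_of_season(params, state)
    return SeasonState(s_hat=host_recruitment(s_T, params), v_hat=max(v2_T, 0.0))


def infection_free_survivors(s_hat: float, params: ModelParams) -> float:
    """Closed-form ``s(T)`` with no parasites:
    ``s_hat (exp(-mu(T-t_l)) - exp(-mu T)) / (mu t_l)`` (limit ``s_hat e^{-mu T}``
    for synchronous emergence)."""
    p = params
    if p.t_l == 0.0:
        return s_hat * np.exp(-p.mu * p.T)
    return s_hat * (np.exp(-p.mu * (p.T - p.t_l)) - np.exp(-p.mu * p.T)) / (p.mu * p.t_l)
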
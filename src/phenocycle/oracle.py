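"""Brute-force delay-ODE integration of the within-season system.

This module is the independent numerical ground truth for
:func:`phenocycle.season.within_season`.  It integrates the full delay system
(including the trivially decaying ``v1`` equation) by the method of steps:
the season is cut at every point ``k*tau``, ``k*tau + t_l`` where the
right-hand side has a kink or where the delayed argument crosses a previous
cut, and each segment is advanced with an adaptive high-order Runge-Kutta
scheme, the delayed state being read from the stored dense output of earlier
segments.  No code is shared with the semi-analytic path.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams, SeasonState, WithinSeasonTrajectory

__all__ = ["oracle_within_season", "oracle_end_of_season"]


def _segment_boundaries(T: float, t_l: float, tau: float) -> np.ndarray:
    pts = {0.0, T}
    k = 0
    while k * tau <= T:
        for b in (k * tau, k * tau + t_l):
            if 0.0 < b < T:
                pts.add(b)
        k += 1
        if k > 10_000:  # tau pathologically small relative to T
            raise RuntimeError("step-size underflow: tau too small for method of steps")
    return np.asarray(sorted(pts))


def oracle_within_season(
    params: ModelParams,
    state: SeasonState,
    n_grid: int = 201,
    rtol: float = 1e-10,
) -> WithinSeasonTrajectory:
    """Method-of-steps integration of one season at per-step tolerance ~1e-10."""
    p = params
    s_hat, v_hat = state.s_hat, state.v_hat
    release = p.alpha * p.beta * np.exp(-p.mu * p.tau)
    # absolute floors well below each component's natural scale, so that the
    # relative tolerance governs everywhere the densities are non-negligible
    atol = 1e-13 * np.array([max(s_hat, 1.0), max(v_hat, 1.0), max(v_hat, 1.0)])

    segments: list[tuple[float, float, object]] = []  # (t0, t1, dense solution)

    def history(t: float) -> np.ndarray:
        """(s, v1) at time t from stored dense output; zero before t=0."""
        if t < 0.0:
            return np.array([0.0, 0.0])
        for t0, t1, sol in segments:
            if t0 - 1e-12 <= t <= t1 + 1e-12:
                y = sol(min(max(t, t0), t1))
                return y[:2]
        raise RuntimeError(f"history requested outside integrated range: t={t!r}")

    if p.t_l > 0.0:
        y0 = np.array([0.0, v_hat, 0.0])
    else:
        y0 = np.array([s_hat, v_hat, 0.0])  # synchronous emergence: atom at t=0

    bounds = _segment_boundaries(p.T, p.t_l, p.tau)
    y = y0
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (a + b)
        g = (1.0 / p.t_l) if (p.t_l > 0.0 and mid < p.t_l) else 0.0
        delayed_on = mid >= p.tau

        def rhs(t: float, yv: np.ndarray, g=g, delayed_on=delayed_on) -> list[float]:
            s, v1, v2 = yv
            src = 0.0
            if delayed_on:
                s_d, v1_d = history(t - p.tau)
                src = release * s_d * v1_d
            return [
                s_hat * g - p.mu * s - p.alpha * s * v1,
                -p.delta * v1,
                src - p.delta * v2,
            ]

        res = solve_ivp(
            rhs, (a, b), y, method="DOP853", dense_output=True, rtol=rtol, atol=atol
        )
        if not res.success:
            raise RuntimeError(f"oracle integration failed on [{a}, {b}]: {res.message}")
        segments.append((a, b, res.sol))
        y = res.y[:, -1]

    t = np.linspace(0.0, p.T, n_grid)
    out = np.empty((3, t.size))
    for j, tj in enumerate(t):
        for t0, t1, sol in segments:
            if t0 - 1e-12 <= tj <= t1 + 1e-12:
                out[:, j] = sol(min(max(tj, t0), t1))
                break
    # progeny release cannot have begun before tau
    out[2, t < p.tau] = 0.0
    if p.tau >= p.T:
        out[2, :] = 0.0
    return WithinSeasonTrajectory(t_grid=t, s=out[0], v1=out[1], v2=out[2], params=p)


def oracle_end_of_season(params: ModelParams, state: SeasonState) -> tuple[float, float]:
    """``(s(T), v2(T))`` from the method-of-steps integration."""
    traj = oracle_within_season(params, state, n_grid=2)
    return float(traj.s[-1]), float(traj.v2[-1])
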
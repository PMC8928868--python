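"""Multi-season iteration, attractor classification, and bifurcation scans.

The between-season dynamics are a 2-D discrete map on ``(s_hat, v_hat)``
obtained by composing the within-season solve with Beverton-Holt host
recruitment and parasite carry-over.  Depending on the virulence phenotype
``tau`` and the phenology ``(T, t_l)`` the map settles on a fixed point
(parasite-free or endemic) or on a quasiperiodic invariant curve born in a
Neimark-Sacker bifurcation; this module detects which, measures cycle
statistics, and scans parameter axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.optimize

from .params import ModelParams, SeasonState
from .season import (
    NumericalFailure,
    end_of_season,
    host_recruitment,
    season_map,
    infection_free_survivors,
)

__all__ = [
    "MultiSeasonSeries",
    "DynamicsClassification",
    "FixedPointError",
    "iterate_seasons",
    "classify_dynamics",
    "BifurcationScan",
    "bifurcation_scan",
    "phase_boundary",
    "parasite_free_fixed_point",
    "endemic_fixed_point",
    "map_jacobian",
    "map_jacobian_stability",
]

#: Default initial condition for long runs (classification is insensitive to
#: this over at least an order of magnitude; see tests).
DEFAULT_INITIAL = SeasonState(s_hat=1e4, v_hat=1e2)

#: Extinction threshold on between-season parasite density: densities are
#: absolute counts, so a population below one individual is extinct.
EXTINCTION_THRESHOLD = 1.0


class FixedPointError(RuntimeError):
    """No fixed point of the season map could be located."""


@dataclass
class MultiSeasonSeries:
    """Host and parasite densities over ``n_seasons`` seasons.

    ``s_hat_series`` and ``v_hat_series`` are measured at season start
    (emerging cohort, parasite inoculum); ``s_end_series`` is the uninfected
    survivor density ``s(T)`` at the end of the same season — the hosts that
    actually reproduce, which is the quantity whose peaks lead the parasite
    peaks through the delayed density dependence.
    """

    params: ModelParams
    initial: SeasonState
    s_hat_series: np.ndarray
    v_hat_series: np.ndarray
    s_end_series: np.ndarray | None = None

    @property
    def n_seasons(self) -> int:
        return self.s_hat_series.size - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "season": np.arange(self.s_hat_series.size),
                "s_hat": self.s_hat_series,
                "v_hat": self.v_hat_series,
                "s_end": self.s_end_series,
            }
        )


@dataclass(frozen=True)
class DynamicsClassification:
    """Attractor label with amplitude and, when cycling, cycle statistics.

    ``relative_amplitude`` is ``(max - min) / mean`` of the end-of-window
    parasite series; ``period_estimate`` is the mean spacing of host-cohort
    local maxima in seasons; ``host_parasite_peak_lag`` the mean offset from a
    host peak to the next parasite peak, modulo the period.
    """

    label: str  # parasite_free | endemic_equilibrium | cycling
    relative_amplitude: float
    period_estimate: float | None = None
    host_parasite_peak_lag: float | None = None


def iterate_seasons(
    params: ModelParams,
    initial: SeasonState = DEFAULT_INITIAL,
    n: int = 900,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> MultiSeasonSeries:
    """Apply the season map ``n`` times.

    A between-season parasite density below ``extinction_threshold`` is set to
    zero (extinct) and stays there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = np.empty(n + 1)
    v = np.empty(n + 1)
    s_end = np.empty(n + 1)
    s[0], v[0] = initial.s_hat, initial.v_hat
    state = initial
    for k in range(1, n + 1):
        try:
            s_T, v2_T = end_of_season(params, state)
        except NumericalFailure as err:
            raise NumericalFailure(f"season {k - 1}: {err}") from err
        s_end[k - 1] = s_T
        v_next = v2_T if v2_T >= extinction_threshold else 0.0
        state = SeasonState(host_recruitment(s_T, params), v_next)
        s[k], v[k] = state.s_hat, state.v_hat
    s_end[n], _ = end_of_season(params, state)
    return MultiSeasonSeries(
        params=params, initial=initial, s_hat_series=s, v_hat_series=v, s_end_series=s_end
    )


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-left local maxima; plateaus take the first index."""
    idx = []
    n = x.size
    for i in range(1, n - 1):
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j + 1 < n and x[j + 1] < x[j]:
                idx.append(i)
    return np.asarray(idx, dtype=int)


def classify_dynamics(
    series: MultiSeasonSeries,
    burn_in: int = 800,
    window: int = 100,
    amplitude_threshold: float = 1e-3,
) -> DynamicsClassification:
    """Label the post-burn-in dynamics as parasite-free, equilibrial, or cycling."""
    if burn_in + window > series.n_seasons:
        raise ValueError("burn_in + window exceeds the number of simulated seasons")
    sl = slice(burn_in + 1, burn_in + window + 1)
    v = series.v_hat_series[sl]
    s = series.s_hat_series[sl]
    if v[-1] == 0.0 or v.mean() == 0.0:
        return DynamicsClassification(label="parasite_free", relative_amplitude=0.0)
    amp = float((v.max() - v.min()) / v.mean())
    if amp <= amplitude_threshold:
        return DynamicsClassification(label="endemic_equilibrium", relative_amplitude=amp)
    # host peaks on the end-of-season survivor density (the reproducing
    # hosts): through the one-season carry-over these lead the parasite
    # inoculum peaks by the cycle's delayed-density-dependence lag
    s_host = series.s_end_series[sl] if series.s_end_series is not None else s
    s_peaks = _local_maxima(s_host)
    v_peaks = _local_maxima(v)
    period = float(np.mean(np.diff(s_peaks))) if s_peaks.size >= 2 else None
    lag = None
    if period is not None and v_peaks.size:
        offsets = []
        for ip in s_peaks:
            later = v_peaks[v_peaks > ip]
            if later.size:
                offsets.append((later[0] - ip) % period)
        if offsets:
            lag = float(np.mean(offsets))
    return DynamicsClassification(
        label="cycling",
        relative_amplitude=amp,
        period_estimate=period,
        host_parasite_peak_lag=lag,
    )


@dataclass
class BifurcationScan:
    """End-of-season parasite densities and classification per scanned ``tau``."""

    tau_grid: np.ndarray
    v_hat_windows: list = field(repr=False, default_factory=list)
    classifications: list = field(repr=False, default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classifications]

    def cycling_window(self) -> tuple[float, float]:
        """(lower, upper) edges of the contiguous cycling interval, each the
        midpoint between the outermost non-cycling and first cycling grid value."""
        cyc = np.array([lab == "cycling" for lab in self.labels])
        if not cyc.any():
            raise ValueError("no cycling tau in the scanned grid")
        idx = np.nonzero(cyc)[0]
        lo, hi = idx[0], idx[-1]
        tau = self.tau_grid
        lower = tau[lo] if lo == 0 else 0.5 * (tau[lo - 1] + tau[lo])
        upper = tau[hi] if hi == tau.size - 1 else 0.5 * (tau[hi] + tau[hi + 1])
        return float(lower), float(upper)

    def to_frame(self):
        import pandas as pd

        rows = []
        for t, vals, c in zip(self.tau_grid, self.v_hat_windows, self.classifications):
            for n, v in enumerate(vals):
                rows.append({"tau": t, "window_season": n, "v_hat": v, "label": c.label})
        return pd.DataFrame(rows)


def bifurcation_scan(
    params: ModelParams,
    tau_grid: Sequence[float],
    burn_in: int = 800,
    window: int = 100,
    initial: SeasonState = DEFAULT_INITIAL,
    amplitude_threshold: float = 1e-3,
) -> BifurcationScan:
    """For each ``tau`` iterate ``burn_in + window`` seasons and collect the
    end-of-season parasite densities of the window plus a classification."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau_grid must be non-empty")
    scan = BifurcationScan(tau_grid=tau_grid)
    for tau in tau_grid:
        series = iterate_seasons(params.replace(tau=float(tau)), initial, burn_in + window)
        scan.v_hat_windows.append(series.v_hat_series[burn_in + 1 : burn_in + window + 1].copy())
        scan.classifications.append(
            classify_dynamics(series, burn_in, window, amplitude_threshold)
        )
    return scan


def phase_boundary(
    T_grid: Sequence[float],
    t_l_grid: Sequence[float],
    params: ModelParams,
    ess_provider: Callable[[float, float], float],
    burn_in: int = 800,
    window: int = 100,
    amplitude_threshold: float = 1e-3,
) -> np.ndarray:
    """Label grid over phenology space for optimally virulent parasites.

    For each ``(T, t_l)`` with ``t_l <= T`` the resident ``tau`` is set to the
    optimum ``tau*(T, t_l)`` returned by ``ess_provider`` and the long-run
    dynamics are classified.  Cells where the optimum cannot be computed are
    labelled ``"undetermined"``; cells with ``t_l > T`` are ``"invalid"``.
    Returns an object array of shape ``(len(T_grid), len(t_l_grid))``.
    """
    out = np.empty((len(T_grid), len(t_l_grid)), dtype=object)
    for i, T in enumerate(T_grid):
        for j, t_l in enumerate(t_l_grid):
            if t_l > T:
                out[i, j] = "invalid"
                continue
            try:
                tau_star = ess_provider(float(T), float(t_l))
            except Exception:
                out[i, j] = "undetermined"
                continue
            p = params.replace(T=float(T), t_l=float(t_l), tau=float(tau_star))
            series = iterate_seasons(p, DEFAULT_INITIAL, burn_in + window)
            c = classify_dynamics(series, burn_in, window, amplitude_threshold)
            out[i, j] = "stable" if c.label == "endemic_equilibrium" else c.label
    return out


# ---------------------------------------------------------------------------
# fixed points and linear stability of the season map


def parasite_free_fixed_point(params: ModelParams) -> SeasonState:
    """Closed-form host-only fixed point of the season map.

    With survivor fraction ``q = s(T)/s_hat`` of the infection-free season,
    the Beverton-Holt fixed point is ``s* = (sigma q - 1) / (rho q)`` when
    ``sigma q > 1``, else extinction (0).
    """
    q = infection_free_survivors(1.0, params)
    if params.sigma * q <= 1.0:
        return SeasonState(0.0, 0.0)
    return SeasonState((params.sigma * q - 1.0) / (params.rho * q), 0.0)


def endemic_fixed_point(
    params: ModelParams,
    guess: SeasonState | None = None,
    tol: float = 1e-9,
) -> SeasonState:
    """Locate the coexistence fixed point of the season map by root finding.

    Works in log coordinates for conditioning; the fixed point is returned
    even when it is unstable (inside the cycling regime), where it organizes
    the surrounding invariant curve.  Raises :class:`FixedPointError` if no
    root is found or the residual check fails.
    """
    if guess is None:
        # orbit average is a serviceable guess in both regimes
        series = iterate_seasons(params, DEFAULT_INITIAL, 400, extinction_threshold=0.0)
        s0 = float(np.mean(series.s_hat_series[200:]))
        v0 = float(np.mean(series.v_hat_series[200:]))
        if v0 <= 0 or not np.isfinite(v0):
            raise FixedPointError(f"parasite dies out at {params!r}; no endemic fixed point")
        guess = SeasonState(s0, max(v0, 1.0))

    def residual(x: np.ndarray) -> np.ndarray:
        # clip trial points to a physically sane box (hosts bounded by the
        # Beverton-Holt ceiling sigma/rho, parasites by beta * hosts); the
        # residual is still computed against the raw x so the solver is
        # pulled back inside
        sv = np.exp(np.clip(x, -20.0, [17.0, 24.0]))
        st = season_map(params, SeasonState(float(sv[0]), float(sv[1])))
        if st.s_hat <= 0 or st.v_hat <= 0:
            return np.array([1e6, 1e6])
        return np.array([np.log(st.s_hat) - x[0], np.log(st.v_hat) - x[1]])

    x0 = np.log([guess.s_hat, guess.v_hat])
    sol = scipy.optimize.root(residual, x0, method="hybr", options={"xtol": 1e-12})
    if not sol.success:
        raise FixedPointError(f"no endemic fixed point found at {params!r}: {sol.message}")
    fp = SeasonState(float(np.exp(sol.x[0])), float(np.exp(sol.x[1])))
    check = season_map(params, fp)
    if abs(check.s_hat - fp.s_hat) > tol * max(fp.s_hat, 1.0) or abs(
        check.v_hat - fp.v_hat
    ) > tol * max(fp.v_hat, 1.0):
        raise FixedPointError(f"fixed-point residual check failed at {params!r}")
    return fp


def map_jacobian(
    params: ModelParams, fixed_point: SeasonState, rel_step: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian of the season map at a fixed point."""
    check = season_map(params, fixed_point)
    scale = np.array([max(fixed_point.s_hat, 1.0), max(fixed_point.v_hat, 1.0)])
    if (
        abs(check.s_hat - fixed_point.s_hat) > 1e-6 * scale[0]
        or abs(check.v_hat - fixed_point.v_hat) > 1e-6 * scale[1]
    ):
        raise FixedPointError("supplied state is not a fixed point of the season map")
    x = np.array([fixed_point.s_hat, fixed_point.v_hat])
    J = np.empty((2, 2))
    for j in range(2):
        h = rel_step * scale[j]
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        fp = season_map(params, SeasonState(*xp))
        fm = season_map(params, SeasonState(*xm))
        J[:, j] = (np.array([fp.s_hat, fp.v_hat]) - np.array([fm.s_hat, fm.v_hat])) / (
            xp[j] - xm[j]
        )
    return J


def map_jacobian_stability(
    params: ModelParams, fixed_point: SeasonState, rel_step: float = 1e-6
) -> np.ndarray:
    """Eigenvalues of the season-map Jacobian; stable iff max modulus < 1."""
    return np.linalg.eigvals(map_jacobian(params, fixed_point, rel_step))
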
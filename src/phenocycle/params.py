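"""Model parameters and season-level state for the seasonal obligate-killer model.

The model follows a monocyclic, obligate-killer parasite infecting a host with
non-overlapping generations in a seasonal environment.  Within a season of
length ``T`` hosts emerge at a constant per-capita rate over a window of length
``t_l`` and are infected by free parasites; an infected host dies (releasing
``beta`` parasite progeny) a fixed delay ``tau`` after infection.  Between
seasons the surviving uninfected hosts reproduce with Beverton-Holt density
dependence and parasite progeny carry over.

``tau`` is the inverse of virulence: a short incubation delay means a highly
virulent parasite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np

__all__ = [
    "ModelParams",
    "SeasonState",
    "WithinSeasonTrajectory",
    "DEFAULT_PARAM_VALUES",
]

#: Baseline parameter values (phenology T, t_l and virulence tau are the
#: quantities varied in experiments; the values here are the short-season,
#: synchronous-emergence reference environment).
DEFAULT_PARAM_VALUES: dict[str, float] = {
    "alpha": 3.5e-7,  # transmission rate, per (parasite * time)
    "beta": 200.0,    # parasites released per killed host
    "delta": 2.0,     # environmental parasite decay rate, per time
    "mu": 0.25,       # host background death rate, per time
    "tau": 2.8,       # incubation delay infection -> host death (1/virulence)
    "sigma": 500.0,   # host fecundity multiplier
    "rho": 1e-4,      # density dependence of reproduction, per host
    "T": 4.0,         # season length
    "t_l": 1.0,       # host emergence window length
}


@dataclass(frozen=True)
class ModelParams:
    """All rates and phenology constants for one parasite strain in one environment.

    Parameters
    ----------
    alpha : float
        Transmission rate, per (parasite x time).
    beta : float
        Number of parasites released upon host death.
    delta : float
        Environmental parasite decay rate, per time.
    mu : float
        Host background death rate, per time.
    tau : float
        Delay between infection and parasite-induced host death (inverse
        virulence).  May exceed ``T``, in which case no progeny are released.
    sigma : float
        Host fecundity multiplier of the between-season Beverton-Holt map.
    rho : float
        Density-dependence parameter of host reproduction, per host.
    T : float
        Season length.
    t_l : float
        Host emergence window length; hosts emerge uniformly on ``[0, t_l]``.
        ``t_l = 0`` means perfectly synchronous emergence at ``t = 0``.
    """

    alpha: float = DEFAULT_PARAM_VALUES["alpha"]
    beta: float = DEFAULT_PARAM_VALUES["beta"]
    delta: float = DEFAULT_PARAM_VALUES["delta"]
    mu: float = DEFAULT_PARAM_VALUES["mu"]
    tau: float = DEFAULT_PARAM_VALUES["tau"]
    sigma: float = DEFAULT_PARAM_VALUES["sigma"]
    rho: float = DEFAULT_PARAM_VALUES["rho"]
    T: float = DEFAULT_PARAM_VALUES["T"]
    t_l: float = DEFAULT_PARAM_VALUES["t_l"]

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "delta", "mu", "sigma", "rho", "T"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise ValueError(f"parameter 'tau' must be strictly positive, got {self.tau!r}")
        if not np.isfinite(self.t_l) or self.t_l < 0:
            raise ValueError(f"parameter 't_l' must be non-negative, got {self.t_l!r}")
        if self.t_l > self.T:
            raise ValueError(
                f"emergence window t_l={self.t_l!r} cannot exceed season length T={self.T!r}"
            )

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ModelParams":
        unknown = set(data) - set(DEFAULT_PARAM_VALUES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{**DEFAULT_PARAM_VALUES, **data})


@dataclass(frozen=True)
class SeasonState:
    """Host cohort size and parasite density at the start of a season.

    Densities are absolute counts; the extinction threshold used elsewhere
    (density 1) only makes sense on this absolute scale.
    """

    s_hat: float
    v_hat: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.s_hat) or self.s_hat < 0:
            raise ValueError(f"s_hat must be finite and >= 0, got {self.s_hat!r}")
        if not np.isfinite(self.v_hat) or self.v_hat < 0:
            raise ValueError(f"v_hat must be finite and >= 0, got {self.v_hat!r}")

    def __iter__(self) -> Iterator[float]:
        yield self.s_hat
        yield self.v_hat


@dataclass(frozen=True)
class WithinSeasonTrajectory:
    """Densities on a time grid over one season for a single parasite strain.

    Attributes
    ----------
    t_grid : ndarray
        Strictly increasing times in ``[0, T]``.
    s : ndarray
        Susceptible host density.
    v1 : ndarray
        Infecting-generation parasite density (``v_hat * exp(-delta t)``).
    v2 : ndarray
        Progeny parasite density; zero for ``t < tau``.
    """

    t_grid: np.ndarray
    s: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    params: ModelParams = field(compare=False, default=None)  # type: ignore[assignment]

    def to_frame(self, season: int = 0):
        """Tidy DataFrame with columns season, t, s, v1, v2."""
        import pandas as pd

        return pd.DataFrame(
            {"season": season, "t": self.t_grid, "s": self.s, "v1": self.v1, "v2": self.v2}
        )
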
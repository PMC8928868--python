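"""Stochastic adaptive walks of the virulence trait.

A monomorphic parasite population runs on its ecological attractor; every
1000 seasons a single mutant particle with a virulence delay drawn from
``Normal(dominant tau, 0.1)`` is introduced, and the multi-strain ecological
dynamics decide its fate (strains below unit density are pruned).  The walk
records each mutant event and stops once the dominant trait has settled at
the optimum.  Disabling the between-season host feedback (constant emerging
cohort) gives the stable control in which demographic cycles cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, SeasonState
from .dynamics import iterate_seasons, DEFAULT_INITIAL, EXTINCTION_THRESHOLD
from .invasion import StrainTraits, MultiStrainState, multistrain_season_map

__all__ = ["WalkSettings", "AdaptiveWalkRecord", "adaptive_walk"]


@dataclass(frozen=True)
class WalkSettings:
    """Protocol knobs of the adaptive-walk experiment.

    The defaults are the experiment as run: first mutant at season 100 (the
    ecological dynamics are on their attractor by then), one mutant per 1000
    seasons, mutation kernel SD 0.1, extinction below density 1, and the walk
    terminates once the dominant ``tau`` has stayed within 0.05 (half a
    mutational step) of ``tau*`` for three consecutive events.
    """

    first_mutant_season: int = 100
    mutant_interval_seasons: int = 1000
    mutation_sd: float = 0.1
    extinction_threshold: float = EXTINCTION_THRESHOLD
    ess_tolerance: float = 0.05
    ess_consecutive: int = 3
    max_events: int = 200
    initial: SeasonState = DEFAULT_INITIAL
    host_constant: float | None = None  # set -> demographic feedback disabled


@dataclass
class AdaptiveWalkRecord:
    """One row per introduced mutant, plus the walk-level outcome.

    ``events_to_optimum`` counts mutants introduced up to and including the
    first event of the confirmed arrival at ``tau*`` (None if never reached).
    """

    params: ModelParams
    tau0: float
    tau_star: float
    seed: int | None
    settings: WalkSettings
    events: list[dict] = field(default_factory=list)
    status: str = "running"  # reached_optimum | max_events | parasite_extinct
    events_to_optimum: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.events,
            columns=[
                "event_index",
                "season",
                "resident_tau",
                "mutant_tau",
                "outcome",
                "dominant_tau_after",
            ],
        )


def _dominant_tau(state: MultiStrainState) -> float:
    traits, _ = max(state.strains, key=lambda sv: sv[1])
    return traits.tau_m


def adaptive_walk(
    params: ModelParams,
    tau0: float,
    tau_star: float,
    seed: int | np.random.Generator | None = None,
    settings: WalkSettings = WalkSettings(),
) -> AdaptiveWalkRecord:
    """Run one adaptive walk starting from resident virulence delay ``tau0``.

    ``tau_star`` is the optimum used in the stopping rule (computed once by
    :func:`phenocycle.invasion.ess_tau` and passed in, so replicate walks
    share it).  ``seed`` feeds one generator for the whole walk; the record
    stores it for bit-reproducibility.
    """
    if not 0.0 < tau0 < params.T:
        raise ValueError(f"tau0={tau0!r} must lie in (0, T)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    st = settings
    p = params.replace(tau=tau0)
    record = AdaptiveWalkRecord(
        params=p, tau0=tau0, tau_star=tau_star, seed=seed_val, settings=st
    )

    # burn-in: monomorphic resident settles on its attractor
    if st.host_constant is None:
        base = iterate_seasons(p, st.initial, st.first_mutant_season, st.extinction_threshold)
        s_hat = float(base.s_hat_series[-1])
        v_hat = float(base.v_hat_series[-1])
    else:
        state1 = MultiStrainState(
            s_hat=st.host_constant, strains=[(StrainTraits.from_params(p), st.initial.v_hat)]
        )
        for _ in range(st.first_mutant_season):
            state1 = multistrain_season_map(
                p, state1, st.extinction_threshold, host_constant=st.host_constant
            )
            if not state1.strains:
                break
        s_hat = st.host_constant
        v_hat = state1.strains[0][1] if state1.strains else 0.0
    if v_hat <= 0.0:
        record.status = "parasite_extinct"
        return record

    state = MultiStrainState(s_hat=s_hat, strains=[(StrainTraits.from_params(p), v_hat)])
    season = st.first_mutant_season
    consecutive = 0

    for event in range(1, st.max_events + 1):
        resident_tau = _dominant_tau(state)
        while True:
            tau_m = resident_tau + rng.normal(0.0, st.mutation_sd)
            if 0.0 < tau_m < p.T:  # redraw trivially dead phenotypes
                break
        mut_traits = StrainTraits.from_params(p, tau_m=tau_m)
        state = MultiStrainState(
            s_hat=state.s_hat, strains=state.strains + [(mut_traits, 1.0)]
        )
        for _ in range(st.mutant_interval_seasons):
            state = multistrain_season_map(
                p, state, st.extinction_threshold, host_constant=st.host_constant
            )
            if not state.strains:
                break
        season += st.mutant_interval_seasons
        if not state.strains:
            record.status = "parasite_extinct"
            return record
        mutant_alive = any(tr is mut_traits for tr, _ in state.strains)
        dominant_after = _dominant_tau(state)
        record.events.append(
            {
                "event_index": event,
                "season": season,
                "resident_tau": resident_tau,
                "mutant_tau": float(tau_m),
                "outcome": "invaded" if mutant_alive else "extinct",
                "dominant_tau_after": dominant_after,
            }
        )
        if abs(dominant_after - tau_star) <= st.ess_tolerance:
            consecutive += 1
            if consecutive >= st.ess_consecutive:
                record.status = "reached_optimum"
                record.events_to_optimum = event - st.ess_consecutive + 1
                return record
        else:
            consecutive = 0
    record.status = "max_events"
    return record
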
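"""High-level experiment drivers shared by the CLI, examples, and scripts.

Each driver takes a validated :class:`~phenocycle.config.ScenarioConfig`
(and a seed where randomness is involved) and returns plain tabular results;
the CLI layers file output and provenance on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .params import ModelParams, SeasonState
from .dynamics import (
    iterate_seasons,
    classify_dynamics,
    bifurcation_scan,
    phase_boundary,
    parasite_free_fixed_point,
)
from .invasion import ess_tau, phase_dependent_invasion
from .evolve import adaptive_walk, WalkSettings

__all__ = [
    "run_simulate",
    "run_bifurcation",
    "run_phase_diagram",
    "run_ess",
    "run_invade",
    "run_evolve",
    "WalkExperimentResult",
    "walk_experiment",
]


def _initial(cfg: ScenarioConfig) -> SeasonState:
    return SeasonState(cfg.settings["s_hat0"], cfg.settings["v_hat0"])


def run_simulate(cfg: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Multi-season run; returns the series and its classification summary."""
    s = cfg.settings
    series = iterate_seasons(cfg.params, _initial(cfg), s["n_seasons"])
    window = min(s["window"], s["n_seasons"])
    burn_in = min(s["burn_in"], s["n_seasons"] - window)
    cls = classify_dynamics(series, burn_in, window)
    summary = {
        "label": cls.label,
        "relative_amplitude": cls.relative_amplitude,
        "period_estimate": cls.period_estimate,
        "host_parasite_peak_lag": cls.host_parasite_peak_lag,
    }
    return series.to_frame(), summary


def run_bifurcation(cfg: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Scan virulence delays; returns per-tau window densities and the edges."""
    s = cfg.settings
    n = int(round((s["tau_max"] - s["tau_min"]) / s["tau_step"]))
    grid = s["tau_min"] + s["tau_step"] * np.arange(n + 1)
    scan = bifurcation_scan(
        cfg.params, grid, s["burn_in"], s["window"], _initial(cfg), s["amplitude_threshold"]
    )
    try:
        lower, upper = scan.cycling_window()
        summary = {"cycling_tau_lower": lower, "cycling_tau_upper": upper}
    except ValueError:
        summary = {"cycling_tau_lower": None, "cycling_tau_upper": None}
    return scan.to_frame(), summary


def run_phase_diagram(cfg: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Stable-vs-cycling label over a (T, t_l) phenology grid at the local optimum."""
    s = cfg.settings
    provider = lambda T, t_l: ess_tau(cfg.params.replace(T=T, t_l=t_l))
    grid = phase_boundary(s["T_grid"], s["t_l_grid"], cfg.params, provider,
                          s["burn_in"], s["window"])
    rows = [
        {"T": T, "t_l": t_l, "label": grid[i, j]}
        for i, T in enumerate(s["T_grid"])
        for j, t_l in enumerate(s["t_l_grid"])
    ]
    df = pd.DataFrame(rows)
    return df, {"n_cycling": int((df["label"] == "cycling").sum())}


def run_ess(cfg: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    s = cfg.settings
    hc = s["host_constant"]
    tau_star = ess_tau(cfg.params, host_constant=hc)
    df = pd.DataFrame([{"T": cfg.params.T, "t_l": cfg.params.t_l, "tau_star": tau_star}])
    return df, {"tau_star": tau_star}


def run_invade(cfg: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    s = cfg.settings
    intro = range(s["burn_in"], s["burn_in"] + s["intro_count"])
    results = phase_dependent_invasion(
        cfg.params, s["resident_tau"], s["mutant_tau"], intro,
        burn_in=s["burn_in"], horizon=s["horizon"], persist=s["persist"],
    )
    df = pd.DataFrame(
        [
            {
                "intro_season": r.intro_season,
                "s_hat_at_intro": r.s_hat_at_intro,
                "v_hat_at_intro": r.v_hat_at_intro,
                "outcome": r.outcome,
            }
            for r in results
        ]
    )
    n_inv = int((df["outcome"] == "invaded").sum())
    return df, {"n_invaded": n_inv, "n_extinct": len(df) - n_inv}


@dataclass
class WalkExperimentResult:
    """Replicate adaptive walks under one condition."""

    tau_star: float
    records: list
    condition: str  # cycling | stable

    @property
    def events_to_optimum(self) -> list[int | None]:
        return [r.events_to_optimum for r in self.records]

    def mean_events(self) -> float:
        vals = [e for e in self.events_to_optimum if e is not None]
        if not vals:
            raise RuntimeError("no walk reached the optimum")
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for i, r in enumerate(self.records):
            df = r.to_frame()
            df.insert(0, "replicate", i)
            df.insert(1, "tau0", r.tau0)
            df.insert(2, "walk_seed", r.seed)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def walk_experiment(
    params: ModelParams,
    seed: int,
    n_replicates: int = 12,
    constant_cohort: bool = False,
    tau0_offset: float = 0.5,
    settings: WalkSettings | None = None,
    tau_star: float | None = None,
) -> WalkExperimentResult:
    """Replicate adaptive walks, half starting below and half above the optimum.

    With ``constant_cohort`` the emerging host cohort is pinned at the
    parasite-free equilibrium size, removing the demographic feedback (the
    stable control); the optimum used for starting points and the stopping
    rule is computed for the corresponding system.
    """
    hc = parasite_free_fixed_point(params).s_hat if constant_cohort else None
    if tau_star is None:
        tau_star = ess_tau(params, host_constant=hc)
    base = settings or WalkSettings()
    st = WalkSettings(**{**base.__dict__, "host_constant": hc})
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_replicates):
        tau0 = tau_star - tau0_offset if i < n_replicates // 2 else tau_star + tau0_offset
        walk_seed = int(rng.integers(2**31))
        records.append(adaptive_walk(params, tau0, tau_star, seed=walk_seed, settings=st))
    return WalkExperimentResult(
        tau_star=tau_star, records=records, condition="stable" if constant_cohort else "cycling"
    )


def run_evolve(cfg: ScenarioConfig, seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    s = cfg.settings
    st = WalkSettings(
        first_mutant_season=s["first_mutant_season"],
        mutant_interval_seasons=s["mutant_interval_seasons"],
        mutation_sd=s["mutation_sd"],
        extinction_threshold=s["extinction_threshold"],
        max_events=s["max_events"],
    )
    use_seed = seed if seed is not None else s["seed"]
    if use_seed is None:
        use_seed = 0
    res = walk_experiment(
        cfg.params,
        seed=int(use_seed),
        n_replicates=s["n_replicates"],
        constant_cohort=bool(s["constant_cohort"]),
        settings=st,
    )
    summary = {
        "condition": res.condition,
        "tau_star": res.tau_star,
        "mean_events_to_optimum": res.mean_events(),
        "n_reached": sum(e is not None for e in res.events_to_optimum),
    }
    return res.to_frame(), summary
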
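"""Named reference scenarios: the headline experiments shipped as configs.

Each scenario reproduces one of the package's flagship analyses in the
short-season, synchronous-emergence environment (``T=4``, ``t_l=1``):
the virulence bifurcation scan and a cycling run, the phenology phase
diagram, the phase-dependent invasion experiment, and the paired adaptive
walks (cycling vs constant-cohort control).
"""

from __future__ import annotations

from .config import ScenarioConfig
from .params import ModelParams

__all__ = ["reference_scenarios"]


def reference_scenarios() -> dict[str, ScenarioConfig]:
    """Version-controlled scenario set keyed by name."""
    base = ModelParams(T=4.0, t_l=1.0, tau=2.8)
    return {
        "fig2_bifurcation": ScenarioConfig(
            experiment="bifurcation",
            params=base,
            settings={"tau_min": 2.5, "tau_max": 3.5, "tau_step": 0.01,
                      "burn_in": 800, "window": 100},
            name="fig2_bifurcation",
        ),
        "fig2_cycling_run": ScenarioConfig(
            experiment="simulate",
            params=base,
            settings={"n_seasons": 900, "burn_in": 800, "window": 100},
            name="fig2_cycling_run",
        ),
        "fig3_phase": ScenarioConfig(
            experiment="phase_diagram",
            params=base,
            settings={"T_grid": [3.0, 4.0, 5.0, 6.0, 8.0], "t_l_grid": [0.5, 1.0, 2.0]},
            name="fig3_phase",
        ),
        "fig4_invasion": ScenarioConfig(
            experiment="invade",
            params=base,
            settings={"resident_tau": 2.8, "mutant_tau": 2.81, "burn_in": 800,
                      "intro_count": 15},
            name="fig4_invasion",
        ),
        "fig5_cycling_evolution": ScenarioConfig(
            experiment="evolve",
            params=base,
            settings={"n_replicates": 12, "constant_cohort": False},
            name="fig5_cycling_evolution",
        ),
        "fig5_stable_evolution": ScenarioConfig(
            experiment="evolve",
            params=base,
            settings={"n_replicates": 12, "constant_cohort": True},
            name="fig5_stable_evolution",
        ),
    }
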
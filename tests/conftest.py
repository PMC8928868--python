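import numpy as np
import pytest

from phenocycle import ModelParams, SeasonState


@pytest.fixture(scope="session")
def ref_params() -> ModelParams:
    """Short-season, synchronous-emergence reference environment."""
    return ModelParams(T=4.0, t_l=1.0, tau=2.8)


@pytest.fixture(scope="session")
def ref_state() -> SeasonState:
    return SeasonState(s_hat=1e4, v_hat=1e4)


@pytest.fixture(scope="session")
def random_draws(ref_params):
    """Randomized parameter/state draws, log-uniform around the baseline values."""
    rng = np.random.default_rng(20260925)
    draws = []
    for _ in range(20):
        f = lambda: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        T = ref_params.T * f()
        t_l = min(T, ref_params.t_l * f())
        p = ModelParams(
            alpha=ref_params.alpha * f(),
            beta=ref_params.beta * f(),
            delta=ref_params.delta * f(),
            mu=ref_params.mu * f(),
            tau=float(rng.uniform(0.5, T * 1.2)),  # tau > T draws are legal
            sigma=ref_params.sigma * f(),
            rho=ref_params.rho * f(),
            T=T,
            t_l=t_l,
        )
        st = SeasonState(
            s_hat=float(10 ** rng.uniform(3, 6)), v_hat=float(10 ** rng.uniform(2, 6))
        )
        draws.append((p, st))
    return draws


@pytest.fixture(scope="session")
def cycling_series(ref_params):
    """Long run on the quasiperiodic attractor at tau=2.8, T=4, t_l=1."""
    from phenocycle import iterate_seasons

    return iterate_seasons(ref_params, SeasonState(1e4, 1e2), 900)
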
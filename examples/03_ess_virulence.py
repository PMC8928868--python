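"""Invasion fitness and the evolutionarily stable virulence delay.

A rare mutant's fitness is its end-of-season progeny count v2m(T) from one
particle introduced into the resident-at-equilibrium environment: invasion
requires v2m(T) >= 1.  The ESS tau* zeroes the selection gradient; shorter
host emergence windows select for later host killing (larger tau*).
"""

from phenocycle import (
    ModelParams, StrainTraits, endemic_fixed_point, invasion_fitness, ess_tau,
)

params = ModelParams(T=4.0, t_l=1.0, tau=3.5)  # stable-regime resident
env = endemic_fixed_point(params)
print(f"resident equilibrium: s_hat* = {env.s_hat:.4g}, v_hat* = {env.v_hat:.4g}")

for tau_m in (3.3, 3.5, 3.7):
    f = invasion_fitness(env, StrainTraits.from_params(params, tau_m=tau_m), params)
    if abs(f - 1.0) < 1e-3:
        verdict = "neutral (the resident's own trait)"
    else:
        verdict = "invades" if f >= 1.0 else "fails"
    print(f"  mutant tau_m={tau_m}: v2m(T) = {f:.4f}  -> {verdict}")

for t_l in (1.0, 0.5):
    tau_star = ess_tau(params.replace(t_l=t_l))
    print(f"ESS virulence delay at T=4, t_l={t_l}: tau* = {tau_star:.3f}")
print("more synchronous emergence (smaller t_l) pushes the optimal kill time")
print("later, so progeny spend less time decaying in the environment.")
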
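# Methods

## Model

The model couples continuous within-season transmission dynamics to a
discrete between-season demographic map (a "semi-discrete" model).  One
parasite generation per season (monocyclic), obligate killing, and no
reinfection by the progeny generation within the season are structural
assumptions; hosts are univoltine with non-overlapping generations.

Within a season of length `T` (time units arbitrary but fixed):

* hosts emerge at per-capita rate `g(t, t_l)`, uniform on `[0, t_l]`
  (`t_l = 0` is supported as a distinct code path: the whole cohort is
  present at `t = 0`);
* free parasites `v1` start at the season's inoculum `v̂(n)` and only decay
  (`δ`); parasite loss through transmission is neglected, the standard
  assumption for free-living stages produced in large bursts;
* an infection at time `t` kills the host at `t + τ` and releases `β`
  progeny, discounted by `e^{−μτ}` for infected hosts that die of
  background mortality first; progeny decay at `δ` until season end;
  infections whose delay crosses the season end release nothing.

Between seasons: Beverton–Holt recruitment `ŝ(n+1) = σ s(T)/(1 + ρ s(T))`
and parasite carry-over `v̂(n+1) = v2(T)`.  Densities are absolute counts;
a between-season parasite density below 1 individual is set extinct.  This
threshold is applied to `v̂` (and per strain in multi-strain runs), matching
the evolutionary protocol and preventing sub-unity densities from
sustaining dynamics.

Parameter defaults: `α = 3.5e-7` per (parasite·time), `β = 200`, `δ = 2`,
`μ = 0.25`, `σ = 500`, `ρ = 1e-4`, with phenology `T = 4`, `t_l = 1` and
virulence delay `τ = 2.8` as the reference environment.  These defaults are
the study conditions for every experiment in the package; `τ`, `T`, `t_l`
are the axes the experiments scan.

## Within-season solver

Because `v1` is autonomous linear decay, the host equation is a linear
scalar ODE with integrating factor `exp(Φ(t))`,
`Φ(t) = μt + Σ_i (α_i v̂_i/δ_i)(1 − e^{−δ_i t})` (summed over all strains
sharing the host), giving

    s(t) = (ŝ/t_l) ∫_0^{min(t, t_l)} e^{Φ(u) − Φ(t)} du.

In the progeny quadrature the decay factors cancel exactly
(`e^{−δ(t−x)} v1(x−τ) = v̂ e^{−δ(t−τ)}`), so

    v2(t) = α β e^{−μτ} v̂ e^{−δ(t−τ)} ∫_0^{t−τ} s(y) dy.

The two integrals are evaluated on composite 12-point Gauss–Legendre
panels.  Panel boundaries include the kink at `t = t_l` and every
requested output time, and are refined so that `Φ` changes by at most 1
per panel (`Φ` is increasing and concave, so its initial slope
`μ + Σ α_i v̂_i` bounds the step); with that bound the integrands are
analytic and vary by at most a factor `e` per panel, and the scheme is
accurate to ~1e-12 relative.  All exponentials are computed as
differences of `Φ` values, so the solver does not overflow even at the
10^8–10^9 parasite densities reached on the cycling attractor.  Inner
(partial-panel) integrals for `∫ s` use a nested 12-point rule.  The
invasion-fitness routine deliberately does **not** reuse this engine: it
evaluates the same closed forms by nested adaptive Gauss–Kronrod
quadrature (`scipy.integrate.quad`, abs tol 1e-10 / rel tol 1e-8, with the
emergence-window kink as an explicit breakpoint), so the two computations
of a mutant's seasonal growth are independent and are cross-checked in the
tests to 1e-3 relative.

An independent oracle (`phenocycle.oracle`) integrates the full delay
system by the method of steps: the season is segmented at
`{kτ, kτ + t_l}`, each segment advanced by adaptive 8th-order Runge–Kutta
(rtol 1e-10, per-component absolute floors 1e-13 of each density scale),
with delayed state read from stored dense output.  Semi-analytic and
oracle end-of-season states agree to better than 1e-5 relative on
randomized draws spanning a factor of 4 around every rate parameter.

## Attractor classification

Long runs iterate the season map from `(ŝ, v̂) = (1e4, 1e2)` (classification
is insensitive to this choice across an order of magnitude in each
coordinate; inocula too small to clear the unit extinction threshold on
the initial transient are genuinely parasite-free).  After a burn-in of
800 seasons, a 100-season window is classified:

* **parasite_free** if the parasite is extinct;
* relative amplitude `(max − min)/mean` of the window's parasite inoculum
  series; **endemic_equilibrium** if ≤ 1e-3 (separates numerical ringing
  from genuine orbits at the solver tolerances), else **cycling**;
* when cycling, the period is the mean spacing of local maxima (plateaus
  take the first index) and the host→parasite lag is the mean offset,
  modulo the period, from a host peak to the next parasite peak.

The lag pairs the **end-of-season survivor density** `s(T)` (the hosts that
actually reproduce) with the season-start parasite inoculum `v̂`.  This is
the pairing that expresses the delayed density dependence driving the
cycle — survivors in season `n` set the cohort of `n+1`, whose infections
produce the inoculum peak of `n+2` — and it is measured at 2–3 seasons on
the reference attractor.  Pairing season-start cohort with season-start
inoculum instead gives the same period with a lag smaller by exactly one
season.

Bifurcation edges are reported as the midpoint between the last
non-cycling and first cycling grid value.  Stability is checked
independently of the amplitude criterion by a central-difference Jacobian
of the season map at its fixed point (found by root-finding in log
coordinates, so the unstable coexistence point inside the cycling regime
is still located); a complex eigenvalue pair crossing the unit circle at
the window edges identifies the bifurcation as Neimark–Sacker type.

## Invasion fitness and the ESS

A mutant's invasion fitness is `v2m(T)` produced by a single particle
(`v1m(0) = 1`) over one season in the resident-at-equilibrium environment,
with the host depleted by both strains; invasion requires `v2m(T) ≥ 1`, and
a mutant identical to the resident has fitness exactly 1 (neutrality, a
tested property).  The expression changes analytic form at
`τm = T − t_l` (whether the release integral ends inside the emergence
window); the quadrature treats the boundary as a panel edge and the value
is continuous there.  `ess_tau` zeroes the central-difference selection
gradient (step 1e-3 in `τm`, resident equilibrium recomputed at every
candidate, Brent's method to 1e-3) and verifies local concavity of the
fitness profile.  Inside the cycling window the coexistence fixed point is
unstable; the solver still uses it as the resident environment — the same
analytic continuation the equilibrium theory rests on — and the adaptive
walks confirm by simulation that evolution settles at this optimum.  For
the constant-cohort control the resident environment is the 1-D parasite
equilibrium on the fixed cohort, and the control's own `τ*` (2.981 vs
2.976 with feedback at the reference phenology) is used.

## Adaptive walks

Protocol per walk: 100 burn-in seasons of the monomorphic resident; then,
every 1000 seasons, one mutant particle with `τm ~ Normal(dominant τ, 0.1)`
(redrawn if outside `(0, T)`, since such phenotypes are trivially dead);
strains below density 1 pruned at season ends; no cap on concurrent
strains (pruning keeps the count small); mutation decoupled from parasite
population size.  The dominant trait is that of the highest-density
strain.  A walk has reached the optimum when the dominant `τ` stays within
0.05 of `τ*` (half a mutational SD) for three consecutive events; the
reported mutants-to-optimum is the first event of that run.  Walks are
capped at 200 events so a run always terminates; the cap is far above the
observed range.  One seeded generator drives each walk and the seed is
stored in the record, so a walk is bit-reproducible.

The experiment runs 12 replicates per condition, six starting at
`τ* − 0.5` and six at `τ* + 0.5` (five mutational SDs, outside the cycling
window on both sides).  The stable control pins the emerging cohort at the
parasite-free equilibrium (~4.98e6 hosts at the reference parameters),
the cohort the feedback system would sustain without parasitism.  With
feedback, cycling begins once the dominant trait enters the cycling
window and a large fraction of advantageous mutants is lost to
demographic bottlenecks; the mean mutants-to-optimum is therefore
substantially larger than in the control, and the terminal approach (the
last ~0.1 of `τ`) is the slowest stage.  The mean count in the cycling
condition is sensitive to protocol details that have no canonical choice
(starting distance, arrival definition); the ordering cycling > stable is
robust to all of them.

## What the experiments do and do not show

All inputs are generated by the model itself; there is no external data.
The synthetic conditions emulate a tightly seasonal obligate-killer
system with deterministic ecology — demographic stochasticity, drift,
host evolution, polycyclic transmission, and non-obligate killing are all
outside scope.  In particular the extinction threshold stands in for
demographic stochasticity at low density, and mutants appear at a fixed
schedule regardless of population size, so the walk results quantify the
ecological filter on adaptive mutants, not mutation limitation.

## Problem sizes

Default experiment sizes: 900-season runs for classification (bifurcation
scans: 101 τ values × 900 seasons); 12 introduction phases × 250–300
seasons for the phase-dependent invasion sweep; 12 replicate walks per
condition with 1000 seasons per mutant event.  The full acceptance run
takes ~10 minutes on one CPU.

## Known limitations

* The `(T, t_l)` phase diagram solves an ESS per grid cell and is the most
  expensive analysis; grids should stay coarse.
* `quad`-based invasion fitness warns/falls back slowly when the resident
  equilibrium density is extreme (α v̂*/δ ≫ 10²); the panel engine handles
  those regimes and is used everywhere performance matters.
* Period and lag estimates are discrete (season-resolution) statistics on
  a quasiperiodic orbit; they are means with spread ~1 season, not sharp
  frequencies.
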
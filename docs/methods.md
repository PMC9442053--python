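# Methods

## Model

`drumalg` implements a reduced kinetic model of the central carbon metabolism
of the haptophyte microalga *Tisochrysis lutea* under nitrogen limitation.
The full metabolic network is replaced by seven macroscopic reactions (MRs),
each the net stoichiometry of a quasi-steady-state sub-network —
photosynthesis (MR1), upper glycolysis in both directions (MR2/MR2'), lower
glycolysis (MR3, reversible), carbohydrate synthesis (MR4, reversible),
neutral-lipid synthesis (MR5, reversible) and functional-biomass synthesis
(MR6).  The junction metabolites GAP, G6P, PEP, PA (neutral lipids as
phosphatidic acid) and CARB (carbohydrates) are allowed to accumulate;
functional biomass B (proteins, nucleic acids, chlorophyll, membrane lipids)
is everything else.  Four excretion variants each add a single macro-reaction
MR7 draining one accumulating pool to a dissolved product: CARB→EPS,
G6P→EPS, PEP→acetate, GAP→glycerol.  The no-excretion variant is `w/oEx`.

The dynamic state x = (S, GAP, G6P, PEP, PA, CARB, B, P) in mol/L (S nitrate,
P the excreted product) obeys

    dx/dt = K' α(x, t) B + D(t) S_in(t) e_S − D(t) x

with K' the stoichiometric matrix over the dynamic species, D the dilution
rate and S_in the inflow nitrate.  Kinetics are mass action on intracellular
ratios: α_MR1 = k_MR1·I(t), α_MR2 = k_MR2·GAP/B, reversible reactions carry a
primed reverse constant (e.g. α_MR4 = k_MR4·G6P/B − k_MR4'·CARB/B),
α_MR5 = k_MR5·(GAP/B)(PEP/B) − k_MR5'·PA/B, and biomass synthesis
α_MR6 = k_MR6·(PEP/B)(G6P/B)(PA/B)·S.  All α are specific rates in 1/h; the
published per-mole unit annotations of the rate constants are not dimensionally
self-consistent, so the package adopts the convention that pool ratios are
dimensionless and each k·(ratio product) is an hourly rate (k_MR6 additionally
carries L/mol for the nitrate factor, k_MR1 carries the per-light-intensity
unit).  k_MR1 is capped at the quantum limit of photosynthesis,
4.5×10⁻³ µE⁻¹ m² s h⁻¹ molB⁻¹ (16 m²/gChl absorption, 10 photons per fixed
carbon).

Element bookkeeping is solved, not assumed: carbon/nitrogen atom counts per
species follow uniquely from requiring every reaction to balance, anchored at
CO2 (1 C), NO3 (1 N) and GAP (3 C).  This yields C(PA) = 36.22,
C(B) = 8.5442, N(B) = 1.31, C(EPS) = 6, C(acetate) = 2, C(glycerol) = 3, and
is enforced by tests for all five variants (tolerance 1e-6 atoms, well below
the two-decimal print rounding of the coefficients).  Cofactors (ATP/ADP,
NAD(H), NADP(H), Pi, H, H2O, O2, SO4, Mg) are carried in the stoichiometry
but are carbon/nitrogen-free audit species, excluded from the dynamic state.

Observables: particulate carbon X_C = Σ C_A·A + C_B·B and nitrogen
X_N = N_B·B (mol/L and g/L); storage quotas as carbon fractions of X_C;
N:C quota in gN/gC; chlorophyll as a fixed fraction θ_chl of the carbon mass
of B (default 0.05 g Chl per gC of B — the composition of B is not published,
so this is one exposed scaling constant).  The excreted product P is
dissolved organic carbon and is excluded from (particulate) X_C.

## Numerics

Integration uses LSODA (default rtol 1e-8, atol 1e-12) with forcing
discontinuities — day/night light kinks, dilution/inflow steps, nitrate
pulses — as segment boundaries; pulses are instantaneous state jumps.
Reversible ratio kinetics can numerically drive an exhausted pool negative;
any reaction rate is zeroed in the direction that consumes a pool at or below
a floor of 1e-12 mol/L.  Whole reactions are switched off, never single
stoichiometric entries, so element balance is preserved exactly: on the
default day/night protocol the carbon and nitrogen closure residuals
(integrated net CO2 exchange and dilution bookkeeping carried as auxiliary
quadratures) are at the 1e-14 relative level.

Light under day/night forcing is a half-sinusoid,
I(t) = I_max·sin(π t_day/12 h) during the photoperiod and 0 at night
(I_max = 1500 µmol m⁻² s⁻¹ by default), a standard reconstruction of a
monitored 12h:12h cycle; any callable I(t) can be injected instead.

### Chemostat steady states

Because dilution cancels in the pool ratios a = A/B, the intensive subsystem
da/dt = (K'α)_A − a·α_MR6 at fixed nitrate S is autonomous and small.  The
solver (i) settles this subsystem (integration in chunks with a Newton
finish; Newton directly when warm-started along a nitrate continuation),
giving the maximum sustainable growth rate μ*(S); (ii) declares washout when
D > μ*(S_in); (iii) otherwise root-finds the residual nitrate S* with
μ*(S*) = D and reconstructs biomass from the nitrogen balance
B = (S_in − S*)/N_B; then (iv) confirms the candidate on the full system by
integrating until the relative state change over a 24 h window is below
tolerance (default 1e-6) and polishing with a Newton solve.  Additional
settles from randomly perturbed ratios (seeded) check that the internal
equilibrium does not depend on the start; the maximum disagreement is
reported.  At a converged non-washout equilibrium the specific net
particulate-carbon production equals D to roundoff, which the acceptance
suite checks at 1e-3 relative.

A consequence of the pure mass-action nitrate dependence of MR6 is that
steady-state quotas are independent of S_in (which only scales biomass),
while the washout threshold μ*(S_in) grows slowly with S_in.  The default
chemostat inflow (5×10⁻² molN/L, a concentrated non-limiting feed) keeps the
standard dilution sweep 0.1–1.0 d⁻¹ below washout for the EPS-excretion
variant; sweeps extending to 1.4 d⁻¹ flag the top rates as washout and
exclude them from exported tables.

## Calibration

Parameters are estimated by minimising the scaled sum of squared residuals
between simulated observables and measurements, simulated from 5 days before
the first measurement (warm-up) so results do not depend on the initial
state.  Residual scale is the per-observation standard deviation where given,
else the observable's dataset mean — so absolute SSE values depend on this
convention but SSE ratios between variants do not.  Optimisation is
multistart Nelder–Mead in log10 parameter space (constants are positive and
span decades), with starts drawn log-uniformly inside order-of-magnitude
bounds and per-start seeds derived deterministically from one master seed.
Box constraints, including the quantum-limit cap on k_MR1, are enforced by a
smooth quadratic penalty (weight 1e6 on relative violation) plus a hard clamp
at the cap, which keeps the simplex well behaved near bounds.

Uncertainty uses the Fisher information matrix FIM = Σ_i J_i W J_iᵀ with
diagonal measurement precision W = 1/scale² and output sensitivities by
central finite differences (relative step 1e-4).  Parameter standard
deviations are sqrt(diag(FIM⁻¹)) (Moore–Penrose fallback, flagged); output
uncertainty bands propagate σ_y²(t) = Σ_j (∂y/∂θ_j)² σ_θj² and deliberately
ignore parameter covariances, a known understatement.  Variants are compared
with AICc = n ln(SSE/n) + 2(p+1) + 2(p+1)(p+2)/(n−p−2).  Where a reported
table gives (SSE, p, AICc) but not n, `infer_sample_size` recovers every
integer n consistent with the rounded AICc values — a consistency oracle used
by the acceptance script.

The recovery experiments shipped with the package estimate the three
well-identified constants (k_MR1, k_MR5', k_EX, the ones with small relative
standard deviation in the reference calibration) with the remaining constants
held at their generating values.  The full 11-parameter problem is heavily
ill-identified (several constants have reference standard deviations larger
than their estimates), so subset recovery is the meaningful desk-scale check:
noiseless data are recovered within 5%, and over 20 noisy replicates at 5% CV
the 95% Wald intervals cover the generating values in ≥80% of checks.

## Droop add-on

Chemostat sweeps motivate a two-parameter quota law with an excretion add-on:
μ(q) = μ̄(1 − Q0/q), η(q) = η̄·Q0/q (excretion maximal at the minimum quota
and linear in the C/N ratio), and net primary production
μ + η = μ̄[1 − (1 − η̄/μ̄)Q0/q].  μ is linear in (μ̄, μ̄Q0) against 1/q, so
`fit_droop` is an exact linear least-squares solve (error minimised in μ
given q; the converse orientation is not implemented), exactly recovering
parameters from noiseless tables.  μ(q) is returned negative below Q0 as the
law is written; consumers clamp it when simulating.

Fitting the add-on to the EPS-excretion variant's own steady-state sweep
(D = 0.1–1.0 d⁻¹) yields μ̄ ≈ 1.7 d⁻¹ and Q0 ≈ 0.034 gN/gC — the minimum
quota emerges from carbon excretion capping storage accumulation, not from a
nitrogen reserve, which is the mechanistic reading of the Droop law this
model family supports.

## Synthetic data

The generator emulates two experiment layouts with the model itself:

* **Day/night starvation** — 12h:12h light peaking at 1500 µmol m⁻² s⁻¹ over
  8 measured days plus a 5-day warm-up; nitrogen starvation from day 1
  (inflow nitrate removed, dilution lowered from 0.25 to 0.1 d⁻¹ to avoid
  washout) to day 5.5, ended by a 2.7 mgN/L (0.193 mmol/L) nitrate pulse with
  simultaneous inflow restoration.  The replete-phase inflow (2 mmolN/L) and
  the nominal initial state (the dawn state of the replete periodic regime)
  are documented stand-ins: the real schedule is not published.  Sampling
  defaults to every 3 h in the photoperiod plus one night point; observables
  are X_C, X_N, chlorophyll, carbohydrate and lipid quotas, and nitrate.
* **Chemostat sweep** — constant light 430 µmol m⁻² s⁻¹, dilution rates in
  (0, 1.4] d⁻¹, exporting steady-state (q, μ = D, η, storage quotas, excreted
  fraction); washouts are flagged and excluded.

Noise is multiplicative Gaussian with configurable CV (default 5%), truncated
at zero, with the reported `sd` equal to CV × the noiseless value —
measurement errors in these assays scale with magnitude.  Everything is
reproducible from the integer seed.

What the generator does *not* emulate: instrument drift and detection limits,
replicate-vessel structure (available as an option, unused by default),
photoacclimation and any light-history dependence of the chlorophyll quota,
and self-shading in the reactor.  Passing the recovery tests therefore shows
the calibration machinery is correct and well calibrated under the model's
own assumptions, not that the model or the pipeline is validated against real
cultures.

## Known limitations

* The cofactor audit runs at macro-reaction granularity; the net ATP/NADPH
  balance is exact at this level, but the gross production/consumption split
  (and hence the percentage unbalance) differs from a whole-network flux
  decomposition, so unbalance figures are order-of-magnitude diagnostics.
  The sign convention (positive = excess production) is explicit; NADH
  pooling into the NADPH audit is optional and off by default.
* Per-reaction flux maps of the underlying 162-reaction network require the
  elementary-flux-mode matrices of the original reduction, which are not
  published; they are out of scope.
* Spatial light attenuation, temperature/pH dependence and simultaneous
  multiple excretion products are not modelled.
* Absolute SSE values depend on the residual-scaling convention and on the
  synthetic protocol; only scale-invariant comparisons (SSE ratios, AICc
  differences at fixed data) are meaningful across implementations.
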
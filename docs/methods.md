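# Methods

## Model and assumptions

The model couples two well-mixed compartments — prostate gland and lymphoid
tissue — through dendritic-cell, CTL and Treg trafficking, each migrating
cell reaching the other compartment with probability 0.5. All nineteen
state variables are dimensionless fold-changes relative to their value at
simulation start (an already-developed tumor in a 14-week-old animal), so
the baseline initial condition is 1 for every biological variable except
the androgen-independent clone (X2 = 0, absent before selective pressure)
and 0 for the five drug levels. Total tumor burden is X1 + X2 on the same
scale.

Key structural choices:

* **Androgen deprivation** is a boolean forcing, not a state: while active
  the androgen equation reduces to exponential decay with
  `lambda_A = ln(2)/7 d`; while inactive androgen self-restores to 1, so an
  untreated simulation keeps A = 1 exactly and therefore X2 = 0 exactly
  (there is no mutation flux without androgen depression).
* **Checkpoint blockade** multiplies the CTL killing rate by
  `1 + delta_ICB * I_CB`; **Treg/MDSC suppression of NK killing** uses the
  sum of two negative exponentials, which saturates to full suppression as
  either population grows.
* **Derived parameters.** `mu_N = K/m^(1/4)` with K = 0.0371 and
  m = 0.029 kg (0.09/day); `rho_N = mu_N - a_IN/(s_N + 1)` from the
  tumor-free steady state at baseline IL-2 (computed exactly rather than
  approximated by `mu_N`, preserving the no-tumor equilibrium); every drug
  decay rate is `ln(2)/t_half` with half-lives of 7 d (androgen, vaccine,
  anti-IL-2, anti-Treg), 5 d (checkpoint blockade) and 3.5 h (anti-MDSC).
* **Dosing resets.** Administration sets a drug variable *to* the dose
  amount instead of adding to the residual level; with additive dosing the
  daily anti-MDSC schedule would accumulate past its nominal amount, for
  which the drug-level semantics ("1 when administered") gives no support.
  NK transfer adds nine times the physiological pool per unit dose to the
  NK initial condition and is only meaningful at time 0.
* The two equations' shared IL-2-neutralisation constant is one parameter
  (`k_antiI`); the NK tumor-killing and NK-inactivation constants are kept
  distinct (`k_NX` vs `k_XN`), with `k_NT` accepted as an alias of `k_NX`
  at load time.

## Protocols

* **Uniform screening protocol** (28-day horizon): every selected therapy
  starts at day 0; castration stays active throughout; vaccine, anti-IL-2,
  anti-Treg and NK are single boluses at day 0 (their week-scale half-lives
  sustain exposure; a re-dosing frequency for them within the window is not
  specified anywhere, so the single bolus is the documented choice and
  screen rankings could shift under denser dosing); checkpoint blockade is
  given on days {0, 2, 4} of each week (a deterministic reading of
  "three times per week") and anti-MDSC daily.
* **ADT-then-immunotherapy protocol** (49-day horizon): castration from
  day 0, checkpoint blockade and/or anti-MDSC from day 21 for four weeks,
  endpoint at week 7. Where the sources disagree on which of the two drugs
  is thrice-weekly versus daily, the model-definition table wins (ICB
  3x/week, AM daily).
* **Calibration scenarios** (35-day horizon): the seven in-vivo fold-change
  scenarios are untreated, CX, V, AI, AR, CX+V and AI+AR, with tumor, CTL
  and Treg observed in both compartments at weeks 0, 2.5 and 5. The exact
  historical scenario list is not printed in the sources; this package's
  choice (the four monotherapies it can observe plus two pairings) is
  declared here and carried by the dataset schema, which is
  scenario-agnostic.

## Numerics

Integration is piecewise between dose events and castration boundaries
with LSODA at rtol 1e-8 / atol 1e-10 (a stiff-capable contract; the
short-half-life anti-MDSC drug makes the system moderately stiff), sampled
daily plus at all breakpoints; samples at a dose time store the post-dose
value. Calibration and objective evaluations relax to rtol 1e-6 — residuals
are compared at the 1e-2 level, and this halves runtime. Event-split
integration agrees with single-span integration to ~1e-7 absolute, which
is the tolerance used by the consistency tests. Negative states are
rejected at the public derivative interface but the integrator may probe
transiently negative values; trajectory non-negativity is guaranteed to
solver tolerance (~1e-9) because every variable's production terms are
non-negative at that variable's zero.

## Nominal parameters (synthetic)

The published supplementary parameter table was not available, so the
packaged file `params_nominal_synthetic.json` is an explicit synthetic
stand-in. Literature-fixed values are used verbatim: the migration
probabilities (0.5), all half-lives, the NK allometry (K = 0.0371,
m = 0.029 kg) and the 9x NK injection multiplier. The remaining rates were
fixed once from the model's documented behavioural anchors, in this order:

1. in-vitro NK co-culture (10:1 effector:target, 2 days) halves the tumor
   — fixes `k_NX` given `k_XN`;
2. in-vitro MDSC co-culture (5 days) leaves 42% of CTLs — fixes `k_MC`;
3. untreated tumor grows several-fold over 7 weeks while Tregs and MDSCs
   roughly double and CTLs/dendritic cells decline — fixes `r_p1` net of
   the killing terms and the Treg/MDSC source/turnover scales;
4. castration slows growth several-fold with full conversion to the
   androgen-independent clone by week 7 — fixes the `mu_1`/`r_M` balance
   and `r_p2 - mu_2`;
5. monotherapy inhibitions stay modest (tens of percent, castration
   strongest) — bounds `delta_ICB`, `k_antiMM`, `k_antiRR`.

With these nominals the headline simulations give untreated growth of
~10x, castration ~5x lower at week 7 (entirely androgen-independent), and
85% inhibition for castration plus ICB+anti-MDSC. Quantities that depend
on the unavailable calibrated values (exact inhibition percentages,
pairwise Bliss indices, the half-dose result) are *not* reproduced and are
not asserted anywhere; the test suite instead pins structure: oracle
agreement of the equations, closed forms, invariants, and calibration /
sensitivity self-consistency. In-vitro co-culture initial values are named
constants in the parameter file (`invitro_*_0`, fold-change units, both
arms starting at 1 except the 10:1 NK arm) because the cited absolute
counts were likewise unavailable.

## In-vitro sub-models

Co-culture simulations zero every variable absent from the experiment and
integrate the surviving equations unchanged. Two deliberate readings are
documented: androgen is held at 1 (cultured tumor lines keep proliferating;
zeroing A would engage the androgen-deprivation death term, which has no
in-vitro counterpart), and the constant NK/MDSC source terms survive in the
control arms, which therefore regrow a small effector population — the
effect is part of the model, not removed ad hoc. The MDSC anchor is
interpreted as a suppressed/unsuppressed *ratio* of 0.42, following the
least-squares target literally rather than the looser "reduced by 42%"
phrasing.

## Calibration

`Opt = Opt1 + Opt2 + Opt3`: nested mean absolute residuals over the seven
scenarios; weighted squared deviations of the two in-vitro ratios from
0.5 and 0.42; and weighted squared deviations of week-7 tumor and MDSC
ratios (each immunotherapy arm over the castration-only arm, shared
reference run). All weights default to 1 — the historical weights were
"empirically estimated" without published values — and are overridable.
`extrapolate_baseline` converts absolute infiltrate counts at weeks 6/9/16
of age to the fold-change scale by evaluating an OLS line at weeks 16 and
14 and taking the ratio.

The GA is real-coded with tournament selection (k = 2), BLX-0.5 blend
crossover on a 0.9 fraction of children, gaussian mutation whose scale
decays by 0.85 per generation (so late generations refine rather than
explore), 5% elitism, and a stall-based stop at the 1e-2 tolerance.
Population 200 / crossover 0.9 / tolerance 1e-2 are the published GA
settings and are the defaults; the operator details are this package's
own, chosen for deterministic, bounded-box real-parameter search, and are
logged with every run. Reduced budgets (population 20-24, ~20-40
generations) recover 2-5 free parameters from noiseless synthetic data to
an objective below 1e-2 in about one to two minutes on one CPU; those are
the problem sizes the tests use.

The synthetic dataset generator samples the seven scenarios at the
observation cadence, adds independent gaussian noise (truncated at zero)
to the time series only, and computes the ratio targets noiselessly from
the same parameters, so the generating parameters score exactly zero on a
noiseless dataset. It emulates sparse fold-change series with additive
noise; it does not emulate measurement-correlated errors, inter-animal
variability, or digitisation bias, so passing recovery tests demonstrate
identifiability under the model's own dynamics, not robustness to real
experimental error structure.

## Sensitivity analysis

Local: endpoint log-sensitivity by central finite difference with a 1%
relative step at day 49; a parameter multiplying an inactive term scores
exactly zero, and the step choice is validated against a fourth-order
stencil (agreement to O(delta^2)). Global: one-at-a-time integrated
central-difference profiles (trapezoidal quadrature on the daily output
grid — the continuous-integral definition names no quadrature rule, so the
output grid is the natural choice) evaluated at Latin-hypercube draws of
the parameter space, reporting the per-parameter median; failed draws are
dropped and counted. This is an OAT-at-random-points design, deliberately
not a variance-based (Sobol) analysis. Default sampled space: calibration
bounds for estimated parameters, +/-30% for the rest; default scenario set
{untreated, CX, CX+ICB}.

## Known limitations

* The nominal parameter set is synthetic; absolute screen rankings, Bliss
  indices and dose-reduction factors are illustrative of the machinery,
  not reproductions of published values.
* Screen rankings depend on the single-bolus convention for V/AI/AR/NK
  (see Protocols).
* No pharmacokinetic compartments beyond the two tissues, no spatial
  structure, no stochastic mutation, no toxicity model; structural
  identifiability analysis is out of scope.
* The bisection dose search assumes a monotone dose-response, which holds
  for the checked ICB-within-CX+ICB case but is not guaranteed globally.
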
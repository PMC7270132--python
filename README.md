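# pcaqsp

A quantitative systems pharmacology (QSP) model of prostate cancer
immunotherapy: a two-compartment ordinary-differential-equation description
of the tumor and its immune microenvironment, with tools for in-silico
combination-therapy screening, Bliss synergy analysis, genetic-algorithm
calibration and parameter sensitivity analysis.

The intended users are modellers and computational pharmacologists who want
to explore how androgen deprivation and six immunotherapies interact in
castration-resistant disease before committing to pre-clinical experiments.

## The model

Nineteen ODEs span two compartments. The **prostate gland** holds
androgen-dependent and androgen-independent tumor cells (X1, X2), mature
dendritic cells (Dm), effector CTLs (C2), NK cells (N), regulatory T cells
(R2), myeloid-derived suppressor cells (M), IL-2 (I2) and the androgen
level (A); the **lymphoid tissue** holds functional/regulatory dendritic
cells (Df, Dr), CTLs (C1), Tregs (R1) and IL-2 (I1). Five more variables
track exponentially decaying drug levels. Every biological variable is a
fold-change relative to its initial value. The androgen-dependent tumor
obeys

    dX1/dt = r_p1 A X1 - mu_1 (1 - A) X1 - r_M (1 - A) X1
             - k_CX (1 + delta_ICB I_CB) C2 X1
             - k_NX (e^(-k_RN R2) + e^(-k_MN M)) N X1

so checkpoint blockade potentiates CTL killing linearly and Tregs/MDSCs
damp NK killing through two negative exponentials; the mutation term feeds
the androgen-independent clone only while androgen is depressed. Androgen
deprivation forces `dA/dt = -lambda_A A` with `lambda_A = ln 2 / 7 d`; the
NK turnover follows the allometric law `mu_N = 0.0371 / m^(1/4) = 0.09/day`
for a 0.029 kg mouse, and the NK source is fixed by the tumor-free steady
state.

Seven treatments are supported: castration (CX), dendritic-cell vaccine
(V), anti-IL-2 (AI), anti-Treg (AR), NK transfer (NK, a 9x bump of the NK
initial condition), checkpoint blockade (ICB, 3x/week) and anti-MDSC (AM,
daily). Combinations are ranked by tumor inhibition
`Ti = 1 - T_treated/T_untreated` at week 4 and by the Bliss combination
index `BCI = (Ti_A + Ti_B - Ti_A Ti_B) / Ti_{A+B}` (< 1 means synergy).

The packaged parameter file is a **synthetic nominal set**
(`src/pcaqsp/data/params_nominal_synthetic.json`): the published
probabilities, half-lives and allometric constants are used verbatim, and
the remaining rates are package-chosen nominals (see `docs/methods.md`),
not a published calibration.

## A worked example

```sh
python examples/01_simulate_scenarios.py
```

prints, with the packaged nominal parameters:

```
week-7 total tumor (fold-change vs day 0):
  untreated              9.77
  castration alone       1.95  (AIPC fraction 1.00)
  castration + ICB+AM    1.51

inhibition of the full regimen vs untreated: 85%
```

Untreated disease grows ~10-fold in 7 weeks and remains entirely
androgen-dependent; castration slows growth but selects a fully
androgen-independent tumor; adding checkpoint blockade plus anti-MDSC
therapy from day 21 inhibits 85% of the untreated burden. The other
examples screen all 127 combinations, build the castration-rooted synergy
tree, recover parameters from synthetic data and rank parameter
sensitivities. The same capabilities are exposed on the command line:

```sh
pcaqsp simulate --combo CX+ICB --protocol standard --out traj.csv
pcaqsp screen --out screen.csv
pcaqsp tree --out tree.json
pcaqsp sensitivity --method lsa --out lsa.csv
```

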
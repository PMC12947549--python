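# gelcomp

Competitive-inhibition modelling of dynamic hydrogel mechanics.

Dynamic hydrogels are cross-linked by reversible bonds (boronate
esters, hydrazones, ...), so a small molecule that binds one of the
cross-linking partners competes with network formation. `gelcomp`
predicts how the plateau modulus, sol/gel state, terminal relaxation
time and syringe injectability of such a network respond to a
competitor of known affinity and concentration — and, run in reverse,
extracts an unknown binding constant from a modulus titration. It is
aimed at people who formulate injectable or stimulus-responsive
hydrogels and at rheologists who want a quantitative bridge from
binding thermodynamics to bulk mechanics.

## Model

The competitor reduces the effective cross-link affinity exactly as a
competitive inhibitor reduces a substrate's apparent affinity:

    K_app = K_XL / (1 + K_C [C])

For a stoichiometric tetra-arm network with end-group concentration
N_XL, mass action `N_XL K_app (1-p)^2 = p` fixes the cross-link
conversion

    p = a - sqrt(a^2 - 1),    a = 1 + 1/(2 N_XL K_app)

Mean-field connectivity statistics (binomial bonded-arm counting by
default, Miller–Macosko-style extinction-probability counting as an
option) convert p into the densities of elastically active chains
(nu_e) and junctions (mu), and rubber elasticity gives the plateau
modulus

    G_p = nu_e kB T   (affine)      G_p = (nu_e - mu) kB T   (phantom)

Predictions are compared on the normalized scale G_p([C])/G_p(0).
Relaxation times follow a single-parameter Langmuir-type decay
`tau([C]) = tau0 - (tau0 - tau_min)(1 - nu_e/nu_e(0))`; stress
relaxation curves are fit with the stretched exponential
`G(t)/G0 = exp(-(t/tau)^beta)`. The sol/gel boundary is the
Flory–Stockmayer point p = 1/(f-1), and a bipartite random-graph
assembly oracle validates all the mean-field formulas empirically.

## Worked example

A boronate-ester gel (K_XL = 2200 M^-1, 38 mM end groups) titrated
with its strongest diol competitor (K_C = 6700 M^-1), using the config
in the snippet below:

```toml
[binding]
ka_xl = 2200.0
ka_c = 6700.0

[network]
n_xl_molar = 0.038
```

```
$ gelcomp predict --config boronate.toml --conc 0 --conc 0.005 \
      --conc 0.010 --conc 0.030 --out pred.csv --verbose
trace: conc=0 M ka_app=2200 p=0.896448 nu_e=0.0330448 M mu=0.0179398 M G_phantom=37444.7 Pa gel=True
trace: conc=0.005 M ka_app=63.7681 p=0.531613 nu_e=0.0110573 M mu=0.00686571 M G_phantom=10390.8 Pa gel=True
trace: conc=0.01 M ka_app=32.3529 p=0.417355 nu_e=0.00598159 M mu=0.00379557 M G_phantom=5419.04 Pa gel=True
trace: conc=0.03 M ka_app=10.8911 p=0.239415 nu_e=0.00131473 M mu=0.000855682 M G_phantom=1137.97 Pa gel=False
```

Reading the trace: 10 mM of competitor cuts the apparent association
constant from 2200 to 32 M^-1, conversion falls from 0.90 to 0.42, and
the normalized phantom modulus drops to 0.145 — an 85.5% softening,
within a few percent of the 83% drop measured for this condition. At
30 mM conversion falls below the tetra-functional gel point of 1/3 and
the formulation is classified sol, matching the observed dissolution.
The same chain drives the other subcommands: `band` adds an
uncertainty envelope propagated from the binding-constant errors,
`fit-affinity` inverts a measured titration to recover K_C or K_XL,
`tau`/`fit-tau-min` handle relaxation, `simulate` generates noisy
synthetic datasets, `oracle` runs the stochastic assembly check, and
`inject` maps predicted moduli onto syringe injection force against
the 38 N hand-injectability threshold.

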
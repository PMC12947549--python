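# Methods

## Scope and model chain

`gelcomp` implements a mean-field description of a stoichiometric
A_f + B_f dynamic network (default f = 4, tetra-arm macromers) whose
cross-links form by 1:1 reversible association, in the presence of a
monovalent small-molecule competitor for one of the partners. The
forward chain is

1. apparent association constant `K_app = K_XL / (1 + K_C [C])`;
2. equilibrium conversion `p` from `N_XL K_app (1-p)^2 = p`, using the
   closed-form root written as `1/(a + sqrt(a^2-1))`,
   `a = 1 + 1/(2 N_XL K_app)` — the conjugate form avoids catastrophic
   cancellation for weak binding (residuals stay below 1e-12 across
   four orders of magnitude in either parameter);
3. per-macromer connectivity statistics, then chain/junction densities
   `nu_e = c_M Σ_{i≥3} i P_i / 2`, `mu = c_M Σ_{i≥3} P_i` with
   `c_M = 2 N_XL / f`;
4. plateau modulus, affine `nu_e kB T` or phantom `(nu_e - mu) kB T`.

Key assumptions: ideal stoichiometric mixing (equal end-group
concentrations of both species), no loops or dangling-end defects, no
depletion of competitor by default (see below), temperature 298.15 K
unless configured otherwise.

## Two connectivity conventions

The literature is ambiguous about what "connected arm" means in the
mean-field counting, so both are implemented:

- `bonded_arm` (default): P_i = Binomial(f, p). An arm counts once its
  end-group pair has reacted. This convention reproduces measured
  normalized-modulus changes of competitively inhibited tetra-PEG gels
  to within the ~10% experimental agreement band, which is why it is
  the default.
- `gel_connected`: the arm-extinction probability q is the smallest
  root of `q = 1 - p + p q^(f-1)` (damped fixed-point iteration from
  q = 0, tolerance 1e-12, max 1e4 iterations; q = 1 below the gel
  point), and P_i = Binomial(f, 1-q). Predictions are systematically
  lower than `bonded_arm`, coinciding at p = 1, and vanish below the
  gel point.

Neither is asserted to be "the" literature formulation; the
Monte-Carlo assembly oracle validates both (bonded-arm counts against
the binomial, giant-component membership against the extinction root).

## Normalization and uncertainty bands

Absolute phantom predictions over-estimate measured moduli (the
worked example predicts ~37 kPa where ~22 kPa is measured) because
network defects are unmodelled; quantitative use is therefore on the
normalized scale `G_p([C]) / G_p(0)`. Uncertainty bands evaluate the
normalized chain at the four `(K_XL ± sd) × (K_C ± sd)` corners and
take pointwise extrema; each corner is normalized by its own
zero-competitor prediction, so pure K_XL rescaling cancels at [C] = 0.

## Competitor depletion

The apparent-constant formula is evaluated at the TOTAL added
competitor concentration by default, matching how such models are used
against experiments. An opt-in correction solves the coupled mass
balances A + B <-> AB, A + C <-> AC (A_tot = B_tot = N_XL,
C_tot = [C]); the three balances reduce to one monotone equation in
free [A], bracketed on (0, N_XL] and solved by Brent's method
(residual tolerance 1e-9·N_XL). Depletion raises p relative to the
default, since bound competitor no longer inhibits.

## Sol/gel classification

Flory–Stockmayer: gel iff `p > 1/(f-1)` (1/3 for f = 4). The boundary
itself is classified sol because the incipient network has zero
modulus. The Monte-Carlo oracle confirms the transition empirically
(giant-component fraction < 2% at p = 0.30, > 99% at p = 0.90 for
1e5 macromers per side).

## Relaxation

- Crossover: `tau = 1/omega_c`. The root of `log G' - log G''` is
  located around the lowest-frequency sign change by straight-line
  regression over the contiguous points with `|log G'/G''| ≤ 2`
  (about a decade either side of the crossover, where near-Maxwellian
  sweeps are log-linear). This is exact on noiseless single-mode
  Maxwell data and keeps the error of recovered tau under ~5% at 5%
  multiplicative point noise on the default 12-points-per-decade grid;
  multiple crossings resolve to the lowest frequency; a sweep with
  G' > G'' throughout returns an explicit no-crossover result.
- KWW: bounded least squares of `G(t)/G0 = exp(-(t/tau)^beta)`,
  tau > 0, beta ∈ (0, 1], amplitude fitted; initial guesses from the
  log–log linearization `log(-log y) = beta log t - beta log tau`.
  `beta = 1` fixed gives the single-element Maxwell fit. G0 defaults
  to the first sample. Requires ≥ 5 points spanning a decade of decay.
- Langmuir-type tau decay. The printed literature form
  `tau = tau0 - (tau0 - tau_min)(2 nu_e / N_XL)` does not return tau0
  at [C] = 0 under this package's nu_e convention (the uninhibited
  bracket is 0.795, not 1) and moves opposite to the observed
  acceleration; the default here is the equivalent occupancy form
  `tau = tau0 - (tau0 - tau_min)(1 - nu_e/nu_e(0))`, which guarantees
  tau(0) = tau0 and tau -> tau_min as nu_e -> 0. The as-printed form
  is retained behind `variant="as_printed"` (bracket clipped to
  [0, 1]). This is the package's principal interpretive decision.
  `fit_tau_min` is a bounded 1-D least squares over
  tau_min ∈ [0, tau0).

## Inverse inference

With one of K_XL/K_C unknown, normalized measured moduli are fit by
1-D least squares over log10 of the unknown (grid scan on
[1e-2, 1e8] M^-1, 201 points, refined by bounded minimization —
constants of interest span four orders of magnitude, hence the log
parametrization). R^2 is computed on normalized moduli. The
confidence interval is profile-likelihood style: all grid constants
with `RSS ≤ RSS_min (1 + F_{0.95}(1, n-1)/(n-1))`. Identifiability
requires the fit to beat the no-competitor-effect null model by more
than 5% relative residual improvement; weak competitors (K_C ~ 6 M^-1
at ≤ 15 mM under 5% noise) correctly fail this gate instead of
returning an arbitrary optimum.

## Monte-Carlo assembly oracle

Each of the n·f A-ends bonds independently with probability p; the
bonded A-ends are matched uniformly at random (without replacement) to
B-ends, giving each B-end marginal bond probability p as well — the
symmetric mass-action interpretation of conversion. Components come
from `scipy.sparse.csgraph.connected_components` on the bipartite
macromer multigraph. "Gel-connected" is approximated by membership in
the largest component; this matches arm-level percolation counting
only well above the gel point (at p = 0.9 the discrepancy in the
per-arm success probability is ~1e-3; at p = 0.6 roughly 10% of
bonded arms lead to finite dangling trees, so empirical gel-connected
histograms are only compared near-quantitatively at high p). Runs are
deterministic per seed.

## Synthetic data

Generators cover every fitter: single-mode Maxwell sweeps
(`G' = G_p w^2 tau^2/(1+w^2 tau^2)`, `G'' = G_p w tau/(1+w^2 tau^2)`),
KWW decay curves, and forward-model titrations. Noise is
multiplicative Gaussian `y (1 + sd·z)`, clipped at zero, default
sd = 0.05 — mimicking the relative calibration error of rheometers
(reported at up to ±8%) rather than additive instrument noise.
Noiseless outputs are exact fixed points of the corresponding fitters.
What the generators do NOT emulate: instrument inertia and slip,
multi-mode relaxation spectra, pH/ionic-strength drift of the binding
constants, and network defects — so passing recovery tests demonstrate
estimator correctness under the stated noise model, not robustness to
every artefact of measured rheology.

## Injectability

Ordinary least squares of injection force on plateau modulus
(≥ 2 distinct moduli required), then classification against a 38 N
hand-injectability threshold. The comparison is inclusive (exactly
38 N passes) since the threshold is a comfort bound; the CLI flags
predictions within ±5% of the threshold as borderline. The linear
force–modulus map is an acknowledged first approximation: injection
force also depends on relaxation time, needle geometry and yield
behaviour, none of which are modelled.

## Problem sizes and numerical defaults

Monte-Carlo validations use 1e5 macromers per side (standard errors of
per-macromer means ~3e-3, small enough to resolve the mean-field
values while keeping a full validation run in seconds). Inverse-fit
quality is summarised as the median over 50 seeded noise replicates;
estimator bias is checked over 200 replicates. All tolerances quoted
above are the defaults of the public functions.

## Known limitations

Multivalent competitors are treated as effective 1:1 binders;
loop/defect-corrected elasticity, swelling coupling, associative (as
opposed to dissociative) exchange, and prediction of tau from
competitor dissociation rates are out of scope.
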
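# Methods

## Lin-log kinetics and the steady state

The rate of reaction *j* is modeled as

    v_j = v*_j (e_j/e*_j) (1 + Σ_i εx[j,i] ln(x_i/x*_i) + Σ_k εy[j,k] ln(y_k/y*_k))

with internal metabolites `x` (balanced at steady state), external
metabolites `y` (media components and secreted products, treated as
boundary conditions), and the reference state `*` defining the
linearization point.  Enzyme levels are relative (`e* = 1` everywhere)
because proteomics are measured as ratios to a reference strain; flux
units (mmol gDCW⁻¹ h⁻¹) live entirely in `v*`.

Setting `N v = 0` and writing `w = v* ∘ e_rel` gives one linear system
per strain,

    (N diag(w) εx) x_log = −N (w ∘ (1 + εy y_log)),

valid when `N` has full row rank; `remove_conserved_moieties` drops
dependent rows first (rank from SVD at relative tolerance 1e-9, row
selection by pivoted QR, and a link matrix to reconstruct the dropped
rows).  The solver flags condition numbers above 1e10 and optionally
falls back to the Moore–Penrose solution.

Control coefficients come from the implicit function theorem on this
system:

    C_X = −(N diag(v*) εx)⁻¹ N diag(v*),    C_J = I + εx C_X.

Both MCA theorems hold identically under these formulas (summation uses
`N v* = 0`), and the analytic `C_J` is verified against central finite
differences of log steady-state flux w.r.t. log enzyme level (h = 1e-6,
agreement ≤ 1e-5 relative) in the test suite — the finite-difference
path through the solver is the independent oracle.

Gene deletions are represented as a relative enzyme level of 0.05
(configurable floor) rather than 0, where the lin-log form is undefined;
this keeps the model in its log-linear regime while strongly reducing
flux.  How deletion strains should enter a lin-log fit is genuinely
open; the floor is this package's convention and is applied consistently
in the generator and the simulator.

## Exchange rates and E-Flux2

Batch growth is fit as `X(t) = X0 exp(μ t)` by log-linear least
squares.  A constant specific exchange rate `q` then implies
`S(t) = S0 + (q X0/μ)(exp(μ t) − 1)`; `(S0, q)` are linear least
squares, with the `μ → 0` limit `S = S0 + q X0 t`.  Rates are computed
per strain on replicate-averaged series (replicate-level rates are a
config away but were not needed).  Uptake is negative, excretion
positive.

E-Flux2 proceeds in two phases: (1) maximize the objective flux subject
to `N v = 0`, measured exchange fluxes constrained to a ±5% band
(absorbing measurement noise; exact equality is a config option), and
`|v_j| ≤ M·(expression_j / max expression)` with flux ceiling `M = 100`;
(2) among phase-1 optima, return the minimum-Euclidean-norm flux.
Phase 1 is an LP (scipy/HiGHS); phase 2 eliminates fixed coordinates and
uses the least-squares minimum-norm solution of the equality system,
refined by SLSQP only when box bounds are active.  GPR rules aggregate
protein abundances with sum over isozyme groups and min within a
complex; reactions without measured proteins are bounded only by the
ceiling.

## The generative model and priors

Per strain `s`, latent log enzyme levels `ℓ_s ~ Normal(0, 1)` (every
reaction, observed or not), known media deviations `y_log,s`, and the
shared elasticities determine the steady state `(x_s, v_s)`.
Observation model per sample:

- protein log-ratio ~ Normal(ℓ_s, σ_p)
- metabolite log-ratio ~ Normal(x_log,s, σ_m)
- flux ~ Normal(v_s, σ_f |v*|)  (noise scaled by the reference flux so
  a single dimensionless scale applies)

Elasticity priors exist only for reaction–metabolite pairs present in
the stoichiometry (regulatory cross-talk is off by default; an
allow-list can add pairs with zero-mean priors): substrates
Normal(+0.5, 1.0), products Normal(−0.5, 1.0).  Noise scales get
half-normal(0.5) hyperpriors unless pinned in config.

Observations with |log-ratio| > 2.0 natural-log units (configurable)
are clipped to the bound; flux deviations are clipped on the
`(v − v*)/|v*|` scale.  Clipped entries contribute censored terms
(tail mass beyond the bound, computed with stable `log Φ` / inverse
Mills ratios) rather than being treated as exact values — they carry
the information "at least this extreme" without anchoring the fit to
the bound.

## Inference

The default fit is mean-field Gaussian ADVI: single-sample
reparameterization gradients of the ELBO, Adagrad steps (learning rate
0.1), convergence when the 500-iteration window mean of the negative
ELBO changes by < 1e-4 relative (cap 20,000 iterations, flagged if
hit).  Gradients of the log-joint are analytic, with an adjoint pass
through the batched per-strain linear solves; they are unit-tested
against finite differences, and the optimizer against a conjugate
Gaussian closed form.  Everything is reproducible bitwise given the
seed.

**Known limitation:** the elasticity posterior is strongly correlated
(a scaling ridge between elasticities and the metabolite deviations
they multiply), and mean-field VI underestimates marginal spread there
by roughly 4× — point estimates and FCC sign calls are excellent, but
mean-field marginal intervals under-cover the truth.  Two
correlation-aware alternatives are provided: `fit_laplace` (MAP by
L-BFGS with exact gradients, covariance from a finite-difference
Hessian; fast and well calibrated — ~84% coverage of true elasticities
at 95% nominal on the default fixture) and a full-rank ADVI flag
(slower to converge; mean-field remains the default).  Posterior
predictive intervals are much less affected because observation noise
dominates their width.

FCC posteriors are formed per draw via the analytic formula; singular
draws are masked and counted (> 50% masked aborts).  The HPD interval
is the narrowest contiguous window containing ⌈level·n⌉ sorted samples.
A reaction is a target when its 95% HPD excludes zero **and** the
|posterior median| clears a magnitude floor of 0.05 — the floor mirrors
the qualitative selection threshold practitioners draw on forest plots
and is reported alongside the calls, as is the posterior probability of
a positive FCC.

## Synthetic data

`make_toy_network("branched_3hp")` builds a 15-reaction, 10-internal-
metabolite emulation of a central-carbon + β-alanine production
network: glucose → pyruvate, an anaplerotic route (pyruvate carboxylase
analog) feeding aspartate → β-alanine → malonic semialdehyde → 3-HP
export, a competing malonic-semialdehyde dehydrogenase drain to
acetyl-CoA, a TCA-like succinyl-CoA loop (with a two-isozyme GPR), a
pyruvate-dehydrogenase complex (two-subunit AND rule) and an ethanol
drain.  The reference flux is a hand-balanced steady state scaled to a
glucose uptake of 1 mmol gDCW⁻¹ h⁻¹.  True elasticities are drawn
sign-consistently (substrates Uniform(0.3, 1.2), products
Uniform(−1.2, −0.3), zero elsewhere), redrawing until the steady-state
system is well conditioned (< 1e6), every design strain is solvable,
and the preset's defining control pattern holds (drain negative,
anaplerotic feed positive on product export).  The 17-strain panel
combines pathway dosage (×2), single overexpressions (×5), deletions
(floor 0.05), stacks thereof, and a no-pathway wild type; strain-level
glucose deviations (log-normal, sd 0.2) emulate differing residual
glucose.

`simulate_dataset` observes each strain's steady state in triplicate
with log-scale noise sd 0.1, 80% observation coverage for proteins and
metabolites (fluxes fully observed, as an E-Flux2 stage would supply
them), clipping at 2.0, and writes batch time-series (inoculation plus
days 3/5/7) from the exponential-growth closed form (μ ≈ 0.015 h⁻¹,
X0 = 0.3 gDCW L⁻¹, 555 mM initial glucose ≈ 100 g/L) so the rate
estimators can re-derive the generating exchange rates exactly at zero
noise.  These defaults mirror the structure of the real study design
(17 strains, 51 samples, triplicates, clipped log-ratios); what they do
**not** emulate is real-data misspecification — non-lin-log kinetics far
from reference, correlated measurement error, batch effects, and
proteoform/compartment ambiguity — so passing recovery tests show the
inference machinery is correct and well calibrated under the model, not
that the model captures any particular organism.

Problem sizes throughout (15-reaction network, 5 recovery seeds, 1,000
posterior draws, 500 PPD draws) were chosen so the full study runs in
well under a minute while leaving the statistics stable; they scale up
by config.

## Numerical choices

- Model reduction drops reactions with |reference flux| ≤ 1e-9
  mmol gDCW⁻¹ h⁻¹ (the "zero flux" threshold is not standardized).
- Metabolite/reaction order is lexicographic by id everywhere, so all
  matrices are reproducible across runs and serializations.
- Steady-state solves use LAPACK `solve` with a 1e10 condition-number
  flag; control-coefficient systems error on singularity unless the
  pseudoinverse fallback is requested.
- The ADVI gradient is norm-clipped at 1e5 as a guard against rare
  extreme variational draws; Adagrad accumulators make the step size
  scale-free thereafter.
- Ties in the HPD window search resolve to the leftmost narrowest
  window; degenerate (constant) samples give a zero-width interval.
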
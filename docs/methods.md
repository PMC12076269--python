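# Methods

## The damage model and its calibration problem

The package models mechanically induced hemolysis with the empirical power
law `HI = C · τ^β · t^α`, where τ is a scalar shear stress in Pa, t an
exposure time in s, and HI a dimensionless hemolysis index.  C, α and β
are calibration constants with no independent physical meaning; C carries
the implied compound units and is treated as a plain positive number under
the τ-in-Pa, t-in-s convention.  The deterministic reference parameter set
used throughout (`REFERENCE_PARAMS`: C = 1.228e-5, α = 0.6606, β = 1.9918)
is a published multivariate-regression fit to ovine-blood Couette
experiments and serves as the generating truth for synthetic studies.

Calibrating all three constants to replicated shear experiments by
least squares is ill-posed in practice: over a finite calibration envelope
a change in C can be almost exactly offset by a change in β (at a single
operating point the compensation `C → kC`, `β → β − ln k / ln τ0` is
exact), so the SSE objective has a long, flat valley.  The
`powerlaw` module makes this visible: an exhaustive grid search stores the
SSE at every (C, α, β) node, `min_sse_per_c` extracts the per-C minimum
curve, and `prediction_spread_within_margin` evaluates a caller-supplied
device functional (typically an MIH integral) on every node whose SSE is
within a relative margin of the global minimum, reporting the spread of
device predictions that are statistically indistinguishable at that margin.

## Probabilistic model

Observations are modelled as Student-t around the power-law mean:

```
HI_i ~ t( μ = C·τ_i^β·t_i^α,  scale = σ,  dof = ν )
```

with priors C ~ Uniform(0, 1) (or fixed), α, β ~ Normal(0, 1),
σ ~ HalfNormal(1), ν ~ Exponential(mean 30).  The priors are deliberately
uninformed so the posterior is driven by the data; the half-normal for σ is
the standard positivity-constrained reading of a unit-scale "uninformed"
prior on a scale parameter.  ν is latent by default (heavy tails guard
against outlying replicates); a fixed-ν mode exists.  The t-density is
evaluated in log space via `gammaln`; parameter vectors outside the support
(σ ≤ 0, ν ≤ 0, C outside its prior box) get log-posterior −∞.

### Sampling

Posteriors are sampled with the affine-invariant ensemble sampler (emcee).
Each requested chain is an independent ensemble run (default 32 walkers)
seeded from `seed + 997·chain`; after a burn-in of `n_tune` ensemble steps
the flattened walker draws are thinned to exactly `n_draws` retained
samples per chain, so draw bookkeeping follows the familiar
chains × draws contract.  `target_accept` is part of the configuration
surface but advisory: ensemble moves have no step-size adaptation, and a
low ensemble acceptance fraction is surfaced as a metadata warning
instead.  Walkers start in a tight relative ball (1e-3) around a
posterior-mode estimate obtained by Nelder-Mead from a log-log
least-squares regression start; this makes runs reproducible
(identical seeds → identical draws on one platform) and robust on the
degenerate geometries below.  Convergence is checked with the split-chain
R̂ (arviz); summaries are pooled empirical quantiles (median, 5%, 95%).

Two configurations are bundled: the reference configuration
(4 chains × 50,000 draws after 1,000 burn-in steps, 200,000 retained
draws) and `SamplerConfig.quick()` (4 × 2,000) used by the tests and the
inner optimisation loops.

### Degenerate posteriors

Two degeneracies are expected and handled rather than hidden:

* With all three parameters free, the C–β valley produces a strongly
  correlated posterior (|corr(C, β)| close to 1, corr(C, α) weak).  This is
  the model's identifiability failure, reproduced and asserted in the
  tests, and the motivation for the fixed-C workflow.
* On *noise-free* data the σ-posterior is an improper funnel: the
  likelihood grows like σ^(−n) as σ → 0 at a perfect fit, so σ drifts
  toward zero while α and β pin to the generating values with vanishing
  spread.  This is precisely the intended credibility check — posterior
  width comes only from data variance — and the mode-centred
  initialisation keeps it numerically stable (the t-density stays finite
  in log space down to σ ~ 1e-300).

### Fixed-C selection

`optimize_fixed_c` minimises `c ↦ median(σ posterior | C = c)` over
bounds 1e-6..1e-3.  Because each objective evaluation is an MCMC fit, the
search is sequential model-based: a Matern-5/2 Gaussian process with
expected-improvement acquisition over log10(C) (the bounds span three
decades; log scaling conditions the GP), 10 stratified initial points,
100 evaluations total by default.  The inner sampler is reduced
(2 chains × 1,000 draws, 24 walkers) and each point's seed is a stable
hash of (c, base seed), making the objective deterministic in (c, seed).
Failed inner fits are recorded as NaN in the trace and skipped by the GP.
A same-budget random-search baseline (`random_search_fixed_c`) is provided
for honesty checks.

## Device-level post-processing

`scalar_shear_stress` reduces per-cell velocity-gradient tensors to

```
SSS = η·[2(∂u/∂x)² + 2(∂v/∂y)² + 2(∂w/∂z)²
       + (∂u/∂y+∂v/∂x)² + (∂u/∂z+∂w/∂x)² + (∂v/∂z+∂w/∂y)²]^(1/2)
```

which depends only on the symmetric part of the gradient (rigid rotation
gives exactly zero).  `mih` evaluates the flow-rate-normalised volume
integral `MIH = ((1/Q)·Σ_cells (C·SSS^β)^(1/α)·V_cell)^α · 1e6` as a
cell-wise Riemann sum over (stress, volume) pairs — no mesh topology is
needed, because for steady flow with a clean inlet the volume integral of
the transported damage species equals its outlet flux (Gauss's theorem),
making device hemolysis a pure post-processing step.  The inner power is
computed in log space; zero-stress cells contribute exactly 0 (requires
β > 0 if present, and α > 0 always — both enforced).  The discrete sum is
invariant under cell subdivision and strictly increasing in C.  `rih`
divides MIH values by a reference condition's value.

## Uncertainty propagation

Posterior marginals of the free parameters are summarised as log-normal
fits (maximum likelihood, location fixed at 0) truncated at their own
1%/99% quantiles to keep downstream sampling away from extreme tails.
Per flow condition, an order-4 polynomial-chaos surrogate of MIH is
trained on a design of 200 Latin-hypercube samples of the truncated laws
plus all 2^d corner combinations of the truncation bounds (204 points for
the fixed-C case d = 2); coefficients are ordinary least squares on a
total-degree ≤ 4 product-Legendre basis, with rank-deficient designs
rejected by name.  Marginal correlation of the inputs is treated as
independent (the posterior fits are marginal); the training design and
propagation sampler share this assumption.

Germ choice: each input is standardised to z ∈ [−1, 1] by an *affine* map
of its truncated support, so the surrogate is a polynomial in the raw
parameters — the space in which the MIH response is smooth and
quasi-polynomial.  A probability-integral-transform germ (mapping through
the truncated CDF) was considered and rejected: its inverse steepens near
the truncation bounds, making the composed response materially harder for
a fixed-order polynomial.  Because coefficients are found by regression
rather than spectral projection, the fitted polynomial is independent of
the basis weight, so this is purely an approximation-space/conditioning
choice.  Surrogates are validated against
the direct volume integral on fresh seeded draws (max and mean relative
error stored on the model; evaluation outside the truncation bounds raises
an extrapolation warning, not an error).

`propagate` pushes one common matrix of 10,000 truncated draws
(out-of-bounds draws resampled) through every condition's surrogate;
`rih_distributions` divides all samples by the *median* of the reference
condition's distribution (so the reference RIH median is exactly 1 — this
is a median normalisation, not a ratio of paired samples);
`compare_models` tabulates probabilistic median/5%/95% against the
deterministic point prediction with a coverage flag.

## Synthetic data: what it emulates, what it does not

`generate_couette_dataset` emulates a Couette shearing-device calibration
campaign: a 6 × 6 log-spaced grid of shear stresses spanning 50–320 Pa and
exposure times spanning 0.039–1.48 s, n = 3 replicates per operating point
(108 records), HI generated from the power law at known parameters plus
noise.  The published experiments state the envelope and replicate count
but not the grid layout, so the 6 × 6 log-spaced default is a declared
assumption, not a reconstruction.  Default noise is Student-t with
σ_true = 0.1, ν_true = 30 — a mid-range experimental scatter chosen so the
SSE at the generating parameters is of order a few units on 108 records,
consistent with the scatter scale such calibrations exhibit.  Negative HI
draws are resampled (a slight truncation of the nominal law at the
physical bound HI ≥ 0; negligible except at the lowest operating points).

`generate_stress_volume_field` produces per-cell (stress, volume)
histograms with log-normal stress distributions and randomised volumes
rescaled to conserve the total exactly.  Six labelled condition presets in
two flow-rate regimes stand in, qualitatively, for a benchmark-pump
campaign at two rotational speeds.  These fixtures contain no geometry, no
turbulence and no solver physics: passing tests demonstrate the
correctness of the calibration/propagation chain, not the fidelity of any
CFD solution.  `generate_velocity_gradient_field` provides analytic
tensor presets (pure shear, rigid rotation, uniaxial extension) for the
stress-reduction identities.

All generators and stages take explicit seeds; the pipeline derives stage
seeds from one master seed by fixed offsets, and a full run is reproducible
byte-for-byte at the summary level.

## Numerical choices

* Grid search is vectorised over (α, β, record) blocks with the powers
  τ^β and t^α precomputed per axis; the multiplication order matches the
  scalar expression `c·τ^β·t^α`, so results are bitwise identical to a
  naive triple loop.  Landscape storage dtype is configurable (float64
  default — 96 MB for the 12-million-node reference grid; float32 halves
  that).  Argmin ties break to the first node in lexicographic
  (C, α, β) index order.
* The 12 C levels of the reference grid are linearly equidistant on the
  raw scale (plain reading of "equidistant"); α and β axes linearly
  spaced.  All axes configurable.
* Quantities compared across refinement or closed forms (MIH subdivision,
  uniform-field identity) hold to 1e-12 relative; surrogate polynomial
  exactness to 1e-8 relative.
* Problem sizes in the test suite (quick sampler configs, 2,000-cell
  fields, 100-iteration C search with a reduced inner sampler) are chosen
  as desk-scale defaults that finish in minutes while preserving every
  qualitative property at reference scale.

## Known limitations

* The ensemble sampler explores the strongly correlated full-model
  posterior more slowly than a gradient-based sampler would; the fixed-C
  model is the recommended (and better-identified) workflow, matching the
  package's emphasis.
* Absolute MIH values from synthetic fields are illustrative only; only
  relative comparisons (RIH) across conditions of the same field family
  are meaningful, which mirrors how device hemolysis results are reported.
* The truncated log-normal marginal fits discard posterior correlation
  between α and β.  For fixed-C posteriors this correlation is weak; for
  the full three-parameter model it is not, which is another reason the
  propagation workflow assumes fixed C.
* No transport-equation (PDE) hemolysis solve is provided; the
  volume-integral equivalence covers steady flows with clean inlets only.
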
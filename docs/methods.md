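# Methods

## Model and assumptions

The package models polarised polymorphism data under the Poisson random
field: a panmictic diploid population of constant effective size N_e,
infinite-sites mutation, free recombination between sites, and genic
selection (fitnesses 1, 1 + s, 1 + 2s). Under these assumptions the number
of polymorphic sites with derived-allele count i in a sample of n alleles
is Poisson with mean ψ_i, and bins are independent, so the log likelihood
is Σ_i (−ψ_i + x_i ln ψ_i) up to an additive constant.

Only the compound parameters θ = 4N_e u and γ = 4N_e s are identifiable;
N_e, u, and s are never estimated separately. Within a discrete model all
classes sharing one γ collapse to a single class with pooled θ and
rate-weighted error ε\* = Σ ε_c θ_c / θ; this identity is enforced as a
numerical check (`identifiability_collapse_check`, tolerance 1e−10) and is
the reason fitted class counts should be read as "resolvable classes", not
biological truth.

Polarisation error is a per-class probability ε ∈ [0, 0.5] that the
ancestral state is misassigned, sending a count-i variant to count n − i.
ε is capped at 0.5 because beyond that point the parameter is aliased with
globally swapping ancestral/derived labels, which removes a reflection
symmetry from the search space. For INDELs the misassignment also swaps the
variant's type (insertion ↔ deletion), so insertion and deletion spectra
are modelled jointly and the package refuses to model one without the
other.

Demography and linked selection are absorbed by nuisance multipliers
r_2…r_{n−1} applied to the uncorrected spectra (r_1 ≡ 1), shared across
all variant types and regions of a joint model and identified by a neutral
reference region. The operation order is fixed by the model's definition —
scale by r first, then apply polarisation mixing — and is enforced by the
spectrum-stage bookkeeping rather than being configurable.

## DFE forms

Two DFE families are supported: discrete mixtures of point masses
(θ_c, γ_c, ε_c), where γ may take either sign, and the reflected Gamma,
−γ ~ Γ(shape a, scale b), restricted to γ ≤ 0. Discrete and continuous
machinery share one code path (a discrete class is a point-mass DFE).
Mixtures of continuous distributions and positive-mass continuous DFEs are
not implemented.

## Numerics

**Sojourn integral.** τ_i(γ) is evaluated after the stability rewrite
(1 − e^{−γ(1−x)})/(1 − e^{−γ}) = e^{−gx}·expm1(−g(1−x))/expm1(−g) for
γ = −g < 0 (symmetrically for γ > 0), which never exponentiates a large
positive argument; |γ| < 1e−8 is routed to the exact neutral value 1/i
(removable singularity). The integral uses a composite Gauss–Legendre rule
whose panel count grows as ⌈|γ|/25⌉ (single 128-node panel for mild γ,
32 nodes per panel otherwise), so the e^{γx} boundary layer is always
resolved; results are refined by node doubling and re-refined if two
consecutive rules disagree beyond 1e−8 relative. For γ < −2000 the layer
is instead integrated exactly-in-spirit by substituting t = −γx and using
a generalized Gauss–Laguerre rule with weight t^{i−1}e^{−t}, computed in
log space to avoid premature underflow. Unit tests pin both routes to a
≥10⁵-point Riemann oracle (rel. 1e−5 over γ ∈ [−100, 20], n ∈ {4, 10, 50})
and to tight-tolerance adaptive quadrature at γ = −1566.4 and −3000
(rel. 1e−8).

**Gamma-DFE expectation.** E[τ_i(γ)] uses Gauss quadrature against the
Γ(a, b) weight: generalized Gauss–Laguerre nodes of parameter a − 1,
rescaled by b, 64 nodes by default (configurable). This mirrors the
classical statmod-style construction; for very large scale parameters the
rule under-resolves the near-neutral mass, a deliberate fidelity/cost
trade-off that matters only deep in the optimiser's excursion region.

**Mean fixation rate.** γ/(1 − e^{−γ}) is computed through expm1
(g e^{−g}/(1 − e^{−g}) for γ = −g < 0). For the continuous DFE, folding
the integrand's own e^{−g} decay into the Gamma weight (substituting
g = u·b/(1+b)) leaves only the smooth factor g/(1 − e^{−g}) under a pure
Gauss–Laguerre rule, so 128 nodes are converged far past 1e−6. Tests
cross-check this against the closed form a·b^{−a}·ζ(a+1, 1 + 1/b)
(Hurwitz zeta, from the geometric-series expansion of 1/(e^g − 1)) and
against 10⁶-draw Monte Carlo.

**Fast evaluator for fitting.** Optimisers evaluate τ at thousands of
nearby γ values, so the likelihood path uses a per-n cubic-spline surrogate
of log τ_i over log(1 + |γ|) (two branches, γ ≤ 0 and γ > 0), built once
from the exact quadrature (~1 s) and accurate to ~1e−7 relative; tests
validate it against the exact path. All public kernel operations, expected-
spectrum builders, and the simulator stay on exact quadrature, so the
generative model is independent of the fitting surrogate. Exact τ vectors
are additionally memoised per (n, γ).

## Fitting

Optimisation works in a transformed space — log for θ, b, and r; logit on
[0, 0.5] for ε; identity for γ and log for a — with box bounds
θ ∈ [1e−12, 0.1], γ ∈ [−5000, 100], a ∈ [0.01, 100], b ∈ [1e−4, 1e6],
r ∈ [0.01, 100]. The bounds cover every MLE magnitude this model family is
known to produce (including γ̂ ≈ −1600 on real data) with margin. Each fit
runs `n_starts` L-BFGS-B starts followed by a Nelder-Mead polish of the
best one (gradient-based plus derivative-free, which also guards against
finite-difference artefacts). Start 1 is a deterministic moment-style
guess (Watterson's θ split across classes, a γ ladder −0.5, −10, −50, …,
ε = 0.05); the remaining starts perturb it randomly, drawing θ log-uniform
within ×30 of the Watterson estimate, γ uniform on [−100, 10], ε on
[0.005, 0.3], a log-uniform on [0.05, 5] and b on [0.5, 5000]. Draws are
confined to this plausible window rather than the full bounds because
full-range draws put most starts in regions of vanishing likelihood and
waste the optimisation budget; the bounds still allow travel anywhere.
All randomness is seeded; fits are bit-reproducible.

Discrete classes are exchangeable, so MLEs are reported sorted by γ
descending. A parameter making no likelihood contribution (e.g. ε when the
spectrum is symmetric) simply returns near its start value with a flat
profile; ψ_i = 0 under positive counts yields −∞ (mapped to a large finite
penalty inside the optimiser so it can retreat).

Reduced models are expressed structurally: shared ε ties class ε's to one
free parameter (per type, optionally across types), ε = 0 fixes them, and
ratio constraints derive one θ as a fixed multiple of the sum of others
(used, e.g., to anchor a neutral SNP mutation rate to INDEL rates through
an external mutation-accumulation ratio). Model comparison offers the
chi-square LRT and AIC. The LRT for dropping a site class sits on a
boundary/label-switching non-regularity; the plain χ² reference is used
regardless, matching standard practice for this model family, and should
be read as approximate for that comparison. The default significance level
is 0.05 (configurable).

## Simulator and what it does (not) show

`simulate_sfs` draws independent Poisson counts per bin around the exact
expected spectrum — the precise generative dual of the likelihood, with no
conditioning on observing at least one variant. Replicate studies spawn
per-replicate RNG streams from one root seed, so single replicates can be
re-run in isolation, and record per-replicate MLEs, mean fixation rates,
and LRT outcomes; failures are counted, not fatal.

Because the generator matches the inferential model exactly, passing
studies demonstrate statistical identifiability, estimator calibration,
and numerical correctness — not robustness to real-data violations
(linkage, demographic change, selection on the neutral reference, variant-
calling artefacts). Demographic distortions and their r-based correction
are exercised only through the likelihood identities, not simulated
forward.

Default study conditions are n = 50 samples, 100 replicates, with the SNP
design at m = 10⁶ sites and θ = (0.005, 0.01), γ = (−5, −20),
ε = (0.05, 0.01), and the INDEL designs at m = 2×10⁶ with rates ~10×
lower and error rates ~2× higher than the SNP case (insertions 5×10⁻⁴ vs
deletions 10⁻³), reflecting INDELs' lower prevalence and harder
polarisation. Studies fit the selected region alone (no neutral reference,
no r), which is the conservative assessment: joint fitting with a neutral
reference only adds information. The replicate studies and the acceptance
script use n_starts = 5; these designs are well identified and the
multi-start surface search converges to the same optimum from 3, 5, or 12
starts in spot checks.

## Known limitations

- No Hessian-based standard errors; uncertainty comes from across-replicate
  spread (or could be added by profile likelihood).
- The continuous DFE is reflected-Gamma only and strictly non-positive.
- The Gamma-weight quadrature loses relative accuracy for extreme scale
  parameters (b ≫ 10⁴) where the likelihood is anyway nearly flat in b.
- Free-recombination independence between bins is assumed by the Poisson
  likelihood; linked-site effects are only argued (not modelled) to be
  absorbed by r.
- File I/O accepts integer counts only; real-valued spectra are an
  in-memory device for noise-free recovery testing.
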
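# Methods

`fbdage` reimplements, end to end, a simulation study of fossil-age
estimation under the fossilized birth-death (FBD) process: synthetic clades
with a poorly dated fossil deposit are generated, Bayesian total-evidence
inference treats every fossil age as a free parameter bounded by its
assigned range, and recovery of ages, topologies and node times is scored.
This note records the models, the defaults and the design decisions a
maintainer would want to know.

## Time convention and tree representation

Ages are in Myr before present; the present is 0 and ages increase into the
past. Trees are rooted; every tree carries an *origin age* in addition to
the root (first-split) age, because the FBD process starts from a single
lineage at the origin and the density conditions on it. Branches are
half-open `[older, younger)` intervals for event attribution. Sampled
ancestors — fossils on a lineage ancestral to other samples — are
represented as zero-length terminal branches (a fossil tip whose age equals
its parent's age, flagged explicitly), which keeps every tree bifurcating
and lets the same pruning machinery handle their character data.

## Simulation of the study conditions

**Complete trees.** Forward birth-death simulation from one lineage at
origin 120 Myr with speciation λ = 0.05 /Myr and extinction μ = 0.02 /Myr;
extant tips are independently marked sampled with probability ρ = 0.5.
Survival and size conditioning is purely by rejection: a tree is accepted
when it has 20–30 sampled extant tips. No analytic conditioning is applied,
mirroring the original rejection scheme.

**Deposit trait.** Inside the 30–50 Myr window every lineage alive at the
older edge starts in state 1 and switches 1→2 with rate q12 and 2→1 with
rate q21 (a continuous-time two-state Markov chain simulated along the
tree, daughters inheriting the parental state at speciation). Outside the
window the state is 1 by definition. The calibrated rate sets per target
proportion of imprecise-date fossils are

| target | q12 | q21 | ψ_bg | ψ_int |
|--------|-----|-----|------|-------|
| 0.1    | 0.6 | 0.7 | 0.03 | 0.04  |
| 0.3    | 0.8 | 0.5 | 0.02 | 0.08  |
| 0.5    | 1.0 | 0.4 | 0.01 | 0.15  |

**Fossil record.** An inhomogeneous Poisson process on every branch of the
complete tree (extinct and unsampled-extant lineages included): rate ψ_int
where the age lies in the closed window, ψ_bg elsewhere. Each occurrence
takes the lineage's trait state at its age; state 2 defines the
imprecise-date (deposit) class. A record is accepted when the total count
is 45–55 and the state-2 proportion is within 10% of the target. The 10%
band is read as *relative* (±0.1 × target): an absolute ±0.1 band would
leave the 0.1-target condition effectively unconstrained on one side.
Rejection resamples the whole replicate (tree, trait and fossils) rather
than only the fossil record, to avoid conditioning the accepted trees on
the fossil outcome; a configurable attempt cap (default 10 000) raises an
explicit error instead of looping forever.

**Age ranges.** Imprecise-date fossils all get the deposit window (30, 50).
A precise-date fossil of true age *a* gets a range of fixed width *m·a*
(multiplier m ∈ {0.1, 0.2, 0.3}) whose minimum is uniform on (a − m·a, a),
so the range always contains the true age; for m ≤ 1 the minimum cannot be
negative, which is asserted rather than clamped.

**Character data.** Molecular: HKY with five discrete-gamma rate
categories (shape 0.35), 4500 sites, strict clock 0.05
substitutions/site/Myr, simulated along the extant-restricted tree only.
The HKY transition/transversion parameter and base frequencies are not part
of the published study design; the defaults are κ = 2 and equal
frequencies (configurable). Morphology: 120 *variable* characters under the
symmetric k-state Mk model (70% binary, 20% ternary, 10% quaternary), five
gamma categories, strict clock 0.1 substitutions/character/Myr, simulated
for all sampled taxa. The morphological gamma shape is likewise not
published; it defaults to 0.35, mirroring the molecular shape. Characters
invariant across all tips are re-simulated (same state count) until the
target count of variable characters is reached, which preserves the
state-count mix in expectation. Five percent of characters ("soft"
characters) are recoded as `?` in every fossil taxon, emulating characters
that do not preserve. Gamma discretization uses category medians with equal
weights, normalized to mean exactly 1; the same discretization is used in
simulation and inference.

What the generator deliberately does not emulate: indels and alignment
uncertainty, among-lineage rate variation (both clocks are strict),
geological structure of the deposit, character correlation, and
non-uniform taxon sampling. Passing tests therefore demonstrate internal
consistency of the method under the stated generating process, not
robustness to these real-data complications.

## FBD tree density

The constant-rate FBD density over sampled trees (extant tips, fossil tips,
sampled ancestors), conditioned on the origin age, in the standard
`p0`/`q` parameterization:

    c1 = sqrt((λ − μ − ψ)² + 4λψ),  c2 = −(λ − μ − 2λρ − ψ)/c1
    q(t)  = 4 e^{−c1 t} / (e^{−c1 t}(1−c2) + (1+c2))²
    p0(t) = (λ + μ + ψ + c1·(e^{−c1 t}(1−c2) − (1+c2))
                          /(e^{−c1 t}(1−c2) + (1+c2))) / (2λ)

    log f(T | x0) = log q(x0) + Σ_bifurcations [log 2λ + log q(x_i)]
                  + Σ_fossil tips [log ψ + log p0(y_j) − log q(y_j)]
                  + k_SA · log ψ + n_extant · log ρ

All computations stay in log space with `e^{−c1 t} ≤ 1`, so no overflow
for any admissible age. The factor 2 per bifurcation is the
oriented-to-unordered conversion; it is not a constant across tree space
because converting a fossil tip to a sampled ancestor removes a
bifurcation, so omitting it biases the sampled-ancestor posterior. A
constant 1/n! over extant labelings is dropped; it cancels from every MCMC
ratio. The density was validated three independent ways: (i) at ψ = 0 it
equals the closed-form sampled birth-death density to 1e−8; (ii) absolute
class probabilities for one-extant-tip configurations (no fossil / one
sampled-ancestor fossil / one fossil tip) match quadrature of the density
against direct forward simulation; (iii) prior-only MCMC over tree space
reproduces direct-simulation distributions of node ages and the
sampled-ancestor probability. No survival conditioning is applied (the
study fixes the simulation origin and does not publish an origin prior for
inference; here the origin age is a free parameter with a bounded uniform
prior, default maximum 150 Myr).

## Likelihoods

Felsenstein pruning over pattern-compressed columns with per-node,
per-pattern rescaling (log-accumulated), gamma-category averaging at the
root, and stationary root frequencies. Taxa absent from a matrix contribute
all-ones partials, which makes fossil tips transparent to the molecular
partition; the sampler exploits this by evaluating the molecular likelihood
on the extant-restricted tree. Missing states (`?`) are all-states-equal
partials. HKY transition matrices come from a cached symmetric
eigendecomposition; Mk matrices use the two-eigenvalue closed form. The
morphological likelihood conditions on character variability (the "Mkv"
correction) separately per state-count class, subtracting
`n_k · log(1 − P_k(invariant))` with `P_k(invariant)` computed by pruning
the k constant columns; the correction uses the all-taxa tree and ignores
the soft-character missingness pattern (the simulation ascertains
variability over all taxa before masking, so this matches the generating
process). The inner pruning loop is JIT-compiled with numba.

## MCMC

Random-scan Metropolis–Hastings over (topology, node ages, fossil ages and
attachments, sampled-ancestor configuration, origin age, λ, μ, ψ, both
clock rates, κ, both gamma shapes); ρ is fixed to its true value and never
proposed. Priors: Exponential(10) on λ, μ, ψ and both clocks (prior mean
0.1); uniform on each fossil age over its assigned range; uniform on the
origin age up to a configurable maximum; κ ~ Exponential(0.5) and gamma
shapes ~ Exponential(1) (the study delegates these to standard tutorial
settings without printing them). Moves and their default weights:

* scale moves on each rate/shape (weight 1 each): multiplier e^u,
  u ~ U(−δ, δ), log-Hastings u;
* node-age slide (5): uniform redraw between the oldest child and the
  parent, symmetric;
* fossil-age slide (5): reflected random walk inside
  [range ∩ attachment constraints], symmetric; for a sampled ancestor the
  attachment node moves with the fossil;
* origin slide (1): reflected walk between the root age and the prior
  maximum;
* narrow exchange (3): swap a node with its uncle when ages permit; the
  candidate set (nodes with a grandparent) has constant size, so the move
  is symmetric; exchanges that would detach a sampled-ancestor tip are
  rejected;
* fossil reattachment (2): detach a fossil tip, choose a compatible branch
  uniformly, draw the attachment age uniformly on the feasible interval;
  log-Hastings = log(new interval length) − log(old interval length);
* sampled-ancestor toggle (2): reversible-jump collapse/expansion of the
  attachment age, log-Hastings ∓ log(interval length).

Per-partition log-likelihoods are cached and only the components a move
can change are recomputed (e.g. fossil moves never touch the molecular
partition); the cached posterior is re-derived from scratch every 10⁴
generations and must agree to 1e−6 relative, which guards the invalidation
logic. A generation is one proposal. Chains are initialized at the true
topology (a standard starting-tree shortcut) with fossil ages *redrawn from
their priors* and rates at prior means, so age estimates are not seeded
with the truth. Convergence follows the study rule: posterior ESS ≥ 200 in
each of two chains (autocorrelation-based, via arviz; a constant series is
defined to have ESS 0) and post-burn-in posterior medians within 10%
relative; burn-in is the first 25% of samples (not published; a standard
choice). Non-converged replicates are excluded from summaries and counted.

## Assessment

Point estimate = posterior median. Relative error = |true − median|/true.
Coverage uses the shortest interval containing ⌈0.95 n⌉ sorted samples
(closed at the boundaries). Normalized RF = symmetric difference of
non-trivial rooted clade sets divided by 2(n − 2), with sampled ancestors
as zero-length tips. "Correct placement" is formalized as: the extant-tip
set of the smallest clade containing the fossil and at least one extant tip
equals the corresponding set in the true tree (the underlying study does
not give a formula; this operationalization is pluggable). Full-tree MRCA
age = root age of the sampled tree; extant MRCA age = age of the most
recent common ancestor of the sampled extant tips.

## Problem sizes used by the test suite

The published study ran 100 replicates per condition with chains up to
1.5×10⁸ generations in compiled samplers. This package's default test and
example runs use desk-scale substitutes chosen as the largest sizes that
keep the whole suite interactive: calibration checks use ≥100 accepted
simulation replicates per condition (no inference needed); the coverage and
placement checks use 3 replicates per condition at 1500 molecular sites,
120 morphological characters and single 40 000-proposal chains (at this
scale the absolute coverage levels sit above the full-scale values because
posteriors are wider and the rate-misspecification effect is weaker; the
monotone decrease with the deposit proportion is the robust signal); the
matched-model calibration check uses 20 replicates of a reduced design
(8–12 extant tips, ~6–14 fossils, 400 sites, 40 characters) with fixed
topology. The corresponding Monte-Carlo bands are wide and are stated in
each test; the monotone effect directions are the load-bearing assertions.

## Known limitations

* The sampler is a reference implementation in Python/numpy/numba; it is
  suitable for the reduced problem sizes above, not for the full published
  chain lengths.
* Only strict clocks and the constant-rate FBD prior are implemented
  (relaxed-clock variants and skyline rates are out of scope by design);
  the deliberate mismatch between piecewise-constant simulation rates and
  the constant-rate inference model is the object of study, not a bug.
* Tip dates of extant taxa are exactly 0; serially sampled extant data are
  not supported.
* The empirical reanalysis that motivated the range-masking operation is
  out of scope; only the masking operation itself is provided.
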
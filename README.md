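# fbdage

**Estimating the ages of poorly dated fossils with Bayesian total-evidence
dating under the fossilized birth-death process.**

Many important fossil deposits — Baltic amber is the canonical example —
cannot be dated precisely: every specimen from the deposit carries the same
wide age interval (e.g. 30–50 Ma), while fossils from well-dated formations
have narrow individual ranges. `fbdage` is a simulation-and-inference
toolkit for asking how well a Bayesian total-evidence analysis can recover
the ages of such specimens when fossil ages are treated as free parameters:
it simulates clades containing a poorly dated deposit, runs Markov chain
Monte Carlo over trees and fossil ages under the fossilized birth-death
(FBD) prior, and scores the accuracy, calibration and topology recovery of
the estimates. It is aimed at researchers in phylogenetics and
paleobiology studying fossil-age uncertainty and at method developers who
need a transparent, fully testable reference implementation.

## The model

The FBD process generates a dated tree of extant and fossil samples from a
single lineage at the origin time x₀ with speciation rate λ, extinction
rate μ, fossil-recovery rate ψ and extant sampling probability ρ. With

    c₁ = √((λ−μ−ψ)² + 4λψ),    c₂ = −(λ−μ−2λρ−ψ)/c₁

and the standard helper functions p₀(t) (no sampled descendants) and q(t)
(per-branch factor), the log-density of a sampled tree with bifurcation
ages xᵢ, fossil-tip ages yⱼ, k sampled ancestors and n extant tips is

    log f(T|x₀) = log q(x₀) + Σᵢ [log 2λ + log q(xᵢ)]
                + Σⱼ [log ψ + log p₀(yⱼ) − log q(yⱼ)]
                + k log ψ + n log ρ .

Total-evidence data combine an HKY+Γ molecular alignment (extant taxa
only) and an Mk+Γ morphological matrix (all taxa, conditioned on variable
characters) under strict clocks; each fossil age gets a uniform prior over
its assigned range and is sampled jointly with topology, node ages,
sampled-ancestor configuration and all rates. `docs/methods.md` has the
full specification, priors, move kernels and validation strategy.

## Worked example

`examples/01_simulate_deposit_replicate.py` draws one accepted replicate of
the deposit design (target 30% imprecise-date fossils, precise ranges 0.2×
the true age):

```text
accepted after 208 tree and 19 fossil-record attempts
extant sampled taxa: 26 (accepted window 20-30)
fossils: 51 of which 16 imprecise-date (target proportion 0.3 +/- 10% relative)
alignment: 26 taxa x 1000 sites (extant only)
morphology: 77 taxa x 120 variable characters

first fossil age ranges (imprecise-date fossils all share 30-50):
taxon   min_age    max_age
   F1 91.539791 114.005650
   F2 82.502329 100.702203
   F3 43.020931  52.815525
   F4 30.000000  50.000000
   ...
```

16/51 ≈ 0.31 lies inside the accepted band around the 0.3 target;
precise-date fossils (F1–F3, …) get individual ranges of width 0.2 × true
age containing the true age, while deposit fossils (F4, F5, …) all share
the 30–50 Myr interval that inference will use as their age prior.

`examples/02_fbd_density_vs_birth_death.py` evaluates the tree prior:

```text
sampled tree: 6 extant tips, root age 31.58 Myr, origin 60.0 Myr
FBD log-density (psi=0.05): -28.399502
FBD log-density (psi=0):    -19.078982
birth-death closed form:    -19.078982
```

With ψ=0 the FBD density equals the classical sampled birth-death density
(the last two lines agree to machine precision); with ψ>0 the same
fossil-free tree is less probable because observing no fossils becomes an
informative event.

`examples/03_total_evidence_inference.py` runs the full inference on a
reduced replicate and prints per-class relative errors, HPD coverages and
placement accuracies; `examples/04_mask_empirical_age_table.py` shows the
deposit-masking operation used for empirical-style age tables; and
`examples/05_plot_study_metrics.py` draws boxplots from a finished study
directory.

The same pipeline is scriptable from the shell:

```bash
fbdage simulate --target-prop 0.3 --range-mult 0.2 --replicates 2 --seed 7 --out sim
fbdage infer sim/rep0 --generations 200000 --chains 2
fbdage assess sim/rep0
fbdage run-study --target-props 0.1,0.5 --replicates 2 --out study_output
```

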
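# Methods

## Model

The package scores physiological adaptedness as the outcome of an acute
challenge experiment on a *regulating* (homeostatic) organism. Four states
are distinguished per subject: intact baseline `F0`, pre-load `F1` (after
any chronic conditioning factor; for unconditioned controls `F0 = F1`),
immediately post-load `F2`, and post-rest `F3`. Two dimensionless,
scale-free fractions summarise each parameter:

* response `|K″ − K′| / K′` — the relative shift under the load (the
  modulus makes rises and falls comparable; the division removes units);
* recovery `|K‴ − K′| / |K‴ − K″|` — distance still to go over the size of
  the recovery step; small when the parameter snapped back quickly.

The subject index `a` sums these with signs fixed by the investigator's
classification of each parameter — homeostatic responses negative, adaptive
(allostatic) responses positive, recovery always negative, indifferent
parameters exactly zero — optionally weighting every parameter's term by
its stability coefficient `S = 1 − SD/mean` estimated on an intact baseline
cohort. The weighting encodes that a large excursion of a tightly regulated
constant is far more meaningful than the same relative excursion of a
labile variable. An index value has no meaning in isolation; only
comparisons between subjects or groups measured on the identical panel with
identical options are interpretable, and the package enforces matching
homeostatic/adaptive counts, recovery availability and weighting mode
before any comparison.

### Assumptions and admissibility

* All pre-load values are strictly positive (relative fractions need a
  positive reference); non-positive references are rejected.
* Baseline distributions are approximately normal: `SD ≥ mean` makes `S`
  non-positive and is rejected, and `S < 0.5` is admitted with a warning
  (the bundled horse example itself uses S = 0.424 for lactate).
* The rest interval must actually resolve recovery. `K‴ = K″ ≠ K′` makes
  the recovery fraction diverge and raises an error by default; a finite
  user-supplied cap can stand in for the diverging term. `K‴ = K′` — and in
  particular the 0/0 case where the parameter never moved — is taken as
  perfect recovery, fraction 0 (the numerator-zero convention; the
  published "−0" recovery cells are consistent with it).
* Statistically negligible ("paradoxical") responses can be taken for zero,
  either from a user mask or from a Welch test between the `F1` and `F2`
  cells at `alpha` (default 0.05). Automatic zeroing is **off** by default:
  the bundled worked examples did not apply it, and silently nulling terms
  would change published totals.

## Designs

**Case I** compares two subjects directly. **Case II** computes per-subject
indices and aggregates per group: `A = mean(a)`, sample SD, a
normal-approximation confidence interval (default 95%), and pairwise Welch
t-tests (or a seeded permutation test for small n) on the individual `a`
values. **Case III** (destructive sampling) substitutes per-state group
means for individual values and computes `A` on the resulting
pseudo-profile. The model itself leaves Case III's dispersion undefined;
the package offers a parametric bootstrap — each cell mean resampled from
`Normal(mean, sd/√n)`, resampled means clipped at 1% of the observed mean
to preserve positivity, `A` recomputed per replicate — reported with an
explicit "extension" note. Groups are ranked by descending `A` (dense
ranks, ties warned).

## Numerical choices

* Full precision throughout; only reports render at 3 decimals, mirroring
  the layout of the published tables.
* Sample SD (n − 1) everywhere a series is summarised.
* Equality of two subject indices is declared below 1e-9; the index equals
  the sum of its per-parameter breakdown to better than 1e-12.
* Stability sources are configurable: fixed (supplied) values, one
  reference baseline cohort, per-group baselines, or the mean of per-group
  values. The rat fixture supplies the published S values so the
  reproduction isolates the index arithmetic from rounding of S (a
  separate test confirms the supplied values agree with recomputation from
  the reference rest cohort within 0.001). The horse fixture pins
  `weighting: none` because its published totals are the unweighted sums of
  its published fraction columns.
* During bootstrap resampling a large finite recovery cap is substituted
  for the (measure-zero) degenerate recovery draws so a single pathological
  replicate cannot abort the run.

## Synthetic cohorts

The generator produces study data with known ground truth so the index's
discriminative behaviour is measurable. Each group carries a latent
adaptedness `θ ∈ [0, 1]`; per subject and parameter

```
K′ ~ Normal(μ, σ)
K″ = K′ · (1 + δ·(1−θ) + ε)        homeostatic
K″ = K′ · (1 + γ·θ + ε)            adaptive
K‴ = K″ + ρ(θ)·(1+η)·(K′ − K″)     ρ(θ) = ρ0 + ρ1·θ ≤ 1
```

with `ε ~ N(0, load_noise_sd)` and `η ~ N(0, recovery_noise_sd)`. Effects
are multiplicative so θ acts scale-free across parameters of very
different magnitudes, matching an index built entirely on relative
fractions. Recovery noise perturbs the recovery *rate*, not the level:
with rate noise the recovery fraction reduces to `|1 − ρ(1+η)| / (ρ(1+η))`
and stays bounded, which is exactly the regime a competent experimenter
creates by choosing the rest interval so the recovery step is resolvable.
Additive level noise would instead let the fraction's denominator cross
zero, giving heavy-tailed (infinite-mean) recovery terms — the degenerate
situation the method explicitly requires the design to avoid, and not a
property of a well-run study. Values are clipped at 1% of the baseline
mean (clipping counted and reported) rather than resampled, for seed
stability. Per-group random streams are derived from `(seed, group index)`
so a cohort's data do not depend on what else is simulated.

Defaults emulate a realistic exercise-biochemistry panel patterned on the
rat study: one adaptive stress hormone (γ = 1.5) and four homeostatic
substrates/metabolites (δ = 0.3–0.6), baseline CV 0.10, load noise
sd 0.05, recovery-rate noise sd 0.02, ρ(θ) = 0.5 + 0.4·θ, four groups at
θ = 0.2/0.4/0.6/0.8 with n = 25. With these sizes the full 200-replicate
ordering-recovery experiment completes in a few seconds.

What the generator does **not** emulate: supercompensation (post-recovery
overshoot), nonlinear/exponential recovery kinetics, time-resolved
trajectories, non-Gaussian baselines, and correlated parameters. Passing
tests on synthetic data therefore demonstrate that the index recovers a
monotone latent ordering under Gaussian, multiplicative, independent
perturbations — not that it is robust to skewed biomarkers, floor/ceiling
effects or badly chosen rest intervals in real data.

## Known limitations

* Case III uncertainty is a beyond-the-basic-model bootstrap; treat its
  intervals as indicative.
* No multiple-comparison correction across pairwise group tests; raw p
  values are reported with that caveat.
* Which variables are homeostatic vs adaptive is scientific judgement the
  package deliberately refuses to automate; misclassification flips signs.
* No Δt-normalised variant of the recovery fraction exists; studies should
  use equal rest intervals across compared arms.
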
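# Methods

## Model

A binary classification problem over sample paths of two independent
multivariate Gaussian processes `X⁰`, `X¹` in `R^p`, all observed on one
strictly increasing observation time vector `t_N = (t_1, …, t_N)`. A path
is stacked time-major into one `Np`-vector, so the class-conditional laws
are `N(μ^y, Σ^y)` on `R^{Np}` with block covariance `Σ^y[i,j] =
Cov(X_{t_i}, X_{t_j})`. The class-1 mixing probability `α₁` is assumed
known: under separate (stratified) sampling the per-class path counts are
fixed by design and carry no information about `α₁`.

Mechanistic knowledge enters as a narrow-sense linear Itô SDE per class,

    dX_t = (A(t) X_t + a(t)) dt + B(t) dW_t,    X_{t0} = c,

with `A(t) ∈ R^{p×p}`, `a(t) ∈ R^p`, `B(t) ∈ R^{p×q}` measurable and
bounded, `W` a standard q-dimensional Wiener process, and `c` constant or
Gaussian — exactly the class for which the solution is a Gaussian process.
Mean and covariance follow from the fundamental matrix `Φ(t)` of the
homogeneous system (`Φ(t0) = I`):

    m(t)      = Φ(t) (E[c] + ∫_{t0}^t Φ(s)⁻¹ a(s) ds)
    Ψ(ti,tj)  = Φ(ti) (Cov[c] + ∫_{t0}^{ti} Φ(u)⁻¹ B(u)B(u)ᵀ Φ(u)⁻ᵀ du) Φ(tj)ᵀ,
                 ti ≤ tj.

## Classifiers

**Plug-in Bayes / stochastic QDA.** The Gaussian log posterior-odds

    ψ(x) = −½(x−m⁰)ᵀΨ⁰⁻¹(x−m⁰) + ½(x−m¹)ᵀΨ¹⁻¹(x−m¹)
           + ½ log(|Ψ¹|/|Ψ⁰|) − log(α₁/(1−α₁)),

with label 0 iff `ψ(x) > 0`. Fed with the exact SDE moments this is the
Bayes classifier (the lower bound reported by the experiment drivers); fed
with empirical training moments it is the stochastic QDA, which requires
`min(n⁰, n¹) > Np` for invertible sample covariances. Note the sign of the
log-determinant term: it is the one that makes ψ the exact Gaussian
log-odds — plugging the true moments into any other sign convention would
not be Bayes-optimal when the class covariances differ.

**Optimal Bayesian classifier (OBC).** The class parameters `(μ^y, Σ^y)`
are uncertain with the conjugate normal-inverse-Wishart prior

    Σ ~ IW(κ, Ψ̆),    μ | Σ ~ N(m̆, Σ/ν).

Believing the SDE moments *on average* fixes the hyperparameter mapping
`m̆ = m`, `Ψ̆ = (κ − Np − 1) Ψ`, so the prior mean of `Σ` is exactly the
SDE covariance; this is why the package enforces `κ > Np + 1` at prior
construction (strictly stronger than the propriety condition
`κ > Np − 1`). `ν` and `κ` are user-set confidence knobs — the study
convention is `ν = κ = Np + κ_extra` with `κ_extra ∈ {20, 50, 100, 500}`.

The batch conjugate update with `n` training paths of sample mean `μ̂` and
unbiased sample covariance `Σ̂` is

    ν* = ν + n,   κ* = κ + n,   m* = (ν m̆ + n μ̂)/(ν + n),
    Ψ* = Ψ̆ + (n−1) Σ̂ + (ν n/(ν+n)) (μ̂ − m̆)(μ̂ − m̆)ᵀ.

The resulting effective (posterior-predictive) class density is
multivariate Student-t with `k = κ* − Np + 1` degrees of freedom, location
`m*`, scale `Π = (ν*+1)/(k ν*) Ψ*`; the OBC assigns label 0 iff

    log(1−α₁) + log t_k⁰(x) ≥ log α₁ + log t_k¹(x),

ties to class 0. The decision is computed entirely in log space: the
equivalent polynomial form of the discriminant raises the quadratic forms
to the power `k + Np` and overflows around `Np ≈ 60`, while the log form
defines the same boundary. The same construction applied to the prior
(no data) yields the robust, zero-training-path classifier.

## Numerical choices

- **Quadrature** (mean/covariance integrals): composite Gauss–Legendre per
  inter-observation interval, node count doubled from 8 until the panel
  changes by < 1e-9 relative (cap 256). Stacked moments reuse cumulative
  integrals across the grid, so the cost is linear in `N`.
- **Fundamental matrix**: matrix exponential for constant `A`; otherwise
  the matrix ODE is integrated column-wise with DOP853 at rtol 1e-11 — no
  commutativity assumption, since `exp(∫A)` is wrong for non-commuting
  `A(t)`.
- **Simulation**: Euler–Maruyama with `substeps` uniform internal steps per
  inter-observation interval (default 10); Wiener increments are
  `N(0, dt·I_q)`. The weak bias is O(dt): moment-validation runs use
  100–400 substeps so that discretization bias sits below the Monte-Carlo
  resolution being tested, while the classification experiments keep the
  default (both classes share the bias, so decisions are barely affected).
- **Linear algebra**: every quadratic form and log-determinant comes from
  one Cholesky factorization per class; covariances are never explicitly
  inverted. Non-positive-definite inputs raise immediately rather than
  being silently regularized.
- **Ties**: exact equality of the weighted OBC log densities assigns class
  0; the QDA rule requires strictly positive ψ for class 0.
- **Randomness**: one root seed; each experiment cell/replicate derives its
  streams via `SeedSequence(root_seed, spawn_key=(offset_i, n_i, kappa_i,
  r))`, so any cell reruns bit-identically and cells are independent.

## Synthetic study systems

- `eq33`: two p=3 linear SDEs sharing `A = diag(0.01)`, `a = 0`, dispersion
  `B = 0.1·[[1,.4,.4],[.4,1,.4],[.4,.4,1]]` (used directly as dispersion;
  the instantaneous noise covariance is `BBᵀ`), differing only in initial
  condition `[0,0,0]` vs `[0.25,0.25,0.25]`; grid `t = 1..20`, so
  `Np = 60`. Misspecification knobs: `Δμ` added to each diagonal entry of
  the class-1 a-priori drift, `Δρ` added to the class-1 dispersion
  correlation (before the 0.1 scale).
- `ou_beta010` / `ou_beta015`: OU trait evolution for two species,
  `θ⁰ = 80`, `θ¹ = 85`, `σ = 1`, common ancestor `X_a = 1`, grid
  `t = 1..30` (units of 10⁶ years), `Np = 30`; knob `Δβ` added to the
  class-1 a-priori adaptation rate.

The experiment protocol per cell `(offset, n, κ)`: simulate `n` training
and `n_test` test paths per class from the ground truth, build priors from
the (possibly offset) a-priori SDEs, update, score OBC and data-QDA on the
test paths, attach the plug-in Bayes error on the same test sets, and
average over `T` replicates. Defaults run at reduced scale — `T = 50`
replicates, `n_test = 500` per class, training sizes `{65, 80, 100, 120}`
(p=3 system; must exceed `Np = 60`) or `{60, 100, 140}` (OU) — which
resolves the error differences of interest at a few Monte-Carlo standard
errors in seconds; the full-scale setting (`T = 1000`, `n_test = 2000`) is
a config change. Prior and plug-in moments default to the analytic closed
forms; Monte-Carlo moment estimation from `l` simulated paths (the
protocol's other route, `l = 2000`) is available via `moment_source=
"simulated"`.

## What the synthetic generator does and does not show

The generator produces exactly the model class the classifiers assume:
Gaussian paths on a shared, complete, regular grid, with known `α₁` and
correctly specified (or deliberately offset) SDEs. Passing tests therefore
demonstrate correctness of the moment computations, the prior mapping, the
conjugate update, and the decision rules, and they reproduce the
qualitative misspecification trends — they do *not* certify performance on
real data with non-Gaussian dynamics, irregular or per-path observation
grids, missing values, or unknown mixing probabilities, none of which the
model covers. Classification at observation times outside the training
grid is out of scope (sub-grids work by slicing paths and rebuilding the
prior on the sub-grid).

## Known limitations

- Linear drift and state-free dispersion only; nonlinear SDEs (non-Gaussian
  solutions) and Stratonovich calculus are out of scope.
- `ν`, `κ` are user-set, never estimated from data, and no posterior over
  `α₁` exists under separate sampling.
- The data-QDA baseline genuinely requires `n > Np`; the OBC has no such
  requirement (the prior scale keeps `Ψ*` positive definite at any `n ≥ 1`).
- Euler–Maruyama is weak order 1; studies that compare simulated moments
  against closed forms must budget the O(dt) bias (see Numerical choices).
- The cost of one discriminant evaluation is dominated by the `Np × Np`
  Cholesky factorizations, i.e. O(N³p³) once per classifier and O(N²p²)
  per test path thereafter.
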
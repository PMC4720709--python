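# sdebayes

Optimal Bayesian classification of Gaussian-process sample paths, with prior
knowledge supplied as linear stochastic differential equations.

## The problem

Many time-series classification problems in biology come with *mechanistic*
knowledge: a quantitative trait evolving toward an optimum, expression
dynamics driven by a known regulatory structure, diffusion-like measurement
processes. When only a handful of sample paths per class can be measured, a
purely data-driven classifier is unreliable — but the mechanism, written as
a stochastic differential equation (SDE), pins down exactly the kind of
prior information a Bayesian classifier can exploit.

`sdebayes` implements that pipeline for the linear vector SDE

```
dX_t = (A(t) X_t + a(t)) dt + B(t) dW_t,     X_{t0} = c,
```

whose solution is a Gaussian process. Observed at a common time grid
`t_1 < … < t_N`, each sample path becomes one `Np`-dimensional Gaussian
vector with stacked mean `m` and block covariance `Ψ`, both available in
closed form through the fundamental matrix `Φ(t)` of `dΦ/dt = A(t)Φ`:

```
m(t)     = Φ(t) (E[c] + ∫ Φ(s)⁻¹ a(s) ds)
Ψ(ti,tj) = Φ(ti) (Cov[c] + ∫₀^{ti} Φ(u)⁻¹ B(u)B(u)ᵀ Φ(u)⁻ᵀ du) Φ(tj)ᵀ
```

Three classifiers are provided over these stacked observations:

* **Plug-in Bayes** — QDA with the true SDE moments: the optimal
  classifier when the SDEs describe the data perfectly, and the lower
  bound every other rule is measured against.
* **Stochastic QDA** — QDA with the empirical moments of the training
  paths (needs more paths per class than `Np`).
* **OBC** — the optimal Bayesian classifier. The class moments `(μ, Σ)`
  get a conjugate normal-inverse-Wishart prior whose location is the SDE
  moment pair (`m̆ = m`, `Ψ̆ = (κ − Np − 1)Ψ`, confidence knobs `ν, κ`);
  after the conjugate update with training paths, each class's *effective*
  density is a multivariate Student-t with `k = κ* − Np + 1` degrees of
  freedom, location `m*` and scale `Π = (ν*+1)/(k ν*) Ψ*`, and the OBC
  compares the prior-weighted effective densities in log form.

The package also ships Euler–Maruyama simulation of the SDEs, the
Ornstein–Uhlenbeck (OU) trait-evolution model `dX = −β(X − θ)dt + σ dW` as
a ready-made spec, and experiment drivers that measure how the OBC degrades
when the prior SDEs are *misspecified* (wrong drift, dispersion, or
adaptation rate) at varying prior confidence `κ` and training size `n`.

## Worked example

Two species' quantitative traits evolve from a common ancestral state
`X_a = 1` toward optima `θ⁰ = 80` and `θ¹ = 85` at adaptation rate
`β = 0.1` (OU model, σ = 1), observed over 30 My at 1-My steps. With 100
training paths per class and a confident, correctly specified prior
(`ν = κ = Np + 500`):

```python
import sdebayes as sb
from sdebayes.model import PathClassificationModel

fx = sb.datasets.make_fixture("ou_beta010")
kappa = fx.grid.dim + 500.0
pri0 = sb.prior_from_sde(fx.spec0, fx.grid, nu=kappa, kappa=kappa)
pri1 = sb.prior_from_sde(fx.spec1, fx.grid, nu=kappa, kappa=kappa)
tr0 = sb.simulate_paths(fx.spec0, fx.grid, 100, seed=1, label=0)
tr1 = sb.simulate_paths(fx.spec1, fx.grid, 100, seed=2, label=1)

res = PathClassificationModel(tr0, tr1, prior0=pri0, prior1=pri1).fit()
print(res.summary())
```

```
Path classification results
==============================================
method:            OBC
observation grid:  N=30, p=1, Np=30
training paths:    n0=100, n1=100
alpha1 (known):    0.5
apparent error:    0.0200
cond(cov) class 0: 2.552e+02
cond(cov) class 1: 2.549e+02
posterior nu*:     630 / 630
posterior kappa*:  630 / 630
effective dof k:   601 / 601
```

Scoring on 500 fresh test paths per class:

```python
te0 = sb.simulate_paths(fx.spec0, fx.grid, 500, seed=3, label=0)
te1 = sb.simulate_paths(fx.spec1, fx.grid, 500, seed=4, label=1)
print(res.error_rate(te0, te1))                       # 0.0960
print(PathClassificationModel(tr0, tr1).fit("qda").error_rate(te0, te1))  # 0.1940
bayes = sb.build_qda_from_sde(fx.spec0, fx.spec1, fx.grid, alpha1=0.5)
print(sb.true_error(bayes, te0, te1, 0.5))            # 0.0900
```

The OBC (9.6% error) sits close to the plug-in Bayes bound (9.0%) while the
purely data-driven QDA, with only 100 paths in a 30-dimensional stacked
space, pays roughly double (19.4%).

A command-line interface mirrors the library:
`sdebayes fixtures | simulate | prior | train | classify | experiment`
(see `sdebayes --help`; every run writes a `.meta.json` reproduction
record with its root seed and settings hash).

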
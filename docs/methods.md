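# Methods

## Model

A panel holds `p` time series of common length `n`, each tagged with an
exponential family: Gaussian, binomial (Bernoulli), Poisson, gamma, or
inverse-Gaussian.  Target series `x_i` is modeled as an intercept-free
GLM of the lagged panel at order `d`: response row `r` (the observation
at time `r + d`) regresses on the `d` preceding values of every selected
series, so the full design is `(n−d) × (d·p)` and a candidate subset
keeps `d`-column blocks.  Identifiability requires `n − d > p·d`.

Mean models per family:

| family | mean model | dispersion `φ̂` | Fisher weight `W_t` |
| --- | --- | --- | --- |
| gaussian | `μ = η` | mean squared residual | `1` |
| binomial | `μ = logistic(η)` | `1` | `μ(1−μ)`; robust: `(x−μ)²` |
| poisson | `μ = exp(η)` | Pearson `χ²/(n−d−dk)` | `μ`, or `(x−μ)²` when `|φ̂−1| > 0.1` |
| gamma | `μ = 1/η`, `η > 0` | `κ = 1/shape`, marginal ML fit, once per target | `μ²` |
| inverse-Gaussian | `μ = η`, `η > 0` | `mean((x−μ)²/(μ²x))` | `1/μ` |

Coefficients are fitted by a generic hand-written IRLS (working response
`z = η + (x−μ) g′(μ)`, weights `1/(V(μ) g′(μ)²)`, least-squares solve
with a tiny ridge fallback on rank deficiency, deviance-based
convergence at relative 1e−8, 100 iterations max).  The gamma and
inverse-Gaussian mean models require a strictly positive linear
predictor; a violating fit yields a `−inf` log-likelihood sentinel, and
the candidate scores `+inf` (rejected).  All log-likelihoods are exact,
including constant terms, and were verified pointwise against
scipy.stats densities to 1e−10; the IRLS was verified against
statsmodels GLM to 1e−6 for the families whose links coincide.

The empty subset (`k = 0`) is the intercept-free null: zero linear
predictor for gaussian/binomial/poisson (means 0, ½, 1); for gamma and
inverse-Gaussian, whose mean domains exclude `η = 0`, the null is the
constant marginal-mean model.

## Message-length criterion

For a subset with `k` of `p` series selected (`dk` coefficients `β̂`),
the message length at ridge hyperparameter `λ` is, in nats,

```
MML(λ) = −L(β̂, φ̂) + ½ log det(X'WX + λI) + (k/2) log(2πλ)
         + (λ / 2φ̂) β̂'β̂ + ½ log(n−d) − ((k+1)/2) log 2π
         + ½ log((k+1)π) + log C(p,k) + log(p+1)
```

with `log C(p,k) + log(p+1)` the structure code.  The score of the
subset is `min_{λ ∈ [0.1, 1000]} MML(λ)` with `β̂, φ̂` held fixed: a
13-point log-spaced grid scan initializes a Nelder–Mead simplex on
`log λ`, clamped to the box.  `X'WX` is eigendecomposed once per subset
so every λ evaluation costs `O(dk)` via
`log det(X'WX + λI) = Σ_j log(e_j + λ)`.

Two documented ambiguities are exposed as switches, defaults as stated:
`count_coefficients=True` replaces `k` by `dk` in the prior/constant
terms (default counts selected series, `k`); `product_form=True` uses
`log(p·k)` instead of `log C(p,k)` in the structure code.

**Numerical observation.** With the `+(k/2) log(2πλ)` term, `MML(λ)` is
in practice monotonically increasing on `[0.1, 1000]` for every fit we
examined (the Fisher log-determinant and the quadratic penalty are also
increasing in λ), so the minimizer is essentially always the lower box
edge 0.1.  A Gaussian `N(0, φ/λ)` coefficient prior would contribute
`−(dk/2) log λ` instead and give an interior optimum.  The implemented
form is the criterion as specified; the λ search machinery is retained
and tested, but users should not expect the selected λ to vary.

## Subset search

- **Exhaustive (`exHMML`)**: all `2^p` subsets per target, refused above
  `p = 20`.
- **Genetic (`HMMLGA`)**: population `m = 20` (even), `ng = 10`
  generations; each generation keeps the best `m/2` as elite, crosses
  consecutive elite pairs at a uniform single point, flips one random bit
  of one random elite member, and refills from the best children.
  Scores are memoized by bitstring; the best subset ever evaluated is
  returned.
- **Parsimony tie-break**: among scores within 1e−9 of the minimum,
  fewest selected series wins; remaining ties resolve deterministically
  by bitstring value.

Per-target searches are independent; row `i` of the adjacency is the
selected indicator of target `i` (self-loops admissible).  Genetic runs
derive per-target RNG streams from `(seed, target)` so rows are
reproducible in any execution order.

## Synthetic generator (full disclosure)

Benchmark truth graphs draw `n_edges` distinct directed non-self edges
uniformly at random.  Panels are then simulated forward in time:

- Parentless series and the first `d` values of every series are
  baseline draws: gaussian `N(0,1)`, Bernoulli(½), Poisson(1), gamma
  (shape 2, scale 1), inverse-Gaussian (mean 1, shape 1).
- For series `i` with parents `J` at time `t`:
  `η_i(t) = Σ_{j∈J} Σ_{l=1..d} (strength/d) · s_j(x_j(t−l))`, where
  `s_j(x) = clip((x − m_j)/sd_j, −3, 3)` standardizes by the parent
  family's baseline moments and clamps at ±3 SD.  The `d` lag
  coefficients of an edge are equal and sum to `strength`; all
  coefficients are positive.
- `η` is clipped to ±3, then the value is drawn from the family with
  mean given by its own (baseline-shifted) inverse link: gaussian
  `N(η, 1)`; Bernoulli(`logistic(η)`); Poisson(`exp(η)`); gamma with
  shape 2 and mean `1/max(½ + η, 0.2)`; inverse-Gaussian with shape 1
  and mean `max(1 + η, 0.2)`.
- Mixed-family cells shuffle the family-to-node assignment per
  replicate.

Design rationale: the clamp-linear squash keeps the simulated dynamics
inside the model class the analysis fits (a saturating squash such as
tanh makes parent signals partially reconstructible from the target's
own past and defeats any lag-regression method); the η clip and the
positive-mean floors keep conditional means within about one order of
magnitude of baseline so count/positive series stay stationary and
non-degenerate; positive coefficients keep the gamma and
inverse-Gaussian predictors away from their positivity floor, which
random signs would saturate.

Graphs are scored by directed-edge F-measure (`2PR/(P+R)` over the full
`p×p` adjacency including the diagonal; both-empty scores 1).  The
uninformed baseline includes each admissible off-diagonal edge
independently with probability ½.

## Parameters

| symbol | meaning | default |
| --- | --- | --- |
| `d` | lag order | 3 |
| `λ` box | ridge search interval | `[0.1, 1000]` |
| `m`, `ng` | GA population, generations | 20, 10 |
| tie tolerance | parsimony tie-break | 1e−9 |
| IRLS | deviance rtol / max iterations | 1e−8 / 100 |
| Poisson robust switch | `|φ̂−1|` threshold | 0.1 |

## Assumptions

- Stationary-enough series; the lag regression is fitted as a fixed
  design (no initial-condition modeling).
- No intercepts anywhere; series are assumed centered/scaled compatibly
  with their family's null mean.
- Dispersion is estimated per target (gamma: once from the marginal
  series; others: from each candidate fit) and treated as known in the
  message length.
- Binomial panels must be coded 0/1; Poisson panels nonnegative
  integers; gamma/inverse-Gaussian strictly positive.

## Limitations

- **Recall under the printed criterion.** On the benchmark cells the
  criterion's per-parent cost (≈ `(d/2) log(n−d)` from the Fisher term
  plus the structure code) exceeds the likelihood gain of weaker true
  edges, so dense graphs are recovered with high precision (0.8–0.9
  observed) but recall around 0.5–0.7.  At seed 1 the five benchmark
  cells average F = 0.64, 0.73, 0.58, 0.16, 0.67.  The effect is
  extreme on the p=8, n=100, strength-0.3 dense cell, where the code
  penalty per parent (~7 nats) dwarfs any attainable gain and near-empty
  sets are selected.  A coin-flip baseline scores ~0.67 against
  near-complete truths by construction, so on those dense cells the
  method does not beat it.  These are properties of the criterion plus
  the disclosed generator, not of the search (exhaustive search shows
  the same recall, and the genetic search matches the exhaustive optimum
  ≥ 80% of the time on oracle tests).
- The λ minimization is effectively pinned to the lower box edge (see
  the numerical observation above).
- The gamma reciprocal and inverse-Gaussian identity links make whole
  subsets infeasible when fitted predictors cross zero; such candidates
  are rejected rather than refitted under a different link.
- Exhaustive search is exponential in `p` (guarded at `p ≤ 20`); the
  genetic search is a heuristic with no optimality guarantee.
- No handling of missing data, unequal series lengths, or
  contemporaneous (lag-0) effects.
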
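# Methods

## The model and the ensemble

`minedesign` studies sequential experimental design for the linear model

    y = X beta + eps,    eps ~ N(0, sigma^2 I),

in the discovery regime: many candidate regressors (p up to thousands), few
observations (n < p), a sparse unknown truth, and a known noise scale. The
analyst's state of knowledge after n observations is the *ensemble* — the
exact Gaussian posterior under a zero-mean conjugate prior whose precision is
`b/sigma^2 I` (the scaled-conjugate form in which the prior width tracks the
noise scale):

    Gamma = sigma^2 (X^T X + b I)^{-1},
    mu    = (X^T X + b I)^{-1} X^T y.

The mean is the ridge solution of the normal equations and `Gamma` its
classical covariance; both are well defined for any `n`, including `n = 0`
(`mu = 0`, `Gamma = (sigma^2 / b) I`). No generalized inverse is ever used.

A convention note: placements of `sigma^2` in this family differ across the
literature (prior precision `b I` versus `b/sigma^2 I` amounts to the
reparameterization `b -> b/sigma^2`). The form above is the one under which
the package's simulated discovery behaviour — rapid power growth at low
noise with a sharp noise-dependent transition — emerges, and it keeps the
significance covariance equal to `sigma^2 (X^T X + bI)^{-1}`, i.e. the
regularized Gram inverse scaled by the error variance.

## The MINE criterion

A candidate next experiment is a batch `X_new` of `d` planned observation
rows. Across the ensemble the predicted responses have covariance

    D = X_new Gamma X_new^T.

Normalizing to a correlation matrix `R` and taking the determinant gives the
Maximally Informative Next Experiment criterion `Psi = det R`, the squared
volume of the prism spanned by the normalized predictions. `Psi = 1` means
the batch probes `d` mutually uncorrelated directions of remaining
uncertainty; `Psi = 0` means at least one planned observation is predictable
from the others and teaches nothing new. By the Hadamard inequality,
`det D <= prod_i D_ii`, with the gap `det D / prod D_ii` equal to `Psi`; the
criterion is invariant to rescaling any row by a positive constant.

If `S` is the symmetric inverse square root of `Gamma` and `{u_i}` any
orthonormal set, the batch with rows `x_i = S u_i` has `D = I_d`, hence
`Psi = 1`: any standardized orthonormal basis maximizes the criterion. Under
the shared constraint that each planned prediction have unit ensemble
variance (`diag(D) = 1`), these designs are also D-optimal: the refinement
factor `det(I_d + X_new Gamma X_new^T)` attains its constrained maximum
`2^d` exactly at them, and `refinement.verify_doptimal_equivalence` checks
both the attainment and the bound numerically on random feasible designs.

An observation worth recording: a batch of exact eigenvectors of `Gamma`
(standardized or not) always has diagonal `D`, so its criterion value is
also exactly 1. The criterion therefore does not discriminate between the
naive eigenvector method and the standardized methods; what differs between
them is the *scale* of their rows — how much information each observation
actually injects — and, within a degenerate eigenspace, *which* directions
the linear-algebra backend happens to hand back (see "Backend sensitivity").

## The four design generators

All four variants are driven by the eigenstructure of `Gamma`. The top
eigenspace at the prior ceiling `sigma^2/b` — eigenvalues tied with the
maximum at relative tolerance 1e-8 — is the *unexplored subspace*: directions
no experiment has touched.

* `mine_like`: the `d` leading eigenvectors, unit norm, no standardization.
* `mine`: the same eigenvectors standardized by `S` (eigenvector `v_i` maps
  to `v_i / sqrt(lam_i)`).
* `random_basis`: a fresh Haar-random orthonormal set, standardized by `S`.
* `random_rotation`: a Haar-random orthonormal `d`-frame *inside the
  unexplored subspace*, standardized by `S`; if the unexplored subspace has
  fewer than `d` dimensions the batch is padded with the next-largest
  eigenvectors, standardized. Drawing the `d`-frame directly is
  distributionally identical to rotating the full degenerate basis by a
  random orthogonal matrix and keeping the first `d` rows, at a fraction of
  the cost.

Random orthonormal sets are built by modified Gram–Schmidt on i.i.d.
Gaussian rows; MGS is also exposed directly and errors identify the first
numerically dependent row. Eigenvector signs are fixed (first non-negligible
component positive) for backend-independent output; `inv_sqrt` refuses
matrices with eigenvalue ratio below 1e-14.

## Significance and the simulated discovery cycle

Every coefficient is tested with the known-variance z statistic
`z_i = mu_i / sqrt(Gamma_ii)`, two-sided standard-normal p-values, and
Benjamini–Hochberg step-up at level `alpha` (default 1%). BH is implemented
directly (sort, largest k with `p_(k) <= k alpha / m`) and is cross-checked
in the tests against both an exhaustive subset-enumeration oracle and
`statsmodels.stats.multitest`.

A simulated replicate runs: random pilot (entries Uniform(0,10)/p, 10 rows
for p > 50, else 5–9 rows) -> loop of {design a `d`-row batch from the
current posterior, simulate `y = X_new beta_true + sigma z`, append, refit,
test}. Records per experiment: counts of true discoveries and false
positives, the criterion value of the chosen batch, and the posterior means
of a tracked window (first 20 coefficients by default). Significance for
experiment `i` is computed after experiment `i`'s data are in, so "power
after 30 experiments" reflects 30 appended batches.

Randomness discipline: the pilot (design and responses) comes from a stream
seeded by (study seed, replicate) only, so all methods share bit-identical
pilots within a replicate; everything after the pilot comes from a stream
additionally keyed by a CRC of the method label. Replicates are exactly
reproducible and independent of the worker count.

## The benchmark configuration

The packaged preset mirrors a standard sparse-discovery benchmark: p = 1000
coefficients of which the first ten are nonzero (11, −36, −26, 9, 33, −50,
−45, 15, 3, 17), sigma = 0.01, d = 10 observations per experiment, pilot of
10, alpha = 1%, and 99 post-pilot experiments by default (10 + 99·10 ≤ 1000
observations). The prior scale follows the tail-bound rule
`b = 1/beta_max^2` with beta_max = 50, i.e. b = 4e-4: on the unscaled
(normal-equation) scale the prior root-uncertainty `1/sqrt(b)` equals the
largest anticipated coefficient, so the truth is not out in the prior's
tails, while `b > 0` keeps the Gram matrix invertible (the ridge role). The
looser data-dominance check (posterior uncertainty never exceeding prior
uncertainty per eigendirection) holds automatically and is validated by
`prior.check_prior`.

Desk-scale defaults used by the reproduction script: 50 replicates of 30
experiments for the sigma = 0.01 benchmark (about ten minutes on one core);
the test suite uses smaller replicate counts with correspondingly widened
statistical bounds.

## Numerical choices

* One symmetric eigendecomposition of `X^T X + b I` per posterior fit
  provides the mean, the covariance, its diagonal, and the eigenstructure
  the design generators need; nothing is refactorized twice per cycle.
* `X^T X` is PSD by construction, so exact eigenvalues of `X^T X + b I` are
  at least `b`; computed eigenvalues below `b` (round-off once the Gram
  matrix dwarfs `b`) are clamped to `b`. Eigenvalues below `-1e-8` times the
  largest indicate genuinely bad input and raise.
* Prediction covariances are assembled through the cached eigendecomposition
  (`D = T diag(lam) T^T`, `T = X_new V`): the diagonal is a sum of
  non-negative terms, which keeps `D` PSD even for design rows large enough
  that the direct triple product `X Gamma X^T` loses the small eigenvalues
  of `Gamma` to cancellation.
* `det R` is computed by Cholesky of the correlation matrix; on failure
  (predictions almost linearly dependent) the eigenvalue product is used
  with negative eigenvalues clipped and values below 1e-12 of the maximum
  treated as exact singularity (`Psi = 0`).
* The refinement factor and gradient go through Cholesky of the regularized
  Gram matrix and `slogdet`; `phi >= 1` always since the added term is PSD.

## What the generator emulates — and what it does not

The synthetic studies emulate the designed-experiment setting: the analyst
fully controls every regressor value of each new observation, the model is
exactly linear, the noise is exactly Gaussian with known sigma, and the
truth is exactly sparse. Real screening data break all four assumptions
(uncontrollable covariates, model misspecification, unknown and non-constant
noise, approximate sparsity), so passing tests here demonstrate the internal
consistency and the comparative behaviour of the design strategies, not
field performance.

Two structural features of the simulated process deserve explicit mention
because they shape the results:

* **Pilot anisotropy.** Pilot entries are drawn Uniform(0,10)/p — entrywise
  positive — so all pilot rows lie near the all-ones direction. The
  pilot-dominated posterior therefore mostly reflects `1^T beta / p` in
  every coordinate. With the benchmark's nonzero values summing to −69 this
  injects a small negative bias into each early posterior mean, which can
  transiently flip the sign of the weakest coefficient (3) at small p; the
  bias fades as designed exploration replaces the pilot's information.
* **Projection cross-talk.** Standardized probes measure explored directions
  nearly exactly, so the posterior mean approximates the projection of the
  true `beta` onto the explored subspace. For a truly-zero coefficient that
  projection fluctuates with standard deviation about
  `|beta| sqrt(f(1-f)/p)` at explored fraction `f`, while the reported
  posterior standard deviation shrinks like `sqrt(1-f)`. False positives
  under BH are dominated by this geometric cross-talk, not by measurement
  noise; their rate grows with `f` until exploration completes. Reported
  false-positive percentages are therefore sensitive to exactly how much
  information each probe injects, which depends on the `sigma^2` convention
  and on `b` — two quantities that reasonable implementations of this
  pipeline can and do place differently.

## Backend sensitivity of the eigenvector methods

Within the unexplored subspace all eigenvalues are exactly tied, and "the
leading eigenvectors" are whatever orthonormal basis of that subspace the
eigensolver returns — a pure implementation artifact. LAPACK's choice is
close to coordinate-axis-aligned in index order, so `mine_like` and `mine`
effectively probe coefficients one index at a time starting from the lowest
— and the benchmark places its nonzero coefficients at indices 1–10. The
naive method consequently looks artificially strong on this benchmark under
this backend, and comparisons among `mine_like`/`mine` versus the
randomized variants are not portable across linear-algebra backends. This is
precisely the machine-precision dependence the random-rotation variant
exists to remove; `random_rotation` and `random_basis` are the
backend-independent members of the family and the recommended defaults.

## Known limitations

* Known, homoscedastic noise only; no unknown-variance (t-statistic)
  extension, no non-Gaussian priors, no MCMC ensembles for nonlinear models.
* The criterion is maximized constructively (standardized bases), not by
  numerical search; no constrained convex max-det machinery.
* `random_basis` re-probes already-explored directions whose standardized
  rows grow with accumulated information; very long runs at low noise push
  the Gram matrix toward the limits of double precision (the eigenvalue
  clamp keeps the posterior defined, but the simulated "observations" become
  physically implausible long before that).
* Uncontrollable covariates (a partitioned design matrix) are out of scope;
  the full design matrix is assumed controllable.
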
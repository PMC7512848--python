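# Methods

## Model and estimator

Data are multinomial: `X ~ M_k(n; π)` with `π` in the closed simplex (zero
entries allowed).  A parametric family `P(θ)`, `θ ∈ Θ ⊆ R^s` open, has
strictly positive, twice continuously differentiable cell probabilities
summing to one, with `k − s − 1 > 0`.  For a strictly convex generator φ
with `φ(1) = 0` and a penalty `h > 0`, the penalized divergence between a
possibly sparse `Q` and a positive `P` is

    D_{φ,h}(Q, P) = Σ_{q_i>0} p_i φ(q_i/p_i) + h Σ_{q_i=0} p_i ,

and the estimator minimizes `θ ↦ D_{φ,h}(π̂, P(θ))` over the open box.  The
penalty matters only on empty cells, which are detected by exact equality
(`X_i = 0`), never by a floating tolerance: emptiness is a discrete event.
With no empty cells the estimator is identical for every `h`.

Power-divergence generators `PD_λ` are evaluated through algebraically
rearranged per-cell forms for λ ∈ {−2, −1, 0, 1, 2} (e.g. `(q−p)²/(2q)` for
λ = −2, `q log(q/p) − q + p` for λ = 0) to avoid cancellation near `q = p`
and overflow for tiny `p`; other λ use the generic closed form.  `φ(0)` is
stored as the right limit — `1/(λ+1)` for λ > −1 (λ ≠ 0), `1` at λ = 0,
`+∞` for λ ≤ −1 — which decides when the *unpenalized* divergence is
infinite.  User generators are supplied as three callables plus `φ(1)` and
`φ″(1)`; strict convexity is spot-checked on a log-spaced grid with a
warning (it cannot be proven mechanically).

## Asymptotics under (possible) misspecification

Write the positive cells of π as the first m coordinates, `π⁺` their
vector, `Σ_{π⁺} = Diag(π⁺) − π⁺π⁺ᵗ`.  If the projection
`θ₀ = argmin_θ D_{φ,h}(π, P(θ))` is unique and interior, the minimizer is
an implicit function `g` of `π̂⁺` near `π⁺`, and

    √n (θ̂ − θ₀)  →  N_s(0, G Σ_{π⁺} Gᵗ),     G = D₂⁻¹ D₁ Diag(ϖ),

with, at `x_i = π_i / p_i(θ₀)` and summing over the m positive cells,

    v_i = φ(x_i) − x_i φ′(x_i) − h·1{m<k}
    w_i = π_i² / p_i³ · φ″(x_i)        ϖ_i = π_i / p_i² · φ″(x_i)
    D₁  = [∂p_1/∂θ, …, ∂p_m/∂θ]        (s × m)
    D₂  = Σ_i (∂²p_i/∂θ∂θᵗ) v_i + Σ_i (∂p_i/∂θ)(∂p_i/∂θ)ᵗ w_i .

`D₂` must be positive definite (checked by Cholesky; failure raises an
error naming the identification assumption).  The first-order condition
`Σ_i (∂p_i/∂θ) v_i = 0` is verified at every interior minimizer to 1e-6;
minimizers pinned at the (clamped) domain boundary are constrained optima
where stationarity does not apply, so the check is skipped there — this is
routine when the truth sits near the boundary and a sparse cell is empty.
When the model holds and φ generates the MLE, `G Σ G ᵗ` reduces to the
inverse Fisher information (for the Hardy–Weinberg-type family,
`θ(1−θ)/2`).

For the goodness-of-fit statistic under a fixed alternative, the centered
divergence `√n {D_{φ₁,h₁}(π̂, P(θ̂)) − D_{φ₁,h₁}(π, P(θ₀))}` is
asymptotically `N(0, ϱ²)`.  ϱ² is computed by the delta method on the
explicit composite map `u ↦ D_{φ₁,h₁}(u, P(g(u)))` over the positive
cells: the gradient in cell j is `φ₁′(x_j) + (D₁ v^{(φ₁,h₁)})ᵗ G[:,j]` and
ϱ² sandwiches it around `Σ_{π⁺}`.  This construction is well defined for
any pair of generator/penalty settings; a direct matrix factorization of
the same quantity is dimensionally ambiguous, so the composite-map form is
authoritative here and is validated in the tests against (i) numerical
differentiation of the composite map and (ii) a Monte-Carlo oracle
(20,000 samples of size 10,000, agreement within 10%).  When
`(φ₁,h₁) = (φ₂,h₂)` the second gradient term vanishes by the first-order
condition; when all cells are positive ϱ² does not depend on h at all; at a
model point ϱ² = 0 (the statistic collapses to its chi-square regime).

Plug-in covariances substitute `π̂` for π and `θ̂` for `θ₀` — the standard
sandwich-style plug-in; `m` is then the number of observed nonzero cells.

## Goodness of fit and the bootstrap

`T = 2n/φ₁″(1) · {D_{φ₁,h₁}(π̂, P(θ̂_{φ₂,h₂})) − φ₁(1)}` is asymptotically
`χ²_{k−s−1}` under the null for any generators/penalties.  With
`φ₁ = PD₁, h₁ = 1/2`, T is exactly Pearson's X² at the fitted
probabilities (a zero cell contributes `(0−p)²/(2p) = p/2 = h·p`); with
`φ₁ = PD₀, h₁ = 1` it is the likelihood-ratio G².  The chi-square
approximation degrades badly when a cell probability is tiny, so the
parametric bootstrap is provided: draw B multinomial resamples from
`P(θ̂)`, refit each with `(φ₂,h₂)`, compute `T*` with `(φ₁,h₁)`, and report
`p̂ = #{T* ≥ T_obs}/B` — the weak inequality, no +1 correction, so `p̂` has
resolution 1/B and may be 0.  Resamples whose refit fails are excluded
from the denominator with a warning; more than 10% failures is an error
(with the vectorized one-parameter fitter, refits do not fail).

## Randomness and reproducibility

Every stochastic routine takes a seed.  A root `SeedSequence` spawns one
independent substream per replicate (and, in the bootstrap-within-
simulation design, one per data set and one per its bootstrap), so results
are bit-reproducible, independent of batching, and invariant to execution
order.  Grid cells in `run_table` offset the config seed by cell index so a
sub-grid rerun reproduces its rows.

## Optimization

For s = 1: a 64-point uniform scan of the clamped box `[lo+ε, hi−ε]`
(ε = 1e-10 of the box width) locates every local minimum of the grid
profile; each is refined by bounded Brent to `xatol = 1e-10`; restarts
agreeing within 1e-6 are counted, and distinct minimizers attaining the
same minimal value trigger a non-uniqueness warning (the identification
assumption would fail).  For s > 1: L-BFGS-B from a 4^s multistart grid.
The optimizer is deterministic given its inputs and is tested against an
exhaustive 1e-6-step scan on random count vectors for all built-in models.

Simulation-scale work uses `fit_mpe_batch`: the same 64-point scan
evaluated once per grid point across all replicates, then a vectorized
golden-section contraction (70 iterations, final bracket far below 1e-10)
per replicate.  It agrees with the scalar path to ~1e-7 and makes the
Monte-Carlo studies (millions of fits) run in seconds.

## Simulation designs

The shipped configs mirror the standard study layout: three one-parameter
families — `(1/3−t, 2/3−t, 2t)` at θ = 0.3333 (a deliberately
boundary-sparse regime: the first cell has probability 3.33e-5, so it is
empty in ~99.3% of samples at n = 200), `(0.5−2t, 0.5+t, t)` at θ = 0.24,
and the Hardy–Weinberg-type law at θ = 0.8 — with n ∈ {100, 150, 200},
generators λ₁ ∈ {−2, 1, 2}, estimation by PD₋₂, and penalties
h ∈ {0.5, 1, 2}, equal or crossed.  θ = 0.3333 is treated as the literal
decimal (1/3 itself lies outside the open box).  Asymptotic tables run at
10,000 replicates; bootstrap tables ship both full-scale (10,000 × B=1000)
and default reduced-scale (1,000 × B=200) configs — the reduced scale keeps
a desk run in minutes while its binomial error (~0.007 at α = 0.05) still
resolves calibration.  Rejection uses the weak inequality `p ≤ α`.  RMSD is
`sqrt(mean (θ̂ − θ*)²)` — root of the mean of squares, per the name.

What the generator emulates — and does not.  Samples are exact multinomial
draws from the stated families, so the studies exercise sparsity, boundary
effects and calibration exactly as designed; they do not emulate
overdispersion, dependence between sites, or misclassification structure
beyond the multinomial, so passing tests say nothing about such data.

## Numerical and design choices

* Cells are positional; labels are metadata.  Internal covariance sums run
  over the positive cells in their original order (no physical reordering
  is needed; outputs index cells by `positive_cells`).
* Numeric derivatives (for user models without analytic ones): central
  differences, step `max(1e-6, |θ|·1e-6)` for the jacobian and
  `max(1e-4, |θ|·1e-4)` for Hessians (second differences lose ~eps/h² to
  roundoff), one-sided with a warning within a step of the boundary.
  Models loaded from symbolic expressions get exact derivatives via sympy.
* In the boundary-sparse regime the fitted parameter frequently lies on the
  clamped boundary (an empty cell pulls its fitted probability to zero).
  This is the true constrained minimizer of the penalized objective, and
  the chi-square calibration of T then behaves near-nominally: the
  empty-cell contribution the penalty would charge is optimized away.
  Published tables that instead show near-certain rejection in this regime
  correspond to a fit that stays interior; the difference is analyzed in
  the repository's external notes and the acceptance suite keeps the
  affected comparisons at their stated bands.
* The estimator-accuracy study was cross-checked against an exact
  enumeration of the sample space (the count distribution at n = 200 is
  effectively supported on a small lattice), giving RMSD 0.00081 (h = 0.5)
  and 0.00040 (h = 1); the Monte-Carlo experiment reproduces these.

## Limitations

* Finite k only; families with infinitely many cells are out of scope.
* Confidence intervals are Wald intervals from the plug-in covariance.
* Multi-parameter (s > 1) models are supported by the contract and the
  generic optimizer, but all built-in families and all replicated studies
  are one-parameter; the vectorized batch fitter requires s = 1.
* Power under fixed alternatives is exercised only through the consistency
  of the test, not tabulated.
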
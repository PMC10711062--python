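# Methods

## Model and rotation algebra

The package works in the population common factor model
`Σ = Λ Φ Λ' + Ψ²` with standardized observed variables, so Σ is a
correlation matrix and `Ψ² = I − diag(Λ Φ Λ')`. Both rotation methods
start from an orthogonal loading matrix Λu (from extraction) and a 0/1
target pattern Λ_T describing an independent clusters structure; the
uniform target `I_q ⊗ 1_{p/q}` is built automatically when q divides p,
and any custom binary pattern with at least one salient entry per column
is accepted for unequal block sizes.

**OT (complete oblique target rotation).** The unconstrained least-squares
transform `T = (Λu'Λu)⁻¹ Λu'Λ_T` is column-normalized,
`Tn = T diag(T'T)^{-1/2}`, giving the reference structure `Λ₂ = Λu Tn`,
the pattern `Λo = Λ₂ diag((Tn'Tn)⁻¹)^{1/2}` and the inter-correlations
`Φo = (Λo'Λo)⁻¹ Λo'(ΛuΛu')Λo (Λo'Λo)⁻¹`. This construction preserves the
common part: `Λo Φo Λo' = Λu Λu'` exactly for non-degenerate transforms
(enforced in tests at 1e−6 max-abs).

**OMT (oblique mean-target rotation).** Λu is first rotated toward Λ_T by
orthogonal Procrustes (SVD solution; a degenerate spectrum only makes the
optimum non-unique, any branch is accepted because the final alignment
step canonicalizes the solution). The salient-weighted block means
`Λ₁m = [(Λ₁ ∘ Λ_T)'Λ₁]·[(Λ₁ ∘ Λ_T)'Λ_T]⁻¹` collapse each block to one row:
entry (j, k) is the mean loading of block-j variables on factor k,
weighted by their own salient loadings. The same oblique algebra as above
is then fitted from Λ₁m toward I_q and the resulting Tn is applied to the
*complete* matrix Λ₁. The parenthesization of the block-mean formula is
the only reading that makes Λ₁m a q × q matrix and reproduces the worked
example's fixed-point behaviour; it is locked in by tests.

**Ridge safeguard.** Before inverting a Gram matrix `S'S` its condition
number κ (ratio of extreme singular values) is recorded. When κ exceeds
1e4 — the point where we start treating the inversion as numerically
untrustworthy — the transform is re-fitted over a ridge grid
c ∈ {0, 0.001, …, 0.01, 0.02, …, 0.30} added to the Gram diagonal, and
the candidate solution with the largest mean Tucker congruence between
Λo and Λ_T is retained (ties keep the smallest ridge). With
well-conditioned inputs the grid never runs and the ridge is exactly 0.
The threshold and grid are package defaults; congruence-maximizing ridge
selection trades obliqueness for stability, so more aggressive settings
systematically shrink estimated factor inter-correlations toward zero in
noisy high-q conditions (see "Known limitations").

**Column alignment.** Rotation is indeterminate up to column permutation
and reflection. After every fit the columns are reordered by optimal
assignment to maximize absolute Tucker congruence with the target and
reflected so each factor's salient-weighted mean loading is positive; Φ
rows/columns follow. For simulation scoring, `align_to_population`
repeats the same assignment against the known population pattern.
Φ is symmetrized as (Φ+Φ')/2 with the diagonal forced to exactly 1; the
adjustment is at machine-precision level and is logged.

## Simulation design

`ConditionSpec` encodes one cell of the default grid: q ∈ {3, 6, 9, 12}
factors, p/q ∈ {5, 8} salient variables per factor, mean salient loading
λ ∈ {0.50, 0.70}, zero vs non-zero cross-loadings, factor
inter-correlation φ ∈ {0.00, 0.25, 0.50} (constant off-diagonal Φ) and
n ∈ {100, 150, 200, 300, 500} — 480 cells, all verified free of
population Heywood cases. Salient blocks use fixed ramps with SD ≈ 0.08
(e.g. .40/.45/.50/.55/.60 for p/q = 5 at level 0.50); the non-zero
cross-loading columns are balanced vectors whose largest magnitude is one
third of the mean salient loading with alternating signs and near-zero
mean (e.g. .17/−.08/.06/−.04/.03). The 8-variable cross columns extend
the same decay pattern and are frozen in code for reproducibility. Cross
columns land on the cyclically next factor with every second block's
column sign-flipped; both the placement and the flip schedule are
configurable because other balanced layouts are equally admissible.

Samples are raw multivariate-normal draws, `x = ξΛ' + δ·diag(Ψ)` with
`ξ ~ N(0, Φ)` and `δ ~ N(0, I)`, so true factor scores exist for the
determinacy metric; a Wishart path (`sample_correlation_wishart`) serves
runs that only need correlation matrices. Per-replication seeds derive
deterministically from (base seed, condition index, replication), so any
cell re-runs in isolation and whole studies are bit-reproducible.

**Extraction.** ULS/minres minimizes the sum of squared surplus
eigenvalues of `R − diag(u)` over the uniquenesses u (equivalently the
off-diagonal least-squares criterion at the optimum) by bounded L-BFGS-B
with the analytic gradient `−2 Σ_{k>q} e_k v_ik²`, SMC start values, and
communalities capped at 0.998 as a Heywood guard. Principal axis
factoring iterates the reduced eigendecomposition from SMC starts until
the largest communality change is below 1e−6 (200-iteration cap,
non-convergence flagged, never imputed). Returned columns are ordered by
explained variance and sign-oriented; downstream alignment makes this
immaterial.

## Metrics

* **phi bias / phi mean** — mean of the upper off-diagonal of the aligned
  Φ̂ (minus the population φ for the bias).
* **RMS loading error** — root mean square over all p·q cells of the
  aligned pattern minus the population pattern. The subsample-stability
  variant truncates values above 1 so a few divergent solutions cannot
  dominate the mean, and scores Φ on off-diagonals only (the diagonal is
  fixed at 1 and uninformative).
* **Factor score indeterminacy** — regression weights `W = R⁻¹ Λo Φo`
  applied to the standardized sample; per factor the agreement between
  predictor and true factor score. Two conventions are implemented. The
  default is the Pearson correlation, whose large-n limit at the true
  parameters is the classical determinacy
  `ρ = sqrt(diag(Φ Λ'Σ⁻¹Λ Φ))` (verified at n = 100,000). The study
  summaries and the acceptance analysis instead report the cross-moment
  of the predictor *in its natural regression metric* (model-implied
  variance ρ², not re-standardized) with the unit-variance factor —
  i.e. correlation × predictor SD. The natural metric penalizes unstable
  weight estimates twice, through both the direction and the length of
  the weight vector, which is the appropriate scale when scoring
  coefficients are applied as computed; it is also the scale on which the
  two rotation methods are compared here.
* **Subsample stability** — every subsample's rotated solution is aligned
  to the total-sample solution (the reference for this design), then the
  truncated RMS statistics above are summarized across subsamples;
  non-converged subsamples are skipped and counted.

## Problem sizes in the acceptance analysis

`scripts/acceptance.py` re-derives every reported quantity at runtime:
the 18 × 3 worked example (deterministic); the indeterminacy study with
200 replications in each of the four cells (n = 100, p/q = 5, φ = 0.25,
λ = 0.50, q ∈ {6, 9} × zero/non-zero cross-loadings); and 100
replications of the hardest cell (q = 12, p/q = 5, λ = 0.50, φ = 0.50,
n = 100). The test suite additionally sweeps all 240 zero-cross-loading
cells at 20 replications for the design-wide bias means. These
replication counts are the package's chosen trade-off between Monte-Carlo
error (≈ 0.005–0.01 SE on the reported means) and turnaround; all runs
are seed-reproducible.

## What the synthetic data do and do not show

The generator emulates exactly the idealized regime the rotation methods
are designed for: multivariate-normal continuous indicators, a loading
pattern that is blockwise simple with at most one balanced cross-loading
column per block, constant factor inter-correlations, and a correctly
specified number of factors. Real data violate most of these —
ordinal/skewed items, heterogeneous Φ, model error from minor factors,
uncertain q. Passing tests therefore certify the algebra and the
comparative behaviour of OT vs OMT under sampling error, not performance
under model misspecification.

## Known limitations

* The ridge loop's threshold and grid are free design parameters. Under
  the defaults the safeguard is dormant in almost all default-design
  cells; settings that engage it aggressively reproduce a stronger
  shrinkage of OMT inter-correlations in noisy conditions (with q = 9,
  n = 100 the natural-metric score recovery moves from ≈ 0.65 to ≈ 0.58
  while the q = 12 mean inter-correlation collapses from ≈ 0.4 to ≈ 0).
  Because no single setting is best everywhere, the defaults favour
  numerical-rescue-only behaviour and both knobs are exposed.
* Extended target rotation with a specified Φ target, partial target
  rotation via gradient projection, and analytic rotations (geomin,
  oblimin) are out of scope; a dense grid-search minimizer exists only as
  a test oracle.
* Bootstrap or analytic standard errors of rotated loadings are not
  provided.
* Factor-number selection is not addressed: the true q is always
  supplied.
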
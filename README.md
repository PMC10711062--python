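# meantarget

Oblique **mean**-target rotation (OMT) and conventional complete oblique
target rotation (OT) for exploratory factor analysis, together with the
Monte-Carlo machinery needed to evaluate how well each method recovers a
known oblique simple structure from small samples.

## The problem

In exploratory factor analysis of a correlation matrix **R** the common
factor model is

```
x = Λ ξ + δ,        Σ = Λ Φ Λ' + Ψ² = Λu Λu' + Ψ²
```

with loadings Λ (p × q), factor inter-correlations Φ (unit diagonal) and
unique variances Ψ². Extraction yields an *orthogonal* loading matrix Λu
that must be rotated before interpretation. When the expected structure is
an independent clusters model (ICM) — each variable salient on exactly one
factor — oblique *target* rotation toward the 0/1 pattern
Λ_T = I_q ⊗ 1_{p/q} is the standard tool. Complete target rotation (OT)
fits the least-squares transform

```
T = (Λu'Λu)⁻¹ Λu'Λ_T ,   Tn = T diag(T'T)^{-1/2}
Λ₂ = Λu Tn ,   Λo = Λ₂ diag((Tn'Tn)⁻¹)^{1/2}
Φo = (Λo'Λo)⁻¹ Λo' (ΛuΛu') Λo (Λo'Λo)⁻¹
```

directly to the *single* loadings, so sampling error in individual
cross-loadings propagates into the rotated pattern and — especially with
many factors and small n — biases the factor inter-correlations toward
zero.

**Mean-target rotation (OMT)** instead (i) orthogonally Procrustes-rotates
Λu toward Λ_T, (ii) collapses the rotated loadings into a q × q matrix of
*salient-weighted block means*

```
Λ₁m = [(Λ₁ ∘ Λ_T)' Λ₁] · [(Λ₁ ∘ Λ_T)' Λ_T]⁻¹      (∘ = Hadamard product)
```

(iii) fits the oblique transform from Λ₁m toward I_q (with a ridge
safeguard when Λ₁m'Λ₁m is ill-conditioned), and (iv) applies the resulting
normalized transform to the complete loading matrix. Because block means
average out sampling error in single cross-loadings, OMT is markedly more
robust for small samples and large factor numbers, and it leaves patterns
whose block-mean cross-loadings are already zero untouched.

The package is aimed at psychometricians and methodologists who want to
use OMT/OT on their own loading matrices, or to re-run the supporting
simulation evidence: population ICM and zero-mean cross-loading (ZCLM)
models, multivariate-normal sampling with known true factor scores,
least-squares (minres) and principal-axis extraction, and the recovery
metrics (inter-correlation bias, RMS loading error, factor score
indeterminacy, subsample stability).

## Worked example

The package's canonical example is an 18-variable, 3-factor orthogonal
pattern with salient loadings 0.50 and perfectly balanced ±0.20
cross-loadings (so every salient-weighted mean cross-loading is exactly
zero):

```python
from meantarget import TargetRotation
from meantarget.fixtures import balanced_example_initial

lam = balanced_example_initial()
print(TargetRotation(lam, method="ot").fit().summary())
```

```
OT-rotated factor solution
  variables: 18   factors: 3
  kappa: 1.48   ridge: 0.0
  mean Tucker congruence with target: 0.8853

Rotated pattern:
        F1     F2     F3
x1   0.525  0.253 -0.109
x2   0.525 -0.109  0.253
...
x18 -0.109  0.253  0.525

Factor inter-correlations:
    F1   1.000  -0.221  -0.221
    F2  -0.221   1.000  -0.221
    F3  -0.221  -0.221   1.000
```

OT inflates each salient loading to 0.52, turns the balanced ±0.20
cross-loadings into an asymmetric 0.25/−0.11 pair and buys this apparent
simplification with spurious factor inter-correlations of −0.22. The same
call with `method="omt"` returns the input pattern unchanged with Φ = I:
when the block-mean cross-loadings are already zero there is nothing left
for a mean-target rotation to do, which is exactly the intended behaviour.

The command-line interface wraps the same objects:

```bash
meantarget rotate --input loadings.csv --method omt --out results/omt
meantarget simulate --grid grid.yaml --reps 100 --seed 42 --out results/
```

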
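"""Dependent variables of the Monte-Carlo evaluation.

The recovery of a rotated solution is scored against the population model
by (i) the bias of the factor inter-correlations, (ii) the root mean
square difference of the loading pattern from the population pattern, and
(iii) factor score indeterminacy — the correlation of the regression
factor-score predictor with the true factor scores.  A subsample-stability
statistic compares rotated subsample solutions with the total-sample
solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .loadings import LoadingMatrix
from .rotation import RotationResults
from .sampling import SyntheticSample, align_to_population

__all__ = [
    "phi_bias",
    "phi_mean",
    "rms_difference",
    "factor_score_indeterminacy",
    "population_determinacy",
    "StabilityResult",
    "subsample_stability",
]


def _offdiag(phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    q = phi.shape[0]
    iu = np.triu_indices(q, k=1)
    return phi[iu]


def phi_mean(phi_hat: np.ndarray) -> float:
    """Mean of the q(q-1)/2 upper off-diagonal factor inter-correlations."""
    off = _offdiag(phi_hat)
    if off.size == 0:
        raise ValueError("phi_mean undefined for q < 2")
    return float(off.mean())


def phi_bias(phi_hat: np.ndarray, phi_pop: float) -> float:
    """Mean deviation of estimated inter-correlations from the population value."""
    return phi_mean(phi_hat) - float(phi_pop)


def rms_difference(
    a, b, truncate_at_one: bool = False
) -> float:
    """Root mean square element-wise difference between two aligned matrices.

    With ``truncate_at_one`` a raw RMS above 1 is reported as 1 — the
    convention used for subsample-stability summaries, where a few wildly
    divergent solutions would otherwise dominate the mean.
    """
    av = np.asarray(a.values if isinstance(a, LoadingMatrix) else a, dtype=float)
    bv = np.asarray(b.values if isinstance(b, LoadingMatrix) else b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    rms = float(np.sqrt(np.mean((av - bv) ** 2)))
    if truncate_at_one and rms > 1.0:
        return 1.0
    return rms


def factor_score_indeterminacy(
    sample: SyntheticSample,
    rotated: RotationResults | tuple[np.ndarray, np.ndarray],
    standardize_scores: bool = True,
) -> np.ndarray:
    """Agreement of regression factor-score predictors with the true factors.

    Regression weights are ``W = R^-1 Lo Phi`` from the sample correlation
    matrix and the rotated pattern/inter-correlations; predictor scores are
    the standardized observed scores times W.  Returns one value per factor;
    the rotated solution must already be aligned to the population.

    With ``standardize_scores=True`` (default) the value is the Pearson
    correlation of predictor and true factor.  With ``False`` the predictor
    is left in its natural regression metric (its model-implied variance is
    the squared determinacy, below 1) and the value is its cross-moment
    with the standardized true factor, i.e. correlation times predictor SD.
    The natural metric penalizes unstable weight estimates twice — once
    through the angle of the weight vector and once through its length —
    and is the convention used in the simulation summaries.
    """
    if isinstance(rotated, RotationResults):
        pattern, phi = rotated.pattern.values, rotated.phi
    else:
        pattern, phi = rotated
    r = sample.corr
    structure = np.asarray(pattern, dtype=float) @ np.asarray(phi, dtype=float)
    try:
        w = np.linalg.solve(r, structure)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular sample correlation matrix; ridge-regularizing",
                      stacklevel=2)
        w = np.linalg.solve(r + 1e-8 * np.eye(r.shape[0]), structure)
    x = sample.data
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    scores = z @ w
    out = np.empty(scores.shape[1])
    for j in range(scores.shape[1]):
        xi = sample.factor_scores[:, j]
        sd_xi = xi.std(ddof=1)
        sd_s = scores[:, j].std(ddof=1)
        if sd_xi == 0 or sd_s == 0:
            out[j] = 0.0
            continue
        cov = np.cov(scores[:, j], xi, ddof=1)[0, 1]
        out[j] = cov / (sd_s * sd_xi) if standardize_scores else cov / sd_xi
    return out


def population_determinacy(
    loadings: np.ndarray, phi: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Closed-form determinacy ``sqrt(diag(Phi Lambda' Sigma^-1 Lambda Phi))``.

    The population correlation between the regression factor-score
    predictor and the factor itself; the large-n limit of
    :func:`factor_score_indeterminacy` at the true parameters.
    """
    lam = np.asarray(
        loadings.values if isinstance(loadings, LoadingMatrix) else loadings, float
    )
    structure = lam @ np.asarray(phi, float)
    return np.sqrt(np.diag(structure.T @ np.linalg.solve(sigma, structure)))


@dataclass(frozen=True)
class StabilityResult:
    """Subsample-stability RMS statistics relative to a total-sample solution."""

    rms_loadings: np.ndarray  # one value per converged subsample
    rms_phi: np.ndarray
    n_used: int
    n_skipped: int

    @property
    def mean_rms_loadings(self) -> float:
        return float(self.rms_loadings.mean())

    @property
    def sd_rms_loadings(self) -> float:
        return float(self.rms_loadings.std(ddof=1)) if self.rms_loadings.size > 1 else 0.0

    @property
    def mean_rms_phi(self) -> float:
        return float(self.rms_phi.mean())

    @property
    def sd_rms_phi(self) -> float:
        return float(self.rms_phi.std(ddof=1)) if self.rms_phi.size > 1 else 0.0


def subsample_stability(
    total_pattern,
    total_phi: np.ndarray,
    sub_patterns: Sequence,
    sub_phis: Sequence[Optional[np.ndarray]],
    truncate_at_one: bool = True,
) -> StabilityResult:
    """Stability of rotated subsample solutions against the total sample.

    Every subsample pattern is aligned (permutation + signs) to the
    total-sample pattern, then the RMS difference of the loading patterns
    and of the Phi off-diagonals is computed per subsample, truncating
    values above 1.  ``None`` entries mark non-converged subsample
    solutions; they are skipped and counted.
    """
    total = np.asarray(
        total_pattern.values if isinstance(total_pattern, LoadingMatrix) else total_pattern,
        dtype=float,
    )
    total_phi = np.asarray(total_phi, dtype=float)
    rms_l, rms_p = [], []
    skipped = 0
    for pat, phi in zip(sub_patterns, sub_phis):
        if pat is None or phi is None:
            skipped += 1
            continue
        pat = np.asarray(pat.values if isinstance(pat, LoadingMatrix) else pat, float)
        aligned, phi_a, _, _ = align_to_population(pat, np.asarray(phi, float), total)
        rms_l.append(rms_difference(aligned, total, truncate_at_one=truncate_at_one))
        off = rms_difference(_offdiag(phi_a), _offdiag(total_phi))
        rms_p.append(min(off, 1.0) if truncate_at_one else off)
    return StabilityResult(
        rms_loadings=np.asarray(rms_l),
        rms_phi=np.asarray(rms_p),
        n_used=len(rms_l),
        n_skipped=skipped,
    )
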
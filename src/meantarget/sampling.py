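"""Sample generation and least-squares factor extraction.

Samples are drawn as raw multivariate-normal data from a population model,
``x = xi Lambda' + delta diag(Psi)``, so the true common-factor scores
``xi`` exist alongside the observed scores — a requirement for the factor
score indeterminacy metric.  A Wishart fast path is available when only
the sample correlation matrix is needed.

Unrotated loadings are extracted from the sample correlation matrix by
unweighted least squares (minres) or by iterated principal axis factoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize

from .loadings import LoadingMatrix
from .population import PopulationModel
from .rotation import _congruence_matrix

__all__ = [
    "SyntheticSample",
    "ExtractionResult",
    "LeastSquaresFactor",
    "simulate_sample",
    "sample_correlation_wishart",
    "extract_uls",
    "extract_paf",
    "align_to_population",
    "HEYWOOD_CAP",
]

SeedLike = Union[int, Sequence[int], np.random.Generator]

#: Communalities are capped here to guard against Heywood cases.
HEYWOOD_CAP = 0.998


@dataclass(frozen=True)
class SyntheticSample:
    """One simulated sample with its known true factor scores."""

    data: np.ndarray  # n x p observed scores
    factor_scores: np.ndarray  # n x q true common-factor scores
    unique_scores: np.ndarray  # n x p unique-factor scores
    corr: np.ndarray  # p x p sample correlation matrix
    seed: object  # seed the sample was drawn with

    @property
    def n(self) -> int:
        return self.data.shape[0]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_sample(
    model: PopulationModel, n: int, seed: SeedLike
) -> SyntheticSample:
    """Draw an n-case multivariate-normal sample from a population model.

    Common-factor scores are drawn as ``xi ~ N(0, Phi)`` and unique scores
    as ``delta ~ N(0, I)``; observed scores are
    ``x = xi Lambda' + delta diag(sqrt(Psi^2))`` so their population
    covariance equals the model-implied Sigma.
    """
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    p, q = model.p, model.q
    if n < p:
        import warnings

        warnings.warn(
            f"n={n} < p={p}: the sample correlation matrix is singular",
            stacklevel=2,
        )
    rng = _rng(seed)
    chol = np.linalg.cholesky(model.phi_matrix)
    xi = rng.standard_normal((n, q)) @ chol.T
    delta = rng.standard_normal((n, p))
    x = xi @ model.loadings.values.T + delta * np.sqrt(model.uniqueness)
    corr = np.corrcoef(x, rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return SyntheticSample(
        data=x, factor_scores=xi, unique_scores=delta, corr=corr, seed=seed
    )


def sample_correlation_wishart(
    model: PopulationModel, n: int, seed: SeedLike
) -> np.ndarray:
    """Sample correlation matrix via a Wishart draw (no individual scores).

    Faster than raw-data generation when only bias/RMS metrics are needed.
    """
    from scipy.stats import wishart

    rng = _rng(seed)
    cov = wishart.rvs(df=n - 1, scale=model.sigma, random_state=rng) / (n - 1)
    d = 1.0 / np.sqrt(np.diag(cov))
    corr = cov * np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass(frozen=True)
class ExtractionResult:
    """Unrotated loadings extracted from a correlation matrix."""

    loadings_u: LoadingMatrix
    communalities: np.ndarray
    converged: bool
    iterations: int
    method: str  # "ULS" | "PAF"


def _smc(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (classic communality start values)."""
    try:
        rinv = np.linalg.inv(r)
        smc = 1.0 - 1.0 / np.diag(rinv)
    except np.linalg.LinAlgError:
        smc = np.full(r.shape[0], 0.5)
    return np.clip(smc, 0.0, HEYWOOD_CAP)


def _loadings_from_reduced(
    reduced: np.ndarray, q: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-q eigenpairs of a reduced correlation matrix -> loadings."""
    vals, vecs = np.linalg.eigh(reduced)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    lam = vecs[:, :q] * np.sqrt(np.clip(vals[:q], 0.0, None))
    return lam, vals, vecs

def _order_columns(lam: np.ndarray) -> np.ndarray:
    """Order columns by decreasing sum of squares; orient sums positive."""
    ss = (lam * lam).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    lam = lam[:, order]
    signs = np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
    return lam * signs


def _check_corr(r: np.ndarray, q: int) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    if r.ndim != 2 or r.shape[1] != p:
        raise ValueError("correlation matrix must be square")
    if np.abs(r - r.T).max() > 1e-8 or np.abs(np.diag(r) - 1.0).max() > 1e-8:
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    if not 1 <= q < p:
        raise ValueError(f"need 1 <= q < p, got q={q}, p={p}")
    return (r + r.T) / 2.0


def extract_uls(
    r: np.ndarray, q: int, max_iter: int = 500, tol: float = 1e-8
) -> ExtractionResult:
    """Unweighted least-squares (minres) factor extraction.

    Minimizes the sum of squared residuals of the reduced correlation
    matrix after its best rank-q approximation — equivalently the sum of
    squared surplus eigenvalues of ``R - diag(u)`` over the uniquenesses
    ``u`` — by L-BFGS-B with the analytic gradient
    ``d/du_i = -2 sum_{k>q} e_k v_ik^2``.  Loadings come from the top-q
    eigenpairs at the optimum; communalities are capped at 0.998.
    """
    r = _check_corr(r, q)
    p = r.shape[0]

    def objective(u: np.ndarray) -> tuple[float, np.ndarray]:
        vals, vecs = np.linalg.eigh(r - np.diag(u))
        tail_vals = vals[: p - q]  # ascending: all but the q largest
        tail_vecs = vecs[:, : p - q]
        f = float(tail_vals @ tail_vals)
        g = -2.0 * (tail_vecs * tail_vecs) @ tail_vals
        return f, g

    u0 = 1.0 - _smc(r)
    bounds = [(1.0 - HEYWOOD_CAP, 1.0)] * p
    res = minimize(
        objective,
        np.clip(u0, 1.0 - HEYWOOD_CAP, 1.0),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": tol},
    )
    lam, _, _ = _loadings_from_reduced(r - np.diag(res.x), q)
    lam = _order_columns(lam)
    comm = np.clip((lam * lam).sum(axis=1), 0.0, HEYWOOD_CAP)
    return ExtractionResult(
        loadings_u=LoadingMatrix(lam),
        communalities=comm,
        converged=bool(res.success),
        iterations=int(res.nit),
        method="ULS",
    )


def extract_paf(
    r: np.ndarray, q: int, max_iter: int = 200, tol: float = 1e-6
) -> ExtractionResult:
    """Iterated principal axis factoring with SMC start values.

    The diagonal of R is replaced by current communalities, the top-q
    eigenpairs give updated loadings, and the loop runs until the largest
    communality change falls below ``tol`` (or ``max_iter``, flagged as
    non-converged).
    """
    r = _check_corr(r, q)
    h = _smc(r)
    converged = False
    iterations = max_iter
    reduced = r.copy()
    lam = np.zeros((r.shape[0], q))
    for it in range(1, max_iter + 1):
        np.fill_diagonal(reduced, h)
        lam, _, _ = _loadings_from_reduced(reduced, q)
        h_new = np.clip((lam * lam).sum(axis=1), 0.0, HEYWOOD_CAP)
        delta = np.abs(h_new - h).max()
        h = h_new
        if delta < tol:
            converged = True
            iterations = it
            break
    lam = _order_columns(lam)
    return ExtractionResult(
        loadings_u=LoadingMatrix(lam),
        communalities=h,
        converged=converged,
        iterations=iterations,
        method="PAF",
    )


class LeastSquaresFactor:
    """Model-style entry point for least-squares factor extraction.

    Parameters
    ----------
    corr : p x p sample correlation matrix
    n_factors : number of common factors to extract
    method : {"uls", "paf"}
    """

    def __init__(self, corr: np.ndarray, n_factors: int, method: str = "uls"):
        method = method.lower()
        if method not in ("uls", "paf"):
            raise ValueError(f"method must be 'uls' or 'paf', got {method!r}")
        self.corr = _check_corr(np.asarray(corr, dtype=float), n_factors)
        self.n_factors = n_factors
        self.method = method

    def fit(self, **kwargs) -> ExtractionResult:
        extract = extract_uls if self.method == "uls" else extract_paf
        return extract(self.corr, self.n_factors, **kwargs)


def align_to_population(
    pattern: np.ndarray,
    phi: np.ndarray,
    pop_loadings: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve column permutation and sign against a reference pattern.

    Chooses the permutation maximizing the sum of absolute Tucker
    congruences with the reference columns (optimal assignment) and flips
    each matched column so its congruence is positive; Phi rows and columns
    follow.  Returns ``(pattern, phi, permutation, signs)`` where
    ``permutation[k]`` is the original column placed at position k.
    """
    pattern = np.asarray(pattern, dtype=float)
    phi = np.asarray(phi, dtype=float)
    ref = np.asarray(
        pop_loadings.values if isinstance(pop_loadings, LoadingMatrix) else pop_loadings,
        dtype=float,
    )
    if pattern.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pattern.shape} vs {ref.shape}")
    c = _congruence_matrix(pattern, ref)
    rows, cols = linear_sum_assignment(-np.abs(c))
    perm = np.empty_like(rows)
    perm[cols] = rows
    aligned = pattern[:, perm]
    signs = np.where(c[perm, np.arange(len(perm))] < 0, -1.0, 1.0)
    aligned = aligned * signs
    phi_aligned = phi[np.ix_(perm, perm)] * np.outer(signs, signs)
    np.fill_diagonal(phi_aligned, 1.0)
    return aligned, phi_aligned, perm, signs
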
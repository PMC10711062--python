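"""Population factor models for the Monte-Carlo design.

Two families of population structures are built on contiguous salient
blocks:

* **ICM** (independent clusters model): every variable loads on exactly one
  factor, all cross-loadings are zero.
* **ZCLM** (zero-mean cross-loading model): each block additionally carries
  a balanced column of non-zero cross-loadings on one other factor whose
  (near) zero mean keeps the oblique simple structure well defined.

The default condition grid crosses q in {3, 6, 9, 12} factors, p/q in
{5, 8} salient loadings per factor, mean salient loading in {0.50, 0.70},
zero vs non-zero cross-loadings, factor inter-correlation phi in
{0.00, 0.25, 0.50} and sample size n in {100, 150, 200, 300, 500} — 480
cells in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .loadings import LoadingMatrix

__all__ = [
    "ConditionSpec",
    "PopulationModel",
    "salient_vector",
    "cross_vector",
    "build_population",
    "default_grid_conditions",
    "DEFAULT_LEVELS",
]

#: The default simulation design levels.
DEFAULT_LEVELS = {
    "q": (3, 6, 9, 12),
    "p_per_q": (5, 8),
    "loading_level": (0.50, 0.70),
    "cross_loadings": ("zero", "nonzero"),
    "phi": (0.00, 0.25, 0.50),
    "n": (100, 150, 200, 300, 500),
}

# Salient-loading ramps per block; both have SD ~ 0.08 about the mean level.
_SALIENT = {
    (5, 0.50): (0.40, 0.45, 0.50, 0.55, 0.60),
    (5, 0.70): (0.60, 0.65, 0.70, 0.75, 0.80),
    (8, 0.50): (0.38, 0.42, 0.45, 0.48, 0.52, 0.55, 0.58, 0.62),
    (8, 0.70): (0.58, 0.62, 0.65, 0.68, 0.72, 0.75, 0.78, 0.82),
}

# Balanced cross-loading columns: max |entry| = level/3, alternating signs,
# decaying magnitudes, near-zero mean.  The 5-variable columns are the
# canonical ones; the 8-variable columns extend the same decay pattern and
# are frozen here for reproducibility.
_CROSS = {
    (5, 0.50): (0.17, -0.08, 0.06, -0.04, 0.03),
    (5, 0.70): (0.23, -0.12, 0.08, -0.06, 0.05),
    (8, 0.50): (0.17, -0.09, 0.07, -0.05, 0.04, -0.03, 0.02, -0.02),
    (8, 0.70): (0.23, -0.12, 0.09, -0.07, 0.05, -0.04, 0.03, -0.02),
}


def salient_vector(
    p_per_q: int, level: float, extended: bool = False
) -> np.ndarray:
    """The block's salient-loading ramp for a design cell.

    Outside the default levels (and with ``extended=True``) an arithmetic
    ramp with the requested mean and an SD of ~0.08 is generated.
    """
    key = (p_per_q, round(float(level), 2))
    if key in _SALIENT:
        return np.array(_SALIENT[key])
    if not extended:
        raise ValueError(
            f"(p_per_q={p_per_q}, level={level}) is outside the default "
            "design; pass extended=True for an arithmetic ramp"
        )
    offsets = np.linspace(-1.0, 1.0, p_per_q)
    sd = offsets.std() or 1.0
    return level + offsets * (0.08 / sd)


def cross_vector(p_per_q: int, level: float) -> np.ndarray:
    """The block's balanced non-zero cross-loading column.

    Largest absolute entry is one third of the mean salient loading
    (rounded to two decimals); signs alternate and magnitudes decay so the
    column mean is close to zero.
    """
    key = (p_per_q, round(float(level), 2))
    if key not in _CROSS:
        raise ValueError(
            f"no cross-loading column for (p_per_q={p_per_q}, level={level}); "
            f"defined cells: {sorted(_CROSS)}"
        )
    return np.array(_CROSS[key])


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design."""

    q: int
    p_per_q: int
    loading_level: float
    cross_loadings: str  # "zero" | "nonzero"
    phi: float
    n: int
    extended: bool = False

    def __post_init__(self) -> None:
        if self.cross_loadings not in ("zero", "nonzero"):
            raise ValueError("cross_loadings must be 'zero' or 'nonzero'")
        if self.extended:
            return
        for name in ("q", "p_per_q", "loading_level", "phi", "n"):
            value = getattr(self, name)
            if value not in DEFAULT_LEVELS[name]:
                raise ValueError(
                    f"{name}={value} is outside the default design levels "
                    f"{DEFAULT_LEVELS[name]}; set extended=True to allow it"
                )

    @property
    def p(self) -> int:
        return self.q * self.p_per_q

    def label(self) -> str:
        return (
            f"q{self.q}_ppq{self.p_per_q}_l{self.loading_level:g}_"
            f"cl-{self.cross_loadings}_phi{self.phi:g}_n{self.n}"
        )


@dataclass(frozen=True)
class PopulationModel:
    """Population loadings, factor correlations, uniquenesses and Sigma."""

    loadings: LoadingMatrix  # p x q pattern (Lambda)
    phi_matrix: np.ndarray  # q x q, constant off-diagonal
    uniqueness: np.ndarray  # p positive unique variances (Psi^2 diagonal)
    sigma: np.ndarray  # p x p model-implied correlation matrix
    condition: Optional[ConditionSpec] = None

    def __post_init__(self) -> None:
        if np.any(self.uniqueness <= 0):
            raise ValueError("unique variances must be strictly positive")
        if np.abs(np.diag(self.sigma) - 1.0).max() > 1e-12:
            raise ValueError("Sigma diagonal must be 1")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-10:
            raise ValueError("Sigma must be positive semi-definite")

    @property
    def p(self) -> int:
        return self.loadings.p

    @property
    def q(self) -> int:
        return self.loadings.q


def build_population(
    cond: ConditionSpec, flip_schedule: Optional[Sequence[int]] = None
) -> PopulationModel:
    """Construct the population model for one design cell.

    The loading pattern has contiguous salient blocks.  With non-zero
    cross-loadings, block j places the balanced cross column on the
    cyclically next factor; every second block's cross column is multiplied
    by -1 (overridable via ``flip_schedule``, one +-1 per block) so positive
    and negative columns balance across the pattern.  Phi has constant
    off-diagonal ``cond.phi``; unique variances complete unit diagonals:
    ``Psi^2 = I - diag(Lambda Phi Lambda')`` and
    ``Sigma = Lambda Phi Lambda' + Psi^2``.
    """
    q, ppq = cond.q, cond.p_per_q
    p = q * ppq
    sal = salient_vector(ppq, cond.loading_level, extended=cond.extended)
    lam = np.zeros((p, q))
    for j in range(q):
        lam[j * ppq : (j + 1) * ppq, j] = sal
    if cond.cross_loadings == "nonzero":
        cl = cross_vector(ppq, cond.loading_level)
        if flip_schedule is None:
            flips = [1 if j % 2 == 0 else -1 for j in range(q)]
        else:
            flips = list(flip_schedule)
            if len(flips) != q or any(f not in (-1, 1) for f in flips):
                raise ValueError("flip_schedule needs one +-1 entry per block")
        for j in range(q):
            lam[j * ppq : (j + 1) * ppq, (j + 1) % q] = flips[j] * cl
    phi = (1.0 - cond.phi) * np.eye(q) + cond.phi * np.ones((q, q))
    common_diag = np.einsum("ij,jk,ik->i", lam, phi, lam)
    psi2 = 1.0 - common_diag
    heywood = np.flatnonzero(psi2 <= 0)
    if heywood.size:
        raise ValueError(
            f"population Heywood case: communality >= 1 for variable(s) "
            f"{heywood.tolist()} in condition {cond.label()}"
        )
    sigma = lam @ phi @ lam.T + np.diag(psi2)
    var_labels = tuple(f"x{i + 1}" for i in range(p))
    factor_labels = tuple(f"F{j + 1}" for j in range(q))
    return PopulationModel(
        loadings=LoadingMatrix(lam, var_labels, factor_labels),
        phi_matrix=phi,
        uniqueness=psi2,
        sigma=sigma,
        condition=cond,
    )


def default_grid_conditions() -> list[ConditionSpec]:
    """All 480 cells of the default design, in a fixed deterministic order."""
    cells = []
    for q, ppq, level, cl, phi, n in itertools.product(
        DEFAULT_LEVELS["q"],
        DEFAULT_LEVELS["p_per_q"],
        DEFAULT_LEVELS["loading_level"],
        DEFAULT_LEVELS["cross_loadings"],
        DEFAULT_LEVELS["phi"],
        DEFAULT_LEVELS["n"],
    ):
        cells.append(
            ConditionSpec(
                q=q, p_per_q=ppq, loading_level=level,
                cross_loadings=cl, phi=phi, n=n,
            )
        )
    return cells
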
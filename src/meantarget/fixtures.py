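"""Reference matrices for the worked population examples.

These small matrices are the canonical test inputs of the package: an
18-variable, 3-factor orthogonal loading pattern whose block-wise
salient-weighted mean cross-loadings are exactly zero (so mean-target
rotation leaves it untouched while conventional target rotation does not),
the corresponding expected rotated solutions, and a 9-variable population
pattern with one positive cross-loading block pair.  All values are exact
two-decimal numbers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .loadings import LoadingMatrix, write_loadings
from .population import cross_vector, salient_vector

__all__ = [
    "balanced_example_initial",
    "balanced_example_ot_pattern",
    "balanced_example_ot_phi",
    "balanced_example_omt_pattern",
    "balanced_example_omt_phi",
    "crossloaded_population",
    "FixtureSet",
    "make_fixtures",
]


def _labels(p: int, q: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    return (
        tuple(f"x{i + 1}" for i in range(p)),
        tuple(f"F{j + 1}" for j in range(q)),
    )


def balanced_example_initial() -> LoadingMatrix:
    """18 x 3 orthogonal pattern: salient 0.50 blocks, balanced +-0.20 crosses.

    Within each block of six variables the cross-loadings alternate in sign
    (three +0.20, three -0.20 per off factor), so every salient-weighted
    mean cross-loading is exactly zero.
    """
    rows = np.zeros((18, 3))
    for b in range(3):
        others = [k for k in range(3) if k != b]
        for i in range(6):
            r = b * 6 + i
            rows[r, b] = 0.50
            sign = 1.0 if i % 2 == 0 else -1.0
            rows[r, others[0]] = 0.20 * sign
            rows[r, others[1]] = -0.20 * sign
    return LoadingMatrix(rows, *_labels(18, 3))


def balanced_example_ot_pattern() -> LoadingMatrix:
    """Expected complete-target (OT) rotated pattern of the balanced example.

    Salient loadings become 0.52 and each +-0.20 cross-loading pair becomes
    (0.25, -0.11): the rotation minimizes the negative single cross-loadings
    at the price of negative factor inter-correlations.
    """
    rows = np.zeros((18, 3))
    for b in range(3):
        others = [k for k in range(3) if k != b]
        for i in range(6):
            r = b * 6 + i
            rows[r, b] = 0.52
            sign = 1.0 if i % 2 == 0 else -1.0
            rows[r, others[0]] = 0.25 if sign > 0 else -0.11
            rows[r, others[1]] = -0.11 if sign > 0 else 0.25
    return LoadingMatrix(rows, *_labels(18, 3))


def balanced_example_ot_phi() -> np.ndarray:
    """Expected OT factor inter-correlations: all off-diagonals -0.22."""
    phi = np.full((3, 3), -0.22)
    np.fill_diagonal(phi, 1.0)
    return phi


def balanced_example_omt_pattern() -> LoadingMatrix:
    """Expected OMT pattern: identical to the initial orthogonal loadings."""
    return balanced_example_initial()


def balanced_example_omt_phi() -> np.ndarray:
    """Expected OMT factor inter-correlations: the identity."""
    return np.eye(3)


def crossloaded_population() -> LoadingMatrix:
    """9 x 3 orthogonal population pattern with one shared cross-loading pair.

    Blocks one and two (0.48 salient) carry 0.13 cross-loadings on each
    other's factor; the third block (0.50 salient) is clean.  Obliquely
    rotated, the shared positive cross-loadings translate into a positive
    inter-correlation of the first two factors.
    """
    rows = np.array(
        [
            [0.48, 0.13, 0.00],
            [0.48, 0.13, 0.00],
            [0.48, 0.13, 0.00],
            [0.13, 0.48, 0.00],
            [0.13, 0.48, 0.00],
            [0.13, 0.48, 0.00],
            [0.00, 0.00, 0.50],
            [0.00, 0.00, 0.50],
            [0.00, 0.00, 0.50],
        ]
    )
    return LoadingMatrix(rows, *_labels(9, 3))


@dataclass(frozen=True)
class FixtureSet:
    """Paths of the fixture files written by :func:`make_fixtures`."""

    initial: str
    ot_expected: str
    omt_expected: str
    crossloaded: str
    design_vectors: str


def make_fixtures(out_dir: str) -> FixtureSet:
    """Write every reference matrix as CSV/JSON under ``out_dir``; idempotent."""
    os.makedirs(out_dir, exist_ok=True)
    paths = FixtureSet(
        initial=os.path.join(out_dir, "balanced_example_initial.csv"),
        ot_expected=os.path.join(out_dir, "balanced_example_ot.csv"),
        omt_expected=os.path.join(out_dir, "balanced_example_omt.csv"),
        crossloaded=os.path.join(out_dir, "crossloaded_population.csv"),
        design_vectors=os.path.join(out_dir, "design_vectors.json"),
    )
    write_loadings(balanced_example_initial(), paths.initial)
    write_loadings(balanced_example_ot_pattern(), paths.ot_expected)
    write_loadings(balanced_example_omt_pattern(), paths.omt_expected)
    write_loadings(crossloaded_population(), paths.crossloaded)
    vectors = {
        "salient": {
            f"ppq{ppq}_level{level:g}": salient_vector(ppq, level).tolist()
            for ppq in (5, 8)
            for level in (0.50, 0.70)
        },
        "cross": {
            f"ppq{ppq}_level{level:g}": cross_vector(ppq, level).tolist()
            for ppq in (5, 8)
            for level in (0.50, 0.70)
        },
    }
    with open(paths.design_vectors, "w", encoding="utf-8") as fh:
        json.dump(vectors, fh, indent=2)
    return paths
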
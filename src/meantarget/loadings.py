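"""Loading matrices and binary target patterns.

The currency of every stage of the package is a labelled p x q loading
matrix.  :class:`LoadingMatrix` is a thin, immutable wrapper around a
float ndarray with variable labels (rows) and factor labels (columns);
:class:`TargetSpec` holds a 0/1 target pattern for target rotation, either
the uniform independent-clusters construction ``I_q (x) 1_{p/q}`` or a
user-supplied binary pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LoadingMatrix",
    "TargetSpec",
    "build_icm_target",
    "read_loadings",
    "write_loadings",
]


@dataclass(frozen=True)
class LoadingMatrix:
    """A p x q matrix of factor loadings with row/column labels."""

    values: np.ndarray
    var_labels: tuple[str, ...] = ()
    factor_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"loadings must be 2-D, got shape {values.shape}")
        p, q = values.shape
        if not (p >= q >= 1):
            raise ValueError(f"need p >= q >= 1, got p={p}, q={q}")
        if not np.all(np.isfinite(values)):
            raise ValueError("loadings contain non-finite entries")
        values = values.copy()
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        var_labels = tuple(self.var_labels) or tuple(f"x{i + 1}" for i in range(p))
        factor_labels = tuple(self.factor_labels) or tuple(
            f"F{j + 1}" for j in range(q)
        )
        if len(var_labels) != p:
            raise ValueError(f"{len(var_labels)} variable labels for {p} rows")
        if len(factor_labels) != q:
            raise ValueError(f"{len(factor_labels)} factor labels for {q} columns")
        object.__setattr__(self, "var_labels", var_labels)
        object.__setattr__(self, "factor_labels", factor_labels)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.var_labels), columns=list(self.factor_labels)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LoadingMatrix":
        return cls(
            df.to_numpy(dtype=float),
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
        )

    def with_values(self, values: np.ndarray) -> "LoadingMatrix":
        """Same labels, new values (shape must agree)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError(f"shape {values.shape} != {self.shape}")
        return LoadingMatrix(values, self.var_labels, self.factor_labels)


@dataclass(frozen=True)
class TargetSpec:
    """A 0/1 target pattern for (mean-)target rotation.

    ``construction`` records whether the pattern is the uniform
    independent-clusters Kronecker construction or user supplied.
    """

    pattern: np.ndarray
    construction: str = "custom"

    def __post_init__(self) -> None:
        pat = np.asarray(self.pattern, dtype=float)
        if pat.ndim != 2:
            raise ValueError("target pattern must be 2-D")
        if not np.all(np.isin(pat, (0.0, 1.0))):
            raise ValueError("target pattern entries must be 0 or 1")
        empty = np.flatnonzero(pat.sum(axis=0) == 0)
        if empty.size:
            raise ValueError(
                f"target columns {empty.tolist()} contain no salient (1) entries"
            )
        pat = pat.copy()
        pat.flags.writeable = False
        object.__setattr__(self, "pattern", pat)

    @property
    def p(self) -> int:
        return self.pattern.shape[0]

    @property
    def q(self) -> int:
        return self.pattern.shape[1]


def build_icm_target(p: int, q: int) -> TargetSpec:
    """Uniform independent-clusters target: ``I_q`` Kronecker a unit block.

    Variable ``i`` (0-based) is salient on factor ``floor(i*q/p)``; each of
    the q contiguous blocks holds p/q variables.  Requires q to divide p;
    for unequal block sizes supply a custom :class:`TargetSpec` instead.
    """
    if q < 1 or p < q:
        raise ValueError(f"need p >= q >= 1, got p={p}, q={q}")
    if p % q != 0:
        raise ValueError(
            f"q={q} does not divide p={p}; the uniform independent-clusters "
            "target needs equal blocks — supply a custom TargetSpec for "
            "unequal block sizes"
        )
    pattern = np.kron(np.eye(q), np.ones((p // q, 1)))
    return TargetSpec(pattern, construction="uniform-ICM")


def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_loadings(path: str) -> LoadingMatrix:
    """Read a labelled loading matrix from CSV/TSV.

    First column = variable labels, header row = factor labels.  The
    delimiter is sniffed from the header; Unicode minus signs are accepted.
    """
    sep = _sniff_sep(str(path))
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    if df.columns.size == 0:
        raise ValueError(f"{path}: no factor columns found (missing header?)")
    cleaned = df.apply(lambda col: col.str.replace("−", "-", regex=False))
    try:
        values = cleaned.astype(float)
    except ValueError as exc:
        bad = cleaned.apply(pd.to_numeric, errors="coerce")
        rows, cols = np.nonzero(bad.isna().to_numpy())
        loc = (df.index[rows[0]], df.columns[cols[0]]) if rows.size else ("?", "?")
        raise ValueError(
            f"{path}: non-numeric cell at row {loc[0]!r}, column {loc[1]!r}"
        ) from exc
    return LoadingMatrix.from_frame(values)


def write_loadings(matrix: LoadingMatrix, path: str, sep: str = ",") -> None:
    """Write a loading matrix as labelled CSV/TSV at full precision (17 significant digits, bit-lossless)."""
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.17g")
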
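"""Correlation estimation and matrix-level comparison statistics.

This module implements the correlation machinery used throughout the
package: Fisher's variance-stabilizing z transform, pairwise-complete
Pearson matrices with per-cell pair counts, z-based averaging of absolute
correlations, the mean absolute deviation between two correlation
matrices, a chi-square test of matrix equality (sum of squared differences
of z-transformed coefficients, scaled by sampling variance), confidence
intervals on the z scale, and the classical correction for attenuation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: correlations are clipped to this magnitude before atanh so that unit
#: correlations map to a large finite z instead of infinity
CLIP = 1.0 - 1e-12

__all__ = [
    "CorrelationMatrix",
    "MatrixComparisonResult",
    "fisher_z",
    "inverse_fisher",
    "pairwise_correlations",
    "average_absolute_correlation",
    "matrix_mad",
    "matrix_equality_test",
    "disattenuate",
    "correlation_ci",
]


def fisher_z(r, clip: float = CLIP):
    """Fisher z transform, ``z = atanh(r)``.

    Magnitudes at or above 1 are clipped to ``clip`` (default ``1 - 1e-12``)
    so the transform stays finite; clipping is logged when triggered.
    Accepts scalars or array-likes and preserves NaN.
    """
    arr = np.asarray(r, dtype=float)
    if np.nanmax(np.abs(arr), initial=0.0) > 1.0 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(arr[~np.isnan(arr)]) >= clip):
        logger.info("fisher_z: |r| >= %g clipped before atanh", clip)
    out = np.arctanh(np.clip(arr, -clip, clip))
    return float(out) if np.isscalar(r) else out


def inverse_fisher(z):
    """Inverse Fisher transform, ``r = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


@dataclass
class CorrelationMatrix:
    """A labeled correlation matrix with per-cell pair counts.

    ``values`` is a DataFrame (rows x columns of variable labels); cells
    with fewer than four complete pairs are NaN (undefined).  ``pair_n``
    holds the number of complete observation pairs behind each cell.  A
    symmetric matrix represents intercorrelations of one variable set; a
    rectangular one a cross-correlation block (e.g. self x informant).
    """

    values: pd.DataFrame
    pair_n: pd.DataFrame | None = None
    symmetric: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if self.symmetric:
            if not v.index.equals(v.columns):
                raise ValueError("symmetric matrix requires identical row/column labels")
            a = v.to_numpy(dtype=float)
            if not np.allclose(a, a.T, atol=1e-10, equal_nan=True):
                raise ValueError("matrix flagged symmetric is not symmetric")
        finite = v.to_numpy(dtype=float)
        if np.nanmax(np.abs(finite), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def row_labels(self) -> list:
        return list(self.values.index)

    @property
    def column_labels(self) -> list:
        return list(self.values.columns)

    def cells(self, include_diagonal: bool = False) -> pd.Series:
        """Unique comparable cells as a Series indexed by (row, col) pairs.

        For a symmetric matrix this is the upper triangle (excluding the
        diagonal unless requested); for a rectangular matrix, every cell.
        """
        v = self.values
        if self.symmetric:
            k = 0 if include_diagonal else 1
            iu = np.triu_indices(len(v), k)
            idx = pd.MultiIndex.from_arrays(
                [v.index[iu[0]], v.columns[iu[1]]], names=["row", "col"]
            )
            return pd.Series(v.to_numpy(dtype=float)[iu], index=idx)
        stacked = v.stack(dropna=False)
        stacked.index.names = ["row", "col"]
        return stacked

    @classmethod
    def from_square(
        cls, frame: pd.DataFrame, pair_n: pd.DataFrame | None = None
    ) -> "CorrelationMatrix":
        return cls(values=frame, pair_n=pair_n, symmetric=True)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, float_format="%.6f")


@dataclass
class MatrixComparisonResult:
    """Comparison of two correlation matrices.

    ``mad`` is the mean absolute deviation of corresponding correlations;
    ``q_statistic`` the chi-square statistic (sum of squared z differences
    over their sampling variance), with ``df`` equal to the number of
    compared cells and an upper-tail p-value.
    """

    mad: float
    q_statistic: float
    df: int
    p_value: float
    cells_compared: int
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mad < 0 or not (0.0 <= self.p_value <= 1.0):
            raise ValueError("invalid comparison result")


def pairwise_correlations(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    min_pairs: int = 4,
    listwise: bool = False,
) -> CorrelationMatrix:
    """Pearson correlation matrix with pairwise-complete deletion.

    Parameters
    ----------
    table : wide per-subject score table (one column per variable).
    columns : optional subset/order of columns.
    min_pairs : cells with fewer complete pairs are set to NaN.
    listwise : drop rows with any missing value first (optional mode).

    Constant columns within the complete pairs yield undefined (NaN) cells.
    """
    data = table[list(columns)] if columns is not None else table
    data = data.astype(float)
    if listwise:
        data = data.dropna()
    notna = data.notna().to_numpy(dtype=float)
    pair_n = pd.DataFrame(
        (notna.T @ notna).astype(int), index=data.columns, columns=data.columns
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = data.corr(method="pearson", min_periods=min_pairs)
    corr = corr.mask(pair_n < min_pairs)
    n_undef = int(corr.isna().to_numpy().sum()) - 0
    if n_undef:
        logger.info("pairwise_correlations: %d undefined cells", n_undef)
    return CorrelationMatrix(values=corr, pair_n=pair_n, symmetric=True)


def average_absolute_correlation(values: Iterable[float]) -> float:
    """z-based average of absolute correlations.

    Each |r| is Fisher-z transformed, the z values are averaged, and the
    mean is transformed back: ``tanh(mean(atanh(|r_i|)))``.  Because atanh
    is convex on [0, 1), this average is never below the plain arithmetic
    mean of the |r|.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("average_absolute_correlation: empty input")
    return float(inverse_fisher(np.mean(fisher_z(np.abs(arr)))))


def _aligned_cells(
    m1: CorrelationMatrix,
    m2: CorrelationMatrix,
    include_diagonal: bool,
    relabel: Mapping | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    v2 = m2.values
    if relabel is not None:
        v2 = v2.rename(index=relabel, columns=relabel)
        m2 = CorrelationMatrix(v2, symmetric=m2.symmetric)
    if set(m1.row_labels) != set(m2.row_labels) or set(m1.column_labels) != set(
        m2.column_labels
    ):
        raise ValueError(
            "matrix labels do not match; supply a relabeling map to align them"
        )
    a = m1.cells(include_diagonal)
    b = m2.cells(include_diagonal).reindex(a.index)
    keep = ~(a.isna() | b.isna())
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("matrix comparison: %d undefined cells excluded", dropped)
    return a[keep].to_numpy(), b[keep].to_numpy(), dropped


def matrix_mad(
    m1: CorrelationMatrix,
    m2: CorrelationMatrix,
    include_diagonal: bool = False,
    relabel: Mapping | None = None,
) -> float:
    """Mean absolute deviation between corresponding correlations.

    Symmetric matrices are compared over unique off-diagonal cells
    (the diagonal is excluded by default).
    """
    a, b, _ = _aligned_cells(m1, m2, include_diagonal, relabel)
    if a.size == 0:
        raise ValueError("no comparable cells")
    return float(np.mean(np.abs(a - b)))


def matrix_equality_test(
    m1: CorrelationMatrix,
    n1,
    m2: CorrelationMatrix,
    n2,
    include_diagonal: bool = False,
    relabel: Mapping | None = None,
    cell_set: str = "unique",
    dependent_samples: bool = False,
) -> MatrixComparisonResult:
    """Chi-square test that two correlation matrices are equal.

    Each pair of corresponding correlations is z-transformed and the
    squared difference divided by its sampling variance
    ``1/(n1-3) + 1/(n2-3)``; the sum over compared cells is referred to a
    chi-square distribution with df equal to the number of cells.

    ``cell_set="unique"`` (default) compares unique off-diagonal cells of
    symmetric matrices.  ``cell_set="kxk"`` is a compatibility mode that
    counts every ordered off-diagonal cell twice and the (zero-difference)
    diagonal as well, giving df = k^2 for k variables; some published
    applications report df this way.  Its chi-square calibration is not
    asserted.

    Sample sizes may be scalars or per-cell counts aligned with the cells.
    Set ``dependent_samples=True`` when the two matrices were computed on
    the same subjects; the statistic is unchanged but the result carries a
    "dependence ignored" note, replicating the common (approximate)
    practice rather than correcting it.
    """
    if cell_set not in {"unique", "kxk"}:
        raise ValueError("cell_set must be 'unique' or 'kxk'")
    if np.isscalar(n1) and n1 <= 3 or np.isscalar(n2) and n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    a, b, dropped = _aligned_cells(m1, m2, include_diagonal, relabel)
    if a.size == 0:
        raise ValueError("no comparable cells")
    var = 1.0 / (np.asarray(n1, dtype=float) - 3.0) + 1.0 / (
        np.asarray(n2, dtype=float) - 3.0
    )
    q = float(np.sum((fisher_z(a) - fisher_z(b)) ** 2 / var))
    df = int(a.size)
    notes: list[str] = []
    if cell_set == "kxk" and m1.symmetric:
        k = len(m1.row_labels)
        q *= 2.0
        df = k * k
        notes.append("k-squared compatibility cell set")
    if dropped:
        notes.append(f"{dropped} undefined cells excluded")
    if dependent_samples:
        notes.append("dependence ignored")
    mad = float(np.mean(np.abs(a - b)))
    return MatrixComparisonResult(
        mad=mad,
        q_statistic=q,
        df=df,
        p_value=float(stats.chi2.sf(q, df)),
        cells_compared=int(a.size),
        notes=tuple(notes),
    )


def disattenuate(r: float, rel1: float, rel2: float) -> float:
    """Correct a correlation for attenuation: ``r / sqrt(rel1 * rel2)``.

    Reliabilities must lie in (0, 1].  Corrected values beyond |1| are
    returned as computed and logged as out of range.
    """
    if not (0.0 < rel1 <= 1.0 and 0.0 < rel2 <= 1.0):
        raise ValueError("reliabilities must lie in (0, 1]")
    out = r / np.sqrt(rel1 * rel2)
    if abs(out) > 1.0:
        logger.warning("disattenuated correlation %.3f outside [-1, 1]", out)
    return float(out)


def correlation_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation.

    ``z +- z_crit / sqrt(n - 3)``, back-transformed with tanh.
    """
    if n <= 3:
        raise ValueError("confidence interval requires n > 3")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must lie in (0, 1]")
    z = fisher_z(r)
    crit = stats.norm.ppf(0.5 + level / 2.0)
    half = crit / np.sqrt(n - 3.0)
    return (float(inverse_fisher(z - half)), float(inverse_fisher(z + half)))
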
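"""Profile similarity via the double-entry intraclass correlation.

The double-entry ICC compares two profiles (here: columns of correlations
of two measures with a common set of external variables) by entering every
element pair twice in reversed order and correlating the doubled vectors.
Unlike the ordinary Pearson correlation of the two profiles it penalizes
differences in elevation and scatter, not just in shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlations import CorrelationMatrix, fisher_z

__all__ = [
    "ProfileComparison",
    "ProfileMatrixResult",
    "icc_double_entry",
    "profile_matrix",
    "matrix_profile_similarity",
]


def _apply_transform(a: np.ndarray, transform: str | None) -> np.ndarray:
    if transform in (None, "none"):
        return a
    if transform == "fisher_z":
        return fisher_z(a)
    raise ValueError(f"unknown transform {transform!r}")


def icc_double_entry(a, b) -> float:
    """Double-entry intraclass correlation of two equal-length profiles.

    With ``m`` the grand mean of the 2k pooled values, returns

        2 * sum((a_i - m)(b_i - m)) / (sum((a_i - m)^2) + sum((b_i - m)^2))

    which equals the literal Pearson correlation of the double-entered
    vectors (a then b, paired with b then a).  Profiles must have length
    >= 3 and nonzero pooled variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1-d sequences")
    if a.size < 3:
        raise ValueError("profiles must have at least 3 elements")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("profiles must be complete; align them first")
    m = np.concatenate([a, b]).mean()
    da, db = a - m, b - m
    denom = np.sum(da**2) + np.sum(db**2)
    if denom == 0.0:
        raise ValueError("zero pooled variance: ICC_DE undefined")
    return float(2.0 * np.sum(da * db) / denom)


@dataclass
class ProfileComparison:
    """Two labeled correlation profiles and their double-entry ICC."""

    labels: tuple
    profile_a: np.ndarray
    profile_b: np.ndarray
    transform: str | None
    icc_de: float

    @classmethod
    def from_profiles(cls, labels, a, b, transform: str | None = "fisher_z"):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ta, tb = _apply_transform(a, transform), _apply_transform(b, transform)
        return cls(tuple(labels), a, b, transform, icc_double_entry(ta, tb))


@dataclass
class ProfileMatrixResult:
    """All-pairs profile similarity over measure columns.

    ``values`` holds ICC_DE for every measure pair; ``n_shared`` the number
    of profile elements the pair was computed on (pairs with missing cells
    fall back to their shared complete subset).
    """

    values: pd.DataFrame
    n_shared: pd.DataFrame


def profile_matrix(
    block: pd.DataFrame, transform: str | None = "fisher_z"
) -> ProfileMatrixResult:
    """Symmetric matrix of double-entry ICCs over measure columns.

    ``block`` is a correlates x measures table of correlations (the
    nomological net); each pair of measure columns is compared over the
    shared complete correlate subset after the chosen transform
    (Fisher z by default).
    """
    measures = list(block.columns)
    k = len(measures)
    vals = np.ones((k, k))
    ns = np.full((k, k), len(block), dtype=int)
    t = _apply_transform(block.to_numpy(dtype=float), transform)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = t[:, i], t[:, j]
            keep = ~(np.isnan(a) | np.isnan(b))
            ns[i, j] = ns[j, i] = int(keep.sum())
            vals[i, j] = vals[j, i] = icc_double_entry(a[keep], b[keep])
    return ProfileMatrixResult(
        values=pd.DataFrame(vals, index=measures, columns=measures),
        n_shared=pd.DataFrame(ns, index=measures, columns=measures),
    )


def matrix_profile_similarity(
    m1: CorrelationMatrix,
    m2: CorrelationMatrix,
    transform: str | None = "fisher_z",
    include_diagonal: bool = False,
) -> float:
    """Double-entry ICC between the cell profiles of two matrices.

    The unique off-diagonal cells of each matrix (matched by label) form
    one profile each; the ICC_DE of the transformed profiles measures how
    similar the two correlation structures are, elevation included.
    """
    a = m1.cells(include_diagonal)
    b = m2.cells(include_diagonal).reindex(a.index)
    keep = ~(a.isna() | b.isna())
    ta = _apply_transform(a[keep].to_numpy(), transform)
    tb = _apply_transform(b[keep].to_numpy(), transform)
    return icc_double_entry(ta, tb)
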
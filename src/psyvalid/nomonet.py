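"""Nomological-net blocks and constrained-correlation model comparisons.

A nomological net is the pattern of correlations between a set of focal
measures and external correlates grouped into domains (demography,
personality, satisfaction, network).  Whether two measures differ in
their association with a correlate is tested by a likelihood-ratio
comparison of two multivariate-normal models: a saturated model with all
correlations free, and a constrained model forcing
``corr(m1, y) == corr(m2, y)``.  Minus twice the log-likelihood ratio,
``N * (F_constrained - F_saturated)`` with the ML discrepancy

    F = log|Sigma| + tr(S Sigma^-1) - log|S| - p,

is referred to chi-square with 1 degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .correlations import average_absolute_correlation, pairwise_correlations

logger = logging.getLogger(__name__)

__all__ = [
    "NomologicalBlock",
    "PairTestResult",
    "correlate_block",
    "constrained_pair_test",
    "pairwise_difference_scan",
    "block_average",
]


@dataclass
class NomologicalBlock:
    """Correlates x measures correlation block with domain tags.

    ``values``: correlations (rows = correlates, columns = measures);
    ``pair_n``: complete pairs per cell; ``p_values``: two-sided p from the
    t transform of r; ``domains``: correlate -> domain tag;
    ``flags``: per-cell markers at the alpha thresholds used for display
    (cells with p >= the loosest threshold are the "italicized" ones).
    """

    values: pd.DataFrame
    pair_n: pd.DataFrame
    p_values: pd.DataFrame
    domains: dict[str, str]
    alpha_flags: tuple[float, ...] = (0.01, 0.001)

    def __post_init__(self) -> None:
        missing = [c for c in self.values.index if c not in self.domains]
        if missing:
            raise ValueError(f"correlates without a domain tag: {missing}")

    @property
    def measures(self) -> list:
        return list(self.values.columns)

    def domain_rows(self, domain: str) -> pd.DataFrame:
        rows = [c for c, d in self.domains.items() if d == domain and c in self.values.index]
        if not rows:
            raise ValueError(f"no correlates in domain {domain!r}")
        return self.values.loc[rows]

    def significance(self, alpha: float) -> pd.DataFrame:
        return self.p_values < alpha

    def averages(self) -> pd.DataFrame:
        """z-based average absolute correlation per domain and measure."""
        doms = sorted(set(self.domains.values()))
        return pd.DataFrame(
            {d: block_average(self, d) for d in doms}
        ).T.reindex(doms)


def _corr_p_values(r: pd.DataFrame, n: pd.DataFrame) -> pd.DataFrame:
    rv = r.to_numpy(dtype=float)
    nv = n.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((nv - 2.0) / np.clip(1.0 - rv**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), np.clip(nv - 2.0, 1.0, None))
    p = np.where(np.isnan(rv), np.nan, p)
    p = np.where(np.abs(rv) >= 1.0, 0.0, p)
    return pd.DataFrame(p, index=r.index, columns=r.columns)


def correlate_block(
    scores: pd.DataFrame,
    correlates: pd.DataFrame,
    domains: dict[str, str],
    alpha_flags: tuple[float, ...] = (0.01, 0.001),
    min_pairs: int = 4,
) -> NomologicalBlock:
    """Pairwise-complete correlations of measures with external correlates.

    ``scores``: targets x measures; ``correlates``: targets x correlates
    (matched on the index); ``domains`` tags every correlate column.
    """
    joint = correlates.add_prefix("c::").join(scores.add_prefix("m::"), how="outer")
    full = pairwise_correlations(joint, min_pairs=min_pairs)
    rows = ["c::" + c for c in correlates.columns]
    cols = ["m::" + m for m in scores.columns]
    values = full.values.loc[rows, cols]
    pair_n = full.pair_n.loc[rows, cols]
    values.index = list(correlates.columns)
    values.columns = list(scores.columns)
    pair_n.index, pair_n.columns = values.index, values.columns
    return NomologicalBlock(
        values=values,
        pair_n=pair_n,
        p_values=_corr_p_values(values, pair_n),
        domains=dict(domains),
        alpha_flags=tuple(alpha_flags),
    )


def block_average(block: NomologicalBlock, domain: str) -> pd.Series:
    """Per-measure z-based average absolute correlation over one domain."""
    rows = block.domain_rows(domain)
    return pd.Series(
        {m: average_absolute_correlation(rows[m]) for m in rows.columns},
        name=domain,
    )


@dataclass
class PairTestResult:
    """Result of one constrained-correlation likelihood-ratio test."""

    measure_1: str
    measure_2: str
    correlate: str
    chi2_diff: float
    df: int
    p_value: float
    n: int
    batch: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.df != 1:
            raise ValueError("pairwise constraint tests have 1 df")


def _ml_discrepancy(sigma: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return np.inf
    p = s.shape[0]
    return float(logdet + np.trace(s @ inv) - logdet_s - p)


def _fit_constrained(
    s: np.ndarray, i1: int, i2: int, iy: int
) -> tuple[float, bool]:
    """Minimize the ML discrepancy over covariance matrices whose
    correlation structure satisfies corr(i1, iy) == corr(i2, iy).

    Parameterization: one log-SD per variable plus one Fisher-z per unique
    correlation, with the two constrained correlations sharing a single z
    parameter.  Smooth and unconstrained; positive definiteness is checked
    inside the objective (non-PD points get +inf, which BFGS backtracks
    away from since the start is PD).
    """
    p = s.shape[0]
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    iu = list(zip(*np.triu_indices(p, 1)))
    shared_cells = {(min(i1, iy), max(i1, iy)), (min(i2, iy), max(i2, iy))}
    free_cells = [c for c in iu if c not in shared_cells]
    z_start = np.arctanh(np.clip(r, -0.999999, 0.999999))
    shared0 = np.mean([z_start[c] for c in sorted(shared_cells)])
    theta0 = np.concatenate(
        [np.log(d), [z_start[c] for c in free_cells], [shared0]]
    )
    logdet_s = float(np.linalg.slogdet(s)[1])

    def unpack(theta: np.ndarray) -> np.ndarray:
        sd = np.exp(theta[:p])
        corr = np.eye(p)
        for c, z in zip(free_cells, theta[p:-1]):
            corr[c] = corr[c[::-1]] = np.tanh(z)
        for c in shared_cells:
            corr[c] = corr[c[::-1]] = np.tanh(theta[-1])
        return corr * np.outer(sd, sd)

    def objective(theta: np.ndarray) -> float:
        return _ml_discrepancy(unpack(theta), s, logdet_s)

    res = optimize.minimize(objective, theta0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    best = float(res.fun)
    # polish with Nelder-Mead if the gradient-based step got stuck
    if not res.success or not np.isfinite(best):
        res2 = optimize.minimize(objective, res.x if np.all(np.isfinite(res.x)) else theta0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if res2.fun < best or not np.isfinite(best):
            best, res = float(res2.fun), res2
    return best, bool(np.isfinite(best))


def constrained_pair_test(
    data: pd.DataFrame,
    pair: tuple[str, str, str],
    scope: list[str] | None = None,
    n_scale: str = "n",
    batch: int = 0,
) -> PairTestResult:
    """Likelihood-ratio test that two measures correlate equally with a
    correlate.

    Parameters
    ----------
    data : per-subject scores; must contain the three pair variables and
        any additional ``scope`` variables.  Complete cases are used.
    pair : ``(measure_1, measure_2, correlate)`` naming the constrained
        correlations ``corr(m1, y)`` and ``corr(m2, y)``.
    scope : full variable set entered in the models (default: just the
        three pair variables).  The saturated fit is exact (F = 0) either
        way; with a wider scope the constrained optimum can differ
        slightly.
    n_scale : ``"n"`` multiplies the discrepancy by the complete-case
        count; ``"n-1"`` by one less.

    Raises on non-convergence and on a materially negative chi-square
    difference (the constrained model can never beat the saturated one;
    more than ~1e-6 below zero indicates optimizer failure).
    """
    m1, m2, y = pair
    cols = list(dict.fromkeys([m1, m2, y] + list(scope or [])))
    sub = data[cols].dropna()
    n = len(sub)
    if n < 20:
        raise ValueError(f"constrained test needs >= 20 complete cases, got {n}")
    x = sub.to_numpy(dtype=float)
    s = np.cov(x, rowvar=False, ddof=0)
    idx = {c: k for k, c in enumerate(cols)}
    f_con, converged = _fit_constrained(s, idx[m1], idx[m2], idx[y])
    if not converged:
        raise RuntimeError(
            f"constrained fit did not converge for ({m1}, {m2}, {y})"
        )
    scale = float(n) if n_scale == "n" else float(n - 1)
    chi2 = scale * f_con  # saturated F is exactly 0 (Sigma-hat = S)
    if chi2 < -1e-6:
        raise RuntimeError(f"negative chi-square difference ({chi2:.2e}): optimizer failure")
    chi2 = max(chi2, 0.0)
    return PairTestResult(
        measure_1=m1,
        measure_2=m2,
        correlate=y,
        chi2_diff=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, 1)),
        n=n,
        batch=batch,
        converged=converged,
    )


def pairwise_difference_scan(
    scores: pd.DataFrame,
    correlates: pd.DataFrame,
    batches: list[list[str]] | None = None,
    alpha: float = 0.001,
    scope: str = "triplet",
) -> pd.DataFrame:
    """All within-batch measure pairs tested against every correlate.

    ``batches`` partitions the measures into sets whose pairs are tested
    (e.g. facet scores are never tested against their own total by placing
    total and facets in different batches); default is a single batch of
    all measures.  ``scope="batch"`` enters all batch measures plus the
    correlate into each model; ``"triplet"`` (default) uses the minimal
    three-variable set, which has the identical saturated fit and is much
    faster.

    Returns a long DataFrame (measure_1, measure_2, correlate, chi2, df,
    p, significant, batch, n); ``significant`` applies ``alpha`` with no
    further multiplicity correction.
    """
    if batches is None:
        batches = [list(scores.columns)]
    joint = scores.join(correlates, how="outer", lsuffix="", rsuffix="::c")
    rows = []
    for b, batch in enumerate(batches):
        for i in range(len(batch)):
            for j in range(i + 1, len(batch)):
                for y in correlates.columns:
                    res = constrained_pair_test(
                        joint,
                        (batch[i], batch[j], y),
                        scope=batch if scope == "batch" else None,
                        batch=b,
                    )
                    rows.append(
                        (res.measure_1, res.measure_2, res.correlate, res.chi2_diff,
                         res.df, res.p_value, res.p_value < alpha, res.batch, res.n)
                    )
    return pd.DataFrame(
        rows,
        columns=["measure_1", "measure_2", "correlate", "chi2", "df", "p",
                 "significant", "batch", "n"],
    )
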
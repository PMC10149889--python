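"""Informant aggregation, rater consensus, and self-informant agreement.

Input is a long-format rating table with the columns

    target, rater, role, wave, measure, score

where ``role`` is ``"self"`` or ``"informant"``.  Informant ratings of a
target are averaged per measure; consensus among informants is quantified
with the one-way random-effects intraclass correlations ICC(1) (a single
rater) and ICC(1,k) (the mean of the available raters); agreement between
self- and aggregated informant-ratings is summarized by cross-correlation
matrices, paired t tests and standardized mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlations import CorrelationMatrix, disattenuate, pairwise_correlations

__all__ = [
    "RATING_COLUMNS",
    "AgreementSummary",
    "ConsensusResult",
    "aggregate_informants",
    "self_scores",
    "consensus_icc",
    "self_informant_matrix",
    "paired_mean_difference",
    "agreement_summaries",
    "informant_count_correlation",
]

RATING_COLUMNS = ("target", "rater", "role", "wave", "measure", "score")


def _check_ratings(ratings: pd.DataFrame) -> None:
    missing = set(RATING_COLUMNS) - set(ratings.columns)
    if missing:
        raise ValueError(f"rating table lacks columns: {sorted(missing)}")


def aggregate_informants(ratings: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean informant rating per target and measure.

    Returns ``(means, counts)``: wide target x measure tables of the
    arithmetic mean over available informants and of the informant count
    behind each mean.
    """
    _check_ratings(ratings)
    inf = ratings[ratings["role"] == "informant"]
    if inf.empty:
        raise ValueError("no informant ratings present")
    g = inf.groupby(["target", "measure"])["score"]
    means = g.mean().unstack("measure")
    counts = g.size().unstack("measure").fillna(0).astype(int)
    return means, counts


def self_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Wide target x measure table of self-ratings."""
    _check_ratings(ratings)
    s = ratings[ratings["role"] == "self"]
    return s.pivot_table(index="target", columns="measure", values="score", aggfunc="mean")


@dataclass
class ConsensusResult:
    """One-way random-effects consensus of informant ratings of one measure."""

    measure: str
    icc1: float
    icc1k: float
    n_targets: int
    mean_raters_per_target: float


def consensus_icc(ratings: pd.DataFrame, measure: str) -> ConsensusResult:
    """ICC(1) and ICC(1,k) of single informant ratings, one-way design.

    Decomposes informant ratings of ``measure`` into between-target and
    within-target mean squares.  With group sizes ``k_i`` and
    ``k0 = (N - sum(k_i^2)/N) / (n_targets - 1)`` for unbalanced designs:

        ICC(1)   = (MSB - MSW) / (MSB + (k0 - 1) * MSW)
        ICC(1,k) = (MSB - MSW) / MSB

    Requires at least two targets and at least one target with two or more
    raters (otherwise the within-target mean square is undefined).
    """
    _check_ratings(ratings)
    sub = ratings[(ratings["role"] == "informant") & (ratings["measure"] == measure)]
    sub = sub.dropna(subset=["score"])
    groups = [g.to_numpy(dtype=float) for _, g in sub.groupby("target")["score"]]
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("consensus requires ratings of at least two targets")
    sizes = np.array([len(g) for g in groups])
    n_total = int(sizes.sum())
    if n_total - n_groups == 0:
        raise ValueError("all targets have a single rater: within-target MS undefined")
    grand = np.concatenate(groups).mean()
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (n_groups - 1)
    msw = ssw / (n_total - n_groups)
    k0 = (n_total - (sizes**2).sum() / n_total) / (n_groups - 1)
    if msb == 0.0 and msw == 0.0:
        raise ValueError("no variance in ratings: ICC undefined")
    icc1 = (msb - msw) / (msb + (k0 - 1.0) * msw)
    icc1k = (msb - msw) / msb if msb > 0 else -np.inf
    return ConsensusResult(
        measure=measure,
        icc1=float(icc1),
        icc1k=float(icc1k),
        n_targets=n_groups,
        mean_raters_per_target=float(sizes.mean()),
    )


def self_informant_matrix(
    self_wide: pd.DataFrame, informant_wide: pd.DataFrame, min_pairs: int = 4
) -> CorrelationMatrix:
    """Full cross-correlation of self measures x informant measures.

    Targets are matched on the index; pairwise-complete Pearson
    correlations.  The diagonal holds same-measure self-informant
    agreement, off-diagonal cells cross-measure agreement.
    """
    s = self_wide.add_prefix("self::")
    i = informant_wide.add_prefix("inf::")
    joint = s.join(i, how="outer")
    full = pairwise_correlations(joint, min_pairs=min_pairs)
    rows = [c for c in joint.columns if c.startswith("self::")]
    cols = [c for c in joint.columns if c.startswith("inf::")]
    values = full.values.loc[rows, cols]
    pair_n = full.pair_n.loc[rows, cols]
    values.index = [r.split("::", 1)[1] for r in rows]
    values.columns = [c.split("::", 1)[1] for c in cols]
    pair_n.index, pair_n.columns = values.index, values.columns
    return CorrelationMatrix(values=values, pair_n=pair_n, symmetric=False)


@dataclass
class AgreementSummary:
    """Per-measure self-informant agreement summary."""

    measure: str
    self_informant_r: float
    pairs_n: int
    mean_self: float
    mean_informant: float
    t_statistic: float
    p_value: float
    d: float
    disattenuated_r: float | None = None
    degenerate: bool = False


def paired_mean_difference(
    self_values: pd.Series,
    informant_values: pd.Series,
    measure: str = "",
    d_denominator: str = "pooled",
) -> AgreementSummary:
    """Paired t test and standardized mean difference, self minus informant.

    ``d_denominator="pooled"`` standardizes the mean difference by the
    pooled standard deviation of the two score distributions (comparable
    to a between-group d); ``"diff"`` gives the difference-score variant
    d_z (mean difference over the SD of the differences).  Positive values
    mean the self-ratings are higher.  Zero-variance differences are
    flagged degenerate (t and p undefined).
    """
    pair = pd.concat({"s": self_values, "i": informant_values}, axis=1).dropna()
    if len(pair) < 2:
        raise ValueError("paired comparison requires at least 2 complete pairs")
    s, i = pair["s"].to_numpy(dtype=float), pair["i"].to_numpy(dtype=float)
    diff = s - i
    r = float(np.corrcoef(s, i)[0, 1]) if np.std(s) > 0 and np.std(i) > 0 else np.nan
    if d_denominator == "pooled":
        denom = np.sqrt((np.var(s, ddof=1) + np.var(i, ddof=1)) / 2.0)
    elif d_denominator == "diff":
        denom = np.std(diff, ddof=1)
    else:
        raise ValueError("d_denominator must be 'pooled' or 'diff'")
    if np.std(diff, ddof=1) == 0.0:
        # identical shifts (or identical scores): t is undefined unless diff==0
        t, p = (0.0, 1.0) if np.all(diff == 0.0) else (np.nan, np.nan)
        degenerate = not np.all(diff == 0.0)
    else:
        t, p = stats.ttest_rel(s, i)
        degenerate = False
    d = float(diff.mean() / denom) if denom > 0 else 0.0
    return AgreementSummary(
        measure=measure,
        self_informant_r=r,
        pairs_n=len(pair),
        mean_self=float(s.mean()),
        mean_informant=float(i.mean()),
        t_statistic=float(t),
        p_value=float(p),
        d=d,
        degenerate=degenerate,
    )


def agreement_summaries(
    self_wide: pd.DataFrame,
    informant_wide: pd.DataFrame,
    reliabilities: dict[str, float] | None = None,
    d_denominator: str = "pooled",
) -> list[AgreementSummary]:
    """Agreement summary per shared measure, optionally disattenuated.

    ``reliabilities`` maps measure id to a reliability coefficient (e.g.
    omega); when both a self and informant reliability matter, supply the
    product's components via the same value per measure (the conventional
    same-instrument case) -- the corrected r is r / sqrt(rel_self * rel_inf)
    with both set to the given value.
    """
    out = []
    for m in [c for c in self_wide.columns if c in informant_wide.columns]:
        summ = paired_mean_difference(
            self_wide[m], informant_wide[m], measure=m, d_denominator=d_denominator
        )
        if reliabilities and m in reliabilities:
            rel = reliabilities[m]
            summ.disattenuated_r = disattenuate(summ.self_informant_r, rel, rel)
        out.append(summ)
    return out


def informant_count_correlation(
    self_wide: pd.DataFrame, counts: pd.DataFrame
) -> pd.Series:
    """Diagnostic: correlation of each self-rated measure with the number
    of informants who rated the target (lonelier targets tend to be rated
    by fewer informants in observed data)."""
    n_informants = counts.max(axis=1).astype(float)
    out = {}
    for m in self_wide.columns:
        pair = pd.concat([self_wide[m], n_informants], axis=1).dropna()
        out[m] = float(pair.corr().iloc[0, 1]) if len(pair) >= 4 else np.nan
    return pd.Series(out, name="r_with_n_informants")
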
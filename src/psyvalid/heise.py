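"""Single-item retest reliability from three evenly spaced occasions.

Under a quasi-simplex model -- true scores follow a lag-1 autoregression
across three waves and observed scores add white measurement error -- the
observed autocorrelations satisfy r12 = rho*s1, r23 = rho*s2 and
r13 = rho*s1*s2, where rho is the reliability and s1, s2 the true-score
stabilities.  Reliability is therefore identified as

    rxx = (r12 * r23) / r13

independent of the stabilities.  Interval bounds are propagated by
applying the same formula to the per-lag confidence bounds of the
observed correlations (a literal, conservative convention; a delta-method
interval is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correlations import correlation_ci

__all__ = ["ReliabilityEstimate", "heise_rxx", "heise_with_bounds"]


@dataclass
class ReliabilityEstimate:
    """Heise reliability estimate with propagated interval bounds."""

    r12: float
    r23: float
    r13: float
    n12: int
    n23: int
    n13: int
    rxx: float
    lower: float
    upper: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def heise_rxx(r12: float, r23: float, r13: float) -> float:
    """Point estimate ``(r12 * r23) / r13``.

    No clamping is applied: estimates outside [0, 1] are returned as
    computed (inspect the flags of :func:`heise_with_bounds` or check the
    value).  ``r13`` near zero makes the estimator undefined.
    """
    for name, r in (("r12", r12), ("r23", r23), ("r13", r13)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1]")
    if abs(r13) <= 1e-6:
        raise ValueError("r13 is (numerically) zero: reliability undefined")
    return float(r12 * r23 / r13)


def _pairwise_r(wide: pd.DataFrame, a: str, b: str) -> tuple[float, int]:
    sub = wide[[a, b]].dropna()
    if len(sub) < 4:
        raise ValueError(f"lag {a}-{b} has fewer than 4 complete pairs")
    r = float(sub[a].corr(sub[b]))
    if np.isnan(r):
        raise ValueError(f"lag {a}-{b} correlation undefined (constant scores)")
    return r, len(sub)


def heise_with_bounds(
    scores: pd.DataFrame,
    level: float = 0.95,
    sample: str = "full",
    interval: str = "propagate",
) -> ReliabilityEstimate:
    """Heise reliability from a wide three-wave score table.

    Parameters
    ----------
    scores : DataFrame with exactly three wave columns (in time order);
        missing entries are allowed.
    sample : ``"full"`` uses all available pairs per lag (pairwise
        deletion, so the three correlations may rest on different subject
        sets); ``"panel"`` restricts to subjects observed at all three
        waves.
    interval : ``"propagate"`` applies the rxx formula to the per-lag
        confidence bounds (lower bounds in, upper bounds in), mirroring
        the conventional reporting of this estimator even though the
        result is not a calibrated confidence interval; ``"delta"`` gives
        a first-order delta-method interval on the log scale.

    Flags mark estimates outside [0, 1] and unstable denominators
    (|r13| < .1).
    """
    if scores.shape[1] != 3:
        raise ValueError("expected a table with exactly three wave columns")
    wide = scores.astype(float)
    if sample == "panel":
        wide = wide.dropna()
    elif sample != "full":
        raise ValueError("sample must be 'full' or 'panel'")
    w1, w2, w3 = wide.columns
    r12, n12 = _pairwise_r(wide, w1, w2)
    r23, n23 = _pairwise_r(wide, w2, w3)
    r13, n13 = _pairwise_r(wide, w1, w3)
    rxx = heise_rxx(r12, r23, r13)
    flags: list[str] = []
    if not 0.0 <= rxx <= 1.0:
        flags.append("estimate outside [0, 1]")
    if abs(r13) < 0.1:
        flags.append("unstable denominator (|r13| < .1)")
    if interval == "propagate":
        lo12, hi12 = correlation_ci(r12, n12, level)
        lo23, hi23 = correlation_ci(r23, n23, level)
        lo13, hi13 = correlation_ci(r13, n13, level)
        lower = float(lo12 * lo23 / lo13)
        upper = float(hi12 * hi23 / hi13)
    elif interval == "delta":
        # var(log rxx) ~= sum of var(log r) terms via var(z) = 1/(n-3)
        def var_log_r(r: float, n: int) -> float:
            return (1.0 - r * r) ** 2 / ((n - 3) * r * r)

        se = np.sqrt(
            var_log_r(r12, n12) + var_log_r(r23, n23) + var_log_r(r13, n13)
        )
        crit = stats.norm.ppf(0.5 + level / 2.0)
        lower = float(rxx * np.exp(-crit * se))
        upper = float(rxx * np.exp(crit * se))
    else:
        raise ValueError("interval must be 'propagate' or 'delta'")
    return ReliabilityEstimate(
        r12=r12, r23=r23, r13=r13, n12=n12, n23=n23, n13=n13,
        rxx=rxx, lower=lower, upper=upper, flags=tuple(flags),
    )
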
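"""Synthetic rating data with a known latent structure.

Two generators cover the designs the analysis stages expect:

* A single-factor measurement model with informant ratings.  A latent
  trait loads on every measure; observed scores attenuate the true score
  by the measure's reliability, so the implied correlation of two
  measures is ``loading_1 * loading_2 * sqrt(rel_1 * rel_2)``.  External
  correlates have specified correlations with the trait.  Informants
  share a target-level perception component (its weight sets the rater
  consensus, ICC(1)) that tracks the trait with a specified validity
  (setting self-informant agreement); each target is rated by 1-6
  informants.
* A three-wave quasi-simplex for single items: true scores follow a
  stationary lag-1 autoregression with stability ``s``; observed scores
  mix the true score with white error in proportion ``sqrt(reliability)``.
  The implied autocorrelations are r12 = r23 = rho*s and r13 = rho*s^2,
  so the Heise formula recovers rho.  Wave-on-wave retention is applied
  as missing-completely-at-random dropout.

All randomness flows from the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import CorrelationMatrix

__all__ = [
    "LatentSpec",
    "SimplexSpec",
    "build_target_correlation",
    "sample_ratings",
    "sample_three_wave",
]

#: Defaults mirror a large online validation study: several loneliness
#: measures with high loadings and the internal consistencies such
#: instruments typically print, moderately valid informant perceptions,
#: and 1-6 informants per target.
DEFAULT_LOADINGS = {
    "RTLS_Total": 0.95,
    "UCLA_20": 0.92,
    "SI_Direct": 0.80,
}
DEFAULT_RELIABILITIES = {
    "RTLS_Total": 0.89,
    "UCLA_20": 0.94,
    "SI_Direct": 0.71,
}
DEFAULT_CORRELATES = {
    "Depressiveness": 0.65,
    "SelfEsteem": -0.55,
    "SatFriends": -0.65,
    "Extraversion": -0.35,
}


@dataclass
class LatentSpec:
    """Parameters of the single-factor rating-data generator.

    ``measure_loadings`` / ``measure_reliabilities``: per measure, the
    loading on the latent trait (in [0, 1]) and the score reliability
    (in (0, 1]).  ``informant_validity`` is the correlation of the shared
    informant perception with the trait; ``informant_consensus`` the share
    of a single informant's perception variance that is common to all
    informants of the target (this is what ICC(1) tracks).
    ``informants_per_target`` is a distribution over 1..6 raters.
    ``correlate_correlations`` maps correlate ids to their correlation
    with the trait (in (-1, 1)).
    """

    n_targets: int = 700
    measure_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    measure_reliabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELIABILITIES)
    )
    informant_validity: float = 0.65
    informant_consensus: float = 0.55
    informants_per_target: dict[int, float] = field(
        default_factory=lambda: {k: 1.0 / 6.0 for k in range(1, 7)}
    )
    correlate_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_targets < 4:
            raise ValueError("n_targets must be at least 4 (correlations degenerate)")
        if set(self.measure_loadings) != set(self.measure_reliabilities):
            raise ValueError("loadings and reliabilities must name the same measures")
        for m, lam in self.measure_loadings.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"loading of {m} outside [0, 1]")
            rel = self.measure_reliabilities[m]
            if not 0.0 < rel <= 1.0:
                raise ValueError(f"reliability of {m} outside (0, 1]")
        if not 0.0 <= self.informant_validity <= 1.0:
            raise ValueError("informant_validity outside [0, 1]")
        if not 0.0 <= self.informant_consensus <= 1.0:
            raise ValueError("informant_consensus outside [0, 1]")
        probs = self.informants_per_target
        if not probs or not set(probs) <= set(range(1, 7)):
            raise ValueError("informants_per_target must distribute over 1..6")
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise ValueError("informant count probabilities must sum to 1")
        for c, r in self.correlate_correlations.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlate correlation of {c} outside (-1, 1)")

    @property
    def measures(self) -> list[str]:
        return list(self.measure_loadings)

    @property
    def correlates(self) -> list[str]:
        return list(self.correlate_correlations)


def build_target_correlation(spec: LatentSpec) -> CorrelationMatrix:
    """Model-implied correlation matrix over all generated variables.

    Variables: self-rated measure scores, external correlates, and the
    single-informant rating of each measure (prefixed ``informant_``).
    Implied entries follow from the factor structure, e.g.
    ``corr(m, m') = loading_m * loading_m' * sqrt(rel_m * rel_m')``.
    The matrix is checked for positive semi-definiteness; an indefinite
    matrix within numerical tolerance (min eigenvalue > -1e-6) is
    repaired by eigenvalue clipping and rescaling, anything worse raises.
    """
    spec.validate()
    meas, corrs = spec.measures, spec.correlates
    lam = np.array([spec.measure_loadings[m] for m in meas])
    rel = np.array([spec.measure_reliabilities[m] for m in meas])
    c = np.array([spec.correlate_correlations[x] for x in corrs])
    v, a = spec.informant_validity, spec.informant_consensus

    # correlation of each variable with the latent trait
    self_l = lam * np.sqrt(rel)            # self measures
    inf_l = lam * np.sqrt(rel) * np.sqrt(a) * v  # informant measures via perception

    labels = meas + corrs + [f"informant_{m}" for m in meas]
    k = len(labels)
    r = np.eye(k)
    nm, nc = len(meas), len(corrs)
    # blocks: self-self, self-correlate, correlate-correlate follow a
    # one-factor structure; informant blocks share the perception factor
    for i in range(k):
        for j in range(i + 1, k):
            def trait_loading(idx: int) -> float:
                if idx < nm:
                    return self_l[idx]
                if idx < nm + nc:
                    return c[idx - nm]
                return inf_l[idx - nm - nc]

            both_informant = i >= nm + nc and j >= nm + nc
            if both_informant:
                # same informant's ratings share the full perception P_i
                ii, jj = i - nm - nc, j - nm - nc
                rij = lam[ii] * lam[jj] * np.sqrt(rel[ii] * rel[jj])
            else:
                rij = trait_loading(i) * trait_loading(j)
            r[i, j] = r[j, i] = rij

    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() < -1e-6:
        worst = np.unravel_index(np.argmax(np.abs(r - np.eye(k))), r.shape)
        raise ValueError(
            "implied correlation matrix is indefinite "
            f"(min eigenvalue {eigvals.min():.3g}); check entries such as "
            f"({labels[worst[0]]}, {labels[worst[1]]}) = {r[worst]:.3f}"
        )
    if eigvals.min() < 0:
        # nearest-correlation repair: clip tiny negative eigenvalues, rescale
        w, q = np.linalg.eigh(r)
        r = q @ np.diag(np.clip(w, 0, None)) @ q.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    frame = pd.DataFrame(r, index=labels, columns=labels)
    return CorrelationMatrix(values=frame, symmetric=True)


def sample_ratings(
    spec: LatentSpec, discretize: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a long-format rating table and a correlate table.

    Returns ``(ratings, correlates)``: ratings with columns
    (target, rater, role, wave, measure, score) containing one self-rating
    and 1-6 informant-ratings per target and measure; correlates with one
    row per target.  Scores are continuous by default; ``discretize=k``
    maps them onto a k-point scale via equal-probability thresholds.
    """
    spec.validate()
    build_target_correlation(spec)  # validates definiteness before sampling
    rng = np.random.default_rng(spec.seed)
    n = spec.n_targets
    meas, corrs = spec.measures, spec.correlates
    lam = np.array([spec.measure_loadings[m] for m in meas])
    rel = np.array([spec.measure_reliabilities[m] for m in meas])
    v, a = spec.informant_validity, spec.informant_consensus

    trait = rng.standard_normal(n)
    # self scores: X_m = sqrt(rel)*(lam*L + sqrt(1-lam^2)*U) + sqrt(1-rel)*E
    spec_fac = rng.standard_normal((n, len(meas)))
    err = rng.standard_normal((n, len(meas)))
    true_self = trait[:, None] * lam + spec_fac * np.sqrt(1.0 - lam**2)
    self_scores_arr = np.sqrt(rel) * true_self + np.sqrt(1.0 - rel) * err

    # correlates: C_j = c_j*L + sqrt(1-c_j^2)*noise
    cvec = np.array([spec.correlate_correlations[x] for x in corrs])
    cnoise = rng.standard_normal((n, len(corrs)))
    correlates_arr = trait[:, None] * cvec + cnoise * np.sqrt(1.0 - cvec**2)

    # shared informant perception per target: P = v*L + sqrt(1-v^2)*W
    perception = v * trait + np.sqrt(1.0 - v**2) * rng.standard_normal(n)

    counts = rng.choice(
        list(spec.informants_per_target),
        size=n,
        p=list(spec.informants_per_target.values()),
    )

    def maybe_discretize(x: np.ndarray) -> np.ndarray:
        if discretize is None:
            return x
        edges = np.quantile(x, np.linspace(0, 1, discretize + 1)[1:-1])
        return np.digitize(x, edges) + 1.0

    rows: list[tuple] = []
    targets = np.arange(n)
    for m_idx, m in enumerate(meas):
        for t, score in zip(targets, maybe_discretize(self_scores_arr[:, m_idx])):
            rows.append((t, f"self_{t}", "self", 1, m, score))
    total_raters = int(counts.sum())
    # informant i of target t: P_i = sqrt(a)*P_t + sqrt(1-a)*Q_i, then the
    # same measurement model as the self scores applied to P_i
    rater_target = np.repeat(targets, counts)
    q = rng.standard_normal(total_raters)
    p_i = np.sqrt(a) * perception[rater_target] + np.sqrt(1.0 - a) * q
    for m_idx, m in enumerate(meas):
        u = rng.standard_normal(total_raters)
        e = rng.standard_normal(total_raters)
        true_inf = lam[m_idx] * p_i + np.sqrt(1.0 - lam[m_idx] ** 2) * u
        y = np.sqrt(rel[m_idx]) * true_inf + np.sqrt(1.0 - rel[m_idx]) * e
        y = maybe_discretize(y)
        rater_idx = np.concatenate([np.arange(k) for k in counts])
        for t, ri, score in zip(rater_target, rater_idx, y):
            rows.append((t, f"inf_{t}_{ri}", "informant", 1, m, score))
    ratings = pd.DataFrame(rows, columns=["target", "rater", "role", "wave", "measure", "score"])
    correlate_table = pd.DataFrame(correlates_arr, columns=corrs)
    correlate_table.insert(0, "target", targets)
    correlate_table = correlate_table.set_index("target")
    return ratings, correlate_table


@dataclass
class SimplexSpec:
    """Parameters of the three-wave quasi-simplex generator."""

    n_subjects: int = 411
    reliability: float = 0.75
    stability: float = 0.9
    attrition_rates: tuple[float, float, float] = (1.0, 0.67, 0.67)
    seed: int = 0
    n_waves: int = 3  # fixed; the Heise identity needs exactly three

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        if not 0.0 < self.reliability <= 1.0:
            raise ValueError("reliability must lie in (0, 1]")
        if not -1.0 <= self.stability <= 1.0:
            raise ValueError("stability must lie in [-1, 1]")
        if self.n_waves != 3:
            raise ValueError("the design is fixed at three waves")
        if len(self.attrition_rates) != 3 or not all(
            0.0 < f <= 1.0 for f in self.attrition_rates
        ):
            raise ValueError("attrition_rates must be three retention fractions in (0, 1]")


def sample_three_wave(spec: SimplexSpec) -> pd.DataFrame:
    """Wide subject x wave table from the quasi-simplex model.

    Observed score at wave t is ``sqrt(rho)*T_t + sqrt(1-rho)*e_t`` with
    stationary true scores ``T_{t+1} = s*T_t + sqrt(1-s^2)*zeta``.  Each
    wave's retention fraction is applied as missing-completely-at-random
    dropout (independent across waves).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, rho, s = spec.n_subjects, spec.reliability, spec.stability
    t1 = rng.standard_normal(n)
    t2 = s * t1 + np.sqrt(1.0 - s**2) * rng.standard_normal(n)
    t3 = s * t2 + np.sqrt(1.0 - s**2) * rng.standard_normal(n)
    waves = []
    for t in (t1, t2, t3):
        waves.append(np.sqrt(rho) * t + np.sqrt(1.0 - rho) * rng.standard_normal(n))
    wide = pd.DataFrame(
        np.column_stack(waves), columns=["wave_1", "wave_2", "wave_3"]
    )
    wide.index.name = "subject"
    for col, keep in zip(wide.columns, spec.attrition_rates):
        if keep < 1.0:
            dropped = rng.random(n) >= keep
            wide.loc[dropped, col] = np.nan
    return wide
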
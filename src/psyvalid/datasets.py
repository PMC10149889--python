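"""Bundled reference correlation tables.

These are the printed correlation tables of a published three-study
validation of loneliness measures (self- and informant-rated multi-item
scales and single items), shipped as small CSVs so the matrix-comparison
and profile-similarity machinery can be exercised and checked without any
raw data.  Study 1: eight measures, many informants per target, thirty
external correlates.  Study 2: six measures rated by romantic partners,
twenty correlates.  Values are as printed (two decimals).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .correlations import CorrelationMatrix

__all__ = [
    "load_convergent",
    "load_nomological",
    "load_agreement",
    "load_published_profile_similarity",
]

_STUDY1_RATERS = ("self", "informant")
_STUDY2_RATERS = ("self", "partner")


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("psyvalid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kw)


def load_convergent(study: str) -> dict[str, CorrelationMatrix]:
    """Convergent-validity matrices of one study.

    Returns a dict keyed by rating perspective (``self`` and
    ``informant`` for study1, ``self`` and ``partner`` for study2) of
    symmetric :class:`CorrelationMatrix` objects over the study's
    loneliness measures.
    """
    if study == "study1":
        names = {r: f"convergent_study1_{r}.csv" for r in _STUDY1_RATERS}
    elif study == "study2":
        names = {r: f"convergent_study2_{r}.csv" for r in _STUDY2_RATERS}
    else:
        raise ValueError("study must be 'study1' or 'study2'")
    out = {}
    for rater, fname in names.items():
        frame = _read(fname, index_col="measure")
        out[rater] = CorrelationMatrix(values=frame, symmetric=True)
    return out


def load_nomological(study: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Nomological-net block of one study.

    Returns ``(block, domains)``: a correlates x measures DataFrame of
    printed correlations, and a mapping of each correlate to its domain
    (demography, personality, satisfaction, network).
    """
    if study not in ("study1", "study2"):
        raise ValueError("study must be 'study1' or 'study2'")
    frame = _read(f"nomological_{study}.csv", index_col="correlate")
    domains = frame.pop("domain").to_dict()
    return frame, domains


def load_agreement(study: str) -> pd.DataFrame:
    """Self x informant agreement matrix of one study (lower triangle as
    printed; unprinted upper-triangle cells are NaN)."""
    if study not in ("study1", "study2"):
        raise ValueError("study must be 'study1' or 'study2'")
    return _read(f"agreement_{study}.csv", index_col="measure")


def load_published_profile_similarity() -> pd.DataFrame:
    """Published double-entry ICC profile-similarity values (long format:
    measure_a, measure_b, icc_de, study), for cross-checking recomputed
    profile matrices."""
    return _read("profile_similarity_published.csv")
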
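"""Study-shaped orchestration: generate or load data, run every analysis
stage, and write the report bundle.

A run is described by a :class:`RunConfig` holding either a synthetic
generator spec or paths to long-format input tables, a set of analysis
toggles, and output options.  Outputs are delimited tables shaped like
the published report tables (convergent matrices, agreement tables,
nomological blocks with domain averages, profile matrices, reliability
rows) plus one machine-readable JSON summary per run; every number in a
display table is reproducible from the summary plus the rounding rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import nomonet, profiles
from .correlations import matrix_equality_test
from .heise import heise_with_bounds
from .simulate import LatentSpec, SimplexSpec, sample_ratings, sample_three_wave

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_validity_study", "run_heise_study", "load_config"]

ANALYSES = ("convergent", "agreement", "nomonet", "profiles")


def _round_half_away(x: float, ndigits: int) -> float:
    """Half-away-from-zero rounding, applied only at the display layer."""
    scale = 10.0**ndigits
    return float(np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one data source: either ``synthetic`` (a LatentSpec or
    SimplexSpec) or the input paths (``ratings_path`` etc.).
    """

    synthetic: LatentSpec | SimplexSpec | None = None
    ratings_path: str | None = None
    correlates_path: str | None = None
    metadata_path: str | None = None
    analyses: tuple[str, ...] = ANALYSES
    alpha: float = 0.001
    flag_alpha: float = 0.01
    rounding: int = 2
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        has_paths = self.ratings_path is not None
        if has_paths == (self.synthetic is not None):
            raise ValueError("exactly one of synthetic spec or input paths required")
        unknown = set(self.analyses) - set(ANALYSES) - {"heise"}
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        for a in (self.alpha, self.flag_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha thresholds must lie in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file.

    Recognized keys mirror the dataclass; a ``synthetic`` mapping with
    ``kind: latent`` or ``kind: simplex`` builds the generator spec.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    spec = None
    if syn is not None:
        kind = syn.pop("kind", "latent")
        spec = LatentSpec(**syn) if kind == "latent" else SimplexSpec(**syn)
    cfg = RunConfig(synthetic=spec, **raw)
    cfg.validate()
    return cfg


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        if not isinstance(config.synthetic, LatentSpec):
            raise ValueError("validity runs need a LatentSpec")
        spec = config.synthetic
        ratings, correlates = sample_ratings(spec)
        reliabilities = dict(spec.measure_reliabilities)
        return ratings, correlates, reliabilities
    ratings = pd.read_csv(config.ratings_path)
    correlates = (
        pd.read_csv(config.correlates_path).set_index("target")
        if config.correlates_path
        else None
    )
    reliabilities = {}
    if config.metadata_path:
        meta = pd.read_csv(config.metadata_path)
        reliabilities = dict(zip(meta["measure"], meta["reliability"]))
    missing = set()
    if reliabilities:
        missing = set(reliabilities) - set(ratings["measure"].unique())
        if missing:
            raise ValueError(f"metadata references unknown measures: {sorted(missing)}")
    return ratings, correlates, reliabilities


def run_validity_study(config: RunConfig) -> dict[str, Any]:
    """Run the toggled validity analyses and return the report bundle.

    The bundle maps stage names to DataFrames / result objects; when
    ``config.output_dir`` is set, display tables (rounded) and the
    machine-readable ``summary.json`` (full precision) are written there.
    """
    config.validate()
    ratings, correlates, reliabilities = _load_inputs(config)
    self_wide = agr.self_scores(ratings)
    inf_wide, inf_counts = agr.aggregate_informants(ratings)
    bundle: dict[str, Any] = {}
    summary: dict[str, Any] = {"seed": config.seed, "analyses": list(config.analyses)}

    if "convergent" in config.analyses:
        from .correlations import pairwise_correlations

        conv_self = pairwise_correlations(self_wide)
        conv_inf = pairwise_correlations(inf_wide)
        comparison = matrix_equality_test(
            conv_self,
            len(self_wide),
            conv_inf,
            len(inf_wide),
            dependent_samples=True,
        )
        # matrix-level profile similarity needs >= 3 comparable cells
        similarity = (
            profiles.matrix_profile_similarity(conv_self, conv_inf)
            if len(conv_self.row_labels) >= 3
            else float("nan")
        )
        bundle["convergent"] = {
            "self": conv_self,
            "informant": conv_inf,
            "comparison": comparison,
            "profile_similarity": similarity,
        }
        summary["convergent"] = {
            "self": conv_self.values.to_dict(),
            "informant": conv_inf.values.to_dict(),
            "mad": comparison.mad,
            "q": comparison.q_statistic,
            "df": comparison.df,
            "p": comparison.p_value,
            "icc_de": bundle["convergent"]["profile_similarity"],
        }

    if "agreement" in config.analyses:
        cross = agr.self_informant_matrix(self_wide, inf_wide)
        summaries = agr.agreement_summaries(self_wide, inf_wide, reliabilities)
        consensus = [
            agr.consensus_icc(ratings, m) for m in self_wide.columns
        ]
        bundle["agreement"] = {
            "matrix": cross,
            "summaries": summaries,
            "consensus": consensus,
        }
        summary["agreement"] = {
            "matrix": cross.values.to_dict(),
            "per_measure": [vars(s) for s in summaries],
            "consensus": [vars(c) for c in consensus],
        }

    block = None
    if correlates is not None and {"nomonet", "profiles"} & set(config.analyses):
        domains = {c: "correlate" for c in correlates.columns}
        block = nomonet.correlate_block(
            self_wide, correlates, domains, alpha_flags=(config.flag_alpha, config.alpha)
        )

    if "nomonet" in config.analyses and block is not None:
        scan = nomonet.pairwise_difference_scan(
            self_wide, correlates, alpha=config.alpha
        )
        bundle["nomonet"] = {
            "block": block,
            "averages": block.averages(),
            "pairwise_tests": scan,
        }
        summary["nomonet"] = {
            "block": block.values.to_dict(),
            "averages": block.averages().to_dict(),
            "pairwise_tests": scan.to_dict(orient="records"),
        }

    if "profiles" in config.analyses and block is not None:
        prof = profiles.profile_matrix(block.values)
        bundle["profiles"] = prof
        summary["profiles"] = prof.values.to_dict()

    bundle["summary"] = summary
    if config.output_dir:
        _write_bundle(bundle, config)
    return bundle


def run_heise_study(config: RunConfig) -> dict[str, Any]:
    """Three-wave single-item reliability, full sample and panel subset."""
    config.validate()
    if config.synthetic is not None:
        if not isinstance(config.synthetic, SimplexSpec):
            raise ValueError("heise runs need a SimplexSpec or a three-wave table")
        wide = sample_three_wave(config.synthetic)
    else:
        wide = pd.read_csv(config.ratings_path).set_index("subject")
    rows = {}
    for sample in ("full", "panel"):
        est = heise_with_bounds(wide, sample=sample)
        rows[sample] = est
    table = pd.DataFrame(
        {
            s: {
                "rxx": e.rxx, "lower": e.lower, "upper": e.upper,
                "r12": e.r12, "r23": e.r23, "r13": e.r13,
                "n12": e.n12, "n23": e.n23, "n13": e.n13,
            }
            for s, e in rows.items()
        }
    ).T
    bundle = {
        "estimates": rows,
        "table": table,
        "summary": {"seed": config.seed, "heise": table.to_dict()},
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.map(lambda x: _round_half_away(x, config.rounding)).to_csv(
            out / "reliability.csv"
        )
        _dump_summary(bundle["summary"], out)
    return bundle


def _dump_summary(summary: dict, out: Path) -> None:
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str)
    )


def _write_bundle(bundle: dict[str, Any], config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    nd = config.rounding

    def disp(frame: pd.DataFrame) -> pd.DataFrame:
        return frame.map(
            lambda x: _round_half_away(x, nd) if isinstance(x, float) else x
        )

    if "convergent" in bundle:
        disp(bundle["convergent"]["self"].values).to_csv(out / "convergent_self.csv")
        disp(bundle["convergent"]["informant"].values).to_csv(
            out / "convergent_informant.csv"
        )
    if "agreement" in bundle:
        disp(bundle["agreement"]["matrix"].values).to_csv(out / "agreement_matrix.csv")
        pd.DataFrame([vars(s) for s in bundle["agreement"]["summaries"]]).to_csv(
            out / "agreement_summaries.csv", index=False
        )
    if "nomonet" in bundle:
        disp(bundle["nomonet"]["block"].values).to_csv(out / "nomological_block.csv")
        disp(bundle["nomonet"]["averages"]).to_csv(out / "nomological_averages.csv")
        bundle["nomonet"]["pairwise_tests"].to_csv(
            out / "pairwise_tests.csv", index=False
        )
    if "profiles" in bundle:
        disp(bundle["profiles"].values).to_csv(out / "profile_similarity.csv")
    _dump_summary(bundle["summary"], out)
    logger.info("report bundle written to %s", out)
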
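"""End-to-end orchestration: simulate -> score -> consistency -> associate
-> features, from a single config, with a reproducibility manifest.

The default profile runs the full replication chain: simulate the three
cohorts (or load trial tables), compute categorizability, shrinkability,
exclusion-rate and distinctiveness scores, estimate split-half consistency
per paradigm, and run the association analyses in the original order —
the raw within-category z-scored correlations with memorability, the
distinctiveness correlations, the Bonferroni-corrected correlation matrix
over all measures, and finally the reanalysis: partial correlations of
categorizability and shrinkability with memorability controlling
perceived distinctiveness.

Every stage draws its seed from the manifest; rerunning with the same
config reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationReport,
    correlation_matrix,
    mean_vs_sd_correlation,
    partial_correlation,
    pearson_test,
    zscore_within_category,
    align_scores,
)
from .consistency import split_half_consistency
from .core import AnalysisConfig, ParameterError, logger
from .features import KDEConfig, kde_likelihood_scores, sparseness_scores
from .io import write_report, write_scores, write_trials, read_trials
from .scoring import (
    categorizability_scores,
    distinctiveness_scores,
    exclusion_rates,
    sdt_metrics,
    shrinkability_scores,
)
from .synthetic import (
    GenerativeParams,
    generate_feature_vectors,
    generate_image_population,
    simulate_categorization_study,
    simulate_rating_study,
    simulate_search_study,
)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "score", "consistency", "associate", "features")


@dataclass
class PipelineConfig:
    """What to run, from where, and with which parameters."""

    outdir: Path
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    generative: Optional[GenerativeParams] = None
    inputs: Dict[str, str] = field(default_factory=dict)
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    feature_dim: int = 16

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ParameterError(f"unknown stages: {sorted(unknown)}")
        needs_data = set(self.stages) & {"score", "consistency", "associate", "features"}
        if needs_data and "simulate" not in self.stages and not self.inputs:
            raise ParameterError(
                "stages requiring data need either the simulate stage or input paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "analysis" in raw:
            kwargs["analysis"] = AnalysisConfig(**raw["analysis"])
        if "generative" in raw:
            gen = dict(raw["generative"])
            if "rating_thresholds" in gen:
                gen["rating_thresholds"] = tuple(gen["rating_thresholds"])
            kwargs["generative"] = GenerativeParams(**gen)
        for key in ("outdir", "inputs", "stages", "feature_dim"):
            if key in raw:
                kwargs[key] = raw[key]
        if "outdir" not in kwargs:
            raise ParameterError("pipeline config requires an outdir")
        return cls(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages; returns (and writes) the run manifest.

    The manifest records the package version, every parameter and seed,
    and the path of every artifact written, and is itself written as
    ``manifest.json`` in the output directory. Stage failures keep the
    partial outputs and are recorded in the manifest before the exception
    propagates.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "gestaltmem",
        "version": __version__,
        "python": platform.python_version(),
        "analysis": _jsonable(config.analysis),
        "generative": _jsonable(config.generative) if config.generative else None,
        "stages": list(config.stages),
        "inputs": dict(config.inputs),
        "artifacts": {},
        "summary": {},
        "failed_stage": None,
    }
    art = manifest["artifacts"]
    cfg = config.analysis
    tables: Dict[str, pd.DataFrame] = {}
    traits = None
    feature_matrix = None

    try:
        if "simulate" in config.stages:
            params = config.generative or GenerativeParams(seed=cfg.seed)
            manifest["generative"] = _jsonable(params)
            refs, traits, mem = generate_image_population(params)
            tables["memorability"] = mem
            tables["study1"] = simulate_categorization_study(traits, params)
            tables["study2"] = simulate_search_study(traits, params, cfg.rt_limit)
            tables["study3"] = simulate_rating_study(traits, params)
            traits.to_csv(out / "traits.csv")
            art["traits.csv"] = str(out / "traits.csv")
            for name, schema in (("study1", "study1"), ("study2", "study2"),
                                 ("study3", "study3")):
                write_trials(tables[name], out / f"trials_{name}.csv", schema)
                art[f"trials_{name}.csv"] = str(out / f"trials_{name}.csv")
            write_scores(mem, out / "memorability.csv")
            art["memorability.csv"] = str(out / "memorability.csv")
            feature_matrix = generate_feature_vectors(traits, config.feature_dim, params)
            feature_matrix.to_csv(out / "features.csv", index_label="image_id")
            art["features.csv"] = str(out / "features.csv")
        else:
            from .io import read_features, read_scores
            loaders = {
                "study1": lambda p: read_trials(p, "study1"),
                "study2": lambda p: read_trials(p, "study2", rt_limit=cfg.rt_limit),
                "study3": lambda p: read_trials(
                    p, "study3", rating_bounds=(cfg.rating_min, cfg.rating_max)),
                "memorability": read_scores,
            }
            for name, loader in loaders.items():
                if name in config.inputs:
                    tables[name] = loader(config.inputs[name])
            if "features" in config.inputs:
                feature_matrix = read_features(config.inputs["features"])

        scores: Dict[str, pd.DataFrame] = {}
        if "memorability" in tables:
            scores["memorability"] = tables["memorability"]
        if "score" in config.stages:
            missing = {"study1", "study2", "study3"} - set(tables)
            if missing:
                raise ParameterError(
                    f"score stage needs trial tables for {sorted(missing)} "
                    "(simulate them or provide input paths)"
                )
            scores["categorizability"] = categorizability_scores(tables["study1"])
            scores["shrinkability"] = shrinkability_scores(tables["study2"], cfg.rt_limit)
            scores["exclusion_rate"] = exclusion_rates(tables["study2"])
            scores["distinctiveness"] = distinctiveness_scores(tables["study3"])
            sdt = sdt_metrics(tables["study1"], cfg.sdt_correction)
            sdt.to_csv(out / "sdt_metrics.csv", index=False)
            art["sdt_metrics.csv"] = str(out / "sdt_metrics.csv")
            for name in ("categorizability", "shrinkability", "exclusion_rate",
                         "distinctiveness"):
                write_scores(scores[name], out / f"scores_{name}.csv")
                art[f"scores_{name}.csv"] = str(out / f"scores_{name}.csv")
            manifest["summary"]["mean_d_prime"] = float(sdt["d_prime"].mean())
            manifest["summary"]["mean_beta"] = float(sdt["beta"].mean())
            manifest["summary"]["mean_exclusion_rate"] = float(
                scores["exclusion_rate"]["score"].mean()
            )

        if "consistency" in config.stages:
            for name, kind in (("study1", "categorizability"),
                               ("study2", "shrinkability"),
                               ("study3", "distinctiveness")):
                if name not in tables:
                    raise ParameterError(f"consistency stage needs {name} trials")
                res = split_half_consistency(
                    tables[name], kind, n_splits=cfg.n_splits,
                    seed=cfg.seed, rt_limit=cfg.rt_limit,
                )
                write_report(res, out / f"consistency_{kind}.json", "json")
                write_report(res, out / f"consistency_{kind}.csv", "csv")
                art[f"consistency_{kind}.json"] = str(out / f"consistency_{kind}.json")
                art[f"consistency_{kind}.csv"] = str(out / f"consistency_{kind}.csv")
                manifest["summary"][f"consistency_{kind}_mean_rho"] = float(
                    np.nanmean(list(res.mean_rho.values()))
                )

        if "features" in config.stages:
            if feature_matrix is None:
                raise ParameterError("features stage needs a feature matrix")
            scores["sparseness"] = sparseness_scores(feature_matrix, k=cfg.nn_rank)
            scores["cnn_likelihood"] = kde_likelihood_scores(
                feature_matrix, config=KDEConfig()
            )
            for name in ("sparseness", "cnn_likelihood"):
                write_scores(scores[name], out / f"scores_{name}.csv")
                art[f"scores_{name}.csv"] = str(out / f"scores_{name}.csv")

        if "associate" in config.stages:
            needed = {"categorizability", "shrinkability", "distinctiveness",
                      "memorability"}
            missing = needed - set(scores)
            if missing:
                raise ParameterError(
                    f"associate stage needs scores for {sorted(missing)}"
                )
            z = {k: zscore_within_category(scores[k]) for k in needed}
            aligned = align_scores(*(z[k] for k in sorted(needed)))
            report = AssociationReport(alpha=cfg.alpha, correction="none")
            report.add(pearson_test(
                aligned["categorizability"], aligned["memorability"],
                direction="greater", x_name="categorizability", y_name="memorability"))
            report.add(pearson_test(
                aligned["shrinkability"], aligned["memorability"],
                direction="less", x_name="shrinkability", y_name="memorability"))
            report.add(pearson_test(
                aligned["distinctiveness"], aligned["memorability"],
                direction="greater", x_name="distinctiveness", y_name="memorability"))
            report.add(pearson_test(
                aligned["distinctiveness"], aligned["categorizability"],
                direction="less", x_name="distinctiveness", y_name="categorizability"))
            report.add(pearson_test(
                aligned["distinctiveness"], aligned["shrinkability"],
                direction="less", x_name="distinctiveness", y_name="shrinkability"))
            report.add(partial_correlation(
                aligned["categorizability"], aligned["memorability"],
                aligned["distinctiveness"], direction="greater",
                x_name="categorizability", y_name="memorability",
                z_name="distinctiveness"))
            report.add(partial_correlation(
                aligned["shrinkability"], aligned["memorability"],
                aligned["distinctiveness"], direction="less",
                x_name="shrinkability", y_name="memorability",
                z_name="distinctiveness"))
            write_report(report, out / "associations.json", "json")
            art["associations.json"] = str(out / "associations.json")
            for e in report.entries:
                key = f"{e.stat}:{e.x}~{e.y}" + (f"|{e.partial_of}" if e.partial_of else "")
                manifest["summary"][key] = e.value

            matrix_vars = {k: aligned[k].to_numpy() for k in sorted(needed)}
            for extra in ("sparseness", "cnn_likelihood"):
                if extra in scores:
                    zx = zscore_within_category(scores[extra])
                    joined = zx.set_index("image_id")["score"].reindex(aligned.index)
                    if not joined.isna().any():
                        matrix_vars[extra] = joined.to_numpy()
            matrix = correlation_matrix(matrix_vars, "bonferroni", cfg.bonferroni_alpha)
            write_report(matrix, out / "correlation_matrix.json", "json")
            art["correlation_matrix.json"] = str(out / "correlation_matrix.json")

            ceiling = mean_vs_sd_correlation(scores["categorizability"])
            manifest["summary"]["categorizability_mean_vs_sd_r"] = ceiling.value

    except Exception as exc:
        manifest["failed_stage"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    art["manifest.json"] = str(out / "manifest.json")
    logger.info("pipeline complete: %d artifacts in %s", len(art), out)
    return manifest
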
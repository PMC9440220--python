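"""End-to-end orchestration: simulate/read -> impute -> test -> filter ->
call -> cluster -> PCA -> report.

A run is fully described by a :class:`RunConfig`; identical config + seed
yields byte-identical numeric outputs.  Every stage writes its artifact into
the output directory and contributes its feature counts to the
:class:`RunReport`, which mirrors the analysis funnel (features in ->
detected -> tested -> filter-passing -> clustered).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calls import (
    DEFAULT_INCLUSION,
    DEFAULT_VOLCANO,
    InclusionPolicy,
    VolcanoPolicy,
    apply_inclusion_filter,
    tabulate_tissue_summary,
    volcano_table,
)
from .errors import ConfigurationError, GnotodiffError, SchemaError
from .feature_table import FeatureTable, read_table, write_table
from .impute import DEFAULT_POLICY, ImputationPolicy, impute_table
from .multivariate import kmeans_clusters, pca_scores, z_normalize_rows
from .simulate import GroundTruth, SimulationConfig, simulate_feature_table
from .stats import DEFAULT_CONVENTION, FCConvention, differential_all_tissues

logger = logging.getLogger("gnotodiff")


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run.

    Either ``simulation`` is set (the input table is generated) or
    ``features_path``/``samples_path`` point at delimited files.  The
    effective config is written verbatim into the output directory.
    """

    simulation: SimulationConfig | None = None
    features_path: str | None = None
    samples_path: str | None = None
    imputation: ImputationPolicy = DEFAULT_POLICY
    fc_convention: FCConvention = DEFAULT_CONVENTION
    inclusion: InclusionPolicy = DEFAULT_INCLUSION
    volcano: VolcanoPolicy = DEFAULT_VOLCANO
    n_clusters: int = 10
    kmeans_restarts: int = 25
    pca_components: int = 2
    z_ddof: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None and (self.features_path is None or self.samples_path is None):
            raise ConfigurationError(
                "either simulation or features_path+samples_path must be provided"
            )
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be at least 1")
        if self.kmeans_restarts < 1:
            raise ConfigurationError("kmeans_restarts must be at least 1")
        if self.pca_components < 1:
            raise ConfigurationError("pca_components must be at least 1")
        if self.z_ddof not in (0, 1):
            raise ConfigurationError("z_ddof must be 0 (population SD) or 1 (sample SD)")

    # --------------------------------------------------------------- file I/O
    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config field(s): {sorted(unknown)}")
        if isinstance(data.get("simulation"), Mapping):
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        for key, factory in (
            ("imputation", ImputationPolicy),
            ("fc_convention", FCConvention),
            ("inclusion", InclusionPolicy),
            ("volcano", VolcanoPolicy),
        ):
            if isinstance(data.get(key), Mapping):
                data[key] = factory(**data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        out: dict[str, Any] = {}
        for key in self.__dataclass_fields__:
            val = getattr(self, key)
            if key == "simulation":
                out[key] = val.to_dict() if val is not None else None
            elif key in ("imputation", "fc_convention", "inclusion", "volcano"):
                d = asdict(val)
                if key == "volcano":
                    d["fc_windows"] = {k: list(v) for k, v in d["fc_windows"].items()}
                out[key] = d
            else:
                out[key] = val
        return out


@dataclass
class RunReport:
    """Stage-by-stage accounting of one run."""

    seed: int
    version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    tissue_summary: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_inputs(features_path: str | Path, samples_path: str | Path) -> list[str]:
    """All schema violations of an on-disk table (empty list when valid)."""
    for p in (features_path, samples_path):
        if not Path(p).exists():
            return [f"file not found: {p}"]
    try:
        read_table(features_path, samples_path)
    except SchemaError as exc:
        return [part.strip() for part in str(exc).split(";")]
    except GnotodiffError as exc:
        return [str(exc)]
    return []


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = RunReport(seed=config.seed, version=__version__)

    # stage 1: obtain the input table
    ground_truth: GroundTruth | None = None
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
        table, ground_truth = simulate_feature_table(sim)
        write_table(table, out / "features.tsv", out / "samples.tsv")
        ground_truth.table.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        report.notes.append("input simulated")
    else:
        table = read_table(config.features_path, config.samples_path)
        report.notes.append(f"input read from {config.features_path}")
    table.require_valid()
    report.stage_counts["features_in"] = table.n_features
    report.stage_counts["samples_in"] = table.n_samples
    logger.info("input: %d features x %d samples", table.n_features, table.n_samples)

    # stage 2: imputation (the imputed matrix is all downstream stages see)
    imputed, imp_report = impute_table(table, config.imputation)
    imp_report.to_csv(out / "imputation_report.tsv", sep="\t", index=False)
    report.stage_counts["imputation_cells_touched"] = len(imp_report)
    logger.info("imputation: %d (feature, tissue, group) cells touched", len(imp_report))

    # stage 3: tissue-wise differential testing
    records = differential_all_tissues(imputed, config.fc_convention)
    records.to_csv(out / "differential.tsv", sep="\t", index=False)
    tested = int((records["presence"] != "absent").sum())
    report.stage_counts["records_total"] = len(records)
    report.stage_counts["records_tested"] = tested
    logger.info("differential: %d records, %d tested", len(records), tested)

    # stage 4: inclusion filter
    filtered = apply_inclusion_filter(records, imputed.feature_meta, config.inclusion)
    filtered.to_csv(out / "filtered.tsv", sep="\t", index=False)
    report.stage_counts["records_significant"] = len(filtered)
    logger.info("filter: %d significant records", len(filtered))

    # stage 5: volcano coordinates
    volcano = volcano_table(records, config.volcano)
    volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
    report.stage_counts["volcano_highlighted"] = int(volcano["highlighted"].sum())

    # stage 6: per-tissue summaries
    summary = tabulate_tissue_summary(filtered, records, imputed)
    summary.to_csv(out / "tissue_summary.tsv", sep="\t", index=False)
    _write_json(out / "tissue_summary.json", summary.to_dict(orient="records"))
    report.tissue_summary = summary.to_dict(orient="records")

    # stage 7: k-means on the filter-passing features (z-scored rows)
    sig_features = pd.Index(sorted(set(filtered["feature_id"])))
    report.stage_counts["features_significant"] = len(sig_features)
    if len(sig_features) >= config.n_clusters:
        normalized = z_normalize_rows(imputed.abundance.loc[sig_features], ddof=config.z_ddof)
        model = kmeans_clusters(
            normalized,
            k=config.n_clusters,
            seed=config.seed,
            n_restarts=config.kmeans_restarts,
        )
        model.assignments.rename_axis("feature_id").to_frame().to_csv(
            out / "clusters.tsv", sep="\t"
        )
        report.stage_counts["features_clustered"] = len(model.assignments)
        if model.empty_clusters:
            report.notes.append(f"empty clusters: {model.empty_clusters}")
        if normalized.excluded:
            report.notes.append(f"{len(normalized.excluded)} constant rows excluded from clustering")
    else:
        report.stage_counts["features_clustered"] = 0
        report.notes.append(
            f"clustering skipped: {len(sig_features)} significant features < k={config.n_clusters}"
        )

    # stage 8: PCA of the full imputed matrix (unscaled)
    scores, evr = pca_scores(imputed.abundance, n_components=config.pca_components)
    scores = scores.join(imputed.sample_meta[["tissue", "group"]])
    scores.rename_axis("sample_id").to_csv(out / "pca_scores.tsv", sep="\t")
    _write_json(out / "explained_variance.json", [float(v) for v in evr])

    # effective config + report
    (out / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    _write_json(out / "run_report.json", report.to_dict())
    return report
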
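"""End-to-end orchestration: normalize -> cluster -> rank -> filter ->
classify -> screen -> enrich -> (optional) qPCR statistics.

Every artifact of a run is written deterministically (no timestamps inside
output files), so two runs with the same seed and configuration produce
byte-identical TSVs. The run log records the resolved configuration, a hash
of it, and library versions.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .cluster import cluster_samples, write_distance_matrix, write_newick
from .enrichment import category_percentages, write_category_report
from .expression import (read_expression_table,
                         read_gene_annotation, read_sample_metadata,
                         write_expression_table)
from .markers import (FilterCriteria, classify_flaws, rank_top_expressed,
                      select_category, stable_cec_filter,
                      stroma_absent_filter, write_marker_report)
from .normalize import rpm_normalize
from .qpcr import (DEFAULT_HOUSEKEEPING, delta_ct, read_ct_long,
                   relative_expression)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and options of a full analysis run."""

    expression_path: str
    metadata_path: str
    output_dir: str
    unit: str = "counts"
    annotation_path: str | None = None
    ct_path: str | None = None
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    transform: str = "log2p1"
    distance: str = "euclidean"
    linkage: str = "average"
    top_n: int = 20
    categories: tuple = ()
    housekeeping: tuple = DEFAULT_HOUSEKEEPING
    reference_sample: str = "cec_culture"
    seed: int = 0

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a YAML/JSON config file; keyword overrides win."""
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        criteria = FilterCriteria(**raw.pop("criteria", {}))
        raw.update(overrides)
        raw.setdefault("criteria", criteria)
        if isinstance(raw.get("categories"), list):
            raw["categories"] = tuple(raw["categories"])
        return cls(**raw)

    def resolved(self) -> dict:
        out = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.__dict__.items()}
        out["criteria"] = dict(self.criteria.__dict__)
        return out


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError(name, exc) from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a manifest of written artifacts."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(key: str, filename: str) -> Path:
        path = out_dir / filename
        artifacts[key] = str(path)
        return path

    # -- load + normalize ---------------------------------------------------
    matrix = _stage("load")(read_expression_table, config.expression_path,
                            config.unit)
    meta = _stage("load")(read_sample_metadata, config.metadata_path)
    annotation = (_stage("load")(read_gene_annotation, config.annotation_path)
                  if config.annotation_path else None)
    if matrix.unit == "counts":
        rpm = _stage("normalize")(rpm_normalize, matrix, meta)
    else:
        rpm = matrix
    _stage("normalize")(write_expression_table, rpm, emit("rpm", "rpm.tsv"))

    # -- clustering ---------------------------------------------------------
    dendrogram = _stage("cluster")(cluster_samples, rpm, config.transform,
                                   config.distance, config.linkage)
    _stage("cluster")(write_newick, dendrogram,
                      emit("dendrogram", "dendrogram.newick"))
    _stage("cluster")(write_distance_matrix, dendrogram,
                      emit("distances", "distances.tsv"))

    # -- rankings + filters -------------------------------------------------
    top = _stage("rank")(rank_top_expressed, rpm, meta, "cec_young",
                         min(config.top_n, len(rpm.gene_ids)))
    pd.Series(top, name="gene_id").to_csv(
        emit("top_expressed", "top_expressed.tsv"), sep="\t", index=False)

    stable = _stage("stable_filter")(stable_cec_filter, rpm, meta,
                                     config.criteria)
    _stage("stable_filter")(write_marker_report, stable,
                            emit("stable_markers", "stable_markers.tsv"))

    absent = _stage("stroma_absent_filter")(stroma_absent_filter, rpm, meta,
                                            config.criteria)
    _stage("stroma_absent_filter")(write_marker_report, absent,
                                   emit("stroma_absent", "stroma_absent.tsv"))

    # -- flaw classification ------------------------------------------------
    if annotation is not None:
        from .markers import build_record, class_rpms
        table = _stage("classify_flaws")(class_rpms, rpm, meta)
        flagged = [classify_flaws(build_record(g, row.to_dict()), annotation)
                   for g, row in table.iterrows()]
        _stage("classify_flaws")(write_marker_report, flagged,
                                 emit("flaws", "flaws.tsv"))

        for category in config.categories:
            records = _stage("category_screen")(
                select_category, rpm, meta, annotation, category,
                config.criteria)
            safe = category.replace(" ", "_").replace("/", "-")
            _stage("category_screen")(write_marker_report, records,
                                      emit(f"category_{category}",
                                           f"category_{safe}.tsv"))

        results = _stage("enrichment")(category_percentages, top, annotation,
                                       rpm.gene_ids)
        _stage("enrichment")(write_category_report, results,
                             emit("enrichment", "enrichment.tsv"))

    # -- optional qPCR ------------------------------------------------------
    if config.ct_path:
        table = _stage("qpcr")(read_ct_long, config.ct_path,
                               config.housekeeping)
        deltas = _stage("qpcr")(delta_ct, table)
        rel = _stage("qpcr")(relative_expression, deltas,
                             config.reference_sample)
        rel.reset_index().to_csv(emit("qpcr_relative", "qpcr_relative.tsv"),
                                 sep="\t", index=False, float_format="%.6g")

    # -- run log ------------------------------------------------------------
    resolved = config.resolved()
    config_hash = hashlib.sha256(
        json.dumps(resolved, sort_keys=True).encode()).hexdigest()
    log = {
        "config": resolved,
        "config_sha256": config_hash,
        "seed": config.seed,
        "versions": {"cecmarkers": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "scipy": scipy.__version__,
                     "click": importlib.metadata.version("click")},
        "artifacts": artifacts,
    }
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as handle:
        json.dump(log, handle, indent=1, sort_keys=True)
    artifacts["run_log"] = str(out_dir / "run_log.json")
    return artifacts
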
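"""Pipeline orchestration: align -> per-batch drift-correct -> normalise.

The three correction stages are independent and can be used alone or in
combination; the default order runs alignment first, since removing
batch-split noise features improves the drift-stage clustering, but
drift-first is equally valid and selectable.  A run consumes per-batch peak
tables (or generates them with the synthetic module), writes every
intermediate artifact as plain CSV/TSV, and records a machine-readable
manifest (versions, parameters, seed, per-stage feature counts) so a run is
reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .alignment import BatchAlignment
from .drift import DEFAULT_CLUSTER_GRID, DriftCorrectionModel
from .normalization import NormalizationModel
from .peak_table import PeakTable, read_peak_table, write_peak_table
from .simulate import SimulationConfig, simulate

__all__ = ["RunConfig", "PipelineResult", "run", "load_table_prefix", "write_table_prefix"]

_STAGES = ("align", "drift", "normalize")


@dataclass
class RunConfig:
    """Configuration of a full correction run.

    ``input_prefixes`` names existing tables (each prefix expands to
    ``<prefix>.csv``, ``<prefix>_meta.csv``, ``<prefix>_features.csv``);
    alternatively ``simulate`` holds generator parameters and the input is
    synthesised.  ``stages`` lists the stages to run, in order.
    """

    output_dir: str = "batchfix_run"
    input_prefixes: list[str] = field(default_factory=list)
    simulate: SimulationConfig | None = None
    stages: tuple[str, ...] = _STAGES
    seed: int = 1
    # alignment
    mz_tol: float = 0.002
    rt_tol: float = 15.0
    presence_threshold: float = 0.80
    presence_basis: str = "Ref"
    # drift
    cv_limit: float = 30.0
    cluster_grid: tuple[int, ...] = DEFAULT_CLUSTER_GRID
    spline_lam: float | None = None
    # normalisation
    ref_cv_limit: float = 0.3
    fold_limit: float = 5.0
    make_plots: bool = False

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {_STAGES}")
        if not self.input_prefixes and self.simulate is None:
            raise ValueError("config needs input_prefixes or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "cluster_grid" in raw:
            raw["cluster_grid"] = tuple(raw["cluster_grid"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Artifacts of a pipeline run, in memory plus their on-disk manifest."""

    tables: list[PeakTable]
    manifest: dict
    alignment: object | None = None
    drift: dict | None = None
    normalization: object | None = None

    @property
    def final_tables(self) -> list[PeakTable]:
        return self.tables


def load_table_prefix(prefix) -> PeakTable:
    p = Path(prefix)
    return read_peak_table(
        p.with_suffix(".csv"),
        p.parent / (p.name + "_meta.csv"),
        p.parent / (p.name + "_features.csv"),
        zero_as_missing=False,
    )


def write_table_prefix(table: PeakTable, prefix) -> None:
    p = Path(prefix)
    p.parent.mkdir(parents=True, exist_ok=True)
    write_peak_table(
        table,
        p.with_suffix(".csv"),
        p.parent / (p.name + "_meta.csv"),
        p.parent / (p.name + "_features.csv"),
    )


def run(config: RunConfig) -> PipelineResult:
    """Execute the configured stages and write all artifacts.

    Single-batch inputs skip alignment and normalisation (both are
    between-batch operations) with a note in the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "batchfix_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": _jsonable(dataclasses.asdict(config)),
        "stages": [],
    }

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        tables, truth = simulate(sim_cfg)
        for t in tables:
            write_table_prefix(t, out / "input" / f"batch_{t.batches[0]}")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "alias_groups": [sorted(g) for g in truth.alias_groups],
                    "batch_offsets": truth.batch_offsets,
                    "drift_pattern": truth.drift_pattern,
                },
                indent=2,
            )
        )
    else:
        tables = [load_table_prefix(p) for p in config.input_prefixes]
    single_batch = sum(len(t.batches) for t in tables) < 2

    result = PipelineResult(tables=tables, manifest=manifest)
    for stage in config.stages:
        if stage == "align":
            if single_batch:
                manifest["stages"].append(
                    {"stage": "align", "skipped": "single batch"}
                )
                continue
            model = BatchAlignment(
                tables,
                mz_tol=config.mz_tol,
                rt_tol=config.rt_tol,
                threshold=config.presence_threshold,
                basis=config.presence_basis,
            )
            res = model.fit()
            tables = res.apply()
            result.alignment = res
            res.log_frame().to_csv(out / "alignment_log.tsv", sep="\t", index=False)
            manifest["stages"].append(
                {
                    "stage": "align",
                    "features_in": len(res.presence.features),
                    "features_out": len(res.presence.features) - res.map.n_merges,
                    "candidates": len(res.candidates),
                    "events": len(res.events),
                    "groups": len(res.map.groups),
                }
            )
            for t in tables:
                write_table_prefix(t, out / "aligned" / f"batch_{t.batches[0]}")
        elif stage == "drift":
            drift_results = {}
            corrected = []
            for t in tables:
                batch = t.batches[0]
                res = DriftCorrectionModel(
                    t,
                    cv_limit=config.cv_limit,
                    cluster_grid=config.cluster_grid,
                    lam=config.spline_lam,
                    seed=config.seed,
                ).fit()
                drift_results[batch] = res
                corrected.append(res.filtered)
                res.cluster_report().to_csv(
                    out / f"cluster_report_{batch}.tsv", sep="\t", index=False
                )
                manifest["stages"].append(
                    {
                        "stage": "drift",
                        "batch": batch,
                        "features_in": t.n_features,
                        "features_out": res.filtered.n_features,
                        "clusters": res.n_clusters,
                        "clusters_corrected": sum(
                            c.action == "corrected" for c in res.clusters
                        ),
                    }
                )
                if config.make_plots:
                    from .report import cv_histogram

                    cv_histogram(
                        res.qc_cv("before"),
                        res.qc_cv("after"),
                        out / f"cv_histogram_{batch}.png",
                        cv_limit=config.cv_limit,
                    )
            tables = corrected
            result.drift = drift_results
            for t in tables:
                write_table_prefix(t, out / "corrected" / f"batch_{t.batches[0]}")
        elif stage == "normalize":
            if single_batch:
                manifest["stages"].append(
                    {"stage": "normalize", "skipped": "single batch"}
                )
                continue
            res = NormalizationModel(
                tables, cv_limit=config.ref_cv_limit, fold_limit=config.fold_limit
            ).fit()
            result.normalization = res
            res.decision_frame().to_csv(
                out / "normalization_decisions.tsv", sep="\t", index=False
            )
            tables = [res.normalized]
            write_table_prefix(res.normalized, out / "normalized")
            manifest["stages"].append(
                {
                    "stage": "normalize",
                    "common_features": len(res.common),
                    "reference_normalised": res.n_reference,
                    "population_normalised": len(res.decisions) - res.n_reference,
                }
            )
            if config.make_plots:
                from .report import pca_scores

                pca_scores(res.normalized, out / "pca_normalized.png", color_by="batch")

    result.tables = tables
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
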
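"""End-to-end orchestration: sketch -> search -> report.

A pipeline run is a pure function of (inputs, config, seed): the run
manifest records the tool version, the normalized configuration, input
and output checksums and the seed, and a rerun with the same config
produces byte-identical outputs.  Defaults mirror the reference study
design: k-mer sizes 21/31/51 with k=31 as the analysis size, scaled
1000, a 5% containment search threshold, 75/50/25/5% reporting
thresholds, and a 10% floor for map export.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .sketch import SketchParams, build_signature_from_files, save_signatures
from .search import (
    SignatureCollection,
    batch_search,
    hits_to_frame,
    write_hits,
)
from .report import (
    DEFAULT_THRESHOLDS,
    export_map_points,
    join_metadata,
    read_metadata,
    threshold_summary,
    write_geojson,
)

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Normalized configuration of one pipeline run."""

    queries: list[str]
    collection: str
    output_dir: str
    metadata: str | None = None
    ksizes: list[int] = field(default_factory=lambda: [21, 31, 51])
    analysis_ksize: int = 31
    scaled: int = 1000
    hash_seed: int = 42
    track_abundance: bool = True
    search_threshold: float = 0.05
    report_thresholds: list[float] = field(
        default_factory=lambda: list(DEFAULT_THRESHOLDS)
    )
    map_min_containment: float = 0.10
    distinct_threshold: float = 0.25
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(
    config: Mapping | RunConfig, base_dir: str | Path | None = None
) -> RunConfig:
    """Fill defaults, check invariants, resolve paths; reject unknown keys."""
    if isinstance(config, RunConfig):
        cfg = config
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(config) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for required in ("queries", "collection", "output_dir"):
            if required not in config:
                raise ConfigError(f"missing required config key {required!r}")
        try:
            cfg = RunConfig(**dict(config))
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    if not cfg.queries:
        raise ConfigError("queries must be a non-empty list")
    if cfg.analysis_ksize not in cfg.ksizes:
        raise ConfigError(
            f"analysis_ksize {cfg.analysis_ksize} not in ksizes {cfg.ksizes}"
        )
    ts = cfg.report_thresholds
    if any(ts[i] <= ts[i + 1] for i in range(len(ts) - 1)) or not ts:
        raise ConfigError(f"report_thresholds must be strictly descending: {ts}")
    for name in ("search_threshold", "map_min_containment", "distinct_threshold"):
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name} out of [0,1]: {v}")
    if cfg.scaled < 1:
        raise ConfigError(f"scaled must be >= 1: {cfg.scaled}")

    base = Path(base_dir) if base_dir is not None else Path.cwd()

    def _resolve(p: str) -> str:
        path = Path(p)
        return str(path if path.is_absolute() else base / path)

    cfg.queries = [_resolve(q) for q in cfg.queries]
    cfg.collection = _resolve(cfg.collection)
    if cfg.metadata is not None:
        cfg.metadata = _resolve(cfg.metadata)
    cfg.output_dir = _resolve(cfg.output_dir)
    for q in cfg.queries:
        if not Path(q).exists():
            raise ConfigError(f"query file not found: {q}")
    if not Path(cfg.collection).exists():
        raise ConfigError(f"collection not found: {cfg.collection}")
    if cfg.metadata is not None and not Path(cfg.metadata).exists():
        raise ConfigError(f"metadata file not found: {cfg.metadata}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; relative paths resolve against the
    config file's directory."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return validate_config(doc, base_dir=path.parent)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunResult:
    """Artifacts of a completed pipeline run."""

    output_dir: Path
    hits: pd.DataFrame
    summary: pd.DataFrame
    paths: dict[str, Path]
    manifest: dict


def run_pipeline(config: RunConfig | Mapping) -> RunResult:
    """Sketch queries, search the collection, and write all reports.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    run manifest is written last, so its presence marks a complete run.
    """
    cfg = validate_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_dir = out / "signatures"
    sig_dir.mkdir(exist_ok=True)
    stage_log: dict[str, float] = {}

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                stage_log[name] = dt
                if exc is None:
                    logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    # --- sketch queries -----------------------------------------------------
    query_sigs = []
    try:
        with _stage("sketch"):
            for qpath in cfg.queries:
                sigs = []
                for k in cfg.ksizes:
                    params = SketchParams(
                        ksize=k,
                        scaled=cfg.scaled,
                        hash_seed=cfg.hash_seed,
                        track_abundance=cfg.track_abundance,
                    )
                    name = Path(qpath).stem
                    sigs.append(
                        build_signature_from_files([qpath], params, name=name)
                    )
                save_signatures(sigs, sig_dir / f"{Path(qpath).stem}.sig")
                query_sigs.append(
                    next(s for s in sigs if s.params.ksize == cfg.analysis_ksize)
                )
    except Exception as exc:
        raise PipelineError("sketch", str(exc)) from exc

    # --- load collection ----------------------------------------------------
    try:
        with _stage("load_collection"):
            cpath = Path(cfg.collection)
            if cpath.is_dir():
                collection = SignatureCollection.from_directory(cpath)
            else:
                collection = SignatureCollection.from_manifest(cpath)
            if len(collection) == 0:
                logger.warning("collection is empty; reports will be empty")
    except Exception as exc:
        raise PipelineError("load_collection", str(exc)) from exc

    # --- search -------------------------------------------------------------
    try:
        with _stage("search"):
            if len(collection):
                hits = batch_search(query_sigs, collection, cfg.search_threshold)
            else:
                hits = []
            hits_frame = hits_to_frame(hits)
            hits_path = out / "hits.tsv"
            write_hits(hits_frame, hits_path)
    except Exception as exc:
        raise PipelineError("search", str(exc)) from exc

    # --- report -------------------------------------------------------------
    try:
        with _stage("report"):
            if cfg.metadata is not None:
                metadata = read_metadata(cfg.metadata)
            else:
                metadata = pd.DataFrame(
                    columns=["subject_id", "location_label", "latitude", "longitude"]
                )
            annotated = join_metadata(hits_frame, metadata)
            query_names = [s.name for s in query_sigs]
            summary = threshold_summary(
                annotated,
                cfg.report_thresholds,
                distinct_threshold=cfg.distinct_threshold,
                queries=query_names,
            )
            summary_path = out / "summary.tsv"
            summary.to_csv(summary_path, sep="\t", index=False)

            annotated_path = out / "annotated_hits.tsv"
            formatted = annotated.copy()
            for col in ("containment", "cani"):
                formatted[col] = formatted[col].map(lambda v: f"{v:.4f}")
            formatted.to_csv(annotated_path, sep="\t", index=False)

            map_path = out / "map.geojson"
            write_geojson(
                export_map_points(annotated, cfg.map_min_containment), map_path
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    # --- manifest -----------------------------------------------------------
    paths = {
        "hits": hits_path,
        "summary": summary_path,
        "annotated_hits": annotated_path,
        "map": map_path,
    }
    input_checksums = {Path(q).name: _sha256(q) for q in cfg.queries}
    cpath = Path(cfg.collection)
    if cpath.is_file():
        input_checksums[cpath.name] = _sha256(cpath)
    if cfg.metadata is not None:
        input_checksums[Path(cfg.metadata).name] = _sha256(cfg.metadata)
    manifest = {
        "tool": "fracmap",
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "inputs": input_checksums,
        "outputs": {k: _sha256(p) for k, p in sorted(paths.items())},
        "n_hits": int(len(hits_frame)),
        "n_subjects": len(collection),
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    logger.info("stage timings: %s", {k: round(v, 2) for k, v in stage_log.items()})

    return RunResult(
        output_dir=out,
        hits=hits_frame,
        summary=summary,
        paths=paths,
        manifest=manifest,
    )
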
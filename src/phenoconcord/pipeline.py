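"""End-to-end pipeline wiring the analysis stages together.

Stage order follows the analysis's dependency structure: semantic
similarity and score concordance feed the alignment regression;
stratification, diagnostic agreement and biomarker association each run
independently on the score table.  Every run writes a machine-readable
manifest (inputs, seeds, output SHA-256 hashes) so byte-identical
reproduction at a fixed master seed can be verified.

Sub-seeds for stochastic stages are derived from the master seed and the
stage name (CRC-32 of the name, XOR-folded with the seed), so toggling one
stage never perturbs another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker_association as bio
from . import diagnostic_agreement as diag
from . import score_concordance as conc
from . import semantic_similarity as sem
from . import stratification as strat
from .instruments_io import (
    InstrumentCatalog,
    load_biomarker_table,
    load_embedding_table,
    load_instrument_catalog,
    load_score_table,
    load_timeseries_long,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("semantic", "concordance", "stratification", "agreement", "biomarker")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, independent across stages."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Paths, stage toggles and parameters for one pipeline run."""

    catalog: str
    scores: str
    embeddings: str | None = None
    biomarkers: str | None = None
    timeseries: str | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    ks: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    n_boot: int = 100
    stratify_instruments: list[str] | None = None
    grid_a: list[int] = field(default_factory=lambda: list(diag.DEFAULT_GRID_ADOS))
    grid_b: list[int] = field(default_factory=lambda: list(diag.DEFAULT_GRID_ADIR))
    agreement_instruments: tuple[str, str] = ("ADOS", "ADIR")
    q: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "agreement_instruments" in data:
            data["agreement_instruments"] = tuple(data["agreement_instruments"])
        return cls(**data)

    def validate(self) -> None:
        needed = {"catalog": self.catalog, "scores": self.scores}
        if "semantic" in self.stages or "concordance" in self.stages:
            needed["embeddings"] = self.embeddings
        if "biomarker" in self.stages:
            needed["biomarkers"] = self.biomarkers
        for name, p in needed.items():
            if p is None:
                raise ValueError(f"stage configuration requires a {name} path")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, index=index, lineterminator="\n", float_format="%.10g")


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages and write outputs plus a manifest.

    Returns the manifest dict; any stage error aborts the run with the
    stage name attached, leaving already-written outputs flagged partial.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "inputs": {k: getattr(cfg, k) for k in
                   ("catalog", "scores", "embeddings", "biomarkers", "timeseries")
                   if getattr(cfg, k)},
        "outputs": {},
        "complete": False,
    }
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        _write_csv(df, path, index=index)
        written.append(path)

    catalog = load_instrument_catalog(cfg.catalog)
    table = load_score_table(cfg.scores, catalog)

    current = "setup"
    try:
        sim = None
        if "semantic" in cfg.stages:
            current = "semantic"
            clouds = load_embedding_table(cfg.embeddings, catalog)
            order = [s for s in catalog.subscore_ids() if s in clouds.clouds]
            sim = sem.similarity_matrix(clouds, subscores=order)
            emit(sim.similarity, "semantic_similarity.csv")
            emit(sim.raw_distances, "semantic_raw_distances.csv")

        if "concordance" in cfg.stages:
            current = "concordance"
            corr = conc.correlation_matrix(
                table, [s for s in (sim.subscores if sim else catalog.subscore_ids())
                        if s in table.values.columns])
            emit(corr.entries, "score_correlations.csv")
            if sim is not None and sim.subscores == corr.subscores:
                align = conc.alignment_coefficients(sim, corr)
                emit(align.to_frame(), "alignment_coefficients.csv")

        if "stratification" in cfg.stages:
            current = "stratification"
            instruments = cfg.stratify_instruments or [
                i for i in catalog.instrument_ids()
                if len([c for c in catalog.subscore_ids(i) if c in table.values.columns]) >= 2
            ]
            grid = strat.overlap_grid(
                table, catalog, instruments, ks=cfg.ks, n_boot=cfg.n_boot,
                seed=stage_seed(cfg.seed, "stratification"),
            )
            emit(grid, "stratification_overlap.csv", index=False)

        if "agreement" in cfg.stages:
            current = "agreement"
            inst_a, inst_b = cfg.agreement_instruments
            grid = diag.agreement_grid(table, inst_a, inst_b, cfg.grid_a, cfg.grid_b)
            emit(grid.to_long(), "agreement_grid.csv", index=False)

        if "biomarker" in cfg.stages:
            current = "biomarker"
            markers = load_biomarker_table(cfg.biomarkers)
            tests = bio.median_split_tests(table, markers, q=cfg.q)
            emit(bio.group_tests_frame(tests), "biomarker_group_tests.csv", index=False)
            metrics = [c for c in markers.scalars.columns if c != "prs"]
            if metrics:
                tiers = bio.tiered_correlations(table, markers, metrics=metrics)
                emit(bio.tiered_frame(tiers), "biomarker_tiered_correlations.csv", index=False)
            if cfg.timeseries:
                ts_map, labels = load_timeseries_long(cfg.timeseries)
                conns = {p: bio.connectivity_matrix(ts, labels) for p, ts in ts_map.items()}
                shared = [p for p in table.totals.index if p in conns]
                edges = bio.connectivity_associations(
                    {p: conns[p] for p in shared}, table.totals.loc[shared])
                emit(edges, "connectivity_associations.csv", index=False)
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["outputs"] = {p.name: _sha256(p) for p in written}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
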
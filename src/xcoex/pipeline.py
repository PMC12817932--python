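"""End-to-end pipeline with config, provenance, and deterministic seeding.

A :class:`PipelineConfig` names every input file, every threshold (with the
analysis defaults), the output directory, and the seed. ``run_pipeline``
executes normalize → (gmm | bgc) → network → stats in order, writes each
stage's artifacts as TSV/GraphML/JSON, and records provenance (config hash,
seed, record counts). A rerun with the same config and inputs is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as xio
from .errors import ConfigError, XcoexError
from .model import AnalysisOptions, CommunityCoexpression
from .stats import bootstrap_mean_shift, matched_module_correlations

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs, outputs, thresholds, and toggles of one pipeline run."""

    counts: str = ""
    taxa: str = ""
    metadata: str | None = None
    ko_table: str | None = None
    module_db: str | None = None
    gff: str | None = None
    regions: str | None = None
    out_dir: str = "xcoex_out"

    min_count: int = 10
    min_sample_frac: float = 0.5
    min_species_reads: int = 1000
    min_coverage: float = 0.5
    score_estimator: str = "median"
    max_gap: int = 300
    r_min: float = 0.5
    majority_frac: float = 0.7
    r_core: float = 0.5
    discrepancy: float = 0.3
    beta: float = 6.0
    min_weight: float = 0.2
    min_shared: int = 5
    iterations: int = 50_000
    seed: int = 0

    run_gmm: bool = True
    run_bgc: bool = True
    run_network: bool = True
    run_stats: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def options(self) -> AnalysisOptions:
        return AnalysisOptions(
            min_count=self.min_count,
            min_sample_frac=self.min_sample_frac,
            min_species_reads=self.min_species_reads,
            min_coverage=self.min_coverage,
            score_estimator=self.score_estimator,
            max_gap=self.max_gap,
            r_min=self.r_min,
            majority_frac=self.majority_frac,
            r_core=self.r_core,
            discrepancy=self.discrepancy,
            beta=self.beta,
            min_weight=self.min_weight,
            min_shared=self.min_shared,
        )

    def validate(self) -> None:
        self.options().validate()
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if not self.counts or not self.taxa:
            raise ConfigError("counts and taxa inputs are required")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_status(out: Path, status: dict) -> None:
    with open(out / "status.json", "w") as fh:
        json.dump(status, fh, indent=1)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every enabled stage; returns the artifact directory.

    Missing inputs fail before any stage runs; a stage failure retains the
    completed stages' outputs next to a status file naming the failed stage.
    """
    config.validate()
    inputs = {
        "counts": config.counts,
        "taxa": config.taxa,
        "metadata": config.metadata,
        "ko_table": config.ko_table,
        "module_db": config.module_db,
        "gff": config.gff,
        "regions": config.regions,
    }
    for name, path in inputs.items():
        if path and not Path(path).exists():
            raise ConfigError(f"input {name!r} not found: {path}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": [],
    }
    model = CommunityCoexpression.from_files(
        config.counts,
        config.taxa,
        metadata_path=config.metadata,
        ko_table_path=config.ko_table if config.run_gmm else None,
        module_db_path=config.module_db if config.run_gmm else None,
        gff_path=config.gff if config.run_bgc else None,
        regions_path=config.regions if config.run_bgc else None,
        options=config.options(),
    )
    try:
        result = _run_stages(model, config, out, status)
    except XcoexError as exc:
        status["failed"] = str(exc)
        _write_status(out, status)
        raise
    status["ok"] = True
    _write_status(out, status)
    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {
                "config_hash": config.digest(),
                "seed": config.seed,
                "config": dataclasses.asdict(config),
                "stages": status["stages"],
            },
            fh,
            indent=1,
        )
    return out


def _stage(status: dict, name: str, t0: float, **counts) -> None:
    status["stages"].append(
        {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **counts}
    )


def _run_stages(model: CommunityCoexpression, config: PipelineConfig, out: Path,
                status: dict):
    t0 = time.perf_counter()
    result = model.fit()
    norm = result.normalization
    norm_tbl = norm.transformed
    norm_tbl.index.name = "gene_id"
    norm_tbl.to_csv(out / "normalized.tsv", sep="\t")
    presence = norm.presence.astype(int)
    presence.index.name = "taxon"
    presence.to_csv(out / "presence.tsv", sep="\t")
    factors = norm.factors
    factors.index.name = "taxon"
    factors.to_csv(out / "tmm_factors.tsv", sep="\t")
    (out / "removed_genes.txt").write_text(
        "\n".join(norm.removed_genes) + ("\n" if norm.removed_genes else "")
    )
    _stage(status, "normalize", t0,
           genes=int(norm.values.shape[0]), removed=len(norm.removed_genes))

    if result.module_expression is not None:
        t0 = time.perf_counter()
        me = result.module_expression
        tbl = me.values.copy()
        tbl.insert(0, "coverage", me.coverage)
        tbl.to_csv(out / "modules.tsv", sep="\t")
        _stage(status, "gmm", t0, modules=int(len(me.values)))

    if result.subclusters is not None:
        t0 = time.perf_counter()
        rows = [
            {
                "cluster_id": sc.cluster_id,
                "parent_region_id": sc.parent_region_id,
                "suffix": sc.suffix,
                "members": ",".join(sc.member_genes),
                "core_genes": ",".join(sorted(sc.core_genes)),
                "status": sc.status,
                "reason": sc.reason or "",
            }
            for sc in result.subclusters
        ]
        pd.DataFrame(rows).to_csv(out / "subclusters.tsv", sep="\t", index=False)
        pd.DataFrame(result.bgc_audit or []).to_csv(
            out / "bgc_audit.tsv", sep="\t", index=False
        )
        if result.eigengenes:
            pd.DataFrame(result.eigengenes).T.to_csv(
                out / "eigengenes.tsv", sep="\t"
            )
        _stage(status, "bgc", t0, subclusters=len(result.subclusters))

    if config.run_network:
        t0 = time.perf_counter()
        xio.write_edge_table(result.edges, out / "edges.tsv")
        xio.write_graphml(result.network, out / "network.graphml")
        _stage(status, "network", t0,
               edges=int(len(result.edges)),
               retained=int(result.network.n_edges))

    if config.run_stats and result.module_expression is not None:
        t0 = time.perf_counter()
        me = result.module_expression
        pool_mask = (result.edges["removed_by"] == "none") & result.edges[
            "cross_species"
        ]
        pool = result.edges.loc[pool_mask, "r"].to_numpy()
        rows = []
        module_ids = sorted(
            {m for _, m in me.values.index}
        )
        for k, module_id in enumerate(module_ids):
            matched = matched_module_correlations(
                me, module_id, norm.presence,
                min_shared=config.min_shared, discrepancy=config.discrepancy,
            )
            if len(matched.values) == 0 or pool.size == 0:
                continue
            res = bootstrap_mean_shift(
                matched.values, pool,
                iterations=config.iterations, seed=config.seed + k,
            )
            rows.append(
                {
                    "module_id": module_id,
                    "n_taxa": matched.n_taxa,
                    "n_pairs": len(matched.values),
                    "observed_mean": res.observed_mean,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "p_high": res.p_high,
                    "p_low": res.p_low,
                }
            )
        pd.DataFrame(rows).to_csv(out / "stats.tsv", sep="\t", index=False)
        _stage(status, "stats", t0, modules_tested=len(rows))

    return result
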
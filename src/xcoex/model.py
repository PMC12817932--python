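"""Model/results interface for a full cross-species co-expression analysis.

:class:`CommunityCoexpression` is built from a count matrix (plus optional
KO assignments, a module database, gene annotations, and BGC regions);
``fit()`` runs filtering, per-taxon normalization, module scoring, BGC
refinement, correlation, edge filtering, and network assembly, and returns a
:class:`CoexpressionResults` carrying every intermediate product, the edge
table, the network, and the downstream statistical procedures
(bootstrap mean-shift tests, tail fractions, partner ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as xio
from .bgc import cluster_eigengene, filter_regions, refine_region
from .containers import CountMatrix, ModuleDatabase, NormalizedMatrix
from .errors import ConfigError
from .modules import aggregate_ko, score_modules
from .network import (
    CoexpressionNetwork,
    FeatureTable,
    build_network,
    correlate,
    discrepancy_filter,
)
from .normalization import filter_low_expression, normalize_per_taxon
from .stats import (
    bootstrap_mean_shift,
    matched_module_correlations,
    rank_partner,
    tail_fraction,
)

__all__ = ["AnalysisOptions", "CommunityCoexpression", "CoexpressionResults"]


@dataclass
class AnalysisOptions:
    """Thresholds of the analysis, with the pipeline defaults."""

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
    gene_level_discrepancy: bool = False  # discrepancy filter at gene level

    def validate(self) -> None:
        if self.min_count < 0 or not 0 <= self.min_sample_frac <= 1:
            raise ConfigError("low-expression filter parameters out of range")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        for name in ("min_coverage", "majority_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("r_min", "r_core"):
            if not -1 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [-1, 1]")
        if self.discrepancy < 0 or self.beta < 1 or self.min_weight < 0:
            raise ConfigError("discrepancy/beta/min_weight out of range")
        if self.min_shared < 2:
            raise ConfigError("min_shared must be >= 2")


class CommunityCoexpression:
    """Cross-species co-expression model of one community experiment."""

    def __init__(
        self,
        counts: CountMatrix,
        gene_kos: dict | None = None,
        module_db: ModuleDatabase | None = None,
        annotations=None,
        regions=None,
        options: AnalysisOptions | None = None,
    ) -> None:
        self.counts = counts
        self.gene_kos = gene_kos
        self.module_db = module_db
        self.annotations = (
            {a.gene_id: a for a in annotations} if annotations else None
        )
        self.regions = list(regions) if regions else None
        self.options = options or AnalysisOptions()
        self.options.validate()

    @classmethod
    def from_files(
        cls,
        counts_path,
        taxa_path,
        metadata_path=None,
        ko_table_path=None,
        module_db_path=None,
        gff_path=None,
        regions_path=None,
        options: AnalysisOptions | None = None,
    ) -> "CommunityCoexpression":
        counts = xio.read_counts(counts_path, taxa_path, metadata_path)
        gene_kos = xio.read_ko_table(ko_table_path) if ko_table_path else None
        db = xio.read_gmm_database(module_db_path) if module_db_path else None
        annotations = xio.read_gff3(gff_path) if gff_path else None
        regions = (
            xio.read_bgc_regions(regions_path, annotations)
            if regions_path
            else None
        )
        return cls(
            counts,
            gene_kos=gene_kos,
            module_db=db,
            annotations=annotations,
            regions=regions,
            options=options,
        )

    # ------------------------------------------------------------------
    def fit(self) -> "CoexpressionResults":
        opt = self.options
        filtered, removed = filter_low_expression(
            self.counts, min_count=opt.min_count, min_sample_frac=opt.min_sample_frac
        )
        norm = normalize_per_taxon(filtered, min_species_reads=opt.min_species_reads)
        norm.removed_genes = removed

        ko_matrix = None
        module_expr = None
        if self.gene_kos is not None and self.module_db is not None:
            ko_matrix = aggregate_ko(norm, self.gene_kos)
            module_expr = score_modules(
                ko_matrix,
                self.module_db,
                min_coverage=opt.min_coverage,
                estimator=opt.score_estimator,
            )

        subclusters = None
        audit = None
        eigengenes = None
        if self.regions is not None and self.annotations is not None:
            subclusters, audit, eigengenes = self._refine_bgcs(norm)

        if module_expr is not None and len(module_expr.values) > 0:
            features = FeatureTable.from_modules(module_expr, norm.presence)
            level = "module"
            apply_discrepancy = True
        else:
            features = FeatureTable.from_genes(norm)
            level = "gene"
            apply_discrepancy = opt.gene_level_discrepancy
        edges = correlate(features, min_shared=opt.min_shared)
        if apply_discrepancy:
            edges = discrepancy_filter(edges, max_gap=opt.discrepancy)
        network = build_network(
            edges,
            min_weight=opt.min_weight,
            beta=opt.beta,
            module_db=self.module_db,
        )
        return CoexpressionResults(
            model=self,
            normalization=norm,
            ko_matrix=ko_matrix,
            module_expression=module_expr,
            feature_level=level,
            features=features,
            edges=network.edges,
            network=network,
            subclusters=subclusters,
            bgc_audit=audit,
            eigengenes=eigengenes,
        )

    def _refine_bgcs(self, norm: NormalizedMatrix):
        opt = self.options
        expr = norm.transformed
        expressed = set(expr.index)
        subclusters = []
        for region in self.regions:
            scs, _ = refine_region(
                region, self.annotations, expr,
                max_gap=opt.max_gap, r_min=opt.r_min,
            )
            subclusters.extend(scs)
        retained, audit = filter_regions(
            subclusters, expressed, expr,
            majority_frac=opt.majority_frac, r_core=opt.r_core,
        )
        eigengenes = {}
        for sc in retained:
            members = [g for g in sc.member_genes if g in self.counts.genes]
            if len(members) >= 2:
                eig, _, _ = cluster_eigengene(members, self.counts.counts)
                eigengenes[sc.cluster_id] = eig
        return subclusters, audit, eigengenes


@dataclass
class CoexpressionResults:
    """Fitted co-expression analysis: estimates, network, and diagnostics."""

    model: CommunityCoexpression
    normalization: NormalizedMatrix
    ko_matrix: object
    module_expression: object
    feature_level: str
    features: FeatureTable
    edges: pd.DataFrame
    network: CoexpressionNetwork
    subclusters: list = None
    bgc_audit: list = None
    eigengenes: dict = None
    _extra: dict = field(default_factory=dict, repr=False)

    # -- statistics -----------------------------------------------------
    def bootstrap_mean_shift(self, observed, pool=None, iterations=50_000, seed=0):
        """Bootstrap mean-shift test; the default pool is every retained
        cross-species correlation value in the edge table."""
        if pool is None:
            ok = (self.edges["removed_by"] == "none") & self.edges["cross_species"]
            pool = self.edges.loc[ok, "r"].to_numpy()
        return bootstrap_mean_shift(observed, pool, iterations=iterations, seed=seed)

    def matched_module_correlations(self, module_id: str):
        if self.module_expression is None:
            raise ConfigError("no module expression in this fit")
        return matched_module_correlations(
            self.module_expression,
            module_id,
            self.normalization.presence,
            min_shared=self.model.options.min_shared,
            discrepancy=self.model.options.discrepancy,
        )

    def tail_fraction(self, threshold=0.8, exclude_taxon_pairs=()):
        return tail_fraction(
            self.edges[self.edges["removed_by"] == "none"],
            threshold=threshold,
            exclude_taxon_pairs=exclude_taxon_pairs,
        )

    def rank_partners(self, focal_feature: str, cross_species_only=True, by="r"):
        edges = self.edges[self.edges["removed_by"] == "none"]
        if cross_species_only:
            edges = edges[edges["cross_species"]]
        return rank_partner(focal_feature, edges, by=by)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        opt = self.model.options
        norm = self.normalization
        lines = [
            "Cross-species co-expression analysis",
            "=" * 44,
            f"taxa analysed:            {len(norm.presence.index) - len(norm.dropped_taxa)}"
            + (f" (dropped: {', '.join(norm.dropped_taxa)})" if norm.dropped_taxa else ""),
            f"samples:                  {norm.values.shape[1]}",
            f"genes passing filter:     {norm.values.shape[0]}"
            f" (removed {len(norm.removed_genes)})",
            f"feature level:            {self.feature_level}",
        ]
        if self.module_expression is not None:
            lines.append(
                f"modules scored:           {len(self.module_expression.values)}"
                f" (coverage >= {opt.min_coverage})"
            )
        if self.subclusters is not None:
            kept = sum(1 for s in self.subclusters if s.status == "retained")
            lines.append(
                f"BGC sub-clusters:         {kept} retained / {len(self.subclusters)}"
            )
        counts = self.edges["removed_by"].value_counts()
        lines += [
            f"feature pairs correlated: {len(self.edges)}",
            f"  removed (min samples):  {int(counts.get('min_samples', 0))}",
            f"  removed (discrepancy):  {int(counts.get('discrepancy', 0))}",
            f"  removed (zero var):     {int(counts.get('zero_variance', 0))}",
            f"network (beta={opt.beta:g}, |weight| > {opt.min_weight:g}): "
            f"{self.network.n_nodes} nodes, {self.network.n_edges} edges",
        ]
        cross = self.edges[
            (self.edges["removed_by"] == "none") & self.edges["cross_species"]
        ]
        if len(cross) > 0:
            top = cross.reindex(cross["r"].abs().sort_values(ascending=False).index)
            lines.append("strongest cross-species edges:")
            for _, row in top.head(5).iterrows():
                lines.append(
                    f"  {row['taxon_a']}:{row['feature_a']} -- "
                    f"{row['taxon_b']}:{row['feature_b']}  r={row['r']:+.3f} "
                    f"(n={int(row['n_shared'])})"
                )
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot_edge_histogram(self, ax=None, cross_only=True, bins=40):
        """Histogram of retained correlation values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        edges = self.edges[self.edges["removed_by"] == "none"]
        if cross_only:
            edges = edges[edges["cross_species"]]
        ax.hist(edges["r"].dropna(), bins=bins, range=(-1, 1), color="#4878b0")
        ax.set_xlabel("Pearson r")
        ax.set_ylabel("feature pairs")
        ax.set_title("cross-species co-expression" if cross_only else "co-expression")
        return ax

    def plot_network(self, ax=None, seed=0):
        """Spring-layout sketch of the thresholded network, colored by taxon."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        g = self.network.graph
        taxa = sorted({d["taxon"] for _, d in g.nodes(data=True)})
        cmap = plt.get_cmap("tab20")
        colors = [cmap(taxa.index(d["taxon"]) % 20) for _, d in g.nodes(data=True)]
        pos = nx.spring_layout(g, seed=seed)
        nx.draw_networkx(
            g, pos=pos, ax=ax, node_color=colors, node_size=60,
            with_labels=False, edge_color="#999999",
        )
        ax.set_axis_off()
        return ax
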
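"""Within- and cross-species co-expression: correlation, filtering, scaling.

Features (genes, metabolic modules, or BGC sub-cluster summaries) are
correlated pairwise with Pearson's r and Spearman's rho over the samples in
which *both* taxa are present. Edges whose Pearson and Spearman coefficients
disagree by more than a threshold are removed (outlier-driven correlations),
and the surviving correlations are scaled with a sign-preserving power
function, ``weight = sign(r) * |r|^beta`` (default beta 6, selectable by
scale-free topology fit as in WGCNA). Cluster-level correlations are
summarized by Fisher z-averaging all inter-cluster gene-gene coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ModuleDatabase, ModuleExpressionMatrix, NormalizedMatrix
from .errors import ConfigError
from .modules import shared_ko_fraction

__all__ = [
    "FeatureTable",
    "correlate",
    "cross_species_abs_r",
    "discrepancy_filter",
    "signed_power",
    "weight_to_r",
    "pick_soft_threshold",
    "SoftThresholdResult",
    "cluster_correlation",
    "fisher_mean",
    "CoexpressionNetwork",
    "build_network",
]

_CLIP = 1.0 - 1e-6


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Expression features aligned to a common sample universe.

    ``values`` rows are indexed by (taxon, kind, feature_id); ``presence`` is
    the taxon × sample boolean matrix from the normalization stage. Samples
    where a feature's taxon is absent must be NaN in ``values``.
    """

    values: pd.DataFrame
    presence: pd.DataFrame

    @classmethod
    def from_genes(cls, norm: NormalizedMatrix) -> "FeatureTable":
        """Gene-level features on the arcsinh scale."""
        t = norm.transformed
        index = pd.MultiIndex.from_arrays(
            [norm.gene_taxon.to_numpy(), ["gene"] * len(t), t.index],
            names=["taxon", "kind", "feature"],
        )
        return cls(values=pd.DataFrame(t.to_numpy(), index=index, columns=t.columns),
                   presence=norm.presence)

    @classmethod
    def from_modules(
        cls, mods: ModuleExpressionMatrix, presence: pd.DataFrame
    ) -> "FeatureTable":
        v = mods.values
        index = pd.MultiIndex.from_arrays(
            [
                v.index.get_level_values("taxon"),
                ["module"] * len(v),
                v.index.get_level_values("module_id"),
            ],
            names=["taxon", "kind", "feature"],
        )
        return cls(values=pd.DataFrame(v.to_numpy(), index=index, columns=v.columns),
                   presence=presence)

    @classmethod
    def from_profiles(
        cls, profiles: dict, taxa: dict, presence: pd.DataFrame, kind: str = "cluster"
    ) -> "FeatureTable":
        """Arbitrary named sample profiles (e.g. BGC sub-cluster eigengenes)."""
        names = list(profiles)
        data = np.vstack([np.asarray(profiles[n], dtype=float) for n in names])
        index = pd.MultiIndex.from_arrays(
            [[taxa[n] for n in names], [kind] * len(names), names],
            names=["taxon", "kind", "feature"],
        )
        return cls(
            values=pd.DataFrame(data, index=index, columns=presence.columns),
            presence=presence,
        )

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.values.index.get_level_values("taxon"):
            seen.setdefault(t, None)
        return list(seen)


def _taxon_block(features: FeatureTable, taxon: str):
    mask = features.values.index.get_level_values("taxon") == taxon
    block = features.values.loc[mask]
    if taxon in features.presence.index:
        present = features.presence.loc[taxon].to_numpy(dtype=bool)
    else:
        present = np.ones(features.values.shape[1], dtype=bool)
    # a sample only counts when the block actually carries data there
    has_data = np.isfinite(block.to_numpy()).any(axis=0)
    return block, present & has_data


def _block_correlations(a: np.ndarray, b: np.ndarray):
    """Pearson and Spearman matrices between the rows of two blocks."""
    def pearson(x, y):
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        xs = np.sqrt((xc**2).sum(axis=1))
        ys = np.sqrt((yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ yc.T) / np.outer(xs, ys)
        return np.clip(r, -1.0, 1.0)

    ra = np.apply_along_axis(rankdata, 1, a)
    rb = np.apply_along_axis(rankdata, 1, b)
    return pearson(a, b), pearson(ra, rb)


def correlate(
    features: FeatureTable,
    min_shared: int = 5,
    include_within: bool = True,
) -> pd.DataFrame:
    """All pairwise feature correlations as an edge table.

    For each unordered feature pair the samples are restricted to those where
    both taxa are present and both values are non-missing; Pearson r and
    Spearman rho are computed over those samples and the shared sample count
    is recorded. Pairs below ``min_shared`` are marked
    ``removed_by=min_samples``; zero-variance pairs ``removed_by=zero_variance``
    (recorded, not emitted into networks). Self-pairs and duplicate unordered
    pairs are excluded at construction.
    """
    taxa = features.taxa()
    blocks = {t: _taxon_block(features, t) for t in taxa}
    records: list[dict] = []

    def emit(block_a, block_b, r, rho, n_shared, cross, iu=None):
        idx_a = block_a.index
        idx_b = block_b.index
        if iu is None:
            rows, cols = np.meshgrid(
                np.arange(len(idx_a)), np.arange(len(idx_b)), indexing="ij"
            )
            rows, cols = rows.ravel(), cols.ravel()
        else:
            rows, cols = iu
        for i, j in zip(rows, cols):
            ta, ka, fa = idx_a[i]
            tb, kb, fb = idx_b[j]
            rv = r[i, j]
            rhov = rho[i, j]
            if n_shared < min_shared:
                removed = "min_samples"
            elif not np.isfinite(rv) or not np.isfinite(rhov):
                removed = "zero_variance"
            else:
                removed = "none"
            records.append(
                {
                    "taxon_a": ta, "kind_a": ka, "feature_a": fa,
                    "taxon_b": tb, "kind_b": kb, "feature_b": fb,
                    "r": rv, "rho": rhov, "n_shared": n_shared,
                    "cross_species": cross, "removed_by": removed,
                }
            )

    for ia, ta in enumerate(taxa):
        block_a, mask_a = blocks[ta]
        if include_within and len(block_a) > 1:
            cols = np.flatnonzero(mask_a)
            n_shared = len(cols)
            if n_shared >= 2:
                sub = block_a.to_numpy()[:, cols]
                r, rho = _block_correlations(sub, sub)
            else:
                r = rho = np.full((len(block_a),) * 2, np.nan)
            iu = np.triu_indices(len(block_a), k=1)
            emit(block_a, block_a, r, rho, n_shared, False, iu=iu)
        for tb in taxa[ia + 1:]:
            block_b, mask_b = blocks[tb]
            cols = np.flatnonzero(mask_a & mask_b)
            n_shared = len(cols)
            if n_shared >= 2:
                r, rho = _block_correlations(
                    block_a.to_numpy()[:, cols], block_b.to_numpy()[:, cols]
                )
            else:
                r = np.full((len(block_a), len(block_b)), np.nan)
                rho = r
            emit(block_a, block_b, r, rho, n_shared, True)

    edges = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=[
            "taxon_a", "kind_a", "feature_a", "taxon_b", "kind_b", "feature_b",
            "r", "rho", "n_shared", "cross_species", "removed_by",
        ]
    )
    return edges


def cross_species_abs_r(features: FeatureTable, min_shared: int = 5) -> np.ndarray:
    """Flat array of |Pearson r| over all cross-species feature pairs.

    Block-wise computation that never materializes an edge table; intended
    for large gene-level scans (tail fractions, quantiles, maxima).
    """
    taxa = features.taxa()
    blocks = {t: _taxon_block(features, t) for t in taxa}
    out: list[np.ndarray] = []
    for ia, ta in enumerate(taxa):
        block_a, mask_a = blocks[ta]
        for tb in taxa[ia + 1:]:
            block_b, mask_b = blocks[tb]
            cols = np.flatnonzero(mask_a & mask_b)
            if len(cols) < max(min_shared, 2):
                continue
            a = block_a.to_numpy()[:, cols]
            b = block_b.to_numpy()[:, cols]
            ac = a - a.mean(axis=1, keepdims=True)
            bc = b - b.mean(axis=1, keepdims=True)
            sa = np.sqrt((ac**2).sum(axis=1))
            sb = np.sqrt((bc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (ac @ bc.T) / np.outer(sa, sb)
            r = r[np.isfinite(r)]
            out.append(np.abs(np.clip(r.ravel(), -1, 1)))
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# filters and scaling
# ---------------------------------------------------------------------------

def discrepancy_filter(edges: pd.DataFrame, max_gap: float = 0.3) -> pd.DataFrame:
    """Mark edges where |r - rho| strictly exceeds ``max_gap``.

    A large Pearson–Spearman gap indicates an outlier-driven correlation;
    such edges get ``removed_by=discrepancy``. The boundary |r - rho| ==
    max_gap is kept. Returns a copy.
    """
    edges = edges.copy()
    gap = (edges["r"] - edges["rho"]).abs()
    hit = (gap > max_gap) & (edges["removed_by"] == "none")
    edges.loc[hit, "removed_by"] = "discrepancy"
    return edges


def signed_power(r, beta: float = 6):
    """Sign-preserving power scaling, ``weight = sign(r) * |r|^beta``."""
    r = np.asarray(r, dtype=float)
    out = np.sign(r) * np.abs(r) ** beta
    return out if out.ndim else float(out)


def weight_to_r(weight: float, beta: float = 6) -> float:
    """|r| at which the signed power weight reaches ``weight`` (inverse map)."""
    return float(np.abs(weight) ** (1.0 / beta))


@dataclass
class SoftThresholdResult:
    beta: float
    fit_table: pd.DataFrame  # columns beta, fit, slope, r2, mean_k


def pick_soft_threshold(
    edges: pd.DataFrame,
    beta_grid=range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the scaling power by scale-free topology fit (WGCNA-style).

    For each candidate beta, node connectivity ``k_i = sum_j |r_ij|^beta`` is
    computed from the edge list, log-binned, and log(frequency) regressed on
    log(k); the fit index is ``-sign(slope) * R^2`` so that only
    negative-slope (scale-free-like) fits count. Returns the smallest beta
    whose fit reaches ``target_r2``, else the argmax.
    """
    usable = edges[np.isfinite(edges["r"])]
    if len(usable) == 0:
        raise ConfigError("no finite correlations to fit")
    node_a = usable[["taxon_a", "kind_a", "feature_a"]].apply(tuple, axis=1)
    node_b = usable[["taxon_b", "kind_b", "feature_b"]].apply(tuple, axis=1)
    nodes = pd.Index(pd.concat([node_a, node_b]).unique())
    if len(nodes) < 20:
        raise ConfigError("soft-threshold selection needs at least 20 nodes")
    ia = nodes.get_indexer(node_a)
    ib = nodes.get_indexer(node_b)
    absr = usable["r"].abs().to_numpy()
    if np.allclose(absr, absr[0]):
        raise ConfigError("degenerate network: all |r| identical")

    rows = []
    for beta in beta_grid:
        k = np.zeros(len(nodes))
        w = absr**beta
        np.add.at(k, ia, w)
        np.add.at(k, ib, w)
        k = k[k > 0]
        logk = np.log10(k)
        edges_bins = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
        which = np.digitize(logk, edges_bins) - 1
        which = np.clip(which, 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = which == b
            if not sel.any():
                continue
            xs.append(np.mean(logk[sel]))
            ys.append(np.log10(sel.sum() / len(logk)))
        xs, ys = np.array(xs), np.array(ys)
        if len(xs) < 3 or np.ptp(xs) == 0:
            fit, slope, r2 = np.nan, np.nan, np.nan
        else:
            slope, intercept = np.polyfit(xs, ys, 1)
            pred = slope * xs + intercept
            ss_res = ((ys - pred) ** 2).sum()
            ss_tot = ((ys - ys.mean()) ** 2).sum()
            r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
            fit = -np.sign(slope) * r2
        rows.append(
            {"beta": beta, "fit": fit, "slope": slope, "r2": r2, "mean_k": k.mean()}
        )
    table = pd.DataFrame(rows)
    good = table[table["fit"] >= target_r2]
    if len(good) > 0:
        beta = float(good.iloc[0]["beta"])
    else:
        beta = float(table.loc[table["fit"].idxmax(), "beta"])
    return SoftThresholdResult(beta=beta, fit_table=table)


# ---------------------------------------------------------------------------
# cluster-level correlation
# ---------------------------------------------------------------------------

def fisher_mean(r_values) -> float:
    """tanh of the mean of atanh(r), with r clipped away from ±1."""
    r = np.clip(np.asarray(r_values, dtype=float), -_CLIP, _CLIP)
    return float(np.tanh(np.arctanh(r).mean()))


def cluster_correlation(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame, min_shared: int = 5
) -> tuple[float, int]:
    """Fisher z-averaged mean of all inter-cluster gene-gene Pearson r.

    ``expr_a`` and ``expr_b`` are gene × sample expression frames of the two
    clusters (NaN for missing samples). Every pair is computed over the
    samples where both genes are observed. Returns ``(r_mean, n_pairs)``;
    with no valid pair the mean is NaN and the pair count 0.
    """
    zs: list[float] = []
    for _, row_a in expr_a.iterrows():
        a = row_a.to_numpy(dtype=float)
        for _, row_b in expr_b.iterrows():
            b = row_b.to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < max(min_shared, 2):
                continue
            x, y = a[ok], b[ok]
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            zs.append(np.arctanh(np.clip(r, -_CLIP, _CLIP)))
    if not zs:
        return float("nan"), 0
    return float(np.tanh(np.mean(zs))), len(zs)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    """A thresholded co-expression network plus the parameters that built it."""

    graph: nx.Graph
    beta: float
    min_weight: float
    edges: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _node_id(taxon: str, kind: str, feature: str) -> str:
    return f"{taxon}|{kind}|{feature}"


def build_network(
    edges: pd.DataFrame,
    min_weight: float = 0.2,
    beta: float = 6,
    drop_singletons: bool = True,
    module_db: ModuleDatabase | None = None,
) -> CoexpressionNetwork:
    """Scale, threshold, and assemble the co-expression network.

    Edges removed by earlier filters are never included. Retained edges have
    ``|weight| > min_weight`` with ``weight = sign(r)|r|^beta``. Within-species
    edges between modules are annotated with the fraction of shared KOs (when
    a module database is supplied) so that consumers can exclude edges whose
    correlation is inflated by definition overlap.
    """
    edges = edges.copy()
    edges["weight"] = signed_power(edges["r"].to_numpy(), beta=beta)
    edges["shared_ko_fraction"] = np.nan
    if module_db is not None:
        within_mod = (
            (~edges["cross_species"])
            & (edges["kind_a"] == "module")
            & (edges["kind_b"] == "module")
        )
        for i in edges.index[within_mod]:
            fa, fb = edges.at[i, "feature_a"], edges.at[i, "feature_b"]
            if fa in module_db and fb in module_db:
                edges.at[i, "shared_ko_fraction"] = shared_ko_fraction(
                    module_db[fa], module_db[fb]
                )
    keep = (edges["removed_by"] == "none") & (edges["weight"].abs() > min_weight)
    retained = edges[keep]

    graph = nx.Graph(beta=beta, min_weight=min_weight)
    if not drop_singletons:
        all_nodes = pd.concat(
            [
                edges[["taxon_a", "kind_a", "feature_a"]].rename(
                    columns=lambda c: c[:-2]
                ),
                edges[["taxon_b", "kind_b", "feature_b"]].rename(
                    columns=lambda c: c[:-2]
                ),
            ]
        ).drop_duplicates()
        for _, row in all_nodes.iterrows():
            graph.add_node(
                _node_id(row["taxon"], row["kind"], row["feature"]),
                taxon=row["taxon"], kind=row["kind"], label=row["feature"],
            )
    for _, row in retained.iterrows():
        u = _node_id(row["taxon_a"], row["kind_a"], row["feature_a"])
        v = _node_id(row["taxon_b"], row["kind_b"], row["feature_b"])
        graph.add_node(u, taxon=row["taxon_a"], kind=row["kind_a"],
                       label=row["feature_a"])
        graph.add_node(v, taxon=row["taxon_b"], kind=row["kind_b"],
                       label=row["feature_b"])
        graph.add_edge(
            u, v,
            r=float(row["r"]), rho=float(row["rho"]), weight=float(row["weight"]),
            n_shared=int(row["n_shared"]),
            cross_species=bool(row["cross_species"]),
            shared_ko_fraction=(
                float(row["shared_ko_fraction"])
                if np.isfinite(row["shared_ko_fraction"])
                else ""
            ),
        )
    return CoexpressionNetwork(
        graph=graph, beta=beta, min_weight=min_weight, edges=edges
    )
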
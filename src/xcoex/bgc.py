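"""Refinement and filtering of biosynthetic gene cluster (BGC) regions.

antiSMASH delimits BGC regions with fixed offsets around its detection rules,
so regions routinely include flanking genes that are not part of the
biosynthetic operon. Refinement splits each region into runs of genes that
are both co-located (intergenic distance at most ``max_gap`` bp between
genomic neighbours) and co-expressed (Pearson r above ``r_min``); the runs
become sub-clusters named by suffix (``BGC_1.9a``, ``BGC_1.9b``, ...) in
coordinate order. A sub-cluster without a core biosynthetic gene is
discarded. Retention filters then remove clusters whose core genes are not
expressed, whose members mostly fail the low-expression filter, or whose
core genes are not co-expressed with any other member.

Cluster activity is summarized by the eigengene: the first principal
component of the members' scaled, log2-transformed counts, sign-aligned with
the mean member profile.
"""

from __future__ import annotations

import string

import numpy as np
import pandas as pd

from .containers import (
    BGCRegion,
    GeneAnnotation,
    NormalizedMatrix,
    SubCluster,
    intergenic_distance,
)
from .errors import CrossReferenceError, FormatError, XcoexError

__all__ = [
    "refine_region",
    "filter_regions",
    "cluster_eigengene",
]


def _suffixes():
    # a..z, then aa, ab, ... — regions never get close to 26 sub-clusters,
    # but the naming should not break if one does.
    for s in string.ascii_lowercase:
        yield s
    for s1 in string.ascii_lowercase:
        for s2 in string.ascii_lowercase:
            yield s1 + s2


def _pair_r(expr: pd.DataFrame, g1: str, g2: str) -> float:
    a = expr.loc[g1].to_numpy(dtype=float)
    b = expr.loc[g2].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return float("nan")
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def refine_region(
    region: BGCRegion,
    annotations: dict[str, GeneAnnotation],
    expr,
    max_gap: int = 300,
    r_min: float = 0.5,
    linkage: str = "adjacent",
) -> tuple[list[SubCluster], list[str]]:
    """Split a region into co-located, co-expressed sub-clusters.

    ``expr`` is a gene × sample expression frame (or a
    :class:`NormalizedMatrix`, whose arcsinh values are used); genes absent
    from it (removed by the low-expression filter) break chains and are
    returned as unassigned. With the default adjacent linkage, a break is
    placed between genomic neighbours when the intergenic distance exceeds
    ``max_gap`` or their Pearson correlation is not above ``r_min``; the
    ``single`` linkage alternative connects any gene pair satisfying both
    rules and takes connected components.

    Returns ``(subclusters, unassigned_genes)``. Sub-clusters carry suffixes
    a, b, ... in coordinate order; those without a core gene are marked
    discarded("no core gene").
    """
    if len(region.member_genes) == 0:
        raise FormatError(f"region {region.region_id!r} has no member genes")
    if linkage not in {"adjacent", "single"}:
        raise XcoexError(f"unknown linkage {linkage!r}")
    if isinstance(expr, NormalizedMatrix):
        expr = expr.transformed
    missing_ann = [g for g in region.member_genes if g not in annotations]
    if missing_ann:
        raise CrossReferenceError(
            f"region {region.region_id!r}: no annotation for gene(s) {missing_ann}"
        )
    genes = sorted(
        region.member_genes,
        key=lambda g: (annotations[g].start, annotations[g].end, g),
    )
    expressed = [g for g in genes if g in expr.index]
    unassigned = [g for g in genes if g not in expr.index]

    groups: list[list[str]] = []
    if linkage == "adjacent":
        # chain along the genome; filtered genes already act as breakers
        # because runs are built over the expressed genes in genome order,
        # with gaps measured between genomic neighbours in the full list.
        current: list[str] = []
        for gene in genes:
            if gene not in expr.index:
                if current:
                    groups.append(current)
                    current = []
                continue
            if not current:
                current = [gene]
                continue
            prev = current[-1]
            gap = intergenic_distance(annotations[prev], annotations[gene])
            r = _pair_r(expr, prev, gene)
            if gap > max_gap or not (r > r_min):
                groups.append(current)
                current = [gene]
            else:
                current.append(gene)
        if current:
            groups.append(current)
    else:  # single linkage over all expressed pairs
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(expressed)
        for i, g1 in enumerate(expressed):
            for g2 in expressed[i + 1:]:
                first, second = sorted(
                    (g1, g2), key=lambda x: annotations[x].start
                )
                gap = intergenic_distance(annotations[first], annotations[second])
                if gap > max_gap:
                    continue
                r = _pair_r(expr, g1, g2)
                if r > r_min:
                    g.add_edge(g1, g2)
        comps = [sorted(c, key=lambda x: annotations[x].start) for c in
                 nx.connected_components(g)]
        groups = sorted(comps, key=lambda c: annotations[c[0]].start)

    whole = len(groups) == 1 and not unassigned
    subclusters: list[SubCluster] = []
    for suffix, members in zip(_suffixes(), groups):
        cores = frozenset(g for g in members if g in region.core_genes)
        sc = SubCluster(
            parent_region_id=region.region_id,
            suffix=suffix,
            member_genes=tuple(members),
            core_genes=cores,
            is_whole_region=whole,
        )
        if not cores:
            sc.discard("no core gene")
        subclusters.append(sc)
    return subclusters, unassigned


def filter_regions(
    subclusters: list[SubCluster],
    expressed_genes,
    expr,
    majority_frac: float = 0.7,
    r_core: float = 0.5,
) -> tuple[list[SubCluster], list[dict]]:
    """Apply the retention filters; returns (retained, audit log).

    ``expressed_genes`` is the set of gene ids passing the low-expression
    filter; ``expr`` a gene × sample expression frame (or NormalizedMatrix).
    Discard rules, applied in order to clusters not already discarded:

    a. no core gene passes the low-expression filter;
    b. strictly more than ``majority_frac`` of the member genes fail it;
    c. no core gene attains Pearson r > ``r_core`` with any other member.
       For a singleton this is vacuously unattainable: the singleton is
       discarded unless it is the entire region, in which case it is kept
       (flagged via ``is_whole_region``).

    Every discard is recorded in the audit log with its rule.
    """
    if isinstance(expr, NormalizedMatrix):
        expr = expr.transformed
    expressed_genes = set(expressed_genes)
    retained: list[SubCluster] = []
    audit: list[dict] = []

    def log(sc: SubCluster, rule: str, reason: str) -> None:
        audit.append(
            {"cluster_id": sc.cluster_id, "rule": rule, "reason": reason,
             "n_members": len(sc.member_genes)}
        )

    for sc in subclusters:
        if sc.status == "discarded":
            log(sc, "refine", sc.reason or "discarded during refinement")
            continue
        core_expressed = [g for g in sc.core_genes if g in expressed_genes]
        if not core_expressed:
            sc.discard("no core gene passing the low-expression filter")
            log(sc, "a", sc.reason)
            continue
        n = len(sc.member_genes)
        n_fail = sum(1 for g in sc.member_genes if g not in expressed_genes)
        if n_fail / n > majority_frac:
            sc.discard(
                f"{n_fail}/{n} members fail the low-expression filter "
                f"(> {majority_frac:.0%})"
            )
            log(sc, "b", sc.reason)
            continue
        if n == 1:
            if sc.is_whole_region:
                retained.append(sc)
            else:
                sc.discard("singleton sub-cluster (core co-expression undefined)")
                log(sc, "c", sc.reason)
            continue
        best = -np.inf
        for core in core_expressed:
            if core not in expr.index:
                continue
            for other in sc.member_genes:
                if other == core or other not in expr.index:
                    continue
                r = _pair_r(expr, core, other)
                if np.isfinite(r):
                    best = max(best, r)
        if not best > r_core:
            sc.discard(
                f"no core gene with r > {r_core} to another member "
                f"(best {best:.2f})" if np.isfinite(best) else
                f"no core gene with r > {r_core} to another member"
            )
            log(sc, "c", sc.reason)
            continue
        retained.append(sc)
    return retained, audit


def cluster_eigengene(
    members, counts: pd.DataFrame
) -> tuple[pd.Series, float, list[str]]:
    """First principal component of the members' scaled log2 counts.

    Per gene: ``log2(count + 1)``, then centred and scaled to unit variance
    across samples; the eigengene is the first principal-component sample
    score vector, unit norm, sign-aligned so its correlation with the mean
    member profile is non-negative. Returns
    ``(eigengene, variance_explained, warnings)``. Constant genes are
    dropped with a warning; an all-constant cluster is an error.
    """
    members = [g for g in members if g in counts.index]
    if len(members) < 2:
        raise XcoexError("eigengene needs at least two member genes with counts")
    x = np.log2(counts.loc[members].to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1, ddof=1)
    warnings = [
        f"gene {members[i]!r} has constant expression; dropped from eigengene"
        for i in np.flatnonzero(sd == 0)
    ]
    keep = sd > 0
    if not keep.any():
        raise XcoexError("all member genes constant; eigengene undefined")
    x = x[keep]
    sd = sd[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if mean_profile.std() > 0 and np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    eig = eig / np.linalg.norm(eig)
    return (
        pd.Series(eig, index=counts.columns, name="eigengene"),
        var_explained,
        warnings,
    )
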
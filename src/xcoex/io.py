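"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* counts: TSV, first column gene id, remaining columns samples; companion
  two-column TSV maps gene id → taxon.
* gene annotations: GFF3 (coordinates 1-based inclusive) plus an optional
  KO table (TSV, ``gene_id`` and comma-separated ``ko_terms``).
* metabolic module database: flat text. Header line ``module_id<TAB>name``,
  then one line per step where ``,`` separates alternative KOs/complexes and
  ``+`` joins the members of a complex; a line ``///`` terminates a module.
* BGC regions: long-format TSV, one row per member gene with a boolean
  ``core`` column.
* co-expression edges: TSV with a fixed, documented column set.
* networks: GraphML via networkx.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    BGCRegion,
    CountMatrix,
    GeneAnnotation,
    ModuleDatabase,
    ModuleDefinition,
)
from .errors import CrossReferenceError, FormatError

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmm_database",
    "write_gmm_database",
    "read_gff3",
    "write_gff3",
    "read_ko_table",
    "write_ko_table",
    "read_bgc_regions",
    "write_bgc_regions",
    "EDGE_COLUMNS",
    "read_edge_table",
    "write_edge_table",
    "write_graphml",
    "read_graphml",
]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path, taxon_map_path, metadata_path=None) -> CountMatrix:
    """Read a gene × sample count TSV and its gene→taxon map.

    Every entry must be a non-negative integer; violations are reported with
    the offending gene and sample. A gene missing from the taxon map is a
    cross-reference error.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        counts = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        counts = None
    if counts is None or counts.isna().any().any():
        probe = raw.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(probe.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric count at gene {raw.index[bad[0]]!r}, "
            f"sample {raw.columns[bad[1]]!r}: {raw.iloc[bad[0], bad[1]]!r}"
        )
    tmap = pd.read_csv(taxon_map_path, sep="\t", dtype=str)
    if tmap.shape[1] < 2:
        raise FormatError(f"{taxon_map_path}: expected columns gene_id, taxon")
    gene_taxon = pd.Series(
        tmap.iloc[:, 1].to_numpy(), index=pd.Index(tmap.iloc[:, 0], name="gene_id"),
        name="taxon",
    )
    samples = None
    if metadata_path is not None:
        samples = pd.read_csv(metadata_path, sep="\t", index_col=0)
        samples = samples.reindex(counts.columns)
    try:
        return CountMatrix(counts=counts, gene_taxon=gene_taxon, samples=samples)
    except (FormatError, CrossReferenceError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_counts(cm: CountMatrix, path, taxon_map_path=None, metadata_path=None) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    if taxon_map_path is not None:
        tm = cm.gene_taxon.rename("taxon").to_frame()
        tm.index.name = "gene_id"
        tm.to_csv(taxon_map_path, sep="\t")
    if metadata_path is not None:
        md = cm.samples.copy()
        md.index.name = "sample_id"
        md.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# module database (GMM flat format)
# ---------------------------------------------------------------------------

def _parse_step(line: str, module_id: str) -> tuple[frozenset[str], ...]:
    alts = []
    for alt in line.split(","):
        members = frozenset(m.strip() for m in alt.split("+"))
        if any(not m for m in members):
            raise FormatError(f"module {module_id!r}: empty KO in step {line!r}")
        alts.append(members)
    return tuple(alts)


def read_gmm_database(path) -> ModuleDatabase:
    """Parse the flat module format (see module docstring for the dialect)."""
    modules: list[ModuleDefinition] = []
    header: tuple[str, str] | None = None
    steps: list[tuple[frozenset[str], ...]] = []

    def flush() -> None:
        nonlocal header, steps
        if header is None:
            return
        if not steps:
            raise FormatError(f"module {header[0]!r} has no steps")
        modules.append(
            ModuleDefinition(module_id=header[0], name=header[1], steps=tuple(steps))
        )
        header, steps = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip() == "///" or not line.strip():
                flush()
                continue
            if header is None:
                parts = line.split("\t")
                header = (parts[0].strip(), parts[1].strip() if len(parts) > 1 else "")
            else:
                steps.append(_parse_step(line.strip(), header[0]))
    flush()
    return ModuleDatabase(modules=tuple(modules))


def write_gmm_database(db: ModuleDatabase, path) -> None:
    with open(path, "w") as fh:
        for mod in db:
            fh.write(f"{mod.module_id}\t{mod.name}\n")
            for step in mod.steps:
                fh.write(",".join("+".join(sorted(alt)) for alt in step) + "\n")
            fh.write("///\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff3(path, feature_types=("gene", "CDS")) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3, sorted by (contig, start).

    Parsing is delegated to :mod:`gffutils` (in-memory database).
    Recognized attributes: ``ID`` (required), ``taxon``, ``ko_terms``
    (comma-separated), ``product``.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises a mix of error types
        raise FormatError(f"{path}: not valid GFF3 ({exc})") from exc
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in feature_types:
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if not gene_id:
            raise FormatError(f"{path}: feature without ID attribute")
        if gene_id in seen:
            continue  # gene + CDS pair for the same locus
        seen.add(gene_id)
        kos = tuple(
            k for k in feat.attributes.get("ko_terms", [""])[0].split(",") if k
        )
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                taxon=feat.attributes.get("taxon", [""])[0],
                contig=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand if feat.strand in "+-" else ".",
                ko_terms=kos,
                product=feat.attributes.get("product", [""])[0],
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start, g.end, g.gene_id))
    return genes


def write_gff3(genes, path, source="xcoex") -> None:
    genes = sorted(genes, key=lambda g: (g.contig, g.start, g.end, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.taxon:
                attrs.append(f"taxon={g.taxon}")
            if g.ko_terms:
                attrs.append("ko_terms=" + ",".join(g.ko_terms))
            if g.product:
                attrs.append(f"product={g.product}")
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        source,
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_ko_table(path) -> dict[str, tuple[str, ...]]:
    """gene_id → KO tuple from a two-column TSV (KOs comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, tuple[str, ...]] = {}
    for gene_id, kos in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[gene_id] = tuple(k for k in kos.split(",") if k)
    return out


def write_ko_table(gene_kos: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tko_terms\n")
        for gene_id, kos in gene_kos.items():
            fh.write(f"{gene_id}\t{','.join(kos)}\n")


# ---------------------------------------------------------------------------
# BGC regions (long-format TSV, one row per member gene)
# ---------------------------------------------------------------------------

_REGION_COLS = [
    "region_id",
    "taxon",
    "contig",
    "region_start",
    "region_end",
    "product_class",
    "gene_id",
    "core",
]


def read_bgc_regions(path, annotations=None) -> list[BGCRegion]:
    """Read regions; if ``annotations`` given, validate gene cross-references
    and order members by start coordinate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REGION_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    ann_by_id = {a.gene_id: a for a in annotations} if annotations is not None else None
    regions: list[BGCRegion] = []
    for region_id, grp in df.groupby("region_id", sort=False):
        members = list(grp["gene_id"])
        core = frozenset(
            g for g, c in zip(grp["gene_id"], grp["core"])
            if str(c).strip().lower() in {"true", "1", "yes"}
        )
        if ann_by_id is not None:
            unknown = [g for g in members if g not in ann_by_id]
            if unknown:
                raise CrossReferenceError(
                    f"{path}: region {region_id!r} references unknown gene(s) "
                    f"{unknown}"
                )
            members.sort(key=lambda g: (ann_by_id[g].start, ann_by_id[g].end, g))
        first = grp.iloc[0]
        regions.append(
            BGCRegion(
                region_id=str(region_id),
                taxon=first["taxon"],
                contig=first["contig"],
                start=int(first["region_start"]),
                end=int(first["region_end"]),
                product_class=first["product_class"],
                member_genes=tuple(members),
                core_genes=core,
            )
        )
    regions.sort(key=lambda r: (r.contig, r.start, r.region_id))
    return regions


def write_bgc_regions(regions, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REGION_COLS)
        for r in sorted(regions, key=lambda r: (r.contig, r.start, r.region_id)):
            for g in r.member_genes:
                writer.writerow(
                    [
                        r.region_id,
                        r.taxon,
                        r.contig,
                        r.start,
                        r.end,
                        r.product_class,
                        g,
                        str(g in r.core_genes).lower(),
                    ]
                )


# ---------------------------------------------------------------------------
# edges and networks
# ---------------------------------------------------------------------------

#: Fixed column order of the edge TSV.
EDGE_COLUMNS = [
    "taxon_a",
    "kind_a",
    "feature_a",
    "taxon_b",
    "kind_b",
    "feature_b",
    "r",
    "rho",
    "n_shared",
    "weight",
    "cross_species",
    "shared_ko_fraction",
    "removed_by",
]


def write_edge_table(edges: pd.DataFrame, path) -> None:
    """Write a co-expression edge table with the fixed column set."""
    df = edges.copy()
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing edge column(s) {missing}")
    return df


def write_graphml(network, path) -> None:
    """Write a :class:`~xcoex.network.CoexpressionNetwork` (or nx.Graph)."""
    graph = network
    if not isinstance(network, nx.Graph):  # CoexpressionNetwork wrapper
        graph = network.graph
    out = nx.Graph()
    out.graph.update({k: v for k, v in graph.graph.items()})
    for node, attrs in graph.nodes(data=True):
        out.add_node(str(node), **{k: _graphml_safe(v) for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        out.add_edge(str(u), str(v), **{k: _graphml_safe(w) for k, w in attrs.items()})
    nx.write_graphml(out, path)


def _graphml_safe(value):
    if value is None:
        return ""
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, (bool, int, float, str)):
        return value
    return str(value)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
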
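"""In-memory containers shared by all pipeline stages.

The pipeline moves between a small number of well-defined objects: raw counts
with a gene→taxon map (:class:`CountMatrix`), gene coordinates and KO
annotations (:class:`GeneAnnotation`), biosynthetic gene cluster regions
(:class:`BGCRegion`), metabolic module definitions (:class:`ModuleDefinition`
inside a :class:`ModuleDatabase`), and the normalized / aggregated expression
matrices. Containers validate their invariants on construction so that format
errors surface at the boundary, not deep inside a correlation loop.

Coordinates are 1-based inclusive throughout (GFF3 convention); the intergenic
distance between consecutive genes is ``next.start - prev.end - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, CrossReferenceError

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "BGCRegion",
    "ModuleDefinition",
    "ModuleDatabase",
    "NormalizedMatrix",
    "KOMatrix",
    "ModuleExpressionMatrix",
    "SubCluster",
]


@dataclass
class CountMatrix:
    """Gene × sample integer counts with a gene→taxon map and sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows, samples as columns.
    gene_taxon
        Series mapping every gene id in ``counts.index`` to exactly one taxon.
    samples
        Sample metadata indexed by sample id, in the same order as
        ``counts.columns``. May be empty (no metadata columns).
    """

    counts: pd.DataFrame
    gene_taxon: pd.Series
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.counts.columns)
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = c.to_numpy()
        if values.dtype.kind == "f":
            if not np.isfinite(values).all() or (values % 1 != 0).any():
                bad = np.argwhere(~np.isfinite(values) | (values % 1 != 0))[0]
                raise FormatError(
                    f"non-integer count at gene {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}: {values[bad[0], bad[1]]!r}"
                )
            self.counts = c = c.astype(np.int64)
            values = c.to_numpy()
        elif values.dtype.kind not in "iu":
            raise FormatError(f"counts must be integral, got dtype {values.dtype}")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {c.index[bad[0]]!r}, "
                f"sample {c.columns[bad[1]]!r}: {values[bad[0], bad[1]]}"
            )
        missing = c.index.difference(self.gene_taxon.index)
        if len(missing) > 0:
            raise CrossReferenceError(
                f"{len(missing)} gene(s) without a taxon assignment, "
                f"first: {missing[0]!r}"
            )
        if self.gene_taxon.index.duplicated().any():
            dup = self.gene_taxon.index[self.gene_taxon.index.duplicated()][0]
            raise FormatError(f"gene {dup!r} mapped to more than one taxon")
        self.gene_taxon = self.gene_taxon.reindex(c.index)
        if not self.samples.index.equals(c.columns):
            raise CrossReferenceError("sample metadata does not match count columns")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.gene_taxon:
            seen.setdefault(t, None)
        return list(seen)

    def taxon_counts(self, taxon: str) -> pd.DataFrame:
        """Sub-matrix of the genes assigned to ``taxon`` (row order preserved)."""
        return self.counts.loc[self.gene_taxon == taxon]

    def subset_genes(self, genes) -> "CountMatrix":
        genes = pd.Index(genes)
        return CountMatrix(
            counts=self.counts.loc[genes],
            gene_taxon=self.gene_taxon.loc[genes],
            samples=self.samples,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.gene_taxon.equals(other.gene_taxon)
            and self.samples.equals(other.samples)
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene with coordinates and optional KO annotations."""

    gene_id: str
    taxon: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."
    ko_terms: tuple[str, ...] = ()
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise FormatError(f"gene {self.gene_id!r}: coordinates must be positive")
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def intergenic_distance(prev: GeneAnnotation, nxt: GeneAnnotation) -> int:
    """Base pairs strictly between two coordinate-sorted genes on one contig."""
    return nxt.start - prev.end - 1


@dataclass(frozen=True)
class BGCRegion:
    """An antiSMASH-style biosynthetic gene cluster region.

    ``member_genes`` must already be ordered by start coordinate;
    ``core_genes`` flags the core biosynthetic genes and must be a subset of
    the members.
    """

    region_id: str
    taxon: str
    contig: str
    start: int
    end: int
    product_class: str
    member_genes: tuple[str, ...]
    core_genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_genes) == 0:
            raise FormatError(f"region {self.region_id!r} has no member genes")
        if len(set(self.member_genes)) != len(self.member_genes):
            raise FormatError(f"region {self.region_id!r} lists a gene twice")
        extra = set(self.core_genes) - set(self.member_genes)
        if extra:
            raise CrossReferenceError(
                f"region {self.region_id!r}: core flag on non-member gene(s) "
                f"{sorted(extra)}"
            )
        if self.start > self.end:
            raise FormatError(f"region {self.region_id!r}: start > end")


@dataclass(frozen=True)
class ModuleDefinition:
    """A metabolic module: an ordered list of reaction steps.

    Each step is a tuple of alternatives; each alternative is a frozenset of
    KO ids (a set with more than one KO is an enzyme complex whose members
    are all required).
    """

    module_id: str
    name: str
    steps: tuple[tuple[frozenset[str], ...], ...]

    def __post_init__(self) -> None:
        if len(self.steps) == 0:
            raise FormatError(f"module {self.module_id!r} has no steps")
        for i, step in enumerate(self.steps):
            if len(step) == 0:
                raise FormatError(
                    f"module {self.module_id!r} step {i + 1} has no alternatives"
                )
            for alt in step:
                if len(alt) == 0 or any(not ko for ko in alt):
                    raise FormatError(
                        f"module {self.module_id!r} step {i + 1}: empty KO id"
                    )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def kos(self) -> frozenset[str]:
        """All KO ids appearing in any step/alternative."""
        out: set[str] = set()
        for step in self.steps:
            for alt in step:
                out |= alt
        return frozenset(out)


@dataclass(frozen=True)
class ModuleDatabase:
    """An ordered collection of :class:`ModuleDefinition` with unique ids."""

    modules: tuple[ModuleDefinition, ...]

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate module id {dup!r}")

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, module_id: str) -> ModuleDefinition:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def __contains__(self, module_id: str) -> bool:
        return any(m.module_id == module_id for m in self.modules)


@dataclass
class NormalizedMatrix:
    """Per-taxon normalized expression.

    ``values`` holds per-taxon CPM (counts per million of the taxon's own
    effective library); samples where a taxon is absent are NaN, not zero.
    ``factors`` are TMM scaling factors (taxon × sample, NaN where absent)
    with geometric mean 1 within each taxon. ``transformed`` applies the
    variance-stabilizing arcsinh on top.
    """

    values: pd.DataFrame  # gene × sample, float, NaN where taxon absent
    factors: pd.DataFrame  # taxon × sample
    lib_sizes: pd.DataFrame  # taxon × sample raw assigned counts
    presence: pd.DataFrame  # taxon × sample bool
    gene_taxon: pd.Series
    removed_genes: list[str] = field(default_factory=list)
    dropped_taxa: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def transformed(self) -> pd.DataFrame:
        """arcsinh-transformed values (missing stays missing)."""
        return pd.DataFrame(
            np.arcsinh(self.values.to_numpy()),
            index=self.values.index,
            columns=self.values.columns,
        )


@dataclass
class KOMatrix:
    """(taxon, KO) × sample matrix of arcsinh-transformed summed expression."""

    values: pd.DataFrame  # MultiIndex (taxon, ko) rows

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError("duplicate (taxon, KO) row")


@dataclass
class ModuleExpressionMatrix:
    """(taxon, module) × sample module scores with per-row coverage."""

    values: pd.DataFrame  # MultiIndex (taxon, module_id) rows
    coverage: pd.Series  # same index, in [0, 1]
    steps_detected: dict  # (taxon, module_id) -> tuple[bool, ...]


@dataclass
class SubCluster:
    """A refined, co-located, co-expressed gene group within a BGC region."""

    parent_region_id: str
    suffix: str  # "a", "b", ...
    member_genes: tuple[str, ...]  # ordered by coordinate
    core_genes: frozenset[str]
    status: str = "retained"  # "retained" | "discarded"
    reason: str | None = None
    is_whole_region: bool = False

    @property
    def cluster_id(self) -> str:
        return f"{self.parent_region_id}{self.suffix}"

    def discard(self, reason: str) -> None:
        self.status = "discarded"
        self.reason = reason
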
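"""Synthetic multi-species metatranscriptome generator with planted truth.

The generator emulates the data-generating process of a bioreactor
time-course over a synthetic bacterial community: per-sample library sizes,
per-taxon relative abundances following a log-scale random walk (softmax
across taxa), smooth latent expression programs per taxon, an optional
shared environmental confounder entering every taxon's programs with random
loadings, and negative-binomial counts. Cross-species interactions are
planted by letting designated gene groups (features) of two taxa share a
latent trajectory with a chosen sign and coupling strength; the planted
structure is returned as an explicit :class:`SyntheticTruth` object so that
recovery can be scored exactly.

The count model for gene g of taxon t in sample s is

    counts ~ NB(mean = L_s * a_{t,s} * pi_{g,s}, dispersion)

where ``pi`` is the gene's within-taxon expression proportion,
``pi = e_g / sum_g' e_g'`` with ``log e = base + amplitude * trajectory +
noise``, so expected per-taxon column sums equal library size times relative
abundance by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import BGCRegion, CountMatrix, GeneAnnotation
from .errors import ConfigError

__all__ = [
    "PlantedInteraction",
    "CommunityConfig",
    "SyntheticTruth",
    "generate_community",
    "RegionSpec",
    "generate_toy_genome",
    "generate_module_db",
]


@dataclass(frozen=True)
class PlantedInteraction:
    """One planted cross-species co-expression link between two gene groups."""

    taxon_a: str
    feature_a: str
    taxon_b: str
    feature_b: str
    sign: int = 1  # +1 producer/consumer style coupling, -1 competition style
    coupling: float = 0.9  # correlation of the two latent trajectories

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ConfigError("planted sign must be +1 or -1")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling_strength must be in [0, 1]")


@dataclass
class CommunityConfig:
    """Study conditions for one simulated community experiment.

    Defaults describe a mid-sized bioreactor time-course: 8 taxa with 300
    genes each, 40 ordered samples, library sizes spanning an order of
    magnitude, moderate abundance drift and negative-binomial overdispersion.
    """

    n_taxa: int = 8
    genes_per_taxon: int = 300
    n_samples: int = 40
    library_size_range: tuple[float, float] = (1e6, 1e7)
    abundance_walk_sigma: float = 0.15  # log-scale random-walk step per sample
    nb_dispersion: float = 0.1  # var = mu + dispersion * mu^2
    n_programs: int = 4  # latent expression programs per taxon
    program_amplitude: float = 1.0  # sd contribution of a program to log expr
    responsive_fraction: float = 0.3  # genes with strong program response;
    # the rest are near-constitutive, which keeps a stable majority for
    # reference-based normalization, as in real transcriptomes
    base_log_sd: float = 1.2  # spread of baseline gene expression
    gene_noise_sigma: float = 0.3  # iid log-normal gene/sample noise
    trajectory_autocorr: float = 0.3  # AR(1) coefficient of latent trajectories
    confounder_strength: float = 0.0  # in [0, 1]
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    genes_per_feature: int = 8
    # planted features emulate an active operon-like pathway: well expressed,
    # with members at similar baseline levels
    planted_base_log_mean: float = 1.0
    planted_base_log_sd: float = 0.2
    presence_threshold: float = 0.02  # relative abundance below which absent
    n_bioreactors: int = 1
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_taxa, self.genes_per_taxon, self.n_samples,
               self.n_programs, self.genes_per_feature, self.n_bioreactors) < 1:
            raise ConfigError("all sizes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not 0.0 <= self.confounder_strength <= 1.0:
            raise ConfigError("confounder_strength must be in [0, 1]")
        if not 0.0 <= self.trajectory_autocorr < 1.0:
            raise ConfigError("trajectory_autocorr must be in [0, 1)")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ConfigError("library_size_range must be positive and ordered")
        per_taxon_features: dict[str, int] = {}
        for pi in self.planted_interactions:
            per_taxon_features[pi.taxon_a] = per_taxon_features.get(pi.taxon_a, 0) + 1
            per_taxon_features[pi.taxon_b] = per_taxon_features.get(pi.taxon_b, 0) + 1
        for taxon, n_feat in per_taxon_features.items():
            if n_feat * self.genes_per_feature > self.genes_per_taxon:
                raise ConfigError(
                    f"taxon {taxon!r}: {n_feat} planted feature(s) of "
                    f"{self.genes_per_feature} genes exceed {self.genes_per_taxon} genes"
                )

    def taxon_ids(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_taxa)]


@dataclass
class SyntheticTruth:
    """The planted structure behind one generated community."""

    planted: tuple[PlantedInteraction, ...]
    feature_genes: dict[str, tuple[str, ...]]
    gene_program: dict[str, str]
    confounder: pd.Series
    expected_presence: pd.DataFrame  # taxon × sample bool
    rel_abundance: pd.DataFrame  # taxon × sample
    library_sizes: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "planted": [asdict(p) for p in self.planted],
            "feature_genes": {k: list(v) for k, v in self.feature_genes.items()},
            "gene_program": self.gene_program,
            "samples": list(self.confounder.index),
            "taxa": list(self.rel_abundance.index),
            "confounder": [float(x) for x in self.confounder],
            "expected_presence": self.expected_presence.to_numpy().astype(int).tolist(),
            "rel_abundance": self.rel_abundance.to_numpy().tolist(),
            "library_sizes": [float(x) for x in self.library_sizes],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        samples = pd.Index(d["samples"], name="sample_id")
        taxa = pd.Index(d["taxa"], name="taxon")
        return cls(
            planted=tuple(PlantedInteraction(**p) for p in d["planted"]),
            feature_genes={k: tuple(v) for k, v in d["feature_genes"].items()},
            gene_program=dict(d["gene_program"]),
            confounder=pd.Series(d["confounder"], index=samples, name="confounder"),
            expected_presence=pd.DataFrame(
                np.asarray(d["expected_presence"], dtype=bool),
                index=taxa, columns=samples,
            ),
            rel_abundance=pd.DataFrame(
                np.asarray(d["rel_abundance"], dtype=float),
                index=taxa, columns=samples,
            ),
            library_sizes=pd.Series(
                d["library_sizes"], index=samples, name="library_size"
            ),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.planted == other.planted
            and self.feature_genes == other.feature_genes
            and self.gene_program == other.gene_program
            and self.confounder.equals(other.confounder)
            and self.expected_presence.equals(other.expected_presence)
            and self.rel_abundance.equals(other.rel_abundance)
            and self.library_sizes.equals(other.library_sizes)
        )


def _smooth_trajectory(rng: np.random.Generator, n: int, phi: float = 0.7) -> np.ndarray:
    """Standardized AR(1) series — smooth enough to look like a time-course."""
    eps = rng.normal(size=n)
    z = np.empty(n)
    z[0] = eps[0]
    for i in range(1, n):
        z[i] = phi * z[i - 1] + np.sqrt(1 - phi**2) * eps[i]
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def generate_community(config: CommunityConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one community count matrix plus its ground truth.

    Identical ``config`` (including seed) gives identical output; all
    randomness flows through one generator seeded from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxa = config.taxon_ids()
    n_s = config.n_samples
    samples = pd.Index([f"S{i + 1:02d}" for i in range(n_s)], name="sample_id")

    # --- sample-level structure -------------------------------------------
    lo, hi = config.library_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_s))
    logab = np.empty((config.n_taxa, n_s))
    logab[:, 0] = rng.normal(scale=1.0, size=config.n_taxa)
    steps = rng.normal(scale=config.abundance_walk_sigma,
                       size=(config.n_taxa, n_s - 1))
    logab[:, 1:] = logab[:, [0]] + np.cumsum(steps, axis=1)
    rel_ab = np.exp(logab)
    rel_ab /= rel_ab.sum(axis=0, keepdims=True)
    confounder = _smooth_trajectory(rng, n_s, config.trajectory_autocorr)

    # --- planted latent trajectories --------------------------------------
    planted_traj: dict[str, np.ndarray] = {}
    feature_genes: dict[str, tuple[str, ...]] = {}
    for pi in config.planted_interactions:
        u = _smooth_trajectory(rng, n_s, config.trajectory_autocorr)
        v = _smooth_trajectory(rng, n_s, config.trajectory_autocorr)
        planted_traj[pi.feature_a] = u
        planted_traj[pi.feature_b] = pi.sign * (
            pi.coupling * u + np.sqrt(1 - pi.coupling**2) * v
        )

    # --- genes --------------------------------------------------------------
    counts = np.empty((config.n_taxa * config.genes_per_taxon, n_s), dtype=np.int64)
    gene_ids: list[str] = []
    gene_taxon: list[str] = []
    gene_program: dict[str, str] = {}
    n_nb = 1.0 / config.nb_dispersion

    for ti, taxon in enumerate(taxa):
        programs = np.vstack(
            [_smooth_trajectory(rng, n_s, config.trajectory_autocorr)
             for _ in range(config.n_programs)]
        )
        if config.confounder_strength > 0:
            # confounder enters every program with a random-signed loading
            w = config.confounder_strength * rng.uniform(
                0.5, 1.0, size=config.n_programs
            ) * rng.choice([-1.0, 1.0], size=config.n_programs)
            programs = (
                np.sqrt(1 - w[:, None] ** 2) * programs + w[:, None] * confounder
            )
        taxon_features = [
            (pi.feature_a if pi.taxon_a == taxon else pi.feature_b)
            for pi in config.planted_interactions
            if taxon in (pi.taxon_a, pi.taxon_b)
        ]
        ids = [f"{taxon}_g{i + 1:04d}" for i in range(config.genes_per_taxon)]
        traj = np.empty((config.genes_per_taxon, n_s))
        amp = np.empty(config.genes_per_taxon)
        cursor = 0
        for feat in taxon_features:
            members = ids[cursor:cursor + config.genes_per_feature]
            feature_genes[feat] = tuple(members)
            for g in members:
                gene_program[g] = feat
            traj[cursor:cursor + config.genes_per_feature] = planted_traj[feat]
            amp[cursor:cursor + config.genes_per_feature] = config.program_amplitude
            cursor += config.genes_per_feature
        n_bg = config.genes_per_taxon - cursor
        membership = rng.integers(config.n_programs, size=n_bg)
        traj[cursor:] = programs[membership]
        responsive = rng.random(n_bg) < config.responsive_fraction
        amp[cursor:] = np.where(
            responsive,
            config.program_amplitude * rng.uniform(0.5, 1.5, size=n_bg),
            rng.uniform(0.0, 0.15, size=n_bg),
        )
        for g, p in zip(ids[cursor:], membership):
            gene_program[g] = f"{taxon}_program{p + 1}"

        base = rng.normal(scale=config.base_log_sd, size=config.genes_per_taxon)
        if cursor > 0:
            base[:cursor] = rng.normal(
                loc=config.planted_base_log_mean,
                scale=config.planted_base_log_sd,
                size=cursor,
            )
        noise = rng.normal(
            scale=config.gene_noise_sigma, size=(config.genes_per_taxon, n_s)
        )
        log_e = base[:, None] + amp[:, None] * traj + noise
        e = np.exp(log_e)
        pi_gs = e / e.sum(axis=0, keepdims=True)
        mu = lib_sizes[None, :] * rel_ab[ti][None, :] * pi_gs
        p_nb = n_nb / (n_nb + mu)
        block = rng.negative_binomial(n_nb, p_nb)
        row0 = ti * config.genes_per_taxon
        counts[row0:row0 + config.genes_per_taxon] = block
        gene_ids.extend(ids)
        gene_taxon.extend([taxon] * config.genes_per_taxon)

    reactors = [f"R{(i % config.n_bioreactors) + 1}" for i in range(n_s)]
    metadata = pd.DataFrame(
        {
            "condition": ["timecourse"] * n_s,
            "time": np.arange(n_s),
            "replicate": 1,
            "bioreactor": reactors,
        },
        index=samples,
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=samples),
        gene_taxon=pd.Series(gene_taxon, index=pd.Index(gene_ids, name="gene_id"),
                             name="taxon"),
        samples=metadata,
    )
    truth = SyntheticTruth(
        planted=tuple(config.planted_interactions),
        feature_genes=feature_genes,
        gene_program=gene_program,
        confounder=pd.Series(confounder, index=samples, name="confounder"),
        expected_presence=pd.DataFrame(
            rel_ab >= config.presence_threshold,
            index=pd.Index(taxa, name="taxon"), columns=samples,
        ),
        rel_abundance=pd.DataFrame(
            rel_ab, index=pd.Index(taxa, name="taxon"), columns=samples
        ),
        library_sizes=pd.Series(lib_sizes, index=samples, name="library_size"),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# toy genomes with BGC regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """Layout of one toy BGC region.

    ``gaps`` are the exact intergenic distances (bp) between consecutive
    member genes; ``core_positions`` index into the member list (0-based).
    """

    region_id: str
    n_genes: int
    gaps: tuple[int, ...]
    core_positions: tuple[int, ...] = (0,)
    product_class: str = "NRPS"
    contig: str = "ctg1"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError(f"region {self.region_id!r}: n_genes must be >= 1")
        if len(self.gaps) != max(self.n_genes - 1, 0):
            raise ConfigError(
                f"region {self.region_id!r}: need {self.n_genes - 1} gaps, "
                f"got {len(self.gaps)}"
            )
        if any(g < 0 for g in self.gaps):
            raise ConfigError(
                f"region {self.region_id!r}: negative intergenic gap "
                "(overlapping genes)"
            )
        if any(p < 0 or p >= self.n_genes for p in self.core_positions):
            raise ConfigError(f"region {self.region_id!r}: core position out of range")


def generate_toy_genome(
    n_genes: int,
    region_specs,
    taxon: str = "T01",
    gene_length: int = 900,
    background_gap: int = 5000,
    contig: str = "ctg1",
) -> tuple[list[GeneAnnotation], list[BGCRegion]]:
    """Lay out background genes and BGC regions with exact intergenic gaps.

    ``n_genes`` background genes (outside any region) are placed with
    ``background_gap`` spacing after the regions of each contig; regions are
    laid out in the given order, separated by ``background_gap``. Genes are
    grouped per contig and sorted by coordinate.
    """
    if n_genes < 0:
        raise ConfigError("n_genes must be >= 0")
    specs = list(region_specs)
    contigs: dict[str, int] = {}
    genes: list[GeneAnnotation] = []
    regions: list[BGCRegion] = []
    counter = 0

    def place(contig_name: str, length: int, gap: int) -> tuple[int, int]:
        pos = contigs.get(contig_name, 1)
        if pos > 1:
            pos += gap + 1  # pos was last end; next start = end + gap + 1
        start = pos
        end = start + length - 1
        contigs[contig_name] = end
        return start, end

    for spec in specs:
        members: list[str] = []
        for i in range(spec.n_genes):
            gap = background_gap if i == 0 else spec.gaps[i - 1]
            start, end = place(spec.contig, gene_length, gap)
            counter += 1
            gid = f"{taxon}_g{counter:04d}"
            members.append(gid)
            genes.append(
                GeneAnnotation(
                    gene_id=gid, taxon=taxon, contig=spec.contig,
                    start=start, end=end, strand="+",
                )
            )
        first = next(g for g in genes if g.gene_id == members[0])
        last = next(g for g in genes if g.gene_id == members[-1])
        regions.append(
            BGCRegion(
                region_id=spec.region_id,
                taxon=taxon,
                contig=spec.contig,
                start=first.start,
                end=last.end,
                product_class=spec.product_class,
                member_genes=tuple(members),
                core_genes=frozenset(members[p] for p in spec.core_positions),
            )
        )
    for _ in range(n_genes):
        start, end = place(contig, gene_length, background_gap)
        counter += 1
        genes.append(
            GeneAnnotation(
                gene_id=f"{taxon}_g{counter:04d}", taxon=taxon, contig=contig,
                start=start, end=end, strand="+",
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes, regions


# ---------------------------------------------------------------------------
# module databases over synthetic communities
# ---------------------------------------------------------------------------

def generate_module_db(
    n_modules: int,
    steps_range: tuple[int, int] = (2, 4),
    kos_per_taxon: int = 40,
    seed: int = 0,
    community: CountMatrix | None = None,
    truth: SyntheticTruth | None = None,
):
    """Build a module database plus a gene→KO assignment table.

    Background modules draw their KOs from overlapping per-taxon KO pools so
    that some modules are detectable in several taxa. When a community with
    planted interactions is supplied, each planted feature receives a
    dedicated module (one KO per feature gene, one step per KO, so coverage
    is 1.0 in the carrying taxon) named ``<feature>_mod``.

    Returns ``(db, gene_kos, planted_modules)`` where ``planted_modules``
    maps each planted interaction's features to their module ids.
    """
    from .containers import ModuleDatabase, ModuleDefinition

    if n_modules < 0 or kos_per_taxon < 1:
        raise ConfigError("sizes must be >= 1")
    lo, hi = steps_range
    if not 1 <= lo <= hi:
        raise ConfigError("steps_range must be ordered and >= 1")
    rng = np.random.default_rng(seed)

    gene_kos: dict[str, tuple[str, ...]] = {}
    modules: list[ModuleDefinition] = []
    planted_modules: dict[str, str] = {}
    ko_counter = 0

    def fresh_ko() -> str:
        nonlocal ko_counter
        ko_counter += 1
        return f"K{ko_counter:05d}"

    planted_gene_set: set[str] = set()
    if truth is not None:
        for feature, members in truth.feature_genes.items():
            kos = []
            for g in members:
                ko = fresh_ko()
                gene_kos[g] = (ko,)
                kos.append(ko)
            planted_gene_set.update(members)
            mod_id = f"{feature}_mod"
            modules.append(
                ModuleDefinition(
                    module_id=mod_id,
                    name=f"planted module for {feature}",
                    steps=tuple((frozenset([ko]),) for ko in kos),
                )
            )
            planted_modules[feature] = mod_id

    pools: dict[str, list[str]] = {}
    if community is not None:
        universe = [fresh_ko() for _ in range(max(kos_per_taxon * 2, kos_per_taxon))]
        for taxon in community.taxa:
            pool = list(rng.choice(universe, size=kos_per_taxon, replace=False))
            pools[taxon] = pool
            members = [
                g for g in community.genes[community.gene_taxon == taxon]
                if g not in planted_gene_set
            ]
            for g in members:
                gene_kos[g] = (str(rng.choice(pool)),)
        all_kos = sorted({k for pool in pools.values() for k in pool})
    else:
        all_kos = [fresh_ko() for _ in range(kos_per_taxon)]

    for i in range(n_modules):
        n_steps = int(rng.integers(lo, hi + 1))
        steps = []
        for _ in range(n_steps):
            if len(all_kos) >= 2 and rng.random() < 0.2:
                pair = rng.choice(len(all_kos), size=2, replace=False)
                alts = (frozenset([all_kos[pair[0]], all_kos[pair[1]]]),)
            elif len(all_kos) >= 2 and rng.random() < 0.3:
                pair = rng.choice(len(all_kos), size=2, replace=False)
                alts = (frozenset([all_kos[pair[0]]]), frozenset([all_kos[pair[1]]]))
            else:
                alts = (frozenset([all_kos[int(rng.integers(len(all_kos)))]]),)
            steps.append(tuple(alts))
        modules.append(
            ModuleDefinition(
                module_id=f"MS{i + 1:04d}",
                name=f"background module {i + 1}",
                steps=tuple(steps),
            )
        )
    return ModuleDatabase(modules=tuple(modules)), gene_kos, planted_modules
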
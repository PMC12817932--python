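"""The synthetic community generator and its planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from xcoex import (
    CommunityConfig,
    ConfigError,
    PlantedInteraction,
    RegionSpec,
    SyntheticTruth,
    generate_community,
    generate_module_db,
    generate_toy_genome,
)
from xcoex.containers import intergenic_distance


def _planted_cfg(coupling, seed=0, **kw):
    pi = PlantedInteraction("T01", "fa", "T02", "fb", sign=1, coupling=coupling)
    return CommunityConfig(
        n_taxa=3, genes_per_taxon=60, n_samples=30,
        planted_interactions=(pi,), seed=seed, **kw,
    )


def _planted_gene_r(cm, truth):
    """Mean Pearson r between planted partner genes' latent trajectories,
    read off as within-taxon log proportions (taxon depth divided out)."""

    def log_prop(taxon, feature):
        sub = cm.taxon_counts(taxon)
        block = sub.loc[list(truth.feature_genes[feature])].to_numpy(float)
        return np.log1p(block) - np.log(sub.sum(axis=0).to_numpy(float))

    a = log_prop("T01", "fa")
    b = log_prop("T02", "fb")
    rs = [np.corrcoef(x, y)[0, 1] for x, y in zip(a, b)]
    return float(np.mean(rs))


class TestGenerateCommunity:
    def test_deterministic_under_seed(self):
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=30, n_samples=10, seed=5)
        cm1, t1 = generate_community(cfg)
        cm2, t2 = generate_community(cfg)
        assert cm1 == cm2
        assert t1 == t2

    def test_full_coupling_low_noise_gives_near_perfect_r(self):
        # noise -> 0 includes the background programs (they perturb the
        # within-taxon denominator), so the limit uses a constitutive
        # background
        cfg = _planted_cfg(
            1.0, gene_noise_sigma=0.01, nb_dispersion=0.001,
            responsive_fraction=0.0,
        )
        cm, truth = generate_community(cfg)
        assert _planted_gene_r(cm, truth) > 0.97

    def test_zero_coupling_zero_confounder_gives_null_r(self):
        # Monte-Carlo null oracle: mean planted-pair r within 3/sqrt(n-1)
        rs = []
        for seed in range(8):
            cfg = _planted_cfg(0.0, seed=seed, confounder_strength=0.0)
            cm, truth = generate_community(cfg)
            rs.append(_planted_gene_r(cm, truth))
        tol = 3.0 / np.sqrt(cfg.n_samples - 1)
        assert abs(np.mean(rs)) < tol

    def test_negative_sign_flips_correlation(self):
        pi = PlantedInteraction("T01", "fa", "T02", "fb", sign=-1, coupling=1.0)
        cfg = CommunityConfig(
            n_taxa=3, genes_per_taxon=60, n_samples=30,
            planted_interactions=(pi,), seed=2,
            gene_noise_sigma=0.01, nb_dispersion=0.001,
            responsive_fraction=0.0,
        )
        cm, truth = generate_community(cfg)
        assert _planted_gene_r(cm, truth) < -0.97

    def test_expected_column_sums_track_library_and_abundance(self):
        cfg = CommunityConfig(n_taxa=4, genes_per_taxon=150, n_samples=20,
                              seed=3, library_size_range=(2e5, 2e6))
        cm, truth = generate_community(cfg)
        rel_err = []
        for taxon in cm.taxa:
            observed = cm.taxon_counts(taxon).sum(axis=0).to_numpy(float)
            expected = (
                truth.library_sizes.to_numpy()
                * truth.rel_abundance.loc[taxon].to_numpy()
            )
            rel_err.append(np.abs(observed - expected) / expected)
        assert np.mean(rel_err) < 0.05

    def test_confounding_inflates_cross_species_correlation(self):
        from xcoex import filter_low_expression, normalize_per_taxon
        from xcoex.network import FeatureTable, cross_species_abs_r

        def upper_tail(confounder_strength):
            out = []
            for seed in range(3):
                cfg = CommunityConfig(
                    n_taxa=3, genes_per_taxon=80, n_samples=25, seed=seed,
                    confounder_strength=confounder_strength,
                )
                cm, _ = generate_community(cfg)
                filtered, _ = filter_low_expression(cm)
                norm = normalize_per_taxon(filtered)
                absr = cross_species_abs_r(FeatureTable.from_genes(norm))
                out.append(np.quantile(absr, 0.99))
            return np.mean(out)

        assert upper_tail(0.9) > upper_tail(0.0)

    def test_infeasible_planted_config_rejected(self):
        pi = PlantedInteraction("T01", "fa", "T01", "fb", coupling=0.5)
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=10,
                              genes_per_feature=8, planted_interactions=(pi,))
        with pytest.raises(ConfigError):
            generate_community(cfg)

    def test_truth_round_trips_through_json(self, tmp_path):
        cfg = _planted_cfg(0.7)
        _, truth = generate_community(cfg)
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back == truth


class TestToyGenome:
    def test_gaps_realized_exactly(self):
        genes, regions = generate_toy_genome(
            0, [RegionSpec("R1", 3, gaps=(100, 301))]
        )
        by_id = {g.gene_id: g for g in genes}
        members = regions[0].member_genes
        gaps = [
            intergenic_distance(by_id[members[i]], by_id[members[i + 1]])
            for i in range(2)
        ]
        assert gaps == [100, 301]

    def test_region_without_core_genes_allowed(self):
        _, regions = generate_toy_genome(
            0, [RegionSpec("R1", 2, gaps=(50,), core_positions=())]
        )
        assert regions[0].core_genes == frozenset()

    def test_two_contigs_group_genes(self):
        genes, regions = generate_toy_genome(
            3,
            [
                RegionSpec("R1", 2, gaps=(10,), contig="ctg1"),
                RegionSpec("R2", 2, gaps=(10,), contig="ctg2"),
            ],
            contig="ctg1",
        )
        assert {g.contig for g in genes} == {"ctg1", "ctg2"}
        contigs = [g.contig for g in genes]
        assert contigs == sorted(contigs)  # grouped per contig

    def test_overlapping_genes_rejected(self):
        with pytest.raises(ConfigError, match="gap"):
            RegionSpec("R1", 2, gaps=(-5,))


class TestModuleDb:
    def test_sizes(self):
        db, gene_kos, _ = generate_module_db(1, steps_range=(3, 3), seed=1)
        assert len(db) == 1
        assert db.modules[0].n_steps == 3

    def test_planted_modules_cover_planted_genes(self, planted_community):
        cm, truth, db, gene_kos, planted_modules = planted_community
        for feature, module_id in planted_modules.items():
            mod = db[module_id]
            gene_ko = {gene_kos[g][0] for g in truth.feature_genes[feature]}
            assert mod.kos == frozenset(gene_ko)

    def test_planted_module_scores_coverage_one(self, planted_community):
        from xcoex import (
            aggregate_ko,
            filter_low_expression,
            normalize_per_taxon,
            score_modules,
        )

        cm, truth, db, gene_kos, planted_modules = planted_community
        filtered, _ = filter_low_expression(cm)
        norm = normalize_per_taxon(filtered)
        ko = aggregate_ko(norm, gene_kos)
        out = score_modules(ko, db)
        planted = truth.planted[0]
        for taxon, feature in [
            (planted.taxon_a, planted.feature_a),
            (planted.taxon_b, planted.feature_b),
        ]:
            assert out.coverage.loc[(taxon, planted_modules[feature])] == 1.0

    def test_module_with_foreign_kos_scores_zero_coverage(self):
        from xcoex import KOMatrix, score_modules

        db, _, _ = generate_module_db(0, seed=0)
        from xcoex.containers import ModuleDatabase, ModuleDefinition

        db = ModuleDatabase(
            (ModuleDefinition("MX", "foreign", ((frozenset(["KZZZZ"]),),)),)
        )
        ko = KOMatrix(values=pd.DataFrame(
            [[1.0]],
            index=pd.MultiIndex.from_tuples([("A", "K1")], names=["taxon", "ko"]),
            columns=["s0"],
        ))
        out = score_modules(ko, db, min_coverage=0.0)
        assert ("A", "MX") not in out.values.index  # zero coverage, never emitted
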
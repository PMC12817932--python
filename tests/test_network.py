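"""Correlation, edge filtering, power scaling, and network assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fisher_mean_oracle, pearson_oracle
from xcoex import (
    ConfigError,
    build_network,
    cluster_correlation,
    correlate,
    discrepancy_filter,
    fisher_mean,
    pick_soft_threshold,
    signed_power,
    weight_to_r,
)
from xcoex.network import FeatureTable


def _features(rows: dict, presence: dict, kind="module"):
    """rows: (taxon, feature) -> sample vector; presence: taxon -> bool list."""
    n = len(next(iter(rows.values())))
    samples = [f"s{j}" for j in range(n)]
    index = pd.MultiIndex.from_tuples(
        [(t, kind, f) for t, f in rows], names=["taxon", "kind", "feature"]
    )
    pres = pd.DataFrame(presence, index=samples).T
    pres.columns = samples
    values = np.vstack([np.asarray(v, float) for v in rows.values()])
    # mask values where the taxon is absent
    for i, (t, _f) in enumerate(rows):
        values[i, ~pres.loc[t].to_numpy(bool)] = np.nan
    return FeatureTable(
        values=pd.DataFrame(values, index=index, columns=samples), presence=pres
    )


class TestCorrelate:
    def test_shared_samples_are_presence_intersection(self):
        n = 12
        rng = np.random.default_rng(0)
        feats = _features(
            {("A", "m1"): rng.normal(size=n), ("B", "m2"): rng.normal(size=n)},
            {
                "A": [True] * 8 + [False] * 4,   # samples 1-8
                "B": [False] * 4 + [True] * 8,   # samples 5-12
            },
        )
        edges = correlate(feats, min_shared=2)
        assert edges.loc[0, "n_shared"] == 4

    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        feats = _features(
            {("A", "m1"): x, ("B", "m2"): 2 * x + 1},
            {"A": [True] * 10, "B": [True] * 10},
        )
        edges = correlate(feats)
        assert edges.loc[0, "r"] == pytest.approx(1.0)
        assert edges.loc[0, "rho"] == pytest.approx(1.0)
        assert bool(edges.loc[0, "cross_species"]) is True

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=30), rng.normal(size=30)
        feats = _features(
            {("A", "m1"): x, ("B", "m2"): y},
            {"A": [True] * 30, "B": [True] * 30},
        )
        edges = correlate(feats)
        assert edges.loc[0, "r"] == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_min_shared_marks_edge(self):
        rng = np.random.default_rng(1)
        feats = _features(
            {("A", "m1"): rng.normal(size=6), ("B", "m2"): rng.normal(size=6)},
            {"A": [True] * 4 + [False] * 2, "B": [False] * 2 + [True] * 4},
        )
        edges = correlate(feats, min_shared=5)
        assert edges.loc[0, "removed_by"] == "min_samples"

    def test_zero_variance_recorded_not_emitted(self):
        feats = _features(
            {("A", "m1"): np.ones(8), ("B", "m2"): np.arange(8.0)},
            {"A": [True] * 8, "B": [True] * 8},
        )
        edges = correlate(feats)
        assert edges.loc[0, "removed_by"] == "zero_variance"
        net = build_network(edges, min_weight=0.0)
        assert net.n_edges == 0

    def test_no_self_or_duplicate_pairs(self):
        rng = np.random.default_rng(2)
        feats = _features(
            {("A", f"m{i}"): rng.normal(size=10) for i in range(4)},
            {"A": [True] * 10},
        )
        edges = correlate(feats)
        assert len(edges) == 6  # C(4,2)
        pairs = {frozenset((a, b)) for a, b in zip(edges.feature_a, edges.feature_b)}
        assert len(pairs) == 6

    def test_pearson_affine_invariant_spearman_monotone_invariant(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = _features(
            {("A", "m"): x, ("B", "m"): y},
            {"A": [True] * 20, "B": [True] * 20},
        )
        scaled = _features(
            {("A", "m"): 3.5 * x + 2, ("B", "m"): np.arcsinh(y - y.min())},
            {"A": [True] * 20, "B": [True] * 20},
        )
        e1, e2 = correlate(base), correlate(scaled)
        assert e1.loc[0, "r"] == pytest.approx(
            pearson_oracle(3.5 * x + 2, y), abs=1e-12
        )
        assert e2.loc[0, "rho"] == pytest.approx(e1.loc[0, "rho"], abs=1e-12)


class TestDiscrepancyFilter:
    @pytest.mark.parametrize(
        "r, rho, removed",
        # gap of exactly the threshold (0.3 - 0.0) is kept: strict inequality
        [(0.9, 0.5, True), (0.9, 0.7, False), (0.3, 0.0, False)],
    )
    def test_strict_threshold(self, r, rho, removed):
        edges = pd.DataFrame(
            [{"r": r, "rho": rho, "removed_by": "none"}]
        )
        out = discrepancy_filter(edges)
        assert (out.loc[0, "removed_by"] == "discrepancy") is removed

    def test_does_not_overwrite_prior_removal(self):
        edges = pd.DataFrame([{"r": 0.9, "rho": 0.1, "removed_by": "min_samples"}])
        out = discrepancy_filter(edges)
        assert out.loc[0, "removed_by"] == "min_samples"


class TestSignedPower:
    def test_fixed_points(self):
        assert signed_power(1.0) == 1.0
        assert signed_power(-1.0) == -1.0
        assert signed_power(0.0) == 0.0

    def test_weight_cutoffs_match_correlation_cutoffs(self):
        # the display cut-offs used for network views: a weight threshold w
        # corresponds to |r| = w**(1/6)
        assert round(weight_to_r(0.2), 2) == 0.76
        assert round(weight_to_r(0.5), 2) == 0.89
        assert round(weight_to_r(0.3), 2) == 0.82
        assert signed_power(0.7647) == pytest.approx(0.2, abs=5e-4)
        assert signed_power(-0.8909) == pytest.approx(-0.5, abs=5e-4)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.floats(-1, 1), st.floats(1, 12))
    def test_weight_bounded_by_r_and_order_preserving(self, r, beta):
        w = signed_power(r, beta=beta)
        assert abs(w) <= abs(r) + 1e-12
        assert np.sign(w) == np.sign(r) or w == 0.0  # |r|^beta may underflow

    def test_strictly_order_preserving_on_magnitude(self):
        r = np.linspace(0.01, 1, 50)
        w = signed_power(r)
        assert (np.diff(w) > 0).all()


class TestSoftThreshold:
    @staticmethod
    def _power_law_edges(gamma=0.8, n=100, k_max=10.0):
        """|r| constructed so connectivity at beta=6 follows an exact
        rank-size power law (Chung-Lu style expected degrees)."""
        k = k_max * (np.arange(1, n + 1)) ** (-gamma)
        s = k.sum()
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                w6 = k[i] * k[j] / s  # target weight at beta 6
                rows.append(
                    {
                        "taxon_a": "A", "kind_a": "gene", "feature_a": f"n{i}",
                        "taxon_b": "A", "kind_b": "gene", "feature_b": f"n{j}",
                        "r": w6 ** (1 / 6), "rho": w6 ** (1 / 6),
                        "n_shared": 30, "cross_species": False,
                        "removed_by": "none",
                    }
                )
        return pd.DataFrame(rows)

    def test_constructed_power_law_fits_at_beta_6(self):
        edges = self._power_law_edges()
        result = pick_soft_threshold(edges, beta_grid=range(1, 13))
        table = result.fit_table.set_index("beta")
        assert table.loc[6, "fit"] > 0.9
        assert table.loc[6, "slope"] < 0
        assert result.beta <= 6

    def test_all_equal_correlations_degenerate(self):
        edges = self._power_law_edges()
        edges["r"] = 0.5
        with pytest.raises(ConfigError):
            pick_soft_threshold(edges)

    def test_too_few_nodes_rejected(self):
        edges = self._power_law_edges(n=5)
        with pytest.raises(ConfigError):
            pick_soft_threshold(edges)


class TestClusterCorrelation:
    def test_equal_correlations_fixed_point(self):
        assert fisher_mean([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_odd_symmetry(self):
        assert fisher_mean([0.8, -0.8]) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_pair(self):
        assert fisher_mean([0.5, 0.9]) == pytest.approx(
            fisher_mean_oracle([0.5, 0.9]), abs=1e-12
        )
        assert fisher_mean([0.5, 0.9]) == pytest.approx(0.766077, abs=1e-6)

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-0.99, 0.99, size=9)
        assert fisher_mean(r) == pytest.approx(fisher_mean(r[::-1]))
        assert -1 < fisher_mean(r) < 1

    def test_cluster_level_mean_over_gene_pairs(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=25)
        a = pd.DataFrame({"a1": base + rng.normal(0, 0.4, 25),
                          "a2": base + rng.normal(0, 0.4, 25)}).T
        b = pd.DataFrame({"b1": base + rng.normal(0, 0.4, 25)}).T
        r_mean, n_pairs = cluster_correlation(a, b)
        assert n_pairs == 2
        expected = fisher_mean_oracle(
            [pearson_oracle(a.loc[g].to_numpy(), b.loc["b1"].to_numpy())
             for g in ["a1", "a2"]]
        )
        assert r_mean == pytest.approx(expected, abs=1e-12)

    def test_no_valid_pair_undefined(self):
        a = pd.DataFrame({"a1": [np.nan] * 6}).T
        b = pd.DataFrame({"b1": np.arange(6.0)}).T
        r_mean, n_pairs = cluster_correlation(a, b)
        assert np.isnan(r_mean) and n_pairs == 0


class TestBuildNetwork:
    def _edges(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(30):
            r = rng.uniform(-1, 1)
            rows.append(
                {
                    "taxon_a": "A", "kind_a": "module", "feature_a": f"a{i}",
                    "taxon_b": "B", "kind_b": "module", "feature_b": f"b{i}",
                    "r": r, "rho": r, "n_shared": 20,
                    "cross_species": True, "removed_by": "none",
                }
            )
        return pd.DataFrame(rows)

    def test_retained_edges_satisfy_correlation_cutoff(self):
        net = build_network(self._edges(), min_weight=0.2)
        r_min = 0.2 ** (1 / 6)
        for _u, _v, d in net.graph.edges(data=True):
            assert abs(d["r"]) > r_min

    def test_min_weight_one_empty(self):
        net = build_network(self._edges(), min_weight=1.0)
        assert net.n_edges == 0

    def test_within_species_module_edges_annotated(self):
        from xcoex.containers import ModuleDatabase, ModuleDefinition

        db = ModuleDatabase(
            (
                ModuleDefinition("m1", "x", ((frozenset(["K1"]),),)),
                ModuleDefinition("m2", "y", ((frozenset(["K1"]), ),
                                             (frozenset(["K2"]),))),
            )
        )
        edges = pd.DataFrame(
            [
                {
                    "taxon_a": "A", "kind_a": "module", "feature_a": "m1",
                    "taxon_b": "A", "kind_b": "module", "feature_b": "m2",
                    "r": 0.99, "rho": 0.99, "n_shared": 20,
                    "cross_species": False, "removed_by": "none",
                }
            ]
        )
        net = build_network(edges, min_weight=0.2, module_db=db)
        assert net.edges.loc[0, "shared_ko_fraction"] == 0.5
        (_u, _v, d), = net.graph.edges(data=True)
        assert d["shared_ko_fraction"] == 0.5
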
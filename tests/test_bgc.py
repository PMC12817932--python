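"""BGC sub-cluster refinement, retention filters, and eigengenes."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_annotations
from oracles import eigengene_oracle
from xcoex import (
    BGCRegion,
    XcoexError,
    cluster_eigengene,
    filter_regions,
    refine_region,
)


def _expr(profiles: dict, n=12, seed=0):
    """Gene × sample expression with requested pairwise correlation structure.

    ``profiles`` maps gene id -> scale on a shared base signal, or an explicit
    vector; genes given independent noise vectors decorrelate.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n)
    rows = {}
    for gene, spec in profiles.items():
        rows[gene] = base.copy() if spec == "base" else np.asarray(spec, float)
    return pd.DataFrame(rows).T


def _region(members, cores, annotations, region_id="R1"):
    by = annotations
    start = min(by[g].start for g in members)
    end = max(by[g].end for g in members)
    return BGCRegion(region_id, "T01", "ctg1", start, end, "NRPS",
                     tuple(members), frozenset(cores))


def _chain_annotations(gaps, length=200, start=100):
    """Genes g1..gN on one contig with the requested intergenic gaps."""
    rows = []
    pos = start
    for i, gap in enumerate([None] + list(gaps)):
        if gap is not None:
            pos = rows[-1][2] + gap + 1
        rows.append((f"g{i + 1}", pos, pos + length - 1))
        pos = rows[-1][2]
    return make_annotations(rows)


class TestRefineRegion:
    def test_gap_and_correlation_chaining(self):
        anns = _chain_annotations([100, 301, 100, 100])
        genes = [f"g{i}" for i in range(1, 6)]
        expr = _expr({g: "base" for g in genes})
        region = _region(genes, ["g1", "g4"], anns)
        subclusters, unassigned = refine_region(region, anns, expr)
        assert [sc.suffix for sc in subclusters] == ["a", "b"]
        assert subclusters[0].member_genes == ("g1", "g2")
        assert subclusters[1].member_genes == ("g3", "g4", "g5")
        assert all(sc.status == "retained" for sc in subclusters)
        assert unassigned == []

    def test_gap_300_is_within_limit(self):
        anns = _chain_annotations([100, 300, 100, 100])
        genes = [f"g{i}" for i in range(1, 6)]
        expr = _expr({g: "base" for g in genes})
        region = _region(genes, ["g1"], anns)
        subclusters, _ = refine_region(region, anns, expr)
        assert len(subclusters) == 1
        assert subclusters[0].suffix == "a"
        assert subclusters[0].member_genes == tuple(genes)

    def test_low_correlation_breaks_and_no_core_discards(self):
        anns = _chain_annotations([100, 100, 100, 100])
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        other = rng.normal(size=30)  # r(g2, g3) ~ 0
        expr = pd.DataFrame(
            {"g1": base, "g2": base, "g3": other, "g4": other, "g5": other}
        ).T
        region = _region([f"g{i}" for i in range(1, 6)], ["g1"], anns)
        subclusters, _ = refine_region(region, anns, expr)
        assert subclusters[0].member_genes == ("g1", "g2")
        assert subclusters[0].status == "retained"
        assert subclusters[1].member_genes == ("g3", "g4", "g5")
        assert subclusters[1].status == "discarded"
        assert subclusters[1].reason == "no core gene"

    def test_r_exactly_at_threshold_breaks(self):
        # r must be strictly greater than r_min to chain
        anns = _chain_annotations([100])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])  # r = 0.8
        expr = pd.DataFrame({"g1": x, "g2": y}).T
        region = _region(["g1", "g2"], ["g1"], anns)
        joined, _ = refine_region(region, anns, expr, r_min=0.5)
        assert len(joined) == 1
        split, _ = refine_region(region, anns, expr, r_min=0.8)
        assert len(split) == 2

    def test_filtered_gene_breaks_chain_and_is_unassigned(self):
        anns = _chain_annotations([100, 100])
        expr = _expr({"g1": "base", "g3": "base"})  # g2 failed the filter
        region = _region(["g1", "g2", "g3"], ["g1", "g3"], anns)
        subclusters, unassigned = refine_region(region, anns, expr)
        assert [sc.member_genes for sc in subclusters] == [("g1",), ("g3",)]
        assert unassigned == ["g2"]

    def test_input_gene_order_irrelevant(self):
        anns = _chain_annotations([100, 100, 100])
        genes = ["g1", "g2", "g3", "g4"]
        expr = _expr({g: "base" for g in genes})
        a = _region(genes, ["g1"], anns)
        b = _region(list(reversed(genes)), ["g1"], anns)
        sa, _ = refine_region(a, anns, expr)
        sb, _ = refine_region(b, anns, expr)
        assert [s.member_genes for s in sa] == [s.member_genes for s in sb]

    def test_coarsening_monotonicity(self):
        anns = _chain_annotations([50, 400, 150, 500])
        genes = [f"g{i}" for i in range(1, 6)]
        expr = _expr({g: "base" for g in genes})
        region = _region(genes, genes, anns)
        n_at = {}
        for gap in [100, 300, 600]:
            scs, _ = refine_region(region, anns, expr, max_gap=gap)
            n_at[gap] = len(scs)
        assert n_at[100] >= n_at[300] >= n_at[600]

    def test_subclusters_partition_expressed_members(self):
        anns = _chain_annotations([100, 500, 100, 100])
        genes = [f"g{i}" for i in range(1, 6)]
        expr = _expr({g: "base" for g in genes if g != "g4"})
        region = _region(genes, ["g1"], anns)
        subclusters, unassigned = refine_region(region, anns, expr)
        assigned = [g for sc in subclusters for g in sc.member_genes]
        assert sorted(assigned + unassigned) == sorted(genes)
        assert len(set(assigned)) == len(assigned)


class TestFilterRegions:
    def _sc(self, members, cores, **kw):
        from xcoex.containers import SubCluster

        return SubCluster("R1", "a", tuple(members), frozenset(cores), **kw)

    def test_majority_fail_rule(self):
        genes = [f"g{i}" for i in range(10)]
        expressed = set(genes[:2]) | {"g0"}
        expr = _expr({g: "base" for g in expressed})
        sc = self._sc(genes, ["g0"])
        retained, audit = filter_regions([sc], expressed, expr)
        assert retained == []
        assert audit[0]["rule"] == "b"  # 8/10 fail > 0.7

    def test_no_expressed_core_rule(self):
        genes = ["g0", "g1", "g2"]
        expressed = {"g1", "g2"}
        expr = _expr({g: "base" for g in expressed})
        sc = self._sc(genes, ["g0"])
        retained, audit = filter_regions([sc], expressed, expr)
        assert retained == [] and audit[0]["rule"] == "a"

    def test_poor_core_coexpression_rule(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            {"g0": rng.normal(size=40), "g1": rng.normal(size=40),
             "g2": rng.normal(size=40)}
        ).T
        sc = self._sc(["g0", "g1", "g2"], ["g0"])
        retained, audit = filter_regions([sc], {"g0", "g1", "g2"}, expr)
        assert retained == [] and audit[0]["rule"] == "c"

    def test_good_cluster_retained(self):
        genes = [f"g{i}" for i in range(10)]
        expressed = set(genes[:7])  # 30% fail, under the 70% rule
        expr = _expr({g: "base" for g in expressed})
        sc = self._sc(genes, ["g0"])
        retained, audit = filter_regions([sc], expressed, expr)
        assert retained == [sc] and audit == []

    def test_singleton_discarded_unless_whole_region(self):
        expr = _expr({"g0": "base"})
        lone = self._sc(["g0"], ["g0"])
        retained, audit = filter_regions([lone], {"g0"}, expr)
        assert retained == [] and audit[0]["rule"] == "c"
        whole = self._sc(["g0"], ["g0"], is_whole_region=True)
        retained, _ = filter_regions([whole], {"g0"}, expr)
        assert retained == [whole]


class TestEigengene:
    def test_identical_profiles(self):
        rng = np.random.default_rng(0)
        profile = rng.poisson(100, size=10)
        counts = pd.DataFrame({"s%d" % j: [v, v] for j, v in enumerate(profile)},
                              index=["g1", "g2"])
        eig, var_explained, warnings = cluster_eigengene(["g1", "g2"], counts)
        x = np.log2(counts.loc["g1"].to_numpy(float) + 1)
        assert abs(np.corrcoef(eig, x)[0, 1]) == pytest.approx(1.0)
        assert var_explained == pytest.approx(1.0)

    def test_sign_aligned_with_mean_profile(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(5, 12)),
                              index=[f"g{i}" for i in range(5)])
        eig, _, _ = cluster_eigengene(list(counts.index), counts)
        z = np.log2(counts.to_numpy(float) + 1)
        z = (z - z.mean(1, keepdims=True)) / z.std(1, ddof=1, keepdims=True)
        assert np.corrcoef(eig, z.mean(axis=0))[0, 1] >= 0

    def test_matches_svd_free_oracle(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(80, size=(6, 15)),
                              index=[f"g{i}" for i in range(6)])
        eig, _, _ = cluster_eigengene(list(counts.index), counts)
        expected = eigengene_oracle(counts)
        assert np.abs(np.abs(eig.to_numpy()) - np.abs(expected)).max() < 1e-8
        # sign convention matches too
        assert np.abs(eig.to_numpy() - expected).max() < 1e-8

    def test_constant_gene_dropped_with_warning(self):
        counts = pd.DataFrame(
            [[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]],
            index=["flat", "up", "down"],
        )
        eig, _, warnings = cluster_eigengene(["flat", "up", "down"], counts)
        assert len(warnings) == 1 and "flat" in warnings[0]

    def test_all_constant_cluster_is_error(self):
        counts = pd.DataFrame([[5, 5, 5], [2, 2, 2]], index=["a", "b"])
        with pytest.raises(XcoexError):
            cluster_eigengene(["a", "b"], counts)
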
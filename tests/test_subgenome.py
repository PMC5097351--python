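import numpy as np
import pandas as pd
import pytest

from conftest import network_from_edges
from oracles import chi_square_statistic

from coexdup.network import ModuleAssignment
from coexdup.subgenome import (
    EdgeFractionation,
    contingency_edge_test,
    count_subgenome_edges,
    detect_hub_genes,
    hub_subgenome_bias,
    module_subgenome_enrichment,
    pathway_fractionation,
    permute_edge_null,
    _sample_edges,
)


def make_map(m1, m2, ambiguous=()):
    rows = [(g, "maize1", "B1", "chr1", i * 100 + 1, i * 100 + 50) for i, g in enumerate(m1)]
    rows += [(g, "maize2", "B1", "chr6", i * 100 + 1, i * 100 + 50) for i, g in enumerate(m2)]
    rows += [(g, "ambiguous", ".", "chr9", i * 100 + 1, i * 100 + 50) for i, g in enumerate(ambiguous)]
    return pd.DataFrame(rows, columns=["gene_id", "subgenome", "block_id", "chrom", "start", "end"])


def complete_graph(genes):
    return network_from_edges(
        [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]], genes=genes
    )


class TestCountSubgenomeEdges:
    def test_complete_graph_partition(self):
        net = complete_graph(["a1", "a2", "b1", "b2"])
        frac = count_subgenome_edges(net, make_map(["a1", "a2"], ["b1", "b2"]))
        assert (frac.m1_intra, frac.m2_intra, frac.inter) == (1, 1, 4)
        assert frac.densities == (1.0, 1.0, 1.0)

    def test_ambiguous_gene_excluded(self):
        net = complete_graph(["a1", "a2", "b1", "x1"])
        frac = count_subgenome_edges(net, make_map(["a1", "a2"], ["b1"], ambiguous=["x1"]))
        assert (frac.m1_intra, frac.m2_intra, frac.inter) == (1, 0, 2)
        assert frac.dropped_edges == 3

    def test_edge_partition_conservation(self, rng):
        genes = [f"g{i}" for i in range(20)]
        edges = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :] if rng.random() < 0.3]
        net = network_from_edges(edges, genes=genes)
        frac = count_subgenome_edges(net, make_map(genes[:8], genes[8:15], ambiguous=genes[15:]))
        assert frac.total_edges + frac.dropped_edges == len(edges)

    def test_empty_labeled_subset_raises(self):
        net = complete_graph(["x1", "x2"])
        with pytest.raises(ValueError, match="labeled"):
            count_subgenome_edges(net, make_map([], [], ambiguous=["x1", "x2"]))


class TestPathwayFractionation:
    def build(self, edge_probs, rng, n_pathways=10, n1=8, n2=8):
        genes, pathways, edges = [], {}, []
        m1, m2 = [], []
        for p in range(n_pathways):
            pm1 = [f"p{p}m1_{i}" for i in range(n1)]
            pm2 = [f"p{p}m2_{i}" for i in range(n2)]
            members = pm1 + pm2
            pathways[f"PWY{p}"] = members
            genes += members
            m1 += pm1
            m2 += pm2
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    both1 = a in pm1 and b in pm1
                    both2 = a in pm2 and b in pm2
                    pr = edge_probs[0] if both1 else edge_probs[1] if both2 else edge_probs[2]
                    if rng.random() < pr:
                        edges.append((a, b))
        return network_from_edges(edges, genes=genes), make_map(m1, m2), pathways

    def test_min_edges_filter(self, rng):
        net, smap, pathways = self.build((0.5, 0.5, 0.5), rng, n_pathways=3)
        # add one tiny pathway with exactly 6 edges
        extra = [f"t{i}" for i in range(4)]
        tiny_edges = [(a, b) for i, a in enumerate(extra) for b in extra[i + 1 :]][:6]
        net2 = network_from_edges(list(zip(net.edges["gene1"], net.edges["gene2"])) + tiny_edges,
                                  genes=net.gene_ids + extra)
        smap2 = pd.concat([smap, make_map(extra[:2], extra[2:])], ignore_index=True)
        pathways["tiny"] = extra
        per_pathway, _ = pathway_fractionation(net2, smap2, pathways, min_edges=7)
        assert "tiny" not in set(per_pathway["pathway"])

    def test_min_wgd_pairs_filter(self, rng):
        net, smap, pathways = self.build((0.5, 0.5, 0.5), rng, n_pathways=3)
        pairs = pd.DataFrame(
            {
                "gene1": ["p0m1_0", "p0m1_1", "p1m1_0"],
                "gene2": ["p0m2_0", "p0m2_1", "p1m2_0"],
                "dup_type": ["WGD", "WGD", "WGD"],
            }
        )
        with pytest.raises(ValueError, match="pathways pass"):
            # only pathway 0 has >= 2 WGD pairs -> fewer than 2 retained pathways
            pathway_fractionation(net, smap, pathways, pairs=pairs)

    def test_degenerate_differences_give_p_one(self):
        # identical pathway graphs: every paired difference is exactly 0
        genes1 = [f"a{i}" for i in range(6)]
        genes2 = [f"b{i}" for i in range(6)]
        edges = []
        for gs in (genes1, genes2):
            edges += [(x, y) for i, x in enumerate(gs) for y in gs[i + 1 :]]
        net = network_from_edges(edges, genes=genes1 + genes2)
        smap = make_map(genes1[:3] + genes2[:3], genes1[3:] + genes2[3:])
        pathways = {"P1": genes1, "P2": genes2}
        _, tests = pathway_fractionation(net, smap, pathways, min_edges=7)
        stat, p = tests["m1_vs_m2_density"]
        assert stat == 0.0 and p == 1.0


class TestPermuteEdgeNull:
    def test_expected_inter_fraction(self):
        out = permute_edge_null(10, 10, 60, observed_inter=30, n_perm=400, seed=1)
        # uniform pairs: inter fraction 100/190
        assert out["null_mean"] / 60 == pytest.approx(100 / 190, abs=0.02)

    def test_central_observation_large_p(self):
        out = permute_edge_null(15, 15, 80, observed_inter=0, n_perm=200, seed=2)
        center = int(round(out["null_mean"]))
        out2 = permute_edge_null(15, 15, 80, observed_inter=center, n_perm=200, seed=2)
        assert out2["p_value"] > 0.5

    def test_determinism_and_feasibility(self):
        a = permute_edge_null(8, 8, 30, 10, n_perm=100, seed=3)
        b = permute_edge_null(8, 8, 30, 10, n_perm=100, seed=3)
        assert (a["null"] == b["null"]).all() and a["p_value"] == b["p_value"]
        with pytest.raises(ValueError, match="edge count"):
            permute_edge_null(3, 3, 100, 5)

    def test_sampled_edges_distinct_and_counted(self, rng):
        i, j = _sample_edges(rng, 30, 200)
        assert len(i) == 200
        codes = i * 30 + j
        assert len(np.unique(codes)) == 200
        assert (i < j).all()


class TestContingency:
    def test_homogeneous_table_zero_statistic(self):
        frac = EdgeFractionation(10, 10, 20, 100, 100, 200, 15, 15, 0)
        stat, p = contingency_edge_test(frac)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_equal_proportions_example(self):
        # table (10, 90 | 20, 180): both rows have proportion 0.1
        frac = EdgeFractionation(10, 0, 20, 100, 0, 200, 20, 10, 0)
        stat, _ = contingency_edge_test(frac)
        assert stat == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(1, 40, size=4)
        frac = EdgeFractionation(
            int(obs[0]), 0, int(obs[2]),
            int(obs[0] + obs[1]), 0, int(obs[2] + obs[3]),
            5, 5, 0,
        )
        stat, _ = contingency_edge_test(frac)
        table = np.array([[obs[0], obs[1]], [obs[2], obs[3]]])
        assert stat == pytest.approx(chi_square_statistic(table), rel=1e-9)

    def test_empty_row_raises(self):
        frac = EdgeFractionation(0, 0, 0, 10, 10, 20, 5, 5, 0)
        with pytest.raises(ValueError, match="empty"):
            contingency_edge_test(frac)


class TestModuleEnrichment:
    def test_background_proportions_give_zero(self):
        assign = ModuleAssignment({f"a{i}": 0 for i in range(20)} | {f"b{i}": 0 for i in range(10)}, 0)
        smap = make_map(
            [f"a{i}" for i in range(40)] + ["z1", "z2"], [f"b{i}" for i in range(20)] + ["y1"]
        )
        out = module_subgenome_enrichment(assign, smap, background=(2, 1))
        assert out.loc[0, "chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_adjusted"] == pytest.approx(1.0)

    def test_small_module_skipped(self):
        assign = ModuleAssignment(
            {f"a{i}": 0 for i in range(10)} | {f"b{i}": 0 for i in range(9)}  # 19 labeled
            | {f"c{i}": 1 for i in range(15)} | {f"d{i}": 1 for i in range(15)},
            0,
        )
        smap = make_map(
            [f"a{i}" for i in range(10)] + [f"c{i}" for i in range(15)],
            [f"b{i}" for i in range(9)] + [f"d{i}" for i in range(15)],
        )
        out = module_subgenome_enrichment(assign, smap)
        assert out["module_id"].tolist() == [1]

    def test_bonferroni_multiplication(self):
        # 5 tested modules -> adjusted p = 5 * raw p
        modules = {}
        for m in range(5):
            skew = 10 + 4 * m
            modules.update({f"m{m}a{i}": m for i in range(skew)})
            modules.update({f"m{m}b{i}": m for i in range(30 - skew)})
        m1 = [g for g in modules if "a" in g]
        m2 = [g for g in modules if "b" in g]
        out = module_subgenome_enrichment(ModuleAssignment(modules, 0), make_map(m1, m2))
        assert len(out) == 5
        expected = np.minimum(1.0, out["p_value"] * 5)
        assert np.allclose(out["p_adjusted"], expected)

    def test_no_tested_modules_warns_empty(self):
        assign = ModuleAssignment({"a1": 0, "b1": 0}, 0)
        with pytest.warns(UserWarning):
            out = module_subgenome_enrichment(assign, make_map(["a1"], ["b1"]))
        assert len(out) == 0


class TestHubs:
    def test_star_center_flagged(self, rng):
        n_bg, m_bg = 500, 600
        genes = [f"g{i}" for i in range(n_bg)]
        i, j = _sample_edges(rng, n_bg, m_bg)
        edges = [(genes[a], genes[b]) for a, b in zip(i, j)]
        center = "hub0"
        edges += [(center, genes[k]) for k in range(49)]
        net = network_from_edges(edges, genes=genes + [center])
        res = detect_hub_genes(net, n_perm=100, seed=5)
        assert res.hub_flags[center]
        assert res.degrees[center] == 49

    def test_determinism(self, toy_network):
        r1 = detect_hub_genes(toy_network, n_perm=50, seed=7)
        r2 = detect_hub_genes(toy_network, n_perm=50, seed=7)
        assert r1.cutoff == r2.cutoff
        assert r1.hub_flags.equals(r2.hub_flags)

    def test_null_graphs_match_node_and_edge_counts(self, rng):
        i, j = _sample_edges(rng, 40, 75)
        assert len(i) == 75
        assert ((0 <= i) & (i < 40) & (0 <= j) & (j < 40)).all()


class TestHubBias:
    def test_background_proportions_zero_statistic(self):
        degrees = pd.Series([10] * 30, index=[f"a{i}" for i in range(20)] + [f"b{i}" for i in range(10)])
        hubs = _hub_result(degrees, cutoff=5)
        smap = make_map([f"a{i}" for i in range(40)], [f"b{i}" for i in range(20)])
        stat, _ = hub_subgenome_bias(hubs, smap, background=(2, 1))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_all_m1_hubs_against_even_background(self):
        degrees = pd.Series([10] * 20, index=[f"a{i}" for i in range(20)])
        hubs = _hub_result(degrees, cutoff=5)
        smap = make_map([f"a{i}" for i in range(20)], [f"b{i}" for i in range(20)])
        stat, _ = hub_subgenome_bias(hubs, smap, background=(50, 50))
        assert stat == pytest.approx(20.0)

    def test_relabeling_invariance(self, rng):
        idx = [f"a{i}" for i in range(12)] + [f"b{i}" for i in range(8)]
        degrees = pd.Series(rng.integers(6, 20, size=20), index=idx)
        hubs = _hub_result(degrees, cutoff=5)
        smap = make_map([f"a{i}" for i in range(12)], [f"b{i}" for i in range(8)])
        stat1, _ = hub_subgenome_bias(hubs, smap, background=(30, 20))
        renamed = {g: f"x_{g}" for g in idx}
        hubs2 = _hub_result(degrees.rename(renamed), cutoff=5)
        smap2 = smap.assign(gene_id=smap["gene_id"].map(renamed))
        stat2, _ = hub_subgenome_bias(hubs2, smap2, background=(30, 20))
        assert stat1 == pytest.approx(stat2)

    def test_no_labeled_hubs_raises(self):
        degrees = pd.Series([10], index=["q1"])
        with pytest.raises(ValueError, match="label"):
            hub_subgenome_bias(_hub_result(degrees, 5), make_map(["a1"], ["b1"]), background=(1, 1))


def _hub_result(degrees, cutoff):
    from coexdup.subgenome import HubResult

    return HubResult(
        degrees=degrees,
        cutoff=cutoff,
        hub_flags=degrees > cutoff,
        n_permutations=0,
        alpha=0.05,
        null_stat="pooled",
    )
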
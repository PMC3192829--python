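import networkx as nx
import numpy as np
import pytest

import glyconet as g
import glyconet.reporting as rep
from glyconet.netinfer import CoexpressionNetwork


def star_network(center="hub", n_leaves=6):
    graph = nx.Graph()
    for i in range(n_leaves):
        graph.add_edge(center, f"leaf{i}", r=0.95, sign="+")
    return CoexpressionNetwork(graph=graph, tau=0.9, mode="positive")


def annotations(cogs):
    return [g.GeneAnnotation(gid, cog=c) for gid, c in cogs.items()]


class TestCogComposition:
    def make_module(self, size=138, top3=(("G", 19), ("C", 19), ("E", 12)), other=0):
        genes = [f"m{i:03d}" for i in range(size)]
        cogs = {}
        k = 0
        for letter, n in top3:
            for _ in range(n):
                cogs[genes[k]] = letter
                k += 1
        for i in range(other):
            cogs[genes[k]] = "JKLOPQRSTH"[i % 10]
            k += 1
        return genes, annotations(cogs)

    def test_top3_share_prints_36_percent(self):
        genes, anns = self.make_module()
        counts, major = g.cog_composition(genes, anns, top_k=3)
        assert counts == {"G": 19, "C": 19, "E": 12}
        assert major == 36.2
        assert g.display_percent(major) == "36%"

    def test_remaining_members_share_prints_39_1_percent(self):
        remaining = rep.percent(54, 138)
        assert remaining == 39.1

    def test_unannotated_module_gives_zero(self):
        genes = [f"m{i}" for i in range(10)]
        counts, major = g.cog_composition(genes, [], top_k=3)
        assert counts == {} and major == 0.0

    def test_category_percentages_sum_to_about_100(self):
        genes, anns = self.make_module(size=60, top3=(("G", 25), ("C", 20), ("E", 15)))
        counts, _ = g.cog_composition(genes, anns, top_k=3)
        pcts = rep.cog_percentages(counts, 60)
        unannotated = rep.percent(60 - sum(counts.values()), 60)
        total = sum(pcts.values()) + unannotated
        assert abs(total - 100.0) <= 0.1 * (len(pcts) + 1)


class TestHubRanking:
    def test_star_center_ranks_first(self):
        ranked = g.hub_ranking(star_network(), n_top=23)
        assert ranked[0] == ("hub", 6)

    def test_degree_ties_break_on_gene_id(self):
        graph = nx.Graph()
        for leaf in "abcd":
            graph.add_edge("z1", leaf, r=0.95, sign="+")
            graph.add_edge("a1", leaf, r=0.95, sign="+")
        net = CoexpressionNetwork(graph=graph, tau=0.9, mode="positive")
        ranked = g.hub_ranking(net, n_top=2)
        assert [r[0] for r in ranked] == ["a1", "z1"]

    def test_planted_hubs_dominate_top_23(self):
        """Extra factor loading gives the planted hub of each module a
        systematically higher degree at a cutoff inside the module
        correlation band, so hubs fill the top-23 list.  Nine replicates
        per condition keep whole-module sampling luck (the shared factor
        realization shifts all of a module's correlations together) small
        against the hub's loading advantage."""
        conds = g.default_design().conditions()
        samples = []
        for i, (sub, ph) in enumerate(conds):
            for rep in range(1, 10):
                samples.append(g.Sample(f"c{i}_{ph}_{rep}", sub, ph, rep))
        design = g.SampleDesign(tuple(samples))
        found = total = 0
        for seed in range(10):
            spec = g.SyntheticSpec(
                n_genes=360,
                design=design,
                modules=tuple(
                    g.ModuleSpec(f"M{k}", 20, within_module_correlation=0.90,
                                 n_hubs=1)
                    for k in range(13)
                ),
                n_negative_controls=0,
                snr_dropout_rate=0.0,
                seed=seed,
            )
            x, truth = g.simulate(spec)
            c = g.pearson_matrix(x)
            net = g.build_network(c, 0.93, mode="positive")
            top = {gid for gid, _ in g.hub_ranking(net, n_top=23)}
            hubs = {h for hs in truth.hub_genes.values() for h in hs}
            found += len(top & hubs)
            total += len(hubs)
        assert found / total >= 0.8

    def test_planted_hub_is_best_connected_in_its_module(self):
        """At the study's replication level the hub still tops its own
        module's degree ranking."""
        spec = g.SyntheticSpec(
            n_genes=400,
            modules=tuple(
                g.ModuleSpec(f"M{k}", 20, within_module_correlation=0.90, n_hubs=1)
                for k in range(13)
            ),
            n_negative_controls=0, snr_dropout_rate=0.0, seed=0,
        )
        x, truth = g.simulate(spec)
        net = g.build_network(g.pearson_matrix(x), 0.92, mode="positive")
        deg = dict(net.graph.degree)
        on_top = sum(
            deg.get(truth.hub_genes[mid][0], 0)
            == max(deg.get(m, 0) for m in truth.members(mid))
            for mid in truth.hub_genes
        )
        assert on_top >= 11  # 13 modules; allow rare sampling upsets


class TestInterModuleLinks:
    def partition(self, modules):
        assignment = {gid: f"c{k}" for k, mem in enumerate(modules) for gid in mem}
        return g.ModulePartition(
            assignment=assignment, modularity_q=0.5,
            modules=[(k + 1, sorted(mem)) for k, mem in enumerate(modules)],
            unassigned=[], min_module_size=1)

    def two_module_net(self, cross_edges):
        graph = nx.Graph()
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        for mem in (a, b):
            for u, v in zip(mem, mem[1:]):
                graph.add_edge(u, v, r=0.95, sign="+")
        for u, v in cross_edges:
            graph.add_edge(u, v, r=0.95, sign="+")
        net = CoexpressionNetwork(graph=graph, tau=0.9, mode="positive")
        return net, self.partition([a, b])

    def test_no_cross_edges_means_both_standalone(self):
        net, p = self.two_module_net([])
        links = g.inter_module_links(net, p)
        assert rep.standalone_modules(links) == [1, 2]

    def test_single_cross_edge_counted_symmetrically(self):
        net, p = self.two_module_net([("a0", "b0")])
        links = g.inter_module_links(net, p)
        assert links.loc[1, 2] == 1 and links.loc[2, 1] == 1
        assert rep.module_interaction_degrees(links).tolist() == [1, 1]
        assert rep.standalone_modules(links) == []

    def test_matrix_sum_is_twice_cross_edge_count(self):
        net, p = self.two_module_net([("a0", "b0"), ("a1", "b3"), ("a2", "b4")])
        links = g.inter_module_links(net, p)
        assert links.to_numpy().sum() == 2 * 3
        assert (np.diag(links.to_numpy()) == 0).all()
        assert (links.to_numpy() == links.to_numpy().T).all()

    def test_preset_modules_are_standalone(self, preset_result):
        """Planted modules share no latent factor, so the recovered network
        should report them all as standalone."""
        links = g.inter_module_links(preset_result.network, preset_result.partition)
        assert len(rep.standalone_modules(links)) == preset_result.partition.n_modules


class TestFirstNeighbors:
    def test_seed_neighborhood_is_induced_subgraph(self):
        net = star_network(n_leaves=21)
        sub = g.first_neighbors(net, ["hub"])
        assert sub.n_nodes == 22
        assert sub.n_edges == 21

    def test_edge_between_two_neighbors_retained(self):
        graph = nx.Graph()
        graph.add_edge("s", "n1", r=0.95, sign="+")
        graph.add_edge("s", "n2", r=0.95, sign="+")
        graph.add_edge("n1", "n2", r=0.96, sign="+")
        graph.add_edge("n2", "far", r=0.97, sign="+")
        net = CoexpressionNetwork(graph=graph, tau=0.9, mode="positive")
        sub = g.first_neighbors(net, ["s"])
        assert ("n1", "n2") in sub.graph.edges
        assert "far" not in sub.graph

    def test_unknown_seed_skipped_with_warning(self):
        net = star_network()
        with pytest.warns(UserWarning, match="ghost"):
            sub = g.first_neighbors(net, ["hub", "ghost"])
        assert sub.n_nodes == 7

    def test_all_unknown_seeds_error(self):
        with pytest.raises(ValueError):
            g.first_neighbors(star_network(), ["ghost"])

    def test_idempotent_when_reseeded_with_own_nodes(self):
        net = star_network(n_leaves=4)
        once = g.first_neighbors(net, ["hub"])
        twice = g.first_neighbors(once, once.nodes)
        assert set(once.graph.edges) == set(twice.graph.edges)


class TestReport:
    def test_report_determinism_excluding_timestamp(self, preset_result):
        r1 = rep.run_report(n_genes_on_array=100, net=preset_result.network,
                            partition=preset_result.partition, seed=1,
                            config={"a": 1}, timestamp="t1")
        r2 = rep.run_report(n_genes_on_array=100, net=preset_result.network,
                            partition=preset_result.partition, seed=1,
                            config={"a": 1}, timestamp="t2")
        r1.pop("timestamp"), r2.pop("timestamp")
        assert r1 == r2

    def test_empty_network_report_has_warning(self):
        net = CoexpressionNetwork(graph=nx.Graph(), tau=0.94, mode="positive")
        report = rep.run_report(net=net)
        assert report["genes_in_network"] == 0
        assert any("empty" in w for w in report["warnings"])

    def test_missing_stages_are_explicit_nulls(self):
        report = rep.run_report()
        assert report["selected_tau"] is None
        assert report["n_modules"] is None


def test_exports_are_readable(tmp_path, preset_result):
    net = g.first_neighbors(preset_result.network,
                            preset_result.partition.modules[-1][1][:3])
    rep.write_edge_list(net, tmp_path / "edges.tsv")
    rep.write_sif(net, tmp_path / "net.sif")
    rep.write_gml(net, tmp_path / "net.gml")
    import pandas as pd

    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert set(edges.columns) == {"gene_a", "gene_b", "r", "sign"}
    assert len(edges) == net.n_edges
    back = nx.read_gml(tmp_path / "net.gml")
    assert back.number_of_edges() == net.n_edges
    sif = (tmp_path / "net.sif").read_text().splitlines()
    assert len(sif) == net.n_edges
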
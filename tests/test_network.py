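"""Correlation network construction, degree filtering, pathway burden,
ego networks, and the four-priority ranking."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from retinotarget import network as net
from retinotarget.io import Pathway, PathwayCatalog
from retinotarget.peaks import CandidateSet
from conftest import make_matrix

import oracles


def random_matrix(rng, n_genes, n_samples=10):
    ids = [f"TRC_d{d:g}_r{r}" for d in range(n_samples // 2) for r in (1, 2)]
    ids = ids[:n_samples]
    return make_matrix(
        rng.normal(size=(n_genes, len(ids))), [f"g{i:02d}" for i in range(n_genes)], ids
    )


def manual_network(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, pcc=1.0, p_value=0.0)
    return net.CorrelationNetwork(graph=g, pcc_min=0.9, p_max=0.05)


class TestBuildNetwork:
    def test_affine_copy_gets_edge(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=9)
        ids = [f"TRC_d{d:g}_r{r}" for d in (0.0, 1.0, 5.0) for r in (1, 2, 3)]
        m = make_matrix(np.vstack([base, 2 * base + 1]), ["a", "b"], ids)
        network = net.build_pcc_network(m)
        assert network.degree == {"a": 1, "b": 1}
        assert network.edges.iloc[0]["pcc"] == pytest.approx(1.0)

    def test_correlation_exactly_at_threshold_is_excluded(self):
        # strict >: an edge whose |r| equals the threshold float exactly
        # must not appear, while any threshold below it admits the edge
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 2, 10)
        x = m.values.to_numpy()
        r = float(np.corrcoef(x[0], x[1])[0, 1])
        at = net.build_pcc_network(m, pcc_min=abs(r), p_max=1.1)
        below = net.build_pcc_network(m, pcc_min=abs(r) - 1e-9, p_max=1.1)
        assert len(at.edges) == 0
        assert len(below.edges) == 1

    def test_too_few_samples_rejected(self):
        m = make_matrix(np.ones((2, 2)), ["a", "b"], ["TRC_d0_r1", "TRC_d0_r2"])
        with pytest.raises(ValueError, match="3 samples"):
            net.build_pcc_network(m)

    def test_unknown_gene_rejected(self, sim_expression):
        with pytest.raises(ValueError, match="absent"):
            net.build_pcc_network(sim_expression.matrix, genes={"NOPE"})

    def test_zero_variance_gene_is_isolated(self):
        rng = np.random.default_rng(2)
        ids = [f"TRC_d{d:g}_r{r}" for d in (0.0, 1.0) for r in (1, 2, 3)]
        vals = np.vstack([np.full(6, 3.0), rng.normal(size=(2, 6))])
        m = make_matrix(vals, ["flat", "a", "b"], ids)
        network = net.build_pcc_network(m, pcc_min=0.0, p_max=1.1)
        assert network.degree["flat"] == 0

    def test_edges_match_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            m = random_matrix(rng, 30, 10)
            # mix in correlated pairs so edges actually occur
            x = m.values.to_numpy()
            x[1] = x[0] * 1.5 + rng.normal(0, 0.1, size=x.shape[1])
            x[2] = -x[0] + rng.normal(0, 0.05, size=x.shape[1])
            pcc_min = float(rng.uniform(0.3, 0.9))
            network = net.build_pcc_network(m, pcc_min=pcc_min)
            got = {
                (row.gene_a, row.gene_b) for row in network.edges.itertuples()
            }
            assert got == oracles.pcc_edges_bruteforce(m.values, pcc_min, 0.05)

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 20, 8)
        prev = None
        for pcc_min in (0.3, 0.5, 0.7, 0.9):
            network = net.build_pcc_network(m, pcc_min=pcc_min, p_max=1.1)
            edges = {(r.gene_a, r.gene_b) for r in network.edges.itertuples()}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_degree_sum_is_twice_edge_count(self, sim_expression):
        network = net.build_pcc_network(sim_expression.matrix)
        assert sum(network.degree.values()) == 2 * len(network.edges)


class TestDegreeFilter:
    def test_boundary_degree_retained(self):
        edges = [("hub", f"n{i}") for i in range(18)]
        network = manual_network(edges, nodes=["lone"])
        assert "hub" in net.degree_filter(network, 18)
        assert net.degree_filter(network, 19) == set()

    def test_star_graph_keeps_only_hub(self):
        network = manual_network([("hub", f"leaf{i}") for i in range(20)])
        assert net.degree_filter(network) == {"hub"}

    def test_edgeless_network_empty(self):
        network = manual_network([], nodes=["a", "b"])
        assert net.degree_filter(network) == set()


class TestPathwayBurden:
    def test_direct_counts(self):
        catalog = PathwayCatalog(
            {
                "RAS": Pathway("ras", ("SOS2", "KRAS"), oncogenic=True),
                "CC": Pathway("cell cycle", ("SOS2",), oncogenic=True),
                "OTHER": Pathway("other", ("TP53",), oncogenic=False),
            }
        )
        assert net.pathway_burden("SOS2", catalog) == (2, 2)
        assert net.pathway_burden("ABSENT", catalog) == (0, 0)

    def test_matches_membership_scan_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        catalog = PathwayCatalog(
            {
                f"PW{i}": Pathway(
                    f"pw {i}",
                    tuple(rng.choice(genes, size=rng.integers(1, 10), replace=False)),
                    oncogenic=bool(rng.random() < 0.3),
                )
                for i in range(50)
            }
        )
        for g in genes:
            assert net.pathway_burden(g, catalog) == oracles.gmt_counts_bruteforce(
                g, catalog
            )


class TestEgo:
    def test_isolated_center(self):
        network = manual_network([], nodes=["a"])
        ego = net.ego_subnetwork(network, "a")
        assert ego.nodes == ["a"] and len(ego.edges) == 0

    def test_star_hub_returns_full_star(self):
        network = manual_network([("hub", f"leaf{i}") for i in range(5)])
        ego = net.ego_subnetwork(network, "hub")
        assert set(ego.nodes) == {"hub"} | {f"leaf{i}" for i in range(5)}
        assert len(ego.edges) == 5

    def test_absent_center_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            net.ego_subnetwork(manual_network([], nodes=["a"]), "nope")

    def test_neighbors_match_adjacency_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            nodes = [f"g{i}" for i in range(30)]
            edge_set = {
                tuple(sorted(rng.choice(nodes, size=2, replace=False)))
                for _ in range(60)
            }
            network = manual_network(edge_set, nodes=nodes)
            center = nodes[int(rng.integers(30))]
            ego = net.ego_subnetwork(network, center)
            expected = oracles.ego_bruteforce(edge_set, center)
            assert set(ego.nodes) - {center} == expected


class TestPriorityRank:
    @staticmethod
    def _catalog():
        return PathwayCatalog(
            {
                "RAS_SIGNALING": Pathway("ras", ("d",), oncogenic=True),
                "PW": Pathway("pw", ("d", "x"), oncogenic=False),
            }
        )

    def test_membership_breaks_final_tie(self):
        network = manual_network(
            [("a", f"n{i}") for i in range(20)] + [("b", f"n{i}") for i in range(20)]
        )
        cand = CandidateSet(peak_m={"a": 1.0, "b": 1.0}, n_peaks={"a": 1, "b": 1})
        u = pd.DataFrame({"cluster_1": [0.8, 0.3]}, index=["a", "b"])
        catalog = PathwayCatalog({"PW": Pathway("p", ("zzz",), oncogenic=False)})
        ranked = net.priority_rank(cand, network, catalog, u, top_n=10)
        assert list(ranked["gene_id"]) == ["a", "b"]
        assert list(ranked["priority_rank"]) == [1, 2]

    def test_degree_outranks_everything(self):
        network = manual_network(
            [("lo", f"n{i}") for i in range(19)] + [("hi", f"m{i}") for i in range(20)]
        )
        cand = CandidateSet(peak_m={"lo": 2.0, "hi": 0.6}, n_peaks={"lo": 1, "hi": 1})
        u = pd.DataFrame({"cluster_1": [1.0, 0.3]}, index=["lo", "hi"])
        ranked = net.priority_rank(cand, network, self._catalog(), u)
        assert list(ranked["gene_id"]) == ["hi", "lo"]

    def test_below_degree_filter_excluded_and_warns(self):
        network = manual_network([("a", "n0")])
        cand = CandidateSet(peak_m={"a": 1.0}, n_peaks={"a": 1})
        u = pd.DataFrame({"cluster_1": [0.9]}, index=["a"])
        with pytest.warns(UserWarning, match="candidates survive"):
            ranked = net.priority_rank(cand, network, self._catalog(), u)
        assert len(ranked) == 0

    def test_ranking_stable_under_input_permutation(self, sim_expression):
        rng = np.random.default_rng(8)
        matrix = sim_expression.matrix
        network = net.build_pcc_network(matrix)
        genes = matrix.gene_ids
        cand_genes = [g for g, d in network.degree.items() if d >= 18][:6]
        if not cand_genes:
            pytest.skip("no high-degree genes in this draw")
        cand = CandidateSet(
            peak_m={g: float(rng.uniform(0.5, 1.5)) for g in cand_genes},
            n_peaks={g: 1 for g in cand_genes},
        )
        u = pd.DataFrame(
            {"cluster_1": rng.uniform(0.2, 1.0, size=len(genes))}, index=genes
        )
        catalog = self._catalog()
        ranked = net.priority_rank(cand, network, catalog, u)

        perm = rng.permutation(len(genes))
        shuffled = matrix.values.iloc[perm]
        m2 = make_matrix(
            shuffled.to_numpy(), list(shuffled.index), matrix.sample_ids
        )
        ranked2 = net.priority_rank(
            cand, net.build_pcc_network(m2), catalog, u.iloc[perm]
        )
        pd.testing.assert_frame_equal(ranked, ranked2)
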
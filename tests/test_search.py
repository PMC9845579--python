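import networkx as nx
import numpy as np
import pandas as pd
import pytest

from panomicnet import synthetic
from panomicnet.datasets import PanomicDataset, VariableMeta, class_map
from panomicnet.scoring import PenaltyConfig
from panomicnet.search import (
    ConsensusGraph,
    ConstraintSet,
    Ensemble,
    NetworkModel,
    edge_frequencies,
    enumerate_best_dag,
    fit_ensemble,
    hill_climb,
    phenotype_parent_report,
    subnetwork,
)

from conftest import make_chain_dataset, make_noise_dataset, penalty_for


class TestHillClimb:
    def test_pure_noise_returns_empty_dag(self):
        ds = make_noise_dataset(6, 300, seed=10)
        model = hill_climb(ds, penalty_for(ds), seed=0, restarts=2)
        assert len(model.dag.edges) == 0

    def test_chain_attains_enumeration_optimum(self):
        ds = make_chain_dataset(3, 500, seed=1, coef=1.0, noise=0.5)
        cfg = penalty_for(ds)
        best, n_cand = enumerate_best_dag(ds, cfg)
        assert n_cand == 25
        model = hill_climb(ds, cfg, seed=1, restarts=20)
        assert model.score == pytest.approx(best.score, abs=1e-9)

    def test_deterministic_given_seed(self):
        ds = make_chain_dataset(4, 200, seed=2)
        cfg = penalty_for(ds)
        a = hill_climb(ds, cfg, seed=3, restarts=5)
        b = hill_climb(ds, cfg, seed=3, restarts=5)
        assert a.edges == b.edges and a.score == b.score

    def test_score_never_worse_than_empty(self):
        ds = make_noise_dataset(5, 150, seed=4)
        cfg = penalty_for(ds)
        empty = NetworkModel.from_dag(ds, nx.DiGraph(), cfg)
        model = hill_climb(ds, cfg, seed=0, restarts=3)
        assert model.score <= empty.score + 1e-9

    def test_genotype_roots_never_gain_parents(self, default_spec):
        ds = synthetic.sample_dataset(default_spec, 250, seed=5)
        model = hill_climb(ds, penalty_for(ds), seed=0, restarts=2)
        genos = [m.name for m in ds.meta if m.kind == "genotype_additive"]
        for g in genos:
            assert model.dag.in_degree(g) == 0


class TestEnumerate:
    def test_single_variable(self):
        ds = make_noise_dataset(1, 50, seed=6)
        best, count = enumerate_best_dag(ds, penalty_for(ds))
        assert count == 1 and len(best.dag.edges) == 0

    @pytest.mark.parametrize("p,expected", [(3, 25), (4, 543)])
    def test_known_dag_counts(self, p, expected):
        ds = make_noise_dataset(p, 60, seed=p)
        _, count = enumerate_best_dag(ds, penalty_for(ds))
        assert count == expected

    def test_refuses_large_p(self):
        ds = make_noise_dataset(6, 30, seed=7)
        with pytest.raises(ValueError, match="p <= 5"):
            enumerate_best_dag(ds, penalty_for(ds))


class TestEnsemble:
    def test_single_member_reduces_to_hill_climb(self):
        ds = make_chain_dataset(3, 300, seed=8)
        cfg = penalty_for(ds)
        ens = fit_ensemble(ds, cfg, n_networks=1, resample="seed_only", base_seed=5)
        assert len(ens) == 1

    def test_reproducible_from_base_seed(self):
        ds = make_chain_dataset(3, 200, seed=9)
        cfg = penalty_for(ds)
        e1 = fit_ensemble(ds, cfg, n_networks=5, base_seed=11)
        e2 = fit_ensemble(ds, cfg, n_networks=5, base_seed=11)
        assert [m.edges for m in e1] == [m.edges for m in e2]

    def test_true_chain_edges_highly_frequent(self):
        ds = make_chain_dataset(3, 600, seed=12, coef=1.0, noise=0.5)
        cfg = penalty_for(ds)
        ens = fit_ensemble(ds, cfg, n_networks=50, resample="bootstrap", base_seed=13)
        cons = edge_frequencies(ens)
        for u, v in (("v0", "v1"), ("v1", "v2")):
            pair = cons.freq.get((u, v), 0.0) + cons.freq.get((v, u), 0.0)
            assert pair >= 0.8


def _member_with_edges(ds, cfg, edges):
    dag = nx.DiGraph(edges)
    dag.add_nodes_from(ds.names)
    return NetworkModel.from_dag(ds, dag, cfg)


class TestConsensus:
    @pytest.fixture()
    def small(self):
        ds = make_noise_dataset(4, 40, seed=14)
        return ds, penalty_for(ds)

    def test_identical_members_freq_one(self, small):
        ds, cfg = small
        m = _member_with_edges(ds, cfg, [("v0", "v1")])
        cons = edge_frequencies(Ensemble(members=[m, m, m]))
        assert cons.freq[("v0", "v1")] == 1.0
        assert ("v0", "v1") in cons.reported_edges()

    def test_threshold_is_strict(self, small):
        ds, cfg = small
        rare = _member_with_edges(ds, cfg, [("v0", "v1")])
        empty = _member_with_edges(ds, cfg, [])
        cons = edge_frequencies(Ensemble(members=[rare] + [empty] * 19))
        assert cons.freq[("v0", "v1")] == pytest.approx(0.05)
        assert ("v0", "v1") not in cons.reported_edges()  # strict >
        common = Ensemble(members=[rare] * 19 + [empty])
        cons2 = edge_frequencies(common)
        assert cons2.freq[("v0", "v1")] == pytest.approx(0.95)
        assert ("v0", "v1") in cons2.reported_edges()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            edge_frequencies(Ensemble(members=[]))

    def test_export_round_trip(self, small, tmp_path):
        ds, cfg = small
        m = _member_with_edges(ds, cfg, [("v0", "v1"), ("v1", "v2")])
        cons = edge_frequencies(Ensemble(members=[m]))
        cons.to_tsv(tmp_path / "c.tsv")
        df = pd.read_csv(tmp_path / "c.tsv", sep="\t")
        assert set(zip(df["from"], df["to"])) == {("v0", "v1"), ("v1", "v2")}
        cons.to_graphml(tmp_path / "c.graphml")
        g = nx.read_graphml(tmp_path / "c.graphml")
        assert g.number_of_edges() == 2
        cons.to_dot(tmp_path / "c.dot")
        assert '"v0" -> "v1"' in (tmp_path / "c.dot").read_text()


class TestSubnetwork:
    def _consensus(self, edges, nodes):
        return ConsensusGraph(freq={e: 1.0 for e in edges}, nodes=tuple(nodes))

    def test_isolated_focus(self):
        cons = self._consensus([("a", "b")], ["a", "b", "z"])
        sub = subnetwork(cons, "z")
        assert sub.nodes == ("z",) and sub.freq == {}

    def test_star_neighborhood(self):
        cons = self._consensus(
            [("a", "f"), ("f", "b"), ("f", "c"), ("b", "q")], ["a", "b", "c", "f", "q"]
        )
        sub = subnetwork(cons, "f", degree=1)
        assert set(sub.nodes) == {"a", "b", "c", "f"}
        assert len(sub.freq) == 3

    def test_unknown_node_rejected(self):
        cons = self._consensus([], ["a"])
        with pytest.raises(KeyError):
            subnetwork(cons, "nope")


class TestPhenotypeParentReport:
    def test_empty_consensus(self):
        cons = ConsensusGraph(freq={}, nodes=("ph",))
        assert phenotype_parent_report(cons, "ph").empty

    def test_frequencies_match_consensus(self):
        cons = ConsensusGraph(
            freq={("a", "ph"): 0.9, ("b", "ph"): 0.4, ("ph", "c"): 0.8, ("b", "a"): 0.5},
            nodes=("a", "b", "c", "ph"),
        )
        rep = phenotype_parent_report(cons, "ph")
        assert list(rep["parent"]) == ["a", "b"]
        assert list(rep["frequency"]) == [0.9, 0.4]


class TestConstraints:
    def test_tier_ordering_blocks_backward_edges(self):
        c = ConstraintSet(tiers=(("genetics",), ("biomarker",)), root_classes=())
        class_of = {"g": "genetics", "b": "biomarker"}
        assert c.edge_allowed("g", "b", class_of)
        assert not c.edge_allowed("b", "g", class_of)

    def test_sink_nodes_have_no_outgoing(self):
        c = ConstraintSet(sink_nodes=("ph",), root_classes=())
        class_of = {"ph": "phenotype", "b": "biomarker"}
        assert not c.edge_allowed("ph", "b", class_of)
        assert c.edge_allowed("b", "ph", class_of)
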
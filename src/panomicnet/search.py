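"""Constrained DAG structure search, ensembles, and consensus edge frequencies.

A single network is learned by greedy hill climbing over add/delete/reverse
edge moves from the empty graph (the default, fully-disconnected state),
with a tabu list and seeded random restarts.  An ensemble is a collection
of independently learned networks — by default each member refits on a
seeded bootstrap resample of patients — and the consensus graph annotates
every directed edge with the fraction of members containing it.  Edges are
reported when that fraction strictly exceeds the reporting threshold
(default 5%).

Genotype variables are structural roots: no move may point an edge into a
root-class node, so genetic variants act as anchors (instruments) that
orient downstream edges — the network analogue of Mendelian randomization.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import PanomicDataset
from .scoring import LocalModel, PenaltyConfig, class_penalty, local_bic

__all__ = [
    "ConstraintSet",
    "NetworkModel",
    "Ensemble",
    "ConsensusGraph",
    "hill_climb",
    "enumerate_best_dag",
    "fit_ensemble",
    "edge_frequencies",
    "subnetwork",
    "phenotype_parent_report",
]


@dataclass(frozen=True)
class ConstraintSet:
    """Structural constraints honored by every accepted DAG.

    tiers: ordered class groups; an edge may not point from a class in a
    later tier to one in an earlier tier.  root_classes: classes forbidden
    any incoming edge (genotypes by default).  sink_nodes: nodes forbidden
    outgoing edges.  max_parents: per-node in-degree cap.
    """

    tiers: tuple[tuple[str, ...], ...] = ()
    root_classes: tuple[str, ...] = ("genetics",)
    sink_nodes: tuple[str, ...] = ()
    max_parents: int = 3

    def tier_index(self, var_class: str) -> int | None:
        for i, group in enumerate(self.tiers):
            if var_class in group:
                return i
        return None

    def edge_allowed(self, u: str, v: str, class_of: dict[str, str]) -> bool:
        if class_of[v] in self.root_classes:
            return False
        if u in self.sink_nodes:
            return False
        ti, tj = self.tier_index(class_of[u]), self.tier_index(class_of[v])
        if ti is not None and tj is not None and ti > tj:
            return False
        return True


@dataclass
class NetworkModel:
    """A single fitted DAG: structure, local models, score, provenance."""

    dag: nx.DiGraph
    locals: dict[str, LocalModel]
    score: float
    seed: int | None = None
    bootstrap_indices: np.ndarray | None = None

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.dag.edges)

    def scores_frame(self) -> pd.DataFrame:
        """Per-node local scores: parents, loglik, bic, penalty, penalized."""
        rows = [
            (
                node,
                ",".join(lm.parents),
                lm.loglik,
                lm.bic,
                lm.penalized_score - lm.bic,
                lm.penalized_score,
            )
            for node, lm in self.locals.items()
        ]
        return pd.DataFrame(
            rows, columns=["node", "parents", "loglik", "bic", "penalty", "penalized_score"]
        )

    def to_tsv(self, path) -> None:
        self.scores_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dag(
        cls,
        dataset: PanomicDataset,
        dag: nx.DiGraph,
        cfg: PenaltyConfig,
        seed: int | None = None,
        bootstrap_indices: np.ndarray | None = None,
    ) -> "NetworkModel":
        """Fit all local models for a fixed structure."""
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("structure contains a cycle")
        locals_: dict[str, LocalModel] = {}
        total = 0.0
        for node in dataset.names:
            parents = tuple(sorted(dag.predecessors(node))) if dag.has_node(node) else ()
            lm = local_bic(node, parents, dataset, cfg)
            locals_[node] = lm
            total += lm.penalized_score
        full = nx.DiGraph()
        full.add_nodes_from(dataset.names)
        full.add_edges_from(dag.edges)
        return cls(dag=full, locals=locals_, score=total, seed=seed,
                   bootstrap_indices=bootstrap_indices)


@dataclass
class Ensemble:
    """Independently fitted networks over the same variable set."""

    members: list[NetworkModel]
    base_seed: int | None = None

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class ConsensusGraph:
    """Directed edge -> fraction-of-ensemble map with a reporting threshold."""

    freq: dict[tuple[str, str], float]
    threshold: float = 0.05
    nodes: tuple[str, ...] = ()

    def reported_edges(self) -> dict[tuple[str, str], float]:
        """Edges whose frequency strictly exceeds the threshold."""
        return {e: f for e, f in self.freq.items() if f > self.threshold}

    def to_frame(self, reported_only: bool = True) -> pd.DataFrame:
        src = self.reported_edges() if reported_only else self.freq
        rows = sorted(src.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            [(u, v, f) for (u, v), f in rows], columns=["from", "to", "frequency"]
        )

    # -- exports -------------------------------------------------------------

    def to_tsv(self, path, reported_only: bool = True) -> None:
        self.to_frame(reported_only).to_csv(path, sep="\t", index=False)

    def to_graphml(self, path, reported_only: bool = True) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        src = self.reported_edges() if reported_only else self.freq
        for (u, v), f in src.items():
            g.add_edge(u, v, frequency=float(f))
        nx.write_graphml(g, path)

    def to_dot(self, path, reported_only: bool = True) -> None:
        src = self.reported_edges() if reported_only else self.freq
        lines = ["digraph consensus {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for (u, v), f in sorted(src.items()):
            lines.append(f'  "{u}" -> "{v}" [label="{f:.2f}", penwidth={1 + 4 * f:.2f}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# -- scored search -----------------------------------------------------------


class _ScoreCache:
    """Memoized penalized local scores for one dataset/penalty context."""

    def __init__(self, dataset: PanomicDataset, cfg: PenaltyConfig):
        self.dataset = dataset
        self.cfg = cfg
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def score(self, child: str, parents: frozenset[str] | tuple[str, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        val = self._cache.get(key)
        if val is None:
            val = local_bic(child, key[1], self.dataset, self.cfg).penalized_score
            self._cache[key] = val
        return val


def _has_path(parents_of: dict[str, set[str]], src: str, dst: str) -> bool:
    """True if dst is an ancestor-path target of src (src ~~> dst) via child links."""
    # parents_of maps child -> parents; walk from dst upwards to find src?
    # We need: does a directed path src -> ... -> dst exist.  Walk ancestors
    # of dst; src found among them means a path exists.
    stack = [dst]
    seen = {dst}
    while stack:
        w = stack.pop()
        for par in parents_of[w]:
            if par == src:
                return True
            if par not in seen:
                seen.add(par)
                stack.append(par)
    return False


def _structure_key(parents_of: dict[str, set[str]]) -> frozenset[tuple[str, str]]:
    return frozenset((u, v) for v, ps in parents_of.items() for u in ps)


def _climb(
    parents_of: dict[str, set[str]],
    names: list[str],
    cache: _ScoreCache,
    constraints: ConstraintSet,
    class_of: dict[str, str],
    tabu: deque,
    tabu_set: set,
) -> dict[str, set[str]]:
    """Steepest-descent pass from the given structure to a local optimum."""
    node_score = {v: cache.score(v, frozenset(parents_of[v])) for v in names}
    while True:
        best_delta = -1e-9
        best_move = None
        for u, v in itertools.permutations(names, 2):
            if u in parents_of[v]:
                # delete u -> v
                new_par = frozenset(parents_of[v] - {u})
                delta = cache.score(v, new_par) - node_score[v]
                if delta < best_delta:
                    cand = {v: set(new_par)}
                    if _candidate_ok(parents_of, cand, tabu_set):
                        best_delta, best_move = delta, ("del", u, v)
                # reverse u -> v  =>  v -> u
                if (
                    constraints.edge_allowed(v, u, class_of)
                    and len(parents_of[u]) < constraints.max_parents
                ):
                    pv = parents_of[v] - {u}
                    pu = parents_of[u] | {v}
                    # cycle check: with u->v removed, path u ~~> v must not exist
                    tmp = dict(parents_of)
                    tmp[v] = pv
                    if not _has_path(tmp, u, v):
                        delta = (
                            cache.score(v, frozenset(pv))
                            + cache.score(u, frozenset(pu))
                            - node_score[v]
                            - node_score[u]
                        )
                        if delta < best_delta:
                            cand = {v: pv, u: pu}
                            if _candidate_ok(parents_of, cand, tabu_set):
                                best_delta, best_move = delta, ("rev", u, v)
            else:
                # add u -> v
                if not constraints.edge_allowed(u, v, class_of):
                    continue
                if len(parents_of[v]) >= constraints.max_parents:
                    continue
                if _has_path(parents_of, v, u):  # u -> v would close a cycle
                    continue
                new_par = frozenset(parents_of[v] | {u})
                delta = cache.score(v, new_par) - node_score[v]
                if delta < best_delta:
                    cand = {v: set(new_par)}
                    if _candidate_ok(parents_of, cand, tabu_set):
                        best_delta, best_move = delta, ("add", u, v)

        if best_move is None:
            return parents_of
        kind, u, v = best_move
        if kind == "add":
            parents_of[v] = parents_of[v] | {u}
        elif kind == "del":
            parents_of[v] = parents_of[v] - {u}
        else:
            parents_of[v] = parents_of[v] - {u}
            parents_of[u] = parents_of[u] | {v}
            node_score[u] = cache.score(u, frozenset(parents_of[u]))
        node_score[v] = cache.score(v, frozenset(parents_of[v]))
        key = _structure_key(parents_of)
        if key not in tabu_set:
            if len(tabu) == tabu.maxlen:
                tabu_set.discard(tabu[0])
            tabu.append(key)
            tabu_set.add(key)


def _candidate_ok(parents_of, changes: dict[str, set[str]], tabu_set: set) -> bool:
    if not tabu_set:
        return True
    tmp = dict(parents_of)
    tmp.update({k: set(v) for k, v in changes.items()})
    return _structure_key(tmp) not in tabu_set


def hill_climb(
    dataset: PanomicDataset,
    cfg: PenaltyConfig,
    constraints: ConstraintSet | None = None,
    seed: int = 0,
    restarts: int = 5,
    tabu_size: int = 50,
    perturb_moves: int = 4,
) -> NetworkModel:
    """Greedy structure search with tabu list and seeded random restarts.

    Starts from the empty DAG, repeatedly applies the best strictly
    score-improving legal add/delete/reverse move, then perturbs the best
    structure found with seeded random legal moves and climbs again,
    ``restarts`` times.  Deterministic given (dataset, seed).
    """
    constraints = constraints or ConstraintSet()
    names = dataset.names
    class_of = {m.name: m.var_class for m in dataset.meta}
    cache = _ScoreCache(dataset, cfg)
    rng = np.random.default_rng(seed)
    tabu: deque = deque(maxlen=tabu_size)
    tabu_set: set = set()

    def total(parents_of):
        return sum(cache.score(v, frozenset(ps)) for v, ps in parents_of.items())

    parents_of = {v: set() for v in names}
    parents_of = _climb(parents_of, names, cache, constraints, class_of, tabu, tabu_set)
    best = {v: set(ps) for v, ps in parents_of.items()}
    best_score = total(best)

    for _ in range(restarts):
        cur = {v: set(ps) for v, ps in best.items()}
        _perturb(cur, names, constraints, class_of, rng, perturb_moves)
        cur = _climb(cur, names, cache, constraints, class_of, tabu, tabu_set)
        s = total(cur)
        if s < best_score - 1e-12:
            best, best_score = {v: set(ps) for v, ps in cur.items()}, s

    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    dag.add_edges_from((u, v) for v, ps in best.items() for u in ps)
    model = NetworkModel.from_dag(dataset, dag, cfg, seed=seed)
    return model


def _perturb(parents_of, names, constraints, class_of, rng, n_moves) -> None:
    """Apply seeded random legal add/delete moves in place."""
    for _ in range(n_moves):
        pairs = [(u, v) for u, v in itertools.permutations(names, 2)]
        idx = rng.permutation(len(pairs))
        for i in idx:
            u, v = pairs[i]
            if u in parents_of[v]:
                parents_of[v].discard(u)
                break
            if (
                constraints.edge_allowed(u, v, class_of)
                and len(parents_of[v]) < constraints.max_parents
                and not _has_path(parents_of, v, u)
            ):
                parents_of[v].add(u)
                break


def enumerate_best_dag(
    dataset: PanomicDataset,
    cfg: PenaltyConfig,
    constraints: ConstraintSet | None = None,
) -> tuple[NetworkModel, int]:
    """Score every legal DAG (p <= 5) and return the global optimum.

    Ties break by fewest edges, then lexicographic edge order.  Returns the
    optimal model and the number of legal candidates evaluated.
    """
    constraints = constraints or ConstraintSet()
    names = dataset.names
    p = len(names)
    if p > 5:
        raise ValueError("exhaustive enumeration is limited to p <= 5")
    class_of = {m.name: m.var_class for m in dataset.meta}
    cache = _ScoreCache(dataset, cfg)

    slots = [(u, v) for u, v in itertools.permutations(names, 2)]
    n_slots = len(slots)
    best = None  # (score, n_edges, sorted_edges, parents_of)
    count = 0
    for mask in range(1 << n_slots):
        edges = [slots[i] for i in range(n_slots) if mask >> i & 1]
        parents_of: dict[str, set[str]] = {v: set() for v in names}
        ok = True
        for u, v in edges:
            if not constraints.edge_allowed(u, v, class_of):
                ok = False
                break
            parents_of[v].add(u)
            if len(parents_of[v]) > constraints.max_parents:
                ok = False
                break
        if not ok:
            continue
        if _cyclic(parents_of, names):
            continue
        count += 1
        score = sum(cache.score(v, frozenset(ps)) for v, ps in parents_of.items())
        key = (score, len(edges), sorted(edges))
        if best is None or key < best[0]:
            best = (key, parents_of)

    key, parents_of = best
    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    dag.add_edges_from((u, v) for v, ps in parents_of.items() for u in ps)
    return NetworkModel.from_dag(dataset, dag, cfg), count


def _cyclic(parents_of: dict[str, set[str]], names: list[str]) -> bool:
    indeg = {v: len(ps) for v, ps in parents_of.items()}
    children: dict[str, list[str]] = {v: [] for v in names}
    for v, ps in parents_of.items():
        for u in ps:
            children[u].append(v)
    queue = [v for v in names if indeg[v] == 0]
    seen = 0
    while queue:
        w = queue.pop()
        seen += 1
        for c in children[w]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen != len(names)


def fit_ensemble(
    dataset: PanomicDataset,
    cfg: PenaltyConfig,
    constraints: ConstraintSet | None = None,
    n_networks: int = 50,
    resample: str = "bootstrap",
    base_seed: int = 0,
    restarts: int = 2,
) -> Ensemble:
    """Fit an ensemble of independently learned networks.

    ``resample='bootstrap'`` refits each member on a seeded with-replacement
    patient resample; ``'seed_only'`` varies only the search seed.  Members
    are independent, so the ensemble is fully reproducible from base_seed
    and insensitive to fitting order.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if resample not in ("bootstrap", "seed_only"):
        raise ValueError("resample must be 'bootstrap' or 'seed_only'")
    constraints = constraints or ConstraintSet()
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_networks)
    members: list[NetworkModel] = []
    for i, child_ss in enumerate(children):
        member_rng = np.random.default_rng(child_ss)
        member_seed = int(member_rng.integers(0, 2**31 - 1))
        if resample == "bootstrap":
            idx = member_rng.integers(0, dataset.n, size=dataset.n)
            values = dataset.values.iloc[idx].reset_index(drop=True)
            boot = PanomicDataset(
                values, dataset.meta, patient_ids=[f"B{i}_{j}" for j in range(dataset.n)]
            )
            model = hill_climb(boot, cfg, constraints, seed=member_seed, restarts=restarts)
            model.bootstrap_indices = idx
        else:
            model = hill_climb(dataset, cfg, constraints, seed=member_seed, restarts=restarts)
        members.append(model)
    return Ensemble(members=members, base_seed=base_seed)


def edge_frequencies(ensemble: Ensemble, threshold: float = 0.05) -> ConsensusGraph:
    """Fraction of ensemble members containing each directed edge."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    counts: dict[tuple[str, str], int] = {}
    for member in ensemble:
        for e in member.dag.edges:
            counts[e] = counts.get(e, 0) + 1
    m = len(ensemble)
    nodes = tuple(ensemble.members[0].dag.nodes)
    return ConsensusGraph(
        freq={e: c / m for e, c in counts.items()}, threshold=threshold, nodes=nodes
    )


def subnetwork(
    consensus: ConsensusGraph, focus_node: str, degree: int = 1, min_freq: float | None = None
) -> ConsensusGraph:
    """Restrict the consensus to the undirected neighborhood of a focus node.

    Nodes within ``degree`` undirected hops of the focus via reported edges
    are retained, along with the reported edges among them.
    """
    if focus_node not in consensus.nodes:
        raise KeyError(f"unknown node {focus_node!r}")
    thr = consensus.threshold if min_freq is None else min_freq
    reported = {e: f for e, f in consensus.freq.items() if f > thr}
    und: dict[str, set[str]] = {n: set() for n in consensus.nodes}
    for u, v in reported:
        und[u].add(v)
        und[v].add(u)
    keep = {focus_node}
    frontier = {focus_node}
    for _ in range(degree):
        frontier = {w for n in frontier for w in und[n]} - keep
        keep |= frontier
    sub_freq = {(u, v): f for (u, v), f in reported.items() if u in keep and v in keep}
    return ConsensusGraph(freq=sub_freq, threshold=thr, nodes=tuple(sorted(keep)))


def phenotype_parent_report(consensus: ConsensusGraph, phenotype_node: str) -> pd.DataFrame:
    """Variables with a reported directed edge into the phenotype, by frequency."""
    if phenotype_node not in consensus.nodes:
        raise KeyError(f"unknown node {phenotype_node!r}")
    rows = [
        (u, f)
        for (u, v), f in consensus.reported_edges().items()
        if v == phenotype_node
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["parent", "frequency"])
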
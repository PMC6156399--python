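"""Disease semantic similarity from a MeSH-style directed acyclic graph.

Each disease sits in a classification DAG; its ancestors describe it at
decreasing specificity. The contribution of an ancestor ``t`` to a disease
``d`` decays by a factor (default 0.5) per step away from ``d``:

    D_d(d) = 1
    D_d(t) = max over children t' of t inside T(d) of  decay * D_d(t')

which closes to ``decay ** (shortest descending path length from t to d)``.
The semantic value ``DV(d)`` is the sum of contributions over the ancestor
closure ``T(d)`` (including ``d`` itself), and the similarity of two
diseases is the contribution mass they share:

    S(a, b) = sum_{t in T(a) & T(b)} (D_a(t) + D_b(t)) / (DV(a) + DV(b))

S is symmetric, lies in [0, 1], and S(a, a) = 1.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .indexing import EntityIndex
from .matrices import SimilarityMatrix

#: per-step decay of an ancestor's contribution
SEMANTIC_DECAY = 0.5


class DiseaseDAG:
    """Acyclic child -> parent disease graph."""

    def __init__(self, parents: dict[str, set[str]]) -> None:
        self.parents: dict[str, frozenset[str]] = {
            n: frozenset(ps) for n, ps in parents.items()
        }
        dangling = {p for ps in self.parents.values() for p in ps} - set(self.parents)
        if dangling:
            raise ValueError(f"parents not declared as nodes: {sorted(dangling)[:5]}")
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            g.add_edges_from((child, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cycle in disease DAG: {' -> '.join(e[0] for e in cycle)}")
        self._graph = g
        self.children: dict[str, frozenset[str]] = {
            n: frozenset(g.predecessors(n)) for n in g
        }

    @property
    def nodes(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, node: object) -> bool:
        return node in self.parents

    def ancestor_closure(self, d: str) -> set[str]:
        """T(d): the disease itself plus all its ancestors."""
        if d not in self.parents:
            raise KeyError(f"unknown disease: {d!r}")
        return {d} | nx.descendants(self._graph, d)  # edges point child -> parent


@dataclass(frozen=True)
class ContributionMap:
    """Decayed contributions D_d(t) of every ancestor t to the root disease d."""

    root: str
    contrib: dict[str, float]

    def __post_init__(self) -> None:
        if self.contrib.get(self.root) != 1.0:
            raise ValueError("contribution of the disease to itself must be 1")
        if any(not (0.0 < v <= 1.0) for v in self.contrib.values()):
            raise ValueError("contributions must lie in (0, 1]")


def load_dag(path: str | Path) -> DiseaseDAG:
    """Load a child<TAB>parent TSV; isolated nodes appear as ``node<TAB>-``."""
    path = Path(path)
    parents: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: expected 'child<TAB>parent', got {line!r}")
            child, parent = parts[0].strip(), parts[1].strip()
            parents.setdefault(child, set())
            if parent != "-":
                parents[child].add(parent)
    return DiseaseDAG(parents)


def contributions(dag: DiseaseDAG, d: str, decay: float = SEMANTIC_DECAY) -> ContributionMap:
    """D_d(t) for every t in T(d): decay ** (shortest upward distance to d).

    Computed by breadth-first search up the parent edges; a node reachable
    along several paths keeps its maximal (shortest-path) contribution.
    """
    if d not in dag:
        raise KeyError(f"unknown disease: {d!r}")
    contrib: dict[str, float] = {d: 1.0}
    queue = deque([d])
    while queue:
        node = queue.popleft()
        for parent in dag.parents[node]:
            if parent not in contrib:  # BFS: first visit = shortest path
                contrib[parent] = decay * contrib[node]
                queue.append(parent)
    return ContributionMap(root=d, contrib=contrib)


def semantic_value(cm: ContributionMap) -> float:
    """DV(d): total contribution mass of the ancestor closure; always >= 1."""
    return float(sum(cm.contrib.values()))


def semantic_similarity(
    dag: DiseaseDAG, a: str, b: str, decay: float = SEMANTIC_DECAY
) -> float:
    """Shared-ancestor similarity S(a, b) in [0, 1]."""
    ca = contributions(dag, a, decay)
    cb = contributions(dag, b, decay)
    shared = set(ca.contrib) & set(cb.contrib)
    num = sum(ca.contrib[t] + cb.contrib[t] for t in shared)
    return float(num / (semantic_value(ca) + semantic_value(cb)))


def build_dss(
    dag: DiseaseDAG, diseases: EntityIndex, decay: float = SEMANTIC_DECAY
) -> SimilarityMatrix:
    """Pairwise semantic similarity matrix over ``diseases``.

    Contributions are memoised: one DAG traversal per disease.
    """
    maps = {d: contributions(dag, d, decay) for d in diseases}
    dvs = {d: semantic_value(maps[d]) for d in diseases}
    n = len(diseases)
    S = np.eye(n)
    for i, a in enumerate(diseases):
        ca = maps[a].contrib
        for j in range(i + 1, n):
            b = diseases[j]
            cb = maps[b].contrib
            shared = set(ca) & set(cb)
            if shared:
                num = sum(ca[t] + cb[t] for t in shared)
                S[i, j] = S[j, i] = num / (dvs[a] + dvs[b])
    return SimilarityMatrix(S, diseases, kind="precomputed")
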
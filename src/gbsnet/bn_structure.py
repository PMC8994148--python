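"""DAG representation, BIC scoring, constrained tabu search and Markov blankets.

Score-based structure learning for discrete Bayesian networks: the BIC
score decomposes over node families (a node and its parent set), so local
add / delete / reverse moves can be evaluated by rescoring at most two
families.  Tabu search keeps a short memory of recently visited structures
and is allowed a bounded number of non-improving moves past a local
optimum, returning the best structure seen.

Prior knowledge enters as arc constraints: a blacklist of forbidden arcs
(e.g. nothing may point into age or gender) and a whitelist of required
arcs (e.g. age and gender must point at the outcome) that the search may
never delete or reverse.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .report_io import CaseMatrix

__all__ = [
    "DAG",
    "ArcConstraints",
    "MarkovBlanket",
    "ScoredStructure",
    "TabuParams",
    "BicScorer",
    "is_acyclic",
    "family_score",
    "tabu_search",
    "markov_blanket",
    "extract_mb_subnetwork",
    "arc_strength",
]

Arc = tuple[str, str]


class DAG:
    """A directed acyclic graph over named nodes.

    Mutating operations (:meth:`add_arc`, :meth:`remove_arc`,
    :meth:`reverse_arc`) preserve acyclicity, raising on violations.
    """

    def __init__(self, nodes: Iterable[str], arcs: Iterable[Arc] = ()) -> None:
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        self._parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in arcs:
            self.add_arc(u, v)

    # -- queries ---------------------------------------------------------
    def parents(self, node: str) -> set[str]:
        return set(self._parents[node])

    def children(self, node: str) -> set[str]:
        return set(self._children[node])

    @property
    def arcs(self) -> set[Arc]:
        return {(u, v) for v, ps in self._parents.items() for u in ps}

    def has_arc(self, u: str, v: str) -> bool:
        return u in self._parents[v]

    def has_path(self, source: str, target: str) -> bool:
        """True iff a directed path source -> ... -> target exists."""
        if source == target:
            return True
        stack, seen = [source], {source}
        while stack:
            for w in self._children[stack.pop()]:
                if w == target:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def topological_order(self) -> list[str]:
        indeg = {v: len(self._parents[v]) for v in self.nodes}
        queue = [v for v in self.nodes if indeg[v] == 0]
        order: list[str] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in sorted(self._children[v]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if len(order) != len(self.nodes):
            raise RuntimeError("graph contains a cycle")
        return order

    # -- mutations -------------------------------------------------------
    def _check_nodes(self, u: str, v: str) -> None:
        if u not in self._parents or v not in self._parents:
            raise KeyError(f"unknown node in arc ({u!r}, {v!r})")

    def add_arc(self, u: str, v: str) -> None:
        self._check_nodes(u, v)
        if u == v:
            raise ValueError(f"self-loop {u!r} -> {v!r}")
        if self.has_arc(u, v):
            raise ValueError(f"duplicate arc {u!r} -> {v!r}")
        if self.has_path(v, u):
            raise ValueError(f"arc {u!r} -> {v!r} would create a cycle")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_arc(self, u: str, v: str) -> None:
        if not self.has_arc(u, v):
            raise ValueError(f"arc {u!r} -> {v!r} not present")
        self._parents[v].discard(u)
        self._children[u].discard(v)

    def reverse_arc(self, u: str, v: str) -> None:
        self.remove_arc(u, v)
        try:
            self.add_arc(v, u)
        except ValueError:
            self._parents[v].add(u)
            self._children[u].add(v)
            raise

    def copy(self) -> "DAG":
        return DAG(self.nodes, self.arcs)

    def induced_subgraph(self, keep: Iterable[str]) -> "DAG":
        keep_set = set(keep)
        nodes = [v for v in self.nodes if v in keep_set]
        arcs = [(u, v) for u, v in self.arcs if u in keep_set and v in keep_set]
        return DAG(nodes, arcs)

    def key(self) -> frozenset[Arc]:
        """Canonical hashable identity of the structure."""
        return frozenset(self.arcs)

    def descendant_map(self) -> dict[str, set[str]]:
        """node -> set of nodes reachable by a directed path (excl. itself)."""
        order = self.topological_order()
        desc: dict[str, set[str]] = {v: set() for v in self.nodes}
        for v in reversed(order):
            for c in self._children[v]:
                desc[v].add(c)
                desc[v] |= desc[c]
        return desc

    def to_arc_list(self) -> list[Arc]:
        return sorted(self.arcs)

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for u, v in sorted(self.arcs):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DAG)
            and set(self.nodes) == set(other.nodes)
            and self.arcs == other.arcs
        )

    def __repr__(self) -> str:
        return f"DAG({len(self.nodes)} nodes, {len(self.arcs)} arcs)"


def is_acyclic(nodes: Iterable[str], arcs: Iterable[Arc]) -> bool:
    """True iff the directed graph (nodes, arcs) has no directed cycle."""
    nodes = list(dict.fromkeys(nodes))
    children: dict[str, list[str]] = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}
    for u, v in arcs:
        children[u].append(v)
        indeg[v] += 1
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for w in children[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(nodes)


@dataclass(frozen=True)
class ArcConstraints:
    """Blacklisted (forbidden) and whitelisted (required) arcs."""

    blacklist: frozenset[Arc] = frozenset()
    whitelist: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "blacklist", frozenset(self.blacklist))
        object.__setattr__(self, "whitelist", frozenset(self.whitelist))
        overlap = self.blacklist & self.whitelist
        if overlap:
            raise ValueError(f"arcs both black- and whitelisted: {sorted(overlap)}")
        nodes = {x for arc in self.whitelist for x in arc}
        if not is_acyclic(nodes, self.whitelist):
            raise ValueError("whitelist arcs alone contain a cycle")

    @staticmethod
    def outcome_prior(
        outcome: str, exogenous: Sequence[str], all_nodes: Sequence[str]
    ) -> "ArcConstraints":
        """The pipeline's prior: exogenous nodes (age, gender) receive no
        arcs from other variables and are required parents of the outcome."""
        black = {(u, v) for v in exogenous for u in all_nodes if u != v}
        white = {(v, outcome) for v in exogenous}
        return ArcConstraints(frozenset(black - white), frozenset(white))


@dataclass(frozen=True)
class MarkovBlanket:
    """The Markov blanket of a target node.

    Parents, children, and the children's other parents (spouses).  A node
    may hold several roles at once; ``members`` is the plain union.
    """

    target: str
    parents: frozenset[str]
    children: frozenset[str]
    spouses: frozenset[str]

    @property
    def members(self) -> frozenset[str]:
        return self.parents | self.children | self.spouses


@dataclass
class ScoredStructure:
    """A DAG with its decomposed BIC score."""

    dag: DAG
    family_scores: dict[str, float]

    @property
    def total_score(self) -> float:
        return float(sum(self.family_scores.values()))


class BicScorer:
    """Cached per-family BIC scores for one case matrix.

    Convention: natural-log likelihood with the complexity penalty
    subtracted, so higher is better and the score of a DAG is the sum of
    its family scores.
    """

    #: refuse families whose CPT would exceed this many cells
    MAX_TABLE_CELLS = 10_000_000

    def __init__(self, matrix: CaseMatrix) -> None:
        self.matrix = matrix
        self.n = matrix.n
        self._cols = {v.name: matrix.data[:, j].astype(np.int64) for j, v in enumerate(matrix.variables)}
        self._card = {v.name: v.cardinality for v in matrix.variables}
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def family(self, node: str, parents: Iterable[str]) -> float:
        parents = frozenset(parents)
        if node in parents:
            raise ValueError(f"node {node!r} listed among its own parents")
        key = (node, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        score = self._compute(node, sorted(parents))
        self._cache[key] = score
        return score

    def _compute(self, node: str, parents: list[str]) -> float:
        r = self._card[node]
        q = 1
        for p in parents:
            q *= self._card[p]
        if q * r > self.MAX_TABLE_CELLS:
            return -math.inf
        # joint counts over (parent configuration, child state)
        idx = self._cols[node].copy()
        stride = r
        for p in parents:
            idx += self._cols[p] * stride
            stride *= self._card[p]
        counts = np.bincount(idx, minlength=q * r).reshape(q, r)
        config_totals = counts.sum(axis=1)
        nz = counts > 0
        log_totals = np.zeros(q)
        pos = config_totals > 0
        log_totals[pos] = np.log(config_totals[pos])
        ll = float(
            np.sum(counts[nz] * (np.log(counts[nz]) - np.broadcast_to(log_totals[:, None], (q, r))[nz]))
        )
        penalty = 0.5 * math.log(self.n) * (r - 1) * q
        return ll - penalty

    def score_dag(self, dag: DAG) -> ScoredStructure:
        fam = {v: self.family(v, dag.parents(v)) for v in dag.nodes}
        return ScoredStructure(dag.copy(), fam)


def family_score(node: str, parents: Iterable[str], matrix: CaseMatrix) -> float:
    """BIC family term for ``node`` with the given parent set (see
    :class:`BicScorer` for the convention)."""
    return BicScorer(matrix).family(node, parents)


@dataclass(frozen=True)
class TabuParams:
    """Tabu-search settings.

    ``tabu_length`` recently visited structures are off-limits; after a
    local optimum the search may take up to ``max_escape`` consecutive
    non-improving moves before giving up.  The search itself is
    deterministic; ``seed`` is recorded for provenance of downstream
    randomised stages.
    """

    max_iter: int = 10_000
    tabu_length: int = 10
    max_escape: int = 10
    seed: int = 0


_MOVE_RANK = {"delete": 0, "add": 1, "reverse": 2}


def tabu_search(
    matrix: CaseMatrix,
    constraints: ArcConstraints | None = None,
    params: TabuParams | None = None,
    scorer: BicScorer | None = None,
) -> ScoredStructure:
    """Learn a DAG by BIC-scored tabu search under arc constraints.

    Starts from the whitelist-only graph and repeatedly applies the best
    legal add/delete/reverse move; ties are broken deterministically by
    lexicographic arc order then move type (delete < add < reverse).
    Whitelist arcs are never deleted or reversed; blacklist arcs are never
    added.  Returns the best-scoring structure visited.
    """
    constraints = constraints or ArcConstraints()
    params = params or TabuParams()
    scorer = scorer or BicScorer(matrix)
    names = matrix.names

    for u, v in constraints.whitelist | constraints.blacklist:
        if u not in names or v not in names:
            raise ValueError(f"constraint arc ({u!r}, {v!r}) references unknown variable")

    dag = DAG(names)
    for u, v in sorted(constraints.whitelist):
        dag.add_arc(u, v)

    def dag_family(v: str) -> float:
        return scorer.family(v, dag.parents(v))

    current = {v: dag_family(v) for v in names}
    current_total = sum(current.values())
    best = ScoredStructure(dag.copy(), dict(current))
    best_total = current_total

    tabu: list[frozenset[Arc]] = [dag.key()]
    escape = 0
    blacklist = constraints.blacklist
    whitelist = constraints.whitelist

    for _ in range(params.max_iter):
        desc = dag.descendant_map()
        tabu_set = set(tabu)
        best_move: tuple[Arc, str] | None = None
        best_delta = -math.inf
        arcs = dag.arcs

        # candidate moves in deterministic order
        for u, v in sorted(itertools.permutations(names, 2)):
            if (u, v) in arcs:
                pv = dag.parents(v)
                if (u, v) not in whitelist:
                    # delete u -> v
                    delta = scorer.family(v, pv - {u}) - current[v]
                    if delta > best_delta + 1e-12:
                        nk = frozenset(arcs - {(u, v)})
                        if nk not in tabu_set:
                            best_move, best_delta = ((u, v), "delete"), delta
                    # reverse u -> v (legal unless (v, u) blacklisted or a
                    # path u ~> v survives removal of the arc itself)
                    if (v, u) not in blacklist:
                        dag.remove_arc(u, v)
                        cyclic = dag.has_path(u, v)
                        dag._parents[v].add(u)
                        dag._children[u].add(v)
                        if not cyclic:
                            delta = (
                                scorer.family(v, pv - {u})
                                - current[v]
                                + scorer.family(u, dag.parents(u) | {v})
                                - current[u]
                            )
                            if delta > best_delta + 1e-12:
                                nk = frozenset((arcs - {(u, v)}) | {(v, u)})
                                if nk not in tabu_set:
                                    best_move, best_delta = ((u, v), "reverse"), delta
            else:
                # add u -> v
                if (u, v) in blacklist or u in desc.get(v, ()):  # cycle guard
                    continue
                delta = scorer.family(v, dag.parents(v) | {u}) - current[v]
                if delta > best_delta + 1e-12:
                    nk = frozenset(arcs | {(u, v)})
                    if nk not in tabu_set:
                        best_move, best_delta = ((u, v), "add"), delta

        if best_move is None:
            break
        (u, v), kind = best_move
        if kind == "add":
            dag.add_arc(u, v)
            current[v] = dag_family(v)
        elif kind == "delete":
            dag.remove_arc(u, v)
            current[v] = dag_family(v)
        else:
            dag.reverse_arc(u, v)
            current[v] = dag_family(v)
            current[u] = dag_family(u)
        current_total += best_delta

        tabu.append(dag.key())
        if len(tabu) > params.tabu_length:
            tabu.pop(0)

        if current_total > best_total + 1e-9:
            best = ScoredStructure(dag.copy(), dict(current))
            best_total = current_total
            escape = 0
        else:
            escape += 1
            if escape > params.max_escape:
                break

    return best


def markov_blanket(dag: DAG, target: str) -> MarkovBlanket:
    """Parents, children and spouses (children's other parents) of target."""
    if target not in dag.nodes:
        raise KeyError(f"unknown target node {target!r}")
    parents = dag.parents(target)
    children = dag.children(target)
    spouses: set[str] = set()
    for child in children:
        spouses |= dag.parents(child)
    spouses -= {target}
    return MarkovBlanket(
        target, frozenset(parents), frozenset(children), frozenset(spouses)
    )


def extract_mb_subnetwork(dag: DAG, target: str) -> DAG:
    """Induced subgraph on the target and its Markov-blanket members."""
    mb = markov_blanket(dag, target)
    return dag.induced_subgraph({target} | set(mb.members))


def arc_strength(
    structure: ScoredStructure, matrix: CaseMatrix, scorer: BicScorer | None = None
) -> dict[Arc, float]:
    """BIC change caused by removing each arc: (score without) - (score with).

    Negative values mean the arc is supported by the data (removing it
    loses score); only the child's family term needs recomputation.
    """
    scorer = scorer or BicScorer(matrix)
    dag = structure.dag
    strengths: dict[Arc, float] = {}
    for u, v in sorted(dag.arcs):
        with_arc = scorer.family(v, dag.parents(v))
        without = scorer.family(v, dag.parents(v) - {u})
        strengths[(u, v)] = without - with_arc
    return strengths
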
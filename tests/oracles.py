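"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity by the most direct method
available (full enumeration, pairwise counting, exhaustive scans) without
touching the library's own computational paths, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import networkx as nx


def enumerate_joint(bn) -> dict[tuple[int, ...], float]:
    """Full joint table by direct CPT-product enumeration (linear scale)."""
    nodes = list(bn.dag.nodes)
    cards = [bn.cardinality(v) for v in nodes]
    joint: dict[tuple[int, ...], float] = {}
    for states in itertools.product(*(range(c) for c in cards)):
        assignment = dict(zip(nodes, states))
        p = 1.0
        for v in nodes:
            cpt = bn.cpts[v]
            idx = tuple(assignment[q] for q in cpt.parent_order)
            p *= float(cpt.table[idx][assignment[v]])
        joint[states] = p
    return joint


def posterior_by_enumeration(bn, target: str, evidence: dict[str, int]) -> np.ndarray:
    """P(target | evidence) from the full joint table."""
    nodes = list(bn.dag.nodes)
    t = nodes.index(target)
    weights = np.zeros(bn.cardinality(target))
    for states, p in enumerate_joint(bn).items():
        if all(states[nodes.index(k)] == v for k, v in evidence.items()):
            weights[states[t]] += p
    return weights / weights.sum()


def all_dags(nodes: list[str]):
    """Yield every DAG (as an arc set) over the given nodes."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(2 ** len(pairs)):
        arcs = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(arcs)
        if nx.is_directed_acyclic_graph(g):
            yield arcs


def bic_by_direct_count(data: np.ndarray, cards: list[int], node: int,
                        parents: list[int]) -> float:
    """BIC family term by per-row dictionary counting (no vectorisation)."""
    n = data.shape[0]
    config_counts: dict[tuple, int] = {}
    joint_counts: dict[tuple, int] = {}
    for row in data:
        cfg = tuple(int(row[p]) for p in parents)
        config_counts[cfg] = config_counts.get(cfg, 0) + 1
        key = cfg + (int(row[node]),)
        joint_counts[key] = joint_counts.get(key, 0) + 1
    ll = 0.0
    for key, c in joint_counts.items():
        ll += c * math.log(c / config_counts[key[:-1]])
    q = 1
    for p in parents:
        q *= cards[p]
    return ll - 0.5 * math.log(n) * (cards[node] - 1) * q


def best_dag_score(data: np.ndarray, cards: list[int]) -> float:
    """Exhaustive-enumeration maximum BIC score over all DAGs (<=4 nodes)."""
    names = [str(i) for i in range(len(cards))]
    best = -math.inf
    for arcs in all_dags(names):
        parents: dict[int, list[int]] = {i: [] for i in range(len(cards))}
        for u, v in arcs:
            parents[int(v)].append(int(u))
        score = sum(
            bic_by_direct_count(data, cards, i, parents[i])
            for i in range(len(cards))
        )
        best = max(best, score)
    return best


def d_separated(arcs: set[tuple[str, str]], nodes: list[str], x: str, y: str,
                given: set[str]) -> bool:
    """d-separation via the moralised ancestral graph."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(arcs)
    relevant = {x, y} | given
    ancestral = set(relevant)
    for v in relevant:
        ancestral |= nx.ancestors(g, v)
    sub = g.subgraph(ancestral)
    moral = nx.Graph()
    moral.add_nodes_from(sub.nodes)
    moral.add_edges_from(sub.edges)
    for v in sub.nodes:
        preds = list(sub.predecessors(v))
        moral.add_edges_from(itertools.combinations(preds, 2))
    moral.remove_nodes_from(given)
    if x not in moral or y not in moral:
        return True
    return not nx.has_path(moral, x, y)


def concordance_auc(scores, labels) -> float:
    """Mann-Whitney pairwise concordance with 1/2 credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_by_scan(scores, labels) -> tuple[float, float]:
    """(best Youden value, smallest optimal threshold) by exhaustive scan
    over the rule "positive iff score > t" for every observed score value."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_j, best_t = -np.inf, None
    for t in sorted(np.unique(scores)):
        pred = scores > t
        tpr = (pred & labels).sum() / n_pos
        fpr = (pred & ~labels).sum() / n_neg
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_j), float(best_t)
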
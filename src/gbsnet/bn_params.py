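"""Maximum-likelihood conditional probability tables on a fixed DAG.

Given a learned structure, each node's CPT row (one row per parent
configuration) is estimated as the empirical frequency of the node's
states among the training rows matching that configuration.  Parent
configurations never observed in training carry no likelihood information;
they are filled by a fallback policy (uniform by default) and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .bn_structure import DAG
from .report_io import CaseMatrix, Variable

__all__ = ["CPT", "DiscreteBN", "fit_mle", "joint_probability"]


@dataclass
class CPT:
    """Conditional probability table for one node.

    ``table`` has shape ``(*parent_cardinalities, child_cardinality)`` with
    parents in ``parent_order``; every row (last axis) sums to one.
    """

    child: str
    parent_order: tuple[str, ...]
    table: np.ndarray
    unsupported_rows: frozenset[tuple[int, ...]] = frozenset()

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != len(self.parent_order) + 1:
            raise ValueError(
                f"CPT for {self.child!r}: table rank {self.table.ndim} does not "
                f"match {len(self.parent_order)} parents"
            )
        if (self.table < 0).any():
            raise ValueError(f"CPT for {self.child!r} has negative entries")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"CPT rows for {self.child!r} do not sum to 1")

    @property
    def cardinality(self) -> int:
        return self.table.shape[-1]

    def row(self, parent_states: Mapping[str, int] | tuple[int, ...]) -> np.ndarray:
        """Probability vector over child states for one parent configuration."""
        if isinstance(parent_states, Mapping):
            parent_states = tuple(parent_states[p] for p in self.parent_order)
        return self.table[parent_states]


class DiscreteBN:
    """A discrete Bayesian network: a DAG plus one CPT per node.

    The joint distribution factorises as the product of each node's
    conditional distribution given its parents.  States are handled as
    integer indices into each variable's state-label tuple.
    """

    def __init__(self, dag: DAG, variables: Iterable[Variable], cpts: Mapping[str, CPT]):
        self.dag = dag
        self.variables: dict[str, Variable] = {v.name: v for v in variables}
        self.cpts: dict[str, CPT] = dict(cpts)
        if set(self.dag.nodes) != set(self.variables):
            raise ValueError("variable list does not match DAG nodes")
        if set(self.cpts) != set(self.dag.nodes):
            raise ValueError("need exactly one CPT per node")
        for name, cpt in self.cpts.items():
            if set(cpt.parent_order) != self.dag.parents(name):
                raise ValueError(
                    f"CPT parents {cpt.parent_order} of {name!r} do not match DAG"
                )
            expected = tuple(
                self.variables[p].cardinality for p in cpt.parent_order
            ) + (self.variables[name].cardinality,)
            if cpt.table.shape != expected:
                raise ValueError(
                    f"CPT shape {cpt.table.shape} for {name!r}, expected {expected}"
                )

    @property
    def nodes(self) -> list[str]:
        return list(self.dag.nodes)

    def cardinality(self, name: str) -> int:
        return self.variables[name].cardinality

    def log_prob_node(self, name: str, assignment: Mapping[str, int]) -> float:
        cpt = self.cpts[name]
        p = float(cpt.row(assignment)[assignment[name]])
        return math.log(p) if p > 0 else -math.inf

    def log_joint(self, assignment: Mapping[str, int]) -> float:
        missing = set(self.nodes) - set(assignment)
        if missing:
            raise ValueError(f"assignment missing nodes: {sorted(missing)}")
        return sum(self.log_prob_node(v, assignment) for v in self.nodes)

    def state_index(self, name: str, label: str) -> int:
        return self.variables[name].states.index(label)


def joint_probability(bn: DiscreteBN, assignment: Mapping[str, int]) -> float:
    """P(assignment) under the factorisation; requires a full assignment."""
    lp = bn.log_joint(assignment)
    return math.exp(lp) if lp > -math.inf else 0.0


def fit_mle(
    dag: DAG,
    matrix: CaseMatrix,
    fallback: str = "uniform",
    smoothing: float = 0.0,
) -> DiscreteBN:
    """Fit CPTs by maximum likelihood on a fixed structure.

    ``fallback`` governs parent configurations with zero training support:
    "uniform" (default) fills them with the uniform distribution and flags
    them in the CPT's ``unsupported_rows``.  ``smoothing`` > 0 switches to
    add-k estimation for all rows (no row is then unsupported).
    """
    if fallback != "uniform":
        raise ValueError(f"unknown fallback policy {fallback!r}")
    names = set(matrix.names)
    for node in dag.nodes:
        if node not in names:
            raise KeyError(f"DAG node {node!r} absent from case matrix")

    cols = {v.name: matrix.data[:, j].astype(np.int64) for j, v in enumerate(matrix.variables)}
    card = {v.name: v.cardinality for v in matrix.variables}

    cpts: dict[str, CPT] = {}
    for node in dag.nodes:
        parents = tuple(sorted(dag.parents(node)))
        r = card[node]
        pcards = tuple(card[p] for p in parents)
        q = int(np.prod(pcards)) if parents else 1
        # C-order flat index over (parent_1, ..., parent_k, child)
        pf = np.zeros(matrix.n, dtype=np.int64)
        for p in parents:
            pf = pf * card[p] + cols[p]
        idx = pf * r + cols[node]
        counts = (
            np.bincount(idx, minlength=q * r).reshape(q, r).astype(float) + smoothing
        )
        totals = counts.sum(axis=1)
        probs = np.empty_like(counts)
        unsupported: set[tuple[int, ...]] = set()
        zero = totals == 0
        probs[zero] = 1.0 / r
        nz = ~zero
        probs[nz] = counts[nz] / totals[nz, None]
        if zero.any():
            for flat in np.flatnonzero(zero):
                config: list[int] = []
                rem = int(flat)
                for c in reversed(pcards):
                    config.insert(0, rem % c)
                    rem //= c
                unsupported.add(tuple(config))
        table = probs.reshape(*pcards, r) if parents else probs.reshape(r)
        cpts[node] = CPT(node, parents, table, frozenset(unsupported))

    variables = [matrix.variable(n) for n in dag.nodes]
    return DiscreteBN(dag.copy(), variables, cpts)


def save_model(bn: DiscreteBN, path) -> None:
    """Serialise a network (DAG, state labels, CPTs) to round-trippable JSON."""
    import json
    from pathlib import Path

    payload = {
        "nodes": [
            {"name": v.name, "states": list(v.states)} for v in bn.variables.values()
        ],
        "arcs": bn.dag.to_arc_list(),
        "cpts": {
            name: {
                "parents": list(cpt.parent_order),
                "table": cpt.table.tolist(),
                "unsupported_rows": sorted(map(list, cpt.unsupported_rows)),
            }
            for name, cpt in bn.cpts.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> DiscreteBN:
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    variables = [Variable(n["name"], tuple(n["states"])) for n in payload["nodes"]]
    dag = DAG([v.name for v in variables], [tuple(a) for a in payload["arcs"]])
    cpts = {
        name: CPT(
            name,
            tuple(entry["parents"]),
            np.asarray(entry["table"]),
            frozenset(map(tuple, entry.get("unsupported_rows", []))),
        )
        for name, entry in payload["cpts"].items()
    }
    return DiscreteBN(dag, variables, cpts)


def cpt_report(bn: DiscreteBN) -> str:
    """Human-readable dump of all CPTs, one block per node."""
    lines: list[str] = []
    for node in bn.dag.topological_order():
        cpt = bn.cpts[node]
        var = bn.variables[node]
        lines.append(f"# {node} | parents: {', '.join(cpt.parent_order) or '(none)'}")
        header = list(cpt.parent_order) + [f"P({node}={s})" for s in var.states]
        lines.append("\t".join(header))
        pcards = [bn.cardinality(p) for p in cpt.parent_order]
        for config in np.ndindex(*pcards) if pcards else [()]:
            labels = [
                bn.variables[p].states[s] for p, s in zip(cpt.parent_order, config)
            ]
            row = cpt.table[config]
            lines.append("\t".join(labels + [f"{x:.6g}" for x in row]))
        lines.append("")
    return "\n".join(lines)
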
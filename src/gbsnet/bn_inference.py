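"""Exact posterior inference for the outcome node.

The production networks here are small (a Markov-blanket subnetwork of
roughly a dozen nodes), so inference is exact: the posterior over the
target is obtained by enumerating the states of unobserved variables and
summing joint probabilities, in log space.  When every non-target variable
is observed — the prediction setting — only the target's own family and
its children's families vary with the target state, so scoring a cohort
needs just one CPT gather per family and target state.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

import numpy as np

from .bn_params import DiscreteBN
from .report_io import CaseMatrix

__all__ = [
    "posterior",
    "predict_scores",
    "posttest_probability_table",
    "PosttestTable",
]

Evidence = Mapping[str, int]


def _validate_evidence(bn: DiscreteBN, evidence: Evidence) -> None:
    for name, state in evidence.items():
        if name not in bn.variables:
            raise KeyError(f"evidence variable {name!r} not in network")
        if not 0 <= state < bn.cardinality(name):
            raise ValueError(f"invalid state {state} for {name!r}")


def posterior(bn: DiscreteBN, target: str, evidence: Evidence) -> np.ndarray:
    """P(target | evidence) by exact enumeration; sums to 1.

    Raises if the evidence has probability zero under the model (there is
    then no conditional distribution to report).
    """
    if target not in bn.variables:
        raise KeyError(f"unknown target {target!r}")
    if target in evidence:
        raise ValueError(f"target {target!r} must not appear in the evidence")
    _validate_evidence(bn, evidence)

    hidden = [v for v in bn.nodes if v != target and v not in evidence]
    r = bn.cardinality(target)
    log_weights = np.full(r, -np.inf)
    assignment = dict(evidence)
    for t_state in range(r):
        assignment[target] = t_state
        acc = -np.inf
        for hidden_states in itertools.product(
            *(range(bn.cardinality(h)) for h in hidden)
        ):
            assignment.update(zip(hidden, hidden_states))
            acc = np.logaddexp(acc, bn.log_joint(assignment))
        log_weights[t_state] = acc

    top = log_weights.max()
    if top == -np.inf:
        raise ValueError("evidence has probability zero under the model")
    probs = np.exp(log_weights - top)
    return probs / probs.sum()


def _family_log_probs(
    bn: DiscreteBN, node: str, columns: dict[str, np.ndarray]
) -> np.ndarray:
    """ln P(node | parents) per row, reading states from ``columns``."""
    cpt = bn.cpts[node]
    flat = np.zeros(len(next(iter(columns.values()))), dtype=np.int64)
    for p in cpt.parent_order:
        flat = flat * bn.cardinality(p) + columns[p]
    flat = flat * bn.cardinality(node) + columns[node]
    probs = cpt.table.reshape(-1)[flat]
    out = np.full(probs.shape, -np.inf)
    pos = probs > 0
    out[pos] = np.log(probs[pos])
    return out


def predict_scores(
    bn: DiscreteBN,
    matrix: CaseMatrix,
    target: str,
    positive_state: int = 1,
    impossible: str = "error",
) -> np.ndarray:
    """Posterior probability of ``target = positive_state`` for every row.

    Each row's non-target variables act as evidence; columns of ``matrix``
    that are not network nodes are ignored (reports may carry AEs outside
    the Markov blanket).  All network nodes except the target must be
    present, so the posterior reduces to the product of the target's family
    and its children's families, renormalised over target states.

    ``impossible`` governs rows whose evidence has probability zero under
    the model (a child-family CPT cell estimated at exactly zero):
    "error" raises; "parents" falls back to the target's CPT row given the
    row's parent states, dropping the offending child likelihoods.
    """
    if impossible not in ("error", "parents"):
        raise ValueError("impossible must be 'error' or 'parents'")
    if target not in bn.variables:
        raise KeyError(f"unknown target {target!r}")
    missing = [v for v in bn.nodes if v != target and v not in matrix.names]
    if missing:
        raise KeyError(f"case matrix lacks network variables: {missing}")

    columns = {
        v: matrix.column(v).astype(np.int64) for v in bn.nodes if v != target
    }
    relevant = [target] + sorted(bn.dag.children(target))
    r = bn.cardinality(target)
    n = matrix.n
    log_lik = np.zeros((r, n))
    own_log = np.zeros((r, n))
    for t_state in range(r):
        columns[target] = np.full(n, t_state, dtype=np.int64)
        own_log[t_state] = _family_log_probs(bn, target, columns)
        log_lik[t_state] = own_log[t_state]
        for node in relevant[1:]:
            log_lik[t_state] += _family_log_probs(bn, node, columns)

    top = log_lik.max(axis=0)
    dead = top == -np.inf
    if dead.any():
        if impossible == "error":
            raise ValueError("some rows have probability zero under the model")
        log_lik[:, dead] = own_log[:, dead]
        top = log_lik.max(axis=0)
    weights = np.exp(log_lik - top)
    return weights[positive_state] / weights.sum(axis=0)


class PosttestTable:
    """Posterior risk of the target for each configuration of its parents.

    Because a node's parents d-separate it from its other non-descendants,
    the probability in each row is exactly the target's CPT entry for that
    parent configuration; rows enumerate the full configuration product.
    """

    def __init__(self, target: str, positive_label: str,
                 rows: list[tuple[dict[str, str], float]]):
        self.target = target
        self.positive_label = positive_label
        self.rows = rows

    def max_row(self) -> tuple[dict[str, str], float]:
        return max(self.rows, key=lambda row: row[1])

    def probability(self, **parent_labels: str) -> float:
        for config, p in self.rows:
            if config == parent_labels:
                return p
        raise KeyError(f"no row for configuration {parent_labels}")

    def to_dataframe(self):
        import pandas as pd

        frame = pd.DataFrame([dict(c, probability=p) for c, p in self.rows])
        return frame

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def posttest_probability_table(
    bn: DiscreteBN, target: str, positive_state: int = 1
) -> PosttestTable:
    """P(target positive | parent configuration) for all configurations."""
    if target not in bn.variables:
        raise KeyError(f"unknown target {target!r}")
    cpt = bn.cpts[target]
    if not cpt.parent_order:
        raise ValueError(
            f"{target!r} has no parents; use its marginal prior instead"
        )
    rows: list[tuple[dict[str, str], float]] = []
    pcards = [bn.cardinality(p) for p in cpt.parent_order]
    for config in np.ndindex(*pcards):
        labels = {
            p: bn.variables[p].states[s]
            for p, s in zip(cpt.parent_order, config)
        }
        rows.append((labels, float(cpt.table[config][positive_state])))
    return PosttestTable(
        target, bn.variables[target].states[positive_state], rows
    )
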
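"""DAG mechanics, BIC scoring, tabu search and Markov blankets."""

import math

import numpy as np
import pytest

from gbsnet.bn_structure import (
    ArcConstraints,
    BicScorer,
    DAG,
    TabuParams,
    arc_strength,
    extract_mb_subnetwork,
    family_score,
    is_acyclic,
    markov_blanket,
    tabu_search,
)
from gbsnet.report_io import CaseMatrix, Variable
from gbsnet.synthetic_data import (
    FIXTURE_MB_MEMBERS,
    GeneratorSpec,
    random_network,
    sample_cohort,
)

import oracles


def binary_matrix(data, names=None, outcome=None):
    data = np.asarray(data)
    names = names or [f"X{i}" for i in range(data.shape[1])]
    variables = [Variable(n, ("false", "true")) for n in names]
    return CaseMatrix(variables, data, outcome or names[0])


# ---------------------------------------------------------------------------
# DAG / acyclicity
# ---------------------------------------------------------------------------

def test_acyclicity_basics():
    assert is_acyclic([], [])
    assert is_acyclic(["A", "B"], [("A", "B")])
    assert not is_acyclic(["A", "B"], [("A", "B"), ("B", "A")])


def test_back_arc_detected_on_random_dag(rng):
    nodes = [f"n{i}" for i in range(50)]
    order = rng.permutation(50)
    arcs = []
    for _ in range(120):
        i, j = sorted(rng.choice(50, size=2, replace=False))
        arcs.append((nodes[order[i]], nodes[order[j]]))
    assert is_acyclic(nodes, arcs)
    # one arc against the topological order closes a cycle
    u, v = arcs[0]
    assert not is_acyclic(nodes, arcs + [(v, u)])


def test_dag_mutation_guards():
    dag = DAG(["A", "B", "C"], [("A", "B"), ("A", "C"), ("C", "B")])
    with pytest.raises(ValueError):
        dag.add_arc("B", "A")
    with pytest.raises(ValueError):
        dag.add_arc("A", "A")
    with pytest.raises(ValueError):
        dag.add_arc("A", "B")
    # reversing A->B is illegal while the alternate path A->C->B exists
    with pytest.raises(ValueError):
        dag.reverse_arc("A", "B")
    assert dag.has_arc("A", "B")  # failed reversal leaves the graph intact
    dag.remove_arc("C", "B")
    dag.reverse_arc("A", "B")
    assert dag.has_arc("B", "A")


# ---------------------------------------------------------------------------
# BIC family score
# ---------------------------------------------------------------------------

def test_family_score_closed_form():
    data = np.zeros((100, 1), dtype=np.int8)
    data[:30, 0] = 1
    matrix = binary_matrix(data, ["X"])
    expected = 30 * math.log(0.3) + 70 * math.log(0.7) - math.log(100) / 2
    assert family_score("X", set(), matrix) == pytest.approx(expected, abs=1e-9)


def test_independent_parent_lowers_score(rng):
    data = rng.integers(0, 2, size=(10_000, 2)).astype(np.int8)
    matrix = binary_matrix(data, ["A", "B"])
    assert family_score("A", {"B"}, matrix) < family_score("A", set(), matrix)


def test_score_decomposability_against_direct_count(rng):
    data = rng.integers(0, 2, size=(400, 4)).astype(np.int8)
    matrix = binary_matrix(data)
    dag = DAG(matrix.names, [("X0", "X1"), ("X0", "X2"), ("X1", "X3"), ("X2", "X3")])
    scorer = BicScorer(matrix)
    total = scorer.score_dag(dag).total_score
    brute = sum(
        oracles.bic_by_direct_count(
            data, [2, 2, 2, 2], i, [matrix.names.index(p) for p in dag.parents(n)]
        )
        for i, n in enumerate(matrix.names)
    )
    assert total == pytest.approx(brute, abs=1e-9)


def test_family_score_invariances(rng):
    data = rng.integers(0, 2, size=(500, 3)).astype(np.int8)
    matrix = binary_matrix(data)
    base = family_score("X0", {"X1"}, matrix)
    # row order
    shuffled = binary_matrix(data[rng.permutation(500)])
    assert family_score("X0", {"X1"}, shuffled) == pytest.approx(base, abs=1e-9)
    # state relabelling
    relabeled = binary_matrix(1 - data)
    assert family_score("X0", {"X1"}, relabeled) == pytest.approx(base, abs=1e-9)


def test_family_score_rejects_self_parent():
    matrix = binary_matrix(np.zeros((10, 2), dtype=np.int8))
    with pytest.raises(ValueError):
        family_score("X0", {"X0"}, matrix)


# ---------------------------------------------------------------------------
# tabu search
# ---------------------------------------------------------------------------

def test_tabu_independent_variables_yield_empty_graph(rng):
    data = rng.integers(0, 2, size=(10_000, 2)).astype(np.int8)
    result = tabu_search(binary_matrix(data))
    assert result.dag.arcs == set()


def test_tabu_matches_exhaustive_enumeration_on_chain():
    spec = GeneratorSpec(cardinalities=(2, 2, 2, 2), seed=11)
    bn = random_network(spec, names=["A", "B", "C", "D"])
    # overwrite with a strong chain A->B->C->D
    from gbsnet.bn_params import CPT, DiscreteBN
    from gbsnet.report_io import Variable as Var

    dag = DAG(["A", "B", "C", "D"], [("A", "B"), ("B", "C"), ("C", "D")])
    strong = np.array([[0.9, 0.1], [0.1, 0.9]])
    cpts = {
        "A": CPT("A", (), np.array([0.5, 0.5])),
        "B": CPT("B", ("A",), strong),
        "C": CPT("C", ("B",), strong),
        "D": CPT("D", ("C",), strong),
    }
    chain = DiscreteBN(dag, [Var(n, ("f", "t")) for n in "ABCD"], cpts)
    matrix = sample_cohort(chain, 20_000, seed=3, outcome="A")
    result = tabu_search(matrix)
    best = oracles.best_dag_score(matrix.data, [2, 2, 2, 2])
    assert result.total_score == pytest.approx(best, abs=1e-6)


def test_tabu_respects_constraints(rng):
    data = rng.integers(0, 2, size=(2_000, 3)).astype(np.int8)
    matrix = binary_matrix(data, ["age", "outcome", "ae"])
    constraints = ArcConstraints(
        blacklist=frozenset({("ae", "age"), ("outcome", "age")}),
        whitelist=frozenset({("age", "outcome")}),
    )
    result = tabu_search(matrix, constraints)
    assert ("age", "outcome") in result.dag.arcs
    assert not result.dag.parents("age")


def test_tabu_deterministic(rng):
    data = rng.integers(0, 2, size=(3_000, 4)).astype(np.int8)
    matrix = binary_matrix(data)
    r1 = tabu_search(matrix)
    r2 = tabu_search(matrix)
    assert r1.dag.arcs == r2.dag.arcs
    assert r1.total_score == r2.total_score


def test_constraints_validation():
    with pytest.raises(ValueError):
        ArcConstraints(blacklist=frozenset({("a", "b")}), whitelist=frozenset({("a", "b")}))
    with pytest.raises(ValueError):
        ArcConstraints(whitelist=frozenset({("a", "b"), ("b", "a")}))


# ---------------------------------------------------------------------------
# Markov blanket
# ---------------------------------------------------------------------------

def test_markov_blanket_of_fixture_structure(fixture_bn):
    mb = markov_blanket(fixture_bn.dag, "GBS")
    assert mb.parents == {"age", "gender", "erythema"}
    assert mb.children == {"asthenia", "hypesthesia", "muscular weakness", "paresthesia"}
    assert {"chills", "dizziness", "myalgia", "nausea", "pain in extremity"} <= mb.spouses
    assert mb.members == FIXTURE_MB_MEMBERS
    assert len(mb.members) == 12
    assert "GBS" not in mb.members


def test_markov_blanket_isolated_node():
    dag = DAG(["A", "B"], [])
    mb = markov_blanket(dag, "A")
    assert mb.members == frozenset()


def test_markov_blanket_unknown_target():
    with pytest.raises(KeyError):
        markov_blanket(DAG(["A"]), "Z")


def test_markov_blanket_dseparates_nonmembers(rng):
    """target is d-separated from every non-member given the blanket, on
    100 random DAGs (independent moralisation-based oracle)."""
    for trial in range(100):
        spec = GeneratorSpec(cardinalities=(2,) * 8, max_parents=3, seed=trial)
        bn = random_network(spec)
        dag = bn.dag
        target = dag.nodes[int(rng.integers(0, 8))]
        mb = markov_blanket(dag, target)
        outside = set(dag.nodes) - {target} - set(mb.members)
        for other in outside:
            assert oracles.d_separated(
                dag.arcs, dag.nodes, target, other, set(mb.members)
            )


def test_extract_mb_subnetwork_fixture(fixture_bn):
    sub = extract_mb_subnetwork(fixture_bn.dag, "GBS")
    assert len(sub.nodes) == 13
    assert sub.arcs <= fixture_bn.dag.arcs
    # closure: the blanket inside the subnetwork is the original blanket
    mb_sub = markov_blanket(sub, "GBS")
    assert mb_sub.members == markov_blanket(fixture_bn.dag, "GBS").members


def test_extract_mb_subnetwork_trivial():
    sub = extract_mb_subnetwork(DAG(["A", "B"]), "A")
    assert sub.nodes == ["A"] and sub.arcs == set()


# ---------------------------------------------------------------------------
# arc strength
# ---------------------------------------------------------------------------

def test_arc_strength_decomposable_equals_full_rescoring(rng):
    data = rng.integers(0, 2, size=(2_000, 4)).astype(np.int8)
    matrix = binary_matrix(data)
    scorer = BicScorer(matrix)
    dag = DAG(matrix.names, [("X0", "X1"), ("X1", "X2"), ("X0", "X3")])
    structure = scorer.score_dag(dag)
    strengths = arc_strength(structure, matrix)
    for arc, delta in strengths.items():
        reduced = dag.copy()
        reduced.remove_arc(*arc)
        full = scorer.score_dag(reduced).total_score - structure.total_score
        assert delta == pytest.approx(full, abs=1e-9)


def test_arc_strength_strong_dependency_is_negative(fixture_bn):
    matrix = sample_cohort(fixture_bn, 20_000, seed=9)
    scorer = BicScorer(matrix)
    structure = scorer.score_dag(fixture_bn.dag)
    strengths = arc_strength(structure, matrix, scorer)
    assert strengths[("GBS", "paresthesia")] < -10
    assert strengths[("paresthesia", "hypesthesia")] < -10
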
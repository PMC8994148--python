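"""Synthetic cohort generation for end-to-end pipeline testing.

Raw pharmacovigilance report data cannot be redistributed, so this module
generates cohorts with the same shape: a ground-truth discrete Bayesian
network (either random, or the bundled surveillance-calibrated fixture),
ancestral sampling of case matrices from it, and a "raw report" emulator
that renders discrete samples back into messy report tables — continuous
ages, missing values, unknown genders, and independent low-prevalence
decoy AE columns that a correct pipeline should prune.

The bundled fixture mirrors the structure found on the US development
cohort: GBS with parents age, gender and erythema; children asthenia,
hypesthesia, muscular weakness and paresthesia; and spouses chills,
dizziness, myalgia, nausea and pain in extremity.  Its CPTs are artifact
constants calibrated (by direct enumeration at build time) so that the
marginal P(GBS) matches the US cohort's 1.26%, the age and gender
marginals match the US totals, GBS risk rises then falls with age, is
about three times higher for men, and is strongly reduced by erythema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bn_params import CPT, DiscreteBN
from .bn_structure import DAG
from .report_io import (
    AGE_BIN_EDGES,
    AGE_GROUP_LABELS,
    GENDER_LABELS,
    CaseMatrix,
    Report,
    ReportTable,
    Variable,
)

__all__ = [
    "GeneratorSpec",
    "MessConfig",
    "random_network",
    "sample_cohort",
    "emulate_raw_reports",
    "fixture_network",
    "FIXTURE_MB_MEMBERS",
    "OUTCOME_TERM",
    "exact_marginal",
]

OUTCOME_TERM = "guillain-barre syndrome"

#: upper rendering bound for the open-ended >=65 age group, in years
_MAX_RENDERED_AGE = 90.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Settings for a random ground-truth network."""

    cardinalities: tuple[int, ...]
    max_parents: int = 3
    concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 2 for c in self.cardinalities):
            raise ValueError("cardinalities must be >= 2")
        if self.max_parents >= len(self.cardinalities):
            raise ValueError("max_parents must be below the node count")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def random_network(spec: GeneratorSpec, names: Sequence[str] | None = None) -> DiscreteBN:
    """A random DAG with Dirichlet-sampled CPT rows; reproducible per seed.

    Nodes are placed in a random topological order; each node draws its
    parents uniformly from its predecessors (at most ``max_parents``), and
    each CPT row is sampled from a symmetric Dirichlet with the given
    concentration (large concentration => near-uniform rows).
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.cardinalities)
    if names is None:
        names = [f"X{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("names length must match cardinalities")
    order = rng.permutation(p)
    dag = DAG(names)
    for pos in range(1, p):
        node = names[order[pos]]
        pool = [names[order[j]] for j in range(pos)]
        n_par = int(rng.integers(0, min(spec.max_parents, pos) + 1))
        for parent in rng.choice(pool, size=n_par, replace=False):
            dag.add_arc(str(parent), node)

    card = dict(zip(names, spec.cardinalities))
    cpts: dict[str, CPT] = {}
    for node in names:
        parents = tuple(sorted(dag.parents(node)))
        r = card[node]
        shape = tuple(card[q] for q in parents) + (r,)
        q = int(np.prod(shape[:-1])) if parents else 1
        rows = rng.dirichlet([spec.concentration] * r, size=q)
        cpts[node] = CPT(node, parents, rows.reshape(shape))
    variables = [Variable(n, tuple(f"s{i}" for i in range(card[n]))) for n in names]
    return DiscreteBN(dag, variables, cpts)


def sample_cohort(bn: DiscreteBN, n: int, seed: int, outcome: str | None = None) -> CaseMatrix:
    """Draw ``n`` rows by ancestral sampling in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    columns: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        r = bn.cardinality(node)
        if cpt.parent_order:
            flat = np.zeros(n, dtype=np.int64)
            for parent in cpt.parent_order:
                flat = flat * bn.cardinality(parent) + columns[parent]
            probs = cpt.table.reshape(-1, r)[flat]
        else:
            probs = np.broadcast_to(cpt.table, (n, r))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        columns[node] = (u[:, None] > cum).sum(axis=1).astype(np.int8)

    names = list(bn.dag.nodes)
    data = np.column_stack([columns[v] for v in names])
    variables = [bn.variables[v] for v in names]
    outcome = outcome or (names[0] if "GBS" not in names else "GBS")
    return CaseMatrix(variables, data, outcome)


def exact_marginal(bn: DiscreteBN, node: str) -> np.ndarray:
    """Marginal distribution of one node by full-joint enumeration.

    Intended for small networks (the state space is enumerated); used to
    calibrate and sanity-check fixtures against sampled cohorts.
    """
    order = bn.dag.topological_order()
    cards = [bn.cardinality(v) for v in order]
    marg = np.zeros(bn.cardinality(node))
    assignment: dict[str, int] = {}

    def recurse(i: int, logp: float) -> None:
        if logp == -math.inf:
            return
        if i == len(order):
            marg[assignment[node]] += math.exp(logp)
            return
        v = order[i]
        for s in range(cards[i]):
            assignment[v] = s
            recurse(i + 1, logp + bn.log_prob_node(v, assignment))

    recurse(0, 0.0)
    return marg


# ---------------------------------------------------------------------------
# the surveillance-calibrated fixture network
# ---------------------------------------------------------------------------

#: marginals of the exogenous variables, from the US cohort totals
_AGE_MARGINAL = (0.1674, 0.3211, 0.2207, 0.2907)
_MALE_MARGINAL = 0.3010
#: root-AE marginal prevalences, from the US per-mille totals
_ROOT_AE_PREVALENCE = {
    "erythema": 0.08969,
    "chills": 0.06846,
    "dizziness": 0.06345,
    "myalgia": 0.04952,
    "nausea": 0.06270,
    "pain in extremity": 0.08679,
}

#: which spouse AE feeds which child of the outcome (configurable; the
#: qualitative roles are fixed but the published structure does not pin
#: down the exact spouse-to-child wiring, so this mapping is an assumption;
#: spouses are wired into low-arity child families where the induced
#: v-structure is statistically identifiable at realistic cohort sizes)
DEFAULT_SPOUSE_MAP: dict[str, str] = {
    "chills": "asthenia",
    "nausea": "asthenia",
    "pain in extremity": "asthenia",
    "dizziness": "paresthesia",
    "myalgia": "muscular weakness",
}

FIXTURE_MB_MEMBERS = frozenset(
    {
        "age",
        "gender",
        "erythema",
        "asthenia",
        "hypesthesia",
        "muscular weakness",
        "paresthesia",
        "chills",
        "dizziness",
        "myalgia",
        "nausea",
        "pain in extremity",
    }
)

#: relative GBS risk by age group (rise-then-fall, peaking at 50-64)
_GBS_AGE_PROFILE = (1.0, 2.5, 5.5, 3.75)
#: male-to-female GBS risk ratio
_GBS_MALE_RATIO = 3.0
#: multiplicative GBS risk factor when erythema is present ("almost no
#: chance": a 50-fold reduction at every age/gender combination)
_GBS_ERYTHEMA_FACTOR = 0.02
#: target marginal outcome prevalence (US cohort: 1.26%)
_GBS_MARGINAL_TARGET = 0.0126

# child-AE generation: baseline risk multiplied per active parent, capped.
# GBS risk ratios echo the US GBS vs non-GBS prevalence contrasts; the age
# effect on paresthesia/hypesthesia rises then falls.  Spouse effects are
# strong positive associations among background (non-GBS) reports, but
# reverse in GBS reports: spontaneous reports list a limited symptom set,
# so in cases the syndrome dominates and a co-symptom on the report makes
# the child symptom less likely to be listed.  This outcome-by-spouse
# interaction is what makes the collider orientations identifiable.
_CHILD_AGE_PROFILE = (1.0, 1.6, 2.0, 1.4)
#: spouse-effect multiplier applied in GBS reports instead of "extra"
_SPOUSE_IN_CASE_MULT = 0.3
_CHILD_SPECS: dict[str, dict] = {
    "asthenia": {"base": 0.0230, "gbs": 7.0, "age": None,
                 "extra": {"chills": 4.5, "nausea": 4.5,
                           "pain in extremity": 4.5}},
    "paresthesia": {"base": 0.0186, "gbs": 10.0, "age": _CHILD_AGE_PROFILE,
                    "extra": {"dizziness": 4.0}},
    "hypesthesia": {"base": 0.0166, "gbs": 10.0, "age": _CHILD_AGE_PROFILE,
                    "extra": {"paresthesia": 4.0}},
    "muscular weakness": {"base": 0.0103, "gbs": 15.0, "age": None,
                          "extra": {"paresthesia": 3.5, "hypesthesia": 3.5,
                                    "myalgia": 6.0}},
}
_CHILD_PROB_CAP = 0.90


def _bernoulli_cpt(name: str, p: float) -> CPT:
    return CPT(name, (), np.array([1.0 - p, p]))


def _outcome_cpt(scale: float) -> np.ndarray:
    """P(GBS | age, gender, erythema) table, parents in sorted order."""
    parents = ("age", "erythema", "gender")  # sorted order used by fit_mle too
    table = np.zeros((4, 2, 2, 2))
    for a in range(4):
        for e in range(2):
            for g in range(2):
                p1 = scale * _GBS_AGE_PROFILE[a] * (
                    _GBS_MALE_RATIO if g == 1 else 1.0
                )
                if e == 1:
                    p1 *= _GBS_ERYTHEMA_FACTOR
                table[a, e, g] = (1.0 - p1, p1)
    return table


def _solve_outcome_scale() -> float:
    """Scale of the no-erythema block so that marginal P(GBS) hits target.

    The outcome's parents are all roots, so the marginal is a weighted sum
    of CPT entries and is linear in the scale; solved exactly.
    """
    p_ery = _ROOT_AE_PREVALENCE["erythema"]
    weight = 0.0
    for a, pa in enumerate(_AGE_MARGINAL):
        for g, pg in enumerate((1.0 - _MALE_MARGINAL, _MALE_MARGINAL)):
            weight += pa * pg * _GBS_AGE_PROFILE[a] * (
                _GBS_MALE_RATIO if g == 1 else 1.0
            )
    weight *= (1.0 - p_ery) + p_ery * _GBS_ERYTHEMA_FACTOR
    return _GBS_MARGINAL_TARGET / weight


def _child_cpt(name: str, parents: tuple[str, ...], card: Mapping[str, int]) -> CPT:
    spec = _CHILD_SPECS[name]
    shape = tuple(card[p] for p in parents) + (2,)
    table = np.zeros(shape)
    for config in np.ndindex(*shape[:-1]):
        states = dict(zip(parents, config))
        p1 = spec["base"]
        has_outcome = bool(states.get("GBS"))
        if has_outcome:
            p1 *= spec["gbs"]
        if spec["age"] is not None and "age" in states:
            p1 *= spec["age"][states["age"]]
        for extra, mult in spec["extra"].items():
            if states.get(extra):
                p1 *= mult if not has_outcome else _SPOUSE_IN_CASE_MULT
        p1 = min(p1, _CHILD_PROB_CAP)
        table[config] = (1.0 - p1, p1)
    return CPT(name, parents, table)


def fixture_network(spouse_map: Mapping[str, str] | None = None) -> DiscreteBN:
    """The bundled surveillance-calibrated ground-truth network (13 nodes)."""
    spouse_map = dict(spouse_map or DEFAULT_SPOUSE_MAP)
    children_of_outcome = ("asthenia", "hypesthesia", "muscular weakness", "paresthesia")
    for spouse, child in spouse_map.items():
        if child not in children_of_outcome:
            raise ValueError(f"spouse {spouse!r} mapped to non-child {child!r}")

    nodes = ["GBS", "age", "gender"] + sorted(_ROOT_AE_PREVALENCE) + [
        c for c in children_of_outcome if c not in _ROOT_AE_PREVALENCE
    ]
    arcs: set[tuple[str, str]] = {
        ("age", "GBS"), ("gender", "GBS"), ("erythema", "GBS"),
        ("GBS", "asthenia"), ("GBS", "hypesthesia"),
        ("GBS", "muscular weakness"), ("GBS", "paresthesia"),
        ("age", "paresthesia"), ("age", "hypesthesia"),
        ("paresthesia", "hypesthesia"), ("paresthesia", "muscular weakness"),
        ("hypesthesia", "muscular weakness"),
    }
    arcs |= {(s, c) for s, c in spouse_map.items()}
    dag = DAG(nodes, arcs)

    card = {n: 2 for n in nodes}
    card["age"] = 4
    variables = [
        Variable("GBS", ("false", "true")),
        Variable("age", AGE_GROUP_LABELS),
        Variable("gender", GENDER_LABELS),
        *(Variable(n, ("false", "true")) for n in nodes if n not in ("GBS", "age", "gender")),
    ]

    cpts: dict[str, CPT] = {
        "age": CPT("age", (), np.array(_AGE_MARGINAL) / sum(_AGE_MARGINAL)),
        "gender": CPT("gender", (), np.array([1.0 - _MALE_MARGINAL, _MALE_MARGINAL])),
    }
    for ae, prev in _ROOT_AE_PREVALENCE.items():
        cpts[ae] = _bernoulli_cpt(ae, prev)
    cpts["GBS"] = CPT("GBS", ("age", "erythema", "gender"), _outcome_cpt(_solve_outcome_scale()))
    for child in children_of_outcome:
        parents = tuple(sorted(dag.parents(child)))
        cpts[child] = _child_cpt(child, parents, card)
    return DiscreteBN(dag, variables, cpts)


@dataclass(frozen=True)
class MessConfig:
    """Raw-report corruption settings for :func:`emulate_raw_reports`."""

    missing_age: float = 0.0
    under_age: float = 0.0  # fraction given an age below 0.5 years
    unknown_gender: float = 0.0
    n_decoys: int = 40
    decoy_prevalence: tuple[float, float] = (0.015, 0.12)

    def __post_init__(self) -> None:
        for frac in (self.missing_age, self.under_age, self.unknown_gender):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("corruption fractions must lie in [0, 1]")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")


def emulate_raw_reports(
    bn: DiscreteBN, n: int, seed: int, mess: MessConfig | None = None
) -> ReportTable:
    """Sample a cohort and render it as a raw report table.

    Discrete age groups are rendered as continuous ages drawn uniformly
    within the group's interval (the open-ended top group within
    [65, 90)); AE indicators become preferred-term sets (the outcome term
    included when GBS is positive); then the configured fractions of rows
    receive a missing age, an age below 0.5 years, or an unknown gender,
    and independent decoy AE columns are appended.
    """
    mess = mess or MessConfig()
    matrix = sample_cohort(bn, n, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))

    age_groups = matrix.column("age")
    edges = list(AGE_BIN_EDGES) + [_MAX_RENDERED_AGE]
    lo = np.array([edges[g] for g in age_groups])
    hi = np.array([edges[g + 1] for g in age_groups])
    ages = lo + rng.random(n) * (hi - lo)

    genders = [GENDER_LABELS[g] for g in matrix.column("gender")]
    outcome_col = matrix.column("GBS").astype(bool)

    ae_names = [v.name for v in matrix.variables if v.name not in ("GBS", "age", "gender")]
    ae_cols = {name: matrix.column(name).astype(bool) for name in ae_names}
    decoy_cols: dict[str, np.ndarray] = {}
    for j in range(mess.n_decoys):
        prev = rng.uniform(*mess.decoy_prevalence)
        decoy_cols[f"decoy symptom {j + 1:02d}"] = rng.random(n) < prev
    ae_cols.update(decoy_cols)

    missing_mask = rng.random(n) < mess.missing_age
    under_mask = rng.random(n) < mess.under_age
    unknown_mask = rng.random(n) < mess.unknown_gender

    records: list[Report] = []
    for i in range(n):
        terms = {name for name, col in ae_cols.items() if col[i]}
        if outcome_col[i]:
            terms.add(OUTCOME_TERM)
        age: float | None = float(ages[i])
        if under_mask[i]:
            age = float(rng.random() * 0.5)
        if missing_mask[i]:
            age = None
        gender = "unknown" if unknown_mask[i] else genders[i]
        records.append(
            Report(f"r{i + 1:07d}", age, gender, frozenset(terms), bool(outcome_col[i]))
        )
    return ReportTable(records, outcome_term=OUTCOME_TERM)
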
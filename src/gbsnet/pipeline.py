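"""End-to-end orchestration of the two-step modelling workflow.

Step one: clean the raw reports, pick the top-K prevalent AEs, learn a
constrained network structure on the full development cohort, and reduce
it to the Markov blanket of the outcome.  Step two: with the structure
fixed, estimate CPTs by maximum likelihood and evaluate by repeated
stratified cross-validation (and, optionally, on an external cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bn_params import DiscreteBN, fit_mle
from .bn_structure import (
    ArcConstraints,
    DAG,
    MarkovBlanket,
    ScoredStructure,
    TabuParams,
    arc_strength,
    extract_mb_subnetwork,
    markov_blanket,
    tabu_search,
)
from .report_io import CaseMatrix, ReportTable, apply_exclusions, build_case_matrix, select_top_k_aes
from .screening import DEFAULT_ALPHA, ScreeningRecord, screen_aes
from .validation import CVResult, repeated_cv

__all__ = ["PipelineConfig", "PipelineResult", "default_constraints", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of one development run."""

    outcome_name: str = "GBS"
    top_k: int = 50
    alpha: float = DEFAULT_ALPHA
    cv_folds: int = 5
    cv_repeats: int = 100
    seed: int = 0
    search: TabuParams = field(default_factory=TabuParams)


@dataclass
class PipelineResult:
    exclusion_log: dict[str, int]
    vocabulary: list[str]
    matrix: CaseMatrix
    screening: list[ScreeningRecord]
    initial: ScoredStructure
    blanket: MarkovBlanket
    network_dag: DAG
    arc_strengths: dict[tuple[str, str], float]
    model: DiscreteBN
    cv: CVResult | None


def default_constraints(names: list[str], outcome: str) -> ArcConstraints:
    """Demographic prior: nothing points into age or gender; both point at
    the outcome."""
    return ArcConstraints.outcome_prior(outcome, ["age", "gender"], names)


def run_pipeline(
    table: ReportTable,
    config: PipelineConfig | None = None,
    run_cv: bool = True,
) -> PipelineResult:
    """Run cleaning, screening, structure learning, reduction and CV."""
    config = config or PipelineConfig()
    cleaned, log = apply_exclusions(table)
    vocabulary = select_top_k_aes(cleaned, config.top_k)
    matrix = build_case_matrix(cleaned, vocabulary, outcome_name=config.outcome_name)

    screening = screen_aes(matrix, alpha=config.alpha)

    constraints = default_constraints(matrix.names, config.outcome_name)
    search = TabuParams(
        max_iter=config.search.max_iter,
        tabu_length=config.search.tabu_length,
        max_escape=config.search.max_escape,
        seed=config.seed,
    )
    initial = tabu_search(matrix, constraints, search)
    blanket = markov_blanket(initial.dag, config.outcome_name)
    network_dag = extract_mb_subnetwork(initial.dag, config.outcome_name)
    strengths = arc_strength(initial, matrix)
    strengths = {arc: s for arc, s in strengths.items() if arc in network_dag.arcs}

    keep = [v.name for v in matrix.variables if v.name in set(network_dag.nodes)]
    sub_vars = [matrix.variables[matrix.names.index(k)] for k in keep]
    sub_matrix = CaseMatrix(
        sub_vars,
        matrix.data[:, [matrix.names.index(k) for k in keep]],
        config.outcome_name,
    )
    model = fit_mle(network_dag, sub_matrix)

    cv = None
    if run_cv:
        cv = repeated_cv(
            sub_matrix,
            network_dag,
            k=config.cv_folds,
            repeats=config.cv_repeats,
            seed=config.seed,
        )
    return PipelineResult(
        exclusion_log=log,
        vocabulary=vocabulary,
        matrix=matrix,
        screening=screening,
        initial=initial,
        blanket=blanket,
        network_dag=network_dag,
        arc_strengths=strengths,
        model=model,
        cv=cv,
    )
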
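"""The tINIT algorithm: task-driven context-specific model extraction.

Given a reference genome-scale network, per-reaction evidence scores and a
list of metabolic tasks, tINIT produces the sub-network that best matches
the evidence while remaining able to perform every task.  It runs in three
steps:

1. **Task-essential reactions** (:func:`find_essential_reactions`): every
   reaction whose removal from the reference makes at least one task
   infeasible.  These must appear in any functional sub-network, so they are
   forced into the selection.
2. **Score-maximising selection MILP** (:func:`solve_selection_milp`): pick
   the reaction subset maximising the summed evidence score, subject to the
   network being usable at steady state — each positively scored selected
   reaction must be able to carry flux — with the essential set forced in.
   Two refinements over the original INIT formulation: reversible reactions
   may not carry flux in both directions simultaneously (which previously
   let disconnected loops count as "used"), and net accumulation of internal
   metabolites is off by default (optionally allowed with a penalty).
3. **Sequential gap-filling** (:func:`gapfill_task`): each task is tested on
   the selected sub-network in list order; a failing task triggers a
   minimum-cardinality re-insertion of reference reactions that makes it
   feasible.  Because the essential set is already included, the selection
   is near-functional and gap-filling typically adds few reactions; the
   per-task additions are recorded so any order effect is auditable.

:func:`run_tinit` chains the three steps and verifies the functionality
contract: the final model passes every task (and every negative-control
task stays infeasible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._lp import LinearSystem, SolverError
from .evidence import ScoreVector
from .gem_core import Model, SolverOptions, subset_model
from .tasks import Task, TaskResult, build_task_system, check_task, check_tasks

__all__ = [
    "TinitOptions",
    "TinitResult",
    "InfeasibleReferenceError",
    "find_essential_reactions",
    "solve_selection_milp",
    "gapfill_task",
    "run_tinit",
]

_FLUX_TOL = 1e-9  # below this a witness flux counts as zero


class InfeasibleReferenceError(RuntimeError):
    """The reference network cannot perform a task it is supposed to."""


@dataclass
class TinitOptions:
    """Behavioural switches of the tINIT run.

    allow_net_production
        Permit net accumulation of internal metabolites in the selection
        MILP (the original INIT behaviour); each unit of accumulation costs
        ``net_production_penalty`` in the objective.
    forbid_bidirectional_flux
        Forbid a reversible reaction from carrying forward and backward flux
        simultaneously, which would let disconnected loops satisfy the
        "reaction is used" coupling.
    include_growth_in_essentiality
        Whether growth-category tasks participate in step 1; they always
        participate in gap-filling and the final report.
    deterministic_tiebreak
        Resolve ties between equally optimal selections with a secondary
        MILP preferring lower reaction indices, for reproducibility.
    """

    allow_net_production: bool = False
    forbid_bidirectional_flux: bool = True
    net_production_penalty: float = 1.0
    include_growth_in_essentiality: bool = True
    deterministic_tiebreak: bool = True
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.net_production_penalty < 0:
            raise ValueError("net_production_penalty must be >= 0")


@dataclass
class TinitResult:
    selected_reactions: Set[str]            # final model (selection + gap fills)
    required_reactions: Set[str]            # step-1 task-essential set
    milp_selected_reactions: Set[str]       # step-2 selection before gap-filling
    gapfilled_reactions: List[Tuple[str, Set[str]]]  # (task id, added) in order
    objective_value: float
    task_report: List[TaskResult]

    def validate(self) -> None:
        if not self.required_reactions <= self.selected_reactions:
            raise AssertionError("required reactions missing from selection")
        for _, added in self.gapfilled_reactions:
            if not added <= self.selected_reactions:
                raise AssertionError("gap-filled reaction missing from selection")
        if not all(r.passed for r in self.task_report):
            failed = [r.task_id for r in self.task_report if not r.passed]
            raise AssertionError(f"final model fails tasks: {failed}")


# --------------------------------------------------------------------------
# Step 1: task-essential reactions
# --------------------------------------------------------------------------

def _assert_reference_feasible(
    reference: Model, tasks: Sequence[Task], options: SolverOptions
) -> Dict[str, TaskResult]:
    """Check all tasks on the reference; raise naming any violations."""
    results = {t.id: check_task(reference, t, options) for t in tasks}
    bad_feasible = [t.id for t in tasks if not t.should_fail and not results[t.id].feasible]
    bad_controls = [t.id for t in tasks if t.should_fail and results[t.id].feasible]
    if bad_feasible or bad_controls:
        parts = []
        if bad_feasible:
            parts.append(f"tasks infeasible in reference: {bad_feasible}")
        if bad_controls:
            parts.append(f"negative-control tasks feasible in reference: {bad_controls}")
        raise InfeasibleReferenceError("; ".join(parts))
    return results


def find_essential_reactions(
    reference: Model,
    tasks: Sequence[Task],
    options: Optional[SolverOptions] = None,
    use_witness_prefilter: bool = True,
) -> Set[str]:
    """Reactions whose single removal breaks at least one task.

    Negative-control (``should_fail``) tasks are ignored: removing reactions
    can never make an infeasible task feasible.  With the witness pre-filter
    (default), only reactions carrying flux in one feasible witness of a
    task are tested for that task — a reaction at zero flux in a feasible
    witness is provably non-essential for it, since the same witness remains
    valid after the removal.
    """
    options = options or SolverOptions()
    positive = [t for t in tasks if not t.should_fail]
    baseline = _assert_reference_feasible(reference, positive, options)

    essential: Set[str] = set()
    for task in positive:
        if use_witness_prefilter:
            witness = baseline[task.id].witness_flux or {}
            candidates = [r for r, v in witness.items() if abs(v) > _FLUX_TOL]
        else:
            candidates = list(reference.reaction_ids)
        for rid in candidates:
            if rid in essential:
                continue
            res = check_task(reference, task, options,
                             disabled_reactions=frozenset({rid}))
            if not res.feasible:
                essential.add(rid)
    return essential


# --------------------------------------------------------------------------
# Step 2: selection MILP
# --------------------------------------------------------------------------

def _build_selection_system(
    reference: Model,
    scores: ScoreVector,
    required: Set[str],
    options: TinitOptions,
) -> Tuple[LinearSystem, List[str]]:
    sol = options.solver
    eps, M = sol.activation_epsilon, sol.big_M
    sys = LinearSystem()
    rids = reference.reaction_ids

    balance: Dict[str, List[Tuple[int, float]]] = {
        m.id: [] for m in reference.metabolites if not m.is_boundary
    }
    for rxn in reference.reactions:
        w = float(scores[rxn.id])
        fwd_cap = max(rxn.upper_bound, 0.0)
        bwd_cap = max(-rxn.lower_bound, 0.0)
        vf = sys.add_var(f"vf:{rxn.id}", 0.0, fwd_cap)
        vb = sys.add_var(f"vb:{rxn.id}", 0.0, bwd_cap)
        fixed = 1.0 if rxn.id in required else None
        y = sys.add_var(
            f"y:{rxn.id}",
            lb=fixed if fixed is not None else 0.0,
            ub=fixed if fixed is not None else 1.0,
            obj=-w,  # maximise sum of scores
            integer=True,
        )
        for met_id, coef in rxn.stoichiometry.items():
            if met_id in balance:
                balance[met_id].append((vf, coef))
                balance[met_id].append((vb, -coef))
        # inclusion coupling: flux only through selected reactions
        sys.add_constraint([(vf, 1.0), (vb, 1.0), (y, -M)], ub=0.0)
        # positively scored selected reactions must actually be usable
        if w > 0:
            sys.add_constraint([(y, eps), (vf, -1.0), (vb, -1.0)], ub=0.0)
        # no simultaneous bidirectional flux on reversible reactions
        if options.forbid_bidirectional_flux and fwd_cap > 0 and bwd_cap > 0:
            df = sys.add_var(f"df:{rxn.id}", 0.0, 1.0, integer=True)
            db = sys.add_var(f"db:{rxn.id}", 0.0, 1.0, integer=True)
            sys.add_constraint([(vf, 1.0), (df, -M)], ub=0.0)
            sys.add_constraint([(vb, 1.0), (db, -M)], ub=0.0)
            sys.add_constraint([(df, 1.0), (db, 1.0)], ub=1.0)

    for met_id, entries in balance.items():
        if options.allow_net_production:
            b = sys.add_var(f"net:{met_id}", 0.0, M,
                            obj=options.net_production_penalty)
            entries = entries + [(b, -1.0)]
            sys.add_constraint(entries, lb=0.0, ub=0.0)
        else:
            sys.add_constraint(entries, lb=0.0, ub=0.0)
    return sys, rids


def solve_selection_milp(
    reference: Model,
    scores: ScoreVector,
    required: Iterable[str] = (),
    options: Optional[TinitOptions] = None,
) -> Tuple[Set[str], float]:
    """Score-maximising flux-consistent reaction selection (INIT step).

    Returns the selected reaction-id set and the achieved objective
    (summed score of selected reactions minus any net-production penalty).
    """
    options = options or TinitOptions()
    required = set(required)
    unknown = required - set(reference.reaction_ids)
    if unknown:
        raise KeyError(f"required reactions not in reference: {sorted(unknown)}")
    missing_scores = set(reference.reaction_ids) - set(scores)
    if missing_scores:
        raise KeyError(f"scores missing for reactions: {sorted(missing_scores)}")

    sys, rids = _build_selection_system(reference, scores, required, options)
    sol = options.solver
    res = sys.solve(mip_gap=sol.mip_gap, time_limit=sol.time_limit_seconds)
    if not res.feasible:
        raise SolverError("selection MILP infeasible (check required set and bounds)")

    def _selection(r) -> Set[str]:
        return {rid for rid in rids if sys.value(r, f"y:{rid}") > 0.5}

    selected = _selection(res)
    objective = _objective_value(sys, res, rids, scores, options)

    if options.deterministic_tiebreak:
        # second stage: among optimal selections prefer dropping
        # higher-index reactions (deterministic secondary objective)
        tol = max(1e-7, abs(objective) * 1e-9)
        obj_row = [(sys.var(f"y:{rid}"), -float(scores[rid])) for rid in rids]
        if options.allow_net_production:
            obj_row += [
                (sys.var(f"net:{m.id}"), options.net_production_penalty)
                for m in reference.metabolites
                if not m.is_boundary
            ]
        sys.add_constraint(obj_row, ub=-objective + tol)
        sys.set_objective(
            {sys.var(f"y:{rid}"): float(i + 1) for i, rid in enumerate(rids)}
        )
        res2 = sys.solve(mip_gap=sol.mip_gap, time_limit=sol.time_limit_seconds)
        if res2.feasible:
            selected = _selection(res2)
            objective = _objective_value(sys, res2, rids, scores, options)
    return selected, objective


def _objective_value(sys, res, rids, scores, options: TinitOptions) -> float:
    total = sum(scores[rid] for rid in rids if sys.value(res, f"y:{rid}") > 0.5)
    if options.allow_net_production:
        penalty = sum(
            sys.value(res, name)
            for name in sys.names
            if name.startswith("net:")
        )
        total -= options.net_production_penalty * penalty
    return float(total)


# --------------------------------------------------------------------------
# Step 3: gap-filling
# --------------------------------------------------------------------------

def gapfill_task(
    draft: Iterable[str],
    reference: Model,
    task: Task,
    options: Optional[TinitOptions] = None,
    weights: Optional[Dict[str, float]] = None,
) -> Set[str]:
    """Minimum set of reference reactions to add so the task becomes feasible.

    Solves a MILP over the closed-system task LP of the *reference*: draft
    reactions keep their bounds; every candidate (reference minus draft)
    j is coupled to a binary y_j with \\|v_j\\| <= M y_j, and sum of y (or of
    ``weights``) is minimised.  Returns the empty set when the draft already
    performs the task; raises when even the reference cannot.
    """
    options = options or TinitOptions()
    sol = options.solver
    draft = set(draft)
    candidates = [r for r in reference.reaction_ids if r not in draft]

    # already feasible? (clamp candidates to zero)
    pre = check_task(reference, task, sol, disabled_reactions=frozenset(candidates))
    if pre.feasible:
        return set()
    full = check_task(reference, task, sol)
    if not full.feasible:
        raise InfeasibleReferenceError(
            f"task {task.id!r} infeasible even in the full reference "
            f"({full.reason or 'no flux solution'})"
        )

    sys, reason = build_task_system(reference, task, sol)
    assert sys is not None, reason  # full-reference check above succeeded
    obj: Dict[int, float] = {}
    M = sol.big_M
    for rid in candidates:
        v = sys.var(f"v:{rid}")
        y = sys.add_var(f"y:{rid}", 0.0, 1.0, integer=True)
        sys.add_constraint([(v, 1.0), (y, -M)], ub=0.0)
        sys.add_constraint([(v, -1.0), (y, -M)], ub=0.0)
        obj[y] = float(weights[rid]) if weights else 1.0
    sys.set_objective(obj)
    res = sys.solve(mip_gap=sol.mip_gap, time_limit=sol.time_limit_seconds)
    if not res.feasible:
        raise SolverError(f"gap-filling MILP infeasible for task {task.id!r}")
    return {rid for rid in candidates if sys.value(res, f"y:{rid}") > 0.5}


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

def run_tinit(
    reference: Model,
    scores: ScoreVector,
    tasks: Sequence[Task],
    options: Optional[TinitOptions] = None,
) -> TinitResult:
    """Run the three tINIT steps and return the reconstructed selection.

    The returned ``selected_reactions`` define the context-specific model
    (obtain it with :func:`tinit.gem_core.subset_model`); the result carries
    the step-1 essential set, the per-task gap-fill additions in task order,
    and the task report of the final model, which is guaranteed all-passing.
    """
    options = options or TinitOptions()
    sol = options.solver
    _assert_reference_feasible(reference, tasks, sol)

    step1_tasks = [
        t for t in tasks
        if not t.should_fail
        and (options.include_growth_in_essentiality or t.category != "growth")
    ]
    required = find_essential_reactions(reference, step1_tasks, sol)

    milp_selected, objective = solve_selection_milp(
        reference, scores, required, options
    )

    current = set(milp_selected)
    gapfilled: List[Tuple[str, Set[str]]] = []
    for task in tasks:
        if task.should_fail:
            continue
        added = gapfill_task(current, reference, task, options)
        current |= added
        gapfilled.append((task.id, added))

    final_model = subset_model(reference, current)
    report = check_tasks(final_model, tasks, sol)
    result = TinitResult(
        selected_reactions=current,
        required_reactions=required,
        milp_selected_reactions=milp_selected,
        gapfilled_reactions=gapfilled,
        objective_value=objective,
        task_report=report,
    )
    result.validate()
    return result
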
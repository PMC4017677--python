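"""Metabolic tasks: definition, table parsing and feasibility checking.

A *metabolic task* states a function the model must be able to perform: with
all exchange reactions closed, given only the declared inputs (bounded
uptakes), the model must sustain the declared outputs (bounded productions)
and/or a set of enforced net conversions at steady state.  Examples are ATP
re-phosphorylation from glucose, biosynthesis of a precursor, or biomass
growth.  Tasks drive both model reconstruction (the network must keep every
task feasible) and the antimetabolite screen (a blocked metabolite is scored
by which tasks it disables).

Negative controls are expressed with ``should_fail``: such a task *passes*
only when it is infeasible (e.g. free ATP production from nothing, which
would reveal an erroneous energy-generating cycle).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from ._lp import LinearSystem, SolveResult
from .gem_core import Model, SolverOptions

__all__ = [
    "CATEGORIES",
    "TaskIO",
    "TaskEquation",
    "Task",
    "TaskResult",
    "TaskSchemaError",
    "parse_task_table",
    "write_task_table",
    "check_task",
    "check_tasks",
]

CATEGORIES = (
    "energy_and_redox",
    "internal_conversions",
    "substrate_utilization",
    "biosynthesis_of_products",
    "growth",
    "other",
)


class TaskSchemaError(ValueError):
    """Malformed task table."""


@dataclass(frozen=True)
class TaskIO:
    """One task input or output.

    ``metabolite`` is either a bare compartment-agnostic name (``"glucose"``)
    or name plus compartment (``"glucose[e]"``).  Bounds are uptake rates for
    inputs and production rates for outputs.  ``lower`` may be ``None`` on
    outputs, meaning "use the solver's activation epsilon".
    """

    metabolite: str
    lower: Optional[float]
    upper: float

    @property
    def name(self) -> str:
        return _split_met(self.metabolite)[0]

    @property
    def compartment(self) -> Optional[str]:
        return _split_met(self.metabolite)[1]


@dataclass(frozen=True)
class TaskEquation:
    """An enforced net conversion, e.g. ``ATP[c] + H2O[c] => ADP[c] + Pi[c]``.

    Compiled at check time to a temporary lumped reaction forced to carry
    flux of at least the activation epsilon.
    """

    stoichiometry: Tuple[Tuple[str, float], ...]  # (metabolite token, signed coef)
    text: str = ""


@dataclass
class Task:
    id: str
    description: str = ""
    category: str = "other"
    should_fail: bool = False
    inputs: List[TaskIO] = field(default_factory=list)
    outputs: List[TaskIO] = field(default_factory=list)
    equations: List[TaskEquation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise TaskSchemaError(
                f"task {self.id!r}: unknown category {self.category!r}"
            )
        if not self.should_fail and not self.outputs and not self.equations:
            raise TaskSchemaError(
                f"task {self.id!r}: needs at least one output or equation "
                "(unless marked should_fail)"
            )
        for io_ in list(self.inputs) + list(self.outputs):
            if io_.lower is not None and io_.lower > io_.upper:
                raise TaskSchemaError(
                    f"task {self.id!r}: ill-ordered bounds on {io_.metabolite!r}"
                )


@dataclass
class TaskResult:
    task_id: str
    feasible: bool
    should_fail: bool = False
    reason: Optional[str] = None
    witness_flux: Optional[Dict[str, float]] = None

    @property
    def passed(self) -> bool:
        return self.feasible != self.should_fail


# --------------------------------------------------------------------------
# Table I/O
# --------------------------------------------------------------------------

_COLUMNS = (
    "TASK_ID",
    "DESCRIPTION",
    "CATEGORY",
    "SHOULD_FAIL",
    "IN",
    "IN_LB",
    "IN_UB",
    "OUT",
    "OUT_LB",
    "OUT_UB",
    "EQU",
)


def parse_task_table(path: str) -> List[Task]:
    """Parse a task table (TSV or CSV) into Task records.

    Layout mirrors a spreadsheet task list: the first row of a task carries
    TASK_ID / DESCRIPTION / CATEGORY / SHOULD_FAIL; additional rows with a
    blank TASK_ID continue the previous task, each row contributing at most
    one input (IN, IN_LB, IN_UB), one output (OUT, OUT_LB, OUT_UB) and one
    equation (EQU).  Unspecified input bounds default to [0, 1000];
    unspecified output lower bounds default to the activation epsilon at
    check time.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    unknown = set(frame.columns) - set(_COLUMNS)
    if unknown:
        raise TaskSchemaError(f"unknown task-table columns: {sorted(unknown)}")
    if "TASK_ID" not in frame.columns:
        raise TaskSchemaError("task table is missing the TASK_ID column")

    def _get(row, col, default=""):
        return str(row[col]).strip() if col in frame.columns else default

    tasks: List[Task] = []
    current: Optional[Dict] = None
    for _, row in frame.iterrows():
        tid = _get(row, "TASK_ID")
        if tid:
            if current is not None:
                tasks.append(_finish_task(current))
            current = {
                "id": tid,
                "description": _get(row, "DESCRIPTION"),
                "category": _get(row, "CATEGORY") or "other",
                "should_fail": _parse_bool(_get(row, "SHOULD_FAIL")),
                "inputs": [],
                "outputs": [],
                "equations": [],
            }
        elif current is None:
            raise TaskSchemaError("continuation row before any TASK_ID row")
        _append_row_io(current, row, _get)
    if current is not None:
        tasks.append(_finish_task(current))
    return tasks


def _append_row_io(current: Dict, row, _get) -> None:
    met_in = _get(row, "IN")
    if met_in:
        lb = _parse_float(_get(row, "IN_LB"), 0.0)
        ub = _parse_float(_get(row, "IN_UB"), 1000.0)
        current["inputs"].append(TaskIO(met_in, lb, ub))
    met_out = _get(row, "OUT")
    if met_out:
        lb_raw = _get(row, "OUT_LB")
        lb = float(lb_raw) if lb_raw else None  # None => epsilon at check time
        ub = _parse_float(_get(row, "OUT_UB"), 1000.0)
        current["outputs"].append(TaskIO(met_out, lb, ub))
    equ = _get(row, "EQU")
    if equ:
        current["equations"].append(parse_equation(equ))


def _finish_task(data: Dict) -> Task:
    return Task(**data)


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in ("1", "true", "yes", "y")


def _parse_float(raw: str, default: float) -> float:
    return float(raw) if raw.strip() else default


def parse_equation(text: str) -> TaskEquation:
    """Parse ``"A[c] + 2 B[c] => C[c]"`` (or ``<=>``) into a TaskEquation."""
    m = re.split(r"<?=>", text)
    if len(m) != 2:
        raise TaskSchemaError(f"equation {text!r} needs exactly one '=>' or '<=>'")
    stoich: List[Tuple[str, float]] = []
    for side, sign in ((m[0], -1.0), (m[1], +1.0)):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split(None, 1)
            if len(parts) == 2 and _is_number(parts[0]):
                coef, met = float(parts[0]), parts[1].strip()
            else:
                coef, met = 1.0, term
            stoich.append((met, sign * coef))
    if not stoich:
        raise TaskSchemaError(f"empty equation {text!r}")
    return TaskEquation(stoichiometry=tuple(stoich), text=text)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_task_table(tasks: Sequence[Task], path: str, sep: str = "\t") -> None:
    """Write tasks in the row-continuation layout read by parse_task_table."""
    rows = []
    for task in tasks:
        n = max(len(task.inputs), len(task.outputs), len(task.equations), 1)
        for i in range(n):
            row = {c: "" for c in _COLUMNS}
            if i == 0:
                row.update(
                    TASK_ID=task.id,
                    DESCRIPTION=task.description,
                    CATEGORY=task.category,
                    SHOULD_FAIL="true" if task.should_fail else "",
                )
            if i < len(task.inputs):
                io_ = task.inputs[i]
                row.update(IN=io_.metabolite, IN_LB=io_.lower, IN_UB=io_.upper)
            if i < len(task.outputs):
                io_ = task.outputs[i]
                row.update(
                    OUT=io_.metabolite,
                    OUT_LB="" if io_.lower is None else io_.lower,
                    OUT_UB=io_.upper,
                )
            if i < len(task.equations):
                row.update(EQU=task.equations[i].text)
            rows.append(row)
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Feasibility checking
# --------------------------------------------------------------------------

def _split_met(token: str) -> Tuple[str, Optional[str]]:
    m = re.match(r"^(.*)\[([^\[\]]+)\]$", token.strip())
    if m:
        return m.group(1), m.group(2)
    return token.strip(), None


def _resolve(model: Model, token: str) -> List[str]:
    """Metabolite ids matching a task token; [] when unmapped."""
    name, comp = _split_met(token)
    hits = model.metabolites_named(name)
    if comp is not None:
        hits = [m for m in hits if m.compartment == comp]
    return [m.id for m in hits]


def build_task_system(
    model: Model,
    task: Task,
    options: SolverOptions,
    disabled_reactions: FrozenSet[str] = frozenset(),
) -> Tuple[Optional[LinearSystem], Optional[str]]:
    """Assemble the closed-system feasibility LP for one task.

    Returns ``(system, None)`` on success or ``(None, reason)`` when a task
    metabolite cannot be mapped onto the model (reported as infeasibility,
    not an exception, so draft models missing metabolites are handled
    uniformly).

    Construction: every model reaction is a signed flux variable with its own
    bounds, except exchange reactions (closed to [0, 0]) and
    ``disabled_reactions`` (also [0, 0]).  Task inputs
    become temporary uptake variables, outputs temporary sinks, equations
    temporary lumped reactions with flux >= activation epsilon.  A bare
    metabolite name that matches several compartments is pooled: any
    instance may supply/absorb the flux.
    """
    eps = options.activation_epsilon
    sys = LinearSystem()
    balance: Dict[str, List[Tuple[int, float]]] = {m.id: [] for m in model.metabolites
                                                   if not m.is_boundary}

    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.is_exchange or rxn.id in disabled_reactions:
            lb = ub = 0.0
        idx = sys.add_var(f"v:{rxn.id}", lb=lb, ub=ub)
        for met_id, coef in rxn.stoichiometry.items():
            if met_id in balance:
                balance[met_id].append((idx, coef))

    # temporary task machinery
    for k, io_ in enumerate(task.inputs):
        ids = _resolve(model, io_.metabolite)
        if not ids:
            return None, f"unmapped metabolite {io_.metabolite!r}"
        lb = 0.0 if io_.lower is None else io_.lower
        uidx = sys.add_var(f"task_in:{k}:{io_.metabolite}", lb=lb, ub=io_.upper)
        if len(ids) == 1:
            balance[ids[0]].append((uidx, +1.0))
        else:
            # pooled uptake: total inflow bounded, split freely across instances
            parts = [sys.add_var(f"task_in:{k}:part:{mid}", lb=0.0, ub=io_.upper)
                     for mid in ids]
            for mid, pidx in zip(ids, parts):
                balance[mid].append((pidx, +1.0))
            sys.add_constraint(
                [(uidx, -1.0)] + [(p, 1.0) for p in parts], lb=0.0, ub=0.0
            )

    for k, io_ in enumerate(task.outputs):
        ids = _resolve(model, io_.metabolite)
        if not ids:
            return None, f"unmapped metabolite {io_.metabolite!r}"
        lb = eps if io_.lower is None else io_.lower
        sidx = sys.add_var(f"task_out:{k}:{io_.metabolite}", lb=lb, ub=io_.upper)
        if len(ids) == 1:
            balance[ids[0]].append((sidx, -1.0))
        else:
            parts = [sys.add_var(f"task_out:{k}:part:{mid}", lb=0.0, ub=io_.upper)
                     for mid in ids]
            for mid, pidx in zip(ids, parts):
                balance[mid].append((pidx, -1.0))
            sys.add_constraint(
                [(sidx, -1.0)] + [(p, 1.0) for p in parts], lb=0.0, ub=0.0
            )

    for k, equ in enumerate(task.equations):
        eidx = sys.add_var(f"task_equ:{k}", lb=eps, ub=options.big_M)
        for met_token, coef in equ.stoichiometry:
            ids = _resolve(model, met_token)
            if len(ids) != 1:
                reason = (
                    f"unmapped metabolite {met_token!r}"
                    if not ids
                    else f"ambiguous equation metabolite {met_token!r}"
                )
                return None, reason
            balance[ids[0]].append((eidx, coef))

    for met_id, entries in balance.items():
        sys.add_constraint(entries, lb=0.0, ub=0.0)
    return sys, None


def check_task(
    model: Model,
    task: Task,
    options: Optional[SolverOptions] = None,
    disabled_reactions: FrozenSet[str] = frozenset(),
) -> TaskResult:
    """Test whether the model can perform one task in a closed system.

    ``disabled_reactions`` additionally clamps the named reactions to zero
    flux — a cheap stand-in for removing them, used by essentiality sweeps
    and blocking-equivalence checks.
    """
    options = options or SolverOptions()
    sys, reason = build_task_system(model, task, options, disabled_reactions)
    if sys is None:
        return TaskResult(task.id, feasible=False, should_fail=task.should_fail,
                          reason=reason)
    result = sys.solve(mip_gap=options.mip_gap, time_limit=options.time_limit_seconds)
    if not result.feasible:
        return TaskResult(task.id, feasible=False, should_fail=task.should_fail,
                          reason="infeasible")
    witness = {
        rxn.id: sys.value(result, f"v:{rxn.id}") for rxn in model.reactions
    }
    return TaskResult(task.id, feasible=True, should_fail=task.should_fail,
                      witness_flux=witness)


def check_tasks(
    model: Model,
    tasks: Sequence[Task],
    options: Optional[SolverOptions] = None,
    disabled_reactions: FrozenSet[str] = frozenset(),
) -> List[TaskResult]:
    """Check a task list; one independent LP per task, order-preserving."""
    return [check_task(model, t, options, disabled_reactions) for t in tasks]
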
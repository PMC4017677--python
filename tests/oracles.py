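"""Independent brute-force oracles used to validate the optimisation code.

These deliberately avoid the package's MILP formulations: the selection
oracle enumerates reaction subsets (with explicit direction assignments for
reversible reactions) and checks each candidate with a plain signed-flux LP
via ``scipy.optimize.linprog``; the gap-fill oracle enumerates addition
subsets by increasing cardinality; the reachability oracle closes the set
of producible metabolites combinatorially.  They are tractable only for
networks of roughly a dozen reactions, which is exactly the scale the
fixtures use.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from tinit.gem_core import Model, SolverOptions
from tinit.tasks import Task, check_task


def _steady_state_matrix(model: Model, rids: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    mets = [m.id for m in model.metabolites if not m.is_boundary]
    met_pos = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rids)))
    for j, rid in enumerate(rids):
        for met, coef in model.reaction(rid).stoichiometry.items():
            if met in met_pos:
                S[met_pos[met], j] = coef
    return S, mets


def _subset_feasible(
    model: Model,
    rids: Sequence[str],
    subset: Set[str],
    positive: Set[str],
    eps: float,
) -> bool:
    """Does a steady-state flux exist using only ``subset``, with every
    positively scored member carrying |v| >= eps?

    Reversible positively scored members need a direction choice for the
    |v| >= eps constraint; all sign assignments are enumerated.
    """
    S, _ = _steady_state_matrix(model, rids)
    base_lb, base_ub = [], []
    for rid in rids:
        r = model.reaction(rid)
        if rid in subset:
            base_lb.append(r.lower_bound)
            base_ub.append(r.upper_bound)
        else:
            base_lb.append(0.0)
            base_ub.append(0.0)

    need = [rid for rid in rids if rid in subset and rid in positive]
    rev_need = [
        rid for rid in need
        if model.reaction(rid).lower_bound < 0 and model.reaction(rid).upper_bound > 0
    ]
    for signs in itertools.product((1, -1), repeat=len(rev_need)):
        lb, ub = list(base_lb), list(base_ub)
        ok = True
        for rid in need:
            j = rids.index(rid)
            r = model.reaction(rid)
            if rid in rev_need:
                s = signs[rev_need.index(rid)]
            else:
                s = 1 if r.upper_bound > 0 else -1
            if s > 0:
                lb[j] = max(lb[j], eps)
            else:
                ub[j] = min(ub[j], -eps)
            if lb[j] > ub[j]:
                ok = False
                break
        if not ok:
            continue
        res = linprog(
            c=np.zeros(len(rids)),
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lb, ub)),
            method="highs",
        )
        if res.status == 0:
            return True
    return False


def brute_force_selection_optimum(
    model: Model,
    scores: Dict[str, float],
    required: Set[str] = frozenset(),
    options: Optional[SolverOptions] = None,
) -> float:
    """Optimal summed score over flux-consistent reaction subsets.

    A subset is admissible when it contains ``required`` and admits a
    steady-state flux in which every positively scored member is used
    (|v| >= activation epsilon); its value is the sum of member scores.
    Subsets are visited in decreasing value, so the first admissible one is
    the optimum.  The empty subset is always admissible (value 0), so the
    search always terminates with a value.
    """
    options = options or SolverOptions()
    rids = list(model.reaction_ids)
    positive = {r for r in rids if scores[r] > 0}
    weights = np.array([scores[r] for r in rids])

    subsets = []
    for mask in range(1 << len(rids)):
        sub = {rids[i] for i in range(len(rids)) if mask >> i & 1}
        if not required <= sub:
            continue
        subsets.append((float(weights[[rids.index(r) for r in sub]].sum())
                        if sub else 0.0, sub))
    subsets.sort(key=lambda t: -t[0])
    for value, sub in subsets:
        if _subset_feasible(model, rids, sub, positive, options.activation_epsilon):
            return value
    raise AssertionError("no admissible subset found (required set infeasible?)")


def brute_force_gapfill_minimum(
    draft: Set[str],
    reference: Model,
    task: Task,
    options: Optional[SolverOptions] = None,
) -> int:
    """Minimum number of added reference reactions making the task feasible.

    Enumerates candidate subsets by increasing cardinality and tests each
    with the closed-system task LP on the clamped reference.
    """
    options = options or SolverOptions()
    candidates = [r for r in reference.reaction_ids if r not in draft]
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            disabled = frozenset(set(candidates) - set(combo))
            if check_task(reference, task, options,
                          disabled_reactions=disabled).feasible:
                return k
    raise AssertionError(f"task {task.id!r} infeasible even in full reference")


def reachable_metabolites(
    model: Model,
    seeds: Iterable[str],
    subset: Optional[Set[str]] = None,
) -> Set[str]:
    """Combinatorial closure of producible metabolite ids from seed ids.

    A reaction direction can fire once all its substrates (in that
    direction) are available; products then become available.  On the
    acyclic unit-stoichiometry fixtures used in tests this coincides with
    LP producibility, giving an independent reachability oracle.
    """
    available = set(seeds)
    rxns = [r for r in model.reactions
            if (subset is None or r.id in subset) and not r.is_exchange]
    changed = True
    while changed:
        changed = False
        for r in rxns:
            subs = {m for m, c in r.stoichiometry.items() if c < 0}
            prods = {m for m, c in r.stoichiometry.items() if c > 0}
            if r.upper_bound > 0 and subs <= available and not prods <= available:
                available |= prods
                changed = True
            if r.lower_bound < 0 and prods <= available and not subs <= available:
                available |= subs
                changed = True
    return available
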
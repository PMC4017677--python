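"""In-silico antimetabolite screening over panels of context-specific models.

An antimetabolite is a structural analog of an endogenous metabolite that
inhibits the enzymes consuming that metabolite.  Its action is emulated by
*blocking* the real metabolite: every reaction that consumes any
compartment instance of it is constrained to zero flux in the consuming
direction (reversible reactions keep the direction in which the metabolite
is produced).  Candidate targets are then ranked by two readouts:

* **efficacy** — does blocking make the biomass/growth task infeasible in
  the tumor models?  A candidate is ``effective_all`` when growth is
  disabled in every tumor model of the panel, ``effective_subset`` when only
  in some (patient-specific), else ``ineffective``.
* **toxicity** — which metabolic tasks does the block disable in healthy
  cell-type models?  Failure of any energy-and-redox-category task in any
  healthy model sets the toxicity flag and removes the candidate from the
  proposed list, since such tasks are central to all cells, proliferating
  or not.  Other healthy-task failures are reported but do not auto-exclude.

Metabolites matching configurable *pool* patterns (e.g. fatty-acid
derivatives feeding lumped pool pseudo-metabolites) can be excluded up
front, as blocking a pool member is not a realistic single-enzyme
intervention.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .gem_core import Model, SolverOptions, consuming_reactions
from .tasks import Task, TaskResult, check_task, check_tasks

__all__ = [
    "BlockSpec",
    "ScreenReport",
    "PanelScreen",
    "block_metabolite",
    "task_survival",
    "screen_panel",
]


@dataclass
class BlockSpec:
    """The consuming reaction-directions a metabolite block constrains."""

    metabolite: str                      # compartment-agnostic name
    affected: Dict[str, str]             # reaction id -> forward|reverse|both

    @classmethod
    def for_model(cls, model: Model, metabolite_name: str) -> "BlockSpec":
        return cls(metabolite_name, consuming_reactions(model, metabolite_name))


@dataclass
class ScreenReport:
    """Outcome of blocking one metabolite across the whole panel."""

    metabolite: str
    growth_disabled_in: Set[str] = field(default_factory=set)
    healthy_task_failures: Set[Tuple[str, str]] = field(default_factory=set)
    toxicity_flag: bool = False
    excluded_as_pool: bool = False
    verdict: str = "ineffective"  # effective_all | effective_subset | ineffective

    @property
    def classification(self) -> str:
        """Partition label: pool exclusion takes precedence over verdict."""
        return "excluded_as_pool" if self.excluded_as_pool else self.verdict


def block_metabolite(model: Model, metabolite_name: str) -> Model:
    """Copy of ``model`` with all consumption of a metabolite forbidden.

    For each consuming reaction-direction: forward consumption clamps the
    upper bound to 0 (and the lower bound too when the reaction is
    irreversible); reverse consumption clamps the lower bound to 0.
    Stoichiometry is untouched and the input model is never modified.  A
    name matching nothing returns an unchanged copy.
    """
    blocked = model.copy()
    for rid, direction in consuming_reactions(model, metabolite_name).items():
        rxn = blocked.reaction(rid)
        if direction in ("forward", "both"):
            rxn.upper_bound = 0.0
            if rxn.lower_bound > 0.0:
                rxn.lower_bound = 0.0
        if direction in ("reverse", "both"):
            if rxn.lower_bound < 0.0:
                rxn.lower_bound = 0.0
    return blocked


def task_survival(
    model: Model,
    metabolite_name: str,
    tasks: Sequence[Task],
    options: Optional[SolverOptions] = None,
) -> List[TaskResult]:
    """Task results of the model with the metabolite blocked."""
    return check_tasks(block_metabolite(model, metabolite_name), tasks, options)


def _verdict(disabled: Set[str], tumor_ids: Sequence[str]) -> str:
    if not disabled:
        return "ineffective"
    return "effective_all" if set(tumor_ids) <= disabled else "effective_subset"


@dataclass
class PanelScreen:
    """Collection of per-metabolite screen reports plus panel bookkeeping."""

    reports: Dict[str, ScreenReport]
    tumor_ids: List[str]
    healthy_ids: List[str]
    growth_task_id: str

    def effective_all(self) -> List[str]:
        return sorted(
            m for m, r in self.reports.items()
            if r.classification == "effective_all"
        )

    def effective_subset(self) -> List[str]:
        return sorted(
            m for m, r in self.reports.items()
            if r.classification == "effective_subset"
        )

    def proposed_antimetabolites(self) -> List[str]:
        """Effective in every tumor model, non-toxic, not pool-excluded."""
        return sorted(
            m for m, r in self.reports.items()
            if r.classification == "effective_all" and not r.toxicity_flag
        )

    def summary_counts(self) -> Dict[str, int]:
        counts = {
            "effective_all": 0,
            "effective_subset": 0,
            "ineffective": 0,
            "excluded_as_pool": 0,
        }
        for r in self.reports.values():
            counts[r.classification] += 1
        counts["screened"] = len(self.reports)
        counts["toxic"] = sum(r.toxicity_flag for r in self.reports.values())
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.reports):
            r = self.reports[name]
            row = {
                "metabolite": name,
                "n_tumor_disabled": len(r.growth_disabled_in),
                "verdict": r.verdict,
                "toxicity_flag": r.toxicity_flag,
                "excluded_as_pool": r.excluded_as_pool,
                "n_healthy_task_failures": len(r.healthy_task_failures),
            }
            for tid in self.tumor_ids:
                row[f"disabled:{tid}"] = tid in r.growth_disabled_in
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def screen_panel(
    tumor_models: Sequence[Model],
    healthy_models: Sequence[Model],
    tasks: Sequence[Task],
    growth_task_id: str,
    pool_exclusion: Sequence[str] = (),
    options: Optional[SolverOptions] = None,
) -> PanelScreen:
    """Screen every metabolite of the tumor panel as an antimetabolite target.

    Iterates over the union of compartment-agnostic metabolite names across
    the tumor models.  Per metabolite: tumor efficacy is judged on the
    growth task alone; healthy toxicity on all tasks, recording each task
    that passed in the unblocked healthy model but fails under blocking.
    Tumor models that cannot perform the growth task unblocked are reported
    degenerate (warning) and skipped.
    """
    options = options or SolverOptions()
    if not tumor_models:
        raise ValueError("empty tumor panel")
    task_by_id = {t.id: t for t in tasks}
    if growth_task_id not in task_by_id:
        raise KeyError(f"growth task {growth_task_id!r} not in task list")
    growth = task_by_id[growth_task_id]

    usable_tumor: List[Model] = []
    for m in tumor_models:
        if check_task(m, growth, options).passed:
            usable_tumor.append(m)
        else:
            warnings.warn(
                f"tumor model {m.id!r} cannot perform the growth task unblocked; "
                "skipping it in the screen"
            )
    if not usable_tumor:
        raise ValueError("no tumor model passes the growth task unblocked")
    tumor_ids = [m.id for m in usable_tumor]
    healthy_ids = [m.id for m in healthy_models]

    # baseline healthy task outcomes (unblocked)
    healthy_baseline: Dict[str, Dict[str, bool]] = {}
    for m in healthy_models:
        healthy_baseline[m.id] = {
            t.id: check_task(m, t, options).passed for t in tasks
        }

    names: Dict[str, None] = {}
    for m in usable_tumor:
        for name in m.metabolite_names():
            names.setdefault(name, None)

    reports: Dict[str, ScreenReport] = {}
    for name in names:
        report = ScreenReport(metabolite=name)
        report.excluded_as_pool = any(
            fnmatch.fnmatch(name, pat) for pat in pool_exclusion
        )
        for m in usable_tumor:
            if not consuming_reactions(m, name):
                continue  # block is a no-op in this model
            res = check_task(block_metabolite(m, name), growth, options)
            if not res.passed:
                report.growth_disabled_in.add(m.id)
        for m in healthy_models:
            if not consuming_reactions(m, name):
                continue
            blocked = block_metabolite(m, name)
            for t in tasks:
                if not healthy_baseline[m.id][t.id]:
                    continue  # task already failing unblocked: not attributable
                if not check_task(blocked, t, options).passed:
                    report.healthy_task_failures.add((m.id, t.id))
                    if t.category == "energy_and_redox":
                        report.toxicity_flag = True
        report.verdict = _verdict(report.growth_disabled_in, tumor_ids)
        reports[name] = report

    return PanelScreen(
        reports=reports,
        tumor_ids=tumor_ids,
        healthy_ids=healthy_ids,
        growth_task_id=growth_task_id,
    )
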
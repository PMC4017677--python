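"""Synthetic networks, tasks and cohort evidence for testing and demos.

Real reconstructions need a curated reference network (thousands of
reactions) and cohort proteomics — neither of which is bundled here.  This
module generates structurally analogous miniatures in which the ground
truth is known by construction:

* :func:`figure1b_network` — a hand-coded toy network whose reconstruction
  outcome (essential "blue" reactions, MILP-excluded "dotted" reactions, a
  single red reaction restored by gap-filling) can be derived by hand.
* :func:`generate_reference` — seeded random reference networks containing
  a *planted* context model: task-serving pathway chains (positive
  evidence) buried among distractor reactions (dead ends, redundant routes,
  shortcuts, all with negative evidence).  The planted sub-network is
  guaranteed to satisfy every generated task, so exact recovery is a
  well-defined success criterion.
* :func:`generate_cohort_evidence` — ordinal evidence matrices over the
  generated genes: detected levels on planted genes, negative elsewhere,
  with seeded per-cell missingness emulating incompletely measured samples.
* :func:`screen_panel_fixture` — a hand-built tumor/healthy panel with
  planted choke-point metabolites, an energy-coupled toxic metabolite, a
  pool metabolite and a generic-vs-individual disagreement, for exercising
  the antimetabolite screen end to end.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .evidence import EvidenceMatrix, ScoreVector
from .gem_core import GeneRule, Metabolite, Model, Reaction
from .tasks import Task, TaskIO

__all__ = [
    "GenerationError",
    "FixtureSpec",
    "figure1b_network",
    "generate_reference",
    "generate_cohort_evidence",
    "screen_panel_fixture",
    "example_task_library",
]


class GenerationError(ValueError):
    """Unsatisfiable fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one generated reference network + cohort.

    Defaults give a 12-reaction reference with two tasks and a 6-sample
    cohort — the scale at which brute-force oracles stay tractable while
    every algorithm step (essentiality, selection, gap-filling, imputation)
    is still exercised.
    """

    seed: int = 0
    n_metabolites: int = 14
    n_reactions: int = 12
    reversible_fraction: float = 0.2
    n_tasks: int = 2
    planted_fraction: float = 0.6
    evidence_missing_rate: float = 0.1
    n_samples: int = 6
    include_negative_control: bool = True

    def __post_init__(self) -> None:
        if min(self.n_metabolites, self.n_reactions, self.n_tasks,
               self.n_samples) <= 0:
            raise GenerationError("sizes must be positive")
        for rate in (self.reversible_fraction, self.planted_fraction,
                     self.evidence_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise GenerationError("fractions must lie in [0, 1]")


# --------------------------------------------------------------------------
# Hand-coded worked example
# --------------------------------------------------------------------------

def figure1b_network() -> Tuple[Model, List[Task], ScoreVector, Dict[str, Set[str]]]:
    """The worked-example toy network with a fully hand-derived outcome.

    Two tasks: produce D from A, produce E from B.  Reactions carry
    positive ("green") or negative ("red") evidence scores; exchanges are
    mildly positive.  The topology is arranged so that:

    * the only route A -> M -> D and the shared step C -> E are essential
      for the tasks (the "blue" set),
    * E can be made from C uptake without any red reaction, so after the
      selection step the first task works but "E from B" does not,
    * two all-red routes lead from B to C (a one-reaction lower route and a
      two-reaction upper route), so neither is individually essential and
      gap-filling must restore exactly the one-reaction route,
    * a red detour M -> F -> E is usable but never worth selecting
      (the "dotted" reactions).

    Returns ``(model, tasks, scores, expected)`` where ``expected`` maps
    ``required`` / ``milp_selected`` / ``gapfill_added`` / ``final`` /
    ``never_selected`` to hand-derived reaction-id sets.
    """
    mets = [Metabolite(m, m, "c") for m in "ABCDEMXF"]
    U = 1000.0

    def rxn(rid, stoich, score):
        return Reaction(rid, stoich, 0.0, U), score

    defs = [
        rxn("EX_A", {"A": +1}, +1.0),
        rxn("EX_B", {"B": +1}, +1.0),
        rxn("EX_C", {"C": +1}, +1.0),
        rxn("EX_D", {"D": -1}, +1.0),
        rxn("EX_E", {"E": -1}, +1.0),
        rxn("R_AM", {"A": -1, "M": +1}, +5.0),   # green, essential for task 1
        rxn("R_MD", {"M": -1, "D": +1}, +5.0),   # green, essential for task 1
        rxn("R_BD", {"B": -1, "D": +1}, +5.0),   # green
        rxn("R_CE", {"C": -1, "E": +1}, +5.0),   # green, essential for task 2
        rxn("R_BX", {"B": -1, "X": +1}, -5.0),   # red, upper B->C route
        rxn("R_XC", {"X": -1, "C": +1}, -5.0),   # red, upper B->C route
        rxn("R_BC", {"B": -1, "C": +1}, -5.0),   # red, lower B->C route
        rxn("R_MF", {"M": -1, "F": +1}, -5.0),   # red, dotted detour
        rxn("R_FE", {"F": -1, "E": +1}, -5.0),   # red, dotted detour
    ]
    model = Model("figure1b", mets, [r for r, _ in defs])
    model.validate()
    scores: ScoreVector = {r.id: s for r, s in defs}

    tasks = [
        Task(
            id="D_from_A",
            description="produce D from A",
            category="biosynthesis_of_products",
            inputs=[TaskIO("A", 0.0, U)],
            outputs=[TaskIO("D", None, U)],
        ),
        Task(
            id="E_from_B",
            description="produce E from B",
            category="biosynthesis_of_products",
            inputs=[TaskIO("B", 0.0, U)],
            outputs=[TaskIO("E", None, U)],
        ),
    ]

    greens = {"EX_A", "EX_B", "EX_C", "EX_D", "EX_E",
              "R_AM", "R_MD", "R_BD", "R_CE"}
    expected = {
        "required": {"R_AM", "R_MD", "R_CE"},
        "milp_selected": set(greens),
        "gapfill_added": {"R_BC"},
        "final": greens | {"R_BC"},
        "never_selected": {"R_BX", "R_XC", "R_MF", "R_FE"},
    }
    return model, tasks, scores, expected


# --------------------------------------------------------------------------
# Random reference networks with planted context models
# --------------------------------------------------------------------------

_TASK_CATEGORIES = (
    "substrate_utilization",
    "biosynthesis_of_products",
    "internal_conversions",
    "energy_and_redox",
)


def generate_reference(
    spec: FixtureSpec,
) -> Tuple[Model, Set[str], List[Task]]:
    """Seeded random reference with a planted, task-sufficient context model.

    The planted context is a union of linear pathway chains, one per task,
    each running from a fresh input metabolite through intermediates to a
    fresh output metabolite, plus the uptake/secretion exchanges for those
    terminals.  Distractor reactions are then added: dead ends (can never
    carry steady-state flux), duplicates of planted steps and input->output
    shortcuts (redundant routes).  Every internal reaction carries a
    single-gene rule ``g_<reaction id>`` so evidence maps invertibly onto
    reactions; exchanges carry no gene rule.

    Returns ``(model, planted_reaction_ids, tasks)``.  Deterministic in
    ``spec`` (bit-identical regeneration for equal seeds).
    """
    rng = np.random.default_rng(spec.seed)
    n_exchanges = 2 * spec.n_tasks
    n_planted_internal = round(spec.planted_fraction * spec.n_reactions) - n_exchanges
    if n_planted_internal < spec.n_tasks:
        raise GenerationError(
            f"planted_fraction {spec.planted_fraction} too small for "
            f"{spec.n_tasks} tasks at {spec.n_reactions} reactions"
        )
    n_distractors = spec.n_reactions - n_planted_internal - n_exchanges
    if n_distractors < 0:
        raise GenerationError("planted_fraction > 1 after adding exchanges")

    # chain lengths: one reaction minimum per task, extras spread randomly
    lengths = [1] * spec.n_tasks
    for _ in range(n_planted_internal - spec.n_tasks):
        lengths[int(rng.integers(spec.n_tasks))] += 1

    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    genes: List[str] = []
    planted: Set[str] = set()
    tasks: List[Task] = []

    def add_met(name: str) -> str:
        mets.append(Metabolite(name, name, "c"))
        return name

    def add_rxn(rid: str, stoich: Dict[str, float], reversible: bool,
                gene: Optional[str]) -> None:
        lb = -1000.0 if reversible else 0.0
        rule = None
        if gene is not None:
            genes.append(gene)
            rule = GeneRule.leaf(gene)
        rxns.append(Reaction(rid, stoich, lb, 1000.0, gene_rule=rule))

    chain_nodes: List[List[str]] = []
    for t in range(spec.n_tasks):
        inp = add_met(f"I{t}")
        nodes = [inp]
        for j in range(lengths[t] - 1):
            nodes.append(add_met(f"m{t}_{j}"))
        out = add_met(f"O{t}")
        nodes.append(out)
        chain_nodes.append(nodes)
        for j in range(len(nodes) - 1):
            rid = f"P{t}_{j}"
            reversible = bool(rng.random() < spec.reversible_fraction)
            add_rxn(rid, {nodes[j]: -1.0, nodes[j + 1]: +1.0},
                    reversible, gene=f"g_{rid}")
            planted.add(rid)
        for rid, stoich in ((f"EX_I{t}", {inp: +1.0}),
                            (f"EX_O{t}", {out: -1.0})):
            add_rxn(rid, stoich, False, gene=None)
            planted.add(rid)
        tasks.append(
            Task(
                id=f"T{t}",
                description=f"produce O{t} from I{t}",
                category=_TASK_CATEGORIES[t % len(_TASK_CATEGORIES)],
                inputs=[TaskIO(inp, 0.0, 1000.0)],
                outputs=[TaskIO(out, None, 1000.0)],
            )
        )

    for d in range(n_distractors):
        kind = rng.choice(["dead_end", "duplicate", "shortcut"])
        rid = f"D{d}"
        if kind == "dead_end":
            src = str(rng.choice([m.id for m in mets]))
            sink = add_met(f"dead{d}")
            stoich = {src: -1.0, sink: +1.0}
        elif kind == "duplicate":
            t = int(rng.integers(spec.n_tasks))
            nodes = chain_nodes[t]
            j = int(rng.integers(len(nodes) - 1))
            stoich = {nodes[j]: -1.0, nodes[j + 1]: +1.0}
        else:  # shortcut input -> output of one task
            t = int(rng.integers(spec.n_tasks))
            nodes = chain_nodes[t]
            stoich = {nodes[0]: -1.0, nodes[-1]: +1.0}
        add_rxn(rid, stoich, False, gene=f"g_{rid}")

    if len(mets) > spec.n_metabolites:
        raise GenerationError(
            f"construction needs {len(mets)} metabolites but the spec allows "
            f"only {spec.n_metabolites}"
        )

    if spec.include_negative_control:
        # conservation control: no output can appear from nothing
        tasks.append(
            Task(
                id="no_free_lunch",
                description="O0 must not be producible without any input",
                category="other",
                should_fail=True,
                outputs=[TaskIO("O0", None, 1000.0)],
            )
        )

    model = Model(f"ref_seed{spec.seed}", mets, rxns, genes)
    model.validate()
    return model, planted, tasks


def generate_cohort_evidence(
    model: Model,
    planted_context: Set[str],
    spec: FixtureSpec,
) -> EvidenceMatrix:
    """Ordinal cohort evidence consistent with the planted context.

    Genes supporting planted reactions draw a detected level (strong,
    moderate or weak) per sample; all other genes are negative.  Missing
    cells are then injected independently per cell at
    ``evidence_missing_rate``, using a seed derived from the spec so the
    matrix is reproducible yet not correlated with the topology draws.
    """
    if not model.genes:
        raise GenerationError("model has no gene rules; nothing to annotate")
    rng = np.random.default_rng(spec.seed + 10_007)
    planted_genes = {
        g
        for rid in planted_context
        if (rule := model.reaction(rid).gene_rule) is not None
        for g in rule.genes()
    }
    samples = [f"S{i}" for i in range(spec.n_samples)]
    detected_codes = np.array([3, 2, 1], dtype=float)  # strong/moderate/weak
    weights = np.array([0.5, 0.3, 0.2])
    data: Dict[str, Dict[str, float]] = {}
    for gene in model.genes:
        row: Dict[str, float] = {}
        for s in samples:
            if gene in planted_genes:
                row[s] = float(rng.choice(detected_codes, p=weights))
            else:
                row[s] = 0.0
            if rng.random() < spec.evidence_missing_rate:
                row[s] = np.nan
        data[gene] = row
    return EvidenceMatrix(pd.DataFrame(data).T[samples])


# --------------------------------------------------------------------------
# Antimetabolite screen panel with planted outcomes
# --------------------------------------------------------------------------

def screen_panel_fixture() -> Dict[str, object]:
    """Hand-built tumor/healthy panel with known screen classifications.

    Three tumor models share a growth pathway S -> ... -> BIO requiring the
    choke-point metabolite P and the pool metabolite fa_pool; tumor 1 routes
    through W, tumors 2 and 3 have a direct bypass, making W a
    patient-subset target.  All models carry an energy pathway; blocking its
    intermediate Q (or its substrate F) disables the energy-and-redox task
    in a healthy model, planting a toxicity exclusion.  A "generic" model
    with tumor 1's topology demonstrates how a screen on one averaged model
    can call W effective even though individual models escape via the
    bypass.

    Returns a dict with keys ``tumor_models``, ``healthy_models``,
    ``generic_model``, ``tasks``, ``growth_task_id``, ``pool_patterns`` and
    ``expected`` (metabolite name -> expected classification, plus the
    expected toxic and proposed sets).
    """
    U = 1000.0

    def build(model_id: str, reactions: Dict[str, Dict[str, float]]) -> Model:
        met_names = sorted({m for st in reactions.values() for m in st})
        mets = [Metabolite(m, m, "c") for m in met_names]
        rxns = [Reaction(rid, dict(st), 0.0, U) for rid, st in reactions.items()]
        model = Model(model_id, mets, rxns)
        model.validate()
        return model

    energy_via_Q = {
        "EX_F": {"F": +1.0},
        "R_FQ": {"F": -1.0, "Q": +1.0},
        "R_QA": {"Q": -1.0, "ATPeq": +1.0},
        "EX_ATP": {"ATPeq": -1.0},
    }
    growth_core = {
        "EX_S": {"S": +1.0},
        "R_SFA": {"S": -1.0, "fa_pool": +1.0},
        "R_PB": {"P": -1.0, "fa_pool": -1.0, "BIO": +1.0},
        "EX_BIO": {"BIO": -1.0},
    }
    via_W = {"R_SW": {"S": -1.0, "W": +1.0}, "R_WP": {"W": -1.0, "P": +1.0}}
    direct = {"R_SP": {"S": -1.0, "P": +1.0}}

    tumor1 = build("tumor1", {**growth_core, **via_W, **energy_via_Q})
    tumor2 = build("tumor2", {**growth_core, **via_W, **direct, **energy_via_Q})
    tumor3 = build("tumor3", {**growth_core, **direct, **energy_via_Q})
    generic = build("generic", {**growth_core, **via_W, **energy_via_Q})

    healthy1 = build("healthy1", energy_via_Q)
    healthy2 = build(
        "healthy2",
        {
            "EX_F": {"F": +1.0},
            "R_FA": {"F": -1.0, "ATPeq": +1.0},
            "EX_ATP": {"ATPeq": -1.0},
        },
    )

    tasks = [
        Task(
            id="growth",
            description="biomass growth from the carbon source",
            category="growth",
            inputs=[TaskIO("S", 0.0, U)],
            outputs=[TaskIO("BIO", None, U)],
        ),
        Task(
            id="energy",
            description="ATP-equivalent regeneration from fuel",
            category="energy_and_redox",
            inputs=[TaskIO("F", 0.0, U)],
            outputs=[TaskIO("ATPeq", None, U)],
        ),
    ]

    expected_class = {
        "S": "effective_all",
        "P": "effective_all",
        "W": "effective_subset",
        "fa_pool": "excluded_as_pool",
        "BIO": "ineffective",
        "F": "ineffective",
        "Q": "ineffective",
        "ATPeq": "ineffective",
    }
    return {
        "tumor_models": [tumor1, tumor2, tumor3],
        "healthy_models": [healthy1, healthy2],
        "generic_model": generic,
        "tasks": tasks,
        "growth_task_id": "growth",
        "pool_patterns": ["*pool*"],
        "expected": {
            "classification": expected_class,
            "toxic": {"F", "Q"},
            "proposed": {"P", "S"},
            "generic_effective_but_not_in_all_patients": {"W"},
        },
    }


# --------------------------------------------------------------------------
# Example task library (56 tasks, four categories + growth)
# --------------------------------------------------------------------------

def example_task_library() -> Tuple[Model, List[Task]]:
    """A 56-task library with a companion core-metabolism toy network.

    Mirrors the structure of a curated whole-cell task list — 56 tasks
    spanning energy-and-redox, internal conversions, substrate utilization
    and biosynthesis of products, with biomass growth as an extra task and a
    free-energy negative control — but over a synthetic hub network, since
    the curated definitions belong to the original supplementary material
    and are not reproduced here.  Every non-control task is feasible on the
    companion model and the control is infeasible, so the pair exercises
    parsing, checking and reconstruction end to end.

    Topology: 16 substrates feed a hub metabolite; the hub feeds 16
    products, an ATP-equivalent, a waste sink and a biomass precursor;
    every terminal has an exchange reaction.
    """
    U = 1000.0
    n_sub, n_prod = 16, 16
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    genes: List[str] = []

    def met(name: str) -> str:
        mets.append(Metabolite(name, name, "c"))
        return name

    def rxn(rid: str, stoich: Dict[str, float], gene: Optional[str] = None) -> None:
        rule = None
        if gene:
            genes.append(gene)
            rule = GeneRule.leaf(gene)
        rxns.append(Reaction(rid, stoich, 0.0, U, gene_rule=rule))

    hub = met("hub")
    for name in ("ATPeq", "waste", "BIO"):
        met(name)
    for k in range(1, n_sub + 1):
        s = met(f"S{k}")
        rxn(f"U{k}", {s: -1.0, hub: +1.0}, gene=f"g_U{k}")
        rxn(f"EX_S{k}", {s: +1.0})
    for k in range(1, n_prod + 1):
        p = met(f"P{k}")
        rxn(f"B{k}", {hub: -1.0, p: +1.0}, gene=f"g_B{k}")
        rxn(f"EX_P{k}", {p: -1.0})
    rxn("R_atp", {hub: -1.0, "ATPeq": +1.0}, gene="g_atp")
    rxn("R_waste", {hub: -1.0, "waste": +1.0}, gene="g_waste")
    rxn("R_bio", {hub: -1.0, "BIO": +1.0}, gene="g_bio")
    for rid, st in (("EX_atp", {"ATPeq": -1.0}), ("EX_waste", {"waste": -1.0}),
                    ("EX_bio", {"BIO": -1.0})):
        rxn(rid, st)
    model = Model("task_library_ref", mets, rxns, genes)
    model.validate()

    tasks: List[Task] = []

    def task(tid, category, inputs, outputs, should_fail=False, desc=""):
        tasks.append(
            Task(
                id=tid,
                description=desc,
                category=category,
                should_fail=should_fail,
                inputs=[TaskIO(m, 0.0, U) for m in inputs],
                outputs=[TaskIO(m, None, U) for m in outputs],
            )
        )

    # energy and redox: ATP-equivalent regeneration from 7 fuels + control
    for k in range(1, 8):
        task(f"atp_from_S{k}", "energy_and_redox", [f"S{k}"], ["ATPeq"],
             desc=f"regenerate ATP equivalent from S{k}")
    task("no_free_atp", "energy_and_redox", [], ["ATPeq"], should_fail=True,
         desc="ATP equivalent must not appear from nothing")
    # substrate utilization: catabolise each substrate to waste
    for k in range(1, n_sub + 1):
        task(f"utilize_S{k}", "substrate_utilization", [f"S{k}"], ["waste"],
             desc=f"catabolise S{k}")
    # internal conversions: substrate k -> product k through the hub
    for k in range(1, 16):
        task(f"convert_S{k}_P{k}", "internal_conversions", [f"S{k}"], [f"P{k}"],
             desc=f"convert S{k} into P{k}")
    # biosynthesis of products from the first substrate
    for k in range(1, n_prod + 1):
        task(f"make_P{k}", "biosynthesis_of_products", ["S1"], [f"P{k}"],
             desc=f"synthesise P{k}")
    # biomass growth as the extra task
    task("growth", "growth", ["S1"], ["BIO"], desc="biomass growth")

    assert len(tasks) == 56
    return model, tasks
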
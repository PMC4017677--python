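# Methods

This note documents the models and procedures implemented in `tinit`, the
numerical choices behind them, what the synthetic fixtures do and do not
emulate, and the design decisions taken where the method description leaves
room.

## Network model and task semantics

A model is a stoichiometric network at steady state: fluxes `v` with
`S·v = 0` on internal metabolites and per-reaction bounds
`lb_i ≤ v_i ≤ ub_i`.  Boundary species are stripped from stoichiometry when
reading SBML, so reactions that crossed the boundary become one-sided
*exchange* reactions; an exchange is recognised purely structurally (all
coefficients of one sign).  When SBML omits bounds, reversible reactions
default to [−1000, 1000] and irreversible ones to [0, 1000] (the common
constraint-based convention; flux units are arbitrary but model-wide
consistent).

A **metabolic task** is checked in a *closed* system: every exchange
reaction is clamped to zero and replaced by temporary, task-specific
machinery — uptake variables for the declared inputs (bounds as stated,
default [0, 1000]), sink variables for the declared outputs (default lower
bound = the activation epsilon, see below), and one lumped reaction per
equation row forced to carry at least epsilon flux.  Feasibility of the
resulting LP is the task verdict.  Closing exchanges matters: with open
exchanges most utilization/biosynthesis tasks would be trivially satisfiable
from the environment.  Negative-control tasks (`should_fail`) pass only
when infeasible; they guard against erroneous free-energy cycles.

Task metabolites may be compartment-qualified (`atp[m]`) or bare names.  A
bare name that matches several compartment instances is *pooled*: a
temporary pool pseudo-metabolite lets any instance supply or absorb the
required flux.  Equation rows require an unambiguous (single-instance)
match; an ambiguous or unmatched name makes the task infeasible with an
explanatory reason rather than raising, so draft models that lack a
metabolite are handled uniformly during reconstruction.

## The reconstruction algorithm

**Step 1 — task-essential reactions.**  A reaction is essential when its
single removal makes some task infeasible.  The sweep is accelerated by a
witness pre-filter: a feasible witness flux with `v_r = 0` proves `r`
non-essential for that task (the witness remains valid after removal), so
only reactions carrying flux in the witness are re-tested.  The filter is
exact, and the test suite asserts its equivalence with the naive sweep.
Negative-control tasks are ignored here (removal cannot make an infeasible
task feasible).  Growth-category tasks participate by default; a flag
(`TinitOptions.include_growth_in_essentiality`) excludes them from this
step only, since one may prefer not to hard-wire proliferation machinery
into the required set.

**Step 2 — selection MILP.**  Per reaction, split non-negative fluxes
`v_f, v_b` and one inclusion binary `y`; per internal metabolite the steady
state row `Σ s_i (v_f,i − v_b,i) = b_m`.  Constraints:

* `v_f + v_b ≤ M·y` — only selected reactions carry flux;
* `v_f + v_b ≥ ε·y` for positively scored reactions — a selected,
  evidence-supported reaction must be *usable* (this is what makes the
  output flux-consistent);
* `y = 1` on the step-1 essential set;
* for reversible reactions, direction binaries `d_f, d_b` with
  `v_f ≤ M·d_f`, `v_b ≤ M·d_b`, `d_f + d_b ≤ 1` — no simultaneous
  bidirectional flux.  Without this, an isolated reversible conversion can
  run both directions at once and satisfy the use-coupling while
  disconnected from everything (the loop artifact of the original
  formulation; a unit test reproduces it by switching the flag off);
* `b_m = 0` by default; with `allow_net_production`, `b_m ≥ 0` with an
  objective penalty per unit (default penalty 1, a documented choice — no
  value is published for the original implementation).

Objective: maximise `Σ w_i y_i − penalty·Σ b_m`.  Exchange reactions carry
no genes and default to score 0; they enter the solution exactly when they
are needed to let scored reactions carry flux.

Ties between equally optimal selections are resolved by a second stage
that fixes the objective (within 1e-7 absolute or 1e-9 relative) and
minimises `Σ (i+1)·y_i` over the reaction index `i` — a deterministic
secondary objective that prefers dropping later-indexed reactions, chosen
because the solver has no native lexicographic mode.  It can be disabled
(`deterministic_tiebreak=False`).

**Step 3 — sequential gap-filling.**  Tasks are re-tested on the selected
network in task-table order.  For a failing task, a MILP over the full
reference minimises the number of non-selected reactions allowed to carry
flux (`|v_j| ≤ M·y_j`, minimise `Σ y_j`) subject to the task LP; the
enabled set is added.  Cardinality is unweighted by default; a weight map
is accepted for score-aware filling.  Task order can in principle affect
the additions, so the result records per-task additions for audit; with
the essential set already forced in, the selection is near-functional and
fills are small.  The final model is re-checked against *all* tasks and the
run fails loudly if anything is violated — negative controls stay
infeasible automatically, because feasibility is monotone in the reaction
set and they are verified infeasible in the reference up front.

## Evidence processing

Ordinal levels are encoded 0–3 (negative…strong).  A sample's missing genes
are imputed with the cohort median of the other samples; genes missing in
the whole cohort stay missing.  The ordinal median needs a tie rule for
even cohorts: the midpoint when integral, otherwise rounded *down*
(median{strong, weak} = moderate; median{strong, moderate} = moderate).
Any fixed rule would do; this one is implemented, documented, and verified
exhaustively against a direct-sort oracle for all cohorts of size ≤ 4.
Imputation happens on levels, before scoring, and only ever writes cells
that were missing (re-running it is a no-op).

The default level→score map (+20 / +15 / +10 / −8 / −2 for
strong / moderate / weak / negative / missing) keeps detected proteins
strongly positive and undetected ones mildly negative, in the spirit of
published evidence weightings for this family of methods; the true weights
behind any particular study are not published, so the map is fully
configurable (`gene_scores(mapping=...)`, or a `level=score` file on the
CLI).  GPR aggregation is the community convention — OR (isozymes) by
maximum, AND (complex subunits) by minimum — and reactions without a gene
rule get a configurable spontaneous score (default 0).

## Antimetabolite screening

Blocking a metabolite clamps, in every reaction consuming any compartment
instance of its name, the consuming direction to zero: forward consumers
lose their upper bound, reverse (reversible) consumers their negative lower
bound, both-side consumers both.  This equals physically deleting the
consuming directions — an equivalence the tests check model-by-model — and
blocking is anti-monotone: additional blocks never revive a lost task.

The panel screen iterates the union of compartment-agnostic metabolite
names over the tumor models.  Efficacy is binary and judged on the growth
task only (`effective_all` / `effective_subset` / `ineffective` by which
tumor models lose growth).  Toxicity is judged on healthy models across all
tasks, attributing only failures of tasks that passed unblocked; any
energy-and-redox failure in any healthy model sets the toxicity flag and
removes the candidate from the proposed list, while other failures are
reported without auto-exclusion (no failure-count threshold is applied; raw
counts are exposed for the user to threshold).  Metabolites matching
configurable glob patterns (e.g. `*pool*`) are excluded as pool members —
lumped pseudo-metabolite feeders whose "blocking" would not correspond to a
realistic single-analog intervention — and counted separately so the four
classes partition the screened set.  Tumor models that cannot grow
unblocked are reported degenerate and skipped with a warning.

## Synthetic fixtures: what they do and do not show

The generators produce miniatures with known ground truth: linear
task-serving chains (the planted context, one fresh input/output pair per
task, single-gene rules so evidence maps invertibly onto reactions) buried
among distractors — dead ends that can never carry steady-state flux,
duplicated chain steps, and input→output shortcuts, all with negative
evidence.  Defaults: 12 reactions, 2 tasks, 20 % reversible, 60 % planted,
6-sample cohorts with 10 % missing cells, plus a free-production negative
control.  At this scale brute-force oracles (exhaustive subset enumeration
with per-subset LPs; addition subsets by increasing cardinality) are exact
and fast, so MILP optimality and gap-fill minimality are verified by
enumeration on ~100 seeds, and planted recovery / the functionality
contract on dozens more.  A hand-built screening panel plants every
classification outcome, including a "generic" averaged model that lacks a
bypass an individual model has — demonstrating how a generic-model screen
can overcall targets relative to a per-patient panel.

Passing these tests shows the optimisation and bookkeeping are correct at
enumerable scale and that the pipeline's guarantees (functionality,
required-inclusion, determinism) hold.  It does *not* show that real
reconstructions are biologically right: the fixtures have none of the
compartmental structure, cofactor coupling, promiscuous enzymes,
many-to-many GPRs or curated task redundancy of a real reference network,
and evidence noise is idealised (distractor genes are cleanly negative).
The shipped 56-task example library mirrors the *shape* of a curated
whole-cell task list (the four categories plus growth, one negative
control) over a synthetic hub network; the curated definitions themselves
live in the original supplementary material and are not reproduced.

## Numerical choices

* `activation_epsilon = 1e-4` — minimum flux for "used" and the default
  task-output lower bound.  Small enough not to distort solutions with
  bounds of order 1000, large enough to sit far above solver tolerance.
* `big_M = 1000` — matches the default bound magnitude; any flux feasible
  under the bounds satisfies the coupling.  Raise it if a model uses wider
  bounds.
* MILP relative gap `1e-6`; solved with HiGHS through scipy.  HiGHS is
  deterministic for a fixed instance, so fixed seeds give bit-identical
  runs; the optional solver seed field is accepted but HiGHS needs none.
* Witness fluxes below 1e-9 are treated as zero in the essentiality
  pre-filter; output sinks force essential fluxes to at least the order of
  epsilon, so the two scales are well separated.
* Problem sizes in the test-suite and acceptance runs (12-reaction
  fixtures, 40–100 seeds per property) were chosen so the enumeration
  oracles stay exact while the whole suite runs in well under a minute;
  larger networks change nothing structurally, only solve time.

## Known limitations

* Efficacy is binary task feasibility; no fractional growth-rate reduction,
  dose response or pharmacokinetics.
* No thermodynamic or mass/charge-balance constraints; imbalances are the
  modeller's responsibility.
* Gap-filling minimises cardinality, not biological plausibility; the
  score-weighted option is a blunt instrument.
* The compartment-tag stripping on SBML species ids is heuristic
  (configurable patterns for `_c` and `[c]` dialects); models encoding
  compartments some other way should supply species `name` attributes.
* Tasks are independent feasibility checks; no Boolean combinations of
  tasks and no quantitative task scores.
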
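# tinit

Task-driven reconstruction of context-specific genome-scale metabolic
models (GEMs), and in-silico antimetabolite screening on panels of such
models.

## The problem

A reference GEM describes *everything* an organism's metabolism could do;
a given cell type or patient tumor expresses only part of it.  Given

* a reference network (stoichiometric matrix `S`, flux bounds,
  gene–protein–reaction rules),
* ordinal protein evidence per gene and sample
  (strong / moderate / weak / negative / missing, as produced by
  immunohistochemistry annotation), and
* a list of **metabolic tasks** — functions every model must be able to
  perform, stated as bounded conversions (permitted inputs → required
  outputs) in an otherwise closed system —

the tINIT algorithm extracts the sub-network that best agrees with the
evidence while remaining able to perform every task.  The reconstructed
models are simulation-ready: they support flux balance analysis, and in
particular per-patient *antimetabolite* screens, where consumption of a
metabolite is blocked (emulating a structural-analog drug inhibiting the
consuming enzymes) and the models are re-tested for task feasibility.
A candidate is effective when it disables the biomass/growth task in the
tumor models, and flagged toxic when it disables an energy-and-redox task
in any healthy cell-type model.

## The algorithm

Reconstruction runs in three steps:

1. **Task-essential reactions.**  Find every reaction whose single removal
   from the reference makes some task infeasible.  These must be in any
   functional sub-network.
2. **Selection MILP.**  With per-reaction evidence scores `w_i` (positive =
   evidence for inclusion) and inclusion binaries `y_i`, maximise
   `Σ w_i y_i` subject to steady state `S·v = 0`, flux–inclusion coupling
   `|v_i| ≤ M·y_i`, use-coupling `|v_i| ≥ ε·y_i` for positively scored
   reactions, and `y_i = 1` on the essential set.  Two refinements over the
   original INIT formulation: reversible reactions cannot carry flux in
   both directions simultaneously (which would let disconnected loops count
   as "used"), and net accumulation of internal metabolites is disallowed
   by default (optionally permitted with a penalty).
3. **Sequential gap-filling.**  Test each task on the selected network in
   list order; for a failing task, add the minimum-cardinality set of
   reference reactions that makes it feasible (a second MILP).

Scores come from the evidence by median-imputing a sample's missing genes
from the rest of the cohort (on the ordinal 0–3 scale), mapping levels to
numbers (defaults: strong +20, moderate +15, weak +10, negative −8,
missing −2), and aggregating through each reaction's GPR rule
(OR = max, AND = min).

All LPs/MILPs are solved with HiGHS via `scipy.optimize`; SBML I/O
(Level 3 + fbc, legacy Level 2 notes accepted on read) uses libsbml.

## Worked example

The package ships a hand-coded toy network (`figure1b_network`) with two
tasks — produce D from A, produce E from B — where every reaction carries a
positive ("green") or negative ("red") evidence score and the correct
reconstruction is derivable by hand:

```python
from tinit import figure1b_network, run_tinit

model, tasks, scores, expected = figure1b_network()
result = run_tinit(model, scores, tasks)
print("task-essential:", sorted(result.required_reactions))
print("selected by MILP:", sorted(result.milp_selected_reactions))
print("gap-filled:", {t: sorted(a) for t, a in result.gapfilled_reactions if a})
print("tasks passed:", sum(r.passed for r in result.task_report),
      "/", len(result.task_report))
```

prints

```
task-essential: ['R_AM', 'R_CE', 'R_MD']
selected by MILP: ['EX_A', 'EX_B', 'EX_C', 'EX_D', 'EX_E', 'R_AM', 'R_BD', 'R_CE', 'R_MD']
gap-filled: {'E_from_B': ['R_BC']}
tasks passed: 2 / 2
```

Step 1 marks the unavoidable steps A→M→D and C→E essential.  Step 2 keeps
every green reaction and drops all red ones — at that point E can be made
from C uptake, so producing E *from B* still fails.  Step 3 restores the
single cheapest red link B→C, and the final 10-reaction model performs both
tasks.

The same workflow is available from the shell:

```bash
tinit fixtures --seed 4 --out-dir fix/          # synthetic reference + evidence
tinit reconstruct --model fix/reference.xml --tasks fix/tasks.tsv \
      --evidence fix/evidence.tsv --sample S0 --out model.xml --report report.json
tinit screen --tumor t1.xml,t2.xml --healthy h1.xml --tasks tasks.tsv \
      --growth-task growth --out screen.tsv
```

## Layout

| module | contents |
|---|---|
| `tinit.gem_core` | `Model` / `Reaction` / `Metabolite` / `GeneRule` types, SBML I/O, sub-model extraction, consuming-reaction lookup |
| `tinit.tasks` | task table dialect, closed-system feasibility LP |
| `tinit.evidence` | ordinal evidence matrix, cohort median imputation, GPR score aggregation |
| `tinit.tinit_solver` | the three reconstruction steps and `run_tinit` |
| `tinit.antimetabolite` | metabolite blocking, task survival, panel screening |
| `tinit.synthetic_fixtures` | worked-example network, seeded planted-truth generators, 56-task example library |
| `tinit.cli` | `tinit` command group |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
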
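"""Core domain types for genome-scale metabolic models (GEMs) and SBML I/O.

A :class:`Model` is a stoichiometric network: metabolites partitioned into
compartments, reactions with flux bounds, and boolean gene-protein-reaction
(GPR) rules linking reactions to the genes whose products catalyse them.
Everything downstream — task checking, the tINIT selection MILP, the
antimetabolite screen — operates on these types.

Conventions
-----------
* Stoichiometric coefficients are signed: negative = substrate (consumed at
  positive flux), positive = product.
* Boundary species are stripped from reaction stoichiometry at SBML load, so
  reactions that touched them become one-sided *exchange* reactions.  An
  exchange reaction is recognised purely structurally: all of its
  coefficients share one sign.
* The compartment-agnostic identity of a metabolite is its ``name`` field;
  :func:`consuming_reactions` pools all compartment instances of a name, which
  is the identity used by the antimetabolite screen.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "GemError",
    "IntegrityError",
    "SbmlParseError",
    "Metabolite",
    "GeneRule",
    "Reaction",
    "Model",
    "SolverOptions",
    "read_sbml",
    "write_sbml",
    "subset_model",
    "consuming_reactions",
    "strip_compartment_tag",
]

DEFAULT_BOUND = 1000.0


class GemError(Exception):
    """Base class for model-structure errors."""


class IntegrityError(GemError):
    """Referential-integrity violation (dangling metabolite/gene reference)."""


class SbmlParseError(GemError):
    """Malformed SBML input."""


# --------------------------------------------------------------------------
# Metabolites
# --------------------------------------------------------------------------

@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``name`` is the species name without any compartment suffix; it is the
    compartment-agnostic identity used when pooling instances of the same
    chemical across compartments.
    """

    id: str
    name: str
    compartment: str = "c"
    is_boundary: bool = False


_TAG_PATTERNS = (
    # "glc__D_c", "atp_m" style: trailing underscore + compartment id
    r"_(?P<comp>{comps})$",
    # "atp[c]" / "atp[m]" bracket style
    r"\[(?P<comp>{comps})\]$",
)


def strip_compartment_tag(
    species_name: str,
    compartments: Iterable[str],
    patterns: Sequence[str] = _TAG_PATTERNS,
) -> str:
    """Strip a trailing compartment tag from a species identifier.

    Both common dialects are recognised by default: an underscore-joined
    suffix (``atp_c``) and a bracketed suffix (``atp[c]``).  Only tags that
    name one of the model's actual compartments are stripped, so metabolite
    names that merely end in a letter are left alone.
    """
    comps = sorted((c for c in compartments if c), key=len, reverse=True)
    if not comps:
        return species_name
    alternation = "|".join(re.escape(c) for c in comps)
    for pat in patterns:
        m = re.search(pat.format(comps=alternation), species_name)
        if m:
            return species_name[: m.start()]
    return species_name


# --------------------------------------------------------------------------
# Gene rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRule:
    """Boolean expression tree over gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry the gene
    identifier; internal nodes carry two or more children.  Evaluation over
    numeric gene scores uses the community GPR convention: OR (isozymes)
    aggregates by maximum, AND (complex subunits) by minimum.
    """

    op: str
    gene: Optional[str] = None
    children: Tuple["GeneRule", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise GemError("gene leaf requires an identifier")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise GemError(f"'{self.op}' node requires >= 2 children")
        else:
            raise GemError(f"unknown GeneRule op {self.op!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def leaf(cls, gene: str) -> "GeneRule":
        return cls("gene", gene=gene)

    @classmethod
    def all_of(cls, *rules: "GeneRule") -> "GeneRule":
        return rules[0] if len(rules) == 1 else cls("and", children=tuple(rules))

    @classmethod
    def any_of(cls, *rules: "GeneRule") -> "GeneRule":
        return rules[0] if len(rules) == 1 else cls("or", children=tuple(rules))

    @classmethod
    def from_string(cls, text: str) -> Optional["GeneRule"]:
        """Parse a GPR string like ``"(G1 and G2) or G3"``.

        Accepts ``and``/``or`` case-insensitively and ``&&``/``||`` symbols.
        Returns ``None`` for blank input.  ``and`` binds tighter than ``or``.
        """
        tokens = _tokenize_gpr(text)
        if not tokens:
            return None
        rule, pos = _parse_or(tokens, 0)
        if pos != len(tokens):
            raise GemError(f"trailing tokens in gene rule: {tokens[pos:]}")
        return rule

    # -- queries -----------------------------------------------------------

    def genes(self) -> Set[str]:
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: Set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, scores: Mapping[str, float], missing: float = 0.0) -> float:
        """Numeric evaluation: OR = max, AND = min over child values."""
        if self.op == "gene":
            return float(scores.get(self.gene, missing))  # type: ignore[arg-type]
        values = [c.evaluate(scores, missing) for c in self.children]
        return max(values) if self.op == "or" else min(values)

    def evaluate_bool(self, present: Iterable[str]) -> bool:
        present = set(present)
        if self.op == "gene":
            return self.gene in present
        if self.op == "or":
            return any(c.evaluate_bool(present) for c in self.children)
        return all(c.evaluate_bool(present) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            s = child.to_string()
            # parenthesise an OR child under AND to preserve precedence
            if self.op == "and" and child.op == "or":
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_GPR_TOKEN = re.compile(r"\(|\)|&&|\|\||[^\s()]+")


def _tokenize_gpr(text: str) -> List[str]:
    tokens = []
    for tok in _GPR_TOKEN.findall(text or ""):
        low = tok.lower()
        if low in ("and", "&&", "&"):
            tokens.append("and")
        elif low in ("or", "||", "|"):
            tokens.append("or")
        else:
            tokens.append(tok)
    return tokens


def _parse_or(tokens: List[str], pos: int) -> Tuple[GeneRule, int]:
    terms = []
    term, pos = _parse_and(tokens, pos)
    terms.append(term)
    while pos < len(tokens) and tokens[pos] == "or":
        term, pos = _parse_and(tokens, pos + 1)
        terms.append(term)
    return GeneRule.any_of(*terms), pos


def _parse_and(tokens: List[str], pos: int) -> Tuple[GeneRule, int]:
    factors = []
    factor, pos = _parse_factor(tokens, pos)
    factors.append(factor)
    while pos < len(tokens) and tokens[pos] == "and":
        factor, pos = _parse_factor(tokens, pos + 1)
        factors.append(factor)
    return GeneRule.all_of(*factors), pos


def _parse_factor(tokens: List[str], pos: int) -> Tuple[GeneRule, int]:
    if pos >= len(tokens):
        raise GemError("unexpected end of gene rule")
    tok = tokens[pos]
    if tok == "(":
        rule, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GemError("unbalanced parenthesis in gene rule")
        return rule, pos + 1
    if tok in (")", "and", "or"):
        raise GemError(f"unexpected token {tok!r} in gene rule")
    return GeneRule.leaf(tok), pos + 1


# --------------------------------------------------------------------------
# Reactions
# --------------------------------------------------------------------------

@dataclass
class Reaction:
    """A (possibly reversible) biochemical conversion with flux bounds."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_rule: Optional[GeneRule] = None
    subsystem: Optional[str] = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 and self.upper_bound > 0

    @property
    def is_exchange(self) -> bool:
        """True when the stoichiometry is one-sided (boundary transfer)."""
        coeffs = list(self.stoichiometry.values())
        return bool(coeffs) and (all(c > 0 for c in coeffs) or all(c < 0 for c in coeffs))

    def validate(self) -> None:
        if not self.stoichiometry:
            raise IntegrityError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise IntegrityError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        for coef in self.stoichiometry.values():
            if not math.isfinite(coef) or coef == 0:
                raise IntegrityError(
                    f"reaction {self.id!r}: zero or non-finite stoichiometric coefficient"
                )


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass
class Model:
    """A genome-scale metabolic model: metabolites, reactions, genes."""

    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups -----------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolites_named(self, name: str) -> List[Metabolite]:
        """All (non-boundary) compartment instances of a metabolite name."""
        return [m for m in self.metabolites if m.name == name and not m.is_boundary]

    def metabolite_names(self) -> List[str]:
        """Unique compartment-agnostic names, in first-appearance order."""
        seen: Dict[str, None] = {}
        for m in self.metabolites:
            if not m.is_boundary:
                seen.setdefault(m.name, None)
        return list(seen)

    @property
    def exchange_reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`IntegrityError`."""
        if len(self._met_index) != len(self.metabolites):
            raise IntegrityError(f"model {self.id!r}: duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise IntegrityError(f"model {self.id!r}: duplicate reaction ids")
        internal = [m for m in self.metabolites if not m.is_boundary]
        pairs = {(m.name, m.compartment) for m in internal}
        if len(pairs) != len(internal):
            raise IntegrityError(
                f"model {self.id!r}: duplicate (name, compartment) metabolite pairs"
            )
        gene_set = set(self.genes)
        for rxn in self.reactions:
            rxn.validate()
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise IntegrityError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if rxn.gene_rule is not None:
                unknown = rxn.gene_rule.genes() - gene_set
                if unknown:
                    raise IntegrityError(
                        f"reaction {rxn.id!r} gene rule references unknown genes "
                        f"{sorted(unknown)}"
                    )

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise IntegrityError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = rxn

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise IntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = met


# --------------------------------------------------------------------------
# Solver plumbing shared by every optimisation in the package
# --------------------------------------------------------------------------

@dataclass
class SolverOptions:
    """Numeric knobs for LP/MILP construction.

    activation_epsilon
        Minimum absolute flux for a reaction to count as *used* (and the
        default lower bound on required task outputs).
    big_M
        Flux-magnitude cap coupling fluxes to inclusion binaries; must
        dominate every reachable flux, i.e. be >= the largest bound magnitude.
    mip_gap
        Relative MILP optimality tolerance handed to the solver.
    """

    activation_epsilon: float = 1e-4
    big_M: float = 1000.0
    mip_gap: float = 1e-6
    time_limit_seconds: Optional[float] = None
    random_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.activation_epsilon <= 0:
            raise ValueError("activation_epsilon must be > 0")
        if self.big_M <= self.activation_epsilon:
            raise ValueError("big_M must exceed activation_epsilon")
        if self.mip_gap < 0:
            raise ValueError("mip_gap must be >= 0")


# --------------------------------------------------------------------------
# Structural operations
# --------------------------------------------------------------------------

def subset_model(model: Model, reaction_ids: Iterable[str]) -> Model:
    """Extract the sub-model induced by ``reaction_ids``.

    The result contains exactly the requested reactions, only the metabolites
    they touch, and only the genes their rules reference.  Reaction and
    metabolite order follows the parent model, so subsetting is idempotent
    and monotone.
    """
    wanted = set(reaction_ids)
    unknown = wanted - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")

    reactions = [copy.deepcopy(r) for r in model.reactions if r.id in wanted]
    touched = {m for r in reactions for m in r.stoichiometry}
    metabolites = [copy.deepcopy(m) for m in model.metabolites if m.id in touched]
    genes_used: Set[str] = set()
    for r in reactions:
        if r.gene_rule is not None:
            genes_used |= r.gene_rule.genes()
    genes = [g for g in model.genes if g in genes_used]
    sub = Model(id=model.id, metabolites=metabolites, reactions=reactions, genes=genes)
    sub.validate()
    return sub


def consuming_reactions(model: Model, metabolite_name: str) -> Dict[str, str]:
    """Map reaction id -> consuming direction for a metabolite name.

    Compartment instances are pooled: every reaction consuming *any*
    instance of ``metabolite_name`` is reported.  Direction ``"forward"``
    means the metabolite is a substrate at positive flux (negative
    coefficient), ``"reverse"`` means it is consumed when a reversible
    reaction runs backwards (positive coefficient, negative flux possible),
    ``"both"`` when instances appear on both sides.
    """
    instance_ids = {m.id for m in model.metabolites_named(metabolite_name)}
    result: Dict[str, str] = {}
    if not instance_ids:
        return result
    for rxn in model.reactions:
        forward = any(
            met in instance_ids and coef < 0 for met, coef in rxn.stoichiometry.items()
        ) and rxn.upper_bound > 0
        reverse = any(
            met in instance_ids and coef > 0 for met, coef in rxn.stoichiometry.items()
        ) and rxn.lower_bound < 0
        if forward and reverse:
            result[rxn.id] = "both"
        elif forward:
            result[rxn.id] = "forward"
        elif reverse:
            result[rxn.id] = "reverse"
    return result


# --------------------------------------------------------------------------
# SBML I/O (libsbml)
# --------------------------------------------------------------------------

_SBML_ID_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


def _sanitize_sid(raw: str) -> str:
    sid = _SBML_ID_SANITIZE.sub("_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def read_sbml(path: str) -> Model:
    """Read an SBML file (L3+fbc, or L2 with legacy notes) into a Model.

    Boundary species (``boundaryCondition="true"``) are kept in the
    metabolite list, flagged, and removed from reaction stoichiometries, so
    reactions that crossed the boundary become one-sided exchange reactions.
    Gene rules come from fbc gene-product associations when present, else
    from ``GENE_ASSOCIATION`` notes.  Missing bounds default to
    [-1000, 1000] for reversible and [0, 1000] for irreversible reactions.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise SbmlParseError(f"{path}: no model element found")
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SbmlParseError(
                f"{path}: {err.getMessage().strip()} (line {err.getLine()})"
            )
    smodel = doc.getModel()
    fbc = smodel.getPlugin("fbc")

    gene_names: Dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getId()] = gp.getLabel() or gp.getId()

    metabolites: List[Metabolite] = []
    compartments = [
        smodel.getCompartment(i).getId() for i in range(smodel.getNumCompartments())
    ]
    boundary_ids: Set[str] = set()
    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        sid = sp.getId()
        name = sp.getName() or strip_compartment_tag(
            re.sub(r"^M_", "", sid), compartments
        )
        is_boundary = bool(sp.getBoundaryCondition())
        if is_boundary:
            boundary_ids.add(sid)
        metabolites.append(
            Metabolite(
                id=sid,
                name=name,
                compartment=sp.getCompartment() or "c",
                is_boundary=is_boundary,
            )
        )
    met_ids = {m.id for m in metabolites}

    reactions: List[Reaction] = []
    genes: Dict[str, None] = {}
    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            if ref.getSpecies() not in met_ids:
                raise IntegrityError(
                    f"reaction {srxn.getId()!r} references unknown species "
                    f"{ref.getSpecies()!r}"
                )
            if ref.getSpecies() in boundary_ids:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            if ref.getSpecies() not in met_ids:
                raise IntegrityError(
                    f"reaction {srxn.getId()!r} references unknown species "
                    f"{ref.getSpecies()!r}"
                )
            if ref.getSpecies() in boundary_ids:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            # reaction touched only boundary species; represent as a no-op
            # exchange on the first boundary partner to keep it recoverable
            continue

        lb, ub = _read_bounds(srxn, smodel)
        rule = _read_gene_rule(srxn, gene_names)
        if rule is not None:
            for g in sorted(rule.genes()):
                genes.setdefault(g, None)
        reactions.append(
            Reaction(
                id=srxn.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=rule,
                subsystem=_read_subsystem(srxn),
            )
        )

    model = Model(
        id=smodel.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=list(genes),
    )
    model.validate()
    return model


def _read_bounds(srxn, smodel) -> Tuple[float, float]:
    import libsbml  # noqa: F401

    fbc_rxn = srxn.getPlugin("fbc")
    lb = ub = None
    if fbc_rxn is not None:
        lb_id = fbc_rxn.getLowerFluxBound()
        ub_id = fbc_rxn.getUpperFluxBound()
        if lb_id:
            p = smodel.getParameter(lb_id)
            lb = p.getValue() if p is not None else None
        if ub_id:
            p = smodel.getParameter(ub_id)
            ub = p.getValue() if p is not None else None
    if lb is None or ub is None:
        # SBML L2: kinetic-law parameters
        klaw = srxn.getKineticLaw()
        if klaw is not None:
            for j in range(klaw.getNumParameters()):
                p = klaw.getParameter(j)
                if p.getId() == "LOWER_BOUND" and lb is None:
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND" and ub is None:
                    ub = p.getValue()
    reversible = srxn.getReversible()
    if lb is None:
        lb = -DEFAULT_BOUND if reversible else 0.0
    if ub is None:
        ub = DEFAULT_BOUND
    return float(lb), float(ub)


def _read_gene_rule(srxn, gene_names: Dict[str, str]) -> Optional[GeneRule]:
    import libsbml

    fbc_rxn = srxn.getPlugin("fbc")
    if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
        assoc = fbc_rxn.getGeneProductAssociation().getAssociation()
        return _convert_fbc_association(assoc, gene_names)
    # legacy: notes with GENE_ASSOCIATION
    if srxn.isSetNotes():
        notes = srxn.getNotesString()
        m = re.search(r"GENE_ASSOCIATION:\s*([^<]+)", notes)
        if m:
            return GeneRule.from_string(m.group(1).strip())
    return None


def _convert_fbc_association(assoc, gene_names: Dict[str, str]) -> Optional[GeneRule]:
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getGeneProduct()
        return GeneRule.leaf(gene_names.get(gp, gp))
    children = [
        _convert_fbc_association(assoc.getAssociation(i), gene_names)
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    if isinstance(assoc, libsbml.FbcAnd):
        return GeneRule.all_of(*children)
    return GeneRule.any_of(*children)


def _read_subsystem(srxn) -> Optional[str]:
    if srxn.isSetNotes():
        m = re.search(r"SUBSYSTEM:\s*([^<]+)", srxn.getNotesString())
        if m:
            return m.group(1).strip()
    return None


def write_sbml(model: Model, path: str) -> None:
    """Write a Model as SBML Level 3 Version 1 with the fbc (v2) package.

    ``read_sbml`` inverts this writer: ids, stoichiometry, bounds, gene
    rules and subsystem annotations all round-trip.
    """
    import libsbml

    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_sanitize_sid(model.id))
    mplug = smodel.getPlugin("fbc")
    mplug.setStrict(False)

    comps = sorted({m.compartment for m in model.metabolites} or {"c"})
    for cid in comps:
        comp = smodel.createCompartment()
        comp.setId(_sanitize_sid(cid))
        comp.setConstant(True)

    for met in model.metabolites:
        sp = smodel.createSpecies()
        sp.setId(_sanitize_sid(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sanitize_sid(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(bool(met.is_boundary))
        sp.setConstant(False)

    gene_ids: Dict[str, str] = {}
    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gid = _sanitize_sid(f"G_{gene}")
        gp.setId(gid)
        gp.setLabel(gene)
        gene_ids[gene] = gid

    bound_params: Dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = _sanitize_sid(f"fb_{len(bound_params)}")
            p = smodel.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        srxn = smodel.createReaction()
        srxn.setId(_sanitize_sid(rxn.id))
        srxn.setReversible(rxn.lower_bound < 0)
        srxn.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = srxn.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = srxn.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(_sanitize_sid(met_id))
            ref.setConstant(True)
        rplug = srxn.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.gene_rule is not None:
            gpa = rplug.createGeneProductAssociation()
            _write_fbc_association(gpa, rxn.gene_rule, gene_ids)
        if rxn.subsystem:
            srxn.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")


def _write_fbc_association(container, rule: GeneRule, gene_ids: Dict[str, str]) -> None:
    """Recursively build the fbc association tree under ``container``.

    ``container`` is a GeneProductAssociation, FbcAnd or FbcOr — all expose
    createGeneProductRef / createAnd / createOr.
    """
    if rule.op == "gene":
        ref = container.createGeneProductRef()
        ref.setGeneProduct(gene_ids[rule.gene])  # type: ignore[index]
        return
    node = container.createAnd() if rule.op == "and" else container.createOr()
    for child in rule.children:
        _write_fbc_association(node, child, gene_ids)
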
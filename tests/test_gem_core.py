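"""Model structure, gene-rule parsing, SBML round trips."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from tinit.gem_core import (
    GemError,
    GeneRule,
    IntegrityError,
    Metabolite,
    Model,
    Reaction,
    SolverOptions,
    consuming_reactions,
    read_sbml,
    strip_compartment_tag,
    subset_model,
    write_sbml,
)
from tinit.synthetic_fixtures import FixtureSpec, generate_reference


# --------------------------------------------------------------------------
# Gene rules
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,genes,present,expected",
    [
        ("G1", {"G1"}, {"G1"}, True),
        ("G1 and G2", {"G1", "G2"}, {"G1"}, False),
        ("G1 or G2", {"G1", "G2"}, {"G2"}, True),
        ("(G1 and G2) or G3", {"G1", "G2", "G3"}, {"G3"}, True),
        ("G1 and (G2 or G3)", {"G1", "G2", "G3"}, {"G1", "G3"}, True),
        ("G1 && G2 || G3", {"G1", "G2", "G3"}, {"G3"}, True),
    ],
)
def test_gene_rule_parse_and_eval(text, genes, present, expected):
    rule = GeneRule.from_string(text)
    assert rule.genes() == genes
    assert rule.evaluate_bool(present) is expected


def test_gene_rule_precedence_matches_cobra_parser():
    """AND binds tighter than OR, exactly as cobra's GPR ast parser reads it."""
    from cobra.core.gene import GPR

    genes = {"G1", "G2", "G3", "G4"}
    for text in [
        "(G1 and G2) or G3",
        "G1 and G2 or G3",
        "G1 or G2 and G3",
        "G1 and (G2 or G3) and G4",
    ]:
        ours = GeneRule.from_string(text)
        theirs = GPR.from_string(text)
        for present in [set(), {"G1"}, {"G2"}, {"G3"}, {"G1", "G2"},
                        {"G2", "G3"}, {"G1", "G4"}, {"G1", "G2", "G3", "G4"}]:
            # cobra's GPR.eval takes the *knocked-out* genes
            assert ours.evaluate_bool(present) == theirs.eval(genes - present), (
                text, present)


def test_gene_rule_roundtrip_through_string():
    rule = GeneRule.from_string("(G1 and G2) or (G3 and (G4 or G5))")
    again = GeneRule.from_string(rule.to_string())
    for present in [set(), {"G3", "G4"}, {"G1", "G2"}, {"G3"}, {"G4", "G5"}]:
        assert rule.evaluate_bool(present) == again.evaluate_bool(present)


@pytest.mark.parametrize("bad", ["G1 and", "(G1 or G2", "and G1", "G1 ) G2"])
def test_gene_rule_rejects_malformed(bad):
    with pytest.raises(GemError):
        GeneRule.from_string(bad)


def test_gene_rule_minmax_evaluation():
    rule = GeneRule.from_string("(G1 and G2) or G3")
    assert rule.evaluate({"G1": 20, "G2": -8, "G3": 10}) == 10
    assert rule.evaluate({"G1": 20, "G2": 15, "G3": 10}) == 15


# --------------------------------------------------------------------------
# Model invariants
# --------------------------------------------------------------------------

def test_model_validate_catches_dangling_metabolite():
    model = Model(
        "bad",
        [Metabolite("A", "A")],
        [Reaction("R1", {"A": -1.0, "GHOST": 1.0})],
    )
    with pytest.raises(IntegrityError, match="GHOST"):
        model.validate()


def test_model_validate_catches_bad_bounds_and_rules():
    with pytest.raises(IntegrityError, match="lower bound"):
        Reaction("R", {"A": -1.0}, 5.0, -5.0).validate()
    model = Model(
        "bad",
        [Metabolite("A", "A"), Metabolite("B", "B")],
        [Reaction("R", {"A": -1.0, "B": 1.0}, gene_rule=GeneRule.leaf("GX"))],
        genes=[],
    )
    with pytest.raises(IntegrityError, match="GX"):
        model.validate()


def test_solver_options_invariants():
    with pytest.raises(ValueError):
        SolverOptions(activation_epsilon=0.0)
    with pytest.raises(ValueError):
        SolverOptions(activation_epsilon=1.0, big_M=0.5)


# --------------------------------------------------------------------------
# subset_model
# --------------------------------------------------------------------------

def test_subset_identity_and_empty(fig1b):
    model = fig1b[0]
    full = subset_model(model, model.reaction_ids)
    assert set(full.reaction_ids) == set(model.reaction_ids)
    assert set(full.metabolite_ids) == set(model.metabolite_ids)
    empty = subset_model(model, set())
    assert empty.reactions == [] and empty.metabolites == []


def test_subset_drops_uniquely_touched_metabolites(fig1b):
    model = fig1b[0]
    # X is only touched by the upper red route R_BX / R_XC
    keep = set(model.reaction_ids) - {"R_BX", "R_XC"}
    sub = subset_model(model, keep)
    touched = {m for r in sub.reactions for m in r.stoichiometry}
    assert "X" not in touched and "X" not in sub.metabolite_ids


def test_subset_idempotent_and_monotone(fig1b):
    model = fig1b[0]
    big = {"EX_A", "R_AM", "R_MD", "EX_D", "R_CE"}
    small = {"R_AM", "R_MD"}
    once = subset_model(model, big)
    twice = subset_model(once, small)
    direct = subset_model(model, small)
    assert set(twice.reaction_ids) == set(direct.reaction_ids)
    assert set(twice.metabolite_ids) == set(direct.metabolite_ids)


def test_subset_unknown_ids_listed():
    model = Model("m", [Metabolite("A", "A")], [Reaction("R", {"A": 1.0})])
    with pytest.raises(KeyError, match="NOPE"):
        subset_model(model, {"R", "NOPE"})


# --------------------------------------------------------------------------
# consuming_reactions
# --------------------------------------------------------------------------

def _two_compartment_model(comp2="m"):
    mets = [
        Metabolite("X_c", "X", "c"),
        Metabolite(f"X_{comp2}", "X", comp2),
        Metabolite("A_c", "A", "c"),
        Metabolite("Y_c", "Y", "c"),
    ]
    rxns = [
        # irreversible consumer of cytosolic X
        Reaction("R1", {"A_c": -1.0, "X_c": -1.0, "Y_c": 1.0}, 0.0, 1000.0),
        # reversible, X (other compartment) is a product => consumed backwards
        Reaction("R2", {"A_c": -1.0, f"X_{comp2}": 1.0}, -1000.0, 1000.0),
        # produces X only, irreversible: not a consumer
        Reaction("R3", {"A_c": -1.0, "X_c": 1.0}, 0.0, 1000.0),
    ]
    m = Model("cc", mets, rxns)
    m.validate()
    return m


def test_consuming_reactions_directions():
    model = _two_compartment_model()
    assert consuming_reactions(model, "X") == {"R1": "forward", "R2": "reverse"}
    assert consuming_reactions(model, "nothing") == {}


def test_consuming_reactions_pools_compartments():
    """Renaming a compartment never changes the result."""
    assert consuming_reactions(_two_compartment_model("m"), "X") == \
        consuming_reactions(_two_compartment_model("x"), "X")


def test_consuming_reactions_both_sides():
    model = Model(
        "loop",
        [Metabolite("X_c", "X", "c"), Metabolite("X_m", "X", "m")],
        [Reaction("T", {"X_c": -1.0, "X_m": 1.0}, -1000.0, 1000.0)],
    )
    assert consuming_reactions(model, "X") == {"T": "both"}


# --------------------------------------------------------------------------
# compartment-tag stripping
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw,comps,expected",
    [
        ("atp_c", ["c", "m"], "atp"),
        ("glc__D_e", ["c", "e"], "glc__D"),
        ("atp[m]", ["c", "m"], "atp"),
        ("atp", ["c"], "atp"),
        ("cmp_like", ["c"], "cmp_like"),  # "like" is not a compartment
    ],
)
def test_strip_compartment_tag(raw, comps, expected):
    assert strip_compartment_tag(raw, comps) == expected


# --------------------------------------------------------------------------
# SBML round trips
# --------------------------------------------------------------------------

def _models_structurally_equal(a: Model, b: Model) -> None:
    assert set(a.reaction_ids) == set(b.reaction_ids)
    assert {(m.name, m.compartment) for m in a.metabolites} == {
        (m.name, m.compartment) for m in b.metabolites
    }
    assert set(a.genes) == set(b.genes)
    for rxn in a.reactions:
        other = b.reaction(rxn.id)
        assert other.stoichiometry == rxn.stoichiometry
        assert (other.lower_bound, other.upper_bound) == (
            rxn.lower_bound, rxn.upper_bound)
        if rxn.gene_rule is None:
            assert other.gene_rule is None
        else:
            assert other.gene_rule.genes() == rxn.gene_rule.genes()
        assert other.subsystem == rxn.subsystem


def test_sbml_roundtrip_toy_chain(tmp_path, chain_model):
    path = tmp_path / "chain.xml"
    write_sbml(chain_model, str(path))
    again = read_sbml(str(path))
    _models_structurally_equal(chain_model, again)
    assert read_sbml(str(path)).exchange_reaction_ids == ["EX_A", "EX_B"]


def test_sbml_roundtrip_is_fixed_point(tmp_path, fig1b):
    model = fig1b[0]
    p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
    write_sbml(model, str(p1))
    first = read_sbml(str(p1))
    write_sbml(first, str(p2))
    second = read_sbml(str(p2))
    _models_structurally_equal(first, second)
    _models_structurally_equal(model, first)


@pytest.mark.parametrize("seed", [0, 7, 21])
def test_sbml_roundtrip_generated_fixture(tmp_path, seed):
    model, _, _ = generate_reference(FixtureSpec(seed=seed))
    path = tmp_path / "ref.xml"
    write_sbml(model, str(path))
    _models_structurally_equal(model, read_sbml(str(path)))


def test_sbml_gene_rules_roundtrip_and_cross_check(tmp_path):
    """fbc associations round-trip; cobra reads the same GPR semantics."""
    import cobra

    rule = GeneRule.from_string("(G1 and G2) or G3")
    model = Model(
        "gpr",
        [Metabolite("A", "A"), Metabolite("B", "B")],
        [
            Reaction("R1", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0,
                     gene_rule=rule, subsystem="toy pathway"),
            Reaction("R2", {"B": -1.0}, 0.0, 1000.0),  # no gene association
        ],
        ["G1", "G2", "G3"],
    )
    model.validate()
    path = tmp_path / "gpr.xml"
    write_sbml(model, str(path))
    again = read_sbml(str(path))
    _models_structurally_equal(model, again)
    r1 = again.reaction("R1")
    assert r1.reversible and r1.subsystem == "toy pathway"
    for present in [set(), {"G1"}, {"G1", "G2"}, {"G3"}]:
        assert r1.gene_rule.evaluate_bool(present) == rule.evaluate_bool(present)
    assert again.reaction("R2").gene_rule is None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm = cobra.io.read_sbml_model(str(path))
    from cobra.core.gene import GPR

    cobra_rule = GPR.from_string(cm.reactions.get_by_id("R1").gene_reaction_rule)
    for present in [set(), {"G1"}, {"G1", "G2"}, {"G3"}]:
        knockouts = {"G1", "G2", "G3"} - present
        assert cobra_rule.eval(knockouts) == rule.evaluate_bool(present)


def test_read_sbml_legacy_notes_and_boundary_species(tmp_path):
    """L2-style notes GPR + boundary species handling on read."""
    xml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="legacy">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A_ext" name="A" compartment="c" boundaryCondition="true"/>
   <species id="A" name="A" compartment="c"/>
   <species id="B" name="B" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="T_A" reversible="false">
    <listOfReactants><speciesReference species="A_ext"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
   </reaction>
   <reaction id="R_AB" reversible="false">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
      <p>GENE_ASSOCIATION: (G1 and G2) or G3</p></body></notes>
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
    path = tmp_path / "legacy.xml"
    path.write_text(xml)
    model = read_sbml(str(path))
    # boundary species stripped from stoichiometry -> T_A became an exchange
    assert model.reaction("T_A").stoichiometry == {"A": 1.0}
    assert model.reaction("T_A").is_exchange
    assert model.metabolite("A_ext").is_boundary
    rule = model.reaction("R_AB").gene_rule
    assert rule is not None and rule.genes() == {"G1", "G2", "G3"}
    # L2 without explicit bounds: irreversible default [0, 1000]
    assert model.reaction("R_AB").lower_bound == 0.0
    assert model.reaction("R_AB").upper_bound == 1000.0


def test_read_sbml_malformed_raises(tmp_path):
    from tinit.gem_core import SbmlParseError

    path = tmp_path / "bad.xml"
    path.write_text("<sbml>this is not valid</sbml>")
    with pytest.raises(SbmlParseError):
        read_sbml(str(path))


# --------------------------------------------------------------------------
# property: subsetting commutes with round-tripping
# --------------------------------------------------------------------------

@settings(max_examples=15, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000), data=st.data())
def test_roundtrip_then_subset_equals_subset(seed, data, tmp_path_factory):
    model, _, _ = generate_reference(FixtureSpec(seed=seed))
    rids = sorted(model.reaction_ids)
    chosen = set(data.draw(st.lists(st.sampled_from(rids), unique=True)))
    tmp = tmp_path_factory.mktemp("rt") / "m.xml"
    write_sbml(model, str(tmp))
    again = read_sbml(str(tmp))
    a = subset_model(model, chosen)
    b = subset_model(again, chosen)
    assert set(a.reaction_ids) == set(b.reaction_ids)
    assert {m.name for m in a.metabolites} == {m.name for m in b.metabolites}
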
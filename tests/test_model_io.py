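"""SBML round trips, CSV conversion, GPR parsing, summaries, error paths."""

import textwrap

import pytest

from gemflux import (GemModel, Metabolite, ModelIntegrityError, Reaction,
                     from_tables, make_glutamate_core, make_linear_chain,
                     model_summary, read_sbml, write_sbml)
from gemflux.model import eval_gpr, parse_gpr
from gemflux.sbml import SbmlParseError
from gemflux.tables import TableParseError, parse_equation


def _assert_models_equal(a: GemModel, b: GemModel) -> None:
    assert {m.id for m in a.metabolites} == {m.id for m in b.metabolites}
    bm = {m.id: m for m in b.metabolites}
    for met in a.metabolites:
        other = bm[met.id]
        assert other.formula == met.formula
        assert other.charge == met.charge
        assert other.compartment == met.compartment
        assert other.sbo == met.sbo
    br = {r.id: r for r in b.reactions}
    assert set(br) == {r.id for r in a.reactions}
    for rxn in a.reactions:
        other = br[rxn.id]
        assert other.stoichiometry == pytest.approx(rxn.stoichiometry)
        assert other.lower_bound == rxn.lower_bound
        assert other.upper_bound == rxn.upper_bound
        assert other.sbo == rxn.sbo
        if rxn.gpr is None:
            assert other.gpr is None
        else:  # textual form may gain parentheses; semantics must agree
            genes = sorted(a.gene_ids)
            for k in range(len(genes) + 1):
                active = set(genes[k:])
                assert eval_gpr(parse_gpr(other.gpr), active) == \
                    eval_gpr(parse_gpr(rxn.gpr), active)
    assert {g.id for g in a.genes} == {g.id for g in b.genes}
    assert a.groups == b.groups
    assert a.objective == b.objective


@pytest.mark.parametrize("model_factory", [
    lambda: make_linear_chain(5, uptake=10.0),
    lambda: make_linear_chain(1, uptake=3.0),
    make_glutamate_core,
])
def test_sbml_round_trip_preserves_everything(tmp_path, model_factory):
    model = model_factory()
    path = tmp_path / "model.xml"
    write_sbml(model, str(path))
    _assert_models_equal(model, read_sbml(str(path)))


def test_write_is_deterministic(tmp_path, core):
    p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
    write_sbml(core, str(p1))
    write_sbml(core, str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_model_without_genes_round_trips(tmp_path):
    model = GemModel(id="tiny")
    model.metabolites.append(Metabolite(id="a_c", formula="C", charge=0))
    model.reactions.append(Reaction(id="DM_a_c", stoichiometry={"a_c": -1.0},
                                    sbo="SBO:0000628"))
    path = tmp_path / "tiny.xml"
    write_sbml(model, str(path))
    back = read_sbml(str(path))
    assert back.genes == []
    assert back.reaction("DM_a_c").stoichiometry == {"a_c": -1.0}


def test_groups_serialized_with_members(tmp_path, core):
    path = tmp_path / "core.xml"
    write_sbml(core, str(path))
    back = read_sbml(str(path))
    assert back.groups["TCA cycle"] == ["CS", "ACONT", "ICDHyr"]
    assert "TCA cycle" in back.reaction("CS").subsystems


def test_malformed_xml_reports_line(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("<sbml><model></sbml>")
    with pytest.raises(SbmlParseError, match="line"):
        read_sbml(str(bad))


def test_undefined_species_reference_rejected(tmp_path, chain5):
    path = tmp_path / "chain.xml"
    write_sbml(chain5, str(path))
    text = path.read_text().replace('species="M_A_c"', 'species="M_X_c"', 1)
    hacked = tmp_path / "hacked.xml"
    hacked.write_text(text)
    with pytest.raises((ModelIntegrityError, SbmlParseError)):
        read_sbml(str(hacked))


def test_unresolved_reference_refuses_to_write(tmp_path):
    model = GemModel(id="broken")
    model.metabolites.append(Metabolite(id="a_c"))
    model.reactions.append(
        Reaction(id="R1", stoichiometry={"a_c": -1.0, "ghost_c": 1.0}))
    with pytest.raises(ModelIntegrityError, match="ghost_c"):
        write_sbml(model, str(tmp_path / "broken.xml"))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _write_tables(tmp_path, rxn_rows, met_rows):
    mets = tmp_path / "mets.csv"
    rxns = tmp_path / "rxns.csv"
    mets.write_text("id,name,compartment,formula,charge\n" + met_rows)
    rxns.write_text(
        "id,name,equation,lower_bound,upper_bound,gpr,subsystem\n" + rxn_rows)
    return str(rxns), str(mets)


CS_METS = textwrap.dedent("""\
    accoa_c,acetyl-CoA,c,C23H34N7O17P3S,-4
    h2o_c,water,c,H2O,0
    oaa_c,oxaloacetate,c,C4H2O5,-2
    cit_c,citrate,c,C6H5O7,-3
    coa_c,coenzyme A,c,C21H32N7O16P3S,-4
    h_c,proton,c,H,1
    """)


def test_citrate_synthase_row_parses(tmp_path):
    rxns, mets = _write_tables(
        tmp_path,
        "CS,citrate synthase,"
        "accoa_c + h2o_c + oaa_c -> cit_c + coa_c + h_c,,,gltA,TCA cycle\n",
        CS_METS)
    model = from_tables(rxns, mets)
    cs = model.reaction("CS")
    assert cs.stoichiometry == {
        "accoa_c": -1.0, "h2o_c": -1.0, "oaa_c": -1.0,
        "cit_c": 1.0, "coa_c": 1.0, "h_c": 1.0}
    assert (cs.lower_bound, cs.upper_bound) == (0.0, 1000.0)
    assert cs.gpr == "gltA"
    assert model.groups["TCA cycle"] == ["CS"]


@pytest.mark.parametrize("arrow,lb", [("⇌", -1000.0), ("<=>", -1000.0),
                                      ("->", 0.0), ("→", 0.0)])
def test_default_bounds_follow_reversibility(tmp_path, arrow, lb):
    rxns, mets = _write_tables(
        tmp_path, f"AB,conv,accoa_c {arrow} coa_c,,,,\n", CS_METS)
    rxn = from_tables(rxns, mets).reaction("AB")
    assert (rxn.lower_bound, rxn.upper_bound) == (lb, 1000.0)


def test_explicit_bounds_kept(tmp_path):
    rxns, mets = _write_tables(
        tmp_path, "AB,conv,accoa_c -> coa_c,-5,7,,\n", CS_METS)
    rxn = from_tables(rxns, mets).reaction("AB")
    assert (rxn.lower_bound, rxn.upper_bound) == (-5.0, 7.0)


@pytest.mark.parametrize("equation", ["accoa_c + -> coa_c",
                                      "accoa_c coa_c",
                                      "2 3 accoa_c -> coa_c"])
def test_unparsable_equation_is_row_level_error(tmp_path, equation):
    rxns, mets = _write_tables(tmp_path, f"BAD,broken,{equation},,,,\n",
                               CS_METS)
    with pytest.raises(TableParseError, match="BAD"):
        from_tables(rxns, mets)


def test_duplicate_reaction_id_rejected(tmp_path):
    rxns, mets = _write_tables(
        tmp_path,
        "AB,one,accoa_c -> coa_c,,,,\nAB,two,coa_c -> accoa_c,,,,\n",
        CS_METS)
    with pytest.raises(TableParseError, match="duplicate"):
        from_tables(rxns, mets)


def test_converter_idempotent_through_sbml(tmp_path):
    rxns, mets = _write_tables(
        tmp_path,
        "CS,citrate synthase,"
        "accoa_c + h2o_c + oaa_c -> cit_c + coa_c + h_c,,,gltA,TCA cycle\n"
        "AB,conv,accoa_c ⇌ coa_c,,,,\n",
        CS_METS)
    model = from_tables(rxns, mets)
    path = tmp_path / "converted.xml"
    write_sbml(model, str(path))
    _assert_models_equal(model, read_sbml(str(path)))


def test_equation_side_cancellation():
    stoich, reversible = parse_equation("a_c + b_c -> a_c + c_c")
    assert stoich == {"b_c": -1.0, "c_c": 1.0}
    assert not reversible


# ---------------------------------------------------------------------------
# GPR semantics and summary
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rule,active,expected", [
    ("g1 and g2", {"g1", "g2"}, True),
    ("g1 and g2", {"g1"}, False),
    ("g1 or g2", {"g2"}, True),
    ("g1 or g2", set(), False),
    ("(g1 and g2) or g3", {"g3"}, True),
    ("g1 and (g2 or g3)", {"g1", "g3"}, True),
    ("g1 and g2 or g3", {"g3"}, True),  # and binds tighter than or
])
def test_gpr_evaluation(rule, active, expected):
    assert eval_gpr(parse_gpr(rule), active) is expected


def test_model_summary_counts(core):
    summary = model_summary(core)
    assert summary["n_metabolites"] == len(core.metabolites)
    assert summary["n_reactions"] == len(core.reactions)
    assert summary["n_genes"] == len(core.genes)
    assert summary["n_groups"] == 6
    assert sum(summary["sbo_histogram"].values()) == len(core.reactions)
    assert summary["sbo_histogram"]["SBO:0000629"] == 1  # one biomass


def test_model_summary_empty_model():
    summary = model_summary(GemModel(id="empty"))
    assert summary == {"n_metabolites": 0, "n_reactions": 0, "n_genes": 0,
                       "n_groups": 0, "sbo_histogram": {}}
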
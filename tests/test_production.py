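"""Production analyses on the glutamate core with hand-derived expectations.

Analytic reference for the core (glucose uptake 10, unlimited oxygen):
each glucose yields at most one glutamate (PEP + pyruvate pair), 7 ATP when
routed to glutamate and 12 ATP when routed to the acetate overflow, and the
biomass drains 0.0149 glutamate + 40 ATP per unit growth.  Maximising the
glutamate sink at fixed growth mu therefore gives the piecewise line

    p(mu) = 10 - 0.0149 mu            for mu <= 1.75  (carbon-limited)
    p(mu) = 24 - 8.0149 mu            for mu >= 1.75  (ATP-limited)

with mu_max = 24/8.0149.
"""

import numpy as np
import pytest

from gemflux import (add_sink, amino_acid_profile, fba, fix_flux, knockout,
                     knockout_experiment, pinned_reactions, tradeoff_curve)
from gemflux.optimize import InfeasibleModelError
from gemflux.production import amino_acid_map

MU_BREAK = 1.75
MU_MAX = 24.0 / 8.0149


def p_line(mu: float) -> float:
    return 10.0 - 0.0149 * mu if mu <= MU_BREAK else 24.0 - 8.0149 * mu


# ---------------------------------------------------------------------------
# add_sink
# ---------------------------------------------------------------------------

def test_sink_id_drops_compartment_suffix(core):
    assert add_sink(core, "glu__L_c") == "sink_glu__L"
    rxn = core.reaction("sink_glu__L")
    assert rxn.stoichiometry == {"glu__L_c": -1.0}
    assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1000.0)
    assert rxn.sbo == "SBO:0000632"


def test_add_sink_idempotent(core):
    first = add_sink(core, "glu__L_c")
    n = len(core.reactions)
    assert add_sink(core, "glu__L_c") == first
    assert len(core.reactions) == n


def test_add_sink_unknown_metabolite(core):
    with pytest.raises(KeyError):
        add_sink(core, "nope_c")


# ---------------------------------------------------------------------------
# amino-acid profile
# ---------------------------------------------------------------------------

def test_canonical_amino_acid_map_has_twenty_entries():
    mapping = amino_acid_map()
    assert len(mapping) == 20
    assert mapping["L-glutamate"] == "glu__L_c"
    assert mapping["glycine"] == "gly_c"
    assert all(mid.endswith("_c") for mid in mapping.values())


def test_profile_on_core_produces_glutamate_at_fixed_growth(core):
    records = {r.target: r for r in amino_acid_profile(core, growth_fix=0.4)}
    assert len(records) == 20
    glu = records["L-glutamate"]
    assert glu.status == "optimal"
    assert glu.production_rate == pytest.approx(p_line(0.4), abs=1e-6)
    assert glu.yield_on_glucose == pytest.approx(p_line(0.4) / 10.0, abs=1e-7)
    assert glu.co2_rate >= 0.0 and glu.atp_rate > 0.0
    # the core only carries glutamate among the canonical twenty
    others = [r for t, r in records.items() if t != "L-glutamate"]
    assert all(r.status == "absent" for r in others)


def test_profile_atp_accounting_counts_positive_makers_only(core):
    records = {r.target: r for r in amino_acid_profile(core, growth_fix=0.4)}
    glu = records["L-glutamate"]
    # ATP makers at this optimum: glycolysis lump (+1/glc) and oxidative
    # phosphorylation (2 per NADH, 3 NADH per glucose) give 70 at full
    # uptake; the equivalent PC+PYK vertex adds 10 more via pyruvate
    # kinase.  Alternative optima may return either vertex.
    assert 70.0 - 1e-4 <= glu.atp_rate <= 80.0 + 1e-4


def test_profile_infeasible_growth_fix_raises(core):
    with pytest.raises(InfeasibleModelError, match="growth"):
        amino_acid_profile(core, growth_fix=5.0)


# ---------------------------------------------------------------------------
# trade-off curve
# ---------------------------------------------------------------------------

def test_tradeoff_matches_hand_line(core):
    sink = add_sink(core, "glu__L_c")
    grid = [0.0, 0.4, 1.0, 1.75, 2.0, 2.5]
    curve = tradeoff_curve(core, sink, mu_grid=grid)
    for (mu, rate), status in zip(curve.points, curve.statuses):
        assert status == "optimal"
        assert rate == pytest.approx(p_line(mu), abs=1e-6)


def test_tradeoff_endpoint_and_infeasible_beyond(core):
    sink = add_sink(core, "glu__L_c")
    curve = tradeoff_curve(core, sink, mu_grid=[MU_MAX, MU_MAX + 0.05])
    (mu0, r0), (mu1, r1) = curve.points
    assert curve.statuses[0] == "optimal"
    assert r0 == pytest.approx(max(0.0, p_line(MU_MAX)), abs=1e-6)
    assert curve.statuses[1] == "infeasible"


def test_tradeoff_default_grid_monotone_concave(core):
    sink = add_sink(core, "glu__L_c")
    curve = tradeoff_curve(core, sink, n_points=15)
    rates = curve.rates
    assert len(rates) == 15
    diffs = np.diff(rates)
    assert np.all(diffs <= 1e-6)  # non-increasing
    assert np.all(np.diff(diffs) <= 1e-6)  # concave


def test_tradeoff_unknown_sink(core):
    with pytest.raises(KeyError):
        tradeoff_curve(core, "sink_missing")


# ---------------------------------------------------------------------------
# knockout experiment
# ---------------------------------------------------------------------------

def test_pc_knockout_fully_compensated(core):
    result = knockout_experiment(core, reaction_id="PC", product="glu__L_c",
                                 growth_fix=0.4)
    before, after = result["before"], result["after"]
    assert before.production_rate == pytest.approx(p_line(0.4), abs=1e-6)
    assert after.production_rate == pytest.approx(before.production_rate,
                                                  abs=1e-6)
    assert result["fluxes_before"] and result["fluxes_after"]
    assert result["fluxes_after"]["PC"] == 0.0


def test_double_anaplerotic_knockout_abolishes_production(core):
    no_pc = knockout(core, "PC")
    result = knockout_experiment(no_pc, reaction_id="PPC",
                                 product="glu__L_c", growth_fix=0.0)
    assert result["after"].production_rate == pytest.approx(0.0, abs=1e-6)
    # growth itself becomes impossible without glutamate for biomass
    at_growth = knockout_experiment(no_pc, reaction_id="PPC",
                                    product="glu__L_c", growth_fix=0.4)
    assert at_growth["after"].status == "infeasible"
    assert at_growth["after"].production_rate == 0.0


@pytest.mark.parametrize("target", ["PC", "PPC", "PYK", "ACK", "NADHOX",
                                    "GDH", "CS"])
def test_knockout_never_increases_production(core, target):
    result = knockout_experiment(core, reaction_id=target,
                                 product="glu__L_c", growth_fix=0.0)
    assert result["after"].production_rate \
        <= result["before"].production_rate + 1e-6


def test_gene_level_knockout_through_gpr(core):
    # PDH requires aceE AND aceF AND lpd; removing one subunit blocks it
    ko = knockout(core, "aceF")
    assert ko.reaction("PDH").upper_bound == 0.0
    sink = add_sink(ko, "glu__L_c")
    sol = fba(fix_flux(ko, "BIOMASS", 0.0), sink)
    assert sol.objective == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# pinned reactions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def pinned_core():
    from gemflux import make_glutamate_core
    model = make_glutamate_core()
    sink = add_sink(model, "glu__L_c")
    return pinned_reactions(model, sink, growth_fix=0.4, loopless=True)


def test_production_backbone_is_pinned(pinned_core):
    # the unique route glucose -> glutamate pins transporter, TCA entry and
    # the sink itself (the genome-scale analogue lists exactly these ids)
    expected = {"EX_glc__D_e", "GLCpts", "CS", "ACONT", "ICDHyr",
                "sink_glu__L"}
    assert expected <= set(pinned_core.reaction_ids)


def test_alternative_anaplerotic_routes_are_not_pinned(pinned_core):
    # PEP carboxylase and pyruvate carboxylase substitute for one another
    # (with PYK shuttling PEP to pyruvate), so none of the three is pinned
    assert {"PPC", "PC", "PYK"}.isdisjoint(pinned_core.reaction_ids)


def test_pinned_tolerance_rule(pinned_core):
    for rng in pinned_core.ranges:
        tol = 1e-8 + 1e-5 * max(abs(rng.minimum), abs(rng.maximum))
        assert abs(rng.maximum - rng.minimum) <= tol


def test_blocked_reaction_always_pinned(core):
    blocked = knockout(core, "ACK")
    sink = add_sink(blocked, "glu__L_c")
    result = pinned_reactions(blocked, sink, growth_fix=0.4, loopless=False)
    assert "ACK" in result.reaction_ids


def test_every_chain_step_pinned_on_single_path(chain5):
    sink = add_sink(chain5, "E_c")
    result = pinned_reactions(chain5, sink, growth_fix=0.0, loopless=True)
    assert {"EX_A_e", "T_A", "R1", "R2", "R3", "R4",
            "sink_E"} <= set(result.reaction_ids)


def test_pinned_set_invariant_to_reaction_order(core):
    sink = add_sink(core, "glu__L_c")
    shuffled = core.copy()
    shuffled.reactions = list(reversed(shuffled.reactions))
    a = pinned_reactions(core, sink, growth_fix=0.4, loopless=False)
    b = pinned_reactions(shuffled, sink, growth_fix=0.4, loopless=False)
    assert set(a.reaction_ids) == set(b.reaction_ids)
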
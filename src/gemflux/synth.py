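"""Deterministic toy-model generators with analytically known optima.

Two generators cover the pipeline: a linear uptake→conversion→biomass
chain whose FBA optimum equals the uptake bound by flow conservation, and
a fixed ~25-reaction glutamate-producing core (PEP:sugar phosphotransferase
uptake, lumped glycolysis, both anaplerotic carboxylases, citrate synthase
→ aconitase → isocitrate dehydrogenase, glutamate dehydrogenase, acetate
overflow, respiration) whose growth–glutamate trade-off is piecewise
linear and hand-derivable.  All synthetic metabolites carry real molecular
formulas and charges so every audit runs unmodified, and generation is
deterministic: the same spec always yields byte-identical SBML.

Defects (mass imbalance, dead-end, orphan, energy-generating cycle) are
planted as separate branch reactions so each is found by exactly one
detector; planted ids are recorded under ``model.notes["planted_defects"]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase
from typing import Dict, List, Optional

import yaml

from .audit import DISSIPATION_RECIPES
from .formula import format_formula, parse_formula
from .model import (SBO_ATPM, SBO_BIOMASS, SBO_EXCHANGE, SBO_SINK, Gene,
                    GemModel, Metabolite, Reaction)

__all__ = [
    "GeneratorSpec",
    "make_linear_chain",
    "make_glutamate_core",
    "plant_defect",
    "from_spec",
    "load_spec",
    "GLUTAMATE_BIOMASS_COEFF",
    "BIOMASS_ATP_COEFF",
]

SBO_BIOCHEMICAL = "SBO:0000176"
SBO_TRANSPORT = "SBO:0000655"

#: glutamate drain per unit growth in the core biomass reaction
GLUTAMATE_BIOMASS_COEFF = 0.0149
#: growth-associated ATP demand of the core biomass reaction (mmol/gDW)
BIOMASS_ATP_COEFF = 40.0


@dataclass
class GeneratorSpec:
    """Declarative description of a synthetic model."""

    seed: int = 0
    kind: str = "chain"  # "chain" | "glutamate_core"
    n_chain: int = 5
    uptake: float = 10.0
    #: each defect: {"kind": imbalance|dead_end|orphan|egc,
    #:               "count": int, "carrier": str}
    defects: List[Dict[str, object]] = field(default_factory=list)


def _chain_met_id(index: int) -> str:
    if index < len(ascii_uppercase):
        return ascii_uppercase[index]
    return f"M{index:03d}"


def make_linear_chain(n_chain: int = 5, uptake: float = 10.0) -> GemModel:
    """Linear pathway EX -> transport -> unit-stoichiometry chain -> biomass.

    The maximal growth rate equals the uptake bound: every unit of substrate
    flows through the chain unchanged (all coefficients 1).
    """
    if n_chain < 1:
        raise ValueError("n_chain must be >= 1")
    model = GemModel(id=f"chain{n_chain}", name=f"linear chain of {n_chain}")
    formula = "C6H12O6"  # one shared formula keeps every conversion balanced
    first = _chain_met_id(0)
    model.metabolites.append(Metabolite(
        id=f"{first}_e", name=f"substrate {first} (extracellular)",
        compartment="e", formula=formula, charge=0, sbo="SBO:0000247"))
    chain_ids = []
    for i in range(n_chain):
        mid = f"{_chain_met_id(i)}_c"
        chain_ids.append(mid)
        model.metabolites.append(Metabolite(
            id=mid, name=f"intermediate {_chain_met_id(i)}",
            compartment="c", formula=formula, charge=0, sbo="SBO:0000247"))

    model.reactions.append(Reaction(
        id=f"EX_{first}_e", name=f"{first} exchange",
        stoichiometry={f"{first}_e": -1.0},
        lower_bound=-uptake, upper_bound=1000.0, sbo=SBO_EXCHANGE))
    model.genes.append(Gene(id="g_tr", label="g_tr"))
    model.reactions.append(Reaction(
        id=f"T_{first}", name=f"{first} transport",
        stoichiometry={f"{first}_e": -1.0, f"{first}_c": 1.0},
        lower_bound=0.0, upper_bound=1000.0, gpr="g_tr", sbo=SBO_TRANSPORT))
    for i in range(n_chain - 1):
        gene = Gene(id=f"g{i + 1}", label=f"g{i + 1}")
        model.genes.append(gene)
        model.reactions.append(Reaction(
            id=f"R{i + 1}", name=f"step {chain_ids[i]} -> {chain_ids[i + 1]}",
            stoichiometry={chain_ids[i]: -1.0, chain_ids[i + 1]: 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=gene.id,
            sbo=SBO_BIOCHEMICAL))
    model.reactions.append(Reaction(
        id="BIOMASS", name="biomass drain",
        stoichiometry={chain_ids[-1]: -1.0},
        lower_bound=0.0, upper_bound=1000.0, sbo=SBO_BIOMASS))
    model.objective = "BIOMASS"
    model.groups = {"Chain": [f"R{i + 1}" for i in range(n_chain - 1)]}
    model.validate()
    return model


# (id, name, compartment, formula, charge)
_CORE_METS = [
    ("glc__D_e", "D-glucose", "e", "C6H12O6", 0),
    ("g6p_c", "D-glucose 6-phosphate", "c", "C6H11O9P", -2),
    ("pep_c", "phosphoenolpyruvate", "c", "C3H2O6P", -3),
    ("pyr_c", "pyruvate", "c", "C3H3O3", -1),
    ("oaa_c", "oxaloacetate", "c", "C4H2O5", -2),
    ("cit_c", "citrate", "c", "C6H5O7", -3),
    ("icit_c", "isocitrate", "c", "C6H5O7", -3),
    ("akg_c", "2-oxoglutarate", "c", "C5H4O5", -2),
    ("glu__L_c", "L-glutamate", "c", "C5H8NO4", -1),
    ("accoa_c", "acetyl-CoA", "c", "C23H34N7O17P3S", -4),
    ("coa_c", "coenzyme A", "c", "C21H32N7O16P3S", -4),
    ("ac_c", "acetate", "c", "C2H3O2", -1),
    ("ac_e", "acetate (extracellular)", "e", "C2H3O2", -1),
    ("atp_c", "ATP", "c", "C10H12N5O13P3", -4),
    ("adp_c", "ADP", "c", "C10H12N5O10P2", -3),
    ("pi_c", "phosphate", "c", "HO4P", -2),
    ("pi_e", "phosphate (extracellular)", "e", "HO4P", -2),
    ("nad_c", "NAD+", "c", "C21H26N7O14P2", -1),
    ("nadh_c", "NADH", "c", "C21H27N7O14P2", -2),
    ("nadp_c", "NADP+", "c", "C21H25N7O17P3", -3),
    ("nadph_c", "NADPH", "c", "C21H26N7O17P3", -4),
    ("nh4_c", "ammonium", "c", "H4N", 1),
    ("nh4_e", "ammonium (extracellular)", "e", "H4N", 1),
    ("co2_c", "CO2", "c", "CO2", 0),
    ("co2_e", "CO2 (extracellular)", "e", "CO2", 0),
    ("o2_c", "O2", "c", "O2", 0),
    ("o2_e", "O2 (extracellular)", "e", "O2", 0),
    ("h2o_c", "water", "c", "H2O", 0),
    ("h2o_e", "water (extracellular)", "e", "H2O", 0),
    ("h_c", "proton", "c", "H", 1),
    ("h_e", "proton (extracellular)", "e", "H", 1),
]

# (id, name, stoichiometry, lb, ub, gpr, sbo)
_CORE_RXNS = [
    ("EX_glc__D_e", "D-glucose exchange", {"glc__D_e": -1}, -10, 1000, None,
     SBO_EXCHANGE),
    ("EX_o2_e", "O2 exchange", {"o2_e": -1}, -1000, 1000, None, SBO_EXCHANGE),
    ("EX_co2_e", "CO2 exchange", {"co2_e": -1}, 0, 1000, None, SBO_EXCHANGE),
    ("EX_nh4_e", "ammonium exchange", {"nh4_e": -1}, -1000, 1000, None,
     SBO_EXCHANGE),
    ("EX_h_e", "proton exchange", {"h_e": -1}, -1000, 1000, None, SBO_EXCHANGE),
    ("EX_h2o_e", "water exchange", {"h2o_e": -1}, -1000, 1000, None,
     SBO_EXCHANGE),
    ("EX_pi_e", "phosphate exchange", {"pi_e": -1}, -1000, 1000, None,
     SBO_EXCHANGE),
    ("EX_ac_e", "acetate exchange", {"ac_e": -1}, 0, 1000, None, SBO_EXCHANGE),
    ("O2t", "O2 diffusion", {"o2_e": -1, "o2_c": 1}, -1000, 1000, None,
     SBO_TRANSPORT),
    ("CO2t", "CO2 diffusion", {"co2_c": -1, "co2_e": 1}, -1000, 1000, None,
     SBO_TRANSPORT),
    ("NH4t", "ammonium transport", {"nh4_e": -1, "nh4_c": 1}, -1000, 1000,
     None, SBO_TRANSPORT),
    ("H2Ot", "water diffusion", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000, None,
     SBO_TRANSPORT),
    ("Ht", "proton diffusion", {"h_e": -1, "h_c": 1}, -1000, 1000, None,
     SBO_TRANSPORT),
    ("PIt", "phosphate transport", {"pi_e": -1, "pi_c": 1}, -1000, 1000, None,
     SBO_TRANSPORT),
    ("ACt", "acetate export", {"ac_c": -1, "ac_e": 1}, 0, 1000, None,
     SBO_TRANSPORT),
    ("GLCpts", "D-glucose transport via PEP:Pyr",
     {"glc__D_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1}, 0, 1000, "ptsG",
     SBO_TRANSPORT),
    ("GLYC", "glycolysis (lumped, G6P to 2 PEP)",
     {"g6p_c": -1, "nad_c": -2, "adp_c": -1, "pi_c": -2,
      "pep_c": 2, "nadh_c": 2, "atp_c": 1, "h2o_c": 2, "h_c": 3},
     0, 1000, "gap and pgk and eno", SBO_BIOCHEMICAL),
    ("PYK", "pyruvate kinase",
     {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
     0, 1000, "pyk", SBO_BIOCHEMICAL),
    ("PPC", "phosphoenolpyruvate carboxylase",
     {"pep_c": -1, "co2_c": -1, "h2o_c": -1, "oaa_c": 1, "pi_c": 1, "h_c": 1},
     0, 1000, "ppc", SBO_BIOCHEMICAL),
    ("PC", "pyruvate carboxylase",
     {"pyr_c": -1, "co2_c": -1, "h2o_c": -1, "atp_c": -1,
      "oaa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2},
     0, 1000, "pyc", SBO_BIOCHEMICAL),
    ("PDH", "pyruvate dehydrogenase",
     {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
      "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
     0, 1000, "aceE and aceF and lpd", SBO_BIOCHEMICAL),
    ("CS", "citrate synthase",
     {"accoa_c": -1, "h2o_c": -1, "oaa_c": -1,
      "cit_c": 1, "coa_c": 1, "h_c": 1},
     0, 1000, "gltA", SBO_BIOCHEMICAL),
    ("ACONT", "aconitate hydratase", {"cit_c": -1, "icit_c": 1},
     -1000, 1000, "acn", SBO_BIOCHEMICAL),
    ("ICDHyr", "isocitrate dehydrogenase (NADP)",
     {"icit_c": -1, "nadp_c": -1, "akg_c": 1, "co2_c": 1, "nadph_c": 1},
     -1000, 1000, "icd", SBO_BIOCHEMICAL),
    ("GDH", "glutamate dehydrogenase (NADPH)",
     {"akg_c": -1, "nh4_c": -1, "nadph_c": -1, "h_c": -1,
      "glu__L_c": 1, "nadp_c": 1, "h2o_c": 1},
     0, 1000, "gdh", SBO_BIOCHEMICAL),
    ("ACK", "acetate overflow (phosphotransacetylase + acetate kinase)",
     {"accoa_c": -1, "adp_c": -1, "pi_c": -1,
      "ac_c": 1, "coa_c": 1, "atp_c": 1},
     0, 1000, "pta and ackA", SBO_BIOCHEMICAL),
    ("NADHOX", "NADH oxidation + oxidative phosphorylation (P/O = 2)",
     {"nadh_c": -1, "o2_c": -0.5, "h_c": -3, "adp_c": -2, "pi_c": -2,
      "nad_c": 1, "atp_c": 2, "h2o_c": 3},
     0, 1000, "ndh", SBO_BIOCHEMICAL),
    ("ATPM", "ATP maintenance",
     {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
     0, 1000, None, SBO_ATPM),
    ("BIOMASS", "biomass objective function",
     {"glu__L_c": -GLUTAMATE_BIOMASS_COEFF,
      "atp_c": -BIOMASS_ATP_COEFF, "h2o_c": -BIOMASS_ATP_COEFF,
      "adp_c": BIOMASS_ATP_COEFF, "pi_c": BIOMASS_ATP_COEFF,
      "h_c": BIOMASS_ATP_COEFF},
     0, 1000, None, SBO_BIOMASS),
]

_CORE_GROUPS = {
    "Glycolysis": ["GLCpts", "GLYC", "PYK"],
    "Anaplerosis": ["PPC", "PC"],
    "TCA cycle": ["CS", "ACONT", "ICDHyr"],
    "Glutamate synthesis": ["GDH"],
    "Oxidative phosphorylation": ["NADHOX"],
    "Overflow metabolism": ["ACK", "ACt"],
}


def make_glutamate_core() -> GemModel:
    """The fixed glutamate-producing core network.

    Key analytic properties (glucose uptake bound 10, unlimited oxygen):

    * one glutamate per glucose at most (the PEP:pyruvate pair from each
      glucose supplies exactly one oxaloacetate plus one acetyl-CoA);
    * ATP yield 7 per glucose routed to glutamate, 12 per glucose routed
      to the acetate overflow;
    * hence max glutamate production p(mu) = 10 - 0.0149*mu while ATP is
      not limiting (mu <= 1.75) and p(mu) = 24 - 8.0149*mu beyond, with
      mu_max = 24/8.0149;
    * the pyruvate-carboxylase knockout is fully compensated by PEP
      carboxylase, and knocking out both anaplerotic routes abolishes
      glutamate production.
    """
    model = GemModel(id="glutamate_core", name="glutamate-producing core")
    for mid, name, comp, formula, charge in _CORE_METS:
        model.metabolites.append(Metabolite(
            id=mid, name=name, compartment=comp, formula=formula,
            charge=charge, sbo="SBO:0000247"))
    genes = set()
    for rid, name, stoich, lb, ub, gpr, sbo in _CORE_RXNS:
        if gpr:
            for token in gpr.replace("(", " ").replace(")", " ").split():
                if token not in ("and", "or"):
                    genes.add(token)
        model.reactions.append(Reaction(
            id=rid, name=name,
            stoichiometry={k: float(v) for k, v in stoich.items()},
            lower_bound=float(lb), upper_bound=float(ub), gpr=gpr, sbo=sbo))
    model.genes = [Gene(id=g, label=g) for g in sorted(genes)]
    model.groups = {k: list(v) for k, v in _CORE_GROUPS.items()}
    for group, members in model.groups.items():
        for rid in members:
            model.reaction(rid).subsystems.append(group)
    model.objective = "BIOMASS"
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Defect planting
# ---------------------------------------------------------------------------

def _planted(model: GemModel) -> List[Dict[str, str]]:
    return model.notes.setdefault("planted_defects", [])  # type: ignore


def _pick_source(model: GemModel) -> Metabolite:
    for met in model.metabolites:
        if met.compartment == "c" and met.formula is not None \
                and parse_formula(met.formula).balanceable:
            return met
    raise ValueError("model has no cytosolic metabolite with a usable formula")


def plant_defect(model: GemModel, kind: str, count: int = 1,
                 carrier: str = "ATP") -> GemModel:
    """Return a copy of *model* with *count* defects of *kind* planted.

    Kinds: ``imbalance`` (a branch product whose formula is perturbed by
    one hydrogen, drained by a sink so only the planted reaction is
    flagged), ``dead_end``/``orphan`` (one-sided terminal branches), and
    ``egc`` (an internal reaction recharging *carrier* for free, i.e. the
    exact reverse of its dissipation reaction).  Planted entity ids are
    appended to ``notes["planted_defects"]``.
    """
    out = model.copy()
    for _ in range(count):
        index = len(_planted(out))
        if kind == "imbalance":
            src = _pick_source(out)
            tally = parse_formula(src.formula)
            perturbed = dict(tally.counts)
            perturbed["H"] = perturbed.get("H", 0) + 1
            new_met = Metabolite(
                id=f"imb{index}_c", name=f"planted imbalance product {index}",
                compartment="c",
                formula=format_formula(type(tally)(perturbed)),
                charge=src.charge)
            out.add_metabolite(new_met)
            rid = f"IMB{index}"
            out.add_reaction(Reaction(
                id=rid, name="planted imbalanced conversion",
                stoichiometry={src.id: -1.0, new_met.id: 1.0},
                lower_bound=0.0, upper_bound=1000.0, sbo=SBO_BIOCHEMICAL))
            out.add_reaction(Reaction(
                id=f"SK_imb{index}_c", name="drain for planted product",
                stoichiometry={new_met.id: -1.0},
                lower_bound=0.0, upper_bound=1000.0, sbo=SBO_SINK))
            _planted(out).append({"kind": kind, "reaction": rid,
                                  "metabolite": new_met.id})
        elif kind == "dead_end":
            src = _pick_source(out)
            new_met = Metabolite(
                id=f"dead{index}_c", name=f"planted dead end {index}",
                compartment="c", formula=src.formula, charge=src.charge)
            out.add_metabolite(new_met)
            rid = f"TO_DEAD{index}"
            out.add_reaction(Reaction(
                id=rid, name="planted producer of a never-consumed species",
                stoichiometry={src.id: -1.0, new_met.id: 1.0},
                lower_bound=0.0, upper_bound=1000.0, sbo=SBO_BIOCHEMICAL))
            _planted(out).append({"kind": kind, "reaction": rid,
                                  "metabolite": new_met.id})
        elif kind == "orphan":
            src = _pick_source(out)
            new_met = Metabolite(
                id=f"orph{index}_c", name=f"planted orphan {index}",
                compartment="c", formula=src.formula, charge=src.charge)
            out.add_metabolite(new_met)
            rid = f"FROM_ORPH{index}"
            out.add_reaction(Reaction(
                id=rid, name="planted consumer of a never-produced species",
                stoichiometry={new_met.id: -1.0, src.id: 1.0},
                lower_bound=0.0, upper_bound=1000.0, sbo=SBO_BIOCHEMICAL))
            _planted(out).append({"kind": kind, "reaction": rid,
                                  "metabolite": new_met.id})
        elif kind == "egc":
            recipe = DISSIPATION_RECIPES.get(carrier)
            if recipe is None:
                raise ValueError(f"unknown energy carrier {carrier!r}")
            missing = [m for m in recipe if not out.has_metabolite(m)]
            if missing:
                raise ValueError(
                    f"cannot plant {carrier} cycle: species {missing} absent")
            rid = f"EGC_{carrier}_{index}"
            out.add_reaction(Reaction(
                id=rid, name=f"planted free {carrier} recharging",
                stoichiometry={m: -float(c) for m, c in recipe.items()},
                lower_bound=0.0, upper_bound=1000.0, sbo=SBO_BIOCHEMICAL))
            _planted(out).append({"kind": kind, "reaction": rid,
                                  "carrier": carrier})
        else:
            raise ValueError(f"unknown defect kind {kind!r}")
    return out


def from_spec(spec: GeneratorSpec) -> GemModel:
    """Materialise a :class:`GeneratorSpec` (generation is deterministic)."""
    if spec.kind == "chain":
        model = make_linear_chain(n_chain=spec.n_chain, uptake=spec.uptake)
    elif spec.kind == "glutamate_core":
        model = make_glutamate_core()
    else:
        raise ValueError(f"unknown generator kind {spec.kind!r}")
    for defect in spec.defects:
        model = plant_defect(
            model, str(defect["kind"]),
            count=int(defect.get("count", 1)),
            carrier=str(defect.get("carrier", "ATP")))
    return model


def load_spec(path: str) -> GeneratorSpec:
    """Read a GeneratorSpec from YAML."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    return GeneratorSpec(
        seed=int(raw.get("seed", 0)),
        kind=raw.get("kind", "chain"),
        n_chain=int(raw.get("n_chain", 5)),
        uptake=float(raw.get("uptake", 10.0)),
        defects=list(raw.get("defects", [])),
    )
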
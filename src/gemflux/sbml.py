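"""SBML Level 3 Version 1 I/O with the fbc (v2) and groups (v1) packages.

Flux bounds are serialised as constant model parameters in
mmol gDW^-1 h^-1, the model element declares ``extentUnits``/``timeUnits``
(and ``substanceUnits`` mmol gDW^-1, ``volumeUnits`` fl), GPR rules become
fbc gene-product associations, and subsystems become groups with reaction
members.  Missing chemical formulas and charges round-trip as absent, never
as zero.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional

import libsbml

from .model import (
    COMPARTMENT_NAMES,
    Gene,
    GemModel,
    GprNode,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    Units,
    parse_gpr,
)

__all__ = ["read_sbml", "write_sbml", "SbmlParseError"]


class SbmlParseError(ValueError):
    """Malformed SBML input; message carries line information."""


_SID_CLEAN = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, prefix: str = "") -> str:
    sid = _SID_CLEAN.sub("_", raw)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "_" + sid
    return prefix + sid


def _strip(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _check(status, what: str) -> None:
    if status is None:
        raise RuntimeError(f"libsbml returned None while {what}")
    if isinstance(status, int) and status != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {status} while {what}")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _add_units(model: libsbml.Model) -> None:
    """Declare mmol gDW^-1 (substance/extent), hour (time) and fl (volume)."""
    substance = model.createUnitDefinition()
    substance.setId("mmol_per_gDW")
    for kind, exp, scale in ((libsbml.UNIT_KIND_MOLE, 1, -3),
                             (libsbml.UNIT_KIND_GRAM, -1, 0)):
        u = substance.createUnit()
        u.setKind(kind)
        u.setExponent(exp)
        u.setScale(scale)
        u.setMultiplier(1.0)
    hour = model.createUnitDefinition()
    hour.setId("hr")
    u = hour.createUnit()
    u.setKind(libsbml.UNIT_KIND_SECOND)
    u.setExponent(1)
    u.setScale(0)
    u.setMultiplier(3600.0)
    flux = model.createUnitDefinition()
    flux.setId("mmol_per_gDW_per_hr")
    for kind, exp, scale, mult in ((libsbml.UNIT_KIND_MOLE, 1, -3, 1.0),
                                   (libsbml.UNIT_KIND_GRAM, -1, 0, 1.0),
                                   (libsbml.UNIT_KIND_SECOND, -1, 0, 3600.0)):
        u = flux.createUnit()
        u.setKind(kind)
        u.setExponent(exp)
        u.setScale(scale)
        u.setMultiplier(mult)
    femto = model.createUnitDefinition()
    femto.setId("fl")
    u = femto.createUnit()
    u.setKind(libsbml.UNIT_KIND_LITRE)
    u.setExponent(1)
    u.setScale(-15)
    u.setMultiplier(1.0)
    model.setSubstanceUnits("mmol_per_gDW")
    model.setExtentUnits("mmol_per_gDW")
    model.setTimeUnits("hr")
    model.setVolumeUnits("fl")


def _annotate(node, meta_id: str, annotations: Dict[str, List[str]]) -> None:
    if not annotations:
        return
    node.setMetaId(meta_id)
    cv = libsbml.CVTerm()
    cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
    cv.setBiologicalQualifierType(libsbml.BQB_IS)
    for db, ids in sorted(annotations.items()):
        for ident in ids:
            cv.addResource(f"https://identifiers.org/{db}/{ident}")
    node.addCVTerm(cv)


def _set_sbo(node, sbo: Optional[str]) -> None:
    if sbo:
        node.setSBOTerm(sbo)


def _build_association(parent, node: GprNode) -> None:
    """Recursively build an fbc association tree under *parent*."""
    if isinstance(node, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_sid(node, "G_"))
        return
    op, children = node
    sub = parent.createAnd() if op == "and" else parent.createOr()
    for child in children:
        _build_association(sub, child)


def write_sbml(model: GemModel, path: str) -> None:
    """Serialise *model* to an SBML L3V1 file with fbc v2 and groups v1."""
    model.validate()

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)

    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    if model.name:
        sbml_model.setName(model.name)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)
    _add_units(sbml_model)

    compartments = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setName(COMPARTMENT_NAMES.get(comp, comp))
        c.setConstant(True)
        c.setSize(1.0)
        c.setSpatialDimensions(3)
        c.setUnits("fl")

    for met in model.metabolites:
        s = sbml_model.createSpecies()
        s.setId(_sid(met.id, "M_"))
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(True)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        s.setSubstanceUnits("mmol_per_gDW")
        splug = s.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        _set_sbo(s, met.sbo)
        _annotate(s, _sid(met.id, "meta_M_"), met.annotations)

    # one shared constant parameter per distinct bound value
    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            p.setUnits("mmol_per_gDW_per_hr")
            p.setSBOTerm("SBO:0000626")
            bound_params[value] = pid
        return bound_params[value]

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid(gene.id, "G_"))
        gp.setLabel(gene.label or gene.id)
        _set_sbo(gp, gene.sbo)

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(_sid(rxn.id, "R_"))
        r.setName(rxn.name or rxn.id)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            sr = r.createReactant() if coeff < 0 else r.createProduct()
            sr.setSpecies(_sid(met_id, "M_"))
            sr.setStoichiometry(abs(coeff))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            _build_association(gpa, parse_gpr(rxn.gpr))
        _set_sbo(r, rxn.sbo)
        _annotate(r, _sid(rxn.id, "meta_R_"), rxn.annotations)

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(model.objective, "R_"))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    gplug = sbml_model.getPlugin("groups")
    for idx, (name, members) in enumerate(model.groups.items()):
        grp = gplug.createGroup()
        grp.setId(f"group_{idx}")
        grp.setName(name)
        grp.setKind("partonomy")
        for rid in members:
            member = grp.createMember()
            member.setIdRef(_sid(rid, "R_"))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_IDENTIFIERS_URI = re.compile(
    r"identifiers\.org/(?:([^/:]+)[:/])?(.+)$"
)


def _read_annotations(node) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    for i in range(node.getNumCVTerms()):
        cv = node.getCVTerm(i)
        for j in range(cv.getNumResources()):
            uri = cv.getResourceURI(j)
            m = _IDENTIFIERS_URI.search(uri)
            if not m:
                continue
            db, ident = m.group(1), m.group(2)
            if db is None:
                # miriam-style "db:id" tail
                if ":" in ident:
                    db, ident = ident.split(":", 1)
                else:
                    continue
            out.setdefault(db, []).append(ident)
    return out


def _read_sbo(node) -> Optional[str]:
    if node.isSetSBOTerm():
        return node.getSBOTermID()
    return None


def _association_to_gpr(assoc) -> str:
    if assoc is None:
        raise SbmlParseError("empty gene-product association")
    type_code = assoc.getTypeCode()
    if type_code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return _strip(assoc.getGeneProduct(), "G_")
    if type_code == libsbml.SBML_FBC_AND:
        parts = [_association_to_gpr(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if type_code == libsbml.SBML_FBC_OR:
        parts = [_association_to_gpr(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise SbmlParseError(f"unsupported association type code {type_code}")


def read_sbml(path: str) -> GemModel:
    """Parse an SBML L3V1 + fbc file into a fully linked :class:`GemModel`.

    Raises :class:`SbmlParseError` on malformed XML (with line numbers) and
    :class:`ModelIntegrityError` when cross-references do not resolve or a
    reaction lacks its flux-bound parameters.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    errors = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if errors:
        raise SbmlParseError("; ".join(errors))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SbmlParseError(f"no model element in {path}")

    model = GemModel(id=sbml_model.getId() or "model",
                     name=sbml_model.getName() or "",
                     units=Units())

    comp_suffix: Dict[str, str] = {}
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        cid = comp.getId()
        comp_suffix[cid] = _strip(cid, "C_")[-1] if cid else "c"

    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        splug = s.getPlugin("fbc")
        charge = None
        formula = None
        if splug is not None:
            if splug.isSetCharge():
                charge = splug.getCharge()
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
        model.metabolites.append(Metabolite(
            id=_strip(s.getId(), "M_"),
            name=s.getName() or "",
            compartment=comp_suffix.get(s.getCompartment(), "c"),
            formula=formula,
            charge=charge,
            annotations=_read_annotations(s),
            sbo=_read_sbo(s),
        ))

    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            model.genes.append(Gene(
                id=_strip(gp.getId(), "G_"),
                label=gp.getLabel() or "",
                annotations=_read_annotations(gp),
                sbo=_read_sbo(gp),
            ))

    species_ids = {m.id for m in model.metabolites}
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rid = _strip(r.getId(), "R_")
        stoich: Dict[str, float] = {}
        for refs, sign in ((r.getListOfReactants(), -1.0),
                           (r.getListOfProducts(), +1.0)):
            for j in range(refs.size()):
                sr = refs.get(j)
                mid = _strip(sr.getSpecies(), "M_")
                if mid not in species_ids:
                    raise ModelIntegrityError(
                        f"reaction {rid!r} references species "
                        f"{sr.getSpecies()!r} not in listOfSpecies"
                    )
                stoich[mid] = stoich.get(mid, 0.0) + sign * sr.getStoichiometry()
        rplug = r.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound() \
                or not rplug.isSetUpperFluxBound():
            raise ModelIntegrityError(
                f"reaction {rid!r} lacks fbc flux-bound attributes"
            )
        bounds = []
        for pid in (rplug.getLowerFluxBound(), rplug.getUpperFluxBound()):
            param = sbml_model.getParameter(pid)
            if param is None or not param.isSetValue():
                raise ModelIntegrityError(
                    f"reaction {rid!r}: flux-bound parameter {pid!r} missing"
                )
            bounds.append(param.getValue())
        gpr = None
        if rplug.isSetGeneProductAssociation():
            gpr = _association_to_gpr(
                rplug.getGeneProductAssociation().getAssociation())
        model.reactions.append(Reaction(
            id=rid,
            name=r.getName() or "",
            stoichiometry=stoich,
            lower_bound=bounds[0],
            upper_bound=bounds[1],
            gpr=gpr,
            sbo=_read_sbo(r),
            annotations=_read_annotations(r),
        ))

    if mplug is not None:
        obj = mplug.getActiveObjective() or (
            mplug.getObjective(0) if mplug.getNumObjectives() else None)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective = _strip(obj.getFluxObjective(0).getReaction(), "R_")

    gplug = sbml_model.getPlugin("groups")
    if gplug is not None:
        rxn_index = {rx.id: rx for rx in model.reactions}
        for i in range(gplug.getNumGroups()):
            grp = gplug.getGroup(i)
            name = grp.getName() or grp.getId()
            members = []
            for j in range(grp.getNumMembers()):
                ref = grp.getMember(j).getIdRef()
                members.append(_strip(ref, "R_"))
            model.groups[name] = members
            for rid in members:
                rxn = rxn_index.get(rid)
                if rxn is not None and name not in rxn.subsystems:
                    rxn.subsystems.append(name)

    model.validate()
    return model
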
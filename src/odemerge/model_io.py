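"""SBML reading, writing and structural validation (libsbml-backed).

Supports SBML Level 2 and Level 3 core.  Constructs outside the plain
kinetic-ODE scope (events, algebraic/rate/assignment rules, delays,
piecewise laws) are rejected with an explicit "unsupported construct"
error rather than silently ignored.  Reaction-local parameters are
globalized as ``<reaction id>__<parameter id>`` at load time so a merge
policy can address every parameter uniformly.
"""

from __future__ import annotations

import math
import os

import libsbml

from odemerge.expr import ExpressionError, expr_symbols, parse_expr, rename_symbols
from odemerge.model import (
    Compartment,
    KineticModel,
    Parameter,
    Reaction,
    Species,
    ValidationIssue,
    ValidationReport,
)


class ModelIOError(ValueError):
    pass


class NonSBMLError(ModelIOError):
    pass


class UnsupportedConstructError(ModelIOError):
    pass


_BASE_KIND_FACTORS = {
    libsbml.UNIT_KIND_MOLE: ("mole", 1.0),
    libsbml.UNIT_KIND_SECOND: ("second", 1.0),
    libsbml.UNIT_KIND_LITRE: ("litre", 1.0),
    libsbml.UNIT_KIND_LITER: ("litre", 1.0),
    libsbml.UNIT_KIND_ITEM: ("item", 1.0),
    libsbml.UNIT_KIND_DIMENSIONLESS: ("dimensionless", 1.0),
    libsbml.UNIT_KIND_GRAM: ("gram", 1.0),
}


def load_model(path: str) -> KineticModel:
    """Read an SBML Level 2/3 file into a :class:`KineticModel`.

    Raises :class:`NonSBMLError` for files that are not SBML and
    :class:`UnsupportedConstructError` for models using constructs this
    workflow cannot simulate.
    """
    if not os.path.exists(path):
        raise ModelIOError(f"unreadable file: {path!r} does not exist")
    doc = libsbml.readSBMLFromFile(path)
    if doc.getModel() is None:
        raise NonSBMLError(f"non-SBML content in {path!r}")
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR and doc.getModel() is None:
            raise NonSBMLError(f"non-SBML content in {path!r}: {err.getMessage()}")

    _expand_definitions(doc)
    sbml_model = doc.getModel()
    _reject_unsupported(sbml_model)

    model = KineticModel(
        model_id=sbml_model.getId() or os.path.splitext(os.path.basename(path))[0],
        name=sbml_model.getName() or "",
    )
    model.unit_definitions = _read_units(sbml_model, model.notes)

    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        size = c.getSize() if c.isSetSize() else 1.0
        if math.isnan(size):
            size = 1.0
        model.compartments.append(
            Compartment(
                id=c.getId(),
                size=size,
                name=c.getName() or "",
                constant=c.getConstant() if c.isSetConstant() else True,
                cv_uris=_cv_uris(c),
                sbo_term=_sbo(c),
            )
        )

    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        if s.isSetInitialConcentration():
            init = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            init = s.getInitialAmount()
        else:
            init = 0.0
        if math.isnan(init):
            init = 0.0
        model.species.append(
            Species(
                id=s.getId(),
                compartment=s.getCompartment(),
                initial_amount=init,
                name=s.getName() or "",
                boundary=s.getBoundaryCondition(),
                constant=s.getConstant(),
                substance_only=s.getHasOnlySubstanceUnits(),
                cv_uris=_cv_uris(s),
                sbo_term=_sbo(s),
            )
        )

    for i in range(sbml_model.getNumParameters()):
        p = sbml_model.getParameter(i)
        model.parameters.append(
            Parameter(
                id=p.getId(),
                value=p.getValue() if p.isSetValue() else 0.0,
                name=p.getName() or "",
                units=p.getUnits() or None,
                cv_uris=_cv_uris(p),
                sbo_term=_sbo(p),
            )
        )

    for i in range(sbml_model.getNumReactions()):
        model.reactions.append(_read_reaction(sbml_model.getReaction(i), model))

    return model


def _read_reaction(r, model: KineticModel) -> Reaction:
    rid = r.getId()
    reactants = [
        (sr.getSpecies(), sr.getStoichiometry() if sr.isSetStoichiometry() else 1.0)
        for sr in (r.getReactant(j) for j in range(r.getNumReactants()))
    ]
    products = [
        (sr.getSpecies(), sr.getStoichiometry() if sr.isSetStoichiometry() else 1.0)
        for sr in (r.getProduct(j) for j in range(r.getNumProducts()))
    ]
    modifiers = [r.getModifier(j).getSpecies() for j in range(r.getNumModifiers())]

    kl = r.getKineticLaw()
    if kl is None or kl.getMath() is None:
        law = "0"
    else:
        law = libsbml.formulaToL3String(kl.getMath())
        # globalize local parameters
        rename = {}
        for j in range(kl.getNumParameters()):
            lp = kl.getParameter(j)
            gid = f"{rid}__{lp.getId()}"
            rename[lp.getId()] = gid
            model.parameters.append(
                Parameter(
                    id=gid,
                    value=lp.getValue() if lp.isSetValue() else 0.0,
                    name=lp.getName() or "",
                    units=lp.getUnits() or None,
                    scope=rid,
                )
            )
        if hasattr(kl, "getNumLocalParameters"):
            for j in range(kl.getNumLocalParameters()):
                lp = kl.getLocalParameter(j)
                if lp.getId() in rename:
                    continue
                gid = f"{rid}__{lp.getId()}"
                rename[lp.getId()] = gid
                model.parameters.append(
                    Parameter(
                        id=gid,
                        value=lp.getValue() if lp.isSetValue() else 0.0,
                        name=lp.getName() or "",
                        units=lp.getUnits() or None,
                        scope=rid,
                    )
                )
        law = rename_symbols(law, rename)
    try:
        parse_expr(law)
    except ExpressionError as exc:
        raise UnsupportedConstructError(
            f"unsupported construct in kinetic law of reaction {rid!r}: {exc}"
        ) from exc
    return Reaction(
        id=rid,
        reactants=reactants,
        products=products,
        modifiers=modifiers,
        kinetic_law=law,
        name=r.getName() or "",
        reversible=r.getReversible() if r.isSetReversible() else False,
        cv_uris=_cv_uris(r),
        sbo_term=_sbo(r),
    )


def _expand_definitions(doc) -> None:
    """Inline function definitions and initial assignments where possible."""
    model = doc.getModel()
    if model.getNumFunctionDefinitions():
        props = libsbml.ConversionProperties()
        props.addOption("expandFunctionDefinitions", True)
        doc.convert(props)
    if doc.getModel().getNumInitialAssignments():
        props = libsbml.ConversionProperties()
        props.addOption("expandInitialAssignments", True)
        doc.convert(props)


def _reject_unsupported(model) -> None:
    if model.getNumEvents():
        raise UnsupportedConstructError("unsupported construct: event")
    if model.getNumConstraints():
        raise UnsupportedConstructError("unsupported construct: constraint")
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        kind = {
            libsbml.SBML_ALGEBRAIC_RULE: "algebraic rule",
            libsbml.SBML_RATE_RULE: "rate rule",
            libsbml.SBML_ASSIGNMENT_RULE: "assignment rule",
        }.get(rule.getTypeCode(), "rule")
        raise UnsupportedConstructError(f"unsupported construct: {kind}")
    if model.getNumInitialAssignments():
        raise UnsupportedConstructError(
            "unsupported construct: initial assignment (not numerically expandable)"
        )


def _cv_uris(element) -> tuple:
    uris = []
    for i in range(element.getNumCVTerms()):
        term = element.getCVTerm(i)
        if term.getQualifierType() == libsbml.BIOLOGICAL_QUALIFIER:
            qual = libsbml.BiolQualifierType_toString(term.getBiologicalQualifierType())
        elif term.getQualifierType() == libsbml.MODEL_QUALIFIER:
            qual = libsbml.ModelQualifierType_toString(term.getModelQualifierType())
        else:
            qual = "unknown"
        for j in range(term.getNumResources()):
            uris.append((qual or "unknown", term.getResourceURI(j)))
    return tuple(uris)


def _sbo(element):
    return element.getSBOTerm() if element.isSetSBOTerm() else None


def _read_units(sbml_model, notes: list) -> dict:
    units = {}
    roles = {
        "substance": sbml_model.getSubstanceUnits()
        if hasattr(sbml_model, "getSubstanceUnits") and sbml_model.isSetSubstanceUnits()
        else "substance",
        "time": sbml_model.getTimeUnits()
        if hasattr(sbml_model, "getTimeUnits") and sbml_model.isSetTimeUnits()
        else "time",
        "volume": sbml_model.getVolumeUnits()
        if hasattr(sbml_model, "getVolumeUnits") and sbml_model.isSetVolumeUnits()
        else "volume",
    }
    for role, ref in roles.items():
        resolved = _resolve_unit(sbml_model, ref)
        if resolved is None:
            notes.append(f"no {role!r} unit declared; assuming SBML default")
        else:
            units[role] = resolved
    return units


def _resolve_unit(sbml_model, ref: str):
    """Resolve a unit reference to (kind, factor-to-SI) or None."""
    udef = sbml_model.getUnitDefinition(ref)
    if udef is not None and udef.getNumUnits() == 1:
        u = udef.getUnit(0)
        base = _BASE_KIND_FACTORS.get(u.getKind())
        if base is None:
            return None
        kind, f = base
        mult = u.getMultiplier() if u.isSetMultiplier() else 1.0
        scale = u.getScale() if u.isSetScale() else 0
        exp = u.getExponent() if u.isSetExponent() else 1
        if exp != 1:
            return None
        return kind, f * mult * (10.0**scale)
    simple = {
        "mole": ("mole", 1.0),
        "second": ("second", 1.0),
        "litre": ("litre", 1.0),
        "liter": ("litre", 1.0),
        "item": ("item", 1.0),
        "dimensionless": ("dimensionless", 1.0),
    }
    return simple.get(ref)


# ---------------------------------------------------------------------------
# writing


def write_model(model: KineticModel, path: str) -> None:
    """Serialize a :class:`KineticModel` to SBML Level 3 Version 1."""
    doc = libsbml.SBMLDocument(3, 1)
    m = doc.createModel()
    m.setId(model.model_id)
    if model.name:
        m.setName(model.name)

    for role, (kind, factor) in (model.unit_definitions or {}).items():
        udef = m.createUnitDefinition()
        udef.setId(f"{role}_unit")
        u = udef.createUnit()
        u.setKind(libsbml.UnitKind_forName(kind if kind != "litre" else "litre"))
        u.setExponent(1)
        u.setScale(0)
        u.setMultiplier(factor)
        if role == "substance":
            m.setSubstanceUnits(udef.getId())
        elif role == "time":
            m.setTimeUnits(udef.getId())
        elif role == "volume":
            m.setVolumeUnits(udef.getId())

    for comp in model.compartments:
        c = m.createCompartment()
        c.setId(comp.id)
        if comp.name:
            c.setName(comp.name)
        c.setSize(comp.size)
        c.setConstant(comp.constant)
        c.setSpatialDimensions(3)
        _write_semantics(c, comp)

    for sp in model.species:
        s = m.createSpecies()
        s.setId(sp.id)
        if sp.name:
            s.setName(sp.name)
        s.setCompartment(sp.compartment)
        if sp.substance_only:
            s.setInitialAmount(sp.initial_amount)
        else:
            s.setInitialConcentration(sp.initial_amount)
        s.setBoundaryCondition(sp.boundary)
        s.setConstant(sp.constant)
        s.setHasOnlySubstanceUnits(sp.substance_only)
        _write_semantics(s, sp)

    for par in model.parameters:
        p = m.createParameter()
        p.setId(par.id)
        if par.name:
            p.setName(par.name)
        p.setValue(par.value)
        p.setConstant(True)
        _write_semantics(p, par)

    for rxn in model.reactions:
        r = m.createReaction()
        r.setId(rxn.id)
        if rxn.name:
            r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for sid, stoich in rxn.reactants:
            sr = r.createReactant()
            sr.setSpecies(sid)
            sr.setStoichiometry(stoich)
            sr.setConstant(True)
        for sid, stoich in rxn.products:
            sr = r.createProduct()
            sr.setSpecies(sid)
            sr.setStoichiometry(stoich)
            sr.setConstant(True)
        for sid in rxn.modifiers:
            mod = r.createModifier()
            mod.setSpecies(sid)
        kl = r.createKineticLaw()
        math_ast = libsbml.parseL3Formula(rxn.kinetic_law.replace("**", "^"))
        if math_ast is None:
            raise ModelIOError(
                f"cannot serialize kinetic law of reaction {rxn.id!r}: "
                f"{rxn.kinetic_law!r}"
            )
        kl.setMath(math_ast)
        _write_semantics(r, rxn)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, path):
        raise ModelIOError(f"failed to write SBML to {path!r}")


def _write_semantics(sbase, element) -> None:
    if element.sbo_term is not None:
        sbase.setSBOTerm(int(element.sbo_term))
    if element.cv_uris:
        sbase.setMetaId(f"meta_{element.id}")
        by_qual = {}
        for qual, uri in element.cv_uris:
            by_qual.setdefault(qual, []).append(uri)
        for qual, uris in by_qual.items():
            term = libsbml.CVTerm()
            bq = libsbml.BiolQualifierType_fromString(qual)
            if bq != libsbml.BQB_UNKNOWN:
                term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
                term.setBiologicalQualifierType(bq)
            else:
                mq = libsbml.ModelQualifierType_fromString(qual)
                term.setQualifierType(libsbml.MODEL_QUALIFIER)
                term.setModelQualifierType(mq)
            for uri in uris:
                term.addResource(uri)
            sbase.addCVTerm(term)


# ---------------------------------------------------------------------------
# validation


def validate_model(model: KineticModel) -> ValidationReport:
    """Structural validation: duplicate ids, dangling references, missing
    kinetic laws, negative initial amounts, non-positive stoichiometries.

    Problems are reported, never raised.
    """
    report = ValidationReport()
    seen = set()
    for element in model.elements():
        if element.id in seen:
            report.issues.append(
                ValidationIssue("error", f"duplicate id {element.id!r}", element.id)
            )
        seen.add(element.id)

    comp_ids = {c.id for c in model.compartments}
    species_ids = {s.id for s in model.species}
    declared = model.all_ids()

    for sp in model.species:
        if sp.compartment not in comp_ids:
            report.issues.append(
                ValidationIssue(
                    "error",
                    f"species {sp.id!r} references undeclared compartment "
                    f"{sp.compartment!r}",
                    sp.id,
                )
            )
        if sp.initial_amount < 0:
            report.issues.append(
                ValidationIssue(
                    "error", f"species {sp.id!r} has negative initial amount", sp.id
                )
            )

    for rxn in model.reactions:
        for sid, stoich in rxn.reactants + rxn.products:
            if sid not in species_ids:
                report.issues.append(
                    ValidationIssue(
                        "error",
                        f"reaction {rxn.id!r} references undeclared species {sid!r}",
                        rxn.id,
                    )
                )
            if stoich <= 0:
                report.issues.append(
                    ValidationIssue(
                        "error",
                        f"reaction {rxn.id!r} has non-positive stoichiometry for {sid!r}",
                        rxn.id,
                    )
                )
        for sid in rxn.modifiers:
            if sid not in species_ids:
                report.issues.append(
                    ValidationIssue(
                        "error",
                        f"reaction {rxn.id!r} references undeclared modifier {sid!r}",
                        rxn.id,
                    )
                )
        if not rxn.kinetic_law or rxn.kinetic_law == "0":
            report.issues.append(
                ValidationIssue(
                    "error", f"reaction {rxn.id!r} has no kinetic law", rxn.id
                )
            )
            continue
        try:
            symbols = expr_symbols(rxn.kinetic_law)
            parse_expr(rxn.kinetic_law)
        except ExpressionError as exc:
            report.issues.append(ValidationIssue("error", str(exc), rxn.id))
            continue
        for sym in sorted(symbols - declared):
            report.issues.append(
                ValidationIssue(
                    "error",
                    f"kinetic law of reaction {rxn.id!r} references undeclared "
                    f"symbol {sym!r}",
                    rxn.id,
                )
            )
    return report
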
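"""Unit harmonization between two models.

Only the three unit roles that matter for a kinetic ODE model are tracked:
``substance``, ``time`` and ``volume``.  Each role is represented as
``(kind, factor)`` where ``factor`` converts one model unit into the SI
reference unit of its kind (mole, second, litre).  Harmonization rescales
model B's quantities into model A's unit system and logs every factor.

Kinetic laws are interpreted as concentration change per time.  Parameter
rescaling therefore uses dimensional analysis of mass-action terms: in a
term ``k * S1^a * S2^b ...`` of total species order ``n`` the rate constant
converts with ``f_conc**(1 - n) / f_time``.  Laws that are not sums of
single-parameter mass-action monomials cannot be converted automatically
and raise an error naming the reaction (unless no conversion is needed).
"""

from __future__ import annotations

import sympy

from odemerge.expr import ExpressionError, parse_expr

#: (kind, factor to SI unit of that kind)
DEFAULT_UNITS = {
    "substance": ("mole", 1.0),
    "time": ("second", 1.0),
    "volume": ("litre", 1.0),
}


class UnitConversionError(ValueError):
    pass


def unit_factors(model) -> dict:
    out = dict(DEFAULT_UNITS)
    out.update(model.unit_definitions or {})
    return out


def harmonize_units(model_a, model_b):
    """Rescale model B into model A's unit system.

    Returns ``(model_a, model_b', log)``; both models are returned unchanged
    (same objects, empty log) when the unit systems already agree.
    """
    ua, ub = unit_factors(model_a), unit_factors(model_b)
    factors = {}
    for role in ("substance", "time", "volume"):
        kind_a, fa = ua[role]
        kind_b, fb = ub[role]
        if kind_a != kind_b:
            raise UnitConversionError(
                f"non-convertible {role} units: model {model_a.model_id!r} uses "
                f"{kind_a!r}, model {model_b.model_id!r} uses {kind_b!r}"
            )
        factors[role] = fb / fa
    f_sub, f_time, f_vol = factors["substance"], factors["time"], factors["volume"]
    f_conc = f_sub / f_vol
    if f_sub == f_time == f_vol == 1.0:
        return model_a, model_b, []

    log = []
    converted = model_b.copy()
    converted.unit_definitions = dict(ua)

    for comp in converted.compartments:
        if f_vol != 1.0:
            comp.size *= f_vol
            log.append({"element": comp.id, "role": "volume", "factor": f_vol})
    for sp in converted.species:
        f = f_sub if sp.substance_only else f_conc
        if f != 1.0 and sp.initial_amount != 0.0:
            sp.initial_amount *= f
            log.append({"element": sp.id, "role": "initial_amount", "factor": f})

    if f_conc != 1.0 or f_time != 1.0:
        _convert_rate_constants(converted, f_conc, f_time, log)
    return model_a, converted, log


def _convert_rate_constants(model, f_conc: float, f_time: float, log: list) -> None:
    species = set(model.species_ids())
    pids = set(model.parameter_ids())
    wanted = {}  # parameter id -> required factor
    for reaction in model.reactions:
        try:
            expr = sympy.expand(parse_expr(reaction.kinetic_law))
        except ExpressionError as exc:
            raise UnitConversionError(
                f"cannot convert units of reaction {reaction.id!r}: {exc}"
            ) from exc
        terms = expr.as_ordered_terms() if expr != 0 else []
        for term in terms:
            factor = _term_factor(term, species, pids, f_conc, f_time, reaction.id)
            pid, f = factor
            if pid in wanted and not _close(wanted[pid], f):
                raise UnitConversionError(
                    f"parameter {pid!r} appears with inconsistent dimensions; "
                    "cannot convert units automatically"
                )
            wanted[pid] = f
    for pid, f in wanted.items():
        if f != 1.0:
            p = model.get_parameter(pid)
            p.value *= f
            log.append({"element": pid, "role": "rate_constant", "factor": f})


def _term_factor(term, species, pids, f_conc, f_time, rid):
    """Dimensional factor for one mass-action monomial."""
    order = 0
    params = []
    for factor in sympy.Mul.make_args(term):
        base, exponent = factor.as_base_exp()
        if base.is_Symbol:
            name = str(base)
            if name in species:
                if not (exponent.is_integer and exponent >= 0):
                    raise UnitConversionError(
                        f"reaction {rid!r}: non-integer species order in kinetic law; "
                        "cannot convert units automatically"
                    )
                order += int(exponent)
            elif name in pids:
                if exponent != 1:
                    raise UnitConversionError(
                        f"reaction {rid!r}: parameter {name!r} enters nonlinearly; "
                        "cannot convert units automatically"
                    )
                params.append(name)
            # compartment sizes and unknown symbols fall through to validation
        elif not factor.is_Number:
            raise UnitConversionError(
                f"reaction {rid!r}: kinetic law is not mass action; "
                "cannot convert units automatically"
            )
    if len(params) != 1:
        raise UnitConversionError(
            f"reaction {rid!r}: expected exactly one rate constant per term, "
            f"found {len(params)}; cannot convert units automatically"
        )
    return params[0], f_conc ** (1 - order) / f_time


def _close(a: float, b: float, rel: float = 1e-12) -> bool:
    return abs(a - b) <= rel * max(abs(a), abs(b))
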
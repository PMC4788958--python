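"""Core in-memory representation of a kinetic ODE model.

A :class:`KineticModel` is a plain, library-independent container holding
everything needed to simulate the model: species, reactions with kinetic-law
expressions, parameters (reaction-local parameters are globalized at load
time), compartments and the unit system.  Kinetic laws are stored as
expression strings over declared identifiers and are parsed with sympy on
demand (see :mod:`odemerge.expr`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

from odemerge.expr import expr_symbols


@dataclass
class Parameter:
    """A scalar constant of the model.

    ``scope`` is ``"global"`` for model-level parameters, otherwise the id of
    the reaction the parameter was local to before globalization.
    """

    id: str
    value: float
    name: str = ""
    units: Optional[str] = None
    scope: str = "global"
    cv_uris: tuple = ()
    sbo_term: Optional[int] = None


@dataclass
class Compartment:
    id: str
    size: float = 1.0
    name: str = ""
    units: Optional[str] = None
    constant: bool = True
    cv_uris: tuple = ()
    sbo_term: Optional[int] = None


@dataclass
class Species:
    """A chemical species; ``initial_amount`` is in the model's concentration
    units unless ``substance_only`` is set."""

    id: str
    compartment: str
    initial_amount: float = 0.0
    name: str = ""
    boundary: bool = False
    constant: bool = False
    substance_only: bool = False
    cv_uris: tuple = ()
    sbo_term: Optional[int] = None


@dataclass
class Reaction:
    id: str
    reactants: list = field(default_factory=list)  # (species_id, stoichiometry)
    products: list = field(default_factory=list)  # (species_id, stoichiometry)
    modifiers: list = field(default_factory=list)  # species_id
    kinetic_law: str = "0"
    name: str = ""
    reversible: bool = False
    cv_uris: tuple = ()
    sbo_term: Optional[int] = None

    def species_refs(self) -> set:
        refs = {s for s, _ in self.reactants}
        refs |= {s for s, _ in self.products}
        refs |= set(self.modifiers)
        return refs


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str
    element: str = ""


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list:
        return [i for i in self.issues if i.severity == "error"]

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "issues": [
                {"severity": i.severity, "message": i.message, "element": i.element}
                for i in self.issues
            ],
        }


@dataclass
class KineticModel:
    """Parsed ODE model: everything needed for simulation.

    ``unit_definitions`` maps the roles ``substance`` / ``time`` / ``volume``
    to canonical conversion factors relative to SI reference units
    (mole, second, litre); see :mod:`odemerge.units`.
    """

    model_id: str
    species: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    parameters: list = field(default_factory=list)
    compartments: list = field(default_factory=list)
    unit_definitions: dict = field(default_factory=dict)
    name: str = ""
    notes: list = field(default_factory=list)
    input_ids: Optional[list] = None  # explicit input species; None = auto-detect

    # -- lookups ---------------------------------------------------------

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(f"no species {sid!r} in model {self.model_id!r}")

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.model_id!r}")

    def get_parameter(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(f"no parameter {pid!r} in model {self.model_id!r}")

    def get_compartment(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(f"no compartment {cid!r} in model {self.model_id!r}")

    def has_element(self, eid: str) -> bool:
        return eid in self.all_ids()

    def elements(self) -> Iterator:
        yield from self.compartments
        yield from self.species
        yield from self.reactions
        yield from self.parameters

    def all_ids(self) -> set:
        return {e.id for e in self.elements()}

    def species_ids(self) -> list:
        return [s.id for s in self.species]

    def parameter_ids(self) -> list:
        return [p.id for p in self.parameters]

    # -- semantics -------------------------------------------------------

    def fixed_species_ids(self) -> list:
        """Species held constant during simulation (boundary or constant)."""
        return [s.id for s in self.species if s.boundary or s.constant]

    def dynamic_species_ids(self) -> list:
        return [s.id for s in self.species if not (s.boundary or s.constant)]

    def inputs(self) -> list:
        """Input species: explicit ``input_ids`` if set, else every fixed
        species that appears in some kinetic law."""
        if self.input_ids is not None:
            return list(self.input_ids)
        used = set()
        for r in self.reactions:
            used |= expr_symbols(r.kinetic_law)
        return [sid for sid in self.fixed_species_ids() if sid in used]

    def reaction_parameter_ids(self, rid: str) -> list:
        """Parameter ids appearing in a reaction's kinetic law, in order of
        first occurrence in the expression string (positional order used for
        cross-model parameter correspondence)."""
        reaction = self.get_reaction(rid)
        pids = {p.id for p in self.parameters}
        seen = []
        for sym in _symbols_in_order(reaction.kinetic_law):
            if sym in pids and sym not in seen:
                seen.append(sym)
        return seen

    def copy(self) -> "KineticModel":
        return copy.deepcopy(self)


def _symbols_in_order(expr: str) -> list:
    """Identifiers in an expression string, in textual order."""
    import re

    return re.findall(r"[A-Za-z_][A-Za-z0-9_]*", expr)
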
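"""Computing the overlap of two models.

The initial matching is calculated automatically from element identities
(annotation URI sets plus structured names; see :mod:`odemerge.identity`).
Matching is a partial one-to-one map: an element pairs only with a unique
mutual candidate; any ambiguity is left unmatched and surfaced for manual
editing.  Reactions are matched structurally, through their participating
species; kinetic parameters are matched positionally through their owning
reactions, since rate constants rarely carry database annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from odemerge.expr import equivalent_structure
from odemerge.identity import extract_identity

ELEMENT_CLASSES = ("compartment", "species", "reaction", "parameter")

CONFLICT_KINDS = (
    "modification-site",
    "different-compartment",
    "different-state",
    "different-kinetics",
    "modifier-vs-reactant",
    "level-of-detail",
    "annotation-name-disagreement",
)


@dataclass(frozen=True)
class ConflictFlag:
    kind: str
    detail: str

    def __post_init__(self):
        if self.kind not in CONFLICT_KINDS:
            raise ValueError(f"unknown conflict kind {self.kind!r}")
        if not self.detail:
            raise ValueError("every conflict flag needs a human-readable detail")


@dataclass
class MatchEntry:
    element_class: str
    ref_a: str
    ref_b: str
    source: str = "auto"  # auto | manual
    confidence: str = "identical-annotation"  # | identical-name | user-asserted
    conflicts: list = field(default_factory=list)

    def has_conflict(self, kind: str) -> bool:
        return any(f.kind == kind for f in self.conflicts)


@dataclass
class MatchSet:
    """The computed overlap plus the unmatched remainder of both models.

    ``unmatched_a`` / ``unmatched_b`` hold ``(element_class, ref)`` pairs;
    entries and unmatched lists partition each model's elements.
    ``ambiguities`` records elements withheld from automatic matching
    because several candidates were identity-equal.  ``notes`` carries
    cross-model observations on unmatched elements (e.g. same molecule in
    different modification states).
    """

    entries: list = field(default_factory=list)
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)
    ambiguities: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def entry_for_a(self, ref_a: str):
        for e in self.entries:
            if e.ref_a == ref_a:
                return e
        return None

    def entry_for_b(self, ref_b: str):
        for e in self.entries:
            if e.ref_b == ref_b:
                return e
        return None

    def pairs(self, element_class: str = None) -> set:
        return {
            (e.ref_a, e.ref_b)
            for e in self.entries
            if element_class is None or e.element_class == element_class
        }

    def count(self, element_class: str) -> int:
        return sum(1 for e in self.entries if e.element_class == element_class)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "class": e.element_class,
                    "ref_a": e.ref_a,
                    "ref_b": e.ref_b,
                    "source": e.source,
                    "confidence": e.confidence,
                    "conflicts": [
                        {"kind": f.kind, "detail": f.detail} for f in e.conflicts
                    ],
                }
                for e in self.entries
            ],
            "unmatched_a": [list(x) for x in self.unmatched_a],
            "unmatched_b": [list(x) for x in self.unmatched_b],
            "ambiguities": self.ambiguities,
            "notes": self.notes,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "MatchSet":
        ms = cls()
        for e in data.get("entries", []):
            ms.entries.append(
                MatchEntry(
                    element_class=e["class"],
                    ref_a=e["ref_a"],
                    ref_b=e["ref_b"],
                    source=e.get("source", "auto"),
                    confidence=e.get("confidence", "identical-annotation"),
                    conflicts=[
                        ConflictFlag(f["kind"], f["detail"])
                        for f in e.get("conflicts", [])
                    ],
                )
            )
        ms.unmatched_a = [tuple(x) for x in data.get("unmatched_a", [])]
        ms.unmatched_b = [tuple(x) for x in data.get("unmatched_b", [])]
        ms.ambiguities = data.get("ambiguities", [])
        ms.notes = data.get("notes", [])
        return ms

    def to_table(self, model_a=None, model_b=None):
        """Delimited match table: class, id_A, name_A, id_B, name_B, source,
        conflicts."""
        import pandas as pd

        rows = []
        for e in self.entries:
            rows.append(
                {
                    "class": e.element_class,
                    "id_A": e.ref_a,
                    "name_A": _name_of(model_a, e.element_class, e.ref_a),
                    "id_B": e.ref_b,
                    "name_B": _name_of(model_b, e.element_class, e.ref_b),
                    "source": e.source,
                    "conflicts": ";".join(f.kind for f in e.conflicts),
                }
            )
        return pd.DataFrame(
            rows, columns=["class", "id_A", "name_A", "id_B", "name_B", "source", "conflicts"]
        )


def _name_of(model, element_class, ref):
    if model is None:
        return ""
    try:
        getter = {
            "species": model.get_species,
            "reaction": model.get_reaction,
            "parameter": model.get_parameter,
            "compartment": model.get_compartment,
        }[element_class]
        return getter(ref).name
    except KeyError:
        return ""


# ---------------------------------------------------------------------------
# automatic matching


def auto_match(model_a, model_b) -> MatchSet:
    """Annotation-based initial matching of two models.

    Species, compartments and global parameters pair when their identities
    are semantically equal and the pairing is unambiguous in both
    directions.  Reactions pair when all their reactants, products and
    modifiers pair with equal stoichiometries.  Reaction-local parameters
    are then paired positionally through their matched owning reactions.
    """
    ms = MatchSet()
    species_map = {}

    for cls, elems_a, elems_b in (
        ("compartment", model_a.compartments, model_b.compartments),
        ("species", model_a.species, model_b.species),
    ):
        matched_a, matched_b = _identity_match(cls, elems_a, elems_b, ms)
        if cls == "species":
            species_map = {e.ref_a: e.ref_b for e in ms.entries if e.element_class == "species"}
        _ = matched_a, matched_b

    reaction_pairs = _match_reactions(model_a, model_b, species_map, ms)
    _match_parameters(model_a, model_b, reaction_pairs, ms)

    _fill_unmatched(model_a, model_b, ms)
    return ms


def _identity_match(cls, elems_a, elems_b, ms: MatchSet) -> tuple:
    idents_a = {e.id: extract_identity(e) for e in elems_a}
    idents_b = {e.id: extract_identity(e) for e in elems_b}
    cand_ab = {
        a: [b for b, ib in idents_b.items() if ia.semantically_equal(ib)]
        for a, ia in idents_a.items()
    }
    cand_ba = {
        b: [a for a, ia in idents_a.items() if ib.semantically_equal(ia)]
        for b, ib in idents_b.items()
    }

    def resolve(ref, cands, idents_this, idents_other):
        """Unique partner, letting exact structured-name equality break
        URI-group ties; None when genuinely ambiguous or unmatched."""
        if len(cands) == 1:
            return cands[0]
        named = [
            c
            for c in cands
            if idents_other[c].structured_name == idents_this[ref].structured_name
        ]
        return named[0] if len(named) == 1 else None

    matched_a, matched_b = set(), set()
    for a, cands in cand_ab.items():
        b = resolve(a, cands, idents_a, idents_b)
        if b is not None and resolve(b, cand_ba[b], idents_b, idents_a) == a:
            both_annotated = bool(idents_a[a].rdf_uris and idents_b[b].rdf_uris)
            ms.entries.append(
                MatchEntry(
                    element_class=cls,
                    ref_a=a,
                    ref_b=b,
                    source="auto",
                    confidence="identical-annotation" if both_annotated else "identical-name",
                )
            )
            matched_a.add(a)
            matched_b.add(b)
    for side, cand_map, idents_this, idents_other, taken in (
        ("A", cand_ab, idents_a, idents_b, matched_a),
        ("B", cand_ba, idents_b, idents_a, matched_b),
    ):
        for ref, cands in cand_map.items():
            if ref in taken or len(cands) <= 1:
                continue
            ms.ambiguities.append(
                {
                    "side": side,
                    "class": cls,
                    "ref": ref,
                    "candidates": sorted(cands),
                    "flag": {
                        "kind": "annotation-name-disagreement",
                        "detail": f"{cls} {ref!r} is identity-equal to several "
                        f"elements of the other model: {sorted(cands)}",
                    },
                }
            )
    return matched_a, matched_b


def _match_reactions(model_a, model_b, species_map, ms: MatchSet) -> list:
    def mapped_participants(rxn, forward=True):
        m = species_map if forward else {v: k for k, v in species_map.items()}
        reactants = sorted((m.get(s), st) for s, st in rxn.reactants)
        products = sorted((m.get(s), st) for s, st in rxn.products)
        modifiers = sorted(m.get(s) for s in rxn.modifiers)
        return reactants, products, modifiers

    pairs = []
    cand_ab, cand_ba = {}, {}
    for ra in model_a.reactions:
        sig_a = (
            sorted((species_map.get(s), st) for s, st in ra.reactants),
            sorted((species_map.get(s), st) for s, st in ra.products),
            sorted(species_map.get(s) for s in ra.modifiers),
        )
        if any(x[0] is None for x in sig_a[0] + sig_a[1]) or None in sig_a[2]:
            continue
        for rb in model_b.reactions:
            sig_b = (
                sorted((s, st) for s, st in rb.reactants),
                sorted((s, st) for s, st in rb.products),
                sorted(rb.modifiers),
            )
            if sig_a == sig_b:
                cand_ab.setdefault(ra.id, []).append(rb.id)
                cand_ba.setdefault(rb.id, []).append(ra.id)
    for ra_id, cands in cand_ab.items():
        if len(cands) == 1 and cand_ba[cands[0]] == [ra_id]:
            ms.entries.append(
                MatchEntry(
                    element_class="reaction",
                    ref_a=ra_id,
                    ref_b=cands[0],
                    source="auto",
                    confidence="identical-annotation",
                )
            )
            pairs.append((ra_id, cands[0]))
        elif len(cands) > 1:
            ms.ambiguities.append(
                {
                    "side": "A",
                    "class": "reaction",
                    "ref": ra_id,
                    "candidates": sorted(cands),
                    "flag": {
                        "kind": "annotation-name-disagreement",
                        "detail": f"reaction {ra_id!r} structurally matches several "
                        f"reactions: {sorted(cands)}",
                    },
                }
            )
    return pairs


def _match_parameters(model_a, model_b, reaction_pairs, ms: MatchSet) -> None:
    taken_a = {e.ref_a for e in ms.entries if e.element_class == "parameter"}
    taken_b = {e.ref_b for e in ms.entries if e.element_class == "parameter"}
    for ra_id, rb_id in reaction_pairs:
        pa = model_a.reaction_parameter_ids(ra_id)
        pb = model_b.reaction_parameter_ids(rb_id)
        if len(pa) != len(pb):
            continue  # flagged later as different-kinetics
        for a, b in zip(pa, pb):
            if a in taken_a or b in taken_b:
                continue
            ms.entries.append(
                MatchEntry(
                    element_class="parameter",
                    ref_a=a,
                    ref_b=b,
                    source="auto",
                    confidence="identical-annotation",
                )
            )
            taken_a.add(a)
            taken_b.add(b)


def _fill_unmatched(model_a, model_b, ms: MatchSet) -> None:
    matched_a = {(e.element_class, e.ref_a) for e in ms.entries}
    matched_b = {(e.element_class, e.ref_b) for e in ms.entries}
    ms.unmatched_a = [
        (cls, e.id)
        for cls, elems in _classed(model_a)
        for e in elems
        if (cls, e.id) not in matched_a
    ]
    ms.unmatched_b = [
        (cls, e.id)
        for cls, elems in _classed(model_b)
        for e in elems
        if (cls, e.id) not in matched_b
    ]


def _classed(model):
    return (
        ("compartment", model.compartments),
        ("species", model.species),
        ("reaction", model.reactions),
        ("parameter", model.parameters),
    )


# ---------------------------------------------------------------------------
# manual post-editing


class EditError(ValueError):
    pass


def apply_edits(matches: MatchSet, edits: list) -> MatchSet:
    """Apply manual edit commands to a matching.

    Commands (dicts): ``add-match``, ``remove-match``, ``confirm-match``
    with keys ``element_class``/``ref_a``/``ref_b``, and ``flag`` with
    ``kind``/``detail`` to attach a conflict flag (the only way the
    level-of-detail conflict can be raised).  The result satisfies all
    MatchSet invariants; violating edits are rejected with an explanation.
    """
    ms = MatchSet.from_dict(matches.to_dict())
    for edit in edits:
        op = edit.get("op")
        if op == "add-match":
            _edit_add(ms, edit)
        elif op == "remove-match":
            _edit_remove(ms, edit)
        elif op == "confirm-match":
            entry = _find_entry(ms, edit)
            entry.source = "manual"
            entry.confidence = "user-asserted"
        elif op == "flag":
            entry = _find_entry(ms, edit)
            entry.conflicts.append(ConflictFlag(edit["kind"], edit["detail"]))
        else:
            raise EditError(f"unknown edit command {op!r}")
    return ms


def _edit_add(ms: MatchSet, edit: dict) -> None:
    cls, ref_a, ref_b = edit.get("element_class"), edit["ref_a"], edit["ref_b"]
    rec_a = next((x for x in ms.unmatched_a if x[1] == ref_a), None)
    rec_b = next((x for x in ms.unmatched_b if x[1] == ref_b), None)
    if rec_a is None:
        raise EditError(
            f"cannot add match: {ref_a!r} is not an unmatched element of model A "
            "(adding it would break the one-to-one property)"
        )
    if rec_b is None:
        raise EditError(
            f"cannot add match: {ref_b!r} is not an unmatched element of model B "
            "(adding it would break the one-to-one property)"
        )
    if rec_a[0] != rec_b[0]:
        raise EditError(
            f"cannot match elements of different classes: {ref_a!r} is a "
            f"{rec_a[0]}, {ref_b!r} is a {rec_b[0]}"
        )
    if cls is not None and cls != rec_a[0]:
        raise EditError(
            f"edit declares class {cls!r} but {ref_a!r} is a {rec_a[0]}"
        )
    ms.unmatched_a.remove(rec_a)
    ms.unmatched_b.remove(rec_b)
    ms.entries.append(
        MatchEntry(
            element_class=rec_a[0],
            ref_a=ref_a,
            ref_b=ref_b,
            source="manual",
            confidence="user-asserted",
        )
    )


def _edit_remove(ms: MatchSet, edit: dict) -> None:
    entry = _find_entry(ms, edit)
    ms.entries.remove(entry)
    ms.unmatched_a.append((entry.element_class, entry.ref_a))
    ms.unmatched_b.append((entry.element_class, entry.ref_b))


def _find_entry(ms: MatchSet, edit: dict) -> MatchEntry:
    for e in ms.entries:
        if e.ref_a == edit.get("ref_a") and e.ref_b == edit.get("ref_b"):
            return e
    raise EditError(
        f"no match entry pairs {edit.get('ref_a')!r} with {edit.get('ref_b')!r}"
    )


# ---------------------------------------------------------------------------
# conflict classification


def classify_conflicts(matches: MatchSet, model_a, model_b) -> MatchSet:
    """Attach conflict flags to match entries and cross-model notes.

    The level-of-detail conflict is never assigned automatically; it can
    only be attached through a manual ``flag`` edit.
    """
    ms = apply_edits(matches, [])  # deep copy preserving sources
    for src, dst in zip(matches.entries, ms.entries):
        dst.source, dst.confidence = src.source, src.confidence
    species_map = {e.ref_a: e.ref_b for e in ms.entries if e.element_class == "species"}
    comp_pairs = ms.pairs("compartment")

    for entry in ms.entries:
        if entry.element_class == "species":
            _classify_species(entry, model_a, model_b, comp_pairs)
        elif entry.element_class == "reaction":
            _classify_reaction(entry, model_a, model_b, species_map)

    _note_unmatched_states(ms, model_a, model_b)
    return ms


def _classify_species(entry, model_a, model_b, comp_pairs) -> None:
    sa, sb = model_a.get_species(entry.ref_a), model_b.get_species(entry.ref_b)
    ia, ib = extract_identity(sa), extract_identity(sb)
    if (
        ia.rdf_uris
        and ia.rdf_uris == ib.rdf_uris
        and ia.structured_name.modifications != ib.structured_name.modifications
    ):
        entry.conflicts.append(
            ConflictFlag(
                "modification-site",
                f"species {sa.id!r}/{sb.id!r} share annotations but are modified "
                f"on different sites",
            )
        )
    tag_a = ia.structured_name.compartment_tag
    tag_b = ib.structured_name.compartment_tag
    if (sa.compartment, sb.compartment) not in comp_pairs or (
        tag_a != tag_b and (tag_a or tag_b)
    ):
        entry.conflicts.append(
            ConflictFlag(
                "different-compartment",
                f"species {sa.id!r} lives in {sa.compartment!r}, "
                f"{sb.id!r} lives in {sb.compartment!r}",
            )
        )


def _classify_reaction(entry, model_a, model_b, species_map) -> None:
    ra, rb = model_a.get_reaction(entry.ref_a), model_b.get_reaction(entry.ref_b)
    reactants_b = {s for s, _ in rb.reactants}
    reactants_a = {s for s, _ in ra.reactants}
    for sid in ra.modifiers:
        if species_map.get(sid) in reactants_b:
            entry.conflicts.append(
                ConflictFlag(
                    "modifier-vs-reactant",
                    f"species {sid!r} acts as a modifier in {ra.id!r} but as a "
                    f"reactant in {rb.id!r}",
                )
            )
    inverse = {v: k for k, v in species_map.items()}
    for sid in rb.modifiers:
        if inverse.get(sid) in reactants_a:
            entry.conflicts.append(
                ConflictFlag(
                    "modifier-vs-reactant",
                    f"species {inverse.get(sid)!r} acts as a reactant in {ra.id!r} "
                    f"but as a modifier in {rb.id!r}",
                )
            )

    pa = model_a.reaction_parameter_ids(ra.id)
    pb = model_b.reaction_parameter_ids(rb.id)
    rename = dict(species_map and {v: k for k, v in species_map.items()})
    if len(pa) == len(pb):
        rename.update({b: a for a, b in zip(pa, pb)})
        same = equivalent_structure(ra.kinetic_law, rb.kinetic_law, rename)
    else:
        same = False
    if not same:
        entry.conflicts.append(
            ConflictFlag(
                "different-kinetics",
                f"reactions {ra.id!r} and {rb.id!r} use structurally different "
                f"kinetic laws",
            )
        )


def _note_unmatched_states(ms: MatchSet, model_a, model_b) -> None:
    un_a = [ref for cls, ref in ms.unmatched_a if cls == "species"]
    un_b = [ref for cls, ref in ms.unmatched_b if cls == "species"]
    for ref_a in un_a:
        ia = extract_identity(model_a.get_species(ref_a))
        if not ia.rdf_uris:
            continue
        for ref_b in un_b:
            ib = extract_identity(model_b.get_species(ref_b))
            if ia.rdf_uris != ib.rdf_uris:
                continue
            mods_a = ia.structured_name.modifications
            mods_b = ib.structured_name.modifications
            if bool(mods_a) != bool(mods_b):
                ms.notes.append(
                    {
                        "ref_a": ref_a,
                        "ref_b": ref_b,
                        "flag": {
                            "kind": "different-state",
                            "detail": f"species {ref_a!r} and {ref_b!r} describe the "
                            "same molecule in modified vs. unmodified state",
                        },
                    }
                )
            elif mods_a != mods_b:
                ms.notes.append(
                    {
                        "ref_a": ref_a,
                        "ref_b": ref_b,
                        "flag": {
                            "kind": "modification-site",
                            "detail": f"species {ref_a!r} and {ref_b!r} share "
                            "annotations but are modified on different sites",
                        },
                    }
                )
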
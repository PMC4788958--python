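"""Building the merged model from two models and a match set.

Every overlap element appears exactly once (keeping model A's id); the
parameter-source policy decides, per overlap element, whether kinetic
parameters and initial amounts come from model A or model B.  Non-overlap
elements are copied verbatim from their original model, with id collisions
between unmatched elements resolved by suffixing.  Species matched across
different compartments or states are kept as separate species: inserting a
transport or modification reaction needs kinetics only the user can supply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from odemerge.expr import rename_symbols
from odemerge.model import KineticModel
from odemerge.model_io import validate_model
from odemerge.overlap import MatchSet

#: conflict kinds that block merging unless the policy names a source
BLOCKING_CONFLICTS = ("modifier-vs-reactant", "different-kinetics", "level-of-detail")


class MergeError(ValueError):
    pass


@dataclass
class MergePolicy:
    """Which original model parameterizes the overlap.

    ``per_element_source`` overrides the default for individual overlap
    elements, addressed by their model-A id.
    """

    default_source: str = "A"
    per_element_source: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.default_source not in ("A", "B"):
            raise ValueError("default_source must be 'A' or 'B'")
        for ref, src in self.per_element_source.items():
            if src not in ("A", "B"):
                raise ValueError(f"source for {ref!r} must be 'A' or 'B'")

    def source_for(self, ref_a: str) -> str:
        return self.per_element_source.get(ref_a, self.default_source)


@dataclass
class MergedModel:
    model: KineticModel
    provenance: dict  # merged element id -> "A-only" | "B-only" | "overlap"
    policy_used: MergePolicy
    id_map_b: dict = field(default_factory=dict)  # model-B id -> merged id
    matches: MatchSet = None

    def side_elements(self, side: str) -> list:
        """Merged element ids originating from the given side (incl. overlap)."""
        keep = {f"{side}-only", "overlap"}
        return [eid for eid, origin in self.provenance.items() if origin in keep]

    def exclusive_elements(self, side: str) -> list:
        return [e for e, o in self.provenance.items() if o == f"{side}-only"]

    def side_inputs(self, side: str) -> list:
        side_ids = set(self.side_elements(side))
        return [i for i in self.model.inputs() if i in side_ids]

    def provenance_to_json(self, path=None) -> str:
        import json

        text = json.dumps(
            {
                "policy": {
                    "default_source": self.policy_used.default_source,
                    "per_element_source": self.policy_used.per_element_source,
                },
                "provenance": self.provenance,
                "id_map_b": self.id_map_b,
            },
            indent=2,
        )
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def merge_models(
    model_a: KineticModel,
    model_b: KineticModel,
    matches: MatchSet,
    policy: MergePolicy = None,
) -> MergedModel:
    """Merge two models given their overlap and a parameter-source policy.

    Preconditions: units harmonized; every blocking conflict (modifier vs.
    reactant, different kinetics, level of detail) resolved by a
    per-element policy choice.  The merged model passes structural
    validation; counts satisfy |merged| = |A| + |B| - |overlap| per class.
    """
    policy = policy or MergePolicy()
    _check_match_refs(model_a, model_b, matches)
    _check_blocking_conflicts(matches, policy)

    merged = model_a.copy()
    merged.model_id = f"{model_a.model_id}__{model_b.model_id}__merged"
    merged.name = f"merge of {model_a.model_id} and {model_b.model_id}"
    merged.notes = []
    provenance = {e.id: "A-only" for e in merged.elements()}
    for entry in matches.entries:
        provenance[entry.ref_a] = "overlap"

    id_map_b = {e.ref_b: e.ref_a for e in matches.entries}
    used = merged.all_ids()
    for cls, ref_b in matches.unmatched_b:
        new_id = ref_b if ref_b not in used else f"{ref_b}__B"
        while new_id in used:
            new_id += "_"
        id_map_b[ref_b] = new_id
        used.add(new_id)

    # copy unmatched B elements, rewriting references
    for cls, ref_b in matches.unmatched_b:
        new_id = id_map_b[ref_b]
        if cls == "compartment":
            el = _clone(model_b.get_compartment(ref_b), new_id)
            merged.compartments.append(el)
        elif cls == "species":
            el = _clone(model_b.get_species(ref_b), new_id)
            el.compartment = id_map_b.get(el.compartment, el.compartment)
            merged.species.append(el)
        elif cls == "parameter":
            el = _clone(model_b.get_parameter(ref_b), new_id)
            merged.parameters.append(el)
        elif cls == "reaction":
            el = _clone(model_b.get_reaction(ref_b), new_id)
            el.reactants = [(id_map_b.get(s, s), st) for s, st in el.reactants]
            el.products = [(id_map_b.get(s, s), st) for s, st in el.products]
            el.modifiers = [id_map_b.get(s, s) for s in el.modifiers]
            el.kinetic_law = rename_symbols(el.kinetic_law, id_map_b)
            merged.reactions.append(el)
        provenance[new_id] = "B-only"

    _apply_policy(merged, model_b, matches, policy)

    merged.input_ids = _merged_inputs(model_a, model_b, merged, id_map_b)

    report = validate_model(merged)
    if not report.valid:
        details = "; ".join(i.message for i in report.errors())
        raise MergeError(f"merged model fails validation: {details}")
    return MergedModel(
        model=merged,
        provenance=provenance,
        policy_used=policy,
        id_map_b=id_map_b,
        matches=matches,
    )


def _apply_policy(merged, model_b, matches: MatchSet, policy: MergePolicy) -> None:
    """Overwrite overlap values with the chosen source's values."""
    for entry in matches.entries:
        if policy.source_for(entry.ref_a) != "B":
            continue  # A values already in place
        if entry.element_class == "species":
            merged.get_species(entry.ref_a).initial_amount = model_b.get_species(
                entry.ref_b
            ).initial_amount
        elif entry.element_class == "parameter":
            merged.get_parameter(entry.ref_a).value = model_b.get_parameter(
                entry.ref_b
            ).value
        elif entry.element_class == "compartment":
            merged.get_compartment(entry.ref_a).size = model_b.get_compartment(
                entry.ref_b
            ).size
        elif entry.element_class == "reaction":
            # reaction-level choice: pull every positionally corresponding
            # parameter value from B (equal law structure assumed)
            pa = merged.reaction_parameter_ids(entry.ref_a)
            pb = model_b.reaction_parameter_ids(entry.ref_b)
            if len(pa) != len(pb):
                raise MergeError(
                    f"cannot take parameters of reaction {entry.ref_b!r} from B: "
                    f"kinetic laws have different parameter counts"
                )
            for a, b in zip(pa, pb):
                merged.get_parameter(a).value = model_b.get_parameter(b).value


def _merged_inputs(model_a, model_b, merged, id_map_b) -> list:
    inputs = list(model_a.inputs())
    for sid in model_b.inputs():
        mapped = id_map_b.get(sid, sid)
        if mapped not in inputs and merged.has_element(mapped):
            inputs.append(mapped)
    return inputs


def _check_match_refs(model_a, model_b, matches: MatchSet) -> None:
    ids_a, ids_b = model_a.all_ids(), model_b.all_ids()
    for entry in matches.entries:
        if entry.ref_a not in ids_a:
            raise MergeError(f"match references unknown element {entry.ref_a!r} in model A")
        if entry.ref_b not in ids_b:
            raise MergeError(f"match references unknown element {entry.ref_b!r} in model B")


def _check_blocking_conflicts(matches: MatchSet, policy: MergePolicy) -> None:
    for entry in matches.entries:
        for flag in entry.conflicts:
            if (
                flag.kind in BLOCKING_CONFLICTS
                and entry.ref_a not in policy.per_element_source
            ):
                raise MergeError(
                    f"unresolved {flag.kind} conflict on match "
                    f"{entry.ref_a!r}/{entry.ref_b!r}: a manual per-element "
                    "policy decision is required"
                )


def _clone(element, new_id):
    import copy

    el = copy.deepcopy(element)
    el.id = new_id
    return el
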
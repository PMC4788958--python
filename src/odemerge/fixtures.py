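"""Test-bed generation: synthetic overlapping model pairs with ground truth,
and assembly of the two-pathway case study from locally provided SBML files.

The toy topology emulates two receptor branches converging on a shared
downstream cascade: each model has its own step-stimulated input and an
exclusive upstream branch (activated species starting at zero), feeding a
common overlap built from phosphorylation cycles.  Overlap elements carry
identical annotations and names in both models, so the planted matches are
exactly recoverable; model B's overlap rate constants are A's multiplied by
the divergence factor, which shifts the overlap's gain and timescales and
makes the two parameterizations measurably inconsistent (divergence 1
keeps them identical).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from odemerge.model import Compartment, KineticModel, Parameter, Reaction, Species
from odemerge.overlap import MatchEntry, MatchSet, auto_match
from odemerge.simulate import InputSignal, Observable, default_time_grid

RATE_LOW, RATE_HIGH = 1e-3, 1e1
INIT_LOW, INIT_HIGH = 0.1, 10.0

CASE_ACCESSIONS = ("BIOMD0000000262", "BIOMD0000000263")
CASE_OUTPUTS = ("pEGFR", "pTrkA", "pAkt", "pS6")


@dataclass
class ToyPairSpec:
    """Shape of a generated overlapping model pair.

    ``overlap_species``/``overlap_reactions`` control the planted overlap
    (the case-study shape is 5 species / 4 reactions); ``divergence`` is
    the factor applied to B's overlap activation rate constants.
    """

    n_exclusive_a: int = 2
    n_exclusive_b: int = 2
    overlap_species: int = 5
    overlap_reactions: int = 4
    kinetics: str = "mass-action"
    seed: int = 0
    divergence: float = 1.0

    def __post_init__(self):
        if self.kinetics != "mass-action":
            raise ValueError("only mass-action toy kinetics are supported")
        if self.divergence <= 0:
            raise ValueError("divergence must be positive")
        if min(self.n_exclusive_a, self.n_exclusive_b) < 0:
            raise ValueError("negative branch sizes")
        if (self.overlap_species == 0) != (self.overlap_reactions == 0):
            if self.overlap_species == 0:
                raise ValueError("overlap reactions without overlap species are infeasible")


def _overlap_layout(m: int, r: int):
    """Split the overlap into phosphorylation cycles, inert species and
    drain reactions such that counts are exactly (m species, r reactions)."""
    if m == 0:
        return 0, 0, []
    cycles = min(m // 2, (r + 1) // 2)
    inert = m - 2 * cycles
    from_cycles = max(0, 2 * cycles - 1)
    drains_needed = r - from_cycles
    if drains_needed < 0:
        # fewer reactions than the cycle chain provides: use fewer cycles
        while cycles > 0 and 2 * cycles - 1 > r:
            cycles -= 1
        inert = m - 2 * cycles
        from_cycles = max(0, 2 * cycles - 1)
        drains_needed = r - from_cycles
    drain_targets = []
    for j in range(inert):
        if len(drain_targets) == drains_needed:
            break
        drain_targets.append(("inert", j + 1))
    j = cycles
    while len(drain_targets) < drains_needed and j > 0:
        drain_targets.append(("cycle", j))
        j -= 1
    if len(drain_targets) < drains_needed:
        raise ValueError(
            f"infeasible toy spec: cannot place {r} overlap reactions on "
            f"{m} overlap species"
        )
    return cycles, inert, drain_targets


def generate_toy_pair(spec: ToyPairSpec):
    """Generate (model A, model B, ground-truth MatchSet).

    Both models validate and simulate; the ground truth lists exactly the
    planted compartment/species/reaction matches.
    """
    rng = np.random.default_rng(spec.seed)
    m, r = spec.overlap_species, spec.overlap_reactions
    cycles, inert, drains = _overlap_layout(m, r)

    # one draw of shared overlap structure
    cyc_init = rng.uniform(INIT_LOW, INIT_HIGH, size=max(cycles, 1))
    inert_init = rng.uniform(INIT_LOW, INIT_HIGH, size=max(inert, 1))
    k_act = _rates(rng, max(cycles, 1))
    k_deact = _rates(rng, max(cycles, 1))
    k_drain = _rates(rng, max(len(drains), 1))

    shared = {
        "cyc_init": cyc_init,
        "inert_init": inert_init,
        "k_act": k_act,
        "k_deact": k_deact,
        "k_drain": k_drain,
        "cycles": cycles,
        "inert": inert,
        "drains": drains,
    }
    model_a = _build_toy_model("A", spec.n_exclusive_a, shared, rng, 1.0, m)
    model_b = _build_toy_model("B", spec.n_exclusive_b, shared, rng, spec.divergence, m)

    truth = MatchSet()
    if m > 0:
        truth.entries.append(
            MatchEntry("compartment", "cell", "cell", source="auto")
        )
        for j in range(1, cycles + 1):
            truth.entries.append(MatchEntry("species", f"cas{j}", f"cas{j}", source="auto"))
            truth.entries.append(
                MatchEntry("species", f"cas{j}_p", f"cas{j}_p", source="auto")
            )
            truth.entries.append(
                MatchEntry("reaction", f"deact{j}", f"deact{j}", source="auto")
            )
            if j > 1:
                truth.entries.append(
                    MatchEntry("reaction", f"act{j}", f"act{j}", source="auto")
                )
        for j in range(1, inert + 1):
            truth.entries.append(
                MatchEntry("species", f"aux{j}", f"aux{j}", source="auto")
            )
        for i, _target in enumerate(drains, start=1):
            truth.entries.append(
                MatchEntry("reaction", f"drain{i}", f"drain{i}", source="auto")
            )
    return model_a, model_b, truth


def _rates(rng, n):
    return np.exp(rng.uniform(np.log(RATE_LOW), np.log(RATE_HIGH), size=n))


def _build_toy_model(tag, n_exclusive, shared, rng, divergence, m) -> KineticModel:
    model = KineticModel(model_id=f"toy_{tag}")
    comp_id = "cell" if m > 0 else f"cell_{tag}"
    model.compartments.append(
        Compartment(
            id=comp_id,
            size=1.0,
            name=comp_id,
            cv_uris=(("is", "urn:test:compartment:cell"),) if m > 0 else
            (("is", f"urn:test:compartment:cell_{tag}"),),
        )
    )

    lig = f"{tag}_Lig"
    model.species.append(
        Species(
            id=lig,
            compartment=comp_id,
            initial_amount=0.0,
            name=f"Lig{tag}",
            boundary=True,
            cv_uris=(("is", f"urn:test:lig:{tag}"),),
        )
    )

    # exclusive branch: relaxation chain of activated species, silent at t=0
    driver = lig
    for k in range(1, n_exclusive + 1):
        sid = f"{tag}_rec{k}"
        model.species.append(
            Species(
                id=sid,
                compartment=comp_id,
                initial_amount=0.0,
                name=f"Rec{tag}{k}_pY1",
                cv_uris=(("is", f"urn:test:rec:{tag}:{k}"),),
            )
        )
        kp, kd = _rates(rng, 2)
        model.parameters.append(Parameter(id=f"{tag}_kp{k}", value=float(kp)))
        model.parameters.append(Parameter(id=f"{tag}_kd{k}", value=float(kd)))
        model.reactions.append(
            Reaction(
                id=f"{tag}_prod{k}",
                reactants=[],
                products=[(sid, 1.0)],
                modifiers=[driver],
                kinetic_law=f"{tag}_kp{k} * {driver}",
                name=f"production of Rec{tag}{k}",
            )
        )
        model.reactions.append(
            Reaction(
                id=f"{tag}_dec{k}",
                reactants=[(sid, 1.0)],
                products=[],
                kinetic_law=f"{tag}_kd{k} * {sid}",
                name=f"decay of Rec{tag}{k}",
            )
        )
        driver = sid

    if m == 0:
        return model

    cycles, inert, drains = shared["cycles"], shared["inert"], shared["drains"]

    for j in range(1, cycles + 1):
        uri = (("is", f"urn:test:cas:{j}"),)
        model.species.append(
            Species(
                id=f"cas{j}",
                compartment=comp_id,
                initial_amount=float(shared["cyc_init"][j - 1]),
                name=f"Cas{j}",
                cv_uris=uri,
            )
        )
        model.species.append(
            Species(
                id=f"cas{j}_p",
                compartment=comp_id,
                initial_amount=0.0,
                name=f"Cas{j}_pS1",
                cv_uris=uri,
            )
        )

    for j in range(1, inert + 1):
        model.species.append(
            Species(
                id=f"aux{j}",
                compartment=comp_id,
                initial_amount=float(shared["inert_init"][j - 1]),
                name=f"Aux{j}",
                cv_uris=(("is", f"urn:test:aux:{j}"),),
            )
        )

    # coupling: the model's own branch drives the first cycle (exclusive)
    if cycles > 0:
        k_couple = float(_rates(rng, 1)[0])
        model.parameters.append(Parameter(id=f"{tag}_k_couple", value=k_couple))
        model.reactions.append(
            Reaction(
                id=f"{tag}_couple",
                reactants=[("cas1", 1.0)],
                products=[("cas1_p", 1.0)],
                modifiers=[driver],
                kinetic_law=f"{tag}_k_couple * {driver} * cas1",
                name=f"activation of Cas1 by {tag} branch",
            )
        )

    # overlap cycle reactions (identical in both models up to divergence)
    for j in range(1, cycles + 1):
        kd = float(shared["k_deact"][j - 1]) * divergence
        model.parameters.append(Parameter(id=f"k_deact{j}", value=kd))
        model.reactions.append(
            Reaction(
                id=f"deact{j}",
                reactants=[(f"cas{j}_p", 1.0)],
                products=[(f"cas{j}", 1.0)],
                kinetic_law=f"k_deact{j} * cas{j}_p",
                name=f"deactivation of Cas{j}",
            )
        )
        if j > 1:
            ka = float(shared["k_act"][j - 1]) * divergence
            model.parameters.append(Parameter(id=f"k_act{j}", value=ka))
            model.reactions.append(
                Reaction(
                    id=f"act{j}",
                    reactants=[(f"cas{j}", 1.0)],
                    products=[(f"cas{j}_p", 1.0)],
                    modifiers=[f"cas{j-1}_p"],
                    kinetic_law=f"k_act{j} * cas{j-1}_p * cas{j}",
                    name=f"activation of Cas{j} by Cas{j-1}",
                )
            )

    for i, (kind, j) in enumerate(drains, start=1):
        target = f"aux{j}" if kind == "inert" else f"cas{j}_p"
        kdr = float(shared["k_drain"][i - 1]) * divergence
        model.parameters.append(Parameter(id=f"k_drain{i}", value=kdr))
        model.reactions.append(
            Reaction(
                id=f"drain{i}",
                reactants=[(target, 1.0)],
                products=[],
                kinetic_law=f"k_drain{i} * {target}",
                name=f"turnover of {target}",
            )
        )
    return model


def toy_observables(spec: ToyPairSpec):
    """Default observables on the merged toy model, per side.

    Each side observes its branch terminal (exclusive output) plus the
    terminal phospho-species of the overlap cascade (shared output).
    """
    cycles, _, _ = _overlap_layout(spec.overlap_species, spec.overlap_reactions)
    shared = [Observable(f"cas{cycles}_p", label=f"pCas{cycles}")] if cycles else []
    obs = {}
    for tag, n in (("A", spec.n_exclusive_a), ("B", spec.n_exclusive_b)):
        own = []
        if n > 0:
            own.append(Observable(f"{tag}_rec{n}", label=f"pRec{tag}"))
        obs[tag] = own + shared
    return obs


def toy_input(spec_tag: str, level: float = 1.0, label: str = "") -> InputSignal:
    return InputSignal(
        assignments=((f"{spec_tag}_Lig", level),), label=label or f"{spec_tag}@{level:g}"
    )


# ---------------------------------------------------------------------------
# case study


def build_case_study(
    path_a: str,
    path_b: str,
    stimuli_a=None,
    stimuli_b=None,
    time_grid=None,
    scaling_factors=None,
):
    """Assemble the two-pathway case study from local SBML accession files.

    ``path_a``/``path_b`` point at local copies of the two BioModels
    accessions (receptor A: EGF-driven; receptor B: NGF-driven).  Returns a
    dict with the loaded models, the automatic matching, the four shared
    observables and the plan for the twelve step-stimulus datasets (six per
    ligand; stimulus levels and the time grid are configuration — they are
    not printed in the source describing the models and default to a
    log-spaced series on 0..3600 s).
    """
    from odemerge.model_io import load_model
    from odemerge.units import harmonize_units

    for path in (path_a, path_b):
        if not os.path.exists(path):
            raise FileNotFoundError(
                "accession files required: place local copies of "
                f"{CASE_ACCESSIONS[0]} and {CASE_ACCESSIONS[1]} (SBML) at the "
                f"given paths; missing {path!r}"
            )
    model_a = load_model(path_a)
    model_b = load_model(path_b)
    model_a, model_b, unit_log = harmonize_units(model_a, model_b)
    matches = auto_match(model_a, model_b)

    if time_grid is None:
        time_grid = default_time_grid()
    stimuli_a = list(stimuli_a) if stimuli_a is not None else _default_stimuli()
    stimuli_b = list(stimuli_b) if stimuli_b is not None else _default_stimuli()

    input_a = _find_input(model_a, "EGF")
    input_b = _find_input(model_b, "NGF")

    scaling_factors = scaling_factors or {}
    observables = []
    for out in CASE_OUTPUTS:
        sid_a = _find_species(model_a, out)
        sid_b = _find_species(model_b, out)
        sid = sid_a or sid_b
        if sid is None:
            continue
        observables.append(
            Observable(species_ref=sid, scale=scaling_factors.get(out, 1.0), label=out)
        )

    datasets = []
    for level in stimuli_a:
        datasets.append(
            {
                "origin": "A",
                "input": InputSignal(
                    assignments=((input_a, float(level)),), label=f"EGF@{level:g}"
                ),
                "time_grid": time_grid,
            }
        )
    for level in stimuli_b:
        datasets.append(
            {
                "origin": "B",
                "input": InputSignal(
                    assignments=((input_b, float(level)),), label=f"NGF@{level:g}"
                ),
                "time_grid": time_grid,
            }
        )
    return {
        "model_a": model_a,
        "model_b": model_b,
        "matches": matches,
        "observables": observables,
        "datasets": datasets,
        "unit_log": unit_log,
    }


def _default_stimuli(n: int = 6):
    # log-spaced stimulus series; levels are configuration, not reported
    return list(np.logspace(-2, 0.5, n))


def _find_input(model, token: str) -> str:
    inputs = model.inputs()
    for sid in inputs:
        sp = model.get_species(sid)
        if token.lower() in (sp.name or sp.id).lower():
            return sid
    for sp in model.species:
        if token.lower() == (sp.name or sp.id).lower():
            return sp.id
    if inputs:
        return inputs[0]
    raise ValueError(f"cannot identify the {token} input species")


def _find_species(model, token: str):
    tok = token.lower()
    for sp in model.species:
        if tok == (sp.name or "").lower() or tok == sp.id.lower():
            return sp.id
    for sp in model.species:
        if tok in (sp.name or sp.id).lower():
            return sp.id
    return None
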
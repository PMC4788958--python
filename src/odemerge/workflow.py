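"""Orchestration of the integration workflow.

Stages: prepare (load/validate/harmonize) -> match (auto + manual edits +
conflict classification) -> merge (policy) -> check (synthetic datasets +
chi-square consistency) -> refit/check iterations until the integration
goal is met or the iteration limit is reached.  Every stage writes its
artifact so any stage can be re-run standalone; a pre-supplied edit file
takes the place of interactive post-editing between match and merge.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from odemerge.consistency import (
    IntegrationGoal,
    check_consistency,
    make_synthetic_dataset,
)
from odemerge.merge import MergePolicy, merge_models
from odemerge.model_io import load_model, validate_model, write_model
from odemerge.overlap import apply_edits, auto_match, classify_conflicts
from odemerge.refit import FitProblem, apply_fit, candidate_free_parameters, fit_parameters
from odemerge.simulate import InputSignal, Observable, observe, simulate
from odemerge.units import harmonize_units


class WorkflowError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"workflow stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class WorkflowConfig:
    """Round-trippable configuration of a full workflow run."""

    model_a: str = ""
    model_b: str = ""
    policy: dict = field(default_factory=lambda: {"default_source": "A"})
    goal: str = "preserve-A"  # preserve-A | preserve-B | both | none
    edits: list = field(default_factory=list)
    observables: list = field(default_factory=list)
    datasets: list = field(default_factory=list)
    time_grid: dict = field(default_factory=lambda: {"t_end": 3600.0, "n_points": 61})
    fit: dict = field(default_factory=dict)
    seed: int = 0
    max_iterations: int = 3
    outdir: str = "odemerge_out"

    @classmethod
    def from_yaml(cls, path: str) -> "WorkflowConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str = None) -> str:
        data = {
            "model_a": self.model_a,
            "model_b": self.model_b,
            "policy": self.policy,
            "goal": self.goal,
            "edits": self.edits,
            "observables": self.observables,
            "datasets": self.datasets,
            "time_grid": self.time_grid,
            "fit": self.fit,
            "seed": self.seed,
            "max_iterations": self.max_iterations,
            "outdir": self.outdir,
        }
        text = yaml.safe_dump(data, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def goal_object(self) -> IntegrationGoal:
        if self.goal in ("preserve-A", "preserve-B"):
            return IntegrationGoal.preserve(self.goal[-1])
        if self.goal == "both":
            return IntegrationGoal.both_consistent()
        return IntegrationGoal(preserve_exact="none")

    def grid(self) -> np.ndarray:
        return np.linspace(
            0.0, float(self.time_grid.get("t_end", 3600.0)),
            int(self.time_grid.get("n_points", 61)),
        )


def build_observables(config_observables: list, merged) -> list:
    """Resolve configured observables against the merged model, translating
    original-model-B ids where necessary."""
    out = []
    for entry in config_observables:
        ref = entry["species"]
        if not merged.model.has_element(ref):
            ref = merged.id_map_b.get(ref, ref)
        out.append(
            Observable(
                species_ref=ref,
                scale=float(entry.get("scale", 1.0)),
                label=entry.get("label", ref),
            )
        )
    return out


def build_synthetic_datasets(
    model_a, model_b, merged, observables: list, dataset_specs: list, time_grid
):
    """Simulate the originals to produce per-side synthetic datasets.

    Dataset inputs are written in original-model ids and translated to the
    merged model's ids; outputs default to the observables available in the
    originating model (shared outputs plus that side's exclusive ones).
    """
    inv_b = {v: k for k, v in merged.id_map_b.items()}
    datasets_a, datasets_b = [], []
    for spec in dataset_specs:
        origin = spec["origin"]
        original = model_a if origin == "A" else model_b
        grid = np.asarray(spec.get("time_grid", time_grid), dtype=float)
        merged_assignments = {}
        original_assignments = {}
        for sid, level in spec["input"].items():
            if origin == "B":
                merged_id = merged.id_map_b.get(sid, sid)
                original_id = sid if original.has_element(sid) else inv_b.get(sid, sid)
            else:
                merged_id = sid
                original_id = sid
            merged_assignments[merged_id] = float(level)
            original_assignments[original_id] = float(level)
        label = spec.get("label") or f"{origin}:" + ",".join(
            f"{k}={v:g}" for k, v in sorted(original_assignments.items())
        )

        wanted = spec.get("outputs")
        side_obs = []
        for obs in observables:
            original_ref = obs.species_ref if origin == "A" else inv_b.get(obs.species_ref)
            if original_ref is None or not original.has_element(original_ref):
                continue
            if wanted is not None and obs.label not in wanted:
                continue
            side_obs.append(
                Observable(species_ref=original_ref, scale=obs.scale, label=obs.label)
            )
        if not side_obs:
            raise WorkflowError(
                "check", f"dataset {label!r} has no observable outputs in model {origin}"
            )
        traj = simulate(
            original,
            input_signal=InputSignal(
                assignments=tuple(sorted(original_assignments.items())), label=label
            ),
            time_grid=grid,
        )
        ds = make_synthetic_dataset(
            observe(traj, side_obs),
            InputSignal(assignments=tuple(sorted(merged_assignments.items())), label=label),
            origin=origin,
            label=label,
        )
        (datasets_a if origin == "A" else datasets_b).append(ds)
    return datasets_a, datasets_b


def expand_free_parameters(selectors, merged, matches, goal, observables) -> list:
    """Expand config free-parameter selectors into concrete refs.

    ``"auto"`` uses goal-driven candidate selection; ``"non-overlap:A"`` /
    ``"non-overlap:B"`` expand to that side's exclusive parameters; other
    strings pass through as explicit refs.
    """
    if selectors in (None, "auto"):
        return candidate_free_parameters(merged, matches, goal, observables).all()
    out = []
    for sel in selectors:
        if sel in ("non-overlap:A", "non-overlap:B"):
            side = sel[-1]
            exclusive = set(merged.exclusive_elements(side))
            out.extend(p.id for p in merged.model.parameters if p.id in exclusive)
        else:
            out.append(sel)
    return out


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute the full workflow; returns a result dict and writes one
    artifact per stage under ``config.outdir``."""
    os.makedirs(config.outdir, exist_ok=True)
    art = lambda name: os.path.join(config.outdir, name)  # noqa: E731

    # ---- prepare
    try:
        model_a = load_model(config.model_a)
        model_b = load_model(config.model_b)
        for m in (model_a, model_b):
            report = validate_model(m)
            report_path = art(f"validation_{m.model_id}.json")
            with open(report_path, "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            if not report.valid:
                raise ValueError(
                    f"model {m.model_id!r} is invalid: "
                    + "; ".join(i.message for i in report.errors())
                )
        model_a, model_b, unit_log = harmonize_units(model_a, model_b)
        with open(art("unit_conversions.json"), "w") as fh:
            json.dump(unit_log, fh, indent=2)
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError("prepare", str(exc)) from exc

    # ---- match
    try:
        matches = auto_match(model_a, model_b)
        if config.edits:
            matches = apply_edits(matches, config.edits)
        matches = classify_conflicts(matches, model_a, model_b)
        matches.to_json(art("match.json"))
        matches.to_table(model_a, model_b).to_csv(art("match.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise WorkflowError("match", str(exc)) from exc

    # ---- merge
    try:
        policy = MergePolicy(
            default_source=config.policy.get("default_source", "A"),
            per_element_source=config.policy.get("per_element_source", {}) or {},
        )
        merged = merge_models(model_a, model_b, matches, policy)
        write_model(merged.model, art("merged.xml"))
        merged.provenance_to_json(art("provenance.json"))
    except Exception as exc:
        raise WorkflowError("merge", str(exc)) from exc

    # ---- check
    goal = config.goal_object()
    try:
        observables = build_observables(config.observables, merged)
        datasets_a, datasets_b = build_synthetic_datasets(
            model_a, model_b, merged, observables, config.datasets, config.grid()
        )
        report = check_consistency(merged, datasets_a, datasets_b, observables, goal)
        report.to_json(art("consistency_pre.json"))
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError("check", str(exc)) from exc

    result = {
        "stages": ["prepare", "match", "merge", "check"],
        "pre_refit": report.to_dict(),
        "consistent": report.consistent,
        "goal_met": report.goal_result.overall if report.goal_result else report.consistent,
        "iterations": 0,
        "outdir": config.outdir,
    }
    if result["goal_met"]:
        result["post_refit"] = result["pre_refit"]
        return result

    # ---- refit iterations
    current, current_obs = merged, observables
    for iteration in range(1, config.max_iterations + 1):
        try:
            free = expand_free_parameters(
                config.fit.get("free_parameters", "auto"),
                current,
                matches,
                goal,
                current_obs,
            )
            if not free:
                break
            problem = FitProblem(
                merged=current,
                free_parameters=free,
                datasets=datasets_a + datasets_b,
                observables=current_obs,
                bounds={
                    k: tuple(v) for k, v in (config.fit.get("bounds") or {}).items()
                },
            )
            fit = fit_parameters(
                problem,
                n_starts=int(config.fit.get("n_starts", 5)),
                seed=config.seed + iteration - 1,
            )
            fit.to_json(art(f"fit_{iteration}.json"))
            current, current_obs = apply_fit(current, current_obs, fit)
            report = check_consistency(current, datasets_a, datasets_b, current_obs, goal)
            report.to_json(art(f"consistency_post_{iteration}.json"))
        except Exception as exc:
            raise WorkflowError("refit", str(exc)) from exc
        result["iterations"] = iteration
        result["post_refit"] = report.to_dict()
        result["goal_met"] = report.goal_result.overall if report.goal_result else report.consistent
        result["consistent"] = report.consistent
        if result["goal_met"]:
            break
    try:
        write_model(current.model, art("merged_refit.xml"))
    except Exception:
        pass
    return result
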
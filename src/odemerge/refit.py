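"""Goal-driven reparameterization of a merged model.

Candidate selection: when the goal preserves one side exactly, only
quantities that cannot influence the preserved side's outputs under its
isolated inputs may be re-fitted — the reaction parameters exclusive to the
other side, their initial amounts, and scaling factors of outputs exclusive
to the other side.  Overlap parameters and preserved-side parameters are
excluded.

Fitting: multi-experiment weighted least squares (one parameter vector,
per-dataset inputs) with a trust-region reflective solver on
log-transformed parameters and multi-start from log-uniform draws within
bounds.  Deterministic given the seed.

Free-parameter references: a bare id refers to a model parameter,
``init:<species>`` to an initial amount, ``scale:<label>`` to an
observable's scaling factor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from odemerge.consistency import chi2_residuals
from odemerge.simulate import observe, simulate

DEFAULT_BOUND_SPAN = 1000.0
FAILED_RESIDUAL = 1e6


class FitError(RuntimeError):
    pass


@dataclass
class CandidateSet:
    """Refit candidates grouped by origin."""

    reaction_parameters: list = field(default_factory=list)
    initial_amounts: list = field(default_factory=list)  # "init:<species>"
    observable_scales: list = field(default_factory=list)  # "scale:<label>"

    def all(self) -> list:
        return self.reaction_parameters + self.initial_amounts + self.observable_scales


def candidate_free_parameters(merged, matches, goal, observables=()) -> CandidateSet:
    """Parameters whose perturbation cannot change the preserved side's
    outputs under that side's isolated inputs.

    Without a ``preserve_exact`` side no exclusion is forced: all
    non-overlap parameters of both sides are returned with a warning.
    """
    if goal.preserve_exact == "none":
        warnings.warn(
            "goal declares no side to preserve exactly; returning all "
            "non-overlap parameters of both sides",
            stacklevel=2,
        )
        pids = [
            p.id
            for p in merged.model.parameters
            if merged.provenance.get(p.id) != "overlap"
        ]
        inits = [
            f"init:{s.id}"
            for s in merged.model.species
            if merged.provenance.get(s.id) != "overlap" and not (s.boundary or s.constant)
        ]
        scales = [f"scale:{o.label}" for o in observables]
        return CandidateSet(pids, inits, scales)

    other = "B" if goal.preserve_exact == "A" else "A"
    exclusive = set(merged.exclusive_elements(other))
    pids = [p.id for p in merged.model.parameters if p.id in exclusive]
    inits = [
        f"init:{s.id}"
        for s in merged.model.species
        if s.id in exclusive and not (s.boundary or s.constant)
    ]
    scales = [
        f"scale:{o.label}" for o in observables if o.species_ref in exclusive
    ]
    return CandidateSet(pids, inits, scales)


@dataclass
class FitProblem:
    """Multi-experiment estimation problem on a merged model."""

    merged: object  # MergedModel or KineticModel
    free_parameters: list
    datasets: list
    observables: list
    bounds: dict = field(default_factory=dict)  # ref -> (low, high)

    @property
    def model(self):
        return self.merged.model if hasattr(self.merged, "model") else self.merged

    def current_value(self, ref: str) -> float:
        if ref.startswith("init:"):
            return self.model.get_species(ref[5:]).initial_amount
        if ref.startswith("scale:"):
            label = ref[6:]
            for o in self.observables:
                if o.label == label:
                    return o.scale
            raise KeyError(f"no observable labelled {label!r}")
        return self.model.get_parameter(ref).value

    def bounds_for(self, ref: str) -> tuple:
        if ref in self.bounds:
            return self.bounds[ref]
        v = abs(self.current_value(ref))
        if v == 0.0:
            return (1e-12, 1e3)
        return (v / DEFAULT_BOUND_SPAN, v * DEFAULT_BOUND_SPAN)


@dataclass
class FitResult:
    estimates: dict
    chi2_over_n_total: float
    per_side: tuple  # (A value, B value); nan when a side has no data
    per_dataset: dict
    n_starts: int
    converged: bool
    seed: int
    start_costs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "chi2_over_N_total": self.chi2_over_n_total,
            "per_side": {"A": self.per_side[0], "B": self.per_side[1]},
            "per_dataset": self.per_dataset,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_parameters(problem: FitProblem, n_starts: int = 5, seed: int = 0) -> FitResult:
    """Minimize the pooled chi-square over all datasets simultaneously.

    Multi-start: the first start is the current parameterization, further
    starts are log-uniform draws within the bounds.  Returns the best
    result; ``chi2_over_n_total`` equals the consistency statistic
    recomputed at the estimates.
    """
    if not problem.free_parameters:
        raise FitError("free_parameters is empty")
    refs = list(problem.free_parameters)
    lows = np.array([problem.bounds_for(r)[0] for r in refs])
    highs = np.array([problem.bounds_for(r)[1] for r in refs])
    if np.any(lows <= 0):
        raise FitError("fit parameters require positive lower bounds (log transform)")
    x0 = np.array([np.clip(problem.current_value(r), lows[i], highs[i])
                   for i, r in enumerate(refs)])

    log_lo, log_hi = np.log(lows), np.log(highs)
    n_total = sum(ds.n_points for ds in problem.datasets)
    failures = []

    def residuals(theta):
        values = dict(zip(refs, np.exp(theta)))
        try:
            return _stacked_residuals(problem, values)
        except Exception as exc:  # integration failure: push the optimizer away
            failures.append(str(exc))
            return np.full(n_total, FAILED_RESIDUAL)

    rng = np.random.default_rng(seed)
    starts = [np.log(x0)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(log_lo, log_hi))

    best = None
    start_costs = []
    for theta0 in starts:
        theta0 = np.clip(theta0, log_lo, log_hi)
        try:
            sol = least_squares(
                residuals,
                theta0,
                bounds=(log_lo, log_hi),
                method="trf",
                x_scale="jac",
            )
        except Exception:
            start_costs.append(float("inf"))
            continue
        start_costs.append(float(sol.cost))
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(
            "all fit starts failed to integrate; diagnostics: "
            + "; ".join(failures[:3])
        )

    estimates = dict(zip(refs, np.exp(best.x)))
    chi2_total, per_side, per_dataset = _evaluate(problem, estimates)
    return FitResult(
        estimates={k: float(v) for k, v in estimates.items()},
        chi2_over_n_total=chi2_total,
        per_side=per_side,
        per_dataset=per_dataset,
        n_starts=len(starts),
        converged=True,
        seed=seed,
        start_costs=start_costs,
    )


def _split_refs(values: dict):
    params, inits, scales = {}, {}, {}
    for ref, v in values.items():
        if ref.startswith("init:"):
            inits[ref[5:]] = v
        elif ref.startswith("scale:"):
            scales[ref[6:]] = v
        else:
            params[ref] = v
    return params, inits, scales


def _dataset_outputs(problem: FitProblem, ds, params, inits, scales):
    model = problem.model
    obs_by_label = {o.label: o for o in problem.observables}
    traj = simulate(
        model,
        input_signal=ds.input,
        time_grid=ds.time_grid,
        param_overrides=params,
        initial_overrides=inits,
    )
    obs = []
    for label in ds.output_labels():
        o = obs_by_label[label]
        if label in scales:
            o = replace(o, scale=scales[label])
        obs.append(o)
    return observe(traj, obs)


def _stacked_residuals(problem: FitProblem, values: dict) -> np.ndarray:
    params, inits, scales = _split_refs(values)
    res = []
    for ds in problem.datasets:
        outs = _dataset_outputs(problem, ds, params, inits, scales)
        res.append(chi2_residuals(ds, outs))
    return np.concatenate(res)


def _evaluate(problem: FitProblem, values: dict):
    params, inits, scales = _split_refs(values)
    sums = {"A": 0.0, "B": 0.0}
    counts = {"A": 0, "B": 0}
    per_dataset = {}
    total_sum, total_n = 0.0, 0
    for ds in problem.datasets:
        outs = _dataset_outputs(problem, ds, params, inits, scales)
        r = chi2_residuals(ds, outs)
        ssq = float(np.sum(r * r))
        per_dataset[ds.label] = ssq / r.size
        total_sum += ssq
        total_n += r.size
        if ds.origin in sums:
            sums[ds.origin] += ssq
            counts[ds.origin] += r.size
    per_side = tuple(
        sums[s] / counts[s] if counts[s] else float("nan") for s in ("A", "B")
    )
    return total_sum / total_n, per_side, per_dataset


def apply_fit(merged, observables: list, result: FitResult):
    """Return copies of the merged model and observables carrying the
    fitted values."""
    import copy

    model = merged.model if hasattr(merged, "model") else merged
    params, inits, scales = _split_refs(result.estimates)
    new_model = model.copy()
    for pid, v in params.items():
        new_model.get_parameter(pid).value = v
    for sid, v in inits.items():
        new_model.get_species(sid).initial_amount = v
    new_obs = [
        replace(o, scale=scales[o.label]) if o.label in scales else o for o in observables
    ]
    if hasattr(merged, "model"):
        out = copy.copy(merged)
        out.model = new_model
        return out, new_obs
    return new_model, new_obs
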
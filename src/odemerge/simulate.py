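"""Deterministic ODE time-course simulation.

Models are compiled once into a vectorized right-hand side (sympy
``lambdify`` over the stoichiometry-weighted kinetic laws) and integrated
with a variable-step stiff solver (LSODA, atol 1e-10 / rtol 1e-8).  Kinetic
laws are interpreted as concentration change per unit time; boundary and
constant species are held fixed and act as the model's input channels.

Step stimuli are realized as constant values of input species held from
t = 0; input species not assigned by an :class:`InputSignal` are set to
zero (the silent-side convention used when checking a merged model against
one original's data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy
from scipy.integrate import solve_ivp

from odemerge.expr import parse_expr
from odemerge.model import KineticModel

ATOL = 1e-10
RTOL = 1e-8
NEGATIVE_TOL = 1e-6


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries solver diagnostics."""


class _NonFiniteDerivative(RuntimeError):
    pass


@dataclass(frozen=True)
class InputSignal:
    """Step stimulus: constant assignments to input species from t = 0.

    Input species of the model that carry no assignment default to zero.
    """

    assignments: tuple = ()  # ((species_id, amount), ...)
    label: str = ""

    @staticmethod
    def of(label: str = "", **amounts) -> "InputSignal":
        return InputSignal(assignments=tuple(sorted(amounts.items())), label=label)

    def as_dict(self) -> dict:
        return dict(self.assignments)


@dataclass(frozen=True)
class Observable:
    """Scaled readout of one species: output = scale * species value."""

    species_ref: str
    scale: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError(f"observable scale must be > 0, got {self.scale}")
        if not self.label:
            object.__setattr__(self, "label", self.species_ref)


@dataclass
class Trajectory:
    """Time grid plus one value series per label."""

    time_grid: np.ndarray
    values: dict = field(default_factory=dict)  # label -> np.ndarray

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        for label, series in self.values.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.time_grid.shape:
                raise ValueError(
                    f"series {label!r} has {arr.size} values for "
                    f"{self.time_grid.size} time points"
                )
            self.values[label] = arr

    def labels(self) -> list:
        return list(self.values)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.time_grid, **self.values})


class CompiledModel:
    """Model compiled for repeated simulation with varying parameters."""

    def __init__(self, model: KineticModel):
        self.model = model
        self.dynamic_ids = model.dynamic_species_ids()
        self.fixed_ids = model.fixed_species_ids()
        self.param_ids = model.parameter_ids()
        self.input_ids = model.inputs()

        dyn_syms = [sympy.Symbol(s) for s in self.dynamic_ids]
        fix_syms = [sympy.Symbol(s) for s in self.fixed_ids]
        par_syms = [sympy.Symbol(p) for p in self.param_ids]
        comp_vals = {sympy.Symbol(c.id): sympy.Float(c.size) for c in model.compartments}

        rhs = {s: sympy.Integer(0) for s in self.dynamic_ids}
        for rxn in model.reactions:
            rate = parse_expr(rxn.kinetic_law).xreplace(comp_vals)
            for sid, stoich in rxn.reactants:
                if sid in rhs:
                    rhs[sid] = rhs[sid] - stoich * rate
            for sid, stoich in rxn.products:
                if sid in rhs:
                    rhs[sid] = rhs[sid] + stoich * rate
        exprs = [rhs[s] for s in self.dynamic_ids]
        self._f = sympy.lambdify(
            (dyn_syms, fix_syms, par_syms), exprs, modules="numpy", cse=True
        )
        self._param_index = {p: i for i, p in enumerate(self.param_ids)}
        self.default_params = np.array(
            [p.value for p in model.parameters], dtype=float
        )

    def parameter_vector(self, overrides: dict = None) -> np.ndarray:
        p = self.default_params.copy()
        for pid, value in (overrides or {}).items():
            p[self._param_index[pid]] = value
        return p

    def initial_state(self, input_signal: InputSignal = None, overrides: dict = None):
        assigned = input_signal.as_dict() if input_signal else {}
        overrides = overrides or {}
        y0 = []
        for sid in self.dynamic_ids:
            y0.append(overrides.get(sid, self.model.get_species(sid).initial_amount))
        fixed = []
        for sid in self.fixed_ids:
            if sid in assigned:
                fixed.append(assigned[sid])
            elif sid in self.input_ids:
                fixed.append(0.0)  # silent inputs default to zero
            else:
                fixed.append(overrides.get(sid, self.model.get_species(sid).initial_amount))
        return np.array(y0, dtype=float), np.array(fixed, dtype=float)

    def integrate(
        self,
        time_grid,
        input_signal: InputSignal = None,
        param_overrides: dict = None,
        initial_overrides: dict = None,
    ) -> Trajectory:
        time_grid = np.asarray(time_grid, dtype=float)
        if time_grid.ndim != 1 or time_grid.size < 2:
            raise ValueError("time_grid must be a 1-D array with at least two points")
        if np.any(np.diff(time_grid) <= 0) or time_grid[0] != 0:
            raise ValueError("time_grid must be strictly increasing and start at 0")
        y0, fixed = self.initial_state(input_signal, initial_overrides)
        p = self.parameter_vector(param_overrides)

        def rhs(t, y):
            with np.errstate(all="ignore"):
                dy = np.asarray(self._f(y, fixed, p), dtype=float)
            # abort instead of letting the solver grind on inf/nan derivatives
            if not np.all(np.isfinite(dy)):
                raise _NonFiniteDerivative(
                    f"non-finite derivative at t={t:g} "
                    f"(state min {np.min(y):.3g}, max {np.max(y):.3g})"
                )
            return dy

        try:
            sol = solve_ivp(
                rhs,
                (time_grid[0], time_grid[-1]),
                y0,
                method="LSODA",
                t_eval=time_grid,
                rtol=RTOL,
                atol=ATOL,
            )
        except _NonFiniteDerivative as exc:
            raise SimulationError(
                f"integration of model {self.model.model_id!r} failed: {exc}"
            ) from exc
        if not sol.success:
            raise SimulationError(
                f"integration of model {self.model.model_id!r} failed: {sol.message}"
            )
        values = {}
        floor = -NEGATIVE_TOL * max(1.0, float(np.max(np.abs(sol.y))) if sol.y.size else 1.0)
        if sol.y.size and float(np.min(sol.y)) < floor:
            self.model.notes.append(
                f"simulation produced concentrations below -{NEGATIVE_TOL} "
                f"(min {float(np.min(sol.y)):.3e})"
            )
        for i, sid in enumerate(self.dynamic_ids):
            values[sid] = sol.y[i]
        for i, sid in enumerate(self.fixed_ids):
            values[sid] = np.full_like(time_grid, fixed[i])
        return Trajectory(time_grid=time_grid, values=values)


_COMPILE_CACHE: dict = {}


def compile_model(model: KineticModel) -> CompiledModel:
    cached = _COMPILE_CACHE.get(id(model))
    if cached is None or cached.model is not model:
        cached = CompiledModel(model)
        _COMPILE_CACHE[id(model)] = cached
    return cached


def simulate(
    model: KineticModel,
    input_signal: InputSignal = None,
    time_grid=None,
    param_overrides: dict = None,
    initial_overrides: dict = None,
) -> Trajectory:
    """Integrate a model under a step stimulus on the given time grid.

    Returns the raw species trajectories (every species, including the
    constant inputs) evaluated at exactly the requested time points.
    """
    if time_grid is None:
        time_grid = default_time_grid()
    return compile_model(model).integrate(
        time_grid, input_signal, param_overrides, initial_overrides
    )


def observe(traj: Trajectory, observables) -> Trajectory:
    """Apply scaling factors: output = scale * species trajectory."""
    out = {}
    for obs in observables:
        if obs.species_ref not in traj.values:
            raise KeyError(f"unknown species {obs.species_ref!r} in trajectory")
        out[obs.label] = obs.scale * traj.values[obs.species_ref]
    return Trajectory(time_grid=traj.time_grid, values=out)


def default_time_grid(t_end: float = 3600.0, n_points: int = 61) -> np.ndarray:
    """Default horizon for synthetic data: 0..t_end, evenly spaced."""
    return np.linspace(0.0, t_end, n_points)
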
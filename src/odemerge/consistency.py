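"""Consistency testing of a merged model against the originals' data.

Synthetic datasets are produced by simulating an original model and
interpreting its output values as data points with normally distributed
errors (10 % relative plus 5 % of the curve maximum as absolute error).
Agreement is measured by the chi-square merit function per data point,

    chi2/N = (1/N) * sum_i ((y_i - y_model(t_i)) / sigma_i)**2,

pooled per side over all of that side's datasets, outputs and time points.
The merged model is *consistent* when both pooled values are strictly
below one.  An integration goal declares the target relation per side
(strictly below one, or approximately one).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from odemerge.simulate import InputSignal, observe, simulate

REL_ERROR = 0.10
ABS_ERROR_OF_MAX = 0.05
SIGMA_FLOOR_FACTOR = 1e-6
APPROX_ONE_TOL = 1.05


class DatasetError(ValueError):
    pass


@dataclass
class Dataset:
    """One experiment: a step input, a time grid and observed outputs.

    ``observations`` maps output label -> (values, sigmas) arrays; ``N`` is
    the total number of (output, time point) observation pairs.
    """

    label: str
    input: InputSignal
    time_grid: np.ndarray
    observations: dict
    origin: str = "experimental"  # "A" | "B" | "experimental"

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        clean = {}
        for out, (y, s) in self.observations.items():
            y = np.asarray(y, dtype=float)
            s = np.asarray(s, dtype=float)
            if y.shape != self.time_grid.shape or s.shape != self.time_grid.shape:
                raise DatasetError(
                    f"dataset {self.label!r}: observation {out!r} does not cover "
                    "the time grid"
                )
            if np.any(s <= 0):
                raise DatasetError(
                    f"dataset {self.label!r}: non-positive sigma in output {out!r}"
                )
            clean[out] = (y, s)
        self.observations = clean

    @property
    def n_points(self) -> int:
        return len(self.observations) * self.time_grid.size

    def output_labels(self) -> list:
        return list(self.observations)

    def to_frame(self):
        import pandas as pd

        rows = []
        for out, (y, s) in self.observations.items():
            for t, yi, si in zip(self.time_grid, y, s):
                rows.append({"time": t, "output": out, "value": yi, "sigma": si})
        return pd.DataFrame(rows, columns=["time", "output", "value", "sigma"])

    def header(self) -> dict:
        return {
            "label": self.label,
            "origin": self.origin,
            "input": self.input.as_dict(),
        }

    def write(self, table_path, header_path=None) -> None:
        self.to_frame().to_csv(table_path, sep="\t", index=False)
        if header_path:
            with open(header_path, "w") as fh:
                json.dump(self.header(), fh, indent=2)

    @classmethod
    def read(cls, table_path, header_path) -> "Dataset":
        import pandas as pd

        frame = pd.read_csv(table_path, sep="\t")
        with open(header_path) as fh:
            header = json.load(fh)
        grid = np.array(sorted(frame["time"].unique()), dtype=float)
        obs = {}
        for out, chunk in frame.groupby("output"):
            chunk = chunk.sort_values("time")
            obs[out] = (chunk["value"].to_numpy(), chunk["sigma"].to_numpy())
        return cls(
            label=header["label"],
            input=InputSignal(
                assignments=tuple(sorted(header.get("input", {}).items())),
                label=header["label"],
            ),
            time_grid=grid,
            observations=obs,
            origin=header.get("origin", "experimental"),
        )


def make_synthetic_dataset(
    outputs, input_signal: InputSignal, origin: str, label: str = ""
) -> Dataset:
    """Turn simulated outputs into a synthetic dataset.

    The central values are the simulated values (no noise is added);
    sigma_i = 0.10*|y_i| + 0.05*max_t|y(t)| per output curve.  Curves that
    are identically zero get a floored sigma and a warning.
    """
    if outputs.time_grid.size == 0 or not outputs.values:
        raise DatasetError("cannot build a dataset from an empty trajectory")
    global_max = max((float(np.max(np.abs(v))) for v in outputs.values.values()), default=0.0)
    floor = SIGMA_FLOOR_FACTOR * (global_max if global_max > 0 else 1.0)
    observations = {}
    for out, y in outputs.values.items():
        curve_max = float(np.max(np.abs(y)))
        sigma = REL_ERROR * np.abs(y) + ABS_ERROR_OF_MAX * curve_max
        if curve_max == 0.0:
            warnings.warn(
                f"output {out!r} is identically zero; sigma floored at {floor:g}",
                stacklevel=2,
            )
        sigma = np.maximum(sigma, floor)
        observations[out] = (np.array(y, dtype=float), sigma)
    return Dataset(
        label=label or (input_signal.label or origin),
        input=input_signal,
        time_grid=outputs.time_grid,
        observations=observations,
        origin=origin,
    )


def chi2_residuals(dataset: Dataset, model_outputs) -> np.ndarray:
    """Stacked weighted residuals (y_i - y_model)/sigma_i for one dataset."""
    if not np.allclose(dataset.time_grid, model_outputs.time_grid):
        raise DatasetError(
            f"dataset {dataset.label!r}: model outputs evaluated on a different "
            "time grid"
        )
    res = []
    for out, (y, s) in dataset.observations.items():
        if out not in model_outputs.values:
            raise DatasetError(
                f"dataset {dataset.label!r}: model outputs lack label {out!r}"
            )
        res.append((y - model_outputs.values[out]) / s)
    return np.concatenate(res)


def chi2_over_n(dataset: Dataset, model_outputs) -> float:
    """Chi-square per data point of model outputs against one dataset."""
    r = chi2_residuals(dataset, model_outputs)
    return float(np.sum(r * r) / r.size)


@dataclass
class GoalResult:
    relations: list  # of {"side", "target", "value", "passed"}
    overall: bool

    def to_dict(self) -> dict:
        return {"relations": self.relations, "overall": self.overall}


@dataclass
class IntegrationGoal:
    """Declared target relation on the two per-side chi2/N values."""

    preserve_exact: str = "none"  # "A" | "B" | "none"
    relations: list = field(default_factory=list)  # (side, target)

    def __post_init__(self):
        if self.preserve_exact not in ("A", "B", "none"):
            raise ValueError("preserve_exact must be 'A', 'B' or 'none'")
        for side, target in self.relations:
            if side not in ("A", "B") or target not in ("strict-below-one", "approx-one"):
                raise ValueError(f"bad goal relation ({side!r}, {target!r})")

    @classmethod
    def preserve(cls, side: str) -> "IntegrationGoal":
        """Reproduce one side almost exactly, the other as well as possible."""
        other = "B" if side == "A" else "A"
        return cls(
            preserve_exact=side,
            relations=[(side, "strict-below-one"), (other, "approx-one")],
        )

    @classmethod
    def both_consistent(cls) -> "IntegrationGoal":
        return cls(
            preserve_exact="none",
            relations=[("A", "strict-below-one"), ("B", "strict-below-one")],
        )


@dataclass
class ConsistencyReport:
    chi2_a_over_n: float
    chi2_b_over_n: float
    per_dataset: dict = field(default_factory=dict)
    goal_result: GoalResult = None

    @property
    def consistent(self) -> bool:
        return self.chi2_a_over_n < 1.0 and self.chi2_b_over_n < 1.0

    def side_value(self, side: str) -> float:
        return self.chi2_a_over_n if side == "A" else self.chi2_b_over_n

    def to_dict(self) -> dict:
        return {
            "chi2_A_over_N": self.chi2_a_over_n,
            "chi2_B_over_N": self.chi2_b_over_n,
            "per_dataset": self.per_dataset,
            "consistent": self.consistent,
            "goal": self.goal_result.to_dict() if self.goal_result else None,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def check_consistency(
    merged,
    datasets_a: list,
    datasets_b: list,
    observables: list,
    goal: IntegrationGoal = None,
    param_overrides: dict = None,
    initial_overrides: dict = None,
) -> ConsistencyReport:
    """Simulate the merged model against each side's datasets and pool chi2/N.

    For an A-origin dataset the merged model is driven with that dataset's
    inputs while every input originating only from B stays at zero (and
    vice versa) — the silent-side-zero convention is built into the
    simulator's input handling.  Outputs are compared only on the labels
    the dataset observes, so outputs exclusive to the silent side never
    enter the statistic.
    """
    model = merged.model if hasattr(merged, "model") else merged
    obs_by_label = {o.label: o for o in observables}
    per_dataset = {}
    sums = {"A": 0.0, "B": 0.0}
    counts = {"A": 0, "B": 0}
    for side, datasets in (("A", datasets_a), ("B", datasets_b)):
        for ds in datasets:
            missing = [l for l in ds.output_labels() if l not in obs_by_label]
            if missing:
                raise DatasetError(
                    f"dataset {ds.label!r} observes outputs absent from the "
                    f"merged model's observable list: {missing}"
                )
            traj = simulate(
                model,
                input_signal=ds.input,
                time_grid=ds.time_grid,
                param_overrides=param_overrides,
                initial_overrides=initial_overrides,
            )
            outs = observe(traj, [obs_by_label[l] for l in ds.output_labels()])
            r = chi2_residuals(ds, outs)
            per_dataset[ds.label] = float(np.sum(r * r) / r.size)
            sums[side] += float(np.sum(r * r))
            counts[side] += r.size
    report = ConsistencyReport(
        chi2_a_over_n=sums["A"] / counts["A"] if counts["A"] else 0.0,
        chi2_b_over_n=sums["B"] / counts["B"] if counts["B"] else 0.0,
        per_dataset=per_dataset,
    )
    if goal is not None:
        report.goal_result = evaluate_goal(report, goal)
    return report


def evaluate_goal(
    report: ConsistencyReport, goal: IntegrationGoal, approx_tol: float = APPROX_ONE_TOL
) -> GoalResult:
    """Evaluate each goal relation: strict-below-one passes iff value < 1;
    approx-one passes iff value <= approx_tol."""
    relations = []
    for side, target in goal.relations:
        value = report.side_value(side)
        passed = value < 1.0 if target == "strict-below-one" else value <= approx_tol
        relations.append(
            {"side": side, "target": target, "value": value, "passed": bool(passed)}
        )
    return GoalResult(relations=relations, overall=all(r["passed"] for r in relations))
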
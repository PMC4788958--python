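import numpy as np
import pytest

from odemerge import (
    IntegrationGoal,
    MergePolicy,
    ToyPairSpec,
    auto_match,
    check_consistency,
    classify_conflicts,
    generate_toy_pair,
    merge_models,
)
from odemerge.fixtures import toy_observables
from odemerge.workflow import build_synthetic_datasets

#: short grid used throughout the suite to keep simulations cheap
GRID = np.linspace(0.0, 200.0, 31)


def merged_observables(spec):
    obs = toy_observables(spec)
    return list({o.label: o for o in obs["A"] + obs["B"]}.values())


def toy_pipeline(spec, policy="A", levels_a=(1.0,), levels_b=(1.0,), grid=GRID):
    """Run match -> merge -> synthetic datasets for a toy pair."""
    model_a, model_b, truth = generate_toy_pair(spec)
    matches = classify_conflicts(auto_match(model_a, model_b), model_a, model_b)
    merged = merge_models(model_a, model_b, matches, MergePolicy(policy))
    observables = merged_observables(spec)
    dataset_specs = [
        {"origin": "A", "input": {"A_Lig": float(level)}} for level in levels_a
    ] + [{"origin": "B", "input": {"B_Lig": float(level)}} for level in levels_b]
    datasets_a, datasets_b = build_synthetic_datasets(
        model_a, model_b, merged, observables, dataset_specs, grid
    )
    return {
        "model_a": model_a,
        "model_b": model_b,
        "truth": truth,
        "matches": matches,
        "merged": merged,
        "observables": observables,
        "datasets_a": datasets_a,
        "datasets_b": datasets_b,
    }


@pytest.fixture(scope="session")
def diverged_pipeline():
    """Case-study-shaped toy pair with a ten-fold overlap divergence."""
    spec = ToyPairSpec(
        n_exclusive_a=2,
        n_exclusive_b=2,
        overlap_species=5,
        overlap_reactions=4,
        seed=1,
        divergence=10.0,
    )
    out = toy_pipeline(spec, levels_b=(1.0, 0.3))
    out["spec"] = spec
    return out


@pytest.fixture(scope="session")
def refit_pipeline():
    """Small diverged pair plus a completed goal-driven refit (shared by the
    refit and acceptance tests; the fit is the expensive part)."""
    from odemerge.refit import FitProblem, apply_fit, candidate_free_parameters, fit_parameters

    spec = ToyPairSpec(
        n_exclusive_a=1,
        n_exclusive_b=1,
        overlap_species=2,
        overlap_reactions=1,
        seed=0,
        divergence=10.0,
    )
    state = toy_pipeline(spec, levels_b=(1.0, 0.3))
    goal = IntegrationGoal.preserve("A")
    pre = check_consistency(
        state["merged"], state["datasets_a"], state["datasets_b"], state["observables"], goal
    )
    candidates = candidate_free_parameters(
        state["merged"], state["matches"], goal, state["observables"]
    )
    problem = FitProblem(
        merged=state["merged"],
        free_parameters=candidates.all(),
        datasets=state["datasets_a"] + state["datasets_b"],
        observables=state["observables"],
    )
    result = fit_parameters(problem, n_starts=3, seed=0)
    refit_model, refit_obs = apply_fit(state["merged"], state["observables"], result)
    post = check_consistency(
        refit_model, state["datasets_a"], state["datasets_b"], refit_obs, goal
    )
    state.update(
        spec=spec,
        goal=goal,
        pre=pre,
        candidates=candidates,
        problem=problem,
        result=result,
        post=post,
        refit_model=refit_model,
        refit_obs=refit_obs,
    )
    return state
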
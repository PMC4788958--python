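import numpy as np
import pytest

from odemerge import (
    Dataset,
    InputSignal,
    IntegrationGoal,
    chi2_over_n,
    evaluate_goal,
    make_synthetic_dataset,
)
from odemerge.consistency import (
    ConsistencyReport,
    DatasetError,
    chi2_residuals,
    check_consistency,
)
from odemerge.simulate import Trajectory


def traj(values, grid=None):
    values = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    n = len(next(iter(values.values())))
    if grid is None:
        grid = np.linspace(0.0, float(n - 1), n)
    return Trajectory(grid, values)


class TestSyntheticSigma:
    def test_sigma_at_curve_maximum(self):
        # y = 10 on a curve with max 10: sigma = 0.10*10 + 0.05*10 = 1.5
        ds = make_synthetic_dataset(
            traj({"out": [0.0, 5.0, 10.0]}), InputSignal(), origin="A", label="d"
        )
        y, s = ds.observations["out"]
        assert s[2] == pytest.approx(1.5)

    def test_sigma_at_zero_point(self):
        # y = 0 on a curve with max 20: sigma = 0 + 0.05*20 = 1.0
        ds = make_synthetic_dataset(
            traj({"out": [0.0, 20.0]}), InputSignal(), origin="A", label="d"
        )
        y, s = ds.observations["out"]
        assert s[0] == pytest.approx(1.0)

    def test_central_values_carry_no_noise(self):
        ds = make_synthetic_dataset(
            traj({"out": [1.0, 2.0, 3.0]}), InputSignal(), origin="A", label="d"
        )
        np.testing.assert_array_equal(ds.observations["out"][0], [1.0, 2.0, 3.0])

    def test_zero_curve_gets_floor_and_warning(self):
        with pytest.warns(UserWarning, match="identically zero"):
            ds = make_synthetic_dataset(
                traj({"silent": [0.0, 0.0], "loud": [0.0, 20.0]}),
                InputSignal(),
                origin="A",
                label="d",
            )
        y, s = ds.observations["silent"]
        assert np.all(s > 0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(DatasetError):
            make_synthetic_dataset(
                Trajectory(np.array([]), {}), InputSignal(), origin="A"
            )

    def test_n_counts_all_pairs(self):
        ds = make_synthetic_dataset(
            traj({"x": [1.0, 2.0, 3.0], "y": [1.0, 1.0, 1.0]}),
            InputSignal(),
            origin="A",
        )
        assert ds.n_points == 6


class TestChi2:
    def dataset(self, y, sigma, grid=None):
        y = np.asarray(y, dtype=float)
        grid = np.linspace(0.0, float(len(y) - 1), len(y)) if grid is None else grid
        return Dataset(
            label="d",
            input=InputSignal(),
            time_grid=grid,
            observations={"out": (y, np.asarray(sigma, dtype=float))},
            origin="A",
        )

    def test_exact_agreement_gives_zero(self):
        ds = self.dataset([1.0, 2.0], [0.5, 0.5])
        assert chi2_over_n(ds, traj({"out": [1.0, 2.0]})) == 0.0

    def test_single_point_hand_value(self):
        # ((12 - 10) / 2)^2 / 1 = 1.0
        ds = Dataset(
            label="d",
            input=InputSignal(),
            time_grid=np.array([0.0]),
            observations={"out": (np.array([10.0]), np.array([2.0]))},
            origin="A",
        )
        assert chi2_over_n(ds, traj({"out": [12.0]}, grid=np.array([0.0]))) == pytest.approx(1.0)

    def test_residuals_are_squared(self):
        r = chi2_residuals(self.dataset([10.0, 10.0], [2.0, 2.0]),
                           traj({"out": [12.0, 10.0]}))
        assert np.sum(r**2) == pytest.approx(1.0)

    def test_nonnegative_and_zero_iff_exact(self):
        ds = self.dataset([1.0, 2.0], [0.1, 0.1])
        assert chi2_over_n(ds, traj({"out": [1.0, 2.0000001]})) > 0.0

    def test_scale_equivariance(self):
        """Scaling data and model by c leaves chi2/N unchanged because sigma
        is built from the same curve."""
        rng = np.random.default_rng(0)
        y = rng.uniform(1.0, 5.0, 8)
        model = y * rng.uniform(0.8, 1.2, 8)
        for c in (0.1, 3.0, 1000.0):
            ds1 = make_synthetic_dataset(traj({"out": y}), InputSignal(), origin="A")
            ds2 = make_synthetic_dataset(traj({"out": c * y}), InputSignal(), origin="A")
            v1 = chi2_over_n(ds1, traj({"out": model}))
            v2 = chi2_over_n(ds2, traj({"out": c * model}))
            assert v2 == pytest.approx(v1, rel=1e-12)

    def test_grid_mismatch_raises(self):
        ds = self.dataset([1.0, 2.0], [0.5, 0.5])
        with pytest.raises(DatasetError, match="time grid"):
            chi2_over_n(ds, traj({"out": [1.0, 2.0]}, grid=np.array([0.0, 2.0])))

    def test_missing_label_raises(self):
        ds = self.dataset([1.0, 2.0], [0.5, 0.5])
        with pytest.raises(DatasetError, match="out"):
            chi2_over_n(ds, traj({"other": [1.0, 2.0]}))


class TestConsistencyReport:
    def report(self, a, b):
        return ConsistencyReport(chi2_a_over_n=a, chi2_b_over_n=b)

    def test_both_below_one_is_consistent(self):
        assert self.report(0.0004, 0.899).consistent

    def test_large_side_b_is_inconsistent(self):
        assert not self.report(0.0004, 1689.3).consistent

    def test_exactly_one_is_inconsistent(self):
        assert not self.report(0.5, 1.0).consistent

    def test_json_round_trip(self):
        import json

        rep = self.report(0.1, 0.2)
        rep.goal_result = evaluate_goal(rep, IntegrationGoal.preserve("A"))
        assert json.loads(rep.to_json())["consistent"] is True


class TestGoals:
    def test_preserve_a_goal_passes_on_paper_shaped_values(self):
        rep = ConsistencyReport(chi2_a_over_n=0.289, chi2_b_over_n=0.899)
        result = evaluate_goal(rep, IntegrationGoal.preserve("A"))
        assert result.overall

    def test_pre_refit_state_fails_on_side_b(self):
        rep = ConsistencyReport(chi2_a_over_n=0.0004, chi2_b_over_n=1689.3)
        result = evaluate_goal(rep, IntegrationGoal.preserve("A"))
        failed = [r for r in result.relations if not r["passed"]]
        assert not result.overall
        assert failed and all(r["side"] == "B" for r in failed)

    def test_perfect_fit_passes_any_goal(self):
        rep = ConsistencyReport(chi2_a_over_n=0.0, chi2_b_over_n=0.0)
        for goal in (IntegrationGoal.preserve("A"), IntegrationGoal.preserve("B"),
                     IntegrationGoal.both_consistent()):
            assert evaluate_goal(rep, goal).overall

    def test_approx_one_tolerance(self):
        rep = ConsistencyReport(chi2_a_over_n=0.5, chi2_b_over_n=1.04)
        assert evaluate_goal(rep, IntegrationGoal.preserve("A")).overall
        rep2 = ConsistencyReport(chi2_a_over_n=0.5, chi2_b_over_n=1.2)
        assert not evaluate_goal(rep2, IntegrationGoal.preserve("A")).overall

    def test_at_most_one_preserved_side(self):
        with pytest.raises(ValueError):
            IntegrationGoal(preserve_exact="C")


class TestSelfConsistency:
    def test_each_original_matches_its_own_synthetic_data(self, diverged_pipeline):
        """Checked against its own synthetic datasets, the merged model under
        policy A reproduces side A to within pure integration error."""
        state = diverged_pipeline
        report = check_consistency(
            state["merged"],
            state["datasets_a"],
            state["datasets_b"],
            state["observables"],
        )
        assert report.chi2_a_over_n < 1e-6

    def test_diverged_side_fails(self, diverged_pipeline):
        report = check_consistency(
            diverged_pipeline["merged"],
            diverged_pipeline["datasets_a"],
            diverged_pipeline["datasets_b"],
            diverged_pipeline["observables"],
        )
        assert report.chi2_b_over_n > 1.0
        assert not report.consistent

    def test_monotone_degradation_near_optimum(self, diverged_pipeline):
        """Perturbing one overlap parameter away from the data-generating
        value monotonically increases the affected side's chi2/N."""
        state = diverged_pipeline
        pid = "k_deact1"
        base = state["merged"].model.get_parameter(pid).value
        values = []
        for factor in (1.0, 2.0, 4.0, 8.0):
            rep = check_consistency(
                state["merged"],
                state["datasets_a"],
                [],
                state["observables"],
                param_overrides={pid: base * factor},
            )
            values.append(rep.chi2_a_over_n)
        assert values == sorted(values)
        assert values[-1] > values[0]


class TestDatasetIO:
    def test_table_round_trip(self, tmp_path, diverged_pipeline):
        ds = diverged_pipeline["datasets_a"][0]
        table = tmp_path / "ds.tsv"
        header = tmp_path / "ds.json"
        ds.write(table, header)
        again = Dataset.read(table, header)
        assert again.label == ds.label
        assert again.origin == ds.origin
        assert again.input.as_dict() == ds.input.as_dict()
        for out in ds.observations:
            np.testing.assert_allclose(again.observations[out][0], ds.observations[out][0])
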
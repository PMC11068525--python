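import numpy as np
import pytest

from squadflow import (Experiment, FitProblem, build_topology, chi_square,
                       count_free_parameters, default_parameters, fit,
                       fit_multistart, warm_start)
from squadflow.dataprep import MeasurementSeries
from squadflow.errors import ConfigurationError, WarmStartError
from squadflow.fitting import DEFAULT_BOUNDS
from squadflow.simulation import simulate
from squadflow.synthetic import generate_dataset, three_gene_recovery


def _series(gene, times, values, sigma):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    s = np.full_like(values, sigma)
    return MeasurementSeries(gene, times, values, s, s, np.ones(len(values), int))


class TestChiSquare:
    def test_exact_reproduction_gives_zero(self, recovery_fixture):
        topo, truth, _ = recovery_fixture
        exp = generate_dataset(topo, truth, np.linspace(1, 8, 4), 0.0, seed=1)
        problem = FitProblem(topo, [exp], baseline=truth)
        total, _, _ = chi_square(problem, truth)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_single_residual_hand_value(self):
        """One data point off by one sigma contributes exactly 1."""
        topo = build_topology(["A"], [])
        params = default_parameters(topo, x0=0.5)
        # model: x(t) = 0.5 e^{-t}; at t=0 model=0.5, data=0.6, sigma=0.1
        exp = Experiment("e", {"A": _series("A", [0.0], [0.6], 0.1)})
        problem = FitProblem(topo, [exp], baseline=params)
        total, breakdown, n = chi_square(problem, params)
        assert total == pytest.approx(1.0)
        assert breakdown[("e", "A")] == pytest.approx(1.0)
        assert n == 1

    def test_n_data_counts_observed_triples(self):
        """18 observed genes at 4 time points give 72 data points."""
        genes = [f"g{i}" for i in range(18)]
        topo = build_topology(genes, [(genes[i], genes[i + 1], "+")
                                      for i in range(17)])
        params = default_parameters(topo, x0=0.5)
        times = [0.0, 4.0, 24.0, 72.0]
        series = {g: _series(g, times, [0.5, 0.4, 0.3, 0.2], 0.05)
                  for g in genes}
        problem = FitProblem(topo, [Experiment("e", series)], baseline=params)
        _, _, n = chi_square(problem, params)
        assert n == 72

    def test_breakdown_sums_to_total(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = FitProblem(topo, [exp], baseline=truth)
        total, breakdown, _ = chi_square(problem, truth)
        assert total == pytest.approx(sum(breakdown.values()), abs=1e-9)

    def test_multi_experiment_accumulation(self, recovery_fixture):
        topo, truth, _ = recovery_fixture
        e1 = generate_dataset(topo, truth, np.linspace(1, 8, 4), 0.05, 1, label="e1")
        e2 = generate_dataset(topo, truth, np.linspace(1, 8, 4), 0.05, 2, label="e2")
        truth2 = truth.copy()
        truth2.initial_states["e1"] = dict(truth.initial_states["default"])
        truth2.initial_states["e2"] = dict(truth.initial_states["default"])
        both = FitProblem(topo, [e1, e2], baseline=truth2)
        single1 = FitProblem(topo, [e1], baseline=truth2)
        single2 = FitProblem(topo, [e2], baseline=truth2)
        t_both, _, n_both = chi_square(both, truth2)
        t1, _, n1 = chi_square(single1, truth2)
        t2, _, n2 = chi_square(single2, truth2)
        assert t_both == pytest.approx(t1 + t2, rel=1e-12)
        assert n_both == n1 + n2


class TestCountFreeParameters:
    def test_enumeration_small_model(self):
        """2 genes, 1 edge, h and x0 free: 1 + 2 + 2 = 5."""
        topo = build_topology(["A", "B"], [("A", "B", "+")])
        params = default_parameters(topo)
        exp = Experiment("default", {"A": _series("A", [0.0], [0.5], 0.1)})
        problem = FitProblem(topo, [exp], baseline=params)
        assert count_free_parameters(problem) == 5

    def test_all_fixed_requires_explicit_empty(self):
        from squadflow.errors import ParameterError
        topo = build_topology(["A", "B"], [("A", "B", "+")])
        params = default_parameters(topo)
        exp = Experiment("default", {"A": _series("A", [0.0], [0.5], 0.1)})
        with pytest.raises(ParameterError):
            FitProblem(topo, [exp], baseline=params,
                       free_parameters=["__sentinel__"])
        problem = FitProblem(topo, [exp], baseline=params)
        problem.free_parameters = []
        assert count_free_parameters(problem) == 0
        with pytest.raises(ConfigurationError):
            fit(problem)


class TestFit:
    def test_global_optimum_is_fixed_point(self, recovery_fixture):
        topo, truth, _ = recovery_fixture
        exp = generate_dataset(topo, truth, np.linspace(1, 8, 4), 0.0, seed=1)
        problem = FitProblem(topo, [exp], baseline=truth)
        result = fit(problem, truth)
        assert result.chi2_total == pytest.approx(0.0, abs=1e-6)

    def test_descent_from_perturbed_start(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        start = truth.copy()
        for pid, v in truth.to_flat().items():
            if pid.startswith(("a_", "h_")):
                lo, hi = problem.bounds_for(pid)
                start.set_flat(pid, float(np.clip(v * 1.2, lo, hi)))
        chi2_start, _, _ = chi_square(problem, start)
        result = fit(problem, start)
        assert result.chi2_total <= chi2_start + 1e-9

    def test_result_respects_bounds(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        result = fit(problem, truth)
        flat = result.params.to_flat()
        for pid in problem.free_parameters:
            lo, hi = problem.bounds_for(pid)
            assert lo <= flat[pid] <= hi

    def test_objective_agreement_with_resimulation(self, recovery_fixture):
        """The optimizer's reported chi-square equals an independent
        re-evaluation at the returned parameters (no stale caching)."""
        topo, truth, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        result = fit(problem, truth)
        fresh_total, _, _ = chi_square(problem, result.params)
        assert result.chi2_total == pytest.approx(fresh_total, abs=1e-6)

    def test_deterministic_given_start(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        r1 = fit(problem, truth, max_nfev=40)
        r2 = fit(problem, truth, max_nfev=40)
        assert r1.chi2_total == r2.chi2_total
        assert r1.params.to_flat() == r2.params.to_flat()


class TestMultistart:
    def test_best_not_worse_than_any_start(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        result = fit_multistart(problem, n_starts=3, seed=7, max_nfev=60)
        assert result.chi2_total <= min(result.start_chi2) + 1e-12
        assert len(result.start_chi2) == 3

    def test_reproducible_given_seed(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        r1 = fit_multistart(problem, n_starts=2, seed=5, max_nfev=30)
        r2 = fit_multistart(problem, n_starts=2, seed=5, max_nfev=30)
        assert r1.start_chi2 == r2.start_chi2

    def test_rejects_zero_starts(self, recovery_fixture):
        topo, _, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        with pytest.raises(ConfigurationError):
            fit_multistart(problem, n_starts=0, seed=1)


class TestWarmStart:
    def _problem(self, topo, exp):
        return FitProblem(topo, [exp])

    def test_unchanged_topology_is_identity(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = self._problem(topo, exp)
        init, report = warm_start(problem, truth)
        assert init.to_flat() == truth.to_flat()
        assert report["defaulted"] == []

    def test_new_edge_gets_default(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        bigger = build_topology(
            topo.node_ids,
            [(e.source, e.target, e.sign) for e in topo.edges]
            + [("G3", "G1", "activating")])
        problem = self._problem(bigger, exp)
        init, report = warm_start(problem, truth)
        assert "a_G3__G1" in report["defaulted"]
        assert set(report["carried"]) >= {"a_G1__G1", "h_G1"}
        for pid in report["carried"]:
            if pid in truth.to_flat():
                assert init.get_flat(pid) == truth.get_flat(pid)

    def test_out_of_bounds_value_clipped_and_flagged(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        problem = self._problem(topo, exp)
        problem.bounds["a_G1__G2"] = (0.1, 1.5)  # truth holds 2.0
        init, report = warm_start(problem, truth)
        assert init.get_flat("a_G1__G2") == 1.5
        assert "a_G1__G2" in report["clipped"]

    def test_sign_flip_refused(self, recovery_fixture):
        topo, truth, exp = recovery_fixture
        flipped = build_topology(
            topo.node_ids,
            [("G1", "G1", "+"), ("G1", "G2", "-"), ("G2", "G3", "+")])
        problem = self._problem(flipped, exp)
        with pytest.raises(WarmStartError, match="G1->G2"):
            warm_start(problem, truth)
        init, _ = warm_start(problem, truth, allow_sign_change=True)
        assert "b_G1__G2" in init.to_flat()


class TestDefaults:
    def test_default_box_matches_documented_values(self):
        assert DEFAULT_BOUNDS["a"] == (1e-3, 50.0)
        assert DEFAULT_BOUNDS["h"] == (1.0, 50.0)
        assert DEFAULT_BOUNDS["d"] == (0.0, 50.0)
        assert DEFAULT_BOUNDS["x0"] == (0.0, 1.0)

    def test_x0_initial_guess_uses_first_measurement(self, recovery_fixture):
        topo, _, exp = recovery_fixture
        problem = FitProblem(topo, [exp])
        for g, s in exp.series.items():
            assert problem.baseline.initial_states["default"][g] == \
                pytest.approx(float(s.values[0]))
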
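import numpy as np
import pytest
from hypothesis import given, strategies as st

from squadflow import (ParameterSet, StimulusChannel, StimulusProfile,
                       activation_response, build_topology, combined_input,
                       default_parameters, read_parameter_table, squad_rhs,
                       stimulus_term, write_parameter_table)
from squadflow.dynamics import SquadSystem, activation_response_dw
from squadflow.errors import (DegenerateWeightsError, ParameterError)

from oracles import reference_rhs


class TestActivationResponse:
    @pytest.mark.parametrize("h", [1.0, 5.0, 10.0, 50.0])
    def test_anchors(self, h):
        assert activation_response(0.0, h) == pytest.approx(0.0, abs=1e-12)
        assert activation_response(0.5, h) == pytest.approx(0.5, abs=1e-12)
        assert activation_response(1.0, h) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("h", [0.5, 1.0, 5.0, 10.0, 30.0])
    def test_strictly_increasing_on_grid(self, h):
        w = np.linspace(0.0, 1.0, 201)
        vals = activation_response(w, h)
        assert np.all(np.diff(vals) > 0)

    @given(st.floats(0.0, 1.0), st.floats(0.1, 40.0))
    def test_range_stays_in_unit_interval(self, w, h):
        v = activation_response(w, h)
        assert -1e-12 <= v <= 1.0 + 1e-12

    def test_derivative_matches_finite_difference(self):
        w, h, eps = 0.37, 7.0, 1e-6
        fd = (activation_response(w + eps, h) - activation_response(w - eps, h)) / (2 * eps)
        assert activation_response_dw(w, h) == pytest.approx(fd, rel=1e-6)

    def test_nonpositive_steepness_rejected(self):
        with pytest.raises(ParameterError):
            activation_response(0.5, 0.0)


class TestCombinedInput:
    def test_single_activator_hand_value(self):
        # (1+2)/2 * (2*0.5 / (1+2*0.5)) = 1.5 * 0.5 = 0.75
        assert combined_input([0.5], [2.0]) == pytest.approx(0.75)

    def test_saturation_and_null_anchors(self):
        assert combined_input([1.0, 1.0], [1.0, 3.0]) == pytest.approx(1.0)
        assert combined_input([0.0, 0.0], [1.0, 3.0]) == pytest.approx(0.0)

    def test_inhibitor_at_zero_is_neutral(self):
        w_act = combined_input([0.5], [2.0])
        w_both = combined_input([0.5], [2.0], [0.0], [1.5])
        assert w_both == pytest.approx(w_act)

    def test_inhibitors_only_inverts(self):
        # all inhibitors at max -> fully repressed
        assert combined_input([], [], [1.0], [2.0]) == pytest.approx(0.0)
        assert combined_input([], [], [0.0], [2.0]) == pytest.approx(1.0)

    def test_zero_weight_sum_is_degenerate(self):
        with pytest.raises(DegenerateWeightsError):
            combined_input([0.5], [0.0])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=4),
           st.lists(st.floats(0.0, 1.0), min_size=1, max_size=4),
           st.data())
    def test_always_in_unit_interval(self, act, inh, data):
        aw = data.draw(st.lists(st.floats(0.01, 10.0), min_size=len(act),
                                max_size=len(act)))
        iw = data.draw(st.lists(st.floats(0.01, 10.0), min_size=len(inh),
                                max_size=len(inh)))
        assert 0.0 <= combined_input(act, aw, inh, iw) <= 1.0


class TestStimulusTerm:
    def test_up_saturates_at_full_expression(self):
        assert stimulus_term("up", 3.0, 2.0, 1.0) == 0.0

    def test_down_vanishes_at_zero_expression(self):
        assert stimulus_term("down", 3.0, 2.0, 0.0) == 0.0

    def test_up_arithmetic(self):
        assert stimulus_term("up", 2.0, 0.5, 0.25) == pytest.approx(0.75)

    def test_zero_stimulus_is_null(self):
        assert stimulus_term("up", 2.0, 0.0, 0.3) == 0.0
        assert stimulus_term("down", 2.0, 0.0, 0.3) == 0.0


class TestSquadRhs:
    def test_unregulated_gene_decays(self):
        topo = build_topology(["A"], [])
        params = default_parameters(topo, x0=0.8)
        dx = squad_rhs(0.0, np.array([0.8]), topo, params)
        assert dx[0] == pytest.approx(-0.8)

    def test_inhibitor_only_at_zero_gives_full_activation(self):
        topo = build_topology(["A", "B"], [("A", "B", "-")])
        params = default_parameters(topo)
        dx = squad_rhs(0.0, np.array([0.0, 0.0]), topo, params)
        # w_B = 1 (inhibitor silent), activation = 1, decay of 0 is 0
        assert dx[1] == pytest.approx(1.0)

    def test_constant_node_frozen(self):
        topo = build_topology([("C", "constant"), "B"], [("C", "B", "+")])
        params = default_parameters(topo)
        dx = squad_rhs(0.0, np.array([0.4, 0.2]), topo, params)
        assert dx[0] == 0.0

    def test_shape_mismatch_raises(self, tiny_chain):
        params = default_parameters(tiny_chain)
        with pytest.raises(ParameterError):
            squad_rhs(0.0, np.zeros(2), tiny_chain, params)

    def test_missing_parameter_named(self, tiny_chain):
        params = default_parameters(tiny_chain)
        del params.steepness["B"]
        with pytest.raises(ParameterError, match="h_B"):
            squad_rhs(0.0, np.zeros(3), tiny_chain, params)

    def test_boundary_flow_inward(self):
        """At x_j=0 with no down-stimulus the derivative is >= 0; at
        x_j=1 with no up-stimulus it is <= 0 — the boundedness argument."""
        rng = np.random.default_rng(42)
        from squadflow.synthetic import SyntheticSpec, generate_topology, random_parameters
        for trial in range(20):
            spec = SyntheticSpec(n_genes=int(rng.integers(2, 5)),
                                 seed=int(rng.integers(1 << 30)),
                                 edge_prob=0.5)
            topo = generate_topology(spec)
            params = random_parameters(topo, seed=spec.seed + 1)
            system = SquadSystem(topo, params)
            x = rng.uniform(0.0, 1.0, size=system.n)
            for j in range(system.n):
                x_low, x_high = x.copy(), x.copy()
                x_low[j], x_high[j] = 0.0, 1.0
                assert system.rhs(0.0, x_low)[j] >= -1e-12
                assert system.rhs(0.0, x_high)[j] <= 1e-12

    def test_matches_reference_transcription(self):
        """Package right-hand side vs a literal symbol-by-symbol
        transcription of the node equations, with stimuli."""
        topo = build_topology(
            ["A", "B", "C", "D"],
            [("A", "B", "+"), ("C", "B", "-"), ("B", "C", "+"),
             ("A", "A", "+"), ("D", "C", "-")])
        channels = (StimulusChannel("k1", "B", "up"),
                    StimulusChannel("k2", "C", "down"))
        params = default_parameters(topo, channels)
        params.couplings["k1"], params.couplings["k2"] = 1.7, 0.9
        profile = StimulusProfile.constant(["k1", "k2"], [0.6, 1.2], 10.0)
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.uniform(0.0, 1.0, size=4)
            got = squad_rhs(0.0, x, topo, params, channels, profile)
            want = reference_rhs(x, topo, params,
                                 [("B", "up", 1.7, 0.6), ("C", "down", 0.9, 1.2)])
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_analytic_jacobian_matches_finite_differences(self):
        topo = build_topology(
            ["A", "B", "C"],
            [("A", "B", "+"), ("B", "C", "-"), ("C", "A", "+"), ("A", "C", "-")])
        channels = (StimulusChannel("k", "A", "down"),)
        params = default_parameters(topo, channels)
        system = SquadSystem(topo, params, channels)
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 0.9, size=3)
        u = np.array([0.8])
        J = system.jacobian(0.0, x, u)
        eps = 1e-7
        for i in range(3):
            dx = np.zeros(3); dx[i] = eps
            fd = (system.rhs(0.0, x + dx, u) - system.rhs(0.0, x - dx, u)) / (2 * eps)
            np.testing.assert_allclose(J[:, i], fd, atol=1e-6)


class TestParameterTable:
    def test_round_trip(self, tmp_path, tiny_chain):
        params = default_parameters(tiny_chain)
        params.activator_weights[("A", "B")] = 2.5
        path = tmp_path / "params.tsv"
        write_parameter_table(params, path, free=["a_A__B"])
        back, bounds, free = read_parameter_table(path)
        assert back.to_flat() == params.to_flat()
        assert free == ["a_A__B"]
        assert all(lo < hi for lo, hi in bounds.values())

    def test_profile_rejects_negative_levels(self):
        with pytest.raises(ParameterError):
            StimulusProfile(["k"], [0.0, 1.0], [[-0.1]])

    def test_profile_right_open_segments(self):
        p = StimulusProfile(["k"], [0.0, 1.0, 2.0], [[0.3, 0.7]])
        assert p.level_at("k", 0.0) == 0.3
        assert p.level_at("k", 0.999) == 0.3
        assert p.level_at("k", 1.0) == 0.7
        assert p.level_at("k", 2.0) == 0.7
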
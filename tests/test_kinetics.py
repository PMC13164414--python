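import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcrkin.kinetics import (
    SCENARIOS,
    KineticNetwork,
    Step,
    closed_form_chain,
    closed_form_fw,
    generator_network,
    integrate,
    preset_network,
    rhs,
)


def fw_pair(k1=0.01, k2=1.0):
    return KineticNetwork(
        ("D", "P"),
        (Step("first_order", "D", "P", "k1", k1),
         Step("autocatalytic", "D", "P", "k2", k2)),
        (1.0, 0.0),
    )


class TestRhs:
    def test_fw_pair_at_zero_product(self):
        net = fw_pair(k1=0.3, k2=5.0)
        dy = rhs(net, 0.0, np.array([1.0, 0.0]))
        assert np.allclose(dy, [-0.3, 0.3])  # autocatalytic term vanishes at P=0

    def test_lagged_step_inactive_before_tau(self):
        net = KineticNetwork(
            ("A", "B"),
            (Step("lagged_first_order", "A", "B", "k", 1.0, tau=5.0),),
            (1.0, 0.0),
        )
        assert np.allclose(rhs(net, 4.9, np.array([1.0, 0.0])), 0.0)
        assert np.allclose(rhs(net, 5.0, np.array([1.0, 0.0])), [-1.0, 1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_transfers_sum_to_zero_exactly(self, seed):
        rng = np.random.default_rng(seed)
        species = tuple(f"S{i}" for i in range(rng.integers(2, 6)))
        kinds = ["first_order", "autocatalytic", "lagged_first_order"]
        steps = []
        for j in range(rng.integers(1, 6)):
            i, k = rng.choice(len(species), 2, replace=False)
            steps.append(Step(kinds[rng.integers(0, 3)], species[i], species[k],
                              f"k{j}", float(rng.uniform(0, 2)),
                              tau=float(rng.uniform(0, 5))))
        net = KineticNetwork(species, tuple(steps),
                             tuple(rng.uniform(0, 1, len(species))))
        y = rng.uniform(0, 1, len(species))
        assert rhs(net, float(rng.uniform(0, 10)), y).sum() == pytest.approx(0, abs=1e-15)


class TestClosedForms:
    def test_fw_boundary_values(self):
        A, B = closed_form_fw(0.05, 0.8, 1.0, np.array([0.0, 1e4]))
        assert A[0] == pytest.approx(1.0)
        assert B[0] == pytest.approx(0.0)
        assert A[1] == pytest.approx(0.0, abs=1e-12)
        assert B[1] == pytest.approx(1.0)

    def test_fw_matches_brute_force_rk4(self):
        k1, k2, A0, T = 0.01, 1.0, 1.0, 10.0
        h, a = 1e-4, A0
        f = lambda x: -k1 * x - k2 * x * (A0 - x)
        for _ in range(int(T / h)):
            s1 = f(a); s2 = f(a + h / 2 * s1)
            s3 = f(a + h / 2 * s2); s4 = f(a + h * s3)
            a += h / 6 * (s1 + 2 * s2 + 2 * s3 + s4)
        assert closed_form_fw(k1, k2, A0, T)[0] == pytest.approx(a, abs=1e-7)

    def test_fw_zero_growth_degenerates_to_first_order(self):
        A, _ = closed_form_fw(0.3, 0.0, 2.0, 5.0)
        assert A == pytest.approx(2.0 * np.exp(-1.5))

    def test_chain_one_step(self):
        out = closed_form_chain([0.4], [1.0, 0.0], [2.0])
        assert out[0, 0] == pytest.approx(np.exp(-0.8))
        assert out[0, 1] == pytest.approx(1 - np.exp(-0.8))

    def test_chain_equal_rates_limit_form(self):
        k, t = 0.3, 5.0
        out = closed_form_chain([k, k], [1.0, 0.0, 0.0], [t])
        assert out[0, 1] == pytest.approx(t * k * np.exp(-k * t), rel=1e-10)

    def test_chain_cross_checks_integrator(self):
        net = KineticNetwork(
            ("R", "A", "B"),
            (Step("first_order", "R", "A", "k1", 0.2),
             Step("first_order", "A", "B", "k2", 0.05)),
            (1.0, 0.0, 0.0),
        )
        t = np.linspace(0, 10, 21)
        assert np.max(np.abs(integrate(net, t) -
                             closed_form_chain([0.2, 0.05], [1, 0, 0], t))) < 1e-7


class TestIntegrate:
    def test_zero_rates_frozen_at_y0(self):
        net = preset_network("30uL").with_rates([0] * 5)
        traj = integrate(net, np.linspace(0, 50, 11))
        assert np.allclose(traj, traj[0])

    def test_fw_pair_vs_closed_form(self):
        t = np.linspace(0, 100, 201)
        traj = integrate(fw_pair(), t)
        A, B = closed_form_fw(0.01, 1.0, 1.0, t)
        assert np.max(np.abs(traj - np.column_stack([A, B]))) < 1e-7

    def test_lag_splits_at_switch_time(self):
        net = KineticNetwork(
            ("A", "B"),
            (Step("lagged_first_order", "A", "B", "k", 0.5, tau=3.0),),
            (1.0, 0.0),
        )
        t = np.array([0.0, 1.0, 3.0, 5.0])
        traj = integrate(net, t)
        assert np.allclose(traj[:3, 0], 1.0)  # frozen until tau
        assert traj[3, 0] == pytest.approx(np.exp(-0.5 * 2.0), abs=1e-9)

    def test_times_contract(self):
        net = fw_pair()
        with pytest.raises(ValueError):
            integrate(net, [1.0, 2.0])  # must start at 0
        with pytest.raises(ValueError):
            integrate(net, [0.0, 0.0, 1.0])


class TestPresets:
    def test_30uL_has_exactly_one_lag_on_BD(self):
        net = preset_network("30uL")
        lagged = [s for s in net.steps if s.kind == "lagged_first_order"]
        assert len(lagged) == 1
        assert (lagged[0].source, lagged[0].target) == ("B", "D")
        assert lagged[0].tau > 0

    def test_90uL_branches_from_C(self):
        net = preset_network("90uL")
        arrows = {(s.source, s.target) for s in net.steps}
        assert ("C", "P") in arrows and ("C", "D") in arrows

    @pytest.mark.parametrize("scenario", SCENARIOS)
    def test_presets_conserve_mass(self, scenario):
        for net in (preset_network(scenario), generator_network(scenario)):
            traj = integrate(net, np.linspace(0, 80, 41))
            assert np.max(np.abs(traj.sum(axis=1) - sum(net.y0))) < 1e-9

    def test_generator_expands_merged_species(self):
        net = generator_network("60uL")
        assert net.species[:2] == ("R", "A")
        assert net.steps[0].rate >= 100  # reagent step faster than sampling

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="30uL"):
            preset_network("45uL")

    def test_negative_rate_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative rate"):
            Step("first_order", "A", "B", "k", -0.1)

    def test_serialization_roundtrip(self):
        net = preset_network("60uL")
        assert KineticNetwork.from_dict(net.to_dict()) == net


class TestSigmoidality:
    def test_fw_product_has_single_inflection(self):
        # slow nucleation + fast growth: mirrors the sigmoidal product uptake
        t = np.linspace(0, 200, 2001)
        _, B = closed_form_fw(0.005, 1.0, 1.0, t)
        second = np.diff(B, 2)
        signs = np.sign(second[np.abs(second) > 1e-12])
        assert np.sum(np.diff(signs) != 0) == 1
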
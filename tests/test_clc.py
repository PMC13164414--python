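import numpy as np
import pytest

from mcrkin.clc import (
    CLCModel,
    RIPENING_RATE,
    clc_fit,
    clc_fit_multi,
    clc_simulate,
    impacts_from_time,
    observable_profiles,
    preset_clc_model,
    preset_clc_scheme,
)
from mcrkin.kinetics import KineticNetwork, Step


class TestImpactsFromTime:
    def test_values(self):
        assert impacts_from_time(0.0, 1800.0) == 0.0
        assert impacts_from_time(2.0, 1800.0) == 3600.0

    def test_monotone(self):
        t = np.linspace(0, 10, 50)
        assert np.all(np.diff(impacts_from_time(t, 123.0)) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            impacts_from_time(1.0, 0.0)
        with pytest.raises(ValueError):
            impacts_from_time(-1.0, 10.0)


def single_step_scheme(k=0.01):
    return KineticNetwork(("A", "B", "D_n", "D_g", "P"),
                          (Step("first_order", "A", "B", "k_AB", k),),
                          (1, 0, 0, 0, 0))


class TestSimulate:
    def test_kappa_zero_freezes_state(self):
        m = CLCModel(1800.0, 0.0, single_step_scheme(), 0.0)
        traj = clc_simulate(m, np.linspace(1, 60, 10))
        assert np.allclose(traj, traj[0])
        assert traj[0, 0] == 1.0

    def test_first_order_closed_form_in_impact_number(self):
        kappa, k = 0.02, 0.01
        m = CLCModel(1800.0, kappa, single_step_scheme(k), 0.0)
        t = np.array([0.0, 1.0, 5.0, 10.0])
        traj = clc_simulate(m, t)
        expected = 1.0 - np.exp(-kappa * k * 1800.0 * t)
        assert np.max(np.abs(traj[:, 1] - expected)) < 1e-8

    @pytest.mark.parametrize("scenario", ["30uL", "60uL", "90uL"])
    def test_mass_conserved_and_product_monotone(self, scenario):
        m = preset_clc_model(scenario)
        traj = clc_simulate(m, np.arange(0.5, 80.6, 0.5))
        assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-9
        P = traj[:, m.local_scheme.index("P")]
        assert np.all(np.diff(P) >= -1e-12)

    def test_first_impact_seeds_product(self):
        m = CLCModel(60.0, 0.02, single_step_scheme(), 0.05)
        t = np.array([1.0 / 60.0, 2.0])  # exactly one impact, then many
        traj = clc_simulate(m, t)
        p = m.local_scheme.index("P")
        assert traj[0, p] == pytest.approx(0.0, abs=1e-9)  # pre-jump state at n=1
        assert traj[1, p] >= 0.05 - 1e-6
        assert traj.sum(axis=1) == pytest.approx(np.ones(2), abs=1e-9)

    def test_discrete_map_agrees_with_continuum(self):
        # f*t reaches 2000 impacts; continuum error ~ kappa*rate per step
        m = preset_clc_model("60uL", impact_frequency=50.0)
        t = np.arange(1.0, 41.0, 1.0)
        ode = clc_simulate(m, t, mode="ode")
        disc = clc_simulate(m, t, mode="discrete")
        assert np.max(np.abs(ode - disc)) < 1e-3

    def test_invalid_composition_rejected(self):
        scheme = KineticNetwork(("A", "P"), (), (0.0, 0.0))
        m = CLCModel(100.0, 0.1, scheme, 0.0)
        with pytest.raises(ValueError, match="composition"):
            clc_simulate(m, np.array([1.0]))


class TestPresets:
    def test_common_steps_across_all_scenarios(self):
        for scenario in ("30uL", "60uL", "90uL"):
            names = {s.rate_name for s in preset_clc_scheme(scenario).steps}
            assert {"k_AB", "k_DnDg", "k_DP"} <= names

    def test_only_90uL_routes_C_directly_to_product(self):
        arrows = {sc: {(s.source, s.target) for s in preset_clc_scheme(sc).steps}
                  for sc in ("30uL", "60uL", "90uL")}
        assert ("C", "P") in arrows["90uL"]
        assert ("C", "P") not in arrows["60uL"]
        assert "C" not in {a for a, _ in arrows["30uL"]}

    def test_only_30uL_resolves_reagent_step(self):
        assert any(s.rate_name == "k_RA" for s in preset_clc_scheme("30uL").steps)
        for sc in ("60uL", "90uL"):
            assert all(s.rate_name != "k_RA" for s in preset_clc_scheme(sc).steps)

    def test_observable_projection_sums_D_forms(self):
        scheme = preset_clc_scheme("60uL")
        traj = np.arange(12.0).reshape(2, 6)
        names, obs = observable_profiles(scheme, traj)
        i_n = scheme.index("D_n")
        i_g = scheme.index("D_g")
        assert names[-1] == "D"
        assert np.allclose(obs[:, -1], traj[:, i_n] + traj[:, i_g])


class TestFit:
    times = np.arange(0.5, 80.6, 0.5)

    def _truth_profiles(self, scenario, kappa=0.018, alpha=0.05):
        truth = preset_clc_model(scenario, kappa=kappa, alpha_P_start=alpha)
        traj = clc_simulate(truth, self.times)
        return truth, observable_profiles(truth.local_scheme, traj)

    def test_noiseless_self_consistency(self):
        truth, (names, obs) = self._truth_profiles("60uL")
        rng = np.random.default_rng(5)
        sch0 = truth.local_scheme.with_rates(
            truth.local_scheme.rates * rng.uniform(0.7, 1.3, 5))
        fit = clc_fit(obs, self.times, sch0, 1800.0, phases=names,
                      kappa0=0.018 * 1.25, alpha0=0.05 * 0.8)
        assert fit.kappa == pytest.approx(0.018, rel=0.01)
        assert fit.alpha_P_start[0] == pytest.approx(0.05, abs=1e-3)
        truth_rates = {s.rate_name: s.rate for s in truth.local_scheme.steps}
        for k, v in fit.rates[0].items():
            assert v == pytest.approx(truth_rates[k], rel=0.01)

    def test_linear_scheme_products_and_degeneracy_warning(self):
        # purely linear chain without the gauge step: only products are
        # identifiable and the fitter says so
        scheme = KineticNetwork(
            ("A", "B", "C", "P"),
            (Step("first_order", "A", "B", "k_AB", 0.010),
             Step("first_order", "B", "C", "k_BC", 0.006),
             Step("first_order", "C", "P", "k_CP", 0.004)),
            (1, 0, 0, 0))
        truth = CLCModel(1800.0, 0.018, scheme, 0.0)
        traj = clc_simulate(truth, self.times)
        names, obs = observable_profiles(scheme, traj)
        sch0 = scheme.with_rates(scheme.rates * 1.2)
        with pytest.warns(UserWarning, match="products"):
            fit = clc_fit(obs, self.times, sch0, 1800.0, phases=names,
                          kappa0=0.018 * 0.8, alpha0=1e-3)
        for k, v in fit.products[0].items():
            true_prod = 0.018 * {s.rate_name: s.rate for s in scheme.steps}[k.split("*")[1]]
            assert v == pytest.approx(true_prod, rel=0.01)

    def test_row_sums_outside_tolerance_rejected(self):
        _, (names, obs) = self._truth_profiles("60uL")
        with pytest.raises(ValueError, match="compositions"):
            clc_fit(0.5 * obs, self.times, preset_clc_scheme("60uL"), 1800.0,
                    phases=names)

    def test_shared_kappa_spread_across_scenarios(self):
        # data generated with ONE kappa; independent per-scenario fits must
        # land on nearly the same value (the LAG-independence signature)
        rng = np.random.default_rng(11)
        datasets = []
        for sc in ("30uL", "60uL", "90uL"):
            truth, (names, obs) = self._truth_profiles(sc)
            noisy = obs + rng.normal(0, 0.01, obs.shape)
            sch0 = truth.local_scheme.with_rates(
                truth.local_scheme.rates * rng.uniform(0.7, 1.3,
                                                       len(truth.local_scheme.steps)))
            datasets.append((noisy, names, self.times, sch0))
        sep = clc_fit_multi(datasets, 1800.0, share_kappa=False,
                            kappa0=0.02, alpha0=0.04)
        ratio = max(sep.kappa) / min(sep.kappa)
        assert ratio < 1.1
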
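import numpy as np
import pytest

from mcrkin.chemcore import simplisma
from mcrkin.kinetics import integrate, preset_network
from mcrkin.kinetic_mcr import KineticConstraintConfig, mcr_kinetic_fit
from mcrkin.mcr import als_fit, match_components
from mcrkin.synthetic import make_scenario


@pytest.fixture(scope="session")
def bundle30_noisy():
    """Standard 30 uL scenario at the default 2% noise level."""
    return make_scenario("30uL", noise_sd=0.02, seed=0)


@pytest.fixture(scope="session")
def bundle30_clean():
    return make_scenario("30uL", noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def soft_fit_30(bundle30_noisy):
    """Converged unconstrained resolution of the noisy 30 uL scenario."""
    sel = simplisma(bundle30_noisy.series, bundle30_noisy.n_components)
    return sel, als_fit(bundle30_noisy.series, sel.initial_estimate, max_iter=400)


@pytest.fixture(scope="session")
def kinetic_fit_30(bundle30_noisy, soft_fit_30):
    """Hard-constrained resolution of the same scenario, theta0 off by ±30%."""
    b = bundle30_noisy
    sel, soft = soft_fit_30
    net = preset_network("30uL")
    rng = np.random.default_rng(1000)
    net0 = net.with_rates(b.theta_true * rng.uniform(0.7, 1.3, 5),
                          [15.0 * rng.uniform(0.7, 1.3)])
    t_model = np.concatenate([[0.0], b.series.times])
    Y0 = integrate(net0, t_model)[1:]
    perm, _ = match_components(soft.C, Y0)
    mapping = {int(perm[j]): net.species[j] for j in range(5)}
    config = KineticConstraintConfig(network=net0, component_to_species=mapping)
    result = mcr_kinetic_fit(b.series, config, sel.initial_estimate)
    return config, mapping, result
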
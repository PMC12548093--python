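import numpy as np
import pytest

from n2oray import (
    Dataset,
    DeltaSet,
    Observation,
    estimate_rho_tau,
    fit_rayleigh_linear,
    generate_study_like,
    position_specific,
    rayleigh_abscissa,
)

ZERO_NOISE = dict(noise_sd_bulk=0.0, noise_sd_alpha=0.0, noise_sd_d18o=0.0)

# true per-site enrichment factors of the study-like generator (‰)
TRUE_EPS_NA = -7.2
TRUE_EPS_NB = -9.9
TRUE_D15N_S0 = -40.5


def make_dataset(
    abscissa_f,
    d15n_bulk,
    d15n_alpha=None,
    d18o=None,
    no_initial=10300.0,
    replicate_id="rep1",
):
    """Assemble a derived Dataset from f values and delta arrays."""
    f = np.asarray(abscissa_f, dtype=float)
    bulk = np.asarray(d15n_bulk, dtype=float)
    alpha = bulk if d15n_alpha is None else np.asarray(d15n_alpha, float)
    oxy = np.zeros_like(bulk) if d18o is None else np.asarray(d18o, float)
    obs = []
    for i in range(len(f)):
        n2o = no_initial * (1.0 - f[i]) / 2.0
        obs.append(Observation(
            replicate_id=replicate_id, time=float(i), n2o_cum=n2o,
            deltas=DeltaSet(d15n_bulk=bulk[i], d15n_alpha=alpha[i],
                            d18o=oxy[i]),
        ))
    return Dataset(observations=obs, no_initial=no_initial).with_derived()


def mariotti_delta(f, epsilon, delta_s0):
    """Exact linearized-model value: delta_s0 - eps * (-f ln f / (1-f))."""
    return delta_s0 + epsilon * np.array([rayleigh_abscissa(fi) for fi in f])


@pytest.fixture(scope="session")
def zero_noise_sim():
    return generate_study_like(seed=0, **ZERO_NOISE)


@pytest.fixture(scope="session")
def noisy_sim():
    return generate_study_like(seed=7)


@pytest.fixture(scope="session")
def recovery_study():
    """200-seed parameter-recovery study under the study-like conditions.

    Returns per-seed position-specific estimates and their propagated SEs.
    Shared across tests because the simulation sweep is the expensive part.
    """
    rows = {"eps_na": [], "se_na": [], "eps_nb": [], "se_nb": [],
            "eps_bulk": [], "identity_err": []}
    for seed in range(200):
        sim = generate_study_like(seed=seed)
        fit = fit_rayleigh_linear(sim.dataset, "d15n_bulk")
        rt = estimate_rho_tau(sim.dataset)
        ps = position_specific(rt, fit)
        rows["eps_na"].append(ps.epsilon_na)
        rows["se_na"].append(ps.se_epsilon_na)
        rows["eps_nb"].append(ps.epsilon_nb)
        rows["se_nb"].append(ps.se_epsilon_nb)
        rows["eps_bulk"].append(ps.epsilon_bulk)
        rows["identity_err"].append(abs(
            rt.tau * ps.alpha_na + (1 - rt.tau) * ps.alpha_nb - ps.alpha_bulk
        ))
    return {k: np.array(v) for k, v in rows.items()}
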
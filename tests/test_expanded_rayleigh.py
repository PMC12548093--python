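import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2oray import (
    AIR_N2,
    Dataset,
    atom_amounts,
    estimate_rho,
    estimate_rho_tau,
    estimate_tau,
    fit_rayleigh_linear,
    generate_study_like,
    position_specific,
    predict_bulk_delta,
)
from n2oray.rayleigh_bulk import LinearFitResult

from conftest import ZERO_NOISE, make_dataset, mariotti_delta


class TestPredictBulkDelta:
    def test_symmetric_self_consistency(self):
        # rho = 0.5 with equal site deltas reproduces the bulk delta
        a = atom_amounts(0.0, 0.0, 1000.0, AIR_N2)
        pred = predict_bulk_delta(0.5, a.n15_bulk, 1000.0, 0.0, AIR_N2)
        assert pred == pytest.approx(0.0, abs=1e-9)

    def test_hand_derived_value(self):
        # 0.5 * n15_bulk / (1000 - n15_alpha) / R_std is exactly 1 when the
        # inventory comes from delta = 0 at natural abundance
        pred = predict_bulk_delta(0.5, 7.326065719382688, 1000.0, 0.0, AIR_N2)
        assert pred == pytest.approx(0.0, abs=1e-9)

    def test_pole_behaviour(self):
        n15 = 7.3260657
        near_pole = predict_bulk_delta(0.999, n15 * 136.0, 1000.0, 0.0, AIR_N2)
        assert near_pole > 1e5  # diverges as rho*n15_bulk -> n2o
        with pytest.raises(ValueError):
            predict_bulk_delta(0.9, 2000.0, 1000.0, 0.0, AIR_N2)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.1])
    def test_rho_domain(self, rho):
        with pytest.raises(ValueError):
            predict_bulk_delta(rho, 7.0, 1000.0, 0.0, AIR_N2)


class TestEstimateRho:
    def test_zero_noise_recovers_true_alpha_share(self, zero_noise_sim):
        sim = zero_noise_sim
        est = estimate_rho(sim.dataset)
        tr = sim.trajectory
        shares = []
        for c, db, da in zip(tr["conversion"], tr["product_d15n_bulk"],
                             tr["product_d15n_alpha"]):
            n2o = sim.truth.no_initial * c / 2.0
            shares.append(atom_amounts(db, da, n2o).rho)
        assert est.converged
        assert np.max(np.abs(np.array(shares) - est.rho)) < 1e-6
        assert est.nonlinear_rmse < 1e-4

    def test_indistinguishable_sites_give_rho_equal_tau(self):
        sim = generate_study_like(seed=3, kie_na=1.008, kie_nb=1.008)
        est = estimate_rho_tau(sim.dataset)
        assert abs(est.rho - est.tau) < est.se_rho

    def test_order_invariance(self, noisy_sim):
        ds = noisy_sim.dataset
        est = estimate_rho(ds)
        rev = Dataset(observations=list(reversed(ds.observations)),
                      no_initial=ds.no_initial)
        est_rev = estimate_rho(rev)
        assert est.rho == pytest.approx(est_rev.rho, abs=1e-12)

    def test_rescaling_invariance(self, noisy_sim):
        ds = noisy_sim.dataset
        est = estimate_rho(ds)
        scaled = Dataset(
            observations=[
                o.__class__(**{**o.__dict__, "n2o_cum": o.n2o_cum * 3.0})
                for o in ds.observations
            ],
            no_initial=ds.no_initial * 3.0,
        )
        est_s = estimate_rho(scaled)
        assert est.rho == pytest.approx(est_s.rho, abs=1e-10)

    def test_too_few_observations(self):
        ds = make_dataset([0.4, 0.6], [-44.0, -43.0])
        with pytest.raises(ValueError):
            estimate_rho(ds)


class TestEstimateTau:
    def test_identical_site_deltas_give_half(self):
        f = np.linspace(0.3, 0.8, 6)
        bulk = mariotti_delta(f, -8.0, -40.0)
        ds = make_dataset(f, bulk, d15n_alpha=bulk)
        est = estimate_tau(ds)
        assert est.tau == pytest.approx(0.5, abs=1e-9)

    def test_natural_abundance_near_half(self, noisy_sim):
        est = estimate_tau(noisy_sim.dataset)
        assert abs(est.tau - 0.5) < 1e-4

    def test_enriched_alpha_brute_force_oracle(self):
        # alpha site 5 ‰ heavier than beta: tau dips below 0.5 by exactly
        # the per-row atom-accounting average
        f = np.linspace(0.3, 0.8, 6)
        bulk = mariotti_delta(f, -8.0, -40.0)
        ds = make_dataset(f, bulk, d15n_alpha=bulk + 2.5)
        est = estimate_tau(ds)
        oracle = np.mean([
            atom_amounts(o.deltas.d15n_bulk, o.deltas.d15n_alpha,
                         o.n2o_cum).tau
            for o in ds.observations
        ])
        assert est.tau < 0.5
        assert est.tau == pytest.approx(oracle, abs=1e-15)

    def test_p_value_is_one_sample_t(self, noisy_sim):
        from scipy import stats

        est = estimate_tau(noisy_sim.dataset)
        taus = [
            atom_amounts(o.deltas.d15n_bulk, o.deltas.d15n_alpha,
                         o.n2o_cum).tau
            for o in noisy_sim.dataset.observations
        ]
        t, p = stats.ttest_1samp(taus, 0.5)
        assert est.p_tau == pytest.approx(p, rel=1e-9)


class TestPositionSpecific:
    def _fit(self, slope=-8.55, se=0.9):
        return LinearFitResult(slope=slope, intercept=-40.5, se_slope=se,
                               se_intercept=0.3, r2=0.9, rmse=0.4,
                               p_slope=1e-6, n=13)

    def test_no_asymmetry_collapses_to_bulk(self):
        from n2oray.expanded_rayleigh import RhoTauEstimate

        rt = RhoTauEstimate(rho=0.43, se_rho=0.01, tau=0.43, se_tau=0.01)
        ps = position_specific(rt, self._fit())
        assert ps.alpha_na == pytest.approx(ps.alpha_bulk, abs=1e-15)
        assert ps.alpha_nb == pytest.approx(ps.alpha_bulk, abs=1e-15)

    @given(
        st.floats(0.05, 0.95), st.floats(0.05, 0.95),
        st.floats(-50.0, 50.0),
    )
    @settings(max_examples=200)
    def test_weighted_mean_identity(self, rho, tau, slope):
        from n2oray.expanded_rayleigh import RhoTauEstimate

        rt = RhoTauEstimate(rho=rho, se_rho=0.01, tau=tau, se_tau=0.01)
        ps = position_specific(rt, self._fit(slope=slope))
        assert (
            tau * ps.alpha_na + (1 - tau) * ps.alpha_nb
            == pytest.approx(ps.alpha_bulk, abs=1e-12)
        )

    def test_domain_errors(self):
        from n2oray.expanded_rayleigh import RhoTauEstimate

        rt = RhoTauEstimate(rho=1.2, se_rho=0.01, tau=0.5, se_tau=0.01)
        with pytest.raises(ValueError):
            position_specific(rt, self._fit())


def test_recovery_median_within_one_se(recovery_study):
    """Across 200 noisy study-like datasets the median fitted per-site
    enrichment factors sit within one propagated SE of the truth."""
    med_na = np.median(recovery_study["eps_na"])
    med_nb = np.median(recovery_study["eps_nb"])
    assert abs(med_na - -7.2) < np.mean(recovery_study["se_na"])
    assert abs(med_nb - -9.9) < np.mean(recovery_study["se_nb"])
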
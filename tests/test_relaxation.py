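"""Relaxation-time extraction and the Langmuir-type tau decay."""

import numpy as np
import pytest

from gelcomp import (BindingSystem, LangmuirDecayModel, NetworkSpec,
                     StressRelaxationCurve, ValidationError, crossover_tau,
                     fit_kww, fit_maxwell, fit_tau_min, kww_curve,
                     maxwell_sweep, predict_titration, tau_decay,
                     SyntheticSpec, FrequencySweep)


class TestCrossover:
    def test_maxwell_crossover_at_reciprocal_tau(self):
        sweep = maxwell_sweep(g_p=21700.0, tau=0.5)
        res = crossover_tau(sweep)
        assert res.found
        assert res.omega_c == pytest.approx(2.0, rel=1e-6)
        assert res.tau == pytest.approx(0.5, rel=1e-6)

    def test_uninhibited_gel_crossover_frequency(self):
        """tau = 0.725 s puts the crossover at 1.38 rad/s, the measured
        terminal frequency of the uninhibited boronate gel."""
        sweep = maxwell_sweep(g_p=21700.0, tau=0.725)
        res = crossover_tau(sweep)
        assert res.omega_c == pytest.approx(1.379, abs=0.002)

    def test_no_crossover_reported_not_raised(self):
        sweep = maxwell_sweep(g_p=1000.0, tau=1.0,
                              omega=np.logspace(1, 3, 20))  # elastic plateau only
        res = crossover_tau(sweep)
        assert not res.found
        assert res.tau is None

    def test_noisy_sweep_recovers_tau_within_5pct(self):
        sweep = maxwell_sweep(g_p=21700.0, tau=0.5,
                              spec=SyntheticSpec(noise_sd=0.05, seed=11))
        res = crossover_tau(sweep)
        assert res.found
        assert res.tau == pytest.approx(0.5, rel=0.05)

    def test_exact_gridpoint_crossing(self):
        sweep = FrequencySweep(omega=np.array([1.0, 2.0, 4.0]),
                               g_storage=np.array([10.0, 20.0, 40.0]),
                               g_loss=np.array([20.0, 20.0, 10.0]))
        res = crossover_tau(sweep)
        assert res.omega_c == pytest.approx(2.0)


class TestKWW:
    def test_exact_maxwell_curve(self):
        t = np.logspace(np.log10(0.01), np.log10(20.0), 60)
        curve = StressRelaxationCurve(time=t, g_t=np.exp(-t / 2.0))
        fit = fit_kww(curve)
        assert fit.tau_kww == pytest.approx(2.0, rel=1e-6)
        assert fit.beta == pytest.approx(1.0, abs=1e-6)

    def test_exact_stretched_curve(self):
        t = np.logspace(-2, np.log10(20.0), 80)
        curve = StressRelaxationCurve(time=t, g_t=np.exp(-t ** 0.6))
        fit = fit_kww(curve)
        assert fit.tau_kww == pytest.approx(1.0, rel=1e-6)
        assert fit.beta == pytest.approx(0.6, abs=1e-6)

    def test_fixed_beta_equals_free_fit_on_maxwell_data(self):
        curve = kww_curve(g0=1000.0, tau=0.7, beta=1.0)
        free = fit_kww(curve)
        fixed = fit_maxwell(curve)
        assert abs(free.tau_kww - fixed.tau_kww) < 1e-9
        assert fixed.beta == 1.0

    def test_noisy_stretched_curve_recovery(self):
        curve = kww_curve(g0=21700.0, tau=0.8, beta=0.9,
                          spec=SyntheticSpec(noise_sd=0.03, seed=7))
        fit = fit_kww(curve)
        assert fit.beta == pytest.approx(0.9, abs=0.05)
        assert fit.tau_kww == pytest.approx(0.8, rel=0.10)

    def test_three_methods_agree_on_noisy_maxwell(self):
        """Crossover, KWW and Maxwell taus comparable (within 15%) on
        near-Maxwellian data, as observed experimentally."""
        tau_true = 0.725
        sweep = maxwell_sweep(g_p=21700.0, tau=tau_true,
                              spec=SyntheticSpec(noise_sd=0.05, seed=3))
        curve = kww_curve(g0=21700.0, tau=tau_true, beta=1.0,
                          spec=SyntheticSpec(noise_sd=0.05, seed=4))
        taus = [crossover_tau(sweep).tau, fit_kww(curve).tau_kww,
                fit_maxwell(curve).tau_kww]
        for t in taus:
            assert t == pytest.approx(tau_true, rel=0.15)
        assert max(taus) / min(taus) < 1.15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_kww(StressRelaxationCurve(time=np.array([1.0, 2.0, 3.0]),
                                          g_t=np.array([1.0, 0.5, 0.1])))

    def test_shallow_decay_rejected(self):
        t = np.linspace(0.01, 0.1, 20)
        curve = StressRelaxationCurve(time=t, g_t=np.exp(-t))  # barely decays
        with pytest.raises(ValidationError):
            fit_kww(curve)


class TestTauDecay:
    def test_uninhibited_returns_tau0(self):
        m = LangmuirDecayModel(tau0=0.72, tau_min=0.1)
        assert tau_decay(m, nu_e=1.0, nu_e0=1.0)[0] == pytest.approx(0.72)

    def test_half_occupancy_value(self):
        m = LangmuirDecayModel(tau0=0.72, tau_min=0.1)
        assert tau_decay(m, nu_e=0.5, nu_e0=1.0)[0] == pytest.approx(0.41)

    def test_vanishing_chains_reach_tau_min(self):
        m = LangmuirDecayModel(tau0=0.72, tau_min=0.1)
        assert tau_decay(m, nu_e=0.0, nu_e0=1.0)[0] == pytest.approx(0.1)
        assert tau_decay(m, nu_e=1e-9, nu_e0=1.0)[0] == pytest.approx(0.1, abs=1e-6)

    def test_monotone_nonincreasing_in_concentration(self, boronate_binding,
                                                     network):
        concs = np.linspace(0, 0.02, 9)
        preds = predict_titration(boronate_binding, network, concs)
        nu = np.array([p.nu_e for p in preds])
        m = LangmuirDecayModel(tau0=0.72, tau_min=0.05)
        taus = tau_decay(m, nu, nu_e0=nu[0])
        assert np.all(np.diff(taus) <= 1e-12)
        assert taus[0] == pytest.approx(0.72)

    def test_as_printed_variant_clips_bracket(self, network):
        m = LangmuirDecayModel(tau0=0.72, tau_min=0.1, variant="as_printed")
        # 2 nu_e / n_xl > 1 clips to 1 -> tau_min
        taus = tau_decay(m, nu_e=network.n_xl, network=network)
        assert taus[0] == pytest.approx(0.1)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValidationError):
            LangmuirDecayModel(tau0=0.1, tau_min=0.5)


class TestFitTauMin:
    def _observations(self, binding, network, tau0, tau_min, noise_sd, seed):
        concs = np.array([0.0, 2.5e-3, 5e-3, 7.5e-3, 10e-3, 15e-3])
        preds = predict_titration(binding, network, concs)
        nu = np.array([p.nu_e for p in preds])
        m = LangmuirDecayModel(tau0=tau0, tau_min=tau_min)
        taus = tau_decay(m, nu, nu_e0=nu[0])
        rng = np.random.default_rng(seed)
        if noise_sd:
            taus = taus * (1 + noise_sd * rng.standard_normal(taus.shape))
        return concs, taus

    def test_noiseless_exact_recovery(self, boronate_binding, network):
        concs, taus = self._observations(boronate_binding, network,
                                         tau0=0.72, tau_min=0.05,
                                         noise_sd=0.0, seed=0)
        fit, rss = fit_tau_min(concs, taus, boronate_binding, network,
                               tau0=0.72)
        assert fit.tau_min == pytest.approx(0.05, abs=1e-6)
        assert rss < 1e-12

    def test_noisy_recovery_within_20pct(self, boronate_binding, network):
        concs, taus = self._observations(boronate_binding, network,
                                         tau0=0.72, tau_min=0.05,
                                         noise_sd=0.05, seed=21)
        fit, _ = fit_tau_min(concs, taus, boronate_binding, network, tau0=0.72)
        assert fit.tau_min == pytest.approx(0.05, rel=0.20)

    def test_strong_competitor_drives_tau_min_to_zero(self, network):
        """A series whose tail reaches nu_e ~ 0 with tau -> 0 fits
        tau_min ~ 0: relaxation near the gelation point."""
        b = BindingSystem(ka_xl=2200.0, ka_c=6700.0)
        concs = np.array([0.0, 5e-3, 10e-3, 20e-3, 30e-3])
        preds = predict_titration(b, network, concs)
        nu = np.array([p.nu_e for p in preds])
        taus = tau_decay(LangmuirDecayModel(tau0=0.72, tau_min=1e-6), nu,
                         nu_e0=nu[0])
        fit, _ = fit_tau_min(concs, taus, b, network, tau0=0.72)
        assert fit.tau_min < 0.01

    def test_degenerate_concentrations_rejected(self, boronate_binding,
                                                network):
        with pytest.raises(ValidationError):
            fit_tau_min(np.array([0.01, 0.01]), np.array([0.5, 0.5]),
                        boronate_binding, network, tau0=0.72)
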
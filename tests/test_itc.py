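"""Single-site ITC model and fitter: limiting cases, an independent
root-finder oracle, round trips, parameter recovery, and fold changes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from meltkit import itc


PROTOCOL = itc.default_protocol()
WT = itc.BindingParams(kd=itc.REFERENCE_AFFINITIES["MELT2P_wildtype"])


class TestForwardModel:
    def test_no_ligand_means_no_heat(self):
        assert itc.bound_fraction(30e-6, 0.0, 1.0, 1e-7) == 0.0

    def test_stoichiometric_limit_binds_all_injected_ligand(self):
        """K_D -> 0 with ligand below saturation: theta = X_t / (n M_t)."""
        mt, xt = itc.total_concentrations(PROTOCOL)
        sub = xt < 0.9 * mt          # early injections, well below saturation
        theta = itc.bound_fraction(mt[sub], xt[sub], 1.0, 1e-18)
        assert np.allclose(theta, xt[sub] / mt[sub], rtol=1e-6)

    def test_wiseman_c_at_reference_protocol(self):
        """30 µM cell concentration against the 200 nM wild-type affinity
        gives c = 150, a favorable regime for K_D fitting."""
        assert itc.wiseman_c(PROTOCOL, WT) == pytest.approx(150.0)

    def test_zero_enthalpy_returns_pure_dilution_heats(self):
        params = itc.BindingParams(kd=1e-6, dh_cal=0.0, q_dil_ucal=-0.25)
        heats = itc.injection_heats(PROTOCOL, params)
        assert np.allclose(heats, -0.25)

    def test_post_saturation_heats_approach_dilution(self):
        heats = itc.injection_heats(PROTOCOL, WT)
        assert abs(heats[-1] - WT.q_dil_ucal) < 0.05 * abs(heats[0])

    def test_injection_heats_telescope_to_cumulative_heat(self):
        """Summing the corrected injection heats minus the dilution and
        displaced-volume terms recovers the final cumulative heat exactly."""
        q = itc.cumulative_heat(PROTOCOL, WT)
        heats = itc.injection_heats(PROTOCOL, WT)
        qprev = np.r_[0.0, q[:-1]]
        v = np.asarray(PROTOCOL.injection_volumes_ul)
        displaced = (v / PROTOCOL.cell_volume_ul) * (q + qprev) / 2.0
        total = np.sum(heats - WT.q_dil_ucal - displaced)
        assert total == pytest.approx(q[-1], rel=1e-12)

    def test_bound_fraction_agrees_with_root_finder_oracle(self):
        """Quadratic solution vs brentq on the mass-action equation."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            mt = 10 ** rng.uniform(-6, -4)
            xt = 10 ** rng.uniform(-7, -3)
            n = rng.uniform(0.5, 2.0)
            kd = 10 ** rng.uniform(-9, -4)
            s = n * mt

            def f(theta):
                return s * theta ** 2 - (xt + s + kd) * theta + xt

            oracle = brentq(f, 0.0, 1.0, xtol=1e-16, rtol=1e-15)
            assert itc.bound_fraction(mt, xt, n, kd) == pytest.approx(
                oracle, abs=1e-10)

    @given(st.floats(-8.5, -5.0), st.floats(0.5, 2.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_mass_conservation(self, log_kd, n):
        mt, xt = itc.total_concentrations(PROTOCOL)
        theta = itc.bound_fraction(mt, xt, n, 10 ** log_kd)
        bound = theta * n * mt
        assert np.all(bound <= np.minimum(n * mt, xt) + 1e-15)
        assert np.all((theta >= 0) & (theta <= 1))

    def test_sigmoid_inflection_sits_at_unit_molar_ratio(self):
        """At c=150 the heat-per-injection curve drops steepest where the
        molar ratio X_t / M_t crosses the stoichiometry n = 1."""
        heats = itc.injection_heats(PROTOCOL, WT)
        mt, xt = itc.total_concentrations(PROTOCOL)
        ratio = xt / mt
        steepest = ratio[np.argmax(np.abs(np.diff(heats))) + 1]
        assert 0.85 < steepest < 1.15


class TestSimulator:
    def test_zero_noise_reproduces_model_heats(self):
        tg = itc.simulate_thermogram(PROTOCOL, WT, noise_sd=0.0)
        assert np.array_equal(tg.heats_ucal, itc.injection_heats(PROTOCOL, WT))

    def test_seeded_noise_is_reproducible(self):
        t1 = itc.simulate_thermogram(PROTOCOL, WT, noise_sd=0.1, seed=42)
        t2 = itc.simulate_thermogram(PROTOCOL, WT, noise_sd=0.1, seed=42)
        t3 = itc.simulate_thermogram(PROTOCOL, WT, noise_sd=0.1, seed=43)
        assert np.array_equal(t1.heats_ucal, t2.heats_ucal)
        assert not np.array_equal(t1.heats_ucal, t3.heats_ucal)

    def test_csv_round_trip(self, tmp_path):
        tg = itc.simulate_thermogram(PROTOCOL, WT, noise_sd=0.1, seed=1)
        tg.to_csv(tmp_path / "tg.csv")
        back = itc.Thermogram.from_csv(tmp_path / "tg.csv")
        assert np.allclose(back.heats_ucal, tg.heats_ucal)
        assert np.allclose(back.injection_volumes_ul, tg.injection_volumes_ul)


class TestFitting:
    def test_noiseless_fit_recovers_parameters_exactly(self):
        truth = itc.BindingParams(kd=200e-9, n=0.97, dh_cal=-11500.0,
                                  q_dil_ucal=-0.2)
        tg = itc.simulate_thermogram(PROTOCOL, truth, noise_sd=0.0)
        fit = itc.fit_single_site(tg, PROTOCOL)
        assert fit.converged and not fit.no_binding
        assert fit.params.kd == pytest.approx(truth.kd, rel=1e-6)
        assert fit.params.n == pytest.approx(truth.n, rel=1e-6)
        assert fit.params.dh_cal == pytest.approx(truth.dh_cal, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        from meltkit.pipeline import recover_kd
        rec = recover_kd(200e-9, seed=5, n_seeds=25)
        assert rec["n_converged"] == 25
        assert rec["kd_median"] == pytest.approx(200e-9, rel=0.10)

    def test_standard_errors_scale_with_noise(self):
        tgs = [itc.simulate_thermogram(PROTOCOL, WT, noise_sd=sd, seed=3)
               for sd in (0.05, 0.5)]
        fits = [itc.fit_single_site(tg, PROTOCOL) for tg in tgs]
        assert all(f.bse["kd"] > 0 for f in fits)
        assert fits[1].bse["kd"] > fits[0].bse["kd"]

    def test_dilution_only_heats_are_flagged_no_binding(self):
        params = itc.BindingParams(kd=1e-6, dh_cal=0.0, q_dil_ucal=-0.1)
        tg = itc.simulate_thermogram(PROTOCOL, params, noise_sd=0.1, seed=7)
        fit = itc.fit_single_site(tg, PROTOCOL)
        assert fit.no_binding

    def test_summary_reports_the_estimates(self):
        tg = itc.simulate_thermogram(PROTOCOL, WT, noise_sd=0.1, seed=2)
        fit = itc.fit_single_site(tg, PROTOCOL)
        text = fit.summary()
        assert "K_D" in text and "Wiseman" in text
        assert f"{fit.nobs}" in text

    def test_too_few_injections_rejected(self):
        short = itc.default_protocol(n_injections=5)
        tg = itc.simulate_thermogram(short, WT, noise_sd=0.0)
        with pytest.raises(ValueError):
            itc.fit_single_site(tg, short)


class TestFoldChange:
    def _fit(self, kd, seed):
        params = itc.BindingParams(kd=kd)
        noise = 0.01 * np.max(np.abs(itc.injection_heats(PROTOCOL, params)))
        tg = itc.simulate_thermogram(PROTOCOL, params, noise, seed)
        return itc.fit_single_site(tg, PROTOCOL)

    def test_identical_fits_give_unit_ratio(self):
        fit = self._fit(200e-9, 1)
        assert itc.fold_change(fit, fit) == pytest.approx(1.0)

    def test_reader_without_partner_loses_tenfold_affinity(self):
        """Bub3 alone (2 µM) vs the Bub1-Bub3 complex (200 nM): ~10x."""
        wt = self._fit(itc.REFERENCE_AFFINITIES["MELT2P_wildtype"], 11)
        alone = self._fit(itc.REFERENCE_AFFINITIES["MELT2P_Bub3_alone"], 12)
        assert itc.fold_change(wt, alone) == pytest.approx(10.0, rel=0.2)

    def test_phosphate_pocket_mutant_loses_twentyfivefold_affinity(self):
        """R239A (5 µM) vs wild type (200 nM): ~25x."""
        wt = self._fit(itc.REFERENCE_AFFINITIES["MELT2P_wildtype"], 21)
        mut = self._fit(itc.REFERENCE_AFFINITIES["MELT2P_R239A"], 22)
        assert itc.fold_change(wt, mut) == pytest.approx(25.0, rel=0.2)

    def test_flagged_fits_are_rejected(self):
        wt = self._fit(200e-9, 1)
        nb_params = itc.BindingParams(kd=1e-6, dh_cal=0.0)
        tg = itc.simulate_thermogram(PROTOCOL, nb_params, 0.1, 5)
        nb = itc.fit_single_site(tg, PROTOCOL)
        with pytest.raises(ValueError):
            itc.fold_change(wt, nb)


def test_protocol_validation():
    with pytest.raises(ValueError):
        itc.TitrationProtocol(cell_conc=-1e-6, syringe_conc=4e-4,
                              injection_volumes_ul=(2.0,) * 10)
    with pytest.raises(ValueError):
        itc.TitrationProtocol(cell_conc=3e-5, syringe_conc=4e-4,
                              injection_volumes_ul=(30.0,) * 10)
    with pytest.warns(UserWarning):
        itc.TitrationProtocol(cell_conc=3e-5, syringe_conc=4e-4,
                              injection_volumes_ul=(2.0,) * 60)
    with pytest.raises(ValueError):
        itc.BindingParams(kd=-1e-9)
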
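from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aptascreen.itc_binding import (
    ItcExperiment,
    OneSiteBindingModel,
    audit_table,
    derive_thermodynamics,
    fit_one_site,
    predicted_heats,
    read_isotherm_csv,
    simulate_isotherm,
    write_isotherm_csv,
)

from .oracles import mass_balance_bound

ERAPTR4 = dict(n=0.5, ka=1.02e8, dh=-100.2)
STUDY_DESIGN = dict(cell_conc=1e-6, syringe_conc=10e-6, n_injections=25,
                    injection_volume=10e-6, cell_volume=1.4e-3, temperature=298.15)


def _truth():
    return derive_thermodynamics(**ERAPTR4)


class TestDerive:
    def test_unit_ka_gives_zero_dg(self):
        assert derive_thermodynamics(1.0, 1.0, -5.0, T=310.0).dg == 0.0

    def test_dg_from_measured_ka(self):
        fit = derive_thermodynamics(0.5, 1.02e8, -100.2, T=298.15)
        assert fit.dg == pytest.approx(-10.9246, abs=5e-4)

    def test_entropy_closes_the_cycle(self):
        fit = derive_thermodynamics(0.5, 3.3e7, -100.2)
        assert fit.dg + fit.tds == pytest.approx(fit.dh, abs=1e-12)

    def test_printed_identity_for_best_candidate(self):
        # dH - TdS = -100.2 - (-89.1) = -11.10, the printed dG
        assert -100.2 - (-89.1) == pytest.approx(-11.10, abs=1e-9)

    def test_nonpositive_ka_rejected(self):
        with pytest.raises(ValueError):
            derive_thermodynamics(0.5, 0.0, -10.0)


class TestSimulate:
    def test_stoichiometric_limit_heats_equal_dh(self):
        truth = derive_thermodynamics(1.0, 1e15, -10.0)
        exp = simulate_isotherm(truth, ItcExperiment(**STUDY_DESIGN), noise_sd=0.0)
        q = np.array(exp.heats)
        # sites: 1.0 * 1 uM * 1.4 mL = 1.4e-9 mol; 1e-10 mol titrant/injection
        assert np.allclose(q[:10], -10.0, rtol=1e-2)
        assert abs(q[-1]) < 0.1

    def test_zero_enthalpy_gives_zero_heats(self):
        truth = derive_thermodynamics(0.5, 1e8, 0.0)
        exp = simulate_isotherm(truth, ItcExperiment(**STUDY_DESIGN))
        assert np.allclose(exp.heats, 0.0)

    def test_cumulative_heat_is_monotone(self):
        exp = simulate_isotherm(_truth(), ItcExperiment(**STUDY_DESIGN))
        cum = np.cumsum(exp.heats)
        assert np.all(np.diff(cum) <= 0)  # exothermic: strictly accumulating

    def test_total_heat_approaches_site_capacity(self):
        # negligible-dilution design so the conserved limit is clean
        design = ItcExperiment(cell_conc=1e-6, syringe_conc=50e-6, n_injections=300,
                               injection_volume=2e-7, cell_volume=1.4e-3)
        truth = _truth()
        exp = simulate_isotherm(truth, design)
        moles = design.syringe_conc * design.injection_volume
        total = np.sum(np.array(exp.heats) * moles)
        capacity = design.cell_volume * truth.dh * truth.n * design.cell_conc
        assert total == pytest.approx(capacity, rel=0.02)

    def test_bound_complex_matches_independent_solver(self):
        design = ItcExperiment(**STUDY_DESIGN)
        truth = _truth()
        m_tot, x_tot = design.total_concentrations()
        from aptascreen.itc_binding import _bound_complex

        ours = _bound_complex(truth.n * m_tot, x_tot, truth.ka)
        ref = mass_balance_bound(truth.n * m_tot, x_tot, truth.ka)
        assert np.allclose(ours, ref, rtol=1e-9)

    def test_deterministic_given_seed(self):
        a = simulate_isotherm(_truth(), ItcExperiment(**STUDY_DESIGN), 2.0, seed=7)
        b = simulate_isotherm(_truth(), ItcExperiment(**STUDY_DESIGN), 2.0, seed=7)
        assert a.heats == b.heats


class TestFit:
    def test_zero_noise_round_trip(self):
        exp = simulate_isotherm(_truth(), ItcExperiment(**STUDY_DESIGN))
        res = fit_one_site(exp)
        assert res.n == pytest.approx(0.5, rel=1e-3)
        assert res.ka == pytest.approx(1.02e8, rel=1e-3)
        assert res.dh == pytest.approx(-100.2, rel=1e-3)
        assert res.converged

    @pytest.mark.parametrize("c_target", [5.0, 50.0, 500.0])
    def test_round_trip_across_c_range(self, c_target):
        n, m = 0.5, 1e-6
        truth = derive_thermodynamics(n, c_target / (n * m), -80.0)
        exp = simulate_isotherm(truth, ItcExperiment(**STUDY_DESIGN))
        res = fit_one_site(exp)
        assert res.ka == pytest.approx(truth.ka, rel=1e-5)
        assert res.n == pytest.approx(n, rel=1e-6)

    def test_log_ka_recovery_is_unbiased_at_two_percent_noise(self):
        truth = _truth()
        noise = 0.02 * abs(truth.dh)
        log_ka = []
        for seed in range(25):
            exp = simulate_isotherm(truth, ItcExperiment(**STUDY_DESIGN), noise, seed=seed)
            log_ka.append(np.log(fit_one_site(exp).ka))
        bias = np.mean(log_ka) - np.log(truth.ka)
        se = np.std(log_ka, ddof=1) / np.sqrt(len(log_ka))
        assert abs(bias) < 2 * se + 1e-12

    def test_summary_reports_estimates_and_uncertainty(self):
        exp = simulate_isotherm(_truth(), ItcExperiment(**STUDY_DESIGN), 2.0, seed=1)
        text = fit_one_site(exp).summary()
        assert "Ka" in text and "+/-" in text and "kcal/mol" in text

    def test_flat_isotherm_rejected(self):
        exp = ItcExperiment(**STUDY_DESIGN, heats=tuple([0.0] * 25))
        with pytest.raises(ValueError, match="flat isotherm"):
            OneSiteBindingModel(exp)

    def test_too_few_injections_rejected(self):
        design = dict(STUDY_DESIGN, n_injections=5)
        exp = simulate_isotherm(_truth(), ItcExperiment(**design))
        with pytest.raises(ValueError, match="at least 6"):
            OneSiteBindingModel(exp)

    def test_permuted_injection_order_rejected(self, tmp_path):
        exp = simulate_isotherm(_truth(), ItcExperiment(**STUDY_DESIGN))
        path = tmp_path / "iso.csv"
        write_isotherm_csv(exp, path)
        df = read_isotherm_csv(path)
        shuffled = df.sample(frac=1.0, random_state=0)
        with pytest.raises(ValueError, match="strictly increasing"):
            OneSiteBindingModel.from_dataframe(shuffled, cell_conc=1e-6, syringe_conc=10e-6)

    def test_csv_round_trip_fit(self, tmp_path):
        exp = simulate_isotherm(_truth(), ItcExperiment(**STUDY_DESIGN), 1.0, seed=3)
        path = tmp_path / "iso.csv"
        write_isotherm_csv(exp, path)
        model = OneSiteBindingModel.from_dataframe(
            read_isotherm_csv(path), cell_conc=1e-6, syringe_conc=10e-6
        )
        res = model.fit()
        assert res.ka == pytest.approx(1.02e8, rel=0.2)


class TestAudit:
    def test_identity_and_lnka_residuals_for_best_candidate(self, table4):
        report = audit_table(table4)
        r4 = next(r for r in report["rows"] if r["name"] == "ERaptR4")
        assert r4["residual_identity"] == pytest.approx(0.0, abs=0.005)
        assert r4["residual_lnka"] == pytest.approx(-0.175, abs=0.01)
        assert r4["lnka_flag"] and not r4["identity_flag"]

    def test_sign_anomaly_flagged(self, table4):
        report = audit_table(table4)
        r13 = next(r for r in report["rows"] if r["name"] == "ERaptR13")
        assert r13["sign_anomaly"]

    def test_gross_identity_breaks_flagged(self, table4):
        report = audit_table(table4)
        flagged = {r["name"] for r in report["rows"] if r["identity_flag"]}
        assert {"ERaptR3", "ERaptR12", "ERaptR13"} <= flagged
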
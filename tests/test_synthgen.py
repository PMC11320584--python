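"""Generators: determinism, model-surface exactness, analytic ground truth."""

import numpy as np
import pytest

from a3pharm import binding_equilibrium as be
from a3pharm import binding_kinetics as bk
from a3pharm import synthgen as sg
from a3pharm.alchemy import mbar_free_energies, ti_estimate


class TestEquilibriumCurve:
    def test_half_maximal_at_ic50(self, tracer, conc_grid):
        # at [I] = IC50 the noise-free response sits midway between top and bottom
        curve, truth = sg.gen_equilibrium_curve(7.0, tracer, conc_grid)
        resp = be._one_site_response(np.array([truth["ic50"]]), 7.0, 1.0, 0.0, tracer)
        assert resp[0] == pytest.approx(0.5, abs=1e-12)

    def test_generated_ic50_closed_form(self, conc_grid):
        # IC50 = Ki * (1 + L/Kd) = 2*Ki when L = Kd = 5 nM
        tracer = bk.TracerParams(conc=5e-9, kd=5e-9)
        _, truth = sg.gen_equilibrium_curve(7.92, tracer, conc_grid)
        assert truth["ic50"] == pytest.approx(2.0 * 10**-7.92, rel=1e-12)

    def test_noise_free_ignores_seed(self, tracer, conc_grid):
        c1, _ = sg.gen_equilibrium_curve(7.0, tracer, conc_grid, sg.NoiseSpec(0.0, 1))
        c2, _ = sg.gen_equilibrium_curve(7.0, tracer, conc_grid, sg.NoiseSpec(0.0, 2))
        np.testing.assert_array_equal(c1.response, c2.response)

    def test_seed_determinism(self, tracer, conc_grid):
        c1, _ = sg.gen_equilibrium_curve(7.0, tracer, conc_grid, sg.NoiseSpec(0.05, 7), n_replicates=2)
        c2, _ = sg.gen_equilibrium_curve(7.0, tracer, conc_grid, sg.NoiseSpec(0.05, 7), n_replicates=2)
        np.testing.assert_array_equal(c1.response, c2.response)

    def test_replicates_differ_but_share_truth(self, tracer, conc_grid):
        curve, _ = sg.gen_equilibrium_curve(7.0, tracer, conc_grid, sg.NoiseSpec(0.05, 7), n_replicates=2)
        r0 = curve.response[curve.replicate_id == 0]
        r1 = curve.response[curve.replicate_id == 1]
        assert not np.array_equal(r0, r1)

    def test_rejects_bad_grid(self, tracer):
        with pytest.raises(ValueError):
            sg.gen_equilibrium_curve(7.0, tracer, [-1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4])
        with pytest.raises(ValueError):
            sg.gen_equilibrium_curve(7.0, tracer, np.logspace(-8, -7, 8))  # < 4 log units


class TestKineticTraces:
    def test_no_competitor_is_single_site_association(self, tracer):
        times = np.linspace(0, 30, 16)
        traces, _ = sg.gen_kinetic_traces(tracer, 1e6, 0.05, 1.0, [0.0, 1e-7], times)
        k1, k2, L = tracer.k1, tracer.k2, tracer.conc
        kobs = k1 * L + k2
        expected = (k1 * L / kobs) * (1 - np.exp(-kobs * times))
        np.testing.assert_allclose(traces.signal[:, 0], expected, rtol=1e-12)

    def test_signal_zero_at_t0(self, tracer):
        times = np.linspace(0, 30, 16)
        traces, _ = sg.gen_kinetic_traces(tracer, 1e6, 0.05, 1.0, [0.0, 1e-8, 1e-7], times)
        np.testing.assert_allclose(traces.signal[0, :], 0.0, atol=1e-15)

    def test_rejects_negative_rates(self, tracer):
        with pytest.raises(ValueError):
            sg.gen_kinetic_traces(tracer, -1e6, 0.05, 1.0, [0.0], np.linspace(0, 30, 9))

    def test_round_trip_recovers_rates_to_4_digits(self, tracer):
        times = np.linspace(0, 30, 16)
        traces, _ = sg.gen_kinetic_traces(
            tracer, 5.95e6, 0.046, 1.0, [0.0, 1e-8, 3e-8, 1e-7, 3e-7], times
        )
        est = bk.fit_competitor_kinetics(traces)
        assert est.kon == pytest.approx(5.95e6, rel=5e-5)
        assert est.koff == pytest.approx(0.046, rel=5e-5)


class TestDoseResponse:
    def test_no_antagonist_no_shift(self):
        agonist = np.logspace(-11, -5, 8)
        drs, truth = sg.gen_dose_response(8.0, 100.0, 0.0, 7.0, [0.0], agonist)
        from a3pharm.functional_pharm import logistic3

        np.testing.assert_allclose(drs.curves[0].response, logistic3(agonist, 0, 100, 8.0), rtol=1e-12)

    def test_b_equals_kb_doubles_ec50(self):
        agonist = np.logspace(-11, -5, 8)
        kb = 1e-7
        drs, _ = sg.gen_dose_response(8.0, 100.0, 0.0, 7.0, [0.0, kb], agonist)
        from a3pharm.functional_pharm import fit_logistic3

        f0 = fit_logistic3(drs.curves[0])
        f1 = fit_logistic3(drs.curves[1])
        assert f1.ec50 / f0.ec50 == pytest.approx(2.0, rel=1e-6)

    def test_dose_ratio_closed_form(self):
        # DR = 1 + [B]/KB for pkb 7.95 at 10 uM
        agonist = np.logspace(-12, -4, 10)
        drs, truth = sg.gen_dose_response(8.0, 100.0, 0.0, 7.95, [0.0, 1e-5], agonist)
        expected_dr = 1.0 + 1e-5 / 10**-7.95
        from a3pharm.functional_pharm import fit_logistic3

        f0 = fit_logistic3(drs.curves[0])
        f1 = fit_logistic3(drs.curves[1])
        assert f1.ec50 / f0.ec50 == pytest.approx(expected_dr, rel=1e-4)

    def test_rejects_emax_below_basal(self):
        with pytest.raises(ValueError):
            sg.gen_dose_response(8.0, 0.0, 100.0, 7.0, [0.0], np.logspace(-11, -5, 8))


class TestLambdaEnsembles:
    def test_identical_states_zero_delta_a(self):
        model = sg.GaussianModel(means=(0.0, 0.0), sigmas=(1.0, 1.0))
        ens, truth = sg.gen_lambda_ensemble(2, 200, model, seed=0)
        assert truth["delta_a"] == 0.0
        _, leg = mbar_free_energies(ens)
        assert abs(leg.delta_a) < 5 * max(leg.stderr, 1e-12)

    def test_harmonic_analytic_free_energy(self):
        model = sg.HarmonicModel(k0=1.0, k1=4.0)
        # dA = ln(K1/K0) / (2 beta)
        assert model.analytic_delta_a == pytest.approx(np.log(4.0) / (2 * model.beta))

    def test_harmonic_mbar_within_3_stderr(self):
        ens, truth = sg.gen_lambda_ensemble(5, 2000, sg.HarmonicModel(), seed=3)
        _, leg = mbar_free_energies(ens)
        assert abs(leg.delta_a - truth["delta_a"]) < 3 * leg.stderr

    def test_harmonic_ti_with_offset_change(self):
        # a center shift contributes no free energy but nonzero dU/dl samples
        model = sg.HarmonicModel(k0=2.0, k1=2.0, c0=0.0, c1=1.0)
        assert model.analytic_delta_a == 0.0
        ens, truth = sg.gen_lambda_ensemble(11, 2000, model, seed=4)
        leg = ti_estimate(ens)
        assert abs(leg.delta_a - truth["delta_a"]) < 3 * leg.stderr

    def test_unsupported_model_raises(self):
        with pytest.raises(sg.UnsupportedModelError):
            sg.gen_lambda_ensemble(3, 10, object())


class TestPKTimecourse:
    def test_half_life_definition(self):
        df, _ = sg.gen_pk_timecourse(16.9, [0.0, 16.9])
        assert df["pct_remaining"].iloc[0] == pytest.approx(100.0)
        assert df["pct_remaining"].iloc[1] == pytest.approx(50.0)

    def test_round_trip_with_noise(self):
        from a3pharm.pk_profile import half_life

        df, _ = sg.gen_pk_timecourse(16.9, np.arange(0, 61, 5.0), sg.NoiseSpec(1.0, 11))
        assert half_life(df["time_min"], df["pct_remaining"]) == pytest.approx(16.9, rel=0.01)


class TestCurveIO:
    def test_csv_round_trip(self, tmp_path, tracer, conc_grid):
        curve, truth = sg.gen_equilibrium_curve(7.3, tracer, conc_grid, sg.NoiseSpec(0.02, 5), n_replicates=2)
        path = tmp_path / "curve.csv"
        sg.write_curve_csv(path, curve, truth, sg.NoiseSpec(0.02, 5))
        curve2, truth2 = sg.read_curve_csv(path)
        np.testing.assert_allclose(curve2.response, curve.response)
        np.testing.assert_allclose(curve2.competitor_conc, curve.competitor_conc)
        assert truth2["pki"] == truth["pki"]
        assert curve2.tracer.kd == tracer.kd
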
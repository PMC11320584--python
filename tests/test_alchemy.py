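"""Free-energy estimators: TI, MBAR (vs BAR oracle), cycle, experiment link."""

import numpy as np
import pytest

from a3pharm import alchemy, synthgen as sg


def make_ensemble(lambdas, n_k, u_kn, beta=1.0, dudl=None):
    return alchemy.LambdaEnsemble(np.asarray(lambdas), np.asarray(n_k),
                                  np.asarray(u_kn), beta, dudl)


class TestTI:
    def test_constant_integrand(self):
        # <dU/dl> = c everywhere integrates to exactly c
        lambdas = np.linspace(0, 1, 5)
        n = 10
        dudl = np.full(5 * n, 3.7)
        u_kn = np.zeros((5, 5 * n))
        ens = make_ensemble(lambdas, [n] * 5, u_kn, dudl=dudl)
        leg = alchemy.ti_estimate(ens)
        assert leg.delta_a == pytest.approx(3.7, abs=1e-12)

    def test_linear_integrand_exact(self):
        # trapezoid is exact for an integrand linear in lambda: dA = (a+b)/2
        lambdas = np.linspace(0, 1, 6)
        a, b = -2.0, 4.0
        dudl = np.concatenate([[a + (b - a) * lam] * 4 for lam in lambdas])
        u_kn = np.zeros((6, dudl.size))
        ens = make_ensemble(lambdas, [4] * 6, u_kn, dudl=dudl)
        assert alchemy.ti_estimate(ens).delta_a == pytest.approx((a + b) / 2, abs=1e-12)

    def test_harmonic_toy_dense_grid(self):
        ens, truth = sg.gen_lambda_ensemble(11, 2000, sg.HarmonicModel(), seed=21)
        leg = alchemy.ti_estimate(ens)
        # 2 stderr statistical margin plus a small quadrature bias allowance
        assert abs(leg.delta_a - truth["delta_a"]) < 2 * leg.stderr + 0.01

    def test_missing_dudl_inapplicable(self):
        ens, _ = sg.gen_lambda_ensemble(2, 50, sg.GaussianModel(means=(0, 1), sigmas=(1, 1)), seed=0)
        with pytest.raises(ValueError):
            alchemy.ti_estimate(ens)


class TestMBAR:
    def test_identical_states_give_zero_f(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        u = 0.5 * x**2
        u_kn = np.vstack([u, u, u])
        ens = make_ensemble([0, 0.5, 1], [100, 100, 100], u_kn)
        f, leg = alchemy.mbar_free_energies(ens)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)
        assert leg.delta_a == pytest.approx(0.0, abs=1e-10)

    def test_two_state_gaussian_within_3_stderr(self):
        model = sg.GaussianModel(means=(0.0, 1.0), sigmas=(1.0, 0.6))
        ens, truth = sg.gen_lambda_ensemble(2, 2000, model, seed=8)
        _, leg = alchemy.mbar_free_energies(ens)
        assert abs(leg.delta_a - truth["delta_a"]) < 3 * leg.stderr

    def test_two_state_matches_bar_oracle(self):
        model = sg.GaussianModel(means=(0.0, 0.8), sigmas=(1.0, 0.7))
        ens, _ = sg.gen_lambda_ensemble(2, 1500, model, seed=9)
        f, _ = alchemy.mbar_free_energies(ens, tol=1e-12)
        s0, s1 = ens.state_slices()
        w_f = ens.u_kn[1, s0] - ens.u_kn[0, s0]
        w_r = ens.u_kn[0, s1] - ens.u_kn[1, s1]
        df_bar = alchemy.bar_free_energy(w_f, w_r)
        assert f[1] == pytest.approx(df_bar, abs=1e-6)

    def test_invariant_to_per_sample_constant_shift(self):
        model = sg.GaussianModel(means=(0.0, 1.0), sigmas=(1.0, 0.8))
        ens, _ = sg.gen_lambda_ensemble(2, 400, model, seed=10)
        f1, _ = alchemy.mbar_free_energies(ens)
        rng = np.random.default_rng(0)
        shift = rng.normal(size=ens.u_kn.shape[1])
        ens2 = make_ensemble(ens.lambdas, ens.n_k, ens.u_kn + shift[None, :], ens.beta)
        f2, _ = alchemy.mbar_free_energies(ens2)
        np.testing.assert_allclose(f1, f2, atol=1e-7)

    def test_agrees_with_ti_on_harmonic_ladder(self):
        ens, _ = sg.gen_lambda_ensemble(11, 1000, sg.HarmonicModel(), seed=12)
        ti = alchemy.ti_estimate(ens)
        _, mbar = alchemy.mbar_free_energies(ens)
        combined = np.hypot(ti.stderr, mbar.stderr)
        assert abs(ti.delta_a - mbar.delta_a) < 3 * combined + 0.01

    def test_nonconvergence_raises_with_residual(self):
        model = sg.GaussianModel(means=(0.0, 1.0), sigmas=(1.0, 0.8))
        ens, _ = sg.gen_lambda_ensemble(2, 200, model, seed=11)
        with pytest.raises(alchemy.ConvergenceError) as exc:
            alchemy.mbar_free_energies(ens, tol=1e-15, max_iter=2)
        assert exc.value.residual > 0


class TestCycle:
    def test_equal_legs_cancel(self):
        b = alchemy.FreeEnergyLeg(-5.0, 0.1, "bound", "TI", "A -> B")
        s = alchemy.FreeEnergyLeg(-5.0, 0.1, "solvent", "TI", "A -> B")
        ddg, err = alchemy.cycle_ddg(b, s)
        assert ddg == 0.0
        assert err == pytest.approx(np.hypot(0.1, 0.1))

    def test_worked_difference(self):
        b = alchemy.FreeEnergyLeg(-5.0, 0.0, "bound", "TI", "A -> B")
        s = alchemy.FreeEnergyLeg(-4.0, 0.0, "solvent", "TI", "A -> B")
        assert alchemy.cycle_ddg(b, s)[0] == pytest.approx(-1.0)

    def test_reversal_antisymmetry(self):
        b = alchemy.FreeEnergyLeg(-5.0, 0.0, "bound", "TI", "x")
        s = alchemy.FreeEnergyLeg(-4.0, 0.0, "solvent", "TI", "x")
        fwd = alchemy.cycle_ddg(b, s)[0]
        rb = alchemy.FreeEnergyLeg(5.0, 0.0, "bound", "TI", "x")
        rs = alchemy.FreeEnergyLeg(4.0, 0.0, "solvent", "TI", "x")
        assert alchemy.cycle_ddg(rb, rs)[0] == pytest.approx(-fwd)

    def test_mismatched_labels_rejected(self):
        b = alchemy.FreeEnergyLeg(-5.0, 0.0, "bound", "TI", "A -> B")
        s = alchemy.FreeEnergyLeg(-4.0, 0.0, "solvent", "TI", "A -> C")
        with pytest.raises(ValueError):
            alchemy.cycle_ddg(b, s)

    def test_cycle_closure_on_synthetic_chain(self):
        # dA legs from shared ground truths close around a 3-compound cycle
        def legs(k0, k1, seed):
            m = sg.HarmonicModel(k0=k0, k1=k1)
            ens, _ = sg.gen_lambda_ensemble(7, 800, m, seed=seed)
            return alchemy.ti_estimate(ens)

        l01, l12 = legs(1.0, 2.0, 1), legs(2.0, 4.0, 2)
        l02 = legs(1.0, 4.0, 3)
        combined = np.sqrt(l01.stderr**2 + l12.stderr**2 + l02.stderr**2)
        assert abs(l01.delta_a + l12.delta_a - l02.delta_a) < 3 * combined + 0.01


class TestExperimentalDDG:
    def test_equal_affinities_zero(self):
        assert alchemy.ddg_exp_from_affinities(1e-8, 1e-8) == 0.0

    def test_reported_affinity_pair_at_310K(self):
        # 34.7 nM -> 11.7 nM improvement is -0.67 kcal/mol at 310 K
        assert alchemy.ddg_exp_from_affinities(34.7e-9, 11.7e-9, 310.0) == pytest.approx(-0.67, abs=0.005)

    def test_tenfold_improvement(self):
        assert alchemy.ddg_exp_from_affinities(1e-7, 1e-8, 310.0) == pytest.approx(-1.418, abs=0.001)

    def test_antisymmetric_and_additive(self):
        d01 = alchemy.ddg_exp_from_affinities(3e-8, 1e-8)
        d10 = alchemy.ddg_exp_from_affinities(1e-8, 3e-8)
        assert d01 == pytest.approx(-d10, abs=1e-12)
        d12 = alchemy.ddg_exp_from_affinities(1e-8, 5e-9)
        d02 = alchemy.ddg_exp_from_affinities(3e-8, 5e-9)
        assert d01 + d12 == pytest.approx(d02, abs=1e-12)


class TestCorrelationSummary:
    def test_perfect_agreement(self):
        res = [alchemy.PerturbationResult(f"p{i}", x, x) for i, x in enumerate([-1.0, 0.0, 1.0, 2.0])]
        s = alchemy.correlation_summary(res)
        assert s.r == pytest.approx(1.0)
        assert s.slope == pytest.approx(1.0)
        assert s.mue == 0.0

    def test_uniform_offset(self):
        res = [alchemy.PerturbationResult(f"p{i}", x + 0.5, x) for i, x in enumerate([-1.0, 0.0, 1.0])]
        s = alchemy.correlation_summary(res)
        assert s.r == pytest.approx(1.0)
        assert s.mue == pytest.approx(0.5)

    def test_against_brute_force_pearson(self):
        calc = np.array([-1.2, 0.3, 0.8, -0.5, 1.9])
        exp = np.array([-0.9, 0.1, 1.1, -0.2, 1.5])
        res = [alchemy.PerturbationResult(f"p{i}", c, e) for i, (c, e) in enumerate(zip(calc, exp))]
        s = alchemy.correlation_summary(res)
        # Pearson r from the definition
        r_brute = np.sum((calc - calc.mean()) * (exp - exp.mean())) / np.sqrt(
            np.sum((calc - calc.mean()) ** 2) * np.sum((exp - exp.mean()) ** 2)
        )
        assert s.r == pytest.approx(r_brute, abs=1e-12)
        assert s.mue == pytest.approx(np.mean(np.abs(calc - exp)), abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            alchemy.correlation_summary([alchemy.PerturbationResult("a", 0, 0)] * 2)


class TestEnsembleIO:
    def test_text_round_trip(self, tmp_path):
        ens, _ = sg.gen_lambda_ensemble(3, 50, sg.HarmonicModel(), seed=5)
        path = tmp_path / "ens.txt"
        alchemy.write_ensemble(path, ens)
        ens2 = alchemy.read_ensemble(path)
        np.testing.assert_allclose(ens2.lambdas, ens.lambdas)
        np.testing.assert_array_equal(ens2.n_k, ens.n_k)
        np.testing.assert_allclose(ens2.u_kn, ens.u_kn, rtol=1e-10)
        np.testing.assert_allclose(ens2.dudl, ens.dudl, rtol=1e-10)
        assert ens2.beta == pytest.approx(ens.beta)

    def test_round_trip_without_dudl(self, tmp_path):
        ens, _ = sg.gen_lambda_ensemble(2, 30, sg.GaussianModel(means=(0, 1), sigmas=(1, 1)), seed=6)
        path = tmp_path / "ens.txt"
        alchemy.write_ensemble(path, ens)
        assert alchemy.read_ensemble(path).dudl is None
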
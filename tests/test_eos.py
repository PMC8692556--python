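"""PR EoS machinery: parameters, roots, fugacity coefficients, solubility."""

import numpy as np
import pytest
from scipy import integrate

from sccosol import eos
from sccosol.core import R, ComponentSpec
from sccosol.eos import (
    BinaryInteraction,
    PurePR,
    SublimationCoeffs,
    dhsub_eos,
    mix_vdw2,
    phi_mixture,
    phi_pure,
    psub_from_coeffs,
    pure_pr,
    solve_z,
    y2_eos,
)


def _pressure(N, V, T, pures, inter):
    """Total pressure of a vdW2 PR mixture from mole numbers and volume."""
    N = np.asarray(N, dtype=float)
    n = N.sum()
    mix, _, _ = mix_vdw2(N / n, pures, inter)
    nb = n * mix.b
    return n * R * T / (V - nb) - n**2 * mix.a / (V**2 + 2 * nb * V - nb**2)


def _lnphi_by_integral(i, x, T, P, pures, inter):
    """Fugacity coefficient via the volume integral of dP/dN_i - RT/v."""
    mix, _, _ = mix_vdw2(x, pures, inter)
    Z = solve_z(T, P, mix)
    v = Z * R * T / P  # molar volume for n = 1 mol total

    def dPdNi(V):
        h = 1e-7
        Np, Nm = np.array(x, dtype=float), np.array(x, dtype=float)
        Np[i] += h
        Nm[i] -= h
        return (_pressure(Np, V, T, pures, inter)
                - _pressure(Nm, V, T, pures, inter)) / (2 * h)

    def integrand(u):  # u = 1/V
        V = 1.0 / u
        return (dPdNi(V) - R * T * u) * V**2  # dV = -du/u^2, sign via limits

    val, _ = integrate.quad(integrand, 1e-12, 1.0 / v, limit=200)
    return val / (R * T) - np.log(Z)


class TestPureParameters:
    def test_co2_at_critical_point(self, co2):
        pr = pure_pr(304.18, co2)
        assert pr.a == pytest.approx(0.45724 * R**2 * 304.18**2 / 7.38e6, rel=1e-12)
        assert pr.b == pytest.approx(2.666e-5, rel=1e-3)

    def test_alpha_is_unity_at_tc_for_any_omega(self):
        for omega in (0.0, 0.225, 0.6):
            comp = ComponentSpec(M=44.0, Tc=300.0, Pc=5.0, omega=omega)
            pr = pure_pr(300.0, comp)
            assert pr.a == pytest.approx(
                0.45724 * R**2 * 300.0**2 / 5.0e6, rel=1e-12
            )

    def test_attraction_decreases_with_temperature(self, co2):
        T = 0.9 * co2.Tc
        da = (pure_pr(T + 0.5, co2).a - pure_pr(T - 0.5, co2).a)
        assert da < 0


class TestMixing:
    def test_pure_limit(self, co2, clemastine):
        pures = [pure_pr(308.0, co2), pure_pr(308.0, clemastine)]
        mix, a_hat, b_hat = mix_vdw2([1.0, 0.0], pures, BinaryInteraction(0, 0))
        assert mix.a == pytest.approx(pures[0].a, rel=1e-12)
        assert mix.b == pytest.approx(pures[0].b, rel=1e-12)

    def test_identical_species_composition_free(self, co2):
        p = pure_pr(308.0, co2)
        for x in ([0.3, 0.7], [0.5, 0.5]):
            mix, _, _ = mix_vdw2(x, [p, p], BinaryInteraction(0, 0))
            assert mix.a == pytest.approx(p.a, rel=1e-12)
            assert mix.b == pytest.approx(p.b, rel=1e-12)

    def test_unnormalised_composition_rejected(self, co2):
        p = pure_pr(308.0, co2)
        with pytest.raises(ValueError, match="sum to 1"):
            mix_vdw2([0.5, 0.6], [p, p], None)

    def test_partial_quantities_match_numerical_derivatives(self, co2, clemastine):
        pures = [pure_pr(320.0, co2), pure_pr(320.0, clemastine)]
        inter = BinaryInteraction(0.13, -0.07)
        x = np.array([0.7, 0.3])
        mix, a_hat, b_hat = mix_vdw2(x, pures, inter)
        h = 1e-7
        for i in range(2):
            Np, Nm = x.copy(), x.copy()
            Np[i] += h
            Nm[i] -= h

            def n2a(N):
                m, _, _ = mix_vdw2(N / N.sum(), pures, inter)
                return N.sum() ** 2 * m.a

            def nb(N):
                m, _, _ = mix_vdw2(N / N.sum(), pures, inter)
                return N.sum() * m.b

            a_num = (n2a(Np) - n2a(Nm)) / (2 * h)  # (1/n) d(n^2 a)/dN_i at n=1
            b_num = (nb(Np) - nb(Nm)) / (2 * h)
            assert a_hat[i] == pytest.approx(a_num, rel=1e-6)
            assert b_hat[i] == pytest.approx(b_num, rel=1e-6)


class TestCompressibility:
    def test_ideal_gas_limits(self, co2):
        pr = pure_pr(308.0, co2)
        assert solve_z(308.0, 1.0, pr) == pytest.approx(1.0, abs=1e-6)
        assert solve_z(308.0, 1e5, PurePR(a=0.0, b=1e-30)) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_density_consistent_with_reference(self, dataset, co2):
        # PR underpredicts CO2 density by up to ~9% near the critical region
        for p in dataset:
            z = solve_z(p.T, p.P * 1e6, pure_pr(p.T, co2))
            rho = p.P * 1e6 * co2.M * 1e-3 / (z * R * p.T)
            assert rho == pytest.approx(p.rho1, rel=0.10)

    def test_nonpositive_pressure_rejected(self, co2):
        with pytest.raises(ValueError):
            solve_z(308.0, -1.0, pure_pr(308.0, co2))


class TestFugacity:
    def test_ideal_limit(self, co2):
        assert phi_pure(308.0, 10.0, co2) == pytest.approx(1.0, abs=1e-5)

    def test_pure_against_quadrature(self, co2):
        T, P = 318.0, 7.38e6
        phi = phi_pure(T, P, co2)

        def integrand(p):
            z = solve_z(T, p, pure_pr(T, co2))
            return (z - 1.0) / p

        val, _ = integrate.quad(integrand, 1.0, P, limit=200)
        assert np.log(phi) == pytest.approx(val, abs=1e-4)

    def test_mixture_reduces_to_pure(self, co2, clemastine):
        pures = [pure_pr(308.0, co2), pure_pr(308.0, clemastine)]
        phi_m = phi_mixture(0, [1.0, 0.0], 308.0, 12e6, pures,
                            BinaryInteraction(0.3, 0.1))
        assert phi_m == pytest.approx(phi_pure(308.0, 12e6, co2), rel=1e-10)

    def test_partial_coefficient_against_volume_integral(self, co2, clemastine):
        rng = np.random.default_rng(11)
        for _ in range(8):
            T = float(rng.uniform(308.0, 340.0))
            P = float(rng.uniform(8e6, 28e6))
            x1 = float(rng.uniform(0.5, 0.999))
            inter = BinaryInteraction(float(rng.uniform(-0.3, 0.8)),
                                      float(rng.uniform(-0.3, 0.8)))
            pures = [pure_pr(T, co2), pure_pr(T, clemastine)]
            x = [x1, 1.0 - x1]
            for i in range(2):
                direct = np.log(phi_mixture(i, x, T, P, pures, inter))
                oracle = _lnphi_by_integral(i, x, T, P, pures, inter)
                assert direct == pytest.approx(oracle, rel=1e-4, abs=1e-6)

    def test_gibbs_duhem(self, co2, clemastine):
        T, P = 320.0, 15e6
        pures = [pure_pr(T, co2), pure_pr(T, clemastine)]
        inter = BinaryInteraction(0.4, 0.3)
        x1, h = 0.99, 1e-6

        def lnphis(x1v):
            x = [x1v, 1.0 - x1v]
            return np.array(
                [np.log(phi_mixture(i, x, T, P, pures, inter)) for i in range(2)]
            )

        d = (lnphis(x1 + h) - lnphis(x1 - h)) / (2 * h)
        assert x1 * d[0] + (1 - x1) * d[1] == pytest.approx(0.0, abs=1e-6)


class TestSublimationForm:
    def test_reference_temperature_structure(self):
        c = SublimationCoeffs(1.3, -500.0, 7.0)
        assert psub_from_coeffs(298.15, c) == pytest.approx(
            np.exp(1.3 - 500.0 / 298.15)
        )

    def test_published_constants_at_reference(self, table5):
        t = table5["t_independent"]
        c = SublimationCoeffs(t["beta_over_R"], t["gamma_over_R"],
                              t["dsubdelta_over_R"])
        assert psub_from_coeffs(298.15, c) == pytest.approx(0.626, rel=1e-3)

    def test_monotone_when_endothermic(self, table5):
        t = table5["t_independent"]
        c = SublimationCoeffs(t["beta_over_R"], t["gamma_over_R"],
                              t["dsubdelta_over_R"])
        Ts = np.linspace(300.0, 340.0, 50)
        assert np.all(np.diff(psub_from_coeffs(Ts, c)) > 0)

    def test_enthalpy_conventions(self):
        c = SublimationCoeffs(0.0, -100.0, 0.0)
        assert dhsub_eos(c, 323.0) == pytest.approx(-100.0 * R)
        assert dhsub_eos(c, 323.0, literal=True) == pytest.approx(100.0 * R)
        # linear in T: midpoint value is the mean of the endpoints
        c2 = SublimationCoeffs(0.3, -221.54, 11.305)
        assert dhsub_eos(c2, 323.0) == pytest.approx(
            0.5 * (dhsub_eos(c2, 308.0) + dhsub_eos(c2, 338.0)), rel=1e-12
        )


class TestSolidSolubility:
    def test_published_constants_reproduce_measurement(self, table5, clemastine, co2):
        t = table5["t_independent"]
        c = SublimationCoeffs(t["beta_over_R"], t["gamma_over_R"],
                              t["dsubdelta_over_R"])
        inter = BinaryInteraction(t["kij"], t["lij"])
        y = y2_eos(308.0, 27e6, clemastine, co2, inter,
                   psub_from_coeffs(308.0, c))
        assert 5.1e-6 / 1.3 < y < 5.1e-6 * 1.3

    def test_monotone_in_sublimation_pressure(self, clemastine, co2):
        inter = BinaryInteraction(0.8, 0.74)
        ys = [y2_eos(318.0, 20e6, clemastine, co2, inter, p)
              for p in (0.05, 0.5, 5.0)]
        assert ys[0] < ys[1] < ys[2]

    def test_psub_above_pressure_rejected(self, clemastine, co2):
        with pytest.raises(ValueError):
            y2_eos(308.0, 1e5, clemastine, co2, BinaryInteraction(), 2e5)

    def test_tdependent_refit_matches_published_isotherm_values(
        self, dataset, clemastine, co2, table5
    ):
        fit = eos.fit_eos(dataset, clemastine, co2, mode="t_dependent", seed=42)
        for T, ref in table5["t_dependent"].items():
            kij, lij = fit.interaction.at(float(T))
            assert kij == pytest.approx(ref["kij"], abs=0.02)
            assert lij == pytest.approx(ref["lij"], abs=0.02)
            assert fit.per_isotherm_aard[float(T)] == pytest.approx(
                ref["aard_percent"], abs=0.5
            )
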
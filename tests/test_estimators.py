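import math

import numpy as np
import pytest
from scipy.integrate import quad

from otfti import (
    BoreschParameters,
    ThermoConstants,
    abfe_assemble,
    boresch_analytic,
    bootstrap_mean,
    gauss_legendre_schedule,
    integrate,
    rbfe_assemble,
    trapezoid_schedule,
)

# Printed 9- and 12-window quadrature schedules used for the RBFE runs
NODES_9 = [0.01592, 0.08198, 0.19331, 0.33787, 0.5, 0.66213, 0.80669, 0.91802, 0.98408]
NODES_12 = [
    0.00922, 0.04794, 0.11505, 0.20634, 0.31608, 0.43738,
    0.56262, 0.68392, 0.79366, 0.88495, 0.95206, 0.99078,
]
RESTRAINT_NODES = [0.0, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0]


class TestGaussLegendre:
    @pytest.mark.parametrize("n,printed", [(9, NODES_9), (12, NODES_12)])
    def test_reproduces_printed_nodes(self, n, printed):
        sched = gauss_legendre_schedule(n)
        assert [round(float(x), 5) for x in sched.lambdas] == printed

    @pytest.mark.parametrize("n", [2, 5, 9, 12])
    def test_node_symmetry_and_weight_normalization(self, n):
        sched = gauss_legendre_schedule(n)
        assert np.allclose(sched.lambdas + sched.lambdas[::-1], 1.0, atol=1e-12)
        assert np.all(sched.weights > 0)
        assert sched.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_point_rule(self):
        sched = gauss_legendre_schedule(2)
        assert np.allclose(sched.lambdas, [0.5 - 1 / (2 * math.sqrt(3)), 0.5 + 1 / (2 * math.sqrt(3))])
        assert np.allclose(sched.weights, [0.5, 0.5])

    @pytest.mark.parametrize("n", [3, 6, 9])
    def test_exactness_up_to_degree_2n_minus_1(self, n):
        sched = gauss_legendre_schedule(n)
        for deg in range(2 * n):
            exact = quad(lambda x: x**deg, 0.0, 1.0)[0]
            approx = float(np.dot(sched.weights, sched.lambdas**deg))
            assert approx == pytest.approx(exact, abs=1e-10)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            gauss_legendre_schedule(0)


class TestTrapezoidSchedule:
    def test_restraint_schedule_exact_on_linear(self):
        sched = trapezoid_schedule(np.array(RESTRAINT_NODES))
        assert not sched.truncated_domain
        result = integrate(sched, 2.0 * sched.lambdas)
        assert result.delta_g == pytest.approx(1.0, abs=1e-12)

    def test_two_endpoint_constant(self):
        sched = trapezoid_schedule(np.array([0.0, 1.0]))
        assert integrate(sched, np.array([3.3, 3.3])).delta_g == pytest.approx(3.3)

    def test_nine_equal_windows_flagged_truncated(self):
        sched = trapezoid_schedule(np.arange(0.1, 0.95, 0.1))
        assert sched.truncated_domain
        assert sched.weights.sum() == pytest.approx(0.8, abs=1e-12)

    def test_unsorted_or_duplicate_rejected(self):
        with pytest.raises(ValueError):
            trapezoid_schedule(np.array([0.0, 0.5, 0.5, 1.0]))
        with pytest.raises(ValueError):
            trapezoid_schedule(np.array([0.5, 0.2, 1.0]))
        with pytest.raises(ValueError):
            trapezoid_schedule(np.array([-0.1, 1.0]))


class TestBootstrapMean:
    def test_constant_series(self):
        mean, err = bootstrap_mean(np.full(100, 2.5), n_boot=500, seed=1)
        assert (mean, err) == (2.5, 0.0)

    def test_central_limit_scaling(self, rng):
        x = rng.normal(0.0, 1.0, 10_000)
        _, err = bootstrap_mean(x, n_boot=1000, seed=2)
        assert err == pytest.approx(0.01, rel=0.2)

    def test_two_point_enumeration(self):
        # resamples of {0,2} are (0,0),(0,2),(2,0),(2,2): SD of means = sqrt(0.5)
        mean, err = bootstrap_mean(np.array([0.0, 2.0]), n_boot=20_000, seed=3)
        assert mean == 1.0
        assert err == pytest.approx(math.sqrt(0.5), rel=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean(np.array([1.0]))


class TestIntegrate:
    def test_constant_means_with_normalized_weights(self):
        sched = gauss_legendre_schedule(9)
        assert integrate(sched, np.full(9, 7.7)).delta_g == pytest.approx(7.7, rel=1e-12)

    def test_cubic_exact_on_nine_point_rule(self):
        sched = gauss_legendre_schedule(9)
        result = integrate(sched, sched.lambdas**3)
        assert result.delta_g == pytest.approx(0.25, abs=1e-12)

    def test_linearity_in_means(self, rng):
        sched = gauss_legendre_schedule(9)
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        lhs = integrate(sched, 2.0 * a + 3.0 * b).delta_g
        rhs = 2.0 * integrate(sched, a).delta_g + 3.0 * integrate(sched, b).delta_g
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_error_propagation_in_quadrature(self):
        sched = trapezoid_schedule(np.array([0.0, 1.0]))
        result = integrate(sched, np.array([0.0, 0.0]), np.array([2.0, 2.0]))
        assert result.std_err == pytest.approx(math.sqrt(2 * (0.5 * 2.0) ** 2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate(gauss_legendre_schedule(9), np.zeros(8))


class TestCycleAssembly:
    @pytest.mark.parametrize(
        "prot,wat,ddg",
        [
            (3.87, 4.91, -1.04),   # PLpro ligand 1, long-run AED
            (-6.61, -5.01, -1.60), # PLpro ligand 4, protocol E
            (2.2, 2.2, 0.0),
        ],
    )
    def test_rbfe_cycle(self, prot, wat, ddg):
        assert rbfe_assemble(prot, wat).ddg == pytest.approx(ddg, abs=1e-12)

    @pytest.mark.parametrize(
        "solv,vb,prot,analytic,dg",
        [
            (17.32, 2.02, 31.02, -7.51, -8.21),  # long-run AED row
            (17.10, 1.68, 31.42, -7.50, -8.50),  # protocol A row
            (0.0, 0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_abfe_cycle(self, solv, vb, prot, analytic, dg):
        assert abfe_assemble(solv, vb, prot, analytic).dg_bind == pytest.approx(dg, abs=1e-9)

    def test_abfe_sign_convention_constant_across_published_rows(self):
        """Back-computing the analytic restraint term from each of the
        six PLpro ABFE result rows must give one consistent value —
        the check that pins the cycle's sign convention."""
        rows = [  # (overall, complex, solvated, restraint addition)
            (-8.21, 31.02, 17.32, 2.02),
            (-7.65, 30.50, 17.33, 1.97),
            (-7.85, 30.71, 17.32, 1.97),
            (-8.50, 31.42, 17.10, 1.68),
            (-8.64, 31.61, 17.15, 1.69),
            (-8.59, 31.56, 17.14, 1.67),
        ]
        analytic = [solv - vb - prot - dg for dg, prot, solv, vb in rows]
        assert max(analytic) - min(analytic) <= 0.03
        assert np.mean(analytic) == pytest.approx(-7.50, abs=0.02)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rbfe_assemble(math.nan, 0.0)
        with pytest.raises(ValueError):
            abfe_assemble(0.0, math.inf, 0.0, 0.0)


def restrained_integral_oracle(p: BoreschParameters) -> float:
    """Numerical configurational integral of the six-restraint system,
    independent of the closed form."""
    rt = p.tc.RT
    z_r = quad(lambda r: r * r * np.exp(-p.k_r * (r - p.r0) ** 2 / (2 * rt)), 0.0, np.inf)[0]
    z_ta = quad(lambda t: np.sin(t) * np.exp(-p.k_thetaA * (t - p.theta_A) ** 2 / (2 * rt)), 0.0, np.pi)[0]
    z_tb = quad(lambda t: np.sin(t) * np.exp(-p.k_thetaB * (t - p.theta_B) ** 2 / (2 * rt)), 0.0, np.pi)[0]
    z_phi = 1.0
    for k in (p.k_phiA, p.k_phiB, p.k_phiC):
        z_phi *= quad(lambda x: np.exp(-k * x * x / (2 * rt)), -np.pi, np.pi)[0]
    z = z_r * z_ta * z_tb * z_phi
    return -rt * math.log(8.0 * math.pi**2 * p.tc.V_std / z)


class TestBoreschAnalytic:
    def params(self, ks, r0=5.0, thA=math.pi / 2, thB=math.pi / 2, T=300.0):
        return BoreschParameters(r0, thA, thB, *ks, tc=ThermoConstants(T=T))

    def test_doubling_force_constants_shifts_by_minus_3RT_ln2(self):
        p1 = self.params((10, 10, 10, 20, 20, 20))
        p2 = self.params((20, 20, 20, 40, 40, 40))
        rt = p1.tc.RT
        assert boresch_analytic(p2) - boresch_analytic(p1) == pytest.approx(-3 * rt * math.log(2), abs=1e-12)

    @pytest.mark.parametrize(
        "ks",
        [
            (10, 10, 10, 20, 20, 20),  # PLpro restraint constants
            (4, 20, 20, 40, 40, 40),   # lysozyme restraint constants
        ],
    )
    def test_matches_numerical_oracle(self, ks):
        p = self.params(ks)
        assert boresch_analytic(p) == pytest.approx(restrained_integral_oracle(p), abs=0.05)

    @pytest.mark.parametrize("r0", [3.0, 5.0, 8.0])
    @pytest.mark.parametrize("theta", [math.pi / 3, math.pi / 2, 2 * math.pi / 3])
    def test_oracle_agreement_across_stiff_grid(self, r0, theta):
        p = self.params((15, 25, 25, 50, 50, 50), r0=r0, thA=theta, thB=theta)
        assert boresch_analytic(p) == pytest.approx(restrained_integral_oracle(p), abs=0.05)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            BoreschParameters(0.0, 1.0, 1.0, 1, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            BoreschParameters(5.0, 0.0, 1.0, 1, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            BoreschParameters(5.0, 1.0, 1.0, -1, 1, 1, 1, 1, 1)
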
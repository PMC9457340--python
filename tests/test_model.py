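import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_trapezoid

from bnyg import (
    InvalidParameterError,
    PhaseParams,
    PropagatorQuery,
    dry_friction_propagator,
    gaussianity_time,
    laplace_pdf,
    msd,
    observed_curve,
    observed_pdf,
    rms_relative_distance,
    transition_excess_kurtosis,
    transition_pdf,
)
from bnyg.model import laplace_scale, transition_variance


class TestDryFrictionPropagator:
    @pytest.mark.parametrize("tau", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("r0", [0.0, 1.0])
    def test_normalization(self, tau, r0):
        r = np.linspace(-50.0, 50.0, 200001)
        mass = np.trapezoid(dry_friction_propagator(r, tau, r0), r)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_nonnegative(self):
        r = np.linspace(-30.0, 30.0, 5001)
        assert np.all(dry_friction_propagator(r, 2.5, 0.7) >= 0.0)

    def test_long_time_limit_is_laplace(self):
        # stationary Boltzmann–Gibbs law of the linear potential
        r = np.linspace(-25.0, 25.0, 10001)
        p = dry_friction_propagator(r, 50.0, 1.0)
        assert np.abs(p - 0.5 * np.exp(-np.abs(r))).max() < 1e-3

    def test_monte_carlo_agreement(self, rng):
        # independent Euler–Maruyama oracle at τ = 1
        n, dt, tau = 100_000, 2e-3, 1.0
        x = np.zeros(n)
        for _ in range(int(round(tau / dt))):
            x += -np.sign(x) * dt + math.sqrt(2.0 * dt) * rng.standard_normal(n)
        grid = np.linspace(-30.0, 30.0, 20001)
        cdf = cumulative_trapezoid(dry_friction_propagator(grid, tau, 0.0),
                                   grid, initial=0.0)
        cdf /= cdf[-1]
        theory = np.interp(np.sort(x), grid, cdf)
        empirical = np.arange(1, n + 1) / n
        assert np.abs(theory - empirical).max() < 0.01

    def test_query_object(self):
        q = PropagatorQuery(r=0.3, r0=0.0, tau=2.0)
        assert dry_friction_propagator(q) == pytest.approx(
            float(dry_friction_propagator(0.3, 2.0, 0.0)))

    def test_domain_error(self):
        with pytest.raises(InvalidParameterError):
            dry_friction_propagator(0.0, 0.0)
        with pytest.raises(InvalidParameterError):
            PropagatorQuery(r=0.0, r0=0.0, tau=-1.0)


class TestLaplacePDF:
    def test_rescaled_variance(self, paper_phase):
        # Var of Laplace = 2λ²; rescaled λ = sqrt(Davg·t)
        for t in (0.06, 0.6, 3.0):
            lam = laplace_scale(t, paper_phase, rescale=True)
            assert 2.0 * lam**2 == pytest.approx(
                2.0 * paper_phase.Davg * t, rel=1e-9)

    def test_peak_height(self, paper_phase):
        # 1/(2·sqrt(0.40·3)) = 0.456435…
        assert laplace_pdf(0.0, 3.0, paper_phase) == pytest.approx(
            0.4564355, rel=1e-6)

    def test_log_linearity(self, paper_phase):
        x = np.linspace(0.01, 3.0, 500)
        lam = laplace_scale(0.6, paper_phase)
        slope = np.polyfit(x, np.log(laplace_pdf(x, 0.6, paper_phase)), 1)[0]
        assert slope == pytest.approx(-1.0 / lam, rel=1e-9)

    def test_bare_scale(self, paper_phase):
        lam = laplace_scale(2.0, paper_phase, rescale=False)
        assert lam == pytest.approx(math.sqrt(paper_phase.DeffG * 2.0), rel=1e-12)

    def test_domain_error(self, paper_phase):
        with pytest.raises(InvalidParameterError):
            laplace_pdf(0.0, 0.0, paper_phase)


class TestTransitionPDF:
    LAM0 = math.sqrt(0.014 * 4.0)
    DEFFL = 0.79

    def test_zero_time_recovers_laplace(self):
        x = np.linspace(-5.0, 5.0, 2001)
        expected = np.exp(-np.abs(x) / self.LAM0) / (2.0 * self.LAM0)
        got = transition_pdf(x, 0.0, self.LAM0, self.DEFFL)
        assert np.abs(got - expected).max() < 1e-8

    def test_small_lambda_recovers_gaussian(self):
        t_prime = 1.0
        s = math.sqrt(2.0 * self.DEFFL * t_prime)
        lam0 = 1e-4 * s
        x = np.linspace(-8.0, 8.0, 2001)
        gaussian = np.exp(-x**2 / (2.0 * s**2)) / math.sqrt(2.0 * math.pi * s**2)
        got = transition_pdf(x, t_prime, lam0, self.DEFFL)
        assert np.abs(got - gaussian).max() < 1e-6

    def test_unit_mass_and_symmetry(self):
        x = np.linspace(-30.0, 30.0, 120001)
        p = transition_pdf(x, 1.8, self.LAM0, self.DEFFL)
        assert np.trapezoid(p, x) == pytest.approx(1.0, abs=1e-6)
        assert np.abs(p - p[::-1]).max() < 1e-13 * p.max()

    def test_overflow_contract(self):
        # finite for s²/2λ0² up to 10⁴
        lam0 = 1.0
        s_sq = 2.0e4  # s²/2λ0² = 10⁴
        t_prime = s_sq / (2.0 * self.DEFFL)
        x = np.linspace(-5e4, 5e4, 101)
        p = transition_pdf(x, t_prime, lam0, self.DEFFL)
        assert np.all(np.isfinite(p)) and np.all(p >= 0)

    def test_quadrature_convolution_agreement(self):
        # second independent oracle: direct quadrature of Laplace × Gaussian
        rng = np.random.default_rng(7)
        for _ in range(5):
            lam0 = float(rng.uniform(0.5, 2.0))
            s = float(rng.uniform(0.5, 2.0))
            t_prime = s**2 / (2.0 * self.DEFFL)
            sigma = math.sqrt(2.0 * lam0**2 + s**2)
            x = np.linspace(-8.0 * sigma, 8.0 * sigma, 2**15 + 1)
            dx = x[1] - x[0]
            laplace = np.exp(-np.abs(x) / lam0) / (2.0 * lam0)
            kernel_x = np.arange(-int(8 * s / dx), int(8 * s / dx) + 1) * dx
            kernel = np.exp(-kernel_x**2 / (2.0 * s**2))
            kernel /= kernel.sum()
            quadrature = np.convolve(laplace, kernel, mode="same")
            closed = transition_pdf(x, t_prime, lam0, self.DEFFL)
            core = np.abs(x) < 6.0 * sigma
            assert np.abs(quadrature[core] - closed[core]).max() < 1e-6

    def test_variance_rescale(self):
        target = 3.7
        sigma = math.sqrt(target)
        x = np.linspace(-12.0 * sigma, 12.0 * sigma, 2**16 + 1)
        p = transition_pdf(x, 1.8, self.LAM0, self.DEFFL, rescale_to=target)
        mass = np.trapezoid(p, x)
        var = np.trapezoid(x**2 * p, x) / mass
        assert mass == pytest.approx(1.0, abs=1e-6)
        assert var == pytest.approx(target, rel=1e-6)

    def test_kurtosis_closed_form_matches_numeric(self):
        x = np.linspace(-40.0, 40.0, 2**17 + 1)
        p = transition_pdf(x, 1.8, self.LAM0, self.DEFFL)
        m2 = np.trapezoid(x**2 * p, x)
        m4 = np.trapezoid(x**4 * p, x)
        numeric = m4 / m2**2 - 3.0
        closed = transition_excess_kurtosis(self.LAM0, self.DEFFL, 1.8)
        assert numeric == pytest.approx(closed, rel=1e-4, abs=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidParameterError):
            transition_pdf(0.0, -0.1, self.LAM0, self.DEFFL)


class TestMSD:
    def test_zero_time(self, paper_phase):
        assert msd(0.0, paper_phase) == 0.0

    def test_one_dimensional_value(self, paper_phase):
        assert msd(1.0, paper_phase, dims=1) == pytest.approx(0.80, rel=1e-9)

    def test_three_to_one_ratio(self, paper_phase):
        for t in (0.5, 2.0, 10.0):
            assert msd(t, paper_phase, dims=3) == pytest.approx(
                3.0 * msd(t, paper_phase, dims=1), rel=1e-12)

    def test_unsupported_dims(self, paper_phase):
        with pytest.raises(InvalidParameterError):
            msd(1.0, paper_phase, dims=2)


class TestObservedPDF:
    @pytest.mark.parametrize("t", [0.06, 0.6, 3.0, 4.0, 5.8, 9.0])
    def test_variance_contract(self, t, paper_phase):
        sigma = math.sqrt(msd(t, paper_phase))
        x = np.linspace(-40.0 * sigma, 40.0 * sigma, 2**17 + 1)
        p = observed_pdf(x, t, paper_phase)
        mass = np.trapezoid(p, x)
        var = np.trapezoid(x**2 * p, x) / mass
        assert mass == pytest.approx(1.0, abs=1e-6)
        assert var == pytest.approx(2.0 * paper_phase.Davg * t, rel=1e-6)

    def test_laplace_branch_label(self, paper_phase):
        assert observed_curve(3.0, paper_phase).regime_label == "gas"
        assert observed_curve(4.0, paper_phase).regime_label == "gas"

    def test_transition_branch_kurtosis(self, paper_phase):
        curve = observed_curve(5.8, paper_phase)
        assert curve.regime_label == "transition"
        lam0 = math.sqrt(paper_phase.DeffG * paper_phase.tc)
        kurt = transition_excess_kurtosis(lam0, paper_phase.DeffL, 1.8)
        assert 0.0 < kurt < 3.0
        # frozen: 3·(2λ0²)²/(2λ0² + 2·DeffL·t′)² with λ0² = 0.056, DeffL = 0.786
        assert kurt == pytest.approx(0.0043490, rel=1e-3)

    def test_kurtosis_monotone_decay(self, paper_phase):
        lam0 = math.sqrt(paper_phase.DeffG * paper_phase.tc)
        t_primes = np.linspace(0.0, 10.0, 50)
        kurts = [transition_excess_kurtosis(lam0, paper_phase.DeffL, tp)
                 for tp in t_primes]
        assert kurts[0] == pytest.approx(3.0, rel=1e-12)
        assert np.all(np.diff(kurts) < 0)
        assert kurts[-1] < 0.01

    def test_even_symmetry(self, paper_phase):
        for t in (0.6, 5.8):
            curve = observed_curve(t, paper_phase)
            assert np.abs(curve.density - curve.density[::-1]).max() \
                <= 1e-14 * curve.density.max()

    def test_domain_error(self, paper_phase):
        with pytest.raises(InvalidParameterError):
            observed_pdf(0.0, -1.0, paper_phase)


class TestGaussianityTime:
    def test_paper_parameters(self, paper_phase):
        t_prime = gaussianity_time(paper_phase, threshold=0.05)
        lam0_sq = paper_phase.DeffG * paper_phase.tc
        expected = lam0_sq * (math.sqrt(3.0 / 0.05) - 1.0) / paper_phase.DeffL
        assert t_prime == pytest.approx(expected, rel=1e-12)
        assert t_prime <= 2.0

    def test_threshold_is_attained(self, paper_phase):
        t_prime = gaussianity_time(paper_phase, threshold=0.05)
        lam0 = math.sqrt(paper_phase.DeffG * paper_phase.tc)
        assert transition_excess_kurtosis(lam0, paper_phase.DeffL, t_prime) \
            == pytest.approx(0.05, rel=1e-9)

    def test_already_gaussian(self, paper_phase):
        # threshold at or above the Laplace value: transition is immediate
        assert gaussianity_time(paper_phase, threshold=3.0) == 0.0
        assert transition_excess_kurtosis(0.0, paper_phase.DeffL, 1.0) == 0.0

    @given(factor=st.floats(1.1, 10.0))
    @settings(max_examples=25)
    def test_monotone_in_liquid_diffusivity(self, factor):
        slow = PhaseParams(D=0.014, Z_G=1.0, Z_L=0.2, tc=4.0)
        fast = PhaseParams(D=0.014 * factor, Z_G=math.sqrt(factor), Z_L=0.2, tc=4.0)
        # same DeffG (λ0), larger DeffL → faster Gaussianization
        assert fast.DeffG == pytest.approx(slow.DeffG, rel=1e-9)
        assert fast.DeffL > slow.DeffL
        assert gaussianity_time(fast) < gaussianity_time(slow)


class TestRMSRelativeDistance:
    def test_zero_time(self):
        assert rms_relative_distance(0.0, 1.0, 0.5) == 0.0

    def test_sqrt_time_scaling(self):
        assert rms_relative_distance(4.0, 0.3, 0.7) == pytest.approx(
            2.0 * rms_relative_distance(1.0, 0.3, 0.7), rel=1e-12)

    def test_halving_z_doubles(self):
        assert rms_relative_distance(1.0, 0.3, 0.25) == pytest.approx(
            2.0 * rms_relative_distance(1.0, 0.3, 0.5), rel=1e-12)

    def test_zero_z_rejected(self):
        with pytest.raises(InvalidParameterError):
            rms_relative_distance(1.0, 1.0, 0.0)


class TestTransitionVariance:
    @given(lam0=st.floats(0.01, 5.0), d=st.floats(0.01, 5.0),
           tp=st.floats(0.0, 50.0))
    @settings(max_examples=50)
    def test_additive_in_time(self, lam0, d, tp):
        assert transition_variance(lam0, d, tp) == pytest.approx(
            2.0 * lam0**2 + 2.0 * d * tp, rel=1e-12)
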
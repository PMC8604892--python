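import math

import numpy as np
import pytest

from iadtmodels import (
    FitProblem, GeneratorConfig, InsufficientSampleError,
    NonIdentifiableError, PriorEntry, PriorSpec, build_prior, gaussian_loglik,
    generate_cohort, get_model, laplace_log_evidence, log_likelihood,
    map_fit, nested_log_evidence, uniform_prior,
)

SQRT_2PI = math.sqrt(2 * math.pi)


# ---------------------------------------------------------------------------
# toy problems
# ---------------------------------------------------------------------------

class GaussianMeanToy:
    """n observations ~ N(mu, sigma): conjugate, fully analytic."""

    free = ("mu",)

    def __init__(self, data, sigma):
        self.data = np.asarray(data)
        self.sigma = sigma

    def loglik(self, theta):
        mu = theta[0]
        return float(-0.5 * np.sum(((self.data - mu) / self.sigma) ** 2)
                     - self.data.size * math.log(self.sigma * SQRT_2PI))

    def analytic_log_evidence(self, width):
        n = self.data.size
        mu_hat = self.data.mean()
        return (math.log(math.sqrt(2 * math.pi * self.sigma ** 2 / n) / width)
                + self.loglik([mu_hat]))


@pytest.fixture
def gaussian_toy(rng):
    return GaussianMeanToy(2.0 + 0.4 * rng.standard_normal(12), sigma=0.4)


def flat_prior(width=10.0):
    return PriorSpec((PriorEntry(name="mu", lower=0.0, upper=width),))


# ---------------------------------------------------------------------------
# likelihood arithmetic
# ---------------------------------------------------------------------------

class TestGaussianLoglik:
    def test_perfect_fit_constant(self):
        n, e = 7, 0.25
        obs = np.linspace(1, 2, n)
        val = gaussian_loglik(obs, obs, np.full(n, e))
        assert val == pytest.approx(-n * math.log(e * SQRT_2PI))

    def test_unit_residual_costs_half(self):
        obs = np.array([1.0, 2.0])
        e = np.array([0.1, 0.2])
        base = gaussian_loglik(obs, obs, e)
        shifted = gaussian_loglik(obs, obs + np.array([0.0, 0.2]), e)
        assert base - shifted == pytest.approx(0.5)

    def test_three_point_hand_computed(self):
        obs = np.array([5.0, 2.0, 1.0])
        model = np.array([4.5, 2.2, 1.0])
        e = np.array([0.5, 0.1, 0.2])
        expected = (-0.5 * (1.0 + 4.0 + 0.0)
                    - math.log(0.5 * SQRT_2PI) - math.log(0.1 * SQRT_2PI)
                    - math.log(0.2 * SQRT_2PI))
        assert gaussian_loglik(obs, model, e) == pytest.approx(expected)

    def test_doubling_errors_at_perfect_fit(self):
        obs = np.linspace(1, 3, 9)
        e = np.full(9, 0.1)
        assert (gaussian_loglik(obs, obs, e)
                - gaussian_loglik(obs, obs, 2 * e)) == pytest.approx(
            9 * math.log(2))

    def test_zero_error_rejected(self):
        with pytest.raises(ValueError):
            gaussian_loglik([1.0], [1.0], [0.0])


def test_ode_log_likelihood_matches_direct_arithmetic(small_h10_cohort):
    rec = small_h10_cohort.records[0]
    truth = small_h10_cohort.ground_truth[rec.patient_id]
    p = get_model("H10").pvector(truth["params"])
    ll = log_likelihood("H10", p, rec, np.array(truth["init_state"]))
    clean = np.maximum(np.array(truth["clean_psa"]), 0.1)
    # reference: the generator's own noiseless curve vs the noisy data
    ref = gaussian_loglik(rec.psa, clean, rec.errors)
    assert ll == pytest.approx(ref, abs=0.5)


# ---------------------------------------------------------------------------
# MAP search
# ---------------------------------------------------------------------------

class TestMapFit:
    def test_quadratic_toy_reaches_least_squares_solution(self, gaussian_toy):
        fit = map_fit(gaussian_toy, flat_prior(), seed=1, maxiter=200)
        assert fit.map_free[0] == pytest.approx(gaussian_toy.data.mean(),
                                                abs=1e-6)

    def test_seeded_determinism(self, gaussian_toy):
        a = map_fit(gaussian_toy, flat_prior(), seed=3, maxiter=50)
        b = map_fit(gaussian_toy, flat_prior(), seed=3, maxiter=50)
        assert np.array_equal(a.map_free, b.map_free)

    def test_infeasible_prior_raises(self, gaussian_toy):
        prior = PriorSpec((PriorEntry(name="mu", lower=5e5, upper=1e6,
                                      log_space=True),))

        class Hopeless:
            free = ("mu",)

            def loglik(self, theta):
                return -np.inf

        with pytest.raises(RuntimeError, match="feasible"):
            map_fit(Hopeless(), prior, seed=0, maxiter=5)


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

class TestLaplaceEvidence:
    def test_conjugate_gaussian_oracle(self, gaussian_toy):
        prior = flat_prior(10.0)
        fit = map_fit(gaussian_toy, prior, seed=1, maxiter=200)
        lz = laplace_log_evidence(fit, prior)
        assert lz == pytest.approx(gaussian_toy.analytic_log_evidence(10.0),
                                   abs=1e-6)

    def test_occam_factor_of_prior_widening(self, gaussian_toy):
        lzs = []
        for width in (10.0, 100.0):
            prior = flat_prior(width)
            fit = map_fit(gaussian_toy, prior, seed=1, maxiter=200)
            lzs.append(laplace_log_evidence(fit, prior))
        assert lzs[0] - lzs[1] == pytest.approx(math.log(10.0), abs=1e-6)

    def test_zero_free_parameters_returns_loglik(self, gaussian_toy):
        from iadtmodels.inference import FitResult
        fit = FitResult(model_id="toy", patient_id="t", free=(),
                        map_free=np.array([]), map_params=None,
                        log_likelihood_at_map=-3.21, log_prior_at_map=0.0,
                        fisher_info=None, seed=0)
        assert laplace_log_evidence(fit, PriorSpec(())) == -3.21

    def test_flat_direction_is_named(self, gaussian_toy):
        prior = flat_prior()
        fit = map_fit(gaussian_toy, prior, seed=1, maxiter=50)
        fit.fisher_info = np.array([[0.0]])
        with pytest.raises(NonIdentifiableError, match="mu"):
            laplace_log_evidence(fit, prior)

    def test_paper_variant_differs_by_documented_amount(self, gaussian_toy):
        prior = flat_prior()
        fit = map_fit(gaussian_toy, prior, seed=1, maxiter=200)
        std = laplace_log_evidence(fit, prior)
        lit = laplace_log_evidence(fit, prior, paper_variant=True)
        F = fit.fisher_info[0, 0]
        assert lit - std == pytest.approx(
            math.log(F) - 0.5 * math.log(2 * math.pi), abs=1e-9)


class TestNestedEvidence:
    def test_conjugate_gaussian_within_error(self, gaussian_toy):
        prior = flat_prior(10.0)
        logz, err = nested_log_evidence(gaussian_toy, prior, nlive=200,
                                        seed=4)
        assert err > 0
        assert abs(logz - gaussian_toy.analytic_log_evidence(10.0)) < 3 * err

    def test_prior_excluding_mass_matches_quadrature(self, gaussian_toy):
        """With the prior support far from the data, logZ tracks the
        brute-force 1D quadrature of prior × likelihood."""
        from scipy.integrate import quad
        lzs = []
        for lo, hi in ((4.0, 6.0), (6.0, 8.0)):
            prior = PriorSpec((PriorEntry(name="mu", lower=lo, upper=hi),))
            logz, err = nested_log_evidence(gaussian_toy, prior, nlive=200,
                                            seed=9)
            val, _ = quad(lambda mu: math.exp(gaussian_toy.loglik([mu]))
                          / (hi - lo), lo, hi, limit=200)
            lzs.append((logz, math.log(val), err))
        for logz, ref, err in lzs:
            assert abs(logz - ref) < 4 * max(err, 0.05)
        assert lzs[0][0] > lzs[1][0]  # monotone decrease moving away

    def test_evidence_invariant_to_parameter_order(self, rng):
        data = 1.0 + 0.3 * rng.standard_normal(10)

        class TwoParam:
            free = ("mu", "lsig")

            def __init__(self, order):
                self.order = order

            def loglik(self, th):
                mu, lsig = (th[0], th[1]) if self.order == 0 else (th[1],
                                                                   th[0])
                sig = math.exp(lsig)
                return float(-0.5 * np.sum(((data - mu) / sig) ** 2)
                             - data.size * math.log(sig * SQRT_2PI))

        e1 = PriorEntry(name="mu", lower=0.0, upper=3.0)
        e2 = PriorEntry(name="lsig", lower=-3.0 + 3.0, upper=3.0)
        e2 = PriorEntry(name="lsig", lower=0.001, upper=3.0)
        za, ea = nested_log_evidence(TwoParam(0), PriorSpec((e1, e2)),
                                     nlive=150, seed=11)
        zb, eb = nested_log_evidence(TwoParam(1), PriorSpec((e2, e1)),
                                     nlive=150, seed=11)
        assert abs(za - zb) < 3 * (ea + eb)


def test_laplace_and_nested_agree_on_identified_ode_fit():
    """On a well-identified 2-parameter stem-cell-model fit, the Laplace
    and nested-sampling evidences agree to within ~1 nat."""
    cohort = generate_cohort(GeneratorConfig(
        n_patients=1, model_id="B20", noise_sd=0.1, seed=21,
        cycles_max=2, sampling_interval_days=28.0, sampling_jitter_days=5.0,
    ))
    rec = cohort.records[0]
    truth = cohort.ground_truth[rec.patient_id]
    free = ("p_S", "delta_D")
    fixed = {k: v for k, v in truth["params"].items() if k not in free}
    problem = FitProblem("B20", rec, np.array(truth["init_state"]), free,
                         fixed,
                         solver_opts={"method": "LSODA", "rtol": 3e-4,
                                      "atol": 1e-6, "max_rhs_calls": 20000})
    # linear-space flat prior: the Laplace estimate assumes locally flat
    # prior density, so the comparison isolates the Gaussianity of the
    # likelihood peak
    prior = uniform_prior(free, [(1e-3, 0.3), (1e-3, 0.3)])
    fit = map_fit(problem, prior, seed=2, popsize=6, maxiter=20)
    lz_laplace = laplace_log_evidence(fit, prior)
    lz_nested, err = nested_log_evidence(problem, prior, nlive=60, seed=3,
                                         n_steps=10)
    assert abs(lz_laplace - lz_nested) < max(1.0, 3 * err)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

class TestBuildPrior:
    def test_uniform_density_and_transform(self):
        prior = build_prior("B20", "uniform")
        md = get_model("B20")
        for entry, (lo, hi) in zip(prior.entries, md.bounds):
            assert math.exp(entry.logpdf(0.5 * (lo + hi))) == pytest.approx(
                1.0 / (hi - lo))
            assert entry.ppf(0.0) == pytest.approx(lo)
            assert entry.ppf(1.0) == pytest.approx(hi)

    def test_empirical_below_poisson_sample_raises(self):
        with pytest.raises(InsufficientSampleError):
            build_prior("B20", "empirical",
                        {"fits": [None] * 3, "n_pat": 89,
                         "free": ("p_S",)})

    def test_empirical_density_tracks_cohort_map_values(self, rng):
        from iadtmodels.inference import FitResult
        fits = []
        vals = rng.normal(0.3, 0.02, 12)
        for v in vals:
            fits.append(FitResult(
                model_id="B20", patient_id="x", free=("p_S",),
                map_free=np.array([v]), map_params=None,
                log_likelihood_at_map=0.0, log_prior_at_map=0.0,
                fisher_info=None, seed=0))
        prior = build_prior("B20", "empirical",
                            {"fits": fits, "n_pat": 100, "free": ("p_S",),
                             "bounds": {"p_S": (0.0, 1.0)}})
        e = prior.entries[0]
        assert e.logpdf(0.3) > e.logpdf(0.8)
        mass = np.trapezoid(e.density, e.grid)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_jeffreys_constant_for_location_parameter(self):
        """The Fisher information of a Gaussian mean is independent of the
        mean, so the tabulated density is flat."""
        prior = build_prior(
            "B20", "jeffreys",
            {"free": ("p_S",), "bounds": {"p_S": (0.1, 1.0)},
             "fisher": lambda p: np.array([[25.0]]),
             "reference": np.array([0.5])})
        e = prior.entries[0]
        assert np.allclose(e.density, e.density[0])
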
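"""Co-refinement machinery: objective pieces, weighting schemes, the
Gaussian-linear conjugate oracle, alpha scanning and posterior averaging."""

import numpy as np
import pytest

from cosas.corefine import (InvalidWeightError, PriorParam, PriorSet,
                            UNIFORM_ALPHA, alpha_scan, apply_weights, chi2,
                            dataset_weights, evidence, fit_at_alpha,
                            fit_gaussian, fit_uniform, posterior_average,
                            prior_penalty)
from cosas.evaluate import Condition, DatasetSpec, simulate_replicate
from cosas.models import ScatteringModel
from cosas.simulate import Curve, NoiseSpec


# ---------------------------------------------------------------------------
# chi2 / prior penalty
# ---------------------------------------------------------------------------

def _toy_curve(I, sigma=None):
    n = len(I)
    return Curve(q=np.linspace(0.01, 0.5, n), I=np.asarray(I, float),
                 sigma=np.ones(n) if sigma is None else np.asarray(sigma))


class TestChi2:
    def test_perfect_model(self):
        c = _toy_curve([1.0, 2.0, 3.0])
        assert chi2(c, c.I) == 0.0

    def test_one_sigma_residuals(self):
        c = _toy_curve([1.0, 2.0, 3.0, 4.0])
        assert chi2(c, c.I - c.sigma) == pytest.approx(4.0)

    def test_hand_computed(self):
        c = _toy_curve([1.0, 2.0, 3.0])
        assert chi2(c, c.I - np.array([1.0, 2.0, 3.0])) == pytest.approx(14.0)


class TestPriorPenalty:
    def test_zero_at_means(self):
        priors = PriorSet([PriorParam("a", 5.0, 1.0),
                           PriorParam("b", -2.0, 0.5)])
        assert prior_penalty(priors.mu, priors) == 0.0

    def test_two_sigma_offset(self):
        priors = PriorSet([PriorParam("a", 5.0, 1.0)])
        assert prior_penalty(np.array([7.0]), priors) == pytest.approx(4.0)

    def test_uniform_parameters_excluded(self):
        priors = PriorSet([
            PriorParam("a", 5.0, 1.0, kind="gaussian"),
            PriorParam("b", 3.0, 1.0, kind="uniform"),
        ])
        x = np.array([6.0, 99.0 * 0 + 7.0])
        # brute-force over the gaussian subset only
        expected = ((6.0 - 5.0) / 1.0) ** 2
        assert prior_penalty(x, priors) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# weighting schemes
# ---------------------------------------------------------------------------

class TestWeights:
    def _curves(self, sizes=(50, 400)):
        return [_toy_curve(np.ones(n)) for n in sizes]

    def test_naive_no_change(self):
        curves = self._curves()
        ws = dataset_weights(curves, "naive")
        scaled = apply_weights(curves, ws)
        for c, s in zip(curves, scaled):
            np.testing.assert_array_equal(c.sigma, s.sigma)

    def test_reduced_scales_by_sqrt_M(self):
        curves = self._curves((50, 400))
        ws = dataset_weights(curves, "reduced")
        scaled = apply_weights(curves, ws)
        np.testing.assert_allclose(scaled[0].sigma,
                                   np.sqrt(50) * curves[0].sigma)
        np.testing.assert_allclose(scaled[1].sigma,
                                   np.sqrt(400) * curves[1].sigma)

    def test_information_requires_ng(self):
        with pytest.raises(InvalidWeightError):
            dataset_weights(self._curves(), "information")

    def test_information_weights(self):
        ws = dataset_weights(self._curves((50, 400)), "information",
                             ng_bift=[8.0, 12.0])
        np.testing.assert_allclose(ws.w, [8.0 / 50, 12.0 / 400])

    def test_nonpositive_weight_rejected(self):
        from cosas.corefine import WeightScheme
        with pytest.raises(InvalidWeightError):
            WeightScheme(name="bad", w=np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# Gaussian-linear conjugate oracle
# ---------------------------------------------------------------------------

class LineModel(ScatteringModel):
    """y = m*q + c: closed-form conjugate results exist for Gaussian priors."""

    def __init__(self):
        super().__init__(name="line", n_datasets=1)

    @property
    def param_names(self):
        return ["m", "c"]

    @property
    def structural_indices(self):
        return [0, 1]

    def eval_dataset(self, j, q, x):
        return x[0] * q + x[1]

    def eval_dataset_grad(self, j, q, x):
        J = np.column_stack([q, np.ones_like(q)])
        return x[0] * q + x[1], J


def _line_setup(seed=0, n=40):
    rng = np.random.default_rng(seed)
    q = np.linspace(0.1, 2.0, n)
    sigma = np.full(n, 0.3)
    y = 1.7 * q - 0.4 + rng.normal(0, 0.3, n)
    curve = Curve(q=q, I=y, sigma=sigma)
    priors = PriorSet([
        PriorParam("m", 1.0, 2.0, lower=-100, upper=100),
        PriorParam("c", 0.0, 1.5, lower=-100, upper=100),
    ])
    return curve, priors


def _ridge_solution(curve, priors, alpha):
    """Closed-form minimizer of chi2 + alpha*S for the linear model."""
    X = np.column_stack([curve.q, np.ones_like(curve.q)])
    W = np.diag(1.0 / curve.sigma**2)
    D = np.diag(1.0 / priors.sigma**2)
    A = X.T @ W @ X + alpha * D
    b = X.T @ W @ curve.I + alpha * D @ priors.mu
    return np.linalg.solve(A, b)


class TestGaussianLinearOracle:
    @pytest.mark.parametrize("alpha", [1e-3, 1.0, 50.0])
    def test_fit_matches_ridge_closed_form(self, alpha):
        curve, priors = _line_setup()
        model = LineModel()
        ws = dataset_weights([curve], "naive")
        x, info = fit_at_alpha([curve], model, priors, ws, alpha)
        expected = _ridge_solution(curve, priors, alpha)
        np.testing.assert_allclose(x, expected, rtol=1e-8, atol=1e-10)

    def test_evidence_matches_exact_marginal_likelihood(self):
        """The Laplace evidence is exact for a linear model; its alpha
        profile must match the conjugate marginal likelihood up to an
        alpha-independent constant."""
        curve, priors = _line_setup()
        model = LineModel()
        ws = dataset_weights([curve], "naive")
        alphas = np.logspace(-2, 2, 9)
        ours, exact = [], []
        X = np.column_stack([curve.q, np.ones_like(curve.q)])
        Sig = np.diag(curve.sigma**2)
        S0 = np.diag(priors.sigma**2)
        for a in alphas:
            x, info = fit_at_alpha([curve], model, priors, ws, a)
            ours.append(evidence([curve], model, priors, ws, a, x,
                                 Q=info["Q"]))
            C = Sig + X @ (S0 / a) @ X.T
            r = curve.I - X @ priors.mu
            sign, logdet = np.linalg.slogdet(C)
            exact.append(-0.5 * r @ np.linalg.solve(C, r) - 0.5 * logdet)
        ours, exact = np.array(ours), np.array(exact)
        diff = ours - exact
        np.testing.assert_allclose(diff - diff.mean(), 0.0, atol=1e-6)

    def test_posterior_average_matches_brute_force(self):
        curve, priors = _line_setup()
        model = LineModel()
        scan = alpha_scan([curve], model, priors,
                          dataset_weights([curve], "naive"),
                          alpha_range=(1e-2, 1e2))
        xbar = posterior_average(scan)
        expected = sum(p * x for p, x in zip(scan.prob, scan.params))
        np.testing.assert_allclose(xbar, expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# alpha scan behaviour
# ---------------------------------------------------------------------------

class TestAlphaScan:
    def test_eleven_points_and_normalization(self):
        curve, priors = _line_setup()
        scan = alpha_scan([curve], LineModel(), priors,
                          dataset_weights([curve], "naive"))
        assert len(scan.alphas) == 11
        assert scan.prob.sum() == pytest.approx(1.0)

    def test_window_auto_adjustment_recovers_same_maximum(self):
        """Starting the scan two decades off must shift the window until the
        evidence maximum is interior, landing on the same optimum."""
        curve, priors = _line_setup()
        model = LineModel()
        ws = dataset_weights([curve], "naive")
        ref = alpha_scan([curve], model, priors, ws, alpha_range=(1e-2, 1e2))
        offset = alpha_scan([curve], model, priors, ws,
                            alpha_range=(1e2, 1e6))
        a_ref = ref.alphas[np.argmax(ref.prob)]
        a_off = offset.alphas[np.argmax(offset.prob)]
        assert offset.adjusted > 0
        assert abs(np.log10(a_ref) - np.log10(a_off)) < 1.0
        assert offset.converged

    def test_widened_priors_shift_alpha_posterior(self):
        curve, priors = _line_setup()
        model = LineModel()
        ws = dataset_weights([curve], "naive")
        wide = PriorSet([PriorParam("m", 1.0, 4.0, lower=-100, upper=100),
                         PriorParam("c", 0.0, 3.0, lower=-100, upper=100)])
        s1 = alpha_scan([curve], model, priors, ws)
        s2 = alpha_scan([curve], model, wide, ws)
        assert not np.allclose(s1.log_evidence - s1.log_evidence.max(),
                               s2.log_evidence - s2.log_evidence.max())


# ---------------------------------------------------------------------------
# full fits on the benchmark model
# ---------------------------------------------------------------------------

class TestBenchmarkFits:
    def _noiseless_condition(self):
        quiet = lambda s, c: NoiseSpec(s=s, c=c, noise_factor=1e-24)
        return Condition(
            name="noiseless",
            datasets=[DatasetSpec(kind="sans", M=50,
                                  noise=quiet(10, 0.95)),
                      DatasetSpec(kind="saxs", M=400,
                                  noise=quiet(100, 0.85))],
            base_seed=5)

    def test_zero_noise_recovery_all_schemes(self):
        """With vanishing noise every weighting scheme recovers the truth."""
        cond = self._noiseless_condition()
        curves = simulate_replicate(cond, 0)
        model, priors = cond.model(), cond.priors()
        x_true = cond.truth_vector()
        for scheme in ("naive", "reduced"):
            fit = fit_uniform(curves, model, priors, scheme=scheme)
            np.testing.assert_allclose(fit.x[:4], x_true[:4], rtol=1e-3)

    def test_common_weight_factor_leaves_minimizer_unchanged(self):
        from cosas.corefine import WeightScheme
        cond = Condition(
            name="c", datasets=[DatasetSpec(kind="sans", M=50),
                                DatasetSpec(kind="saxs", M=400)],
            base_seed=21)
        curves = simulate_replicate(cond, 0)
        model, priors = cond.model(), cond.priors()
        f1 = fit_uniform(curves, model, priors,
                         scheme=WeightScheme("w", np.array([1.0, 1.0])))
        f2 = fit_uniform(curves, model, priors,
                         scheme=WeightScheme("w", np.array([7.0, 7.0])))
        np.testing.assert_allclose(f1.x, f2.x, rtol=1e-5, atol=1e-8)

    def test_equal_sizes_make_naive_and_reduced_identical(self):
        """With equal M the reduced weights are a common factor of the naive
        ones, so the refined parameters coincide."""
        cond = Condition(
            name="c", datasets=[DatasetSpec(kind="sans", M=300),
                                DatasetSpec(kind="saxs", M=300)],
            base_seed=31)
        curves = simulate_replicate(cond, 0)
        model, priors = cond.model(), cond.priors()
        fn = fit_uniform(curves, model, priors, scheme="naive")
        fr = fit_uniform(curves, model, priors, scheme="reduced")
        np.testing.assert_allclose(fn.x, fr.x, rtol=1e-4, atol=1e-7)

    def test_uniform_fit_ignores_gaussian_widths_except_bounds(self):
        """At alpha = 1e-10 the prior pull is quenched: fits from fixtures
        sharing bounds and means coincide."""
        cond = self._noiseless_condition()
        curves = simulate_replicate(cond, 0)
        model = cond.model()
        pr_uniform = cond.priors()  # Uniform_5sigma fixture
        from cosas import io as cio
        pr_gauss = cio.build_prior_set("Gaussian_best", ["sans", "saxs"])
        f_u = fit_uniform(curves, model, pr_uniform)
        f_g = fit_uniform(curves, model, pr_gauss)
        np.testing.assert_allclose(f_u.x[:4], f_g.x[:4], rtol=1e-4)

    def test_large_alpha_pulls_to_prior_means(self):
        cond = Condition(
            name="c", datasets=[DatasetSpec(kind="sans", M=50),
                                DatasetSpec(kind="saxs", M=400)],
            prior_fixture="Gaussian_poor", base_seed=41)
        curves = simulate_replicate(cond, 0)
        model, priors = cond.model(), cond.priors()
        ws = dataset_weights(curves, "naive")
        x, _ = fit_at_alpha(curves, model, priors, ws, 1e8)
        np.testing.assert_allclose(x[:4], priors.mu[:4], rtol=0.02)

    def test_bounds_respected(self):
        cond = Condition(
            name="c", datasets=[DatasetSpec(kind="sans", M=50),
                                DatasetSpec(kind="saxs", M=400)],
            prior_fixture="Uniform_1sigma", base_seed=51)
        curves = simulate_replicate(cond, 0)
        model, priors = cond.model(), cond.priors()
        fit = fit_uniform(curves, model, priors)
        lo, hi = priors.bounds
        assert np.all(fit.x >= lo - 1e-12) and np.all(fit.x <= hi + 1e-12)

    def test_narrow_uniform_fixture_bounds(self):
        """The Uniform_1sigma fixture restricts R_c to (5, 15) A."""
        from cosas import io as cio
        priors = cio.build_prior_set("Uniform_1sigma", ["sans", "saxs"])
        assert priors[0].lower == 5.0 and priors[0].upper == 15.0


# ---------------------------------------------------------------------------
# mixture stoichiometry with a log-normal ratio prior
# ---------------------------------------------------------------------------

class TestMixtureRecovery:
    def test_fraction_recovered_within_interval(self):
        """A 90/10 two-component mixture refit from noisy data recovers the
        majority fraction within its 68% interval; the log-normal ratio
        prior is centred on a 50/50 mixture (median ratio 1)."""
        from cosas.infocontent import numeric_hessian
        from cosas.models import MixtureModel, ShellSphereParams, \
            coreshell_intensity
        from cosas.simulate import SAXS_NOISE, make_qgrid, sample_curve, \
            sedlak_sigma

        q = make_qgrid(0.001, 0.5, 400)
        I_sym = coreshell_intensity(q, ShellSphereParams(
            R_c=10, shell_radii=[30, 50, 70], rel_contrasts=[2, 3, 4],
            scale=0.5, background=1e-5))
        I_asym = coreshell_intensity(q, ShellSphereParams(
            R_c=14, shell_radii=[38, 55, 78], rel_contrasts=[2, 3, 4],
            scale=0.5, background=1e-5))
        f_true, s_true = 0.9, 1.0
        I_mix = s_true * (f_true * I_sym + (1 - f_true) * I_asym)
        sigma = sedlak_sigma(q, I_mix, SAXS_NOISE)
        curve = sample_curve(q, I_mix, sigma, seed=17)

        model = MixtureModel(components=[(I_sym, I_asym)])
        priors = PriorSet([
            PriorParam("ratio", 1.0, 2.0, kind="lognormal",
                       lower=1e-4, upper=1e4),
            PriorParam("s", 1.0, 0.5, positive=True),
        ])
        fit = fit_gaussian([curve], model, priors, scheme="naive")
        r_hat, s_hat = fit.x
        f_hat = 1.0 / (1.0 + r_hat)

        ws = dataset_weights([curve], "naive")
        def data_chi2(x):
            return chi2(curve, model.eval_dataset(0, curve.q, x))
        H = numeric_hessian(data_chi2, fit.x)
        cov = 2.0 * np.linalg.inv(H)
        sigma_r = np.sqrt(cov[0, 0])
        sigma_f = sigma_r / (1.0 + r_hat) ** 2
        assert abs(f_hat - f_true) < sigma_f
        assert s_hat == pytest.approx(s_true, rel=0.05)

    def test_lognormal_prior_penalty_and_bounds(self):
        priors = PriorSet([PriorParam("ratio", 1.0, 0.5, kind="lognormal")])
        # one log-sigma from the median
        x = np.array([np.exp(0.5)])
        assert prior_penalty(x, priors) == pytest.approx(1.0)
        assert priors[0].lower > 0
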
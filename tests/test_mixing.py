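import numpy as np
import pytest
from scipy.stats import norm

from nitracer.errors import DomainError
from nitracer.io import IsotopeSample, SourceSignatureTable
from nitracer.mixing import (
    MixingConfig,
    fit_mixing_model,
    log_likelihood,
    mixture_moments,
    posterior_summary,
)
from nitracer.synthetic import SCENARIO_DRY, generate_isotope_dataset

FAST = dict(n_chains=4, n_iter=3_000, n_burnin=1_500, thin=3)


def brute_force_moments(p, sig):
    """Straight-loop oracle for the mixture mean/variance sums."""
    K, J = sig.n_sources, sig.n_isotopes
    means, variances = [], []
    for j in range(J):
        denom = sum(p[k] * sig.conc_q[k, j] for k in range(K))
        m = (
            sum(
                p[k] * sig.conc_q[k, j] * (sig.mean_s[k, j] + sig.mean_c[k, j])
                for k in range(K)
            )
            / denom
        )
        v = (
            sum(
                p[k] ** 2
                * sig.conc_q[k, j] ** 2
                * (sig.sd_s[k, j] ** 2 + sig.sd_c[k, j] ** 2)
                for k in range(K)
            )
            / denom**2
        )
        means.append(m)
        variances.append(v)
    return np.array(means), np.array(variances)


class TestMixtureMoments:
    def test_single_source_limit(self):
        sig = SourceSignatureTable(
            ["only"], ["d15n"], np.array([[3.0]]), np.array([[2.0]]),
            mean_c=np.array([[1.0]]), sd_c=np.array([[0.5]]),
        )
        m, v = mixture_moments(np.array([1.0]), sig)
        assert m[0] == pytest.approx(4.0)
        assert v[0] == pytest.approx(4.25)

    def test_equal_mixture_midpoint(self, two_source_signatures):
        sig = two_source_signatures
        sig.sd_s[:] = 0.0
        m, v = mixture_moments(np.array([0.5, 0.5]), sig)
        assert m[0] == pytest.approx(5.0)
        assert v[0] == pytest.approx(0.0)

    def test_matches_brute_force_loop(self, four_source_signatures):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.dirichlet(np.ones(4))
            m, v = mixture_moments(p, four_source_signatures)
            mo, vo = brute_force_moments(p, four_source_signatures)
            np.testing.assert_allclose(m, mo, atol=1e-12)
            np.testing.assert_allclose(v, vo, atol=1e-12)

    def test_off_simplex_rejected(self, two_source_signatures):
        with pytest.raises(DomainError):
            mixture_moments(np.array([0.7, 0.7]), two_source_signatures)


class TestLogLikelihood:
    def test_standard_normal_peak(self, two_source_signatures):
        sig = two_source_signatures
        sig.sd_s[:] = 0.0
        m, _ = mixture_moments(np.array([0.5, 0.5]), sig)
        ll = log_likelihood(
            np.array([0.5, 0.5]), np.array([1.0]), np.array([[m[0]]]), sig
        )
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_decreases_away_from_mean(self, two_source_signatures):
        p = np.array([0.5, 0.5])
        s = np.array([1.0])
        lls = [
            log_likelihood(p, s, np.array([[5.0 + d]]), two_source_signatures)
            for d in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_matches_per_term_density_oracle(self, four_source_signatures):
        sig = four_source_signatures
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(4))
        sigma = np.array([0.7, 1.3])
        X = rng.normal(10, 4, size=(5, 2))
        m, v = mixture_moments(p, sig)
        expected = sum(
            norm.logpdf(X[i, j], m[j], np.sqrt(v[j] + sigma[j] ** 2))
            for i in range(5)
            for j in range(2)
        )
        assert log_likelihood(p, sigma, X, sig) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_off_mean_is_minus_inf(self):
        sig = SourceSignatureTable(
            ["only"], ["d15n"], np.array([[3.0]]), np.array([[0.0]])
        )
        ll = log_likelihood(np.array([1.0]), np.array([0.0]), np.array([[4.0]]), sig)
        assert ll == -np.inf


def grid_posterior_oracle(X, sig, sigma_scale=5.0, n_p=400, n_s=200):
    """Dense grid integration of the K=2, J=1 posterior (flat prior on p1).

    Independent of the MCMC code path: plain quadrature over p1 × sigma.
    """
    p1 = np.linspace(1e-4, 1 - 1e-4, n_p)
    sg = np.linspace(1e-3, 4 * sigma_scale, n_s)
    mu, om = sig.mean_s[:, 0], sig.sd_s[:, 0]
    m = p1 * mu[0] + (1 - p1) * mu[1]
    v = p1**2 * om[0] ** 2 + (1 - p1) ** 2 * om[1] ** 2
    total = v[:, None] + sg[None, :] ** 2  # (n_p, n_s)
    x = np.asarray(X).ravel()
    ll = np.zeros_like(total)
    for xi in x:
        ll += -0.5 * (np.log(2 * np.pi * total) + (xi - m[:, None]) ** 2 / total)
    ll += -0.5 * (sg[None, :] / sigma_scale) ** 2
    w = np.exp(ll - ll.max())
    w /= w.sum()
    wp = w.sum(axis=1)
    mean = float((wp * p1).sum())
    cdf = np.cumsum(wp)
    lo = float(p1[np.searchsorted(cdf, 0.025)])
    hi = float(p1[np.searchsorted(cdf, 0.975)])
    return mean, lo, hi


class TestFitMixingModel:
    def test_single_source_posterior_is_degenerate(self):
        sig = SourceSignatureTable(
            ["only"], ["d15n"], np.array([[3.0]]), np.array([[1.0]])
        )
        X = np.random.default_rng(0).normal(3, 1.5, size=(20, 1))
        post = fit_mixing_model(X, sig, MixingConfig(seed=2, **FAST))
        np.testing.assert_allclose(post.draws_p, 1.0)

    def test_symmetric_problem_gives_half_half(self, two_source_signatures):
        X = np.full((10, 1), 5.0)  # all observations at the midpoint
        post = fit_mixing_model(X, two_source_signatures, MixingConfig(seed=3, **FAST))
        assert post.draws_p[:, 0].mean() == pytest.approx(0.5, abs=0.03)

    def test_matches_grid_oracle_k2_j1(self, two_source_signatures):
        rng = np.random.default_rng(11)
        X = rng.normal(3.0, 1.5, size=(15, 1))
        mean_o, lo_o, hi_o = grid_posterior_oracle(X, two_source_signatures)
        post = fit_mixing_model(
            X, two_source_signatures, MixingConfig(seed=4, **FAST)
        )
        summ = posterior_summary(post, 0.95)
        row = summ[summ.parameter == "A"].iloc[0]
        assert row["mean"] == pytest.approx(mean_o, abs=0.02)
        assert row["lo"] == pytest.approx(lo_o, abs=0.02)
        assert row["hi"] == pytest.approx(hi_o, abs=0.02)

    def test_simplex_conservation(self, four_source_signatures):
        X = np.random.default_rng(1).normal(10, 4, size=(10, 2))
        post = fit_mixing_model(X, four_source_signatures, MixingConfig(seed=5, **FAST))
        np.testing.assert_allclose(post.draws_p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(post.draws_p >= 0)

    def test_prior_recovery_with_zero_observations(self, two_source_signatures):
        alpha = np.array([3.0, 1.0])
        post = fit_mixing_model(
            [],
            two_source_signatures,
            MixingConfig(seed=6, prior_alpha=alpha, **FAST),
        )
        assert post.draws_p[:, 0].mean() == pytest.approx(0.75, abs=0.03)

    def test_label_invariance_of_summaries(self):
        sig = SCENARIO_DRY.signatures
        samples = generate_isotope_dataset(SCENARIO_DRY, seed=8)
        post = fit_mixing_model(samples, sig, MixingConfig(seed=7, **FAST))
        perm = ["MS", "AP", "SN", "CF"]
        post_perm = fit_mixing_model(
            samples, sig.reorder(perm), MixingConfig(seed=7, **FAST)
        )
        means = dict(zip(post.sources, post.draws_p.mean(axis=0)))
        means_perm = dict(zip(post_perm.sources, post_perm.draws_p.mean(axis=0)))
        for s in means:
            assert means_perm[s] == pytest.approx(means[s], abs=0.03)

    def test_parameter_recovery_coverage(self):
        """True proportions fall in the 95% interval for >= 90% of replicates."""
        sig = SCENARIO_DRY.signatures
        true_p = SCENARIO_DRY.true_p
        n_rep, covered = 20, np.zeros(4)
        for rep in range(n_rep):
            samples = generate_isotope_dataset(SCENARIO_DRY, seed=100 + rep)
            post = fit_mixing_model(samples, sig, MixingConfig(seed=rep, **FAST))
            lo = np.quantile(post.draws_p, 0.025, axis=0)
            hi = np.quantile(post.draws_p, 0.975, axis=0)
            covered += (lo <= true_p) & (true_p <= hi)
        assert (covered / n_rep >= 0.9).all()


class TestPosteriorSummary:
    def test_degenerate_posterior_zero_width(self):
        from nitracer.mixing import MixingPosterior

        draws = np.tile([0.3, 0.7], (200, 1))
        post = MixingPosterior(
            ["A", "B"], ["d15n"], draws, np.full((200, 1), 0.5)
        )
        summ = posterior_summary(post)
        row = summ[summ.parameter == "A"].iloc[0]
        assert row["lo"] == row["hi"] == pytest.approx(0.3)

    def test_means_sum_to_one(self, four_source_signatures):
        X = np.random.default_rng(2).normal(10, 4, size=(8, 2))
        post = fit_mixing_model(X, four_source_signatures, MixingConfig(seed=9, **FAST))
        summ = posterior_summary(post)
        assert summ[summ.kind == "source"]["mean"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_quantiles_match_sorted_array_oracle(self, two_source_signatures):
        X = np.random.default_rng(4).normal(4, 2, size=(10, 1))
        post = fit_mixing_model(X, two_source_signatures, MixingConfig(seed=10, **FAST))
        summ = posterior_summary(post, cred_level=0.9)
        d = np.sort(post.draws_p[:, 0])
        row = summ[summ.parameter == "A"].iloc[0]
        assert row["lo"] == pytest.approx(np.quantile(d, 0.05))
        assert row["hi"] == pytest.approx(np.quantile(d, 0.95))

    def test_invalid_cred_level(self, two_source_signatures):
        X = np.full((5, 1), 5.0)
        post = fit_mixing_model(X, two_source_signatures, MixingConfig(seed=1, **FAST))
        with pytest.raises(DomainError):
            posterior_summary(post, cred_level=1.5)
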
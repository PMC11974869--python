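"""Mutual information, Blahut--Arimoto capacity, Gamma fits and KL."""

import numpy as np
import pytest
from scipy import integrate, stats

from nkrsim.info import (Channel, GammaFit, blahut_arimoto, build_channel,
                         entropy_bits, fit_gamma, kl_gamma,
                         mutual_information)


def h2(p):
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


class TestMutualInformation:
    def test_identity_channel_four_inputs(self):
        ch = Channel(inputs=np.arange(4), outputs=np.arange(4),
                     cond=np.eye(4))
        assert mutual_information(ch) == pytest.approx(2.0)

    def test_identical_rows_give_zero(self):
        row = np.array([0.2, 0.5, 0.3])
        ch = Channel(inputs=np.arange(3), outputs=np.arange(3),
                     cond=np.tile(row, (3, 1)))
        assert mutual_information(ch) == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_joint_oracle(self):
        # joint P = [[0.4, 0.1], [0.1, 0.4]]; direct double-sum oracle
        joint = np.array([[0.4, 0.1], [0.1, 0.4]])
        q = joint.sum(axis=1)
        r = joint.sum(axis=0)
        oracle = sum(joint[i, j] * np.log2(joint[i, j] / (q[i] * r[j]))
                     for i in range(2) for j in range(2))
        ch = Channel(inputs=np.arange(2), outputs=np.arange(2),
                     cond=joint / q[:, None], prior=q)
        assert mutual_information(ch, prior=q) == pytest.approx(oracle)

    def test_equals_entropy_difference(self):
        rng = np.random.default_rng(3)
        cond = rng.dirichlet(np.ones(6), size=4)
        ch = Channel(inputs=np.arange(4), outputs=np.arange(6), cond=cond)
        q = np.full(4, 0.25)
        joint = q[:, None] * cond
        r = joint.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            post = np.where(r > 0, joint / r, 0.0)   # P(s|o)
            h_s_given_o = -np.nansum(joint * np.log2(np.where(post > 0, post, 1)))
        assert mutual_information(ch) == pytest.approx(
            entropy_bits(q) - h_s_given_o)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            Channel(inputs=np.arange(2), outputs=np.arange(2),
                    cond=np.array([[0.5, 0.4], [0.5, 0.5]]))


class TestBlahutArimoto:
    def test_binary_symmetric_channel_capacity(self):
        eps = 0.1
        cond = np.array([[1 - eps, eps], [eps, 1 - eps]])
        res = blahut_arimoto(cond)
        assert res.cc == pytest.approx(1 - h2(eps), abs=1e-6)
        assert res.cc == pytest.approx(0.531, abs=0.001)

    def test_noiseless_two_symbol_channel(self):
        res = blahut_arimoto(np.eye(2))
        assert res.cc == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.q_star, [0.5, 0.5], atol=1e-6)

    def test_constant_output_channel_zero_capacity(self):
        cond = np.tile([0.3, 0.7], (3, 1))
        res = blahut_arimoto(cond)
        assert res.cc == pytest.approx(0.0, abs=1e-9)

    def test_objective_monotone_nondecreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            cond = rng.dirichlet(np.ones(8), size=5)
            res = blahut_arimoto(cond, tol=1e-10)
            assert np.all(np.diff(res.objective_trace) >= -1e-12)

    def test_capacity_dominates_uniform_prior_mi(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            cond = rng.dirichlet(np.ones(6), size=4)
            res = blahut_arimoto(cond)
            assert res.cc >= res.mi_uniform - 1e-9

    def test_q_star_is_distribution(self):
        rng = np.random.default_rng(9)
        cond = rng.dirichlet(np.ones(10), size=5)
        res = blahut_arimoto(cond)
        assert res.q_star.sum() == pytest.approx(1.0)
        assert np.all(res.q_star >= 0)


class TestGammaFit:
    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(11)
        x = stats.gamma.rvs(3.0, scale=2.0, size=100_000, random_state=rng)
        fit = fit_gamma(x)
        assert fit.shape == pytest.approx(3.0, rel=0.05)
        assert fit.scale == pytest.approx(2.0, rel=0.05)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma(np.full(100, 4.0))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(12)
        x = stats.gamma.rvs(2.5, scale=1.3, size=20_000, random_state=rng)
        f1, f2 = fit_gamma(x), fit_gamma(3.0 * x)
        assert f2.shape == pytest.approx(f1.shape, rel=1e-6)
        assert f2.scale == pytest.approx(3.0 * f1.scale, rel=1e-6)

    def test_zero_counts_fit_with_recorded_offset(self):
        rng = np.random.default_rng(13)
        x = rng.poisson(2.0, size=500).astype(float)
        fit = fit_gamma(x)
        assert fit.offset == 0.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma([1.0, 2.0, 3.0])


class TestKlGamma:
    def test_identical_fits_zero(self):
        f = GammaFit(shape=2.0, scale=1.5)
        assert kl_gamma(f, f) == 0.0

    def test_matches_numerical_quadrature(self):
        p = GammaFit(shape=2.0, scale=1.0)
        q = GammaFit(shape=3.0, scale=1.0)

        def integrand(x):
            fp = stats.gamma.pdf(x, p.shape, scale=p.scale)
            fq = stats.gamma.pdf(x, q.shape, scale=q.scale)
            return fp * np.log(fp / fq)

        oracle, _ = integrate.quad(integrand, 1e-12, 100)
        assert kl_gamma(p, q, bits=False) == pytest.approx(oracle, rel=1e-6)

    def test_asymmetric(self):
        p = GammaFit(shape=2.0, scale=1.0)
        q = GammaFit(shape=3.0, scale=1.0)
        assert kl_gamma(p, q) != pytest.approx(kl_gamma(q, p))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GammaFit(shape=-1.0, scale=1.0)


class TestBuildChannel:
    def test_disjoint_supports_give_one_bit(self):
        rng = np.random.default_rng(14)
        res = {20: rng.integers(0, 3, 40).astype(float),
               400: rng.integers(50, 60, 40).astype(float)}
        ch = build_channel(res)
        assert mutual_information(ch) == pytest.approx(1.0)

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            build_channel({20: np.ones(40)})

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            build_channel({20: np.ones(5), 400: np.ones(40)})

    def test_gamma_smoothing_close_to_histogram_at_scale(self):
        rng = np.random.default_rng(15)
        res = {20: stats.gamma.rvs(2, scale=2, size=4000, random_state=rng),
               400: stats.gamma.rvs(20, scale=1.5, size=4000,
                                    random_state=rng)}
        mi_h = mutual_information(build_channel(res, method="hist"))
        mi_g = mutual_information(build_channel(res, method="gamma"))
        assert mi_g == pytest.approx(mi_h, abs=0.05)

    def test_replicate_doubling_within_bootstrap_se(self):
        # plug-in MI is stable against doubling the replicate count
        # relative to its own bootstrap uncertainty
        from nkrsim.info import bootstrap_mi_se
        rng = np.random.default_rng(16)
        full = {20: stats.gamma.rvs(2, scale=1.5, size=120, random_state=rng),
                400: stats.gamma.rvs(12, scale=1.5, size=120,
                                     random_state=rng)}
        half = {d: x[:60] for d, x in full.items()}
        mi_full = mutual_information(build_channel(full, method="gamma"))
        mi_half = mutual_information(build_channel(half, method="gamma"))
        se = bootstrap_mi_se(half, n_boot=100, method="gamma", rng=17)
        assert abs(mi_full - mi_half) < 3 * se + 0.02
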
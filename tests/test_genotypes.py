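"""Genotype posteriors: leave-one-out machinery, known-frequency and
inbreeding priors, checked against joint enumeration."""

import itertools
from math import comb

import numpy as np
import pytest

from sfskit.genotypes import (
    InbreedingModel,
    genotype_posterior_known_f,
    genotype_posteriors_sfs,
    genotype_posteriors_sfs_batch,
    leave_one_out_h,
    leave_one_out_saf,
    posterior_af_inbreeding,
    posterior_af_known_f,
)


def joint_genotype_oracle(log_triples, prior, condition=False):
    """Enumeration oracle for the empirical-Bayes genotype posterior:
    sum over all 3^k genotype vectors with hypergeometric configuration
    weights given the sample allele frequency."""
    L = np.exp(log_triples)
    k = L.shape[0]
    post = np.zeros((k, 3))
    for config in itertools.product(range(3), repeat=k):
        j = sum(config)
        if condition and j in (0, 2 * k):
            continue
        w = prior[j] * np.prod([comb(2, g) for g in config]) / comb(2 * k, j)
        term = w * np.prod([L[d, g] for d, g in enumerate(config)])
        for d, g in enumerate(config):
            post[d, g] += term
    return post / post.sum(axis=1, keepdims=True)


def af_oracle(log_triples, priors_per_ind, condition=False):
    """Enumeration oracle for the sample-frequency posterior with
    per-individual genotype priors (labelled individuals, no
    configuration weights)."""
    L = np.exp(log_triples)
    k = L.shape[0]
    out = np.zeros(2 * k + 1)
    for config in itertools.product(range(3), repeat=k):
        j = sum(config)
        out[j] += np.prod(
            [priors_per_ind[d][g] * L[d, g] for d, g in enumerate(config)]
        )
    if condition:
        out[0] = 0.0
        out[-1] = 0.0
    return out / out.sum()


class TestLeaveOneOut:
    def test_completing_with_left_out_individual(self, rng):
        """Convolving h^(-d) with individual d's weighted triple must
        reproduce the full h table (up to overall scale)."""
        lt = np.log(rng.random((4, 3)))
        from sfskit.genotypes import _weighted_lin_triples
        from sfskit.saf import dp_convolve_batch

        wt = _weighted_lin_triples(lt[None])[0]
        # dp_convolve_batch applies the (1,2,1) weights itself
        full, _ = dp_convolve_batch(np.exp(lt)[None])
        full = full[0] / full[0].max()
        loo = leave_one_out_h(lt)
        for d in range(4):
            recon = np.convolve(loo[d], wt[d])
            recon /= recon.max()
            np.testing.assert_allclose(recon, full, rtol=1e-10)

    def test_k2_reduces_to_other_individual(self, rng):
        lt = np.log(rng.random((2, 3)))
        from sfskit.genotypes import _weighted_lin_triples

        wt = _weighted_lin_triples(lt[None])[0]
        loo = leave_one_out_saf(lt, 0)
        np.testing.assert_allclose(loo / loo.max(), wt[1] / wt[1].max(),
                                   rtol=1e-12)

    def test_matches_direct_recomputation(self, rng):
        from sfskit.saf import dp_convolve_batch

        for _ in range(5):
            lt = np.log(rng.random((3, 3)))
            loo = leave_one_out_h(lt)
            for d in range(3):
                rest = np.delete(lt, d, axis=0)
                direct, _ = dp_convolve_batch(np.exp(rest)[None])
                direct = direct[0]
                np.testing.assert_allclose(
                    loo[d] / loo[d].max(), direct / direct.max(), rtol=1e-10
                )

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            leave_one_out_saf(np.zeros((1, 3)), 0)


class TestGenotypePosteriorsSFS:
    def test_k1_prior_weighted_likelihood(self, rng):
        lt = np.log(rng.random((1, 3)))
        prior = rng.dirichlet(np.ones(3))
        post = genotype_posteriors_sfs(lt, prior)[0].probs
        expect = prior * np.exp(lt[0])
        expect /= expect.sum()
        np.testing.assert_allclose(post, expect, rtol=1e-10)

    @pytest.mark.parametrize("condition", [False, True])
    def test_k3_enumeration_oracle(self, rng, condition):
        for _ in range(5):
            lt = np.log(rng.random((3, 3)))
            prior = rng.dirichlet(np.ones(7))
            post = genotype_posteriors_sfs_batch(lt[None], prior, condition)[0]
            expect = joint_genotype_oracle(lt, prior, condition)
            np.testing.assert_allclose(post, expect, rtol=1e-12, atol=1e-15)

    def test_uninformative_individual_follows_others(self, rng):
        """With no reads of its own, an individual's posterior equals the
        other individuals' frequency posterior pushed through the
        hypergeometric genotype-sampling weights."""
        lt = np.log(rng.random((3, 3)))
        lt[0] = 0.0  # individual 0: uniform likelihood
        prior = rng.dirichlet(np.ones(7))
        post = genotype_posteriors_sfs_batch(lt[None], prior)[0][0]
        expect = joint_genotype_oracle(lt, prior)[0]
        np.testing.assert_allclose(post, expect, rtol=1e-12)

    def test_rows_sum_to_one_and_exchangeable(self, rng):
        lt = np.log(rng.random((4, 3)))
        prior = rng.dirichlet(np.ones(9))
        post = genotype_posteriors_sfs_batch(lt[None], prior)[0]
        np.testing.assert_allclose(post.sum(axis=1), 1.0, rtol=1e-12)
        perm = rng.permutation(4)
        post_p = genotype_posteriors_sfs_batch(lt[perm][None], prior)[0]
        np.testing.assert_allclose(post_p, post[perm], rtol=1e-10)

    def test_genotype_marginal_consistent_with_af_posterior(self, rng):
        """Summing the joint (g, j) table over g reproduces the site's
        frequency posterior."""
        from sfskit.posteriors import posterior_sample_af_batch
        from sfskit.saf import saf_from_log_triples

        lt = np.log(rng.random((3, 3)))
        prior = rng.dirichlet(np.ones(7))
        tab = saf_from_log_triples(lt[None])
        af_post = posterior_sample_af_batch(tab, prior)[0]
        # expected genotype dosage from the af posterior equals the mean
        # of the per-individual posterior dosages (both are E[S_m]/2k...)
        geno = genotype_posteriors_sfs_batch(lt[None], prior)[0]
        np.testing.assert_allclose(
            (geno @ np.arange(3)).sum(),
            af_post @ np.arange(7),
            rtol=1e-10,
        )


class TestKnownFrequency:
    def test_uniform_likelihood_returns_hwe_prior(self):
        post = genotype_posterior_known_f(np.ones(3), 0.8)
        np.testing.assert_allclose(post, [0.64, 0.32, 0.04], rtol=1e-12)

    def test_perfect_het(self):
        post = genotype_posterior_known_f(np.array([0.0, 1.0, 0.0]), 0.37)
        np.testing.assert_allclose(post, [0, 1, 0])

    def test_hand_mixed_case(self):
        L = np.array([0.5, 0.3, 0.2])
        f = 0.6
        q = 0.4
        expect = L * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        expect /= expect.sum()
        np.testing.assert_allclose(
            genotype_posterior_known_f(L, f), expect, rtol=1e-12
        )

    def test_af_posterior_uniform_data_is_binomial(self):
        from scipy.stats import binom

        post = posterior_af_known_f(np.zeros((3, 3)), f=0.7)
        np.testing.assert_allclose(
            post, binom.pmf(np.arange(7), 6, 0.3), rtol=1e-10
        )

    def test_af_posterior_conditioned_truncated_binomial(self):
        from scipy.stats import binom

        post = posterior_af_known_f(np.zeros((2, 3)), f=0.7,
                                    condition_on_variable=True)
        expect = binom.pmf(np.arange(5), 4, 0.3)
        expect[0] = expect[-1] = 0
        expect /= expect.sum()
        np.testing.assert_allclose(post, expect, rtol=1e-10)

    @pytest.mark.parametrize("condition", [False, True])
    def test_k2_enumeration_oracle(self, rng, condition):
        lt = np.log(rng.random((2, 3)))
        q = 0.23
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        post = posterior_af_known_f(lt, f=1 - q, condition_on_variable=condition)
        expect = af_oracle(lt, [hwe, hwe], condition)
        np.testing.assert_allclose(post, expect, rtol=1e-10)


class TestInbreeding:
    def test_f_zero_reduces_to_known_f(self, rng):
        for _ in range(5):
            k = int(rng.integers(1, 5))
            lt = np.log(rng.random((k, 3)))
            q = rng.uniform(0.05, 0.95)
            a = posterior_af_known_f(lt, f=1 - q)
            b = posterior_af_inbreeding(
                lt, InbreedingModel(f=q, F=np.zeros(k))
            )
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_full_inbreeding_single_individual(self):
        post = posterior_af_inbreeding(
            np.zeros((1, 3)), InbreedingModel(f=0.3, F=np.ones(1))
        )
        np.testing.assert_allclose(post, [0.7, 0.0, 0.3], atol=1e-14)

    def test_k2_heterogeneous_f_oracle(self, rng):
        lt = np.log(rng.random((2, 3)))
        q = 0.4
        F = np.array([0.5, -0.2])
        model = InbreedingModel(f=q, F=F)
        priors = model.genotype_priors()
        post = posterior_af_inbreeding(lt, model)
        expect = af_oracle(lt, list(priors))
        np.testing.assert_allclose(post, expect, rtol=1e-10)

    def test_priors_rows_normalized(self):
        m = InbreedingModel(f=0.2, F=np.array([-0.1, 0.0, 0.8]))
        np.testing.assert_allclose(m.genotype_priors().sum(axis=1), 1.0,
                                   rtol=1e-12)

    def test_invalid_negative_prior_names_individual(self):
        with pytest.raises(ValueError, match="individual"):
            posterior_af_inbreeding(
                np.zeros((2, 3)), InbreedingModel(f=0.5, F=np.array([0.0, -2.0]))
            )
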
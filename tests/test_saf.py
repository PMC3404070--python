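"""The sample-allele-frequency DP against enumeration and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sfskit.gl import gl_from_base_counts
from sfskit.saf import (
    brute_force_site_af_likelihood,
    fold,
    fold_log,
    fold_saf_table,
    saf_all_pairs,
    saf_from_log_triples,
    saf_unknown_derived,
    site_af_likelihood,
)


def linear(v):
    return v.linear()


class TestSiteAFLikelihood:
    def test_single_het_individual(self):
        v = site_af_likelihood(np.array([[0.2, 0.3, 0.5]]))
        np.testing.assert_allclose(linear(v), [0.2, 0.3, 0.5], rtol=1e-12)

    def test_uniform_triples_flat(self):
        v = site_af_likelihood(np.ones((4, 3)))
        np.testing.assert_allclose(linear(v), np.ones(9), rtol=1e-12)

    def test_hand_enumerated_two_individuals(self):
        v = site_af_likelihood(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 0.0]]))
        np.testing.assert_allclose(
            linear(v), [0.0, 0.5, 2.0 / 3.0, 0.5, 0.0], atol=1e-14
        )

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            site_af_likelihood(np.empty((0, 3)))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            site_af_likelihood(np.array([[np.inf, 1.0, 1.0]]))

    @given(
        triples=arrays(
            float,
            st.tuples(st.integers(1, 4), st.just(3)),
            elements=st.floats(1e-6, 1.0),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, triples):
        a = linear(site_af_likelihood(triples))
        b = linear(brute_force_site_af_likelihood(triples))
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-300)

    def test_brute_force_refuses_large_k(self):
        with pytest.raises(ValueError):
            brute_force_site_af_likelihood(np.ones((9, 3)))

    def test_individual_permutation_invariance(self, rng):
        t = rng.random((5, 3))
        a = linear(site_af_likelihood(t))
        b = linear(site_af_likelihood(t[rng.permutation(5)]))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_per_individual_rescaling_absorbed(self, rng):
        t = rng.random((4, 3))
        c = 7.5
        t2 = t.copy()
        t2[2] *= c
        a = site_af_likelihood(t)
        b = site_af_likelihood(t2)
        np.testing.assert_allclose(linear(b), c * linear(a), rtol=1e-12)

    def test_monomorphic_degeneracy(self):
        t = np.zeros((3, 3))
        t[:, 0] = 1.0
        v = linear(site_af_likelihood(t))
        assert v[0] == pytest.approx(1.0)
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-300)


class TestUnknownDerived:
    def test_single_candidate_pair_dominates(self, rng):
        # only C has likelihood anywhere: the A/C pair carries the signal,
        # the A/G and A/T runs see "hom-ancestral" data
        gl10 = np.full((3, 10), -50.0)
        gl10[:, 0] = 0.0  # AA
        gl10[:, 1] = -0.5  # AC
        gl10[:, 4] = -3.0  # CC
        v = saf_unknown_derived(gl10, "A")
        from sfskit.gl import extract_pair_triples
        triples_ac = extract_pair_triples(gl10, 0, 1)
        direct = site_af_likelihood(np.exp(triples_ac))
        # composition: 1/3 * AC-pair SAF + 2/3 * (monomorphic-shaped)
        other = np.zeros(7)
        mono = np.exp(gl10[:, 0]).prod()
        other[0] = mono
        expect = direct.linear() / 3.0 + 2.0 * other / 3.0
        np.testing.assert_allclose(v.linear(), expect, rtol=1e-10)

    def test_hom_ancestral_mass_at_zero(self):
        depth = 30
        counts = np.zeros((4, 4))
        counts[:, 0] = depth  # every individual: many A reads
        gl10 = gl_from_base_counts(counts, 0.005)
        v = saf_unknown_derived(gl10, "A")
        p = v.linear()
        assert p[0] / p.sum() > 0.999

    def test_weight_convention_scale_invariance(self, rng):
        gl10 = np.log(rng.random((3, 10)))
        v = saf_unknown_derived(gl10, "A")
        v2 = saf_unknown_derived(gl10 + 2.0, "A")  # rescale all likelihoods
        post = np.exp(v.values) / np.exp(v.values).sum()
        post2 = np.exp(v2.values) / np.exp(v2.values).sum()
        np.testing.assert_allclose(post, post2, rtol=1e-10)


class TestAllPairs:
    def test_k1_uniform_is_flat(self):
        combined, _ = saf_all_pairs(np.zeros((1, 10)))
        lin = combined.linear()
        np.testing.assert_allclose(lin, lin[0], rtol=1e-12)

    def test_base_relabeling_symmetry(self, rng):
        from sfskit.gl import GENOTYPE_PAIRS, PAIR_INDEX
        gl10 = np.log(rng.random((2, 10)))
        # swap bases A<->C in the genotype labels
        perm = {0: 1, 1: 0, 2: 2, 3: 3}
        remap = [
            PAIR_INDEX[perm[i], perm[j]] for (i, j) in GENOTYPE_PAIRS
        ]
        gl_sw = gl10[:, remap]
        a, _ = saf_all_pairs(gl10)
        b, _ = saf_all_pairs(gl_sw)
        np.testing.assert_allclose(
            a.values + a.log_scale, b.values + b.log_scale, rtol=1e-10
        )

    def test_matches_pair_enumeration(self, rng):
        """All-pairs sum equals the brute-force sum over ordered pairs."""
        from sfskit.gl import extract_pair_triples
        from sfskit.saf import ORDERED_PAIRS
        gl10 = np.log(rng.random((2, 10)))
        combined, per_pair = saf_all_pairs(gl10)
        expect = np.zeros(5)
        for a, d in ORDERED_PAIRS:
            t = np.exp(extract_pair_triples(gl10, a, d))
            expect += brute_force_site_af_likelihood(t).linear() / 12.0
        np.testing.assert_allclose(combined.linear(), expect, rtol=1e-10)
        assert len(per_pair) == 12


class TestInvalidAncestralFilter:
    def test_flags_sites_without_ancestral_support(self):
        from sfskit.saf import flag_invalid_ancestral

        depth = 25
        counts = np.zeros((2, 3, 4))
        # site 0: C/G segregate, annotated ancestral A absent
        counts[0, 0, 1] = depth
        counts[0, 1, 2] = depth
        counts[0, 2, 1] = counts[0, 2, 2] = depth // 2
        # site 1: ordinary A/C polymorphism
        counts[1, 0, 0] = depth
        counts[1, 1, 1] = depth
        counts[1, 2, 0] = counts[1, 2, 1] = depth // 2
        gl10 = gl_from_base_counts(counts, 0.01)
        flags = flag_invalid_ancestral(gl10, np.zeros(2, dtype=int))
        assert flags.tolist() == [True, False]


class TestFold:
    def test_definition(self):
        np.testing.assert_allclose(
            fold(np.array([0.5, 0.2, 0.1, 0.1, 0.1])), [0.6, 0.3, 0.1]
        )

    def test_palindrome_doubles(self):
        v = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        out = fold(v)
        np.testing.assert_allclose(out[:-1], 2 * v[:2])

    def test_mass_preserved(self, rng):
        v = rng.random(9)
        assert fold(v).sum() == pytest.approx(v.sum())

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            fold(np.ones(4))

    def test_log_fold_matches_linear(self, rng):
        v = rng.random(7)
        np.testing.assert_allclose(np.exp(fold_log(np.log(v))), fold(v), rtol=1e-12)

    def test_fold_saf_table_averages_polarizations(self, rng):
        tab = saf_from_log_triples(np.log(rng.random((10, 2, 3))))
        folded = fold_saf_table(tab)
        lin = np.exp(tab.logvals + tab.log_scale[:, None])
        lin_f = np.exp(folded.logvals + folded.log_scale[:, None])
        expect = np.column_stack(
            [
                (lin[:, 0] + lin[:, 4]) / 2,
                (lin[:, 1] + lin[:, 3]) / 2,
                lin[:, 2],
            ]
        )
        np.testing.assert_allclose(lin_f, expect, rtol=1e-10)
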
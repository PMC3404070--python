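"""Baseline callers and caller-comparison helpers.

The empirical-Bayes machinery lives in :mod:`sfskit.posteriors` and
:mod:`sfskit.genotypes`; this module provides the simpler strategies it is
compared against, plus two closed-form coverage heuristics:

* genotype calling by maximum genotype likelihood (GC-max);
* genotype calling by Hardy-Weinberg posterior at the per-site ML allele
  frequency (the frequency-prior caller);
* a sweepable SNP-call score based on called genotypes (a site scores the
  best log likelihood ratio, over individuals, of a derived-carrying
  genotype against the homozygous-ancestral one — at threshold 0 this is
  "some called genotype carries the derived allele");
* the spectrum implied by hard genotype calls.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .gl import extract_pair_triples
from .posteriors import estimate_maf_ml_batch

__all__ = [
    "prob_het_undercalled",
    "expected_error_fraction",
    "ml_genotype_calls",
    "freqprior_genotype_calls",
    "spectrum_from_calls",
    "snp_score_gc",
]


def prob_het_undercalled(depth: int = 5, min_minor: int = 2) -> float:
    """Probability that a heterozygote with ``depth`` error-free reads is
    called homozygous under the rule "minor allele must be seen at least
    ``min_minor`` times".

    Reads sample the two alleles as Binomial(depth, 1/2); the call is
    homozygous when the rarer allele appears fewer than ``min_minor``
    times.  Computed by enumeration.
    """
    if depth < 1 or min_minor < 1:
        raise ValueError("depth and min_minor must be positive")
    p_hom = 0.0
    for n_alt in range(depth + 1):
        if min(n_alt, depth - n_alt) < min_minor:
            p_hom += binom.pmf(n_alt, depth, 0.5)
    return float(p_hom)


def expected_error_fraction(depth: float = 5.0, error_rate: float = 0.001) -> float:
    """Expected number of error reads per homozygous site at the given
    depth, i.e. the rate at which raw errors masquerade as variants."""
    if depth < 0 or not 0 <= error_rate <= 1:
        raise ValueError("invalid depth or error rate")
    return float(depth * error_rate)


def _triples(gl10: np.ndarray, ancestral, derived) -> np.ndarray:
    return extract_pair_triples(np.asarray(gl10, dtype=float), ancestral, derived)


def ml_genotype_calls(gl10: np.ndarray, ancestral, derived) -> np.ndarray:
    """Maximum-genotype-likelihood calls (GC-max baseline).

    Returns derived-allele counts (S, k); ties (e.g. zero coverage) break
    toward fewer derived copies.
    """
    t = _triples(gl10, ancestral, derived)
    return t.argmax(axis=-1)


def freqprior_genotype_calls(
    gl10: np.ndarray, ancestral, derived
) -> np.ndarray:
    """Genotype calls by highest posterior under a Hardy-Weinberg prior at
    the per-site ML allele frequency (the frequency-prior baseline)."""
    t = _triples(gl10, ancestral, derived)  # (S, k, 3) log
    fhat = estimate_maf_ml_batch(t)  # frequency of the derived allele
    prior = np.stack(
        [(1 - fhat) ** 2, 2 * fhat * (1 - fhat), fhat**2], axis=1
    )  # (S, 3)
    lin = np.exp(t - t.max(axis=2, keepdims=True))
    post = lin * prior[:, None, :]
    return post.argmax(axis=-1)


def spectrum_from_calls(calls: np.ndarray, k: int) -> np.ndarray:
    """Sample spectrum (counts per class 0..2k) implied by hard genotype
    calls of derived-allele counts (S, k)."""
    return np.bincount(calls.sum(axis=1), minlength=2 * k + 1)


def snp_score_gc(gl10: np.ndarray, ancestral, derived) -> np.ndarray:
    """Per-site score for the genotype-calling SNP caller.

    score = max over individuals of max_{g>0} [log L(g) - log L(0)];
    thresholding at 0 reproduces "a called genotype carries the derived
    allele", larger thresholds demand stronger evidence.
    """
    t = _triples(gl10, ancestral, derived)
    return (t[:, :, 1:].max(axis=2) - t[:, :, 0]).max(axis=1)
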
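"""Posterior genotype probabilities per individual.

Three priors are supported for the per-individual genotype posterior at a
variable site:

* the genome-wide estimated SFS, combined with all other individuals' data
  through a leave-one-out sample-allele-frequency likelihood (the
  empirical-Bayes caller);
* a known population allele frequency f under Hardy-Weinberg genotype
  frequencies;
* per-individual inbreeding coefficients F_d deflating (F > 0) or
  inflating (F < 0) heterozygosity relative to Hardy-Weinberg.

The leave-one-out vectors are obtained from prefix/suffix convolutions of
the per-individual weighted triples, never by division, so all k vectors
cost one extra pass over the data and stay numerically stable near zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .saf import W, log_binom

__all__ = [
    "GenotypePosterior",
    "leave_one_out_h",
    "leave_one_out_saf",
    "genotype_posteriors_sfs",
    "genotype_posteriors_sfs_batch",
    "genotype_posterior_known_f",
    "posterior_af_known_f",
    "posterior_af_inbreeding",
    "InbreedingModel",
]


@dataclass
class GenotypePosterior:
    """Posterior over one individual's genotype (0, 1, 2 derived/minor
    copies)."""

    probs: np.ndarray

    @property
    def call(self) -> int:
        return int(np.argmax(self.probs))

    @property
    def call_confidence(self) -> float:
        return float(self.probs[self.call])


def _weighted_lin_triples(log_triples: np.ndarray):
    """Per-individual triples w(g) * L_d(g) on the linear scale, each
    max-normalized (the normalization cancels in every posterior)."""
    log_triples = np.asarray(log_triples, dtype=float)
    m = log_triples.max(axis=-1, keepdims=True)
    if not np.isfinite(m).all():
        raise ValueError("each individual needs one finite log-likelihood")
    return np.exp(log_triples - m) * W


def _prefix_suffix_loo(wt: np.ndarray) -> np.ndarray:
    """All k leave-one-out convolutions of weighted triples.

    Parameters
    ----------
    wt : array (S, k, 3) of linear weighted triples.

    Returns
    -------
    array (S, k, 2k-1): entry [s, d] is the convolution over all
    individuals except d.
    """
    S, k, _ = wt.shape
    if k < 2:
        raise ValueError("leave-one-out undefined for k < 2")
    m = 2 * k - 1  # length of a (k-1)-individual table
    # prefix[d] = conv of individuals < d (length 2d+1, padded)
    prefix = np.zeros((S, k, m))
    suffix = np.zeros((S, k, m))
    cur = np.zeros((S, m))
    cur[:, 0] = 1.0
    for d in range(k):
        prefix[:, d, :] = cur
        if d < k - 1:
            cur = _conv_triple(cur, wt[:, d, :])
    cur = np.zeros((S, m))
    cur[:, 0] = 1.0
    for d in range(k - 1, -1, -1):
        suffix[:, d, :] = cur
        if d > 0:
            cur = _conv_triple(cur, wt[:, d, :])
    out = np.zeros((S, k, m))
    for d in range(k):
        out[:, d, :] = _conv_vec(prefix[:, d, :], suffix[:, d, :], m)
    return out


def _conv_triple(h: np.ndarray, triple: np.ndarray) -> np.ndarray:
    """Convolve (S, m) tables with per-site triples (S, 3), truncated to m."""
    new = h * triple[:, 0, None]
    new[:, 1:] += triple[:, 1, None] * h[:, :-1]
    new[:, 2:] += triple[:, 2, None] * h[:, :-2]
    return new


def _conv_vec(a: np.ndarray, b: np.ndarray, m: int) -> np.ndarray:
    """Full convolution of two (S, m) tables truncated to length m."""
    S = a.shape[0]
    out = np.zeros((S, m))
    # b is sparse in practice (suffix of few individuals) but keep it simple:
    # FFT is overkill at these sizes; direct loop over the shorter support.
    for j in range(m):
        bj = b[:, j]
        if not np.any(bj):
            continue
        out[:, j:] += a[:, : m - j] * bj[:, None]
    return out


def leave_one_out_h(log_triples: np.ndarray) -> np.ndarray:
    """Unnormalized leave-one-out h tables for every individual at one site.

    ``log_triples`` is (k, 3); returns (k, 2k-1) where row d is the
    weighted-triple convolution over all individuals except d (common
    per-site scale factors are dropped; they cancel in posteriors).
    """
    wt = _weighted_lin_triples(np.asarray(log_triples)[None])
    return _prefix_suffix_loo(wt)[0]


def leave_one_out_saf(log_triples: np.ndarray, d: int) -> np.ndarray:
    """Leave-one-out h vector for individual ``d`` (length 2(k-1)+1)."""
    log_triples = np.asarray(log_triples, dtype=float)
    k = log_triples.shape[0]
    if k < 2:
        raise ValueError("leave-one-out undefined for k < 2")
    if not 0 <= d < k:
        raise IndexError(f"individual index {d} out of range")
    return leave_one_out_h(log_triples)[d]


def genotype_posteriors_sfs_batch(
    log_triples: np.ndarray,
    prior: np.ndarray,
    condition_on_variable: bool = False,
) -> np.ndarray:
    """Empirical-Bayes genotype posteriors for all individuals and sites.

    P(G_d = g | X) ∝ sum_j prior_j * w(g) L_d(g) * h^(-d)_{j-g} / C(2k, j),
    with j = 0 and j = 2k zeroed first when conditioning on variability.

    Parameters
    ----------
    log_triples : array (S, k, 3) of log genotype likelihoods
    prior : SFS of length 2k+1

    Returns
    -------
    array (S, k, 3) of genotype posteriors.
    """
    log_triples = np.asarray(log_triples, dtype=float)
    S, k, _ = log_triples.shape
    prior = np.asarray(prior, dtype=float)
    J = 2 * k + 1
    if len(prior) != J:
        raise ValueError("prior length must be 2k+1")
    A = prior / np.exp(log_binom(2 * k, np.arange(J)))
    if condition_on_variable:
        A = A.copy()
        A[0] = 0.0
        A[-1] = 0.0
    wt = _weighted_lin_triples(log_triples)
    if k == 1:
        # no other individuals: posterior ∝ prior_g * w(g) L(g) / C(2, g)
        unnorm = wt * A[:3]
    else:
        hloo = _prefix_suffix_loo(wt)  # (S, k, 2k-1)
        unnorm = np.empty((S, k, 3))
        for g in range(3):
            unnorm[:, :, g] = wt[:, :, g] * (hloo @ A[g : g + 2 * k - 1])
    total = unnorm.sum(axis=2, keepdims=True)
    if np.any(total == 0.0):
        raise ValueError("degenerate site: zero posterior mass for a genotype")
    return unnorm / total


def genotype_posteriors_sfs(
    log_triples: np.ndarray,
    prior: np.ndarray,
    condition_on_variable: bool = False,
) -> list[GenotypePosterior]:
    """Single-site convenience wrapper returning per-individual posteriors."""
    post = genotype_posteriors_sfs_batch(
        np.asarray(log_triples)[None], prior, condition_on_variable
    )[0]
    return [GenotypePosterior(row) for row in post]


def genotype_posterior_known_f(gl_triple: np.ndarray, f: float) -> np.ndarray:
    """Genotype posterior under a known major-allele frequency ``f``.

    The prior is Hardy-Weinberg ordered by minor-allele count:
    (f^2, 2f(1-f), (1-f)^2).  ``gl_triple`` is linear-scale.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    L = np.asarray(gl_triple, dtype=float)
    q = 1.0 - f  # minor-allele frequency
    prior = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    unnorm = L * prior
    total = unnorm.sum()
    if total == 0.0:
        raise ValueError("zero posterior mass")
    return unnorm / total


@dataclass
class InbreedingModel:
    """Per-individual genotype priors with inbreeding coefficients.

    Given minor/derived allele frequency q and coefficient F_d, the
    genotype prior for individual d is

        m_d0 = (1-q)^2 + q(1-q) F_d
        m_d1 = 2 q (1-q) (1 - F_d)
        m_d2 = q^2 + q(1-q) F_d.

    F_d may be negative (heterozygote excess) as long as all m_dg stay
    non-negative.
    """

    f: float  # frequency of the counted (minor/derived) allele
    F: np.ndarray

    def genotype_priors(self) -> np.ndarray:
        q = self.f
        if not 0.0 <= q <= 1.0:
            raise ValueError("allele frequency must be in [0, 1]")
        F = np.asarray(self.F, dtype=float)
        m = np.stack(
            [
                (1 - q) ** 2 + q * (1 - q) * F,
                2 * q * (1 - q) * (1 - F),
                q * q + q * (1 - q) * F,
            ],
            axis=-1,
        )
        bad = np.where(m.min(axis=-1) < 0)[0]
        if bad.size:
            raise ValueError(
                f"invalid inbreeding model: negative genotype prior for "
                f"individual(s) {bad.tolist()} (F too negative for q={q})"
            )
        return m


def _posterior_from_h(h: np.ndarray, condition: bool) -> np.ndarray:
    if condition:
        h = h.copy()
        h[0] = 0.0
        h[-1] = 0.0
    total = h.sum()
    if total == 0.0 or not np.isfinite(total):
        raise ValueError("degenerate site: zero or non-finite posterior mass")
    return h / total


def posterior_af_known_f(
    log_triples: np.ndarray, f: float, condition_on_variable: bool = False
) -> np.ndarray:
    """Posterior over the sample minor-allele count under a binomial prior.

    With known minor frequency q = 1 - f, genotypes are iid Binomial(2, q)
    under HWE, so P(S_m = j | X) ∝ h_j * q^j (1-q)^(2k-j) where h is the
    weighted-triple convolution.  Conditioning on variability restricts to
    j = 1..2k-1.  ``log_triples`` is (k, 3) ordered by minor-allele count.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    log_triples = np.asarray(log_triples, dtype=float)
    k = log_triples.shape[0]
    q = 1.0 - f
    wt = _weighted_lin_triples(log_triples[None])[0]
    h = np.zeros(2 * k + 1)
    h[0] = 1.0
    for d in range(k):
        new = h * wt[d, 0]
        new[1:] += wt[d, 1] * h[:-1]
        new[2:] += wt[d, 2] * h[:-2]
        h = new / max(new.max(), np.finfo(float).tiny)
    j = np.arange(2 * k + 1)
    with np.errstate(divide="ignore"):
        logprior = j * np.log(q) if q > 0 else np.where(j == 0, 0.0, -np.inf)
        logprior = logprior + (
            (2 * k - j) * np.log(1 - q) if q < 1 else np.where(j == 2 * k, 0.0, -np.inf)
        )
    h = h * np.exp(logprior - np.nanmax(logprior[np.isfinite(logprior)]))
    return _posterior_from_h(h, condition_on_variable)


def posterior_af_inbreeding(
    log_triples: np.ndarray,
    model: InbreedingModel,
    condition_on_variable: bool = False,
) -> np.ndarray:
    """Posterior over the sample minor-allele count under per-individual
    inbreeding genotype priors.

    The DP convolves m_dg * L_d(g) (no combinatorial weights: the prior is
    over labelled individuals, not exchangeable configurations).  With
    F_d = 0 for all d this reduces exactly to :func:`posterior_af_known_f`.
    """
    log_triples = np.asarray(log_triples, dtype=float)
    k = log_triples.shape[0]
    m = model.genotype_priors()
    m = np.broadcast_to(m, (k, 3))
    mtrip = np.max(log_triples, axis=1, keepdims=True)
    if not np.isfinite(mtrip).all():
        raise ValueError("each individual needs one finite log-likelihood")
    lin = np.exp(log_triples - mtrip)
    h = np.zeros(2 * k + 1)
    h[0] = 1.0
    for d in range(k):
        t = m[d] * lin[d]
        new = h * t[0]
        new[1:] += t[1] * h[:-1]
        new[2:] += t[2] * h[:-2]
        h = new / max(new.max(), np.finfo(float).tiny)
    return _posterior_from_h(h, condition_on_variable)
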
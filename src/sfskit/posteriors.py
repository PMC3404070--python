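"""Empirical-Bayes per-site inference.

With the genome-wide ML-estimated SFS as prior, the posterior over the
sample allele frequency at a single site is

    P(S = j | X) ∝ p_j * P(X | S = j),

optionally conditioned on the site being variable in the sample by zeroing
the invariant categories (j = 0 and j = 2k; folded: j = 0) before
renormalizing.  A site is called a SNP when the posterior probability of
being invariant falls below a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .saf import SAFTable, SAFVector, fold_likelihood_log

__all__ = [
    "SitePosterior",
    "posterior_sample_af",
    "posterior_sample_af_batch",
    "posterior_sample_af_folded",
    "call_snp",
    "p_not_variable_batch",
    "estimate_maf_ml",
    "MAFEstimate",
]


@dataclass
class SitePosterior:
    """Posterior distribution over the sample allele frequency at one site."""

    probs: np.ndarray
    folded: bool
    conditioned_on_variable: bool = False
    pair: object = None

    @property
    def p_not_variable(self) -> float:
        if self.conditioned_on_variable:
            return 0.0
        if self.folded:
            return float(self.probs[0])
        return float(self.probs[0] + self.probs[-1])

    @property
    def af_mode(self) -> int:
        """Argmax sample frequency, ties broken toward the smaller count."""
        return int(np.argmax(self.probs))

    @property
    def af_mean(self) -> float:
        return float(np.dot(np.arange(len(self.probs)), self.probs))


def _posterior_from_log(logvals: np.ndarray, prior: np.ndarray,
                        condition: bool, folded: bool) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lp = np.log(np.asarray(prior, dtype=float))
    logpost = logvals + lp
    if condition:
        logpost = logpost.copy()
        logpost[..., 0] = -np.inf
        if not folded:
            logpost[..., -1] = -np.inf
    mx = logpost.max(axis=-1, keepdims=True)
    if np.any(~np.isfinite(mx)):
        raise ValueError("degenerate site: zero posterior mass everywhere")
    unnorm = np.exp(logpost - mx)
    return unnorm / unnorm.sum(axis=-1, keepdims=True)


def posterior_sample_af(
    saf: SAFVector, prior: np.ndarray, condition_on_variable: bool = False
) -> SitePosterior:
    """Posterior over the sample allele frequency at one site."""
    prior = np.asarray(prior, dtype=float)
    if len(prior) != len(saf.values):
        raise ValueError("prior length does not match SAF vector")
    probs = _posterior_from_log(
        saf.values, prior, condition_on_variable, saf.folded
    )
    return SitePosterior(probs, saf.folded, condition_on_variable)


def posterior_sample_af_batch(
    saf_table: SAFTable, prior: np.ndarray, condition_on_variable: bool = False
) -> np.ndarray:
    """Posterior matrix (S, J) over sample allele frequencies."""
    prior = np.asarray(prior, dtype=float)
    if len(prior) != saf_table.n_categories:
        raise ValueError("prior length does not match SAF table")
    return _posterior_from_log(
        saf_table.logvals, prior, condition_on_variable, saf_table.folded
    )


def posterior_sample_af_folded(
    saf_pairs: dict, prior: np.ndarray, condition_on_variable: bool = False
) -> SitePosterior:
    """Folded posterior from a per-pair SAF decomposition.

    Sums the per-ordered-pair SAF vectors with equal weights (both
    orientations of each unordered pair enter, which performs the sum over
    foldings), folds to minor-allele counts as a likelihood (each class
    below k averages its two polarizations), and applies the folded prior
    of length k+1.
    """
    prior = np.asarray(prior, dtype=float)
    vecs = list(saf_pairs.values())
    k = vecs[0].k
    if len(prior) != k + 1:
        raise ValueError("folded prior must have length k+1")
    full = np.full(2 * k + 1, -np.inf)
    for v in vecs:
        full = np.logaddexp(full, v.values + v.log_scale)
    full -= np.log(len(vecs))
    folded_log = fold_likelihood_log(full)
    probs = _posterior_from_log(
        folded_log - folded_log.max(), prior, condition_on_variable, True
    )
    return SitePosterior(probs, True, condition_on_variable, pair="summed over pairs")


def p_not_variable_batch(
    saf_table: SAFTable, prior: np.ndarray
) -> np.ndarray:
    """Per-site posterior probability that the site is invariant in the
    sample (the SNP-calling statistic)."""
    post = posterior_sample_af_batch(saf_table, prior, False)
    if saf_table.folded:
        return post[:, 0]
    return post[:, 0] + post[:, -1]


def call_snp(posterior: SitePosterior, cutoff: float = 0.05) -> dict:
    """SNP call from an unconditioned site posterior.

    Returns ``{"is_snp": bool, "p_not_variable": float}``; the site is a
    SNP when P(invariant | X) < cutoff.  Conditioned posteriors are
    rejected (calling on them would be circular).
    """
    if posterior.conditioned_on_variable:
        raise ValueError("SNP calling on a variability-conditioned posterior")
    p0 = posterior.p_not_variable
    return {"is_snp": bool(p0 < cutoff), "p_not_variable": p0}


@dataclass
class MAFEstimate:
    """ML estimate of the population frequency of the counted allele."""

    f: float
    loglik: float
    identifiable: bool = True
    n_iter: int = 0


def estimate_maf_ml(
    gl_triples: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> MAFEstimate:
    """Per-site ML population allele frequency from genotype likelihoods.

    Maximizes  prod_d sum_g Binom(g; 2, f) L_d(g)  over f in [0, 1] by the
    EM update f <- (mean posterior genotype dosage) / 2.  ``gl_triples`` is
    a (k, 3) array of *linear* likelihoods for g = 0, 1, 2 copies of the
    counted allele.  A flat table (all triples constant) is flagged
    non-identifiable and returns f = 0.5 by convention.

    The likelihood in f need not be unimodal (it is a product of
    quadratics, and both boundaries can be local maxima), so the EM
    recursion is run from several starts and the boundary values are
    checked explicitly.
    """
    L = np.asarray(gl_triples, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("gl_triples must have shape (k, 3)")
    if L.shape[0] < 1:
        raise ValueError("need k >= 1")
    if np.all(np.ptp(L, axis=1) < 1e-14 * np.maximum(L.max(axis=1), 1.0)):
        return MAFEstimate(0.5, _maf_loglik(L, 0.5), identifiable=False)
    best = MAFEstimate(0.0, _maf_loglik(L, 0.0))
    ll1 = _maf_loglik(L, 1.0)
    if ll1 > best.loglik:
        best = MAFEstimate(1.0, ll1)
    for f in (0.1, 0.3, 0.5, 0.7, 0.9):
        it = 0
        for it in range(1, max_iter + 1):
            w = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
            post = L * w
            total = post.sum(axis=1, keepdims=True)
            if np.any(total == 0.0):
                break
            post = post / total
            new_f = float((post * np.array([0.0, 0.5, 1.0])).sum() / L.shape[0])
            if abs(new_f - f) <= tol:
                f = new_f
                break
            f = new_f
        ll = _maf_loglik(L, f)
        if ll > best.loglik:
            best = MAFEstimate(f, ll, n_iter=it)
    return best


def estimate_maf_ml_batch(
    gl_log_triples: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Vectorized per-site ML allele frequency.

    ``gl_log_triples`` has shape (S, k, 3) in log space; returns f of
    shape (S,).

    Single interior start per site plus an explicit boundary comparison
    (the per-site likelihood can have maxima at both boundaries).
    """
    logL = np.asarray(gl_log_triples, dtype=float)
    L = np.exp(logL - logL.max(axis=2, keepdims=True))
    S, k, _ = L.shape
    f = np.full(S, 0.25)
    dose = np.array([0.0, 0.5, 1.0])
    for _ in range(max_iter):
        w = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f * f], axis=1)
        post = L * w[:, None, :]
        total = post.sum(axis=2, keepdims=True)
        post = np.divide(post, total, out=post, where=total > 0)
        new_f = (post @ dose).mean(axis=1)
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta <= tol:
            break

    def _ll(fv):
        w = np.stack([(1 - fv) ** 2, 2 * fv * (1 - fv), fv * fv], axis=1)
        with np.errstate(divide="ignore"):
            return np.log(np.einsum("skg,sg->sk", L, w)).sum(axis=1)

    cand = np.column_stack([f, np.zeros(S), np.ones(S)])
    lls = np.column_stack([_ll(cand[:, i]) for i in range(3)])
    return cand[np.arange(S), np.nanargmax(lls, axis=1)]


def _maf_loglik(L: np.ndarray, f: float) -> float:
    w = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
    per = L @ w
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(per)))
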
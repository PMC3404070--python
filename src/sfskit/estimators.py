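"""Scikit-learn style estimator interfaces.

These wrap the functional core so the SFS fit and the two empirical-Bayes
callers compose with sklearn pipelines and model selection:

* :class:`SFSEstimator` — fit a site-frequency spectrum to a SAF table;
* :class:`SNPCaller` — fit the SFS prior, then flag variable sites;
* :class:`GenotypeCaller` — fit the SFS prior, then call genotypes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .genotypes import genotype_posteriors_sfs_batch
from .posteriors import p_not_variable_batch
from .saf import SAFTable, fold_saf_table, saf_from_log_triples
from .sfs import estimate_sfs_em, estimate_sfs_ml, sfs_log_likelihood

__all__ = ["SFSEstimator", "SNPCaller", "GenotypeCaller"]


def _as_saf_table(X, folded: bool) -> SAFTable:
    if isinstance(X, SAFTable):
        table = X
    else:
        table = saf_from_log_triples(np.asarray(X))
    if folded and not table.folded:
        table = fold_saf_table(table)
    if not folded and table.folded:
        raise ValueError("cannot unfold a folded SAF table")
    return table


class SFSEstimator(BaseEstimator):
    """Maximum-likelihood site-frequency-spectrum estimator.

    Parameters
    ----------
    method : "bfgs" (analytical-gradient quasi-Newton) or "em"
    folded : estimate over minor-allele counts (k+1 classes)
    start : optional initial spectrum; defaults to uniform
    max_iter, tol : convergence controls (tol is relative log-likelihood
        change for EM and per-site gradient norm for BFGS)

    Fitted attributes: ``sfs_`` (probability vector), ``loglik_``,
    ``n_iter_``, ``converged_``, ``k_``, ``result_``.

    ``X`` may be a :class:`~sfskit.saf.SAFTable` or an (S, k, 3) array of
    log genotype-likelihood triples.
    """

    def __init__(self, method="bfgs", folded=False, start=None,
                 max_iter=1000, tol=1e-8):
        self.method = method
        self.folded = folded
        self.start = start
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        table = _as_saf_table(X, self.folded)
        if self.method == "bfgs":
            res = estimate_sfs_ml(table, start=self.start,
                                  max_iter=self.max_iter, tol=self.tol)
        elif self.method == "em":
            res = estimate_sfs_em(table, start=self.start,
                                  max_iter=self.max_iter,
                                  tol=min(self.tol, 1e-8))
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.result_ = res
        self.sfs_ = res.probs
        self.loglik_ = res.loglik
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.k_ = res.k
        return self

    def score(self, X, y=None) -> float:
        """Total log-likelihood of ``X`` under the fitted spectrum."""
        return sfs_log_likelihood(_as_saf_table(X, self.folded), self.sfs_)


class SNPCaller(BaseEstimator):
    """Empirical-Bayes SNP caller.

    ``fit`` estimates the SFS prior from a SAF table; ``predict`` flags
    sites whose posterior probability of being invariant in the sample is
    below ``cutoff``.  ``predict_proba`` returns columns
    (P(invariant), P(variable)).
    """

    def __init__(self, cutoff=0.05, folded=False, method="bfgs", prior=None):
        self.cutoff = cutoff
        self.folded = folded
        self.method = method
        self.prior = prior  # optional externally estimated SFS

    def fit(self, X, y=None):
        if self.prior is not None:
            self.prior_ = np.asarray(self.prior, dtype=float)
        else:
            est = SFSEstimator(method=self.method, folded=self.folded).fit(X)
            self.prior_ = est.sfs_
            self.sfs_estimator_ = est
        return self

    def predict_proba(self, X) -> np.ndarray:
        table = _as_saf_table(X, self.folded)
        p0 = p_not_variable_batch(table, self.prior_)
        return np.column_stack([p0, 1.0 - p0])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 0] < self.cutoff


class GenotypeCaller(BaseEstimator):
    """Empirical-Bayes genotype caller with the SFS as joint prior.

    ``X`` is an (S, k, 3) array of log genotype-likelihood triples
    (derived-allele counts).  ``fit`` estimates the unfolded SFS prior
    from the same likelihoods; ``predict_proba`` returns (S, k, 3)
    posteriors, ``predict`` the argmax calls with genotypes below
    ``min_confidence`` masked to -1.
    """

    def __init__(self, condition_on_variable=False, min_confidence=None,
                 method="bfgs", prior=None):
        self.condition_on_variable = condition_on_variable
        self.min_confidence = min_confidence
        self.method = method
        self.prior = prior

    def fit(self, X, y=None):
        if self.prior is not None:
            self.prior_ = np.asarray(self.prior, dtype=float)
        else:
            est = SFSEstimator(method=self.method, folded=False).fit(X)
            self.prior_ = est.sfs_
            self.sfs_estimator_ = est
        return self

    def predict_proba(self, X) -> np.ndarray:
        return genotype_posteriors_sfs_batch(
            np.asarray(X), self.prior_, self.condition_on_variable
        )

    def predict(self, X) -> np.ndarray:
        post = self.predict_proba(X)
        calls = post.argmax(axis=2)
        if self.min_confidence is not None:
            conf = np.take_along_axis(post, calls[:, :, None], axis=2)[:, :, 0]
            calls = np.where(conf >= self.min_confidence, calls, -1)
        return calls
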
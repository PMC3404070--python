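"""Maximum-likelihood estimation of the site frequency spectrum.

The SFS is a probability vector P = (p_0 .. p_2k) on the simplex (folded:
p*_0 .. p*_k over minor-allele counts).  Assuming independent sites, the
log-likelihood given a table of per-site sample-allele-frequency (SAF)
likelihood vectors is

    l(P) = sum_v log sum_j p_j * P(X_v | S = j).

Two optimizers are provided:

* BFGS on an unconstrained softmax reparameterization with the analytical
  gradient dl/dtheta_i = sum_v (posterior_v(i) - p_i);
* an EM fixed-point iteration p_j <- mean_v posterior_v(j), used as an
  independent cross-check (its log-likelihood is monotone non-decreasing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .saf import SAFTable

PROB_FLOOR = 1e-15


@dataclass
class SFSResult:
    """An estimated spectrum with its convergence report."""

    probs: np.ndarray
    folded: bool
    k: int
    loglik: float
    n_iter: int
    converged: bool
    method: str
    identifiable: bool = True

    @property
    def prop_variable(self) -> float:
        """Estimated proportion of sites variable in the sample:
        1 - p_0 (- p_2k if unfolded)."""
        if self.folded:
            return float(1.0 - self.probs[0])
        return float(1.0 - self.probs[0] - self.probs[-1])


def _check_table(saf_table: SAFTable, probs: np.ndarray) -> None:
    if len(probs) != saf_table.n_categories:
        raise ValueError(
            f"SFS length {len(probs)} != SAF categories {saf_table.n_categories}"
        )


def sfs_log_likelihood(saf_table: SAFTable, probs: np.ndarray) -> float:
    """Total log-likelihood of an SFS given a SAF table."""
    probs = np.asarray(probs, dtype=float)
    _check_table(saf_table, probs)
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    per_site = logsumexp(saf_table.logvals + lp, axis=1) + saf_table.log_scale
    return float(per_site.sum())


def site_af_posteriors(saf_table: SAFTable, probs: np.ndarray) -> np.ndarray:
    """Per-site posterior P(S = j | X_v) matrix (S, J) under prior ``probs``."""
    probs = np.asarray(probs, dtype=float)
    _check_table(saf_table, probs)
    unnorm = np.exp(
        saf_table.logvals
        - saf_table.logvals.max(axis=1, keepdims=True)
    ) * probs
    total = unnorm.sum(axis=1, keepdims=True)
    if np.any(total == 0.0):
        raise ValueError("site with zero posterior mass under this SFS")
    return unnorm / total


def theta_to_sfs(theta: np.ndarray) -> np.ndarray:
    """Softmax transform anchored at p_0: theta in R^(J-1) -> simplex point
    of length J."""
    theta = np.asarray(theta, dtype=float)
    z = np.concatenate([[0.0], theta])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def sfs_to_theta(probs: np.ndarray) -> np.ndarray:
    """Inverse transform theta_i = log(p_i / p_0).  Zero probabilities are
    floored at 1e-15 with a warning (the transform needs the open simplex)."""
    probs = np.asarray(probs, dtype=float)
    if np.any(probs <= 0.0):
        warnings.warn(
            "flooring zero/negative probabilities at 1e-15 for the "
            "unconstrained transform",
            RuntimeWarning,
            stacklevel=2,
        )
        probs = np.maximum(probs, PROB_FLOOR)
    return np.log(probs[1:]) - np.log(probs[0])


def sfs_gradient(saf_table: SAFTable, theta: np.ndarray) -> np.ndarray:
    """Analytical gradient of the log-likelihood in theta coordinates:
    dl/dtheta_i = sum_v (posterior_v(i) - p_i), i = 1..J-1."""
    probs = theta_to_sfs(theta)
    post = site_af_posteriors(saf_table, probs)
    g = post.sum(axis=0) - saf_table.n_sites * probs
    return g[1:]


def _growth_rates(saf_table: SAFTable, probs: np.ndarray) -> np.ndarray:
    """Simplex KKT statistic G_j = sum_v a_vj / L_v.

    At the maximum, classes with positive mass have G_j = S and classes at
    zero have G_j <= S; a class with G_j > S can profitably regain mass
    (the EM update is p_j <- p_j G_j / S).
    """
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    logL = logsumexp(saf_table.logvals + lp, axis=1)
    return np.exp(logsumexp(saf_table.logvals - logL[:, None], axis=0))


def _newton_polish(
    saf_table: SAFTable, theta: np.ndarray, max_iter: int = 100,
    tol: float = 1e-12,
) -> np.ndarray:
    """Damped Newton refinement in theta coordinates.

    The log-likelihood is concave in P, but near-collinear SAF columns
    create flat ridges where first-order methods stall with a tiny
    gradient far from the optimum; the analytic Hessian

        H_mn = delta_mn (R_m - S p_m) - sum_v r_vm r_vn + S p_m p_n,

    with r the per-site posteriors and R their column sums, makes those
    ridges cheap to traverse (J is small).  Levenberg damping guarantees
    ascent; stops when the gain is below ``tol`` relative.
    """
    S = saf_table.n_sites
    ll = sfs_log_likelihood(saf_table, theta_to_sfs(theta))
    for _ in range(max_iter):
        p = theta_to_sfs(theta)
        r = site_af_posteriors(saf_table, p)
        R = r.sum(axis=0)
        H = -(r.T @ r) + S * np.outer(p, p)
        H[np.diag_indices_from(H)] += R - S * p
        g = (R - S * p)[1:]
        H = H[1:, 1:]
        lam = 1e-10 * max(1.0, float(np.trace(-H)) / len(g))
        improved = False
        for _ in range(40):
            try:
                step = np.linalg.solve(-H + lam * np.eye(len(g)), g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta + step
            with np.errstate(over="ignore"):
                cand_ll = sfs_log_likelihood(saf_table, theta_to_sfs(cand))
            if np.isfinite(cand_ll) and cand_ll >= ll:
                improved = cand_ll > ll + tol * (abs(ll) + 1.0)
                theta, new_ll = cand, cand_ll
                break
            lam *= 10.0
        else:
            break
        if not improved:
            ll = new_ll
            break
        ll = new_ll
    return theta


def estimate_sfs_ml(
    saf_table: SAFTable,
    start: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> SFSResult:
    """BFGS maximum-likelihood fit of the SFS with the analytical gradient.

    Starts from the uniform spectrum unless ``start`` is given.  Returns the
    estimate with a convergence flag; non-convergence is reported, not
    raised.  A table whose sites are all uninformative (flat SAF) is flagged
    non-identifiable.
    """
    J = saf_table.n_categories
    if saf_table.n_sites < 1:
        raise ValueError("need at least one site")
    flat = np.all(
        np.ptp(saf_table.logvals, axis=1) < 1e-12
    )
    if start is None:
        start = np.full(J, 1.0 / J)
    theta0 = sfs_to_theta(np.asarray(start, dtype=float))

    def neg_ll(theta):
        return -sfs_log_likelihood(saf_table, theta_to_sfs(theta))

    def neg_grad(theta):
        return -sfs_gradient(saf_table, theta)

    # gtol is on the total-gradient infinity norm, which scales with the
    # number of sites; keep the per-site criterion at ``tol``
    S = saf_table.n_sites
    gtol = tol * max(1.0, S)
    res = None
    for _ in range(8):
        res = minimize(
            neg_ll,
            theta0,
            jac=neg_grad,
            method="BFGS",
            options={"maxiter": max_iter, "gtol": gtol},
        )
        # BFGS line searches lose precision near a simplex boundary
        # (theta -> -inf); restart with a fresh Hessian
        for _ in range(3):
            if res.success or np.max(np.abs(res.jac)) <= gtol:
                break
            prev = res.fun
            res = minimize(
                neg_ll,
                res.x,
                jac=neg_grad,
                method="BFGS",
                options={"maxiter": max_iter, "gtol": gtol},
            )
            if res.fun >= prev - 1e-12 * (abs(prev) + 1.0):
                break
        theta = _newton_polish(saf_table, res.x)
        probs = theta_to_sfs(theta)
        # softmax loses first-order information for a class whose mass has
        # collapsed; the simplex KKT condition detects classes that should
        # regain mass, which are bumped back into the interior
        growth = _growth_rates(saf_table, probs)
        bump = (growth > S * (1.0 + 1e-10)) & (probs < 1e-6)
        if not np.any(bump):
            break
        probs = np.where(bump, np.maximum(probs * 10.0, 1e-4 / len(probs)),
                         probs)
        probs /= probs.sum()
        theta0 = sfs_to_theta(probs)
    final_ll = sfs_log_likelihood(saf_table, probs)
    return SFSResult(
        probs=probs,
        folded=saf_table.folded,
        k=saf_table.k,
        loglik=final_ll,
        n_iter=int(res.nit),
        converged=bool(res.success)
        or float(np.max(np.abs(res.jac))) < 100 * gtol,
        method="bfgs",
        identifiable=not flat,
    )


def em_step(saf_table: SAFTable, probs: np.ndarray) -> np.ndarray:
    """One EM update p_j <- mean over sites of posterior_v(j)."""
    return site_af_posteriors(saf_table, probs).mean(axis=0)


def estimate_sfs_em(
    saf_table: SAFTable,
    start: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-10,
    accelerate: bool = True,
) -> SFSResult:
    """EM fixed-point estimate: p_j <- mean over sites of posterior_v(j).

    The accepted log-likelihood sequence is monotone non-decreasing; the
    loop stops when its relative change falls below ``tol``.  With
    ``accelerate`` the squared-extrapolation (SQUAREM-style) step is tried
    each iteration and kept only when it does not decrease the likelihood,
    which greatly speeds convergence along flat ridges while preserving
    monotonicity; ``accelerate=False`` gives the plain EM recursion.
    """
    J = saf_table.n_categories
    if saf_table.n_sites < 1:
        raise ValueError("need at least one site")
    probs = (
        np.full(J, 1.0 / J) if start is None else np.asarray(start, dtype=float)
    )
    ll = sfs_log_likelihood(saf_table, probs)
    converged = False
    it = 0
    rounds = 0
    while it < max_iter:
        it += 1
        p1 = em_step(saf_table, probs)
        if accelerate:
            p2 = em_step(saf_table, p1)
            r = p1 - probs
            v = p2 - p1 - r
            vnorm = float(np.linalg.norm(v))
            cand = p2
            if vnorm > 0:
                alpha = -float(np.linalg.norm(r)) / vnorm
                extrap = probs - 2.0 * alpha * r + alpha * alpha * v
                extrap = np.maximum(extrap, 0.0)
                s = extrap.sum()
                if s > 0:
                    extrap = em_step(saf_table, extrap / s)
                    if sfs_log_likelihood(saf_table, extrap) >= sfs_log_likelihood(
                        saf_table, p2
                    ):
                        cand = extrap
            probs = cand
        else:
            probs = p1
        new_ll = sfs_log_likelihood(saf_table, probs)
        if abs(new_ll - ll) <= tol * (abs(ll) + 1.0):
            ll = new_ll
            # multiplicative updates cannot revive a collapsed class; the
            # simplex KKT statistic flags classes that should regain mass
            growth = _growth_rates(saf_table, probs)
            bump = (growth > saf_table.n_sites * (1.0 + 1e-10)) & (
                probs < 1e-6
            )
            if np.any(bump) and rounds < 6:
                rounds += 1
                probs = np.where(
                    bump, np.maximum(probs * 10.0, 1e-4 / J), probs
                )
                probs /= probs.sum()
                ll = sfs_log_likelihood(saf_table, probs)
                continue
            converged = True
            break
        ll = new_ll
    flat = np.all(np.ptp(saf_table.logvals, axis=1) < 1e-12)
    return SFSResult(
        probs=probs,
        folded=saf_table.folded,
        k=saf_table.k,
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        method="em",
        identifiable=not flat,
    )
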
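"""Classical summaries of the site frequency spectrum.

All three statistics take the vector eta of counts (or expected counts)
per derived-allele frequency class 1..n-1, where n = 2k is the number of
sampled chromosomes.  The Tajima's D variance constants assume integer
segregating-site counts; with expected counts the value is the plug-in
approximation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["watterson_theta", "nucleotide_diversity", "tajimas_d", "sfs_to_eta"]


def _check_eta(eta) -> tuple[np.ndarray, int]:
    eta = np.asarray(eta, dtype=float)
    if eta.ndim != 1 or len(eta) < 1:
        raise ValueError("eta must be a 1-D vector of classes 1..n-1")
    if np.any(eta < 0):
        raise ValueError("eta counts must be non-negative")
    n = len(eta) + 1
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    return eta, n


def sfs_to_eta(probs: np.ndarray, n_sites: float) -> np.ndarray:
    """Expected counts per variable class from a full spectrum
    (p_0..p_2k) and a number of sites."""
    probs = np.asarray(probs, dtype=float)
    return probs[1:-1] * n_sites


def watterson_theta(eta) -> float:
    """Watterson's estimator: S / a_n with a_n = sum_{i<n} 1/i."""
    eta, n = _check_eta(eta)
    a_n = np.sum(1.0 / np.arange(1, n))
    return float(eta.sum() / a_n)


def nucleotide_diversity(eta) -> float:
    """Average pairwise diversity pi = sum_i i (n-i) eta_i / C(n, 2)."""
    eta, n = _check_eta(eta)
    i = np.arange(1, n)
    return float(np.sum(i * (n - i) * eta) / (n * (n - 1) / 2.0))


def tajimas_d(eta) -> float:
    """Tajima's D = (pi - theta_W) / sqrt(e1 S + e2 S (S-1)).

    Raises for n < 4; returns NaN (flagged undefined) when there are no
    segregating sites.
    """
    eta, n = _check_eta(eta)
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 chromosomes")
    S = float(eta.sum())
    if S <= 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    num = nucleotide_diversity(eta) - watterson_theta(eta)
    return float(num / np.sqrt(e1 * S + e2 * S * (S - 1)))
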
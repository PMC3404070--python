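"""Genotype likelihoods from per-read base observations.

A diploid genotype is an unordered pair of bases.  With a symmetric error
model, a read carrying base ``b`` has per-allele likelihoods
``L(b) = 1 - e`` for the observed base and ``e/3`` for each of the other
three.  The genotype likelihood is the product over reads of the mean of
the two allelic likelihoods,

    P(X | G = {b1, b2}) = prod_i [ L_i(b1)/2 + L_i(b2)/2 ],

accumulated in natural-log space.  A site/individual with zero reads gets
a uniform (all-equal) 10-vector so the number of individuals stays fixed
across sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the 10 unordered diploid genotypes in fixed lexicographic order
GENOTYPE_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (0, 3),
    (1, 1), (1, 2), (1, 3),
    (2, 2), (2, 3),
    (3, 3),
)
GENOTYPE_LABELS = tuple(BASES[i] + BASES[j] for i, j in GENOTYPE_PAIRS)

#: PAIR_INDEX[i, j] -> position of unordered pair {i, j} in GENOTYPE_PAIRS
PAIR_INDEX = np.empty((4, 4), dtype=np.intp)
for _g, (_i, _j) in enumerate(GENOTYPE_PAIRS):
    PAIR_INDEX[_i, _j] = _g
    PAIR_INDEX[_j, _i] = _g

#: maximum admissible per-read error rate; at 0.75 a read is uninformative
MAX_ERROR = 0.75


@dataclass(frozen=True)
class ReadObservation:
    """A single sequenced base with its post-calibration error probability."""

    base: str
    error_rate: float

    def __post_init__(self) -> None:
        if self.base not in BASE_INDEX:
            raise ValueError(f"base {self.base!r} not in alphabet {BASES}")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 1]")


def phred_to_error(q) -> np.ndarray | float:
    """Convert phred-scaled quality to an error probability, capped at 0.75.

    The cap reflects that an error cannot be worse than a uniformly random
    base among four.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("phred quality must be non-negative")
    e = np.minimum(10.0 ** (-q / 10.0), MAX_ERROR)
    return float(e) if e.ndim == 0 else e


def allele_likelihoods(read: ReadObservation) -> np.ndarray:
    """Per-allele likelihoods L(b) for one read: 1-e for the observed base,
    e/3 for each other base.  Sums to 1."""
    e = read.error_rate
    out = np.full(4, e / 3.0)
    out[BASE_INDEX[read.base]] = 1.0 - e
    return out


def genotype_log_likelihoods(reads: Iterable[ReadObservation]) -> np.ndarray:
    """Natural-log likelihoods of the 10 unordered genotypes given reads.

    An empty read list yields the uniform statement log 1 = 0 for every
    genotype.
    """
    out = np.zeros(10)
    for read in reads:
        L = allele_likelihoods(read)
        with np.errstate(divide="ignore"):
            for g, (i, j) in enumerate(GENOTYPE_PAIRS):
                out[g] += np.log(0.5 * L[i] + 0.5 * L[j])
    return out


def genotype_likelihoods(reads: Iterable[ReadObservation]) -> np.ndarray:
    """Linear-scale counterpart of :func:`genotype_log_likelihoods`."""
    return np.exp(genotype_log_likelihoods(reads))


def gl_from_base_counts(counts: np.ndarray, error_rate: float) -> np.ndarray:
    """Vectorized genotype log-likelihoods from per-base read counts.

    With a flat error rate reads are exchangeable, so the sufficient
    statistic per individual-site is the 4-vector of observed base counts.

    Parameters
    ----------
    counts : array of shape (..., 4)
        Observed read counts per base (A, C, G, T order).
    error_rate : float
        Symmetric per-read error probability.

    Returns
    -------
    array of shape (..., 10) of natural-log genotype likelihoods.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] != 4:
        raise ValueError("counts must have trailing dimension 4")
    e = float(error_rate)
    if not 0.0 <= e <= MAX_ERROR:
        raise ValueError(f"error_rate {e} outside [0, {MAX_ERROR}]")
    # per observed base b, the read-level mixture L(b1)/2 + L(b2)/2 takes one
    # of three values depending on how many genotype alleles match b
    with np.errstate(divide="ignore"):
        log_mix = np.log(
            [e / 3.0, 0.5 * (1.0 - e) + 0.5 * e / 3.0, 1.0 - e]
        )  # 0, 1, 2 matching alleles
    M = np.empty((10, 4))
    for g, (i, j) in enumerate(GENOTYPE_PAIRS):
        n_match = (np.arange(4) == i).astype(int) + (np.arange(4) == j).astype(int)
        M[g] = log_mix[n_match]
    # counts @ M.T, with 0 * (-inf) treated as 0 (no reads of that base)
    out = np.einsum("...b,gb->...g", counts, np.where(np.isfinite(M), M, 0.0))
    if not np.isfinite(M).all():
        bad = counts @ (~np.isfinite(M)).astype(float).T  # counts hitting -inf
        out = np.where(bad > 0, -np.inf, out)
    return out


def extract_pair_triples(gl10: np.ndarray, ancestral, derived) -> np.ndarray:
    """Slice 10-genotype log-likelihoods down to the (aa, aD, DD) triple.

    ``g`` counts copies of the derived allele.  ``ancestral``/``derived``
    are base indices (scalars or arrays broadcastable over the leading axes
    of ``gl10``).

    Parameters
    ----------
    gl10 : array (..., 10)
    ancestral, derived : int or array of int

    Returns
    -------
    array (..., 3) of log-likelihoods for 0, 1, 2 derived copies.
    """
    gl10 = np.asarray(gl10)
    a = np.asarray(ancestral, dtype=np.intp)
    d = np.asarray(derived, dtype=np.intp)
    idx = np.stack(
        [PAIR_INDEX[a, a], PAIR_INDEX[a, d], PAIR_INDEX[d, d]], axis=-1
    )
    if idx.ndim == 1:  # scalar pair
        return gl10[..., idx]
    # per-site pair: idx has shape (S, 3), gl10 (S, k, 10)
    return np.take_along_axis(
        gl10, idx[:, None, :] if gl10.ndim == 3 else idx, axis=-1
    )
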
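"""Per-site likelihoods of the sample allele frequency (the h_j table).

For k diploid individuals and a fixed ancestral/derived allele pair, the
likelihood of the read data at a site given that the sample carries
j derived alleles is

    P(X | S_A = j) = sum over genotype vectors (g_1..g_k), sum g_d = j, of
                     prod_d P(X_d | G_d = g_d) * prod_d C(2, g_d) / C(2k, j),

i.e. the genotype likelihoods weighted by the hypergeometric probability of
the labelled genotype configuration given j derived alleles under
Hardy-Weinberg sampling.  The sum is computed by dynamic programming: the
unnormalized table h is the sequential convolution of the per-individual
weighted triples (w(g) * L_d(g), w = (1, 2, 1)), followed by terminal
division by C(2k, j).  Cost O(k^2) per site.

Vectors are stored in log space; per-site values are normalized to max 0
with the residual kept in ``log_scale`` so the unscaled likelihoods are
``exp(logvals + log_scale)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.special import gammaln

from .gl import BASES, GENOTYPE_PAIRS, extract_pair_triples

#: combinatorial genotype weights C(2, g)
W = np.array([1.0, 2.0, 1.0])

#: ordered ancestral/derived base-index pairs (12 of them)
ORDERED_PAIRS = tuple(
    (a, d) for a in range(4) for d in range(4) if a != d
)


def log_binom(n: int, j) -> np.ndarray:
    """log C(n, j), vectorized over j."""
    j = np.asarray(j, dtype=float)
    return gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)


@dataclass
class SAFVector:
    """Scaled log-likelihoods of the data at one site given each possible
    sample allele frequency j = 0..2k (unfolded) or minor count 0..k
    (folded)."""

    values: np.ndarray  # log-scale, per-site max normalized to 0
    log_scale: float
    k: int
    folded: bool = False
    site_id: object = None

    def __post_init__(self) -> None:
        n = self.k + 1 if self.folded else 2 * self.k + 1
        if len(self.values) != n:
            raise ValueError(
                f"SAF vector length {len(self.values)} != expected {n}"
            )

    def linear(self) -> np.ndarray:
        """Unscaled linear likelihoods exp(values + log_scale)."""
        return np.exp(self.values + self.log_scale)


@dataclass
class SAFTable:
    """A stack of SAF vectors over sites (shape (S, J))."""

    logvals: np.ndarray
    log_scale: np.ndarray
    k: int
    folded: bool = False
    site_ids: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.logvals.shape[0]

    @property
    def n_categories(self) -> int:
        return self.logvals.shape[1]

    def __getitem__(self, i: int) -> SAFVector:
        return SAFVector(
            self.logvals[i],
            float(self.log_scale[i]),
            self.k,
            self.folded,
            self.site_ids[i] if self.site_ids else i,
        )


def _normalize_log_triples(log_triples: np.ndarray):
    """Rescale each individual's log triple to max 0; return linear triples
    and the per-site accumulated log scale."""
    log_triples = np.asarray(log_triples, dtype=float)
    m = np.max(log_triples, axis=-1, keepdims=True)
    if not np.isfinite(m).all():
        raise ValueError("each individual needs at least one finite log-likelihood")
    lin = np.exp(log_triples - m)
    return lin, m[..., 0].sum(axis=-1)


def dp_convolve_batch(lin_triples: np.ndarray):
    """Sequentially convolve per-individual weighted triples for many sites.

    Parameters
    ----------
    lin_triples : array (S, k, 3)
        Linear-scale genotype likelihood triples, ideally max-normalized
        per individual.

    Returns
    -------
    h : array (S, 2k+1) of unnormalized values, rescaled per site
    log_scale : array (S,) accumulated rescaling
    """
    lin_triples = np.asarray(lin_triples, dtype=float)
    S, k, _ = lin_triples.shape
    J = 2 * k + 1
    h = np.zeros((S, J))
    h[:, 0] = 1.0
    log_scale = np.zeros(S)
    for d in range(k):
        L0 = lin_triples[:, d, 0, None]
        L1 = lin_triples[:, d, 1, None]
        L2 = lin_triples[:, d, 2, None]
        new = h * L0
        new[:, 1:] += 2.0 * L1 * h[:, :-1]
        new[:, 2:] += L2 * h[:, :-2]
        m = new.max(axis=1)
        safe = np.where(m > 0.0, m, 1.0)
        h = new / safe[:, None]
        with np.errstate(divide="ignore"):
            log_scale += np.log(safe) + np.where(m > 0.0, 0.0, -np.inf)
    return h, log_scale


def saf_from_log_triples(log_triples: np.ndarray, site_ids=None) -> SAFTable:
    """SAF table from per-site, per-individual log-likelihood triples.

    ``log_triples`` has shape (S, k, 3), giving log P(X_d | G_d = g) for
    g = 0, 1, 2 copies of the derived allele.
    """
    lin, scale = _normalize_log_triples(log_triples)
    h, dp_scale = dp_convolve_batch(lin)
    k = lin.shape[1]
    with np.errstate(divide="ignore"):
        logvals = np.log(h) - log_binom(2 * k, np.arange(2 * k + 1))
    mx = logvals.max(axis=1)
    shift = np.where(np.isfinite(mx), mx, 0.0)
    logvals -= shift[:, None]
    return SAFTable(
        logvals, scale + dp_scale + shift, k, False, list(site_ids or [])
    )


def site_af_likelihood(gl_triples, k: int | None = None) -> SAFVector:
    """DP likelihood P(X | S_A = j) for a single site.

    ``gl_triples`` is a (k, 3) array of *linear* genotype likelihoods
    (L(0), L(1), L(2) derived copies per individual).
    """
    gl_triples = np.asarray(gl_triples, dtype=float)
    if gl_triples.ndim != 2 or gl_triples.shape[1] != 3:
        raise ValueError("gl_triples must have shape (k, 3)")
    if k is None:
        k = gl_triples.shape[0]
    if k != gl_triples.shape[0] or k < 1:
        raise ValueError(f"need exactly k >= 1 triples, got {gl_triples.shape}")
    if not np.isfinite(gl_triples).all() or (gl_triples < 0).any():
        raise ValueError("linear likelihoods must be finite and non-negative")
    with np.errstate(divide="ignore"):
        table = saf_from_log_triples(np.log(gl_triples)[None])
    return table[0]


def brute_force_site_af_likelihood(gl_triples, k: int | None = None) -> SAFVector:
    """Test oracle: direct sum over all 3^k genotype vectors.

    Same contract as :func:`site_af_likelihood`; refuses k > 8.
    """
    gl_triples = np.asarray(gl_triples, dtype=float)
    if k is None:
        k = gl_triples.shape[0]
    if k > 8:
        raise ValueError("brute force limited to k <= 8")
    if k != gl_triples.shape[0] or k < 1:
        raise ValueError("need exactly k >= 1 triples")
    J = 2 * k + 1
    vals = np.zeros(J)
    for config in itertools.product(range(3), repeat=k):
        j = sum(config)
        term = 1.0
        for d, g in enumerate(config):
            term *= W[g] * gl_triples[d, g]
        vals[j] += term
    vals /= np.array([comb(2 * k, j) for j in range(J)], dtype=float)
    mx = vals.max()
    shift = mx if mx > 0 else 1.0
    with np.errstate(divide="ignore"):
        return SAFVector(np.log(vals / shift), np.log(shift), k)


def _combine_log(parts, log_weights):
    """logsumexp-combine full (logvals + log_scale) tables, renormalize."""
    full = np.full_like(parts[0][0], -np.inf)
    for (lv, ls), lw in zip(parts, log_weights):
        full = np.logaddexp(full, lv + ls[:, None] + lw)
    mx = full.max(axis=1)
    shift = np.where(np.isfinite(mx), mx, 0.0)
    return full - shift[:, None], shift


def saf_unknown_derived_batch(
    gl10: np.ndarray, ancestral: np.ndarray, site_ids=None
) -> SAFTable:
    """Unfolded SAF when the ancestral base is known but the derived base is
    not: the three candidate derived alleles are each given prior weight 1/3
    and their SAF vectors summed on the linear scale.

    Parameters
    ----------
    gl10 : array (S, k, 10) of log genotype likelihoods
    ancestral : int array (S,) of ancestral base indices
    """
    gl10 = np.asarray(gl10, dtype=float)
    ancestral = np.broadcast_to(
        np.asarray(ancestral, dtype=np.intp), gl10.shape[:1]
    )
    parts = []
    for offset in (1, 2, 3):
        derived = (ancestral + offset) % 4
        triples = extract_pair_triples(gl10, ancestral, derived)
        t = saf_from_log_triples(triples)
        parts.append((t.logvals, t.log_scale))
    logvals, shift = _combine_log(parts, [np.log(1.0 / 3.0)] * 3)
    k = gl10.shape[1]
    return SAFTable(logvals, shift, k, False, list(site_ids or []))


def saf_unknown_derived(gl10: np.ndarray, ancestral) -> SAFVector:
    """Single-site convenience wrapper for :func:`saf_unknown_derived_batch`.

    ``ancestral`` may be a base letter or index.
    """
    if isinstance(ancestral, str):
        ancestral = BASES.index(ancestral)
    gl10 = np.asarray(gl10, dtype=float)
    table = saf_unknown_derived_batch(gl10[None], np.array([ancestral]))
    return table[0]


def saf_by_pair(gl10: np.ndarray, pairs=ORDERED_PAIRS) -> dict:
    """Per ordered (ancestral, derived) pair SAF tables for (S, k, 10) input."""
    gl10 = np.asarray(gl10, dtype=float)
    out = {}
    for a, d in pairs:
        triples = extract_pair_triples(gl10, a, d)
        out[(a, d)] = saf_from_log_triples(triples)
    return out


def saf_all_pairs_batch(gl10: np.ndarray, site_ids=None) -> SAFTable:
    """SAF summed over all 12 ordered allele pairs with equal weights.

    Used for inference when neither ancestral nor derived identity is
    known; the result is palindromic in j (each unordered pair enters in
    both orientations), so it is naturally paired with a folded prior.
    """
    per_pair = saf_by_pair(gl10)
    parts = [(t.logvals, t.log_scale) for t in per_pair.values()]
    logvals, shift = _combine_log(parts, [np.log(1.0 / 12.0)] * 12)
    k = np.asarray(gl10).shape[1]
    return SAFTable(logvals, shift, k, False, list(site_ids or []))


def saf_all_pairs(gl10: np.ndarray):
    """Single-site all-pairs SAF plus the per-pair decomposition.

    Returns ``(SAFVector, {(anc, der): SAFVector})``.
    """
    gl10 = np.asarray(gl10, dtype=float)
    combined = saf_all_pairs_batch(gl10[None])
    per_pair = {p: t[0] for p, t in saf_by_pair(gl10[None]).items()}
    return combined[0], per_pair


def fold(vec: np.ndarray) -> np.ndarray:
    """Fold a linear-scale length-(2k+1) vector to minor-count classes:
    out[i] = in[i] + in[2k-i] for i < k, out[k] = in[k]."""
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1 or len(vec) % 2 == 0:
        raise ValueError("fold needs a 1-D vector of odd length")
    k = (len(vec) - 1) // 2
    out = np.empty(k + 1)
    out[:k] = vec[:k] + vec[k + 1 :][::-1]
    out[k] = vec[k]
    return out


def fold_log(logvec: np.ndarray) -> np.ndarray:
    """Log-space fold of a spectrum: logaddexp of classes i and 2k-i."""
    logvec = np.asarray(logvec, dtype=float)
    if logvec.shape[-1] % 2 == 0:
        raise ValueError("fold needs odd length")
    k = (logvec.shape[-1] - 1) // 2
    out = np.empty(logvec.shape[:-1] + (k + 1,))
    out[..., :k] = np.logaddexp(logvec[..., :k], logvec[..., k + 1 :][..., ::-1])
    out[..., k] = logvec[..., k]
    return out


def fold_likelihood_log(logvec: np.ndarray) -> np.ndarray:
    """Fold a *likelihood* vector over derived counts to minor counts.

    A minor count m < k aggregates the two polarizations j = m and
    j = 2k - m with equal prior weight, so the folded likelihood is their
    average, P(X | m) = (P(X|j=m) + P(X|j=2k-m)) / 2; class m = k has a
    single polarization.  (Folding a probability *spectrum* sums instead;
    see :func:`fold`.)
    """
    out = fold_log(logvec)
    k = (np.asarray(logvec).shape[-1] - 1) // 2
    out[..., :k] -= np.log(2.0)
    return out


def fold_saf_table(table: SAFTable) -> SAFTable:
    """Fold an unfolded SAF table to minor-allele-count categories."""
    if table.folded:
        raise ValueError("table already folded")
    logvals = fold_likelihood_log(table.logvals)
    mx = logvals.max(axis=1)
    shift = np.where(np.isfinite(mx), mx, 0.0)
    return SAFTable(
        logvals - shift[:, None],
        table.log_scale + shift,
        table.k,
        True,
        table.site_ids,
    )


def flag_invalid_ancestral(gl10: np.ndarray, ancestral: np.ndarray) -> np.ndarray:
    """Flag sites where the annotated ancestral allele is absent from every
    individual's maximum-likelihood genotype while at least two other bases
    appear: the unfolded spectrum is undefined there and such sites are
    excluded from unfolded analyses.  Heuristic by construction; used only
    as a filter.
    """
    gl10 = np.asarray(gl10, dtype=float)
    S, k, _ = gl10.shape
    ancestral = np.broadcast_to(np.asarray(ancestral, dtype=np.intp), (S,))
    best = gl10.argmax(axis=2)  # (S, k)
    pair_arr = np.array(GENOTYPE_PAIRS)  # (10, 2)
    alleles = pair_arr[best]  # (S, k, 2)
    flags = np.zeros(S, dtype=bool)
    for s in range(S):
        present = np.unique(alleles[s])
        if ancestral[s] not in present and len(present) >= 2:
            flags[s] = True
    return flags
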
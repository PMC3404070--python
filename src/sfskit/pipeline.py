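"""Compositions of the core modules into end-to-end steps (used by the
command-line interface and the analysis scripts)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gl import BASES, extract_pair_triples
from .genotypes import genotype_posteriors_sfs_batch
from .posteriors import posterior_sample_af_batch
from .saf import (
    SAFTable,
    fold_saf_table,
    saf_all_pairs_batch,
    saf_by_pair,
    saf_unknown_derived_batch,
)

__all__ = ["build_saf", "snp_call_table", "genotype_call_table"]


def build_saf(gl10, ancestral=None, folded: bool = False, site_ids=None) -> SAFTable:
    """SAF table from a (S, k, 10) log genotype-likelihood array.

    With a per-site ancestral base (indices, -1 = unknown) the unfolded SAF
    is computed with the three candidate derived alleles weighted 1/3 each;
    without ancestral information (or with ``folded=True``) the SAF is
    summed over all allele pairs and folded to minor-allele counts.
    """
    gl10 = np.asarray(gl10, dtype=float)
    if folded or ancestral is None:
        table = saf_all_pairs_batch(gl10, site_ids=site_ids)
        return fold_saf_table(table)
    ancestral = np.asarray(ancestral)
    if np.any(ancestral < 0):
        raise ValueError(
            "unfolded SAF needs a known ancestral base at every site; "
            "use folded=True otherwise"
        )
    return saf_unknown_derived_batch(gl10, ancestral, site_ids=site_ids)


def _best_pairs(gl10: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per site, the (major, minor) base indices of the unordered allele
    pair with the highest marginal likelihood (uniform over orderings and
    sample frequencies)."""
    per_pair = saf_by_pair(gl10)
    S = np.asarray(gl10).shape[0]
    best = np.full(S, -np.inf)
    major = np.zeros(S, dtype=np.intp)
    minor = np.ones(S, dtype=np.intp)
    seen = set()
    for (a, d), table in per_pair.items():
        if (d, a) in seen:
            continue
        seen.add((a, d))
        other = per_pair[(d, a)]
        marg = np.logaddexp(
            logsumexp(table.logvals, axis=1) + table.log_scale,
            logsumexp(other.logvals, axis=1) + other.log_scale,
        )
        upd = marg > best
        best = np.where(upd, marg, best)
        major[upd] = a
        minor[upd] = d
    return major, minor


def snp_call_table(
    gl_table, prior: np.ndarray, cutoff: float = 0.05, folded: bool | None = None
) -> pd.DataFrame:
    """Per-site SNP-call table.

    Columns: site_id, major, minor, p_not_variable, called (0/1),
    af_postmode, af_postmean.  ``prior`` must match the analysis mode
    (length 2k+1 unfolded with known ancestral alleles, length k+1
    folded).  Major/minor are the pair with the highest marginal
    likelihood, re-oriented when p(S_m > k | X) > 0.5.
    """
    gl10 = gl_table.loglik
    S, k, _ = gl10.shape
    if folded is None:
        folded = len(prior) == k + 1
    anc = None if folded else gl_table.ancestral
    saf = build_saf(gl10, ancestral=anc, folded=folded,
                    site_ids=gl_table.site_ids())
    post = posterior_sample_af_batch(saf, prior, False)
    p0 = post[:, 0] if folded else post[:, 0] + post[:, -1]

    major, minor = _best_pairs(gl10)
    if not folded:
        # orientation against the annotated ancestral allele where possible
        swap = minor == gl_table.ancestral
        major2 = np.where(swap, minor, major)
        minor2 = np.where(swap, major, minor)
        major, minor = major2, minor2
        # re-orient if the posterior puts the "minor" allele in the majority
        p_high = post[:, k + 1 :].sum(axis=1)
        flip = p_high > 0.5
        major, minor = np.where(flip, minor, major), np.where(flip, major, minor)

    mode = post.argmax(axis=1)
    mean = post @ np.arange(post.shape[1])
    return pd.DataFrame(
        {
            "site_id": saf.site_ids or np.arange(S),
            "major": [BASES[b] for b in major],
            "minor": [BASES[b] for b in minor],
            "p_not_variable": p0,
            "called": (p0 < cutoff).astype(int),
            "af_postmode": mode,
            "af_postmean": mean,
        }
    )


def genotype_call_table(
    gl_table,
    prior: np.ndarray,
    condition_on_variable: bool = False,
    min_confidence: float | None = None,
) -> pd.DataFrame:
    """Per-individual genotype-call table under the SFS prior.

    Requires known ancestral alleles (unfolded prior of length 2k+1); the
    derived allele per site is the best-pair partner of the ancestral one.
    Columns: site_id, individual, p_g0, p_g1, p_g2, call, confidence.
    """
    gl10 = gl_table.loglik
    S, k, _ = gl10.shape
    if np.any(gl_table.ancestral < 0):
        raise ValueError("genotype calling needs ancestral annotations")
    major, minor = _best_pairs(gl10)
    # derived = the best-pair partner of the ancestral allele; if the best
    # pair excludes the ancestral base entirely, fall back to its major
    derived = np.where(major == gl_table.ancestral, minor, major)
    triples = extract_pair_triples(gl10, gl_table.ancestral, derived)
    post = genotype_posteriors_sfs_batch(triples, prior, condition_on_variable)
    calls = post.argmax(axis=2)
    conf = np.take_along_axis(post, calls[:, :, None], axis=2)[:, :, 0]
    if min_confidence is not None:
        calls = np.where(conf >= min_confidence, calls, -1)
    ids = gl_table.site_ids()
    inds = gl_table.individuals or [f"ind{i+1}" for i in range(k)]
    return pd.DataFrame(
        {
            "site_id": np.repeat(ids, k),
            "individual": np.tile(inds, S),
            "p_g0": post[:, :, 0].ravel(),
            "p_g1": post[:, :, 1].ravel(),
            "p_g2": post[:, :, 2].ravel(),
            "call": calls.ravel(),
            "confidence": conf.ravel(),
        }
    )
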
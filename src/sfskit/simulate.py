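"""Read simulator for low-coverage multi-individual sequencing.

Each site is variable in the population with probability ``p_var``; a
variable site's derived-allele population frequency x is drawn with
density proportional to 1/x (the neutral-equilibrium shape), truncated to
[freq_min, 1 - freq_min] so the density is proper.  Genotypes are drawn
per individual as Binomial(2, x) (Hardy-Weinberg), read depths are
Poisson(mean_depth) per individual per site, each read copies a uniformly
chosen parental allele and is flipped to one of the three other bases with
probability ``error_rate`` (symmetric errors).  Genotype likelihoods are
then computed under the same error model with the error rate treated as
known.

The simulator is the ground-truth source for every statistical test in
the package; it deliberately omits mapping artifacts, indels and linkage
(sites are independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gl import BASES, gl_from_base_counts

__all__ = ["SimConfig", "SimData", "sample_popfreq", "simulate_dataset"]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    k: int = 10
    n_sites: int = 10_000
    mean_depth: float = 5.0
    error_rate: float = 0.005
    p_var: float = 0.02
    freq_min: float = 0.0005
    seed: int | None = None
    random_ancestral: bool = False
    all_variable: bool = False  # condition every site on being variable

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_sites < 1:
            raise ValueError("k and n_sites must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.error_rate <= 0.75:
            raise ValueError("error_rate must be in [0, 0.75]")
        if not 0.0 <= self.p_var <= 1.0:
            raise ValueError("p_var must be in [0, 1]")
        if not 0.0 < self.freq_min <= 0.5:
            raise ValueError("freq_min must be in (0, 0.5]")


@dataclass
class SimData:
    """Simulated truth plus the derived genotype-likelihood table."""

    config: SimConfig
    is_variable: np.ndarray  # (S,) population-variable flag
    popfreq: np.ndarray  # (S,) derived frequency (0 where invariant)
    ancestral: np.ndarray  # (S,) base index
    derived: np.ndarray  # (S,) base index (ancestral where invariant)
    genotypes: np.ndarray  # (S, k) derived-allele counts
    depths: np.ndarray  # (S, k) read counts
    base_counts: np.ndarray  # (S, k, 4) observed reads per base
    gl: np.ndarray = field(repr=False, default=None)  # (S, k, 10) log GLs

    @property
    def k(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    def sample_allele_counts(self) -> np.ndarray:
        """Per-site true derived-allele counts among the 2k chromosomes."""
        return self.genotypes.sum(axis=1)

    def true_sfs_counts(self) -> np.ndarray:
        """Realized sample spectrum (counts per class 0..2k)."""
        return np.bincount(
            self.sample_allele_counts(), minlength=2 * self.k + 1
        )

    def variable_in_sample(self) -> np.ndarray:
        j = self.sample_allele_counts()
        return (j > 0) & (j < 2 * self.k)

    def reads_dataframe(self) -> pd.DataFrame:
        """Expand base counts to one row per read (site, individual, base,
        phred).  Intended for small simulations and format round-trips."""
        e = self.config.error_rate
        phred = 93.0 if e == 0 else -10.0 * np.log10(e)
        rows = []
        for s in range(self.n_sites):
            for d in range(self.k):
                for b in range(4):
                    for _ in range(int(self.base_counts[s, d, b])):
                        rows.append(("sim", s + 1, f"ind{d + 1}", BASES[b], phred))
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "individual", "base", "phred"]
        )


def sample_popfreq(
    rng: np.random.Generator, size=None, freq_min: float = 0.0005
) -> np.ndarray | float:
    """Draw population frequencies with density proportional to 1/x on
    [freq_min, 1 - freq_min] (log-uniform; inverse CDF x = a (b/a)^u)."""
    a, b = freq_min, 1.0 - freq_min
    if not 0.0 < a < b:
        raise ValueError("freq_min must be in (0, 0.5)")
    u = rng.random(size)
    return a * (b / a) ** u


def simulate_dataset(config: SimConfig, rng=None) -> SimData:
    """Generate one dataset under ``config``.

    Fixed seeds give byte-identical output.  Returns the full truth record
    together with the (S, k, 10) natural-log genotype-likelihood table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    S, k = config.n_sites, config.k
    e = config.error_rate

    if config.all_variable:
        is_var = np.ones(S, dtype=bool)
    else:
        is_var = rng.random(S) < config.p_var
    x = np.where(is_var, sample_popfreq(rng, S, config.freq_min), 0.0)

    if config.random_ancestral:
        anc = rng.integers(0, 4, size=S)
    else:
        anc = np.zeros(S, dtype=np.int64)
    # derived drawn uniformly among the other three bases (defined for all
    # sites; only meaningful where variable)
    der = (anc + rng.integers(1, 4, size=S)) % 4

    genotypes = rng.binomial(2, x[:, None], size=(S, k))
    depths = rng.poisson(config.mean_depth, size=(S, k))

    # reads in canonical slots [ancestral, derived, err1, err2]:
    # derived-origin reads ~ Binomial(depth, g/2), then symmetric errors
    n_der_true = rng.binomial(depths, genotypes / 2.0)
    n_anc_true = depths - n_der_true
    p_anc = np.array([1 - e, e / 3, e / 3, e / 3])
    p_der = np.array([e / 3, 1 - e, e / 3, e / 3])
    canon = rng.multinomial(n_anc_true, p_anc) + rng.multinomial(
        n_der_true, p_der
    )  # (S, k, 4)

    # scatter canonical slots into actual base identities
    other = _other_bases(anc, der)  # (S, 2) the two non-allele bases
    slot_to_base = np.stack([anc, der, other[:, 0], other[:, 1]], axis=1)
    base_counts = np.zeros((S, k, 4), dtype=np.int64)
    np.put_along_axis(
        base_counts,
        np.broadcast_to(slot_to_base[:, None, :], (S, k, 4)),
        canon,
        axis=2,
    )

    gl = gl_from_base_counts(base_counts, e)
    return SimData(
        config=config,
        is_variable=is_var,
        popfreq=x,
        ancestral=anc,
        derived=der,
        genotypes=genotypes,
        depths=depths,
        base_counts=base_counts,
        gl=gl,
    )


def _other_bases(anc: np.ndarray, der: np.ndarray) -> np.ndarray:
    """For each site, the two base indices that are neither allele."""
    S = len(anc)
    all_b = np.broadcast_to(np.arange(4), (S, 4))
    mask = (all_b != anc[:, None]) & (all_b != der[:, None])
    return all_b[mask].reshape(S, 2)
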
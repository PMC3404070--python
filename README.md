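# sfskit

Site-frequency-spectrum estimation, SNP calling and genotype calling from
genotype likelihoods, for low- and medium-coverage (< 20X) multi-individual
sequencing data.

## The problem

At low coverage, per-individual genotype calls are unreliable: a
heterozygote sequenced at 5X with a "minor allele seen at least twice"
rule is called homozygous 37.5% of the time, and with a per-read error
rate of 0.1% a 5X homozygous site shows at least one error read in about
0.5% of sites — the same order as the SNP rate itself. Population-genetic
summaries computed from hard genotype calls are therefore biased (an
excess of false singletons with lenient calling, missing heterozygotes
with strict calling).

`sfskit` instead propagates genotype *likelihoods*. For k diploid
individuals it computes, per site, the vector of likelihoods of the read
data given each possible sample allele frequency j = 0..2k,

    h_j  ∝  Σ_{g_1..g_k : Σg = j}  Π_d  P(X_d | G_d = g_d) · C(2, g_d) / C(2k, j),

by an O(k²) dynamic programme (a sequential convolution of per-individual
genotype-likelihood triples under Hardy-Weinberg sampling). The site
frequency spectrum P = (p_0, …, p_2k) — including the invariant classes —
is then estimated by maximum likelihood over all sites,

    ℓ(P) = Σ_v log Σ_j p_j · P(X_v | S = j),

with BFGS on a softmax reparameterization using the analytic gradient
(an EM iteration is provided as an independent cross-check). The
genome-wide estimate serves as an empirical-Bayes prior for per-site
inference:

* **SNP calling** — a site is variable when the posterior probability of
  the invariant classes, p(S ∈ {0, 2k} | X), falls below a cutoff;
* **allele-frequency estimation** — the full posterior over S, folded or
  unfolded, optionally conditioned on variability;
* **genotype calling** — P(G_d = g | X) combining individual d's
  likelihoods with all other individuals' data through a leave-one-out
  frequency likelihood (prefix/suffix convolutions), or with a known
  population frequency under Hardy-Weinberg, or with per-individual
  inbreeding coefficients F_d allowing heterozygote deficits and
  excesses;
* **downstream summaries** — Watterson's θ, nucleotide diversity π and
  Tajima's D directly from the estimated spectrum.

A read simulator with Poisson depths, 1/x population frequencies and
symmetric base errors provides ground truth for every statistical claim.

## Worked example

```python
import numpy as np
from sfskit import SimConfig, simulate_dataset, SFSEstimator, SNPCaller
from sfskit.saf import saf_unknown_derived_batch

sim = simulate_dataset(SimConfig(k=10, n_sites=50_000, mean_depth=5.0,
                                 error_rate=0.005, p_var=0.02, seed=1))
saf = saf_unknown_derived_batch(sim.gl, sim.ancestral)

est = SFSEstimator(method="bfgs").fit(saf)
print(f"estimated proportion variable: {est.result_.prop_variable:.5f}")
print(f"realized truth:                {sim.variable_in_sample().mean():.5f}")

caller = SNPCaller(cutoff=0.05, prior=est.sfs_).fit(saf)
calls = caller.predict(saf)
truth = sim.variable_in_sample()
print(f"called {calls.sum()} SNPs; "
      f"precision {truth[calls].mean():.3f}, recall {calls[truth].mean():.3f}")
```

Output:

```
estimated proportion variable: 0.00949
realized truth:                0.00942
called 386 SNPs; precision 1.000, recall 0.820
```

The spectrum estimate recovers the realized fraction of variable sites to
about one part in 10⁴ of all sites even though only ~470 of 50,000 sites
are variable and each individual averages 5 reads; the empirical-Bayes
caller then trades precision against recall through the posterior cutoff.

The same pipeline is available from the shell:

```sh
sfskit simulate --k 10 --sites 50000 --depth 5 --error 0.005 --pvar 0.02 \
    --seed 1 --out demo
sfskit saf --gl demo.gl.tsv --out demo.saf.tsv
sfskit sfs --saf demo.saf.tsv --out demo.sfs
sfskit call-snps --gl demo.gl.tsv --sfs demo.sfs --cutoff 0.05 --out demo.snps.tsv
sfskit call-genotypes --gl demo.gl.tsv --sfs demo.sfs --out demo.geno.tsv
sfskit stats --sfs demo.sfs --sites 50000 --out demo.stats.tsv
```

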
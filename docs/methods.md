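# Methods

## Model

Data are per-site, per-individual genotype likelihoods
P(X_d | G_d = g), g ∈ {0, 1, 2} copies of a derived (or minor) allele,
for k diploid individuals at S independent sites. With a flat symmetric
per-read error rate e, a read carrying base b has allele likelihoods
L(b) = 1 − e and e/3 otherwise, and the genotype likelihood is the product
over reads of (L(b₁) + L(b₂))/2. Reads are assumed independent given the
genotype; this does not presuppose Hardy-Weinberg equilibrium (HWE), which
enters only through priors. Individuals without reads carry a uniform
likelihood vector rather than being dropped, so k is constant across
sites — the correct "no data" statement for the dynamic programme.

### Sample-allele-frequency likelihood

Under HWE, conditioning on j derived alleles among the 2k chromosomes
makes the labelled genotype configuration hypergeometric:

    P(X | S = j) = Σ_{Σ g_d = j} Π_d P(X_d|g_d) · Π_d C(2, g_d) / C(2k, j).

The sum over 3^k configurations is computed as a sequential convolution of
the per-individual weighted triples (1·L(0), 2·L(1), 1·L(2)), followed by
division by C(2k, j): O(k²) per site. The weight convention is pinned by a
brute-force enumeration oracle (`brute_force_site_af_likelihood`), which
the DP must match to 1e-12 relative for k ≤ 4.

When the derived allele is unknown but the ancestral base is annotated,
the three candidate derived alleles are weighted 1/3 each and their
likelihood vectors summed (loci are assumed truly di-allelic, extra
alleles being errors; sites whose annotated ancestral allele is absent
while two other alleles segregate are flagged and excluded from unfolded
analyses). Without ancestral information the vectors are summed over all
12 ordered allele pairs with equal weights and folded to minor-allele
counts. Folding a *likelihood* vector averages the two polarizations of
each class below k (each minor count m < k aggregates j = m and j = 2k − m
with equal prior weight); folding a probability *spectrum* sums them.
Empirical substitution-matrix weighting of allele pairs is deliberately
not implemented.

### Spectrum estimation

The spectrum P = (p_0 … p_2k) (folded: k+1 classes) maximizes
ℓ(P) = Σ_v log Σ_j p_j exp(saf_vj). Two optimizers:

* **BFGS** on the softmax transform anchored at p_0
  (p_i = e^{θ_i}/(1+Σe^{θ_j})), with the analytic gradient
  ∂ℓ/∂θ_i = Σ_v (posterior_vi − p_i). Default start: the uniform
  spectrum. Stopping: gradient ∞-norm below tol × S (tol defaults to
  1e-8) or 1000 iterations; non-convergence is reported in the result,
  not raised.
* **EM**: p_j ← mean over sites of the per-site posterior, used as an
  independent cross-check. The accepted iterate sequence is monotone in
  ℓ. A squared-extrapolation (SQUAREM-style) step is attempted each
  iteration and kept only when it does not lower ℓ, which accelerates
  the linear EM rate along flat ridges; `accelerate=False` gives the
  plain recursion.

Two numerical hazards of the softmax parameterization are handled
explicitly. First, near-collinear SAF columns create flat ridges where
quasi-Newton steps stall with a tiny gradient far from the optimum; a
damped-Newton polish with the analytic Hessian
(H_mn = δ_mn(R_m − S p_m) − Σ_v r_vm r_vn + S p_m p_n, r the per-site
posteriors) follows BFGS. Second, once a class's mass collapses, both the
softmax gradient and the EM multiplicative update lose the ability to
revive it even when it belongs in the optimum; after convergence the
simplex KKT statistic G_j = Σ_v a_vj / L_v is checked (interior classes
have G_j = S, profitable zero classes have G_j > S) and violating
near-zero classes are bumped back to 1e-4/(2k+1) mass and the
optimization resumed, up to a handful of rounds. With these safeguards
the two optimizers agree to < 1e-6 in ℓ on random stress tables and at
the 1e-5-site scale. ℓ is concave in P, so the agreed point is the global
maximum. Exact zeros in the inverse transform are floored at 1e-15 with a
warning.

### Per-site empirical-Bayes inference

The estimated spectrum is the prior: posterior ∝ p_j exp(saf_j).
SNP calling thresholds p(S ∈ {0, 2k} | X) (folded: p(S=0 | X)); the
default cutoff 0.05 is a conventional operating point, and the full
posterior is always retained (point estimates use the argmax with ties
toward the smaller count). Conditioning on variability zeroes the
invariant classes before renormalizing, and the same conditioning is
applied in numerator and denominator of any downstream posterior. Calling
SNPs from an already-conditioned posterior is rejected as circular.

Genotype posteriors for individual d combine its likelihood triple with a
leave-one-out frequency likelihood over the other k − 1 individuals:

    P(G_d = g | X) ∝ Σ_j p_j · w(g) L_d(g) · h^{(−d)}_{j−g} / C(2k, j).

All k leave-one-out tables come from prefix/suffix convolutions — one
forward and one backward pass plus a combine, never division by an
individual's triple, which is unstable near zeros. The combinatorial
normalization C(2k, j) (not C(2k−2, j−g)) is pinned by a 3^k joint
enumeration oracle.

With a known population major-allele frequency f (estimated per site by
maximum likelihood via the EM dosage update when not external), the
genotype prior is HWE: ((f)², 2f(1−f), (1−f)²) ordered by minor count,
and the sample-frequency posterior uses the binomial prior q^j(1−q)^{2k−j}
applied as a terminal step of the same DP. The per-site frequency
likelihood is a product of quadratics in f and can have local maxima at
both boundaries, so the EM recursion is run from several interior starts
and both boundary values are checked. Major/minor status is re-assigned
when p(S_m > k | X) exceeds one half.

Deviations from HWE use per-individual inbreeding coefficients F_d with
genotype priors m_d0 = (1−q)² + q(1−q)F_d, m_d1 = 2q(1−q)(1−F_d),
m_d2 = q² + q(1−q)F_d (q the minor frequency). F_d may be negative
(heterozygote excess) as long as every m_dg remains non-negative; the
model validates this and names the offending individual. With F ≡ 0 the
machinery reduces exactly (to 1e-12) to the known-frequency posterior —
this identity plus k = 2 enumeration oracles are the validation surface,
since the prior form is the standard inbreeding genotype-frequency model.

### Downstream summaries

Watterson's θ = S_seg/a_n, π = Σ i(n−i)η_i / C(n,2), and Tajima's D with
the standard variance constants, all from the counts per frequency class
1..n−1 (n = 2k chromosomes). The statistics accept expected counts
(probabilities × sites); the D variance constants assume integer counts,
so with expected counts the value is a plug-in approximation.

## Simulator

The generator emulates the low-coverage study design: each site is
variable in the population with probability p_var (default 0.02);
derived-allele population frequencies follow density ∝ 1/x — the
neutral-equilibrium shape — truncated to [5e-4, 1−5e-4] so the density is
proper (the untruncated form is non-normalizable at 0; rare alleles still
dominate); genotypes are Binomial(2, x) per individual (HWE); depths are
Poisson(λ) per individual-site; each read copies a uniformly chosen
parental allele and flips to one of the other three bases with
probability e (default 0.005); genotype likelihoods are computed with e
treated as known. The ancestral base is fixed to A by default (a flag
randomizes it to exercise the allele-pair machinery); the derived base is
uniform among the rest. One seed drives the whole stream, so output is
byte-identical across runs.

Deliberately not modelled: mapping artifacts, indels, linkage between
sites, cycle-dependent or allele-dependent error structure, and
mis-specified error rates. Passing tests therefore demonstrate
correctness of the inference machinery under its own model, not
robustness to the error mis-calibration real pipelines face.

## Study conditions used in tests and the acceptance script

* Spectrum recovery: k = 10, 100,000 sites, p_var = 2%, e = 0.5%, depths
  1X/5X/10X. The estimated proportion of variable sites is checked at 5X
  and 10X against the realized truth within Monte-Carlo error
  (4·√(p(1−p)/S)); per-class recovery (25% relative, classes with ≥ 50
  realized sites) is checked at 10X; at 1X the frequency-prior hard
  genotype caller must inflate the singleton class by more than 2×. At
  this scaled-down site count the per-class Monte-Carlo noise at 1X–5X is
  itself of order 25%, so those depths are summarized by the
  proportion-variable check instead.
* SNP-caller ROC: k = 10, 20,000 sites, 2X, e = 1%, p_var = 2%;
  true-positive rates compared at false-positive rate 1e-3. "Variable"
  means variable in the sample. The genotype-calling baseline score is
  the best per-individual log likelihood ratio of a derived-carrying
  genotype versus homozygous-ancestral (thresholding at 0 is "some
  called genotype carries the derived allele").
* Genotype-caller comparison: k = 10, 20,000 all-variable sites,
  e = 0.5%, 2X (the low-coverage regime where leveraging the other
  individuals matters most), full call rate, versus
  maximum-genotype-likelihood calls.
* Optimizer cross-validation: 20 random SAF tables, k ≤ 5, S ≤ 200,
  agreement within 1e-6 in ℓ; gradient versus central finite differences
  at 1e-6 relative.

These sizes keep the full suite within a few minutes on one CPU while
leaving the stochastic checks comfortably powered.

## Interfaces and conventions

Genotype likelihood TSV: header `#chrom pos anc ind1..indK`, one row per
site with the ancestral base (or `.`), then 10 natural-log likelihoods
per individual in lexicographic order AA AC AG AT CC CG CT GG GT TT;
finite values round-trip at 6 decimals. SAF dump: per site `site_id, k,
log_scale`, then the per-class log values (max-normalized to 0, with the
residual in log_scale). SFS file: one whitespace-separated probability
line under a header comment recording k, folded flag and final ℓ. SNP and
genotype call tables are TSV; a minimal sites-only VCF export (QUAL =
−10·log₁₀ p(invariant)) is provided without bit-level guarantees.

Scikit-learn-style wrappers (`SFSEstimator`, `SNPCaller`,
`GenotypeCaller`) expose the fits as estimators with `get_params`/
`set_params`, fitted attributes with trailing underscores, and
`fit`/`predict`/`predict_proba`, so they compose with sklearn pipelines;
the module-level functions remain the primitive surface.

## Known limitations

* Quality-score recalibration is out of scope: the likelihood model
  consumes a flat or phred-derived error rate (the symmetric special
  case); cycle- and allele-dependent calibrated likelihoods can be
  supplied externally through the GL table.
* BAM/pileup ingestion is not provided; reads enter via the simulator or
  a plain per-read TSV.
* No confidence intervals on the spectrum.
* Tri-allelic truth is not modelled (extra observed alleles are treated
  as errors).
* The Tajima's D constants assume counts, as noted above.
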
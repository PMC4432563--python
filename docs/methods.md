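# Methods

## Genotype information model

Genotypes are coded on the three-state diploid scale 0/1/2 (hom-ref /
het / hom-alt) with an explicit missing sentinel; multi-allelic sites
and indels are excluded at ingestion, since the whole framework assumes
exactly three genotype states per marker. All information quantities
are in bits (log base 2); the 1.585-bit single-SNP maximum, the
1.5-bit HWE/MAF-0.5 anchor, and the 33-bit world-population threshold
all depend on that base.

Probabilities are plug-in (maximum-likelihood) estimates from genotype
counts, with no pseudocounts and no bias correction (Miller–Madow
etc.). Missing calls are excluded per SNP for entropies and pairwise
(complete-case per pair) for mutual information; they are never
imputed. With ~10² candidate SNPs and ~10³ samples the plug-in bias
(~log₂(e)·df/2n, df ≤ 8) is below 0.01 bits, smaller than the effects
the selection cares about.

## Joint-entropy bounds

The exact joint entropy of N SNPs requires the empirical distribution
over 3^N genotype vectors and is provided only as a small-N oracle
(default cap N = 8, 3⁸ = 6561 cells). For selection, the panel score is
the pairwise lower bound

    H_L = Σ_k H(X_k) − Σ_{j<k} I(X_j; X_k)

and the reported upper bound is

    H_U = Σ_k H(X_k) − Σ_{k≥2} max_{j<k} I(X_j; X_k).

Two caveats are deliberate design choices:

* **H_U variant.** The chain-rule derivation admits either
  max_{j<k} I(X_j;X_k) or I(X_1;X_k) as the per-step subtraction; the
  max variant is tighter and order-robust and is the default, with the
  one-anchor variant available via `upper_rule="first"`.
* **Clamping.** H_L is not a mathematically guaranteed lower bound
  under higher-order dependence (an XOR-type triple violates the
  pairwise-subtraction inequality), and for heavily redundant sets the
  pairwise sum over-subtracts. H_L is therefore clamped below at
  max_k H(X_k) — a joint entropy can never be below any marginal — and
  H_U at H_L. The bracketing property H_L ≤ H(X₁..X_N) ≤ H_U is
  asserted in tests on HWE-independent and pairwise-LD simulated data
  only, which is the dependence regime the method assumes; the tests
  use a 0.05-bit tolerance covering plug-in sampling noise at n = 3000.

## Panel selection

Beam search over subsets, scored by H_L with incremental update
H_L(set ∪ {x}) = H_L(set) + H(x) − Σ_{y∈set} I(y;x). The beam (default
width 1000) is seeded with the highest-entropy singletons; at each step
every beam set is extended by every unused candidate, permutations of
the same member set are collapsed to one canonical (sorted) entry, and
the beam is truncated by H_L. Ties — including float-path noise below
1e-10 bits, which is quantized away before sorting — are broken
lexicographically on the canonical id tuple, so results are exactly
reproducible. With beam width ≥ C(n, N) the search is exhaustive; the
test suite verifies equality with brute force for n ≤ 12, N ≤ 4. H_U is
reported but never optimized. A decrease of the best H_L as the panel
grows (possible in the over-subtraction regime) triggers a logged
warning. Gene restriction is an exact-symbol whitelist against the
annotation; the default candidate universe is all autosomal SNPs in
the supplied annotation.

## Qualification

* **Entropy consistency.** For each SNP shared by two datasets with
  non-missing counts n and m, bootstrap resamples of size n and m are
  drawn (per-SNP genotype resampling, implemented as multinomial draws
  from the plug-in genotype distributions — equivalent to resampling
  individuals for a single SNP), ΔH is recorded for 1000 replicates,
  and the SNP qualifies when 0 lies inside the 95% percentile interval
  of ΔH. The alternative reading — the observed ΔH inside its own
  bootstrap CI — is nearly always true by construction and cannot
  discriminate; it is retained behind `rule="observed-in-ci"` for
  comparison. With more than two datasets, pairwise tests are combined
  by intersection. Per-SNP RNG streams are derived from the master
  seed and the (snp, dataset-pair) labels via SHA-256, so results are
  order-independent and parallelizable.
* **Locus filters.** Mappability ≥ 1.0, GC content in [0.35, 0.55]
  (boundaries inclusive), autosomes only. GC and mappability arrive as
  precomputed per-SNP scores in the annotation TSV; computing them
  from genome tracks is out of scope.
* **Sample overlap.** Cross-dataset identity = matching genotypes /
  co-observed shared SNPs; pairs strictly above 0.95 are reported.
  Under HWE with MAF 0.4–0.5 two unrelated samples match at ≈ 0.38 of
  sites, so the threshold separates duplicates from unrelated pairs by
  a wide margin.

## Closed-form tagging math

For N independent markers with S equiprobable genotypes, the pairwise
Hamming distance is Binomial(N, (S−1)/S): P(k) = C(N,k)(S−1)^k / S^N,
E[d] = N(S−1)/S (2N/3 at S = 3). Per-marker probabilities use exact
`Fraction`/`math.comb` arithmetic (a float 3⁶⁰ path would lose the
printed significant figures), and the population-level duality
probability 1 − (1 − P(≤t))^C(L,2) is evaluated as
−expm1(C(L,2)·log1p(−P)) with C(L,2) an exact integer, stable at
L = 7×10⁹. Both the exponential and the linearized C(L,2)·P forms are
exposed; both are approximations that treat pairs as independent,
accurate when C(L,2)·P(≤t) is small and L ≤ S^N (a warning fires
beyond). The Monte-Carlo cross-check at L = 200, N = 8 allows 3 MC
standard errors plus a 5×10⁻³ absolute allowance for that
pair-independence bias (analytically ≈ L³/6·S^(−2N) ≈ 2×10⁻³ there).
`min_markers` walks integer powers, never float logs, so power-of-S
boundaries are exact.

## Synthetic populations

The simulator draws each genotype as two independent allele draws at
the alt frequency (HWE, no inbreeding), SNPs independent unless an
`LdSpec` injects pairwise copying (SNP j takes SNP i's genotype with
probability p per individual — copy chains allowed, cycles rejected).
Per-SNP and per-group streams derive from `SeedSequence([master, k])`,
so any column regenerates independently. The bundled frequency fixture
(4 groups × 40 SNPs) is synthetic: 30 SNPs at alt frequency 0.40–0.50
with small between-group jitter — the qualified-SNP regime panel
evaluation assumes — plus 10 low-MAF distractors.

What the simulations do **not** emulate: realistic genome-wide LD
beyond injected pairs, population substructure/admixture, relatedness
(families), genotyping error, and missingness patterns of real
pipelines. Passing tests therefore demonstrate correctness of the
estimators and algorithms under the model's own assumptions, not panel
performance on any specific human cohort.

## Evaluation

The mean pairwise Hamming distance is computed exactly in O(L·N) from
per-SNP genotype frequencies (mean = Σ_snp [1 − Σ_g n_g(n_g−1)/(L_s(L_s−1))],
complete-case per SNP); the distance histogram is exact up to 10⁷ pairs
(a few seconds at L ≈ 4500) and otherwise sampled from seeded random
pairs, with the mode recorded in the output. Duality detection hashes
panel genotype byte-strings (O(L·N)); a sample with missing panel calls
is never silently matched — it is flagged and compared by complete-case
distance. Duality frequency is reported both per pair
(dual pairs / C(L,2)) and per individual (individuals in ≥1 dual pair
/ L), since either denominator is defensible.

## Problem sizes and defaults

Simulation-backed checks run at desk scale chosen to keep sampling
error well below the asserted margins: 10,000 individuals for the
30-SNP mean-distance check (exact frequency-identity mean; the ≥18
bound has ~0.7 bits of headroom), 100,000 individuals for the duality
frequency (expected dual pairs ≈ C(L,2)·Π Σf_g² ≈ 2×10⁻³, so the 10⁻⁴
frequency bound is passed by orders of magnitude), 200 null SNPs at
n = m = 500 for bootstrap calibration (3 binomial SEs ≈ ±4.6 points
around 95%), and 20,000 replicate populations for the Monte-Carlo
duality check.

## Known limitations

* H_L/H_U are pairwise constructions; strongly higher-order dependent
  markers can escape both bounds.
* The bootstrap consistency test calibrates near, not exactly at, the
  nominal level (percentile intervals at n = 500 carry O(n^−1)
  coverage error).
* The closed-form duality math assumes uniform, independent genotypes;
  real panels only approach that ideal, so empirical duality rates on
  structured populations exceed the closed form.
* Beam search is a heuristic: outside the exhaustively-verified small
  instances, optimality of the returned panel is not guaranteed, only
  monotone improvement with beam width.
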
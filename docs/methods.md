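# Methods

## The model

For n individuals genotyped at p SNPs, let X be the n x p dosage matrix
({0,1} for inbred lines, {0,1,2} outbred) and Y the phenotype vector.  The
scan estimates the linear-with-interactions model

    Y = X theta_1 + Z theta_2 + eps,        Z = X * X,

where Z is the partial face-splitting (transposed Khatri-Rao) product: one
column per unordered SNP pair (i, j), i < j, holding the elementwise
product x_i ∘ x_j; self-products are excluded, so Z has p(p-1)/2 columns.
Narrow-sense heritability is var(X theta)/var(Y); the broad-sense analog
allows an arbitrary genetic function f(X).  The estimator's output is a
signed effect per term (single SNP or pair), not a p-value: detection is a
sparse-recovery problem, and selection is "take the N* largest |theta|"
rather than multiple testing with FDR control.

## The compressed piecewise solver

The full term dictionary (p + p(p-1)/2 columns) is partitioned by a block
plan: the p SNPs are cut into blocks of B consecutive SNPs; each diagonal
block contributes a singles-only piece and an intra-block pair piece, each
off-diagonal block pair a cross-pair piece.  Every term is *reported* by
exactly one piece; the parent blocks' singles enter pair pieces as
unreported covariates.  Within a piece with standardized design M (n x d)
and centered Y, the compressed ridge estimate is

    c     = (A M'M A' + lambda I_m)^{-1} A M'Y
    theta = A' c,

with A an m x d seeded random sketch (gaussian N(0, 1/m) by default, or
±1/sqrt(m) rademacher), computed via B = M A' so the d x d Gram is never
materialized (O(n d m + m^3) per piece).  Estimates can be averaged over
several independent sketches; the decompression error A'c - ridge solution
is zero-mean over A, so averaging suppresses it at rate 1/S.  When the
sketch-dimension rule

    m = min(d, ceil(c_sketch * k_max * ln d)),   c_sketch = 8, k_max = 50

reaches d — which it does for every desk-scale piece — the solver takes
the exact path (algebraically A = I) and the piece estimate is exact ridge.
The ridge solve switches between primal (d x d) and dual (n x n) normal
equations by aspect ratio.

### Ridge strength

The default penalty is lambda = 10 * trace(G)/dim(G) with G the (sketched)
Gram — i.e. roughly 10n on standardized columns.  This is deliberately
strong.  In the very-high-dimensional regime (piece dimension ~2n or more)
the Gram is singular and a *weak* penalty lets the inverse amplify
null-coordinate noise until the global top-k is pure noise: with the
conventional weak default (0.1 * trace/dim) top-10 recall of planted pairs
in the 1000-SNP landscape is exactly 0.  Recall as a function of the
multiplier is flat for 10-100 (a strong-shrinkage plateau where the scan
behaves like a stabilized, partially decorrelated marginal-correlation
screen); 10 is the smallest plateau value.  lambda is overridable per
config, and the identity-sketch/lambda->0 limit reproduces OLS exactly.

### Block size

Default B = clip(round(sqrt(2n)), 32, 500): a piece then holds about 2n
terms, keeping each piece at the edge of the regime the ridge screen
handles well, while 500 caps memory at real-data scale.  The landscape
scenarios pin B = 45 so the whole n-grid (1000..10,000) is solved by one
configuration.

### Why no compression at desk scale

Sketching below the piece dimension was measured, not assumed away:
forcing m = d/2 with sketch averaging on the 1000-SNP landscape collapses
top-10 recall from ~0.33 to ~0.04.  At n=1000 and h2=0.2 a planted pair's
signal sits ~4.4 sigma above the sampling noise while the maximum of
500,500 null coordinates sits at ~4.5 sigma — there is no headroom for
decompression noise.  Compression is therefore an asset only when the
sketch budget m far exceeds the per-piece dimension needed for recovery,
as it does at the method's intended genome scale (hundreds of thousands of
SNPs, where m ~ c k log d is thousands against billions of terms).

### Debiasing refit (off by default)

The scan ranking has one structural failure mode: in inbred coding a
product column x_s ∘ x_k correlates with its parent x_s at 0.577, so a
strong *simple* effect spawns ~p "relative" pair terms whose screened
scores exceed weak true pairs, while a joint weak-penalty solve instead
dilutes the simple effect across those same relatives.  When simple and
pair effects coexist, the optional debiasing stage fixes this: pool the
top pool_factor * N* (default 500) scan candidates, select up to N* terms
by orthogonal matching pursuit (greedy residual correlation with
re-orthogonalization — this is what conditions the relatives away), and
refit the selected support by OLS.  Selected terms then carry debiased
estimates and a positive support score; the mixed-architecture scenarios
enable it.  For pure-pair landscapes the scan ranking itself is reported,
matching the design in which ranked raw effects are the method's output.

### Ranking scale

Terms are ranked by the standardized-scale |theta| (effect per SD of the
term column); the raw-dosage-scale effect (theta_std / sd(column)) is also
reported, since it is the interpretable "effect relative to the reference
coding".  Ranking on the raw scale would divide by column SD and inflate
low-MAF pair noise (measured: landscape recall drops from 0.30 to 0.13).
Ties break lexicographically by (kind, i, j).

## Simulations

Genotypes are i.i.d. binomial dosages (Bernoulli(0.5) inbred by default).
The architecture disperses non-null terms over simple, pair and quadratic
coordinates; effect magnitudes are uniform on [0.5, 1.5] with random sign
(the original effect-size distribution is not printed anywhere; this
spread makes replicates contain both easy and hard signals).  Pair effects
are either raw products (theta * x_i x_j) or two-locus penetrance lookups:

    type 1  mu (1+t)^(i+j)   multiplicative within and between loci
    type 2  mu (1+t)^(i*j)   two-locus multiplicative interaction
    type 3  mu (1+t) [i>=1 and j>=1]   threshold

Penetrance lookups are centered and scaled to unit SD before multiplying
by the signed effect, so all three types inject the same per-term variance
and "type 3 is harder" statements compare detectability at matched signal
strength, not at different variances.  t = 0 collapses all types to a null
table (the simulator then emits pure noise).  Quadratic effects alias with
simple effects in inbred coding (x^2 = x) and are merged with a warning.

Noise is Gaussian with sigma^2 = var(g)(1 - h2)/h2 computed from the
realized genetic variance, so var(g)/var(Y) -> h2; "random" noise mode
jitters sigma uniformly in [0.8, 1.2] sigma_0 per replicate.  Split-h2
traits standardize the additive and epistatic genetic components
separately and mix them as sqrt(h2_a) g_a + sqrt(h2_p) g_p +
sqrt(1-h2_a-h2_p) eps.

What the simulations do *not* emulate: linkage disequilibrium, population
structure, MAF spectra, missingness.  Passing recovery tests here shows
the estimator works under independent common variants; on real data,
structure correction and LD-aware interpretation remain the user's
responsibility.

## Evaluation, heritability and prediction

Recall@k is |top-k ∩ truth| / |truth| (exact (i, j) match; an optional
±w-SNP window exists for real-data-style evaluation but is off).  For
landscapes whose planted truth is purely epistatic the ranking is taken
over the interaction map (pairs only): diagonal parents of strong pairs
carry genuine marginal signal and would otherwise displace weak true pairs.

PCR heritability: SVD of the standardized selected-feature matrix, OLS of
Y on the top-c component scores, adjusted R^2 = 1-(1-R^2)(n-1)/(n-q-1)
with q = c, over a component grid (default 1,2,5,10,20,30,50, truncated at
rank).  Retrieved heritability is the max-over-grid gap between the
[1D+2D] and [1D] curves, with [1D + random 2D] as the control.  Note the
1D plateau estimates the *linearly accessible* variance: for Bernoulli(0.5)
dosages a product column decomposes into two additive parts (variance 1/16
each) plus a pure interaction part (1/16) out of 3/16 total, so 2/3 of
each product-epistasis term is visible to 1D features and only the
remaining third is "missing".

Prediction study: 50/50 stratified train/test split; scans and feature
selection (top 30 singles + top 30 pairs by default) use the train half
only; quantile-binned classes (3 or 5; boundary ties to the lower class);
standard classifier families (logistic, L1/elastic-net logistic, SVM,
random forest, gradient boosting, small MLP) with documented small
defaults; the score is the maximum per-class one-vs-rest F1 ("best
predicted class"), and the headline statistic is the fraction of paired
(model, trait, classes, features) runs where true 2D features strictly
beat random 2D features.

## Problem sizes and numerical choices

Stock scenarios (also what tests and the acceptance script run): the dense
small landscape (p=100, n=5000, 2 simple + 3 pairs, h2=0.5, 20
replicates); the sparse landscape (p=1000, 500,500 terms, 10 pairs, h2 in
{0.05..0.4}, n in {1000..10,000}, 20 replicates at n=1000; large-n checks
use 2 replicates since one replicate is ~3 CPU-minutes); Marchini-type
outbred runs (p=100, n=2000, 5 pairs, h2=0.4, 15-20 replicates).  Solves
use float32 designs with float64 decompressed estimates (the Cholesky is
well conditioned under the strong ridge; the identity/OLS paths run in
float64 and agree with references to 1e-8).  All randomness flows from
root seeds through named SeedSequence paths, so every scenario, sketch,
permutation and split replays byte-identically.

## Known limitations

- The n=10,000 landscape cell recovers more signal (~0.65 top-10 recall)
  than the ~0.50 a fixed-compression-budget solver reports at that size;
  with exact per-piece solves the large-n ceiling is statistical, not
  sketch-limited.
- No mixed-model kinship correction: on structured populations the scan
  inherits marginal-screen confounding.
- Pyramids materialize dense levels; fine for p up to ~20k (level 0 is
  p x p); genome-scale maps need tiled/streamed export, which the block
  structure supports but this implementation does not stream.
- 3rd-order interactions are out of scope.
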
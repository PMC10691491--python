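# Methods

## Scope and data model

The pipeline operates downstream of denoising: its inputs are a
samples × taxa table of non-negative integer counts, sample metadata
(host plant × compartment × replicate), a rooted phylogeny with branch
lengths covering the taxa, and — for the functional arm — gene count
tables with lengths and category annotations.  On disk, count tables
follow the amplicon convention (taxa in rows); in memory everything is
samples × taxa.  All randomness flows through explicit integer seeds via
`numpy.random.default_rng`, so every stage is bit-reproducible.

## Alpha and beta diversity

Rarefaction subsamples each sample without replacement to a common
depth (default: the minimum per-sample total; shallower samples are
dropped with a logged warning).  Chao1 uses the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)), which stays finite when doubletons are
absent.  Shannon entropy uses the natural log by default; the base is a
flag because conventions differ across toolchains.  Good's coverage is
1 − F₁/N.  Bray-Curtis, PERMANOVA and NMDS operate on raw counts by
default; rarefying first is the caller's choice.

PERMANOVA is single-factor: SS_total = (1/N)Σ_{i<j} d²ᵢⱼ, SS_within the
group-size-weighted analogue, pseudo-F with (a−1, N−a) degrees of
freedom, and p = (#{F_perm ≥ F_obs}+1)/(n_perm+1) over label
permutations (default 999; the add-one rule keeps p > 0).  Multi-factor
designs are handled by concatenating labels (one-hot joint factor), not
by sequential sums of squares; the joint factor therefore always
explains at least as much variance as either margin.  NMDS delegates to
SMACOF with isotonic regression (non-metric, ties averaged) restarted
from several random configurations, reporting Kruskal stress-1.
Degenerate distance matrices (all zeros) return R² = 0, pseudo-F = NaN,
p = 1.

## Differential abundance

The enrichment arm re-implements the classic count-based exact-test
workflow for small balanced designs:

1. filter taxa at overall relative abundance strictly above 0.01%
   (computed over the samples being compared);
2. TMM scaling factors — reference sample chosen by the
   75th-percentile rule, log-ratios trimmed 30%/tail and average
   abundances 5%/tail (symmetric floor-based trim), precision-weighted
   mean, factors normalized to geometric mean 1.  This matches
   Bioconductor edgeR's `calcNormFactors` to machine precision on the
   test fixture;
3. counts scaled to the geometric-mean effective library size (a linear
   pseudo-count adjustment; the full quantile-to-quantile adjustment was
   deliberately not replicated — observed p-value differences against
   edgeR are < 0.11 on the log10 scale with rank correlation > 0.99);
4. a common dispersion estimated by conditional maximum likelihood
   (per-taxon group sums condition out the means; one 1-D bounded
   optimization over log φ).  Tagwise shrinkage is intentionally
   omitted: at n = 6 per group a common dispersion is adequate and far
   easier to reason about;
5. the two-sided exact test conditions each taxon's group split on its
   total: split probabilities come from NB(n_g·μ, φ/n_g) sums, and the
   p-value sums all splits whose probability does not exceed the
   observed one (the "small-p" two-sided rule).  Non-integer pseudo-sums
   are handled by linear interpolation between the flanking integer
   splits.  φ = 0 is the exact Poisson limit, where the conditional law
   is binomial — the oracle used in tests;
6. BH adjustment, then the strict label rule: enriched ⇔ FDR < 0.05 and
   log₂FC > 1; depleted symmetric; everything else ns.  Fold changes
   use a 0.5 prior count on normalized group means.

## Assembly-process partition

βMNTD is abundance-weighted by default (presence-absence by flag); a
shared taxon contributes distance 0.  The βNTI null shuffles taxon
labels across **all** tips of the phylogeny — including tips absent
from the pair — because the question is whether the realized
communities are more (or less) phylogenetically clustered than a random
draw from the whole pool.  Restricting the shuffle to observed taxa
silently conditions on the selection outcome and destroys the
homogeneous-selection signal.  The same permutation set is applied to
every pair.  Pairs with null SD ≤ 1e−12 (identical communities, star
phylogenies) are flagged degenerate, given βNTI = 0, and classified by
RC_bray alone.

RC_bray follows the abundance-based Raup-Crick construction: each null
community draws its observed richness of distinct taxa with probability
proportional to occupancy (weighted sampling without replacement via
Gumbel top-k), seeds one read per drawn taxon, and allocates the
remaining reads multinomially with regional-abundance weights.  Ties
between null and observed dissimilarity count half.  The enumeration
oracle (`rc_bray_exact`) computes the same quantity exactly by summing
over all subsets (sequential-sampling probabilities summed over
orderings) and all read allocations; it is tractable for pools of ≤ ~5
taxa and a few reads, which is exactly the regime used to validate the
Monte-Carlo estimator (max gap ≤ 0.05 at n_null = 9,999).

Classification is strict: βNTI > 2 → heterogeneous selection,
βNTI < −2 → homogeneous selection, otherwise RC > 0.95 → dispersal
limitation, RC < −0.95 → homogenizing dispersal, else drift.  Values
exactly at a threshold fall to the stochastic/drift side.  Process
fractions are computed over within-group pairs.

## The synthetic metacommunity generator

The generator exists to give every stage a ground-truth test bed, so
its design is dictated by recoverability:

- **Phylogeny**: pure-birth (Yule) trees — only relative cophenetic
  distances matter to βMNTD.  **Traits**: Brownian motion from a root
  value of 0, so trait covariance equals rate × shared path length and
  selection regimes are phylogenetically detectable.
- **Regional pool**: lognormal(0, 1.5) base abundances emulate the
  rank-abundance skew of amplicon data.
- **Regimes**: selection multiplies base abundance by a Gaussian niche
  filter exp(−s·(trait − E_g)²) with a per-group environment E_g
  (equal E_g across groups = homogeneous-selection test bed, distinct
  E_g = heterogeneous); dispersal limitation restricts each group to a
  private random subset covering `dispersal_rate` of the pool; drift
  uses the shared pool for every sample.
- **Demographic noise**: every sample's taxon weights are additionally
  multiplied by a lognormal(0, σ_d) jitter (default σ_d = 0.35).  This
  models ecological drift proper — replicate communities diverging by
  demographic stochasticity.  Setting σ_d = 0 recovers exact
  multinomial resampling of one vector, which is the *complete-mixing*
  end-member: the Raup-Crick null then sees observed pairs as far more
  similar than chance (RC → −1, homogenizing dispersal), which is the
  ecologically correct reading of that limit.  A drift regime that the
  classifier should *call* drift therefore requires σ_d > 0.
- **Depth**: Poisson around the configured expectation, counts
  multinomial.

### Frozen study conditions

Chosen once, for realism and cross-seed robustness, during generator
design (verified on ≥ 3 seeds each); they are shared verbatim by the
test suite, `analysis/` scripts and `scripts/acceptance.py`:

| experiment | pool | depth | key knobs |
|---|---|---|---|
| heterogeneous selection | 300 taxa | 2,000 | strength 2, E = ±2, σ_d 0.35 |
| homogeneous selection | 1,200 taxa | 1,000 | strength 10, shared E = 1, σ_d 1.0, pooled over 3 replicate runs |
| drift | 300 taxa | 2,000 | generator defaults |
| dispersal limitation | 300 taxa | 2,000 | rate 0.2, otherwise matched to drift |

Homogeneous selection is the hardest signature: it needs per-sample
richness ≪ the trait-eligible set ≪ the pool, so that replicate
communities hold *different but closely related* taxa.  Hence the
larger pool, narrower niche and stronger demographic noise, and the
pooling over three replicate simulations (a single tree realization
leaves the modal class at the mercy of where the trait-dense clades
happen to sit).

The βNTI null calibration (drift communities, no trait structure)
similarly pools three independent pools (9 samples each, 108 pairs,
999 randomizations).  Per-evaluation means still fluctuate by roughly
±0.3 across seeds because pairs within a data set share one tree; over
30 independent realizations the grand mean is −0.06 ± 0.07, i.e. the
z-scores are unbiased.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific PCR bias, bacterial-vs-fungal biology, and environmental
covariates beyond a single niche axis.  Passing the recovery tests
shows the estimators respond correctly to planted assembly processes at
desk scale; it does not certify their power or calibration on real
tables, whose depth (10⁴–10⁵ reads) and richness (10³–10⁴ ASVs) are one
to two orders of magnitude larger.

## Co-occurrence networks

Dominant taxa (> 0.01% overall relative abundance, present in at least
⌈n/3⌉ samples) are rank-correlated with average-rank ties; constant
taxa get ρ = 0, p = 1 and can never seed an edge.  The RMT threshold
scans cutoffs 0.30–0.95 (step 0.01): at each cutoff the thresholded
matrix's eigenvalue spectrum is unfolded with a degree-7 polynomial fit
of the cumulative spectral density (duplicate eigenvalues merged), and
the nearest-neighbour spacing histogram is compared by chi-square to
the Poisson (e^{−s}) and Wigner-Dyson GOE ((πs/2)e^{−πs²/4}) forms; the
smallest cutoff where Poisson fits better wins.  Degenerate spectra at
every cutoff (e.g. an identity matrix) fall back to the scan maximum
with a warning, and matrices under 20×20 are rejected in favour of a
fixed threshold.  Edges additionally require BH-adjusted correlation
p < 0.05 (switchable off); betweenness is computed on the unweighted
graph with signs kept as attributes.  Keystone taxa: nearest-rank 80th
percentile of degree defines the high-degree set H; within H the
⌈0.2|H|⌉ lowest-betweenness nodes (ties included) are flagged, so a
non-empty H always yields at least one keystone.

## Functional comparison

TPM first, aggregation second (the reverse is not equivalent and is
deliberately fixed): tpm_g = (count_g/length_kb_g) normalized to 10⁶
per sample, category abundance = sum of member-gene TPM (a gene in two
categories counts in both).  Welch t-tests per category, BH across
categories; significance stars follow the raw p (as figure legends do)
with FDR reported alongside.  Fold changes use a 0.5-TPM prior and are
capped at ±20 with a flag when a category is absent from one group.

## Numerical choices and degenerate inputs

- Exact-test tie tolerance 1e−10 on log-probabilities; RC_bray tie
  tolerance 1e−10 on Bray-Curtis values (counts are integers, so true
  ties are exact).
- PERMANOVA p is never 0 (add-one); NMDS ties in the isotonic fit are
  averaged (primary approach).
- βNTI batches null permutations (64 at a time) to bound memory on
  large tip sets.
- Problem sizes throughout the tests and the acceptance script (pools
  of 300–1,200 taxa, depths 800–2,000, 199–999 randomizations) were
  chosen as the smallest at which the statistical behaviour under test
  is stable across seeds.

## Known limitations

- The exact test's library-size equalization is linear scaling, not
  quantile adjustment; p-values differ slightly from edgeR in extreme
  tails.
- RMT thresholding needs a reasonably rich spectrum; small or highly
  structured matrices fall back or error by design.
- The assembly classifier inherits the known sensitivities of the
  βNTI/RC_bray framework: results depend on tree quality and on the
  regional-pool definition (here: all taxa in the table).
- Single niche axis; no spatial structure; no temporal dynamics.
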
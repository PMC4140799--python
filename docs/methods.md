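# Methods

## The inference problem

In haplodiploid social insects, males develop from unfertilized eggs
and are haploid; workers are diploid daughters of one queen. In a
colony headed by a single, multiply mated queen, every worker carries
exactly one maternal and one paternal allele per locus. Given worker
multilocus genotypes at polymorphic microsatellite loci, the package
reconstructs (i) the queen's diploid genotype, (ii) the set of paternal
haplotypes (patrilines) and each worker's patriline membership, and
(iii) from the patriline worker counts, the colony's mating-system
statistics.

## Worker filtering

Workers typed at fewer than 3 loci (configurable `min_loci`) are
excluded before inference; all downstream sample sizes `n` refer to the
retained workers. With no missing data nothing is excluded.

## Queen inference

A candidate queen genotype must supply one allele to every retained
worker at every typed locus. Up to `max_foreign` workers (default 2)
may be set aside as unexplained — workers that plausibly drifted in
from another colony, e.g. after colony fission.

The search has two stages:

1. **Screen.** Per locus, all allele pairs drawn from the observed
   alleles that explain all but at most `max_foreign` typed workers are
   enumerated and scored by a single-locus log-likelihood: the
   Hardy–Weinberg prior of the pair times, per worker, the sum over
   compatible (maternal, paternal) resolutions of the maternal
   segregation probability (½ if the queen is heterozygous, 1 if
   homozygous) times the paternal allele's population frequency. The
   segregation factor is essential: it is what separates a true
   homozygous queen from a spurious heterozygote whose second allele no
   worker ever inherited. Because these scores are additive across
   loci, whole-genotype candidates are generated in descending score
   order by a best-first search over the product of per-locus lists
   (k-best merge), with a fixed penalty per unexplained worker.
2. **Refine.** The leading candidates are re-scored at partition level:
   patrilines are assigned (below) and the log-likelihood charges each
   paternal allele **once per patriline** rather than once per worker
   — the screen's worker-level approximation over-penalizes a rare
   allele whose father happened to sire many workers — plus a ½
   segregation factor per worker per queen-heterozygous typed locus.
   Candidates are ranked by (fewer unexplained workers, fewer implied
   patrilines, higher partition likelihood); `support` is the softmax
   of the partition log-likelihoods over the refined candidates.

On simulated mid-size colonies (10 loci, 8 alleles, 12 patrilines, 100
workers, 2% missing data) the top candidate equals the generating queen
in 100/100 replicates (`tests/test_inference.py`). If no candidate
explains all but `max_foreign` workers the colony is flagged as not
single-queen (`MultiQueenError`).

## Patriline assignment (parsimony)

Per worker per locus the paternal allele is whichever worker allele
leaves a queen allele behind; when the worker's genotype equals a
heterozygous queen's, both resolutions are kept as a 2-allele set.
Workers are then grouped into the minimum number of patrilines such
that each group's allele sets intersect at every locus (a single father
haplotype can explain the group):

- Workers fully typed and unambiguous are grouped by exact haplotype
  identity (a hash join — they dominate the sample).
- The remaining "flexible" workers (ambiguous or missing loci) are
  placed by exact branch-and-bound over group assignments when at most
  25 such workers exist (with a 500k-node budget; exhausted budgets
  fall back to the greedy rule), and greedily otherwise: join the
  largest compatible group, ties by haplotype probability. Flexible
  workers never found a new patriline unless incompatible with every
  existing one, so missing data cannot inflate `k_obs`.
- Ties among equally parsimonious partitions are broken by the larger
  product of best-resolution haplotype probabilities, then
  lexicographically — assignment is deterministic given input order.

On toy instances (≤ 6 workers) the patriline count equals the
exhaustive set-partition minimum; across the studied (k, n) regimes
(k ∈ 5…26, n ∈ 8…154) the inferred `k_obs` equals the number of truly
sampled patrilines in ≥ 95% of simulations, and never exceeds it
(sampling can miss fathers, not invent them, up to the non-detection
error below).

Two distinct fathers are merged only if they share the entire
multilocus haplotype; the probability of that collision is the
**non-detection error** Π_loci Σ_a p_a², reported per colony (order
10⁻⁹–10⁻² for realistic panels of 3–11 polymorphic loci).

## Paternity-frequency estimators

- `k_est = k_obs (1 + e^{-n/k_obs})`: per-patriline counts are modelled
  as Poisson with mean n/k_obs and the expected zero class is added
  back. The single-step form is used (not the iterative solution of
  k(1 − e^{−n/k}) = k_obs): it reproduces all ten bundled reference
  values to 2 decimals, which pins the convention (regression-tested).
- `m_e` uncorrected (Starr): 1/Σ p_i², p_i = n_i/n. Bounded by
  [1, k_obs], maximal at even shares.
- `m_e` corrected (Nielsen et al. 2003):
  `(n−1)² / [(n+1)(n−2) Σ p_i² + 3 − n]` — removes the upward bias of
  squared sample proportions; may exceed `k_obs` at small n (that is
  expected behaviour, not an error); undefined for n < 3 or a
  nonpositive denominator (returned as None). Under even paternity
  (k = 20, n = 100) its mean over 200 simulations is within ±0.5 of 20
  and its bias is smaller than the uncorrected estimator's.
- `g_ww = 0.25 + 0.5/m_e` uses the **uncorrected** m_e: the pedigree
  expectation for worker–worker regression relatedness under
  outbreeding.
- Species summaries: arithmetic means of `k_obs`/`k_est`, harmonic mean
  of `m_e` (the relatedness-relevant average), with delete-one
  jackknife-over-colonies SEs. The jackknife is the standard
  `sqrt((m−1)/m Σ (θ̂_(i) − θ̄)²)`; note this convention can differ
  from SEs printed by other software.
- Table output rounds half-up to 2 decimals; all internal computation
  is full precision.

## Paternity skew

**B-index** (Nonacs): `B = Σ (p_i − 1/k)² − (1 − 1/k)/n`, expectation 0
under uniform multinomial allocation (verified to ±0.002 over 10,000
draws at k = 18, n = 115). One-tailed empirical p-values compare the
observed B to 1,000 uniform-multinomial simulations with add-one
smoothing, `(count + 1)/(n_sims + 1)`, so no p-value is exactly zero;
the type-I error at the 5% level calibrates to 0.05 ± 0.01. Undefined
for a single patriline.

**S-index** (Pamilo): `S = (k_obs − m_e)/(k_obs − 1)`; 0 = even,
1 = monopoly. Negative values (possible when corrected m_e > k_obs) are
conservatively clamped to zero skew and flagged. Because sampling alone
inflates S, each colony gets a 95% Monte-Carlo null interval: n workers
assigned uniformly at random to the k_obs observed patrilines, m_e and
S recomputed, 3,000 iterations, 2.5th/97.5th percentiles by type-7
(linear-interpolation) percentiles. The estimator used inside the null
matches the estimator used for the observed S (corrected by default;
both available). For k = 2, n = 4 the interval agrees with exhaustive
enumeration of all 16 assignments.

## Population structure

- **H_O** from one randomly chosen worker per patriline (seeded;
  optional multi-redraw averaging), which removes most of the family
  structure of a colony sample. **H_S** is Nei's unbiased gene
  diversity `(2N/(2N−1))(1 − Σ p_a²)` from the deduced parents, N the
  diploid-equivalent gene-copy count.
- **F_IS = 1 − H_O/H_S** per locus; the summary is the mean of
  per-locus values (the ratio-of-means alternative differs slightly
  and is not used), with a jackknife SE and two-sided one-sample t
  (df = loci − 1). Mean F_IS on simulated outbred colonies is 0 within
  ±0.03.
- **F_ST**: Weir–Cockerham θ (1984 variance components, summed over
  alleles and loci) treating colonies as subpopulations. Haploid males
  enter as single gene copies: sample sizes are diploid-equivalents
  (gene copies / 2) and males contribute no heterozygosity term; the
  homozygote-diploid male convention used by legacy diploid software is
  available where genotypes are exported (GENEPOP writer). SE by
  delete-one-locus jackknife; the default test is one-tailed for
  θ > 0 with df = loci − 1. Balding–Nichols simulations at θ = 0.05
  (20 demes, 10 loci) are recovered within ±0.02.
- **Relatedness**: symmetrized Queller–Goodnight regression
  relatedness; per focal individual with allele positions {a}, locus
  terms num = Σ_a (P_other(a) − p_a), den = Σ_a (P_focal(a) − p_a),
  summed over both directions, all pairs, and loci (ratio of sums),
  with delete-one-locus jackknife SE. Haploid males have one allele
  position. Self-relatedness is exactly 1; unrelated pairs average 0;
  workers of a singly mated queen average 0.75, and r_ww tracks
  g_ww = 0.25 + 0.5/m_e across k ∈ {1, 2, 5, 10, 20} within ±0.03 —
  the diagnostic for absence of inbreeding. Estimates are reported raw
  (not clamped to [−1, 1]). Reference frequencies are supplied by the
  caller; the pipeline pools all deduced parents (per-colony exclusion
  is available via the same API).

## Cross-species comparative analyses

PGLS under Brownian motion: V[i,j] is the shared root-to-ancestor
branch length; intercept, slope and σ² are fitted by maximum
likelihood, the slope tested by likelihood ratio against the
intercept-only model (χ², df = 1), and R² computed in the V-whitened
space. On a star phylogeny the fit equals OLS to 1e-8. Skew is
transformed log10(S + 1) (zero-safe) and colony size log10(x) before
regression; base 10 is a convention (the base only rescales slopes).
Brownian motion is the only covariance model (no Pagel's λ).

Because S is computed from k_obs, a negative S-on-k_obs association is
expected a priori. The null slope interval refits the PGLS 100 times
with one random uniform-allocation null S per species (negative draws
treated as zero) and takes the 2.5th/97.5th slope percentiles; an
observed slope below the lower limit is steeper than sampling alone
explains.

Correspondence analysis: patriline worker counts are ranked descending
within each group (species or colony) to make rows comparable across
groups, then the rank × group table is decomposed as total
χ² = Σ (o − e)²/e with df = (rows − 1)(columns − 1); each column's
relative inertia is its share of the total χ². Zero-margin rows and
columns are dropped with a warning.

## Synthetic colonies

The generator emulates the study system: a diploid queen and k haploid
mates drawn from population allele frequencies; paternity shares
p ~ Dirichlet(α, …, α) — α is the single skew knob, from near-even
(α → ∞) to heavily skewed (small α); worker counts multinomial(n, p);
each worker one random queen allele plus the father's allele per locus;
worker-locus entries masked missing at a configurable rate.
Substructure follows Balding–Nichols: subpopulation frequencies
~ Dirichlet(p_global (1 − θ)/θ), so θ maps directly to the expected
Weir–Cockerham differentiation and recovery tests are quantitative.
Defaults (10 loci, 8 alleles, 18 mates, 100 workers, 2% missing, 3
colonies) mirror a mid-range genotyped colony; the studied ranges are
3–11 polymorphic loci, 5–26 patrilines and 8–154 workers per colony.
Colony streams are spawned from the master seed, so adding colonies
never perturbs earlier ones.

For the comparative stage, `simulate_skew_gradient` builds a 9-species
set on a fixed 9-tip tree with k spanning 5–26 and Dirichlet
concentration α = 0.05 k²: queens equalize paternity increasingly with
mate number, the mechanism under test. The 0.05 scale was chosen to
make the realized S values span roughly 0.02–0.3, the empirically
realistic range; with 3 colonies of 100 workers per species the fitted
PGLS slope of S on k_obs (≈ −0.005) falls below the randomized null
interval in all of 20 pilot replicate sets. `simulate_species_set`
additionally provides plain Brownian predictor/response traits for
PGLS parameter-recovery tests.

What the generator does **not** emulate: genotyping error other than
missingness, null alleles (available behind a flag is out of scope;
the data model supports excluding an affected locus via the panel),
stepwise mutation structure among alleles, physical linkage, and
polygyny. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to scoring
artefacts in real chromatograms.

## Numerical and design choices

- Percentiles: numpy's default linear interpolation (type 7), pinned in
  tests.
- Rounding for table display: half-up via `decimal`, 2 decimals.
- Empirical p-values: add-one smoothing.
- GENEPOP output: 3-digit diploid coding, one POP per colony, males as
  homozygous diploids, queens duplicated (each parent contributes four
  gene copies, weighting queen and male genomes equally in diploid
  software). Alleles ≥ 1000 are an encoding error.
- Allele-frequency weighting of parents: `gene_copy` (males 1 copy,
  queens 2) is the statistically neutral default; `duplicated_diploid`
  (males 2, queens 4, matching duplicated-diploid input files) is kept
  for reproduction runs.
- The exact parsimony solver is capped (25 flexible workers / 500k
  nodes) because empirical instances are small; beyond the cap the
  greedy rule applies and is the documented approximation.
- Known limitations: queen inference assumes a single queen (polygyny
  is flagged, not partitioned); the jackknife SE convention for
  species summaries may differ from other software; MATESOFT-style
  queen posterior probabilities are not reproduced numerically —
  `support` is defined by the partition likelihood above.
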
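# Methods

## The problem

"Genomic heritability" — the proportion of phenotypic variance a linear
regression on a marker panel can explain — is routinely estimated with
G-BLUP / GREML-type mixed models. But the parameter those models define
(a variance of *random* marker effects, conditional on *fixed* genotypes)
is not the quantitative-genetic parameter one usually has in mind, where
genotypes vary across the population and effects are fixed population
quantities. This package implements the population-parameter algebra that
makes the distinction precise, and a Monte Carlo study that measures what
maximum-likelihood G-BLUP estimates actually converge to when the marker
panel contains, overlaps with, or is independent of the causal loci.

## Population-parameter algebra (`quantgen_params`)

All parameters refer to a conceptual population whose genotypes we hold in
full, so covariances use divisor `n` and nothing is a sample estimate.
With centered QTL dosages `z` (q loci) and marker dosages `x` (p loci):

* allele-substitution effects: `alpha = Sigma_z^{-1} Cov(z, g)` — the
  population regression of genetic value on QTL allele content;
* additive variance: `sigma2_a = alpha' Sigma_z alpha`, LD cross-terms
  included (under linkage equilibrium it collapses to
  `sum_j 2 theta_j (1-theta_j) alpha_j^2`);
* marker effects: `beta = Sigma_x^{-1} Sigma_xz alpha` — a *projection* of
  QTL effects onto the marker span, so marker effects are linear
  combinations of QTL effects, never free parameters;
* genomic variance: `sigma2_g = beta' Sigma_x beta
  = alpha' Sigma_zx Sigma_x^{-1} Sigma_xz alpha`; the residual
  `sigma2_gbar = sigma2_a - sigma2_g` is the quadratic form of the Schur
  complement `Sigma_z - Sigma_zx Sigma_x^{-1} Sigma_xz`, hence >= 0;
* genomic heritability: `h2_g = h2 * sigma2_g / sigma2_a`.

Consequences carried by the implementation and verified by tests: the
parameters are invariant to invertible recodings of the markers; when the
causal loci are all in the panel, `beta` equals `alpha` on the QTL columns
and 0 elsewhere, so `h2_g = h2` (no missing heritability with sequence
data, whatever the LD); for a single marker–QTL pair `h2_g = r^2 h2`; for
mutually-LE pairs the genomic variance decomposes into per-pair terms.
The contrastive IID-effects variance `sigma2_u = sigma2_b sum_j
2 pi_j(1-pi_j)` (or `p sigma2_b` standardized) is provided only to show
what ignoring LD does — in the bundled one-QTL/two-marker example it gives
2/9 where the LD-aware value is 1/3.

Numerics: covariance matrices are symmetrized as `(M + M')/2`; linear
solves fail loudly when the condition number exceeds 1e12, naming the
collinear columns (duplicate markers are the usual culprit); a
Moore–Penrose fallback sits behind an explicit `allow_pinv` flag. The
dense whole-population driver is capped at 5,000 loci; blocked genomes use
`blocked_variance_decomposition`, which exploits between-block linkage
equilibrium to reduce `Sigma_x^{-1}` to per-block inversions (blocks with
perfectly collinear loci, e.g. copy probability 1, fall back to the
pseudo-inverse for that block — `sigma2_g` is invariant to the choice of
generalized inverse on the realized span).

## Genome simulator (`synthetic_genomes`)

A genome is `n_blocks` mutually independent LD blocks. Within a block,
haplotypes follow a stationary two-state copy/refresh Markov chain: locus
`j+1` copies locus `j`'s allele with probability `c`, else redraws
Bernoulli(`theta`). Marginal frequency is `theta` at every locus and the
allele correlation at distance `k` is `c^k`, so diploid genotype r^2
decays geometrically within a block and is exactly 0 between blocks.
Haplotypes (2 per individual) are paired by a seeded permutation; dosage =
sum. Implementation note: a single uniform per transition serves both the
copy decision (`u < c`) and, conditionally on not copying, the refresh
draw (`u < c + (1-c) theta`) — distributionally identical to two draws
and half the RNG cost, which dominates population generation.

Defaults: `c = 0.8` in fixed-transition mode (adjacent genotype
r^2 = 0.64), `c ~ Beta(8, 2)` in random-transition mode (heterogeneous LD
across blocks), `theta ~ Uniform(0.1, 0.5)` per block. These are this
package's choices of "strong but variable short-range LD"; all are
configurable. Two designs mirror a short-block genome (5-locus blocks, one
QTL per selected block) and a long-block genome (50-locus blocks, QTL
positions uniform over loci).

RNG contract: one master seed; each block runs on its own deterministic
substream (`SeedSequence.spawn`), so enlarging the genome never perturbs
existing blocks, and identical seeds give bit-identical dosage matrices.
Monomorphic blocks are kept in the genome but their loci are dropped from
standardized relationship matrices and contribute nothing to covariances.

What the simulator does *not* emulate: recombination maps, mutation,
selection, population structure, relatedness beyond random mating, and
long-range LD. Passing tests therefore speak to the estimator's behaviour
under short-range block LD in unstructured populations — the regime of
distantly related individuals — not to any particular real genome. A
heterogeneous preset (random transitions, genome-random QTL, wider
frequency range) emulates the qualitative structure of a real-genotype
panel but makes no claim of matching any real data's numbers.

## Trait model (`trait_sim`)

`y_i = alpha' z_i + delta_i` with `alpha_j ~ iid N(0,1)` and
`delta ~ N(0, sigma2_delta)`. The residual variance is calibrated against
the *realized* `Var(alpha'z)` of each simulated population, so
`h2 = sigma2_a / (sigma2_a + sigma2_delta)` equals its target (default
0.5) to machine precision in every replicate. Phenotypes are centered on
the full population mean before any subsampling. Note one convention
wrinkle: the calibration's `sigma2_a` is the realized variance including
the O(1/sqrt n) cross-block sampling covariances, while the blocked
parameter algebra sets those to exactly zero; the two differ by ~1–2% at
n = 10,000 and the difference is reported, never hidden.

## Relationship matrices (`grm`) and ML fitting (`gblup_ml`)

GRMs are built from a locus subset (the six panels: QTL, QTL+MRK.LD, ALL,
MRK.LD, MRK.LD+MRK.LE, MRK.LE) under two scalings: `standardized_avg`
(unit-variance columns, `G = WW'/k`; mean diagonal ~1) — the default,
matching the standardized-genotype convention under which the IID-effects
variance reads `p sigma2_b` — and `vanraden` (centered columns,
denominator `sum_j 2 p_j (1-p_j)`). Centering/scaling statistics come
from the estimation sample, because that is all an analyst sees.
In the Monte Carlo driver the six panel GRMs are assembled from three
per-class cross-products via the exact partition identity
`G_AB k_AB = G_A k_A + G_B k_B` of the standardized scaling.

The fitter maximises the likelihood of `y ~ N(0, G sigma2_u + I
sigma2_e)`. Parameterising by `h = sigma2_u/(sigma2_u + sigma2_e)` and
rotating `y` into the eigenbasis of `G`, the total variance profiles out
analytically and the search is one-dimensional on `h in [0, 1)`: a
101-point grid locates the basin, bounded Brent refines to 1e-8.
Eigenvalues below `1e-10 * max(d)` are clipped to zero. Estimates exactly
at the `h = 0` boundary are allowed and flagged (and included in all
averages); a flat profile (e.g. `G = I`, where only the total variance is
identifiable) sets `identifiable = False`. ML, not REML, is the default —
phenotypes are generated centered so no fixed effects are fitted; a REML
switch (1-df Helmert reduction) exists for sensitivity analysis.

## The Monte Carlo study (`mc_study`)

Per replicate: simulate the population (default 10,000 individuals),
place 200 QTL, calibrate to h2 = 0.5, generate phenotypes, compute the
population h2 and the marker-panel h2_g, subsample 1,000 individuals
without replacement, build the six GRMs on the subsample and fit each by
ML. Replicates are keyed by `(master_seed, replicate_index)` and are
bit-reproducible and order-independent. Aggregation reports per-scenario
mean and SD (ddof = 1) of the estimates; `rank_bias` scores each scenario
against its estimand — trait h2 for QTL-containing panels, the panel's
h2_g for marker-only panels, ~0 for the LE-only panel — and reports the
two headline contrasts (SD inflation of ALL vs QTL and of MRK.LD+MRK.LE
vs MRK.LD).

Problem sizes: this package's default study runs the short-block design at
2,000 blocks x 5 loci (10,000 loci) with 100 replicates — chosen as a
desk-scale rendition of the 10,000-block, 3,000-replicate original so a
full study completes in minutes on one core. At this scale the QTL-panel
positive control reproduces the reference behaviour essentially exactly
(mean 0.498, SD 0.022–0.024), and the variance-inflation contrasts hold
with margin (SD ratio ALL/QTL ~3.8; adding LE markers to MRK.LD ~2.9).
The realized marker-panel h2_g (~0.36) is a function of the chain
parameters, which for the original study are not published; it is recorded
per run rather than asserted.

## Known limitations

* Between-block independence is exact in the generator, so the blocked
  parameter algebra is exact here but approximate for any genome with
  residual inter-block LD.
* The dense parameter path inverts `Sigma_x` and is deliberately capped;
  populations are not meant to exceed ~5,000 loci on that path.
* Only a single random effect (one GRM) is fitted; no covariates,
  multi-component models, or Bayesian posterior summaries.
* The IID-effects variance is implemented as a contrast, not an estimator;
  no LD-weighted GRM constructions are provided.
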
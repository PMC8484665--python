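# Methods

`finescale` analyses fine-scale population structure in small,
geographically close cohorts — the motivating system is a set of five
rural valley populations (labelled G, R, U, P, B) sampled along a ~140 km
west-to-east mountain transect — and infers their demographic history from
genome-wide variation. Every analysis in the package can be exercised
end-to-end on synthetic data from the built-in coalescent generator, so the
whole pipeline is testable without access to any cohort data.

## The demographic model

The generator simulates a three-level split model with msprime:

* five terminal populations G, R, U, P, B with effective sizes
  `Ne_G … Ne_B`;
* backwards in time, G and R merge into an ancestral population GR at
  `t_GR`, while U, P and B merge simultaneously (a trifurcation) into UPB
  at `t_UPB`;
* GR and UPB merge into the root population GRUBP at `t_GRUBP`.

Conventions and defaults:

* **Units.** Effective sizes are haploid chromosome counts; msprime's
  diploid population sizes are `Ne/2`. Split times are years before
  present, converted to generations at 29 years/generation and rounded to
  the nearest generation (monotone, so time ordering survives rounding).
* **Priors.** All parameters have uniform priors: root size
  U(15000, 40000); GR and UPB sizes U(1000, 5000); terminal sizes
  U(500, 2500) for G, R, P, U(200, 2000) for U and U(500, 10000) for B;
  `t_GRUBP` U(2320, 14500) years; `t_GR` and `t_UPB` U(870, `t_GRUBP`),
  i.e. with a symbolic upper bound resolved against the drawn root time
  (their marginal priors are therefore not uniform). Symbolic bounds are
  resolved by dependency order; cycles are a configuration error.
* **Migration.** Symmetric migration at rate `m` per generation connects
  all pairs of terminal populations. No canonical rate exists for this
  kind of cohort, so the prior is log-uniform on [1e-5, 1e-2] and `m = 0`
  is allowed (all structure-recovery checks use `m = 0` so that observed
  structure is attributable to drift alone).
* **Rates.** Mutation 1.25e-8 and recombination 1e-8 per bp per
  generation — standard human values; the model itself does not pin them.
* **Samples.** 6 diploids each for G, R, U, P and 5 for B (29 in total),
  matching a small-cohort design where one region lost a sample to
  quality control. Default sequence: one 5 Mb chromosome; desk-scale runs
  in this repository use 0.2–10 Mb depending on the statistic (noted per
  check below).
* **Coordinates.** A packaged west-to-east five-point configuration
  spanning 140 km with small north-south offsets, overridable by a sample
  map TSV. No cartographic accuracy is claimed; only relative planar
  distances matter to the spatial model.

Only segregating biallelic sites are returned (recurrent mutations that
restore monomorphism or create a third allele are dropped). The simulator
is checked against Watterson's expectation: with all splits collapsed to
one generation and equal sizes, the mean number of segregating sites over
200 replicates must match `theta * H_{n-1}` within 5%.

## Coancestry: painting, MDS, Procrustes, clustering

* **IBS distance.** `1 - IBS` from diploid dosages,
  `d(i,j) = mean |g_i - g_j| / 2` over pairwise-complete sites.
* **Classical MDS.** Torgerson scaling (double-centred squared distances,
  eigendecomposition). Negative-eigenvalue axes are dropped with a logged
  warning rather than imputed; requesting more axes than there are
  positive eigenvalues truncates with a warning.
* **Procrustes.** Symmetric Procrustes correlation
  `sqrt(1 - residual SS)` after centring/unit-scaling both
  configurations; significance by permuting row assignments of the second
  configuration, `p = (1 + #{perm >= obs}) / (n_perm + 1)`.
* **Painting.** Each recipient haplotype is painted by scaled
  forward-backward under the Li-Stephens copying model, with the
  haplotypes of all other individuals as donors (all-vs-all, the
  unsupervised setting). Switch probability over a gap of `d` bp is
  `1 - exp(-rho d)` with a uniform landing distribution over donors;
  emissions match the donor allele with probability `1 - mu`
  (defaults `rho = 1e-6`/bp, `mu = 1e-3`). Expected copied length per
  donor is posterior mass times the inter-site span (half-distances to
  neighbouring sites); donor haplotypes collapse to individuals and a
  recipient's two haplotypes are summed, so each column of the coancestry
  matrix sums to twice the first-to-last-site span. Copy lengths are in
  bp under the uniform recombination assumption. The kernels are
  numba-compiled; an independent matrix-form forward-backward serves as
  the test oracle.
* **Switch-rate EM.** `rho` can be re-estimated as expected donor
  *changes* per painted bp (a jump that lands on the same donor does not
  count — this makes the estimate shrink geometrically to its floor when
  the donors are identical and no switching is ever needed). If an update
  would lower the total log-likelihood the previous rate is kept, so the
  recorded trace is non-decreasing.
* **Clustering.** The full fineSTRUCTURE MCMC is out of scope; its role
  is played by a deterministic surrogate: average-linkage agglomerative
  clustering of coancestry profiles (rows of the symmetrized matrix,
  self-entry replaced by the row mean, rows normalized to sum 1) under
  Pearson correlation distance, with the flat clustering chosen by mean
  silhouette over k = 2..k_max. Correlation distance reads the copying
  *pattern* rather than its magnitude; with Euclidean profiles the
  two-group cut was dominated by single outlying individuals, while the
  correlation form recovers the planted {G,R} vs {U,P,B} split in >= 80%
  of old-split replicates and stays below silhouette 0.25 on panmictic
  nulls.

## The anisotropy / genetic-barrier model

Normalized coancestry (symmetrized, divided by its off-diagonal grand
mean) is modelled for every pair of individuals as an exponential decay in
an effective distance:

    c_ij ≈ beta0 + beta1 * exp(-lambda * d_ij)
    d_ij = sqrt(dx' M dx) + b_gh
    M_g  = s_g * R(theta_g)' diag(1, rho_g^2) R(theta_g)

Within a group of regions the metric `M_g` has an anisotropy angle
`theta_g` in [0, pi), axis ratio `rho_g >= 1` and scale `s_g > 0`; across
groups the two metrics are averaged and a nonnegative barrier `b_gh` is
added to the distance. This functional form is this package's own
concrete reconstruction of a coancestry-decay barrier model: it is the
simplest form with per-group anisotropy, a symmetric cross-group rule
that reduces to the within-group formula when the metrics agree, and an
additive barrier.

Numerical choices:

* **Identifiability.** The model is invariant under joint rescaling of
  `(s_g, b_gh, 1/lambda)`, so `lambda` is fixed to 1 (configurable) and
  the scales absorb the decay length; barriers are then expressed in
  units of the decay length.
* **Fitting.** For any candidate nonlinear parameter set the linear pair
  `(beta0, beta1 >= 0)` has a closed-form least-squares solution and is
  profiled out; the remaining parameters are fitted by bounded
  trust-region least squares (`scipy.optimize.least_squares`) with
  multi-start (seeded random interior points plus one data-scaled
  isotropic start). The no-barrier, shared-metric nested model is fitted
  first and its solution is injected as a start of the full model, which
  guarantees the nested-dominance property (barrier fit score never
  exceeds the no-barrier score). On noise-free fixtures generated by the
  model's own predictor, recovery is exact to optimizer tolerance.
* **Partition search.** All set partitions of the regions into k
  nonempty groups are enumerated (15 for five regions at k = 2); each is
  fitted and the table is ranked by residual sum of squares.
* **Significance.** The statistic is the fit-score improvement of the
  barrier model over the nested no-barrier model; the null permutes which
  individual carries which (region, coordinate) assignment. The test
  uses the Besag-Clifford sequential rule: with `early_stop_h` exceedances
  after i permutations it stops and reports `p = h/i`, otherwise
  `p = (1 + count)/(n_perm + 1)`; both forms are valid p-values and the
  early stop only triggers when the result is clearly non-significant,
  which keeps null calibration runs affordable.

## Diversity statistics

* **HR.** Phase-free composite LD between two SNVs: the squared Pearson
  correlation of diploid dosage vectors (the signed correlation is
  available by flag). The exact historical formula behind the name is
  not pinned down by the sources available to this package; squared
  dosage correlation is the standard phase-free composite-LD measure and
  is what the tests oracle against.
* **LD decay.** Pairs within the last bin edge (default 0–500 kb in
  10 kb bins), both sites with MAF >= 0.05, and |MAF_a - MAF_b| < 0.05
  (strict), averaging HR per distance bin. Empty bins report count 0 and
  NaN, never 0. A `max_sites` thinning knob (evenly spaced, deterministic)
  caps the pair count for large panels.
* **RoH.** Sliding-window caller: windows of 50 consecutive called sites
  with at most 1 heterozygote flag their member sites; maximal flagged
  runs are split at gaps > 100 kb and kept if >= 1 Mb and >= 50 SNVs.
  These parameter values are PLINK-style conventions, all exposed in
  `RoHParams`. Missing genotypes are dropped before scanning.
* **Kruskal-Wallis.** Per-individual RoH totals are compared across
  regions with `scipy.stats.kruskal` (average-rank tie correction); a
  fully tied input returns H = 0, p = 1.
* **HetR / nHetR.** HetR = #het / #hom-alt per individual, with a zero
  denominator yielding a flagged undefined result. nHetR draws 5 samples
  per region (5000 replicates by default), restricts to sites polymorphic
  within the pooled drawn set — the ascertainment step that makes
  resampling actually change per-sample HetR — and averages each sample's
  HetR over the replicates that drew it. An exhaustive-enumeration oracle
  on a 6-sample region validates the resampler.

## ABC with learned summaries

The reference implementation of deep-learning ABC trains a DNN on joint
SFS inputs; at desk scale this package uses a documented surrogate
("ABC-DL-lite"): a 64x64 feed-forward regressor (scikit-learn
`MLPRegressor`) mapping a 64-dimensional classical summary vector to the
model parameters, with rejection in the regressor's output space. The raw
summary space is available via `use_net=False` / `--no-net`.

* **Summaries** (fixed, documented order): per-region normalized folded
  SFS; per-region mean site heterozygosity; all 10 pairwise Hudson F_ST
  values (ratio-of-sums estimator; uninformative cases encoded 0 with the
  panel flagged); per-region mean HR in three coarse distance bins
  (0–50 kb, 50–200 kb, 200 kb–1 Mb, <=150 thinned sites per region);
  per-region mean total RoH with lighter window settings (30 SNVs,
  >= 500 kb) so that the statistic is informative on 1–5 Mb panels.
* **Training.** Inputs and outputs are standardized; constant summary
  columns are dropped with a warning; migration enters as log10(m).
  Training is seed-reproducible.
* **Rejection.** Distances are Euclidean after per-dimension
  standardization by the simulation SD (zero-SD dimensions dropped with a
  warning); the lowest `accept_fraction` quantile is accepted.
  `accept_fraction = 1` returns the prior draws exactly, and an observed
  vector equal to one simulation's summary returns that simulation at
  `accept_fraction = 1/n`.
* **Posterior summaries.** Mean; median; half-range mode (iterative
  modal-interval halving: repeatedly keep the half-range window anchored
  at an observed value containing the most points — leftmost on ties —
  until <= 2 values remain, then average; a brute-force oracle covers
  n <= 10); 95% equal-tailed credible interval (empirical 2.5/97.5%
  quantiles, linear interpolation); 89% HDI as the shortest contiguous
  order-statistic interval containing ceil(0.89 n) values (no density
  estimation). At least 10 accepted draws are required.
* **Pipeline.** `run_abc_pipeline` orchestrates priors -> training
  simulations -> regressor -> ABC simulations -> rejection and emits one
  row per demographic parameter with columns prior, mean, median,
  half-range mode, CI 2.5/97.5% and HDI low/high, times in years.
  Library defaults are 5 Mb, n_train = 2000, n_abc = 1000, accept 5%;
  the repository's own calibration checks run at n_train = 500 on 1 Mb
  panels, where the learned summaries already give 89% HDI coverage of
  around 90% for `t_GRUBP` over prior-drawn pseudo-observed datasets.

## What the synthetic data do and do not emulate

The generator reproduces the sampling design (five regions, 5–6 diploids
each), drift-driven differentiation, migration, and human-scale
mutation/recombination. It does not model sequencing or genotyping error,
phasing switch errors, exome capture, or variable recombination maps.
Passing tests therefore demonstrate correctness of the statistics and the
inference machinery under the stated model — not robustness to the
artefacts of real sequencing data, which enter real analyses upstream of
this package.

## Problem sizes used by the repository's checks

Chosen as the smallest scales at which each property is comfortably
resolvable: prior calibration at 10^6 draws; Watterson at 200 x 0.5 Mb;
structure recovery at 20 x 4 Mb panels (the partition ranking between
close competitors is not stable below ~4 Mb) and null calibration at
20 x 1 Mb panels (99 permutations, sequential early stop); the RoH/LD direction
contrast at 20 x 10 Mb (RoH >= 1 Mb needs room on the chromosome); ABC
calibration at 500 training simulations on 1 Mb with 20 pseudo-observed
datasets.

## Known limitations

* The barrier model's functional form is a reconstruction; other decay
  kernels (power-law, resistance distance) are plausible and not
  explored.
* The clustering surrogate returns point partitions, not the posterior
  over partitions an MCMC would give; silhouette-based model choice can
  legitimately prefer k > 2 when finer real substructure exists.
* Painting assumes complete, phased, biallelic data; unphased input is
  redirected to dosage-based analyses rather than being imputed.
* nHetR treats undefined per-replicate ratios (no hom-alt sites in a
  draw) by exclusion, which slightly biases nHetR upward for samples that
  are often undefined; such samples are flagged NaN when never defined.
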
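# Methods

`ploidyshift` detects signatures of whole-genome duplication (WGD) in
reduced-representation (RAD-style) sequencing data and places shifts in
WGD-related traits on a phylogeny. It has three analytic stages — SNP
read-ratio mixture modelling, per-contig haplotype counting, and
Ornstein–Uhlenbeck (OU) shift detection — plus a synthetic-data module
that generates datasets with known ground truth so every stage is
testable without raw reads.

## 1. SNP read-ratio analysis

### Model

At a heterozygous bi-allelic site in a `p`-ploid individual where the
alternate allele occupies `d` of the `p` chromosome copies, a sequencing
read carries the reference allele with probability `(p − d)/p`. The
reference-read fraction `r = ref/(ref + alt)` therefore concentrates
around 0.5 in diploids; around 1/3 and 2/3 in triploids; and around
0.25, 0.5 and 0.75 in tetraploids. A functional tetraploid (disomic
signal not yet re-established) shows all three tetraploid peaks; as
rediploidization proceeds, the outer peaks shrink.

### Filters and replicate confirmation

Raw per-replicate SNP calls are filtered to total depth in [10, 300]
reads and at least 5 reference reads, per replicate. Only variants
observed in both replicate libraries of an individual — matched on
contig, position and both alleles — are treated as real; their read
counts are summed before ratios are taken.

Two filter properties worth knowing:

* The reference-read minimum is asymmetric (there is no mirrored
  alternate-allele minimum). Users wanting symmetry can apply the
  filter twice with alleles swapped.
* At shallow depth the `ref ≥ 5` rule selectively removes sites from
  the 0.25 peak (a `Binomial(30, 0.25)` draw falls below 5 about 10% of
  the time, and both replicates must pass). At per-replicate depth 30
  this depresses the low peak's mixture weight by roughly 15–20%; at
  depth 60 the effect is negligible. Tetraploid analyses are therefore
  best run at combined depths ≥ 60.

### Mixture fit and the peak-ratio statistic

The ratio histogram is summarized by a three-component univariate
Gaussian mixture fitted by EM from the fixed start `mu = (0.25, 0.5,
0.75)`, `sigma = 0.05` each, equal weights. Means, standard deviations
and weights are all free by default (`fixed_means=True` pins the
means, for samples whose outer peaks carry almost no mass). The
initialization is deterministic and no random restarts are used, so the
fit is a pure function of the data. EM stops when the relative
log-likelihood improvement falls below 1e-8 (at most 1000 iterations);
a component standard deviation collapsing below 1e-4 is floored there
and the fit flagged unconverged.

The **peak ratio** is `mean(λ_low, λ_high) / λ_mid`, the mixing weight
of the outer (0.25/0.75) peaks relative to the central (0.5) peak.
Empirically, diploid-like samples score ≲ 0.4, partially
rediploidized samples ~0.5–0.7, and functional tetraploids ~1 and
above. Note the orientation: some descriptions of this statistic state
the inverse (central/outer); the inverse is exposed via
`peak_ratio(fit, inverse=True)` but is inconsistent with the group
ranges above, since a sample dominated by its 0.5 peak must score low,
not high. Peak "heights" are mixing weights (λ), not density maxima.

Individual peak ratios are averaged across the individuals of a species
(two in the replicate design emulated here), and the species mean is
classified with thresholds `t_low = 0.45`, `t_high = 0.9` — midpoints
between the empirically observed groups. The thresholds are
configuration, not constants of the method.

## 2. Haplotype counting per contig

When homeologous loci collapse into a single assembled contig, reads
from all copies pile up and the contig supports more haplotypes than a
diploid locus should. The count is estimated conservatively, in the
spirit of minimal-explanation haplotype reconstruction for
low-diversity, low-coverage data:

1. Reads spanning more than 200 aligned bases are excluded (a span of
   exactly 200 is retained — "stretching beyond" reads as strictly
   greater).
2. Variant columns are positions where at least two alleles each have
   ≥ 2 supporting reads; singleton disagreements (sequencing errors)
   never define a column.
3. Two reads conflict iff they overlap on ≥ 1 variant column and
   disagree there. Any proper coloring of this conflict graph is a
   partition into internally consistent groups; the minimum number of
   colors is the smallest number of haplotypes consistent with the
   alignment. Components of ≤ 15 reads are colored exactly by
   branch-and-bound (seeded with the greedy bound); larger components
   use deterministic greedy coloring in (start, read id) order. The
   exact small-component path exists because greedy coloring on
   subgraphs of interval graphs is not guaranteed optimal, and the
   count is meant to be a minimum, not an upper bound.
4. Color classes whose consensus bases agree at every shared variant
   column are merged (classes sharing no columns merge too — the
   conservative choice).
5. Classes supported by fewer than 20 reads are discarded; the
   surviving class count is the contig's haplotype number. The 20-read
   rule is applied per haplotype by default (`per_contig_support=True`
   applies it per contig instead; the published description is
   ambiguous between the two). A contig with no variant columns counts
   one haplotype if it meets the read threshold.

Contigs scoring 0 are excluded from denominators when haplotype-number
frequencies (1 / 2 / 3+) are computed; an input with no surviving
contig is an error rather than a silent empty table.

## 3. OU shift detection

### Model

Tip traits follow a stationary OU process on an ultrametric tree scaled
to unit height (the scaler accepts any ultrametric input within 1e-6
relative tolerance and rescales; non-parametric rate smoothing of
non-ultrametric trees is upstream of this package). The optimum starts
at `theta0` and may jump on any branch; jumps are inherited by all
descendants. For a branch `b` beginning at depth `t_b` on the path to
tip `i`,

    E[y_i] = theta0 + Σ_b beta_b · (1 − e^(−alpha (1 − t_b)))
    Var    = sigma2/(2 alpha) · e^(−alpha d_ij) · (1 − e^(−2 alpha t_ij))

with `t_ij` the shared root path of tips i, j and `d_ij` their
patristic distance; the Brownian limit `sigma2 · t_ij` is used at
`alpha = 0`. The attenuation factor means an optimum shift approaches
its full offset on old (deep) shifts and is nearly invisible for very
recent ones or under weak selection — shifts are unidentifiable in the
Brownian limit, which is correct behavior, not a defect.

### Selection

For each `alpha` on a log-spaced 20-point grid spanning 0.01–100 (in
units of 1/tree-height), traits and the per-branch design are whitened
by the Cholesky factor of the OU correlation, the unpenalized intercept
is projected out, and a LASSO path over branch coefficients proposes
nested support sets. Every proposed support (plus the empty set, with
supports capped at `n_tips/4` shifts) is refit by generalized least
squares and scored by an information criterion; the minimum over the
grid and path wins, ties broken toward fewer shifts.

The default criterion is a phylogenetic extended BIC:

    pBIC = −2 logL + (K + 3) log n + 2 log C(E, K)

for `K` shifts on a tree with `E` branches (the +3 counts `theta0`,
`alpha`, `sigma2`). The combinatorial term is a uniform model-space
prior over the `C(E, K)` placements of `K` shifts and controls the
selection bias of scanning every branch. Plain BIC
(`criterion="bic"`) is available but not recommended: measured on
32-tip null simulations it reports spurious shifts on >90% of
datasets, the known failure mode that motivates placement-aware
penalties in LASSO-based shift detection. With the default criterion
the measured operating characteristics on a 32-tip balanced tree
(alpha = 2, sigma2 = 1) are ≥ 90% zero-shift selections under the
null and ≥ 90% recovery of a single deep shift sized at 4 stationary
standard deviations of realized tip displacement.

Sister placements can be likelihood-equivalent (identical design
columns, or complementary root-child columns whose difference is
absorbed by the intercept). The fitted model reports the selected edge
and lists equivalent edges explicitly; recovery statistics count an
equivalent placement as a hit.

### Bootstrap support

Residuals from the fitted model are whitened through the fitted OU
covariance — making them uncorrelated and standardized — resampled with
replacement, colored back through the covariance, and added to the
fitted tip expectations; the whole selection is rerun per replicate
(default 100). A shift's support is the fraction of replicates
selecting its edge or an equivalent one. The resampler is seeded and
byte-reproducible.

## 4. Synthetic data: what it does and does not emulate

The generators emulate the features the estimators rely on:

* **SNP depths**: dosage drawn from `dosage_weights`, per-replicate
  depth fixed or Poisson (clipped to ≥ 1 so every record has a read;
  immaterial at the default mean of 30), reference reads binomial with
  a symmetric per-read error flip, and (diploids only) a
  `paralog_fraction` of sites sequenced at 0.25/0.75 to mimic collapsed
  paralog pairs. Defaults: depth 30, two replicates, error 0,
  paralog fraction 0. Tetraploid dosage weights default to
  (1/4, 1/2, 1/4), which places visible mass on all three peaks and
  implies a true peak ratio of 0.5; classification experiments for the
  *functional tetraploid* regime instead use uniform weights
  (1/3, 1/3, 1/3), matching the empirical signature of outer peaks
  rivalling the central one, and depth 60 so the reference-minimum
  filter does not deplete the 0.25 peak (see §1).
* **Contig alignments**: 1–4 haplotype sequences per contig; variant
  columns confined to the window every read covers (contig length =
  1.5 × read span), so recoverability is limited by read support and
  divergence, not read placement; reads are error-free haplotype
  copies assigned round-robin, giving balanced support. Real data add
  sequencing error, uneven coverage and partial overlap — the
  support/consensus machinery absorbs some of this, but passing tests
  on this generator demonstrate correctness of the counting logic, not
  robustness to alignment artifacts.
* **OU traits**: exact multivariate-normal sampling from the model
  above, so trait tests check the estimator against its own generative
  assumptions. Shift-recovery experiments use a 32-tip balanced
  binary tree of unit height with evenly spaced splits — the canonical
  topology for power studies — with the shift on the deepest
  clade-of-8 branch: deep enough to express nearly its full offset,
  while a root-child shift is partly confounded with Brownian clade
  drift (the empty model at the grid's Brownian end absorbs it) and
  with the intercept via its sister. On random coalescent trees with
  short pendant branches the same effect size carries a fraction of
  the information (GLS non-centrality ~6–15 vs ~40) and recovery is
  correspondingly lower; this is a property of the data, not the
  estimator.

No FASTQ-level simulation, restriction-site modelling or assembly is
attempted.

## 5. Numerical choices

* EM: log-space responsibilities, tolerance 1e-8 relative, sigma floor
  1e-4, reported components sorted by mean, log-likelihood reported at
  the final parameters.
* Coloring: exact search up to 15-read components; deterministic
  (start, read id) order everywhere, so results are stable across runs.
* OU: covariance Cholesky without regularization (a proper ultrametric
  tree with positive branch lengths gives an SPD matrix; coincident
  tips raise an error rather than being jittered); LASSO coordinate
  descent tolerance 1e-8, path of 100 penalties, `eps = 1e-4`;
  degenerate zero-residual fits report `sigma2 = 0` and select the
  empty model via the fewer-shifts tie-break.
* Problem sizes in the test suite (1e5 sites for allele balance, 200
  contigs, 100 seeds per OU operating characteristic, 100 bootstrap
  replicates) were chosen to hold sampling error comfortably below the
  asserted tolerances while keeping a full run on one CPU in minutes.

## 6. Known limitations

* The peak-ratio statistic conflates collapsed paralogs with residual
  tetrasomy; without a reference genome the two cannot be separated,
  so "tetraploid-like" is a statement about signal, not karyotype.
* Haplotype counts are minima by construction; allopolyploids whose
  homeologues diverged at unsampled columns undercount.
* Shift detection assumes a single trait, no measurement error and a
  shared `alpha`/`sigma2` across the tree; convergent-regime collapsing
  is out of scope.
* The bootstrap measures selection stability under the fitted model,
  not placement uncertainty among near-equivalent neighboring branches
  (those are reported as equivalence classes instead).
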
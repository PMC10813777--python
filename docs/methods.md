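# Methods

## Neutral community model

The model treats each local community as receiving immigrants from a shared
metacommunity: a taxon with metacommunity relative abundance *p* has local
relative abundance distributed Beta(*Nm·p*, *Nm·(1−p)*), where *Nm* is the
product of local community size *N* and immigration rate *m*. Larger *Nm*
means local communities track the metacommunity more tightly. Its testable
prediction is the relationship between a taxon's mean relative abundance and
its occurrence frequency across communities:

    F(p) = 1 − I_{d/N}(Nm·p, Nm·(1−p)),

the probability that the local abundance exceeds the detection limit *d/N*
(*d* = 1 read by default, exposed as a flag). `predict_frequency` evaluates
this via `scipy.special.betainc` and is verified against direct quadrature
of the beta density to < 1e-8.

**Fitting.** `fit_ncm` sets *N* to the mean sample read total, *p_i* to the
mean relative abundance of taxon *i* over samples, and *f_obs,i* to the
fraction of samples with ≥ *d* reads of taxon *i*. *Nm* is then the
unweighted least-squares minimiser of Σᵢ (f_obs,i − F(p_i))², optimised on
the log scale with five starting points (Nm ∈ {1, 10, 10², 10³, 10⁴}) to
avoid the flat-likelihood plateau at large Nm. Taxa never detected in the
fitted samples are excluded (a (p=0, f=0) point is uninformative and breaks
the total sum of squares). R² = 1 − SSE/SST with SST around the mean
occurrence frequency; it may be negative and is reported as-is. The fit is
invariant to taxon and sample order.

**Prediction band and partitioning.** Taxa are called `above`/`below` when
their observed frequency leaves a central 95% band around the fitted curve.
The default band is the *binomial prediction band*: under the fitted model a
taxon's detection count over *n* samples is Binomial(*n*, F(p)), so the band
holds the α/2 and 1−α/2 binomial quantiles divided by *n* (clamped to
contain the fitted curve, which discreteness can otherwise violate near
F ≈ 0 or 1). A Wilson score interval is available behind the `band` flag but
is *not* the default: a Wilson interval is a confidence interval for an
estimated proportion, roughly √n narrower than the spread of the observed
frequencies themselves, and using it as a gate misclassifies 15–25% of
genuinely neutral taxa in simulations where the prediction band misclassifies
~10%. Widening the band from 95% to 99% can only move taxa toward `neutral`,
never out of it.

**Known bias.** When reads are drawn Binomial(N, x) on top of the beta
abundance (as in our generator and, arguably, in real amplicon sampling),
the exact detection probability is E[1 − (1−x)^N], which exceeds the
threshold form F(p) near the detection boundary. Least squares compensates
with a systematically high Nm: at S=1000 taxa, k=50 samples, N=10⁴ reads and
true Nm=500, the fitted value is ~590–610 (+18–22%), with R² ≈ 0.96. The
bias is monotone, so *comparisons* of Nm across groups — the quantity of
scientific interest — are unaffected: in end-to-end simulations the fitted
Nm ranking reproduces the generated ranking in 10/10 seeds. We keep the
threshold form because it is the field's standard fitting convention;
absolute Nm values should be read with this calibration in mind.

**Community scope.** The pipeline fits one model per treatment group,
pooling lifestyles and timepoints (matching the four-panel presentation
such data usually gets); `--split-by group,lifestyle` fits per lifestyle.

## AVD stability index

For each taxon *i* in a group of *k* samples, the variation degree in sample
*j* is a_ij = |x_ij − x̄_i| / δ_i on rarefied abundances, and

    AVD = Σᵢⱼ a_ij / (k·n).

Conventions, each a flag:

- δ_i is the *sample* standard deviation (divisor k−1); the population
  convention (divisor k) is available via `ddof=0`. At k=2 the sample-SD
  convention gives AVD = 1/√2 for every non-degenerate input — an exact
  analytic regression case.
- the absolute value is applied inside the per-sample degree. A signed
  degree would average to ~0 over samples by construction, which would make
  the summed index meaningless; the absolute form is the only one consistent
  with the index being a dispersion measure.
- taxa with δ_i = 0 are excluded from both the numerator and *n* (default),
  avoiding 0/0; `zero_variance="zero"` keeps them with degree 0 instead.
- inputs are rarefied to the minimum sample depth by default (depth is a
  flag); the equation is defined on rarefied abundances.

**What AVD does and does not measure.** Because every taxon is normalised
by its own SD, AVD is invariant to per-taxon rescaling — it measures the
*shape* of each taxon's abundance distribution, not its variance. A
consequence worth knowing: for independent neutral draws, *higher* Nm
(tighter, more symmetric beta distributions) yields *higher* AVD, because
the mean of |x−x̄|/sd approaches the normal value √(2/π) ≈ 0.80 from below,
while low-Nm communities produce skewed, zero-inflated abundances whose mean
normalised deviation is smaller (~0.61 at Nm=200 vs ~0.71 at Nm=2000 in our
simulations, 10/10 seeds). An intuition that "less dispersal limitation ⇒
lower relative dispersion ⇒ lower AVD" is wrong — the per-taxon SD
normalisation removes exactly the dispersion it appeals to. In real
longitudinal data AVD differences are driven by temporal turnover and
compositional upheaval, which the iid neutral generator deliberately does
not model.

**Significance testing.** Replicate-level AVDs (one per replicate tank,
computed across its timepoints) feed a one-way ANOVA with Tukey HSD and a
compact letter display. Treating the replicate as the unit of replication is
one defensible choice among several (timepoints or bootstraps are
alternatives); it is the default because replicate tanks are the independent
experimental units.

## Synthetic data generator

The generator is the exact sampling counterpart of the fitted model, by
design: metacommunity abundances are lognormal (σ = 2 by default, a typical
amplicon rank-abundance shape) normalised to 1; each sample draws per-taxon
x ~ Beta(Nm·p, Nm·(1−p)) (parameters floored at 1e-8; both parameters below
1e-6 yield x = 0) and reads ~ Binomial(N, x) per taxon independently, so
sample totals vary around N rather than being fixed — matching the
independent-detection model the fit assumes, and avoiding multinomial
coupling the theory ignores. Totals are not renormalised.

The study generator produces one sample per (group, replicate, timepoint,
lifestyle) cell — 192 by default — with per-group Nm (defaults C=1500,
N=1000, T=600, M=800: control most neutrally assembled, *T. weissflogii*
least, mirroring the treatment ranking such experiments report) and equal
per-lifestyle Nm (exposed as a multiplier). Nutrients follow group-specific
linear time trends plus Gaussian noise, with nitrate and phosphate higher in
the microalgae groups than the control; the nutrient model exists to
exercise the Mantel/RDA/ANOVA plumbing, not to model pond chemistry.

**Non-neutral injection.** `above` taxa are drawn from the low-abundance
half and forced to be detected in every sample (one read borrowed from the
sample's most abundant taxon). `below` taxa are drawn from the top abundance
decile *excluding the dominant top 2%* and zeroed in 80% of samples, freed
reads redistributed proportionally (largest-remainder rounding keeps totals
exactly conserved); their surviving occurrences are scaled up so their
across-sample mean abundance stays in the top decile. Excluding the
dominants matters: moving the reads of taxa that hold half the community
distorts every other taxon's relative abundance and degrades the global fit,
which is not what a targeted non-neutrality probe should do.

All randomness flows from one root seed via `numpy.random.default_rng`
seed sequences keyed by (seed, stage, cell), so identical configurations are
bit-identical and per-sample draws do not depend on sample order.

## Distance-based statistics

- **Bray–Curtis** on relative abundances by default (robust to unequal
  depth); raw counts optional. On equal-depth tables the two coincide.
- **PCoA**: Gower double-centering and symmetric eigendecomposition.
  Negative eigenvalues are reported (Lingoes correction behind a flag);
  axis proportions are relative to the positive inertia.
- **PERMANOVA**: McArdle–Anderson trace decomposition of the Gower matrix
  with *sequential* (Type I) sums of squares in the user's term order —
  one R² per term, interactions via `a:b`, every variable treated as a
  categorical factor. p-values by free permutation of sample labels;
  exceedances counted with a 1e-12 relative tolerance so exact ties (e.g.
  the mirror labelling) are not lost to float noise. Aliased terms (zero
  additional rank) are rejected by name. The R² column sums to 1 and the
  df column to n−1 by construction.
- **ANOSIM**: R = (r̄_between − r̄_within)/(M/2) on ranked distances,
  M = n(n−1)/2.
- **MRPP**: δ = Σ_g (n_g/n) · mean within-group distance;
  A = 1 − δ/mean(δ_perm). On equidistant data every permutation gives the
  same δ, so A = 0 exactly.
- **Mantel**: Spearman by default (average ranks on ties), one-sided for
  positive association, permuting one matrix's rows/columns jointly.
- **RDA**: regression of the centered response on centered constraints via
  QR, eigendecomposition of fitted values (constrained) and residuals
  (unconstrained), eigenvalues as variances (divisor n−1); overall pseudo-F
  tested by permuting response rows. Collinear constraints are rejected with
  the aliased set named.
- **db-RDA**: PCoA axes covering ≥ 99.9% of positive inertia fed into RDA;
  with Euclidean input this reproduces plain RDA to machine precision (the
  retention threshold is chosen exactly so that equivalence is exact while
  numerically-zero axes are dropped).
- **UPGMA**: ties in the minimum inter-cluster distance are broken by the
  lexicographically smallest pair of cluster representatives, making the
  Newick output independent of input order; merges sit at height d/2
  (ultrametric, so cophenetic distances reproduce ultrametric inputs).
- every permutation p uses the (1 + exceedances)/(1 + n_perm) estimator,
  guaranteeing p > 0 and exact type-I control under exchangeability
  (verified: rejection rate at nominal 0.05 within [0.03, 0.07] over 1000
  null datasets).
- **compact letter display**: insert-and-absorb over the Tukey significant
  pairs, groups ordered by first appearance.

## Pipeline

One YAML config (CLI flags override) drives simulate/ingest → filter
(singleton removal by default) → rarefy (minimum depth) → per-group NCM →
per-stratum AVD → multivariate battery → `report.json` (schema_version 1).
Stage seeds are derived from the root seed by SHA-256, every stage output is
hashed against its inputs so re-running an output directory recomputes only
what changed (the hash covers configuration and upstream stages, not the
package code itself), and reports are byte-identical for identical configs.
Nutrient change columns are X(t) − X(day 0 of the same group and replicate)
by default; the opposite sign convention is a flag, since published tables
are ambiguous about which direction was reported.

## Problem sizes used in the tests

Reference validations run at S=1000 taxa, k=50 samples, N=10⁴ reads
(model-fit recovery, injection recovery), S=500/k=20/N=5000 (AVD dispersal
contrast), 16-sample null designs × 1000 replicates (PERMANOVA calibration),
and the full 192-sample design at S=120–1000 for end-to-end runs — sizes at
which every statistical property tested is stable across seeds while the
whole suite stays fast.

## Limitations

- No temporal autocorrelation: samples within a group are independent draws,
  so time-related PERMANOVA terms carry no signal in synthetic data.
- No sequence-level simulation (no read errors, chimeras, or taxonomy
  assignment); the synthetic taxonomy labels are arbitrary family names.
- Absolute fitted Nm carries the upward calibration bias described above.
- No phylogeny-aware distances or null models; no biomarker discovery.
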
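# Methods

## Problem and model

DNA methylation at a CpG site is summarised by a Beta value, the proportion
of methylated signal in [0, 1]. Most CpGs are tightly regulated and show
little variation between individuals; a small minority are *hypervariable* —
highly variable between individuals in many tissues and populations at once,
which makes them candidates for methylation states established in the early
embryo rather than driven by tissue, cohort, or technical artefacts.

`hvcpg` implements a cross-dataset screen for such CpGs and the analyses
used to characterise them. The core detection rule is deliberately simple
and rank-based:

> A CpG is an hvCpG if its within-dataset Beta variance is in the top *i* %
> of retained CpGs in at least *j* % of the datasets covering it, requiring
> coverage in at least `min_datasets` datasets. Defaults: *i* = 5, *j* = 65,
> `min_datasets` = 15.

The rule's strength is its null calibration: if each dataset's top-5% set
were independent of the others, the probability that a CpG covered in 15
datasets is flagged in ≥ 65% of them is the binomial tail
P(Bin(15, 0.05) ≥ 10) ≈ 3×10⁻¹⁰, so essentially no CpG should qualify by
chance. The package's acceptance checks verify exactly this property on
simulated independent cohorts, and ≥ 95% recovery of planted shared signal.

## Per-dataset preprocessing

Each cohort is processed independently:

1. **Probe filters** — drop probes with detection p > 0.01 in > 5% of
   samples (when detection p-values exist), probes on supplied
   multi-mapping / X-Y / SNP-affected exclusion lists, and probes with any
   missing Beta value. Filtering is idempotent and reports per-rule counts.
2. **M-value transform** — M = log₂(β/(1−β)); Beta values at exactly 0/1
   are clamped to 10⁻⁶ first. The default back-transform is the exact
   base-2 inverse 2^M/(1+2^M); a `natural` mode (e^M/(1+e^M)) exists for
   compatibility with tools that mix bases, but it does not round-trip and
   is not used by the pipeline.
3. **Residual adjustment** — one OLS model per CpG of M on the sample
   scores of the first `n_pcs` (default 10) principal components of the
   CpG-centred M matrix, plus age and sex where available and
   non-constant. Residuals are re-centred on the fitted intercept before
   back-transform; raw residuals would force every CpG's mean Beta to 0.5.
   PC scores absorb batch, plate, and cell-composition structure; the
   rank-1-batch limit (one PC spanning the data ⇒ zero residual variance)
   is tested.
4. **Outlier removal** — per probe, values outside Tukey's outer fences
   [Q1 − 3·IQR, Q3 + 3·IQR] are set to missing. Quartiles use
   linear-interpolation quantiles; probes with < 4 observed values are
   left unchanged.

Variance for the detection rule is computed on the adjusted,
outlier-masked Beta values (unbiased estimator, pairwise missing
exclusion), following the preprocessing order above. Ties at the top-*i*%
cutoff are all included, which keeps the (i, j) threshold grid monotone:
counts are non-decreasing in *i* and non-increasing in *j*.

## Control sets

**Distribution-matched controls.** Enrichment at hvCpGs can be confounded
by their distributional signature (high variance, intermediate
methylation). Each hvCpG is therefore matched, in a chosen reference
dataset, to the background CpG whose Beta distribution is hardest to
distinguish from it: the candidate with the greatest two-sided
Kolmogorov–Smirnov p-value, required > 0.1. Matching is greedy in sorted
hvCpG-id order and without replacement, so it is injective and
order-independent. When all probes have equal sample counts the
greatest-p candidate equals the smallest-D candidate, which the
vectorised search exploits; the winning pair's p-value is recomputed with
`scipy.stats.ks_2samp`. A (mean, sd) pre-filter window (±0.08 / ±0.06)
narrows the pool for speed and falls back to the full scan whenever the
windowed best fails the p > 0.1 gate; tests verify the window never
changes the selection.

**mQTL-matched controls.** The variance in methylation explained by one
mQTL is 2·β²·MAF·(1−MAF) under Hardy–Weinberg genotype frequencies,
interpreting β as a per-allele effect on variance-standardised
methylation; a CpG's summary is the arithmetic mean over its mQTLs.
Controls must have an identical association count, mean variance
explained within a tolerance (default 0.005), and dataset coverage at
least that of the hvCpG; the nearest eligible candidate wins, without
replacement. cis/trans significance thresholds (10⁻⁸ / 10⁻¹⁴) are plain
row filters on the input table.

## Clusters and co-methylation decay

Co-methylation is quantified as the mean pairwise Spearman ρ of Beta
values in 100-bp inter-CpG distance bins, using only datasets with ≥ 100
samples (smaller cohorts make pairwise ρ too noisy). Per-pair-per-dataset
values are averaged with equal weight by default; a pooled mode is also
provided since the two weightings can differ in principle. Clusters are
maximal single-linkage chains of CpGs ≤ 4000 bp apart (boundary
inclusive) on one chromosome; chains of one CpG are singletons.
De-clustering keeps one uniformly random member per cluster plus all
singletons, giving n_clusters + n_singletons CpGs with minimum
same-chromosome spacing > 4 kb; it is seed-deterministic. An exponential
a·exp(−d/L) fit to the binned profile (`fit_exponential_decay`,
pair-count-weighted `curve_fit`) recovers a planted decay length within a
few percent at the tested scale.

## Cross-germ-layer covariation and SIV power

For a fetal study with two tissues per individual across three
germ-layer-pair groups (endoderm–mesoderm, endoderm–ectoderm,
mesoderm–ectoderm; reference design 9/10/8 = 27 individuals), the
inter-germ-layer correlation of a CpG is the Pearson r between the two
tissues' Beta values across individuals, averaged unweighted over groups
with a defined r. Interindividual variation is the range (max − min) of
per-individual cross-tissue mean Beta values over all individuals.

The SIV (systemic interindividual variation) power simulator asks how
often a small screen would re-detect a CpG: per replicate it draws
`n_individuals` (default 4) independent 3-vectors from MVN(μ, Σ) — μ the
per-tissue mean Beta, Σ the unbiased cross-tissue covariance of the
observed samples — and applies the SIV rule: range of per-individual
cross-tissue means ≥ 0.2, optionally plus a minimum inter-tissue
correlation (all pairs or on average). Power is the passing fraction over
`n_reps` = 1000 replicates with Monte-Carlo SE √(p(1−p)/n_reps). Draws
are clipped to [0, 1] (logged; an unclipped mode exists for oracle
comparisons); Σ is symmetrised with eigenvalues clipped at 0, and
covariances more than 10⁻⁶ below PSD are rejected. Power is 1 exactly
when the range threshold is 0 and 0 exactly for a point mass — both are
asserted, along with agreement with a 10⁶-replicate brute-force estimate.

## Enrichment

All enrichment is a 2×2 Fisher's exact test of a target set vs a
comparator set (distribution-matched controls, mQTL-matched controls, or
the array background) for membership in a feature. The sample
(cross-product) odds ratio is reported, with a Haldane–Anscombe
0.5-corrected companion when a cell is zero, plus the ratio of
proportions ("fold"). Interval proximity uses BED 0-based half-open
intervals against 1-based probe positions (conversion explicit and
tested); a CpG is proximal at threshold x if within x bp of any interval,
distance 0 inside. Published-set reports restrict sets to the array
background, drop sets overlapping < 1% of the target, and append
Benjamini–Hochberg q-values next to the raw p-values. Bootstrap CIs are
percentile intervals over B = 1000 resamples of the CpG (the unit of
analysis), seed-deterministic; degenerate statistics yield a zero-width
interval with a flag.

The sex-split check recomputes top-5% variance flags in male-only and
female-only halves of datasets with both sexes, ≥ 40% of samples in each
sex, and n > 80, reporting the proportion of hvCpGs flagged in at least
one sub-dataset — 1.0 when hypervariability is sex-independent, 0 for
CpGs that are bimodal only when sexes are pooled.

## Synthetic data: what it emulates, and what it does not

The generator produces disjoint cohorts from per-CpG logit-normal
baselines: a bimodal mean-methylation mixture (≈ 35% low ≈ 0.1, 35% high
≈ 0.9, 30% intermediate), per-CpG noise SDs drawn log-normally
(median 0.25 M-units, log-SD 0.35), plus planted structure with disjoint
category labels as ground truth:

- **shared_hv** — 2–3-component mixtures centred at intermediate Beta
  (0.2–0.8), component half-separation 0.12·√multiplier (capped at 0.28),
  active in every dataset with cohort-specific component membership;
- **dataset_specific_hv** — the same construction active in exactly one
  dataset;
- **mqtl_driven** — M = baseline + β·dosage + noise, dosage ~
  Binomial(2, MAF) per cohort (Hardy–Weinberg, no shared individuals);
  dosages are kept in the ground truth for effect-recovery tests;
- **cluster_member** — runs of 3–8 CpGs with consecutive gaps of
  0.1–1.2 kb and multivariate-normal deviations with correlation
  exp(−d/decay length); runs start ≥ 9 kb apart so independent
  cross-cluster pairs stay outside the profiling window;
- low-rank batch components (scores × loadings on the M scale), balanced
  sex and uniform age covariates with optional planted effects, and
  configurable missingness and detection-p failure injection.

By default each cohort draws its own per-CpG baseline means. This is a
deliberate null-model choice: the intersection rule's calibration assumes
independent top-variance sets across datasets, and because Beta variance
scales with b(1−b), sharing baselines across cohorts induces exactly the
cross-dataset variance-rank correlation the null excludes. A
`share_baseline_across_datasets` switch restores shared baselines for
experiments that need cohort-consistent methylation levels. Consequences
for interpretation: passing the null-specificity check demonstrates
correct behaviour of the rule under its own null, not that real datasets
(which share biology, probe chemistry and normalisation pipelines) are
free of correlated variance ranks — on real data the empirical argument
is the preprocessing (PC adjustment) plus the robustness of calls across
thresholds. The generator likewise does not model Infinium probe-type
chemistry, BMIQ-correctable biases, or explicit cell-type mixtures
(batch components stand in).

The fetal simulator plants, for SIV CpGs, a per-individual latent level
shared by both tissues with correlation ρ (Cholesky of the 2×2
correlation matrix, so ρ may be negative), around means in [0.25, 0.75]
with tissue noise SD 0.08 — chosen so clipping at the Beta boundary is
negligible and Pearson r is recovered essentially unbiased with the
9/10/8 group design.

Annotation-track simulation samples interval anchors at CpGs with weight
`fold` for the enriched category and 1 otherwise, placing a 500-bp
interval within 10 kb, so category CpGs are proximal at `fold` times the
background rate in expectation; fold = 1 is the null.

## Numerical choices

- Top-*i*% cutoff: k = ⌊n·i/100⌋-th largest variance, ties included.
- Quartiles: linear interpolation (`numpy.quantile` default).
- Spearman ρ: average ranks for ties; pairs with < 3 complete
  observations skipped; rank-then-Pearson vectorisation.
- KS candidate ranking: asymptotic p (monotone in D at fixed sample
  sizes); the reported p and the > 0.1 gate use the exact two-sample test.
- Fisher p: `scipy.stats.fisher_exact`, verified against exhaustive
  hypergeometric enumeration to 10⁻¹⁰ for all tables with total ≤ 30.
- Beta boundary clamp 10⁻⁶ before the logit; back-transforms always
  strictly inside (0, 1).
- All randomness flows from `numpy.random.SeedSequence(seed)` spawned in
  fixed order; identical configurations are byte-identical after
  serialisation.

## Problem sizes used by the checks

The acceptance-scale checks run 30 cohorts × 100 samples × 20,000 CpGs
(100 seeds for null specificity; 200 planted CpGs for recovery), 500
hvCpGs vs 5,000 background probes for KS matching, ~2,000 clustered CpGs
over two 150-sample cohorts for decay recovery, 10,000 CpGs with the
9/10/8 fetal design, and 10⁶ brute-force replicates for the power
cross-check. These sizes make the Monte-Carlo error small relative to
each asserted tolerance while keeping the default test run fast.

## Known limitations

- The KS pre-filter's exactness guarantee is empirical (validated on
  fixtures), not proved; disable `prefilter` for a certified full scan.
- With unequal per-probe sample counts the KS candidate ranking uses the
  asymptotic p-value; in rare near-ties the exact-p argmax could differ.
- The mQTL variance-explained fraction assumes β on a
  variance-standardised methylation scale; tables with β on other scales
  yield relative, not absolute, fractions.
- `correlation_decay_profile` enumerates same-chromosome pairs in Python;
  it is sized for planted-cluster sets (~10³–10⁴ CpGs), not genome-wide
  scans.
- The pipeline's enrichment stage covers published-set overlap; interval
  proximity and SIV analyses are driven through their own functions/CLI
  subcommands rather than `run_pipeline`.
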
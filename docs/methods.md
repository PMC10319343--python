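# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic-data generators do and do not emulate, and
the design choices made where the underlying procedures are
conventionally under-specified.

## Differential protein abundance

The unit of analysis is one pairwise comparison of two conditions with
replicate label-free intensity columns; zeros encode missing
quantifications.  Fold changes follow the second-over-first convention
throughout the package, so *accumulated* always means more abundant in
the second condition of a comparison.

**Filtering.**  Proteins need at least `min_peptides = 2` supporting
peptides and at most `max_missing = 4` missing values across the two
conditions' samples (ten samples with the default five replicates per
condition).  Both thresholds are parameters; the missing-value budget
is counted over the comparison's samples only, so a protein may pass in
one comparison and fail in another.

**The condition-absent route.**  The missing-value budget and the
pseudo fold-change rule interact: a protein entirely missing in one
five-replicate condition carries at least five missing values and could
never pass the default budget, yet detected-only-in-one-condition
proteins are a reported result class.  `run_comparison` therefore
partitions proteins *before* applying the budget: those entirely
unquantified in exactly one condition (and with at least two quantified
replicates on the detected side) take the pseudo fold-change route and
are exempt from the budget; all others are filtered and tested.  The
standalone `filter_proteins` implements the literal budget rule.

**Normalization.**  Per sample, present intensities are
log2-transformed and standardized by the robust z-score
`(x − median)/(1.4826·MAD)`; the 1.4826 factor makes the MAD a
consistent normal-scale estimate.  If a sample's MAD is zero the
interquartile range (over 1.349) substitutes; if that is also zero the
sample is centered only and a warning logged.  The z-scores of all
samples are then rescaled by the grand median and the median per-sample
scale, so normalized values remain interpretable as log2 intensities
and every sample's median equals the grand median.  The t-test runs on
normalized values; fold changes are computed from raw log2 condition
means, which are unaffected by the per-sample transform.

**Testing.**  The classical pooled-variance two-sample t-test
(`df = n₁+n₂−2`, two-sided p) is computed per protein with at least two
present values per condition; proteins below that are reported
unclassified rather than erroring.  Identical constant groups give
t = 0, p = 1.  Adjustment is Benjamini–Hochberg (step-up with enforced
monotonicity, order-preserving, ties resolved by stable input order);
the adjustment procedure is conventional rather than prescribed, and BH
is the proteome-wide default.

**Pseudo fold change.**  When one condition is fully missing, its group
mean is replaced by the condition's detection floor: the mean of the
smallest `ceil(0.10·m)` per-protein condition means among the `m`
proteins quantified at least once in that condition (minimum one).
Using per-protein condition means (not individual sample intensities)
makes the floor robust to single-replicate outliers; the 10 % fraction
is a parameter.

**Classes.**  With defaults `alpha = 0.05`, `lfc_threshold = 1`:
accumulated / depleted require adjusted p below alpha and |log2FC| at
or beyond the threshold; only-in-first / only-in-second require a
pseudo fold change beyond the threshold toward the detected side.

## Enrichment

Rankings are t-statistics sorted descending, ties keeping stable input
order.  The enrichment score is the weighted running sum: hits add
`|score|^q / Σ_hits |score|^q` (weight exponent `q = 1` by default, the
classic choice; `q = 0` gives the unweighted statistic), misses
subtract `1/(N − n_hits)`, and the ES is the extremum of largest
magnitude.  When the two extrema tie in magnitude the earlier one is
taken; such ties are the one case where negating all scores does not
exactly flip the ES sign.  If every member score is zero, hits fall
back to equal weights.

Significance comes from `n_perm` random member sets of the same size
(gene permutation, the option available without replicate-level data).
NES divides the observed ES by the mean |ES| of same-sign null draws.
The p-value is sign-conditional:
`(1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null})`,
which is uniform under the null — a property the test suite checks by
Kolmogorov–Smirnov — and never smaller than `1/(n_perm+1)`.  Gene sets
with fewer than 5 or more than 500 members present in the ranking are
skipped by default.  Simple permutation is used, not an adaptive
multilevel scheme; at the default permutation depths the smallest
resolvable p is correspondingly bounded.

The over-representation counterpart is the upper-tail hypergeometric
probability of observing at least `k` set members in the selection,
given the set's size in the background, with fold enrichment
`(k/n)/(K/N)` and BH adjustment across sets.

## Germination indices

All indices are computed per replicate dish and then averaged; the
group rate indices are means of per-replicate rates (MGR = 1/MGT,
CVG = 100/MGT), *not* rates of the mean time.  The two differ by a
Jensen gap whenever replicate MGTs differ, and only replicate-level
averaging keeps group tables internally consistent.  Observation times
enter MGT as interval endpoints (the recorded observation day), not
midpoints; this is configurable by supplying adjusted time points.
Uncertainty uses log base 2 (units: bits).  T50 is the time at which
cumulative germination reaches half of the *final* germinated count,
linearly interpolated between bracketing observations; if the first
observation already meets the target, its time is returned, and a
record that never reaches the target between observations returns the
boundary time flagged `reached=False`.  Group comparisons use the
two-tailed heteroscedastic (Welch) t-test with significance stars at
0.05 / 0.01 / 0.001.

## Comet assay

Class assignment is an input: slides arrive as counts over visual
damage classes 0–4.  The arbitrary-unit score `100·Σ(N_c·c)/N_tot` is
linear in counts, invariant to scaling all counts, and bounded by
[0, 400]; its expectation for a multinomial slide is `100·Σ p_c·c`.
One hundred nucleoids per slide is a convention, not enforced.  Slides
are the replicate unit; groups are compared by Welch's t-test for
consistency with the germination comparisons.

## qPCR

Efficiency and Ct are estimated per reaction from background-subtracted
fluorescence.  Candidate cycles have positive signal below 80 % of the
curve maximum; the fitting window is the maximal contiguous run of such
cycles containing the amplification ramp, at least four cycles long.  A
log-linear regression of log2 F on cycle initializes a least-squares
fit of `F = F0·Eᶜ` in linear fluorescence space.  Fitting in linear
space matters: detector noise is approximately additive, so log
transformation inflates the scatter of near-baseline cycles, and a
pure log-space fit lets noise-dominated early cycles steer the slope.
With the exponential fit, noiseless curves are recovered exactly,
noise at 0.1 % of the plateau keeps per-curve efficiency error under
2 %, and noise at 1 % of the plateau keeps the mean error around 2 %
(per-curve errors up to ~8 % are possible there, an information limit
of the few pre-plateau cycles rather than an estimator artifact).
Reported r² is computed in linear space over the window; fits with
r² < 0.99 or E ≤ 1 are flagged low-quality.  Ct is the fractional
cycle where the fitted exponential crosses 20 % of the curve maximum.

Relative expression follows the efficiency-corrected ratio
`E_t^ΔCt_t / E_ref^ΔCt_ref` with ΔCt = control − sample, so induction
gives ratios above one.  Efficiencies are per-assay means across a
gene's reactions by default (per-reaction efficiencies are an option).
Multiple reference genes are combined by the geometric mean of the
per-reference ratios, the standard multi-reference convention; the
choice is order-invariant.  Transition tables report
`log2(mean second / mean first)` per gene with Welch's t-test on
replicate expression values.

## Cross-layer integration

Transcript and protein log2 fold changes are merged per gene ×
transition; pairs with a missing value in either layer are excluded
pairwise and counted.  Two procedures are reported side by side: the
Pearson correlation (two-sided t-based p, requiring at least three
complete pairs and non-zero variance) and a Mann–Whitney U comparison
of the two layers' fold-change distributions.  The Mann–Whitney test
uses exact enumeration of all group assignments (midranks, so ties are
handled naturally; two-sided p doubles the smaller tail, capped at 1)
when both groups have at most eight observations, and the
tie-corrected normal approximation otherwise.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis
assumes, at the study's design sizes:

* **Proteome:** log2 intensities `baseline + effect + N(0, sd)`,
  exponentiated; defaults baseline 20 (≈10⁶ raw), replicate sd 0.5,
  five replicates per condition, peptide counts ≥ 1.  Missingness is
  sporadic (missing completely at random) plus explicit condition-wise
  absence.  Real LFQ data add intensity-dependent dropout, correlated
  proteins, and heavier tails; passing tests therefore demonstrate
  correctness and calibration of the chain under its nominal model,
  not robustness to those real-data features.
* **Germination:** per-interval binomial thinning of the remaining
  ungerminated seeds (three dishes of twenty by default), i.e., a
  discrete hazard model; it does not emulate dormancy fractions or
  between-dish heterogeneity.
* **qPCR:** `min(F0·Eᶜ, plateau)` plus Gaussian noise floored at zero —
  a hard saturation rather than a sigmoid, adequate for exercising the
  exponential-phase fit but not for baseline-drift correction, which
  the package assumes has already happened.
* **Comet:** multinomial class counts (one hundred nucleoids per
  slide); no scorer bias or inter-slide overdispersion.

Every generator takes an explicit seed and owns a private
`numpy.random.Generator`; no global state is used or mutated, and the
same seed reproduces the same data byte for byte.

## Pipeline and reproducibility

`run_pipeline` executes simulate → per-comparison differential
abundance → preranked enrichment → germination → comet → qPCR →
integration from one declarative config, writing per-stage CSVs, a
per-comparison summary JSON (total quantified, accumulated, depleted,
only-in-one-condition), and a run log with the config and derived
seeds.  The bundled default config uses the eight-condition,
ten-transition layout of a priming time course at desk scale
(240 proteins, 24 spiked effects, 6 forced absences, a four-gene qPCR
panel whose programmed transcript shifts equal the mapped proteins'
effects — so the transcript–protein correlation has a known positive
truth).  Outputs are a pure function of (config, seed): CSV floats are
written with a fixed format and JSON keys sorted, and the test suite
asserts byte-identity of two runs.  Problem sizes in the default
config and the acceptance script (2,000-protein null tables, 500
spiked proteins, 500 comet slides, 999 permutations) were chosen to
keep Monte-Carlo error well inside each check's tolerance while
completing in seconds to a few minutes on one CPU.

## Known limitations

* The pooled t-test assumes equal group variances on the normalized
  scale; strongly heteroscedastic proteins are better served by the
  Welch option used in the physiology modules.
* Gene permutation for enrichment ignores inter-protein correlation;
  its p-values are anti-conservative on strongly correlated sets.
* The pseudo fold change depends on the detection-floor estimate and
  should be read as a direction-plus-magnitude flag, not a calibrated
  effect size; no p-value accompanies only-in-one-condition calls.
* Protein and gene identifiers must already agree across layers and
  gene-set files; no identifier mapping is performed.
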
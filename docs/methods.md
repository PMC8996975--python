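# Methods

## Model and procedure

The pipeline addresses a two-class, two-cohort biomarker problem: each
cohort is a probe-level expression study (disease vs. healthy) measured
on the same platform, supplied in two normalizations — a linear-scale
intensity matrix (MAS5 role) and a log2-scale matrix (gcRMA role) — plus
a probe→gene-symbol annotation and a gene-set collection (GMT). The goal
is a panel of genes that drive significant pathway enrichment in *both*
cohorts with concordant direction of change.

### Nonspecific filter

A probe passes when (a) its **mean linear intensity across all samples**
is at least `intensity_floor` (default 50) and (b) its coefficient of
variation on the **log2 track**, CV = 100·sd/mean with the sample
standard deviation (n−1), lies in the **closed** window
`[cv_low, cv_high]` (default [10, 100] %). Both predicates pool the two
phenotype classes. Choices that were genuinely open:

- The CV is sd/mean. The inverse ratio would make a 10–100% window
  nonsensical (it would select probes whose sd is 1–10× their mean).
- "Across all cases" is read as the mean reaching the floor; a strict
  mode (`strict_floor=True`, every sample ≥ floor) is provided because
  the aggregate reading is robust to single dropouts while the strict
  reading is not.
- Window endpoints are inclusive: a CV of exactly 10% passes.
- Rows with zero mean get an undefined CV and simply fail the window
  rather than raising: they are nonvariant by construction.

### Probe collapse

For each gene the single probe with the highest mean expression across
all samples is selected and its full row becomes the gene's row;
unmapped (control) probes are dropped. Ties on the mean go to the
lexicographically smallest probe id, making the collapse deterministic.
The linear matrix is collapsed with the *same* chosen probes as the log2
matrix, so downstream fold changes describe exactly the rows that were
ranked.

### Absolute GSEA

Genes are ranked by the signal-to-noise statistic
s_g = (μ_D − μ_C)/(σ_D + σ_C), with each class σ floored at 0.2·|μ| of
its class (0.2 when μ = 0) — the classical low-variance fix. The metric
is configurable (`s2n`, `t_like`, `log2_ratio`); signal-to-noise is the
default because it is the de-facto standard for two-class microarray
ranking. In absolute mode (default) the list is ordered by |s_g| so that
up- and down-regulated set members both enrich at the list top; the
classic signed mode is kept as an option.

The enrichment score walks the ranked list: hit steps are
|score|^p / N_R (p = 1 by default, N_R = Σ member weights) and miss
steps are 1/(N − n_S). ES is the running-sum excursion of maximal
magnitude. Numerical conventions:

- When positive and negative extrema tie in magnitude the positive one
  wins. The comparison uses an absolute tolerance of 1e−9 so that exact
  rational ties are not resolved by floating-point summation-order
  noise (an exact tie flipped sign depending on summation order before
  this guard).
- If all member weights are zero (all-zero scores with p > 0) the hit
  weights fall back to equal, keeping the statistic defined.
- Sets empty after intersection with the ranked universe, or spanning
  the whole universe, are skipped (the miss denominator degenerates).
- ES = 0 yields an empty leading edge and zero tag/gene/signal.

For permutations an O(n_S) sparse evaluation is used (the running sum
attains its maximum just after a hit and its minimum just before one);
it is tested to agree with the dense walk to 1e−12.

### Permutation statistics

Phenotype permutation is the default null: class labels are reshuffled,
the ranking recomputed, and each set rescored. When the requested
permutation count reaches the number of distinct label splits
C(n, n_D) − 1, the null is enumerated exhaustively (the observed
labeling is excluded); with 3 vs 3 samples this is the 19-split family.
Gene-set permutation (resampled member positions, fixed ranking) is
available for very small cohorts.

- Nominal p = (1 + #{|ES_π| ≥ |ES|}) / (1 + #same-sign permutations),
  the +1-smoothed permutation p within the sign class of the observed
  ES. Note that in absolute mode the label-swapped complement of the
  observed split reproduces the observed |s2n| exactly, so the
  attainable floor for an exhaustive 3-vs-3 family is 2/20, not 1/20.
- NES = ES / mean(same-sign |ES_π|) of that set's own permutations.
- FDR q follows the pooled-permutation procedure: every permutation ES
  is normalized by its set's same-sign mean; q = [fraction of pooled
  same-sign null NES at least as extreme] / [fraction of observed
  same-sign NES at least as extreme], clipped at 1, then made monotone
  (cumulative minimum from the weakest set upward within each sign
  class, so a stronger |NES| never carries a larger q).
- FWER p compares the observed NES with the per-permutation extreme
  normalized score, per sign class.
- The significance gate keeps nominal p < 0.05 (strict) and
  FDR q ≤ 0.25 (inclusive).

### Panel construction

Each gene's frequency is the number of significant sets whose leading
edge contains it. Selection is either `top_k` (default k = 10, boundary
ties kept — a deliberate choice since a frequency threshold is a
judgment call; the min-count mode makes the alternative explicit) or
`min_count`. Fold change is the ratio of linear-scale class means, and
up/down calls use strict comparisons (fc > up_cut, fc < down_cut) so
fc exactly at a cutoff of 1.0 is never called changed. Per-cohort
cutoffs default to 1.0/0.75 and are meant to be set per cohort (e.g.
1.5/0.5 for a tumor cohort). The shared panel intersects up-calls with
up-calls and down-calls with down-calls; pathway-name intersection is
case-insensitive after whitespace normalization.

### Validation statistics

2^−ΔΔCt: per sample ΔCt = mean target Ct − mean reference Ct, after
discarding replicates more than 1 cycle from the replicate median
(standard triplicate QC; at least two usable replicates required);
ΔΔCt subtracts the mean ΔCt of the calibrator *group* (not a single
designated sample, since comparisons are between groups); rq = 2^−ΔΔCt
and log2 fold expression is exactly −ΔΔCt, so a global Ct shift common
to target and reference cancels.

Mann–Whitney U is exact (full enumeration) for combined n ≤ 12 without
ties and otherwise uses the normal approximation with tie and
continuity corrections; each group must have ≥ 3 observations. The
implementation delegates to `scipy.stats.mannwhitneyu` and is
cross-checked in the tests against a brute-force enumeration of all
group assignments.

Survival: the expression split is at the sample median (values equal to
the median go low). An optimized "best cutoff" scan is deliberately not
offered — it inflates significance unless corrected. Kaplan–Meier uses
the product-limit form with events preceding censorings at tied times;
the log-rank statistic is the usual hypergeometric O−E sum, and
HR = (O_h/E_h)/(O_l/E_l) with CI exp(ln HR ± 1.96·√(1/E_h + 1/E_l)).
The O/E estimator is used instead of a Cox fit to stay within log-rank
machinery; for covariate adjustment use a Cox model (out of scope).
KM and log-rank agree with lifelines to numerical precision in the
tests.

## Synthetic-study generator

The generator emulates: multiple probes per gene (default 3); Gaussian
log2 intensities (log-normal linear intensities) with baseline 7.0 ± 1.0
— chosen so the linear mean ≈ 128 clears the intensity floor of 50 and
the log2-scale CV ≈ 14% sits inside the 10–100% window, i.e. ordinary
probes behave like real above-background variant probes; a linear track
derived as 2^x times multiplicative noise with unit median (sd 0.1 log2
units), preserving the premise that both tracks measure the same RNA;
planted gene sets shifting their members' disease-class mean by a signed
log2 effect; and decoy sets size-matched to the planted ones and drawn
from unplanted genes, which makes the permutation FDR meaningful at
desk scale.

The default two-cohort study uses 20 vs 20 samples, 300 genes, three
planted up-regulated sets of 20 genes per cohort that share 7 genes
across cohorts (with cohort-specific filler genes), and an effect size
of delta_log2 = 2. Shared genes therefore recur in ~3 significant
leading edges while fillers appear once — the frequency contrast the
panel stage exploits. All randomness flows from the design seed through
`numpy.random.SeedSequence([seed, crc32(cohort_id)])`, so identical
designs are byte-reproducible and the two cohorts get independent
streams.

qPCR fixtures plant a known log2 shift as a Ct offset (one cycle = one
doubling) with 0.2-cycle sample scatter and 0.15-cycle replicate
scatter, typical of SYBR triplicates. Survival fixtures draw exponential
event times with the hazard multiplied by the chosen ratio for subjects
above the median expression, and independent exponential censoring with
rate base_hazard·c/(1−c) so the censored fraction is near the nominal
rate c in the baseline group.

What the generator does **not** emulate: probe-level PM/MM structure,
GC-content effects, batch effects, correlated genes within sets,
heavy-tailed noise, or array-specific spatial artifacts. Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
statistics under a clean log-normal model — not robustness to the full
messiness of real arrays, nor anything about any particular public
dataset.

## Problem sizes

The test suite and the acceptance script run the pipeline at the scale
the generator defaults define: 900 probes × 40 samples per cohort,
33 sets per collection, 200 phenotype permutations per pipeline run
(nominal-p floor ≈ 0.005, comfortably below the 0.05 gate), 1000
permutations for the null-calibration and exhaustive-vs-Monte-Carlo
checks, and 10 independent study pairs for panel recovery. These sizes
are the package's reference conditions; they complete in seconds and
were chosen so the planted effects, not compute, limit what the checks
can show.

## Known limitations

- The FDR q and FWER procedures assume the permutation family is the
  same for all sets; with exhaustive enumeration on tiny cohorts the
  pooled null is small and q estimates are coarse.
- Absolute-mode ES can still be negative (a set concentrated at the
  list bottom); such sets are handled by the sign-class machinery but
  are rare and weakly powered.
- The O/E hazard ratio is biased toward 1 relative to a Cox estimate
  when hazards are strongly non-proportional or groups are unbalanced;
  the acceptance fixture (true HR = 3) typically yields estimates
  around 2.3–2.9.
- Symbol-level analysis only: probe-variant/isoform resolution is out
  of scope.
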
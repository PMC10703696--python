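# Methods

Coordinates throughout are 0-based half-open (BED convention). All
randomness flows through `numpy.random.default_rng` / `SeedSequence` from
explicit seeds; every public entry point that samples takes a `seed`.

## Per-cell ecDNA calling (`ecdna.caller`)

### Cell QC

A barcode is retained when all of the following hold (`CellQCThresholds`
defaults):

| check | rule | default |
| --- | --- | --- |
| mitochondrial fraction | mito / total < `max_mito_fraction` | 0.1 |
| ATAC fragments | `min_atac` ≤ n ≤ `max_atac` | 1,000 – 70,000 |
| RNA counts (optional) | `min_rna` ≤ n ≤ `max_rna` when present | 500 – 25,000 |

Comparisons are strict on the mito bound and inclusive on the count ranges;
cells without an RNA modality skip the RNA check.

### Null model

For each amplicon (a named set of genomic segments) the caller samples
`n_permutations` random regions of the amplicon's total length, uniformly
over the genome excluding a blacklist plus *all* amplicons. Sampling works
on admissible start positions: an exclusion `[a, b)` forbids starts in
`[a − L + 1, b)`; a chromosome is chosen with probability proportional to
its admissible start space, then a start uniformly within it. If no
admissible start exists, `GenomeExhaustedError` is raised rather than
silently relaxing the constraint. The same null regions are shared by all
cells so per-cell statistics are comparable.

### Test statistic and inference

The statistic is scaled coverage: overlapping fragment count divided by
region length (counts pooled across an amplicon's segments). Fragments are
counted by interval overlap using two `searchsorted` passes over per-chrom
sorted fragment starts (a fragment overlaps `[s, e)` iff `start < e` and
`end > s`; ends are bounded via a maximum fragment length window).

Per cell × amplicon: `r` = number of null regions whose scaled coverage is
≥ the observed (ties count as exceeding), `p = (r + 1)/(n + 1)`. This is
the standard permutation p-value; it is never 0 and is super-uniform under
the null (verified by a KS test in the suite). A z-score
`(obs − null mean)/null sd` (ddof = 1) is reported for effect size; a
zero-variance null yields NaN there, never a call. Benjamini–Hochberg
adjustment runs per amplicon across cells (step-up, hand-written, tested
against the literal definition and `statsmodels`), and a cell is called at
`q < q_threshold` (default 0.10). Zero-fragment cells get p = 1.

`PermutationConfig` defaults: `n_permutations=1000`, `q_threshold=0.10`,
`seed=0`; per-amplicon RNGs are spawned from one `SeedSequence` so results
do not depend on amplicon iteration order.

## FISH quantification (`ecdna.fish`)

Images are normalized to 0–255 (8-bit passes through; wider types are
linearly rescaled). Spot detection (`SpotCallParams`):

1. convolve with a sampled, sum-normalized Gaussian kernel, σ = 3 px, 7×7,
   reflect borders;
2. threshold the smoothed image at 15 (on 0–255);
3. label 8-connected components;
4. keep components whose **raw** peak exceeds image mean + 1 sd and whose
   area ≥ 4 px.

Spots map to cells by the segmentation label under their centroid; a cell
with count strictly greater than 5 is amplified. Between-sample
heterogeneity uses the two-sided Mann–Whitney rank-sum test (asymptotic,
tie-corrected, continuity correction) for location and Levene's test
centered at the mean for scale; identical samples and two constant groups
short-circuit to statistic 0 / p 1 rather than NaN. `fallback_segment`
(Otsu + hole filling + area ≥ 500 px) segments nuclei when no mask exists;
it is intended for synthetic fixtures, not production microscopy.

### Generator geometry

`gen_fish_image` renders nuclei as disjoint disks (radius 45–55 px on a
1,200² canvas, faint interior intensity 8) and spots as Gaussian peaks
(amplitude 200, σ = 1 px). Per-cell counts come from a Poisson(2) /
Poisson(20) mixture (30% amplified). A global minimum center separation of
12 px (4× the detector's smoothing σ) guarantees that smoothed
super-threshold regions of distinct spots never merge: two peaks of
smoothed amplitude P merge only if the saddle between them exceeds the
threshold, i.e. `2 P exp(−d²/(8 σ_eff²)) > 15`, which at d = 12 is safely
below 15 for the rendered amplitudes. When a sampled count cannot be placed
at that separation, the achieved count is recorded as truth rather than
forcing an unverifiable target.

## Fingerprinting (`ecdna.fingerprint`)

VAF = alt/(ref + alt) at panel loci with depth ≥ `min_depth` (default 1).
Pairs are compared by Pearson correlation over co-observed loci; pairs with
fewer than `min_shared = 100` shared loci or zero VAF variance are
indeterminate (NaN) rather than assigned a number. Duplicates are pairs
with r > 0.80. Under the generator (Hardy–Weinberg genotypes at allele
frequencies U(0.05, 0.95), binomial counts at Poisson depth 30, error rate
0.01), same-patient pairs have r ≈ 0.95 and unrelated pairs r ≈ 0.42 —
shared population allele frequencies alone induce that baseline, so the
0.80 threshold has a wide margin on both sides.

## Survival and mediation (`ecdna.survival`)

### Ridge Cox proportional hazards

The partial likelihood with Efron tie handling is written here (the ridge
penalty and its selection are the point of the module). Suffix cumulative
sums give each risk set's `Σw`, `Σwx`, `Σwxx` in O(n); the linear predictor
is stabilized by subtracting its maximum (invariant). Newton iteration with
step halving maximizes `loglik − (λ/2)‖β‖²`; convergence requires the
penalized gradient norm `< grad_tol · max(1, |penalized loglik|)` (default
`grad_tol = 1e-8`; the relative form is needed because the cumulative sums
put a float64 noise floor of ~1e-7 on the gradient at loglik scales of
~10³). Confidence intervals come from the inverse penalized observed
information. `ties="breslow"` is available; Breslow is exactly invariant
under record duplication while Efron is not (duplication creates ties).
The penalty λ is selected by k-fold (default 5) cross-validated held-out
*unpenalized* partial likelihood over `(0, 0.01, 0.1, 1, 10, 100)`; ties go
to the smallest λ, and folds without events are skipped with a warning.

The fit is verified against `lifelines.CoxPHFitter` (coefficients, SEs and
log-likelihood) and against a derivative-free Nelder–Mead maximizer of the
same likelihood.

### Log-normal AFT and mediation

`aft_fit` wraps `lifelines.LogNormalAFTFitter` (log T = Xβ + σε, censored
records contribute log-survival terms). Coefficients are reported with
`100·(e^β − 1)` percentage changes in survival time.
`mediation_baron_kenny` fits (1) mediator ~ exposure by logistic regression
(`statsmodels`), (2) outcome ~ exposure and (3) outcome ~ exposure +
mediator by AFT, and reports attenuation `1 − direct/total`. AFT rather
than Cox is used for the outcome models because hazard ratios are
non-collapsible and cannot be compared across nested models. Constant or
perfectly collinear exposure/mediator columns are rejected.

### 2×2 association

`chi2_2x2` is Pearson's test with Yates correction by default
(`scipy.stats.chi2_contingency`). `fisher_exact_2x2` is the two-sided
Fisher exact test (sum of hypergeometric probabilities of tables at most as
probable as observed, verified against exhaustive enumeration). The
`midp=True` option subtracts half the probability of tables exactly as
probable as the observed one (Lancaster mid-p) — a less conservative
variant sometimes quoted for sparse tables; on the [[12,11],[2,67]] fixture
table the standard two-sided p is 2.6 × 10⁻⁷ and the mid-p is 1.3 × 10⁻⁷.

## Synthetic generators (`ecdna.simulate`)

All generators are pure functions of a config dataclass. Highlights and
limitations:

- **Fragments**: uniform Poisson background over a 30 Mb three-chromosome
  toy genome plus chrM; ecDNA+ cells (10%) get additional amplicon
  fragments so their per-bp rate is CN/2 × background, CN integer
  log-normal (median 20, floor 5); mito fraction Beta(2, 48). No GC bias,
  no peaks/chromatin structure, no doublets — the generator validates the
  caller's statistics, not ATAC realism.
- **FISH**: see geometry above. No spot-intensity variation, no overlapping
  nuclei, no out-of-focus light.
- **Fingerprints**: independent loci (no LD), constant error rate.
- **Cohorts**: log-normal AFT with a binary mediator on the exposure path
  (logit P(M=1) = −2.5 + 3.5·E; log-time = 7 − 0.3·E − 0.8·M + 0.8·ε;
  uniform censoring) and, separately, an exponential proportional-hazards
  cohort (ln HR = ln 2.5) for Cox recovery. Covariates `subgroup`, `age`,
  `sex` are decorative noise, independent of outcome.

`fixture_tables()` carries the two 2×2 contingency tables used by the
association tests (SHH vs other subgroups by ecDNA status; TP53 alteration
by ecDNA status within SHH).

## Numerical conventions

- Empirical p-values are never 0; ties count against the alternative.
- BH is the exact step-up; q ≥ p always.
- Degenerate inputs raise (`FormatError`, `ConfigurationError`,
  `GenomeExhaustedError`, `FitError`) or return NaN sentinels where a
  number would be misleading; they never silently produce a call.
- Determinism: identical configs and seeds reproduce byte-identical tables
  (tested).
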
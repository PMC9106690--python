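# Methods

## Scope and data model

`plateqc` operates on exported plate tables: one row per injection, one
column per compound signal (integrated peak area for LC analytes, peak
intensity for FIA analytes) plus internal-standard columns and injection
metadata (sample type, condition, replicate, dilution factor).  It does not
touch raw instrument files, vendor peak picking, or absolute calibration
against the kit's standard curve; the unit of analysis is the exported
signal.  Vendor quantifiability status columns are accepted and ignored —
the pipeline applies its own detection logic, which is the point of the
method: analytes below the vendor's quantification limits can still be
relatively quantified if they clear a blank-based LOD and behave
monotonically under dilution.

Zeros in the input are measured zeros (and will fail the LOD filter);
empty cells are missing values.  Missing values are never imputed anywhere:
they are absent from sums, detection counts and RSDs.

## Filter cascade

Stage order: LOD filter → 60% detection rule → internal-standard
normalization → MAD sample-outlier removal → detection re-check →
sparsity rule.  Every removed value is recorded exactly once in the audit
trail with one of the rule ids `lod`, `detection_60pct`, `istd_missing`,
`outlier_mad`, `sparse_lt3`, so retained + rejected always equals the
non-missing input count (a tested invariant).

**LOD.** `LOD_c = max(m · median(blank_c), floor)` with multiplier `m = 3`
and `floor = 20 000` counts by default.  Values must *strictly* exceed the
LOD; a value equal to it is rejected.  Compounds without blank coverage
degrade to the floor alone, with a logged warning.  Because the floor is an
absolute count while signals scale with instrument response, a small drop
in overall sensitivity pushes near-threshold compounds out of the detected
set entirely — the pipeline reproduces this between-study irreproducibility
mechanism (see `test_sensitivity_drop_pushes_threshold_compounds_out`).

**Detection rule.** A compound is valid in a condition iff
`n_present / n_replicates ≥ 0.60`.  The denominator is the number of
replicates currently in the condition, so the re-check after outlier
removal uses the retained-replicate denominator (3 of 4 = 75% passes).
Recomputing after outlier removal is the default; `RunConfig.
recheck_detection=False` disables it.

**Outlier rule.** For each condition, normalized signals are summed per
replicate separately over the LC block and the FIA block; bounds are
`median ± k · MAD` with `k = 2.5` and `MAD = b · median(|s − median(s)|)`.
The consistency constant defaults to `b = 1.4826` — the standard scaling
in the canonical median ± 2.5 MAD outlier rule, which makes the MAD
estimate a normal standard deviation; `RunConfig.mad_scale = 1.0` gives the
raw form for sensitivity analysis.  The LC and FIA measurements are
separate acquisitions of the same extract, so a flagged replicate is
removed *from that block only*.  Removals per condition and block are
capped at `n_replicates − min_retained_replicates` (default 5 − 4 = 1),
most extreme first; surplus flags are recorded as `flagged_not_removed`.
At n = 5 the MAD rule is intrinsically trigger-happy: measured over 500
simulated clean plates it removes about 7% of clean (replicate, block)
acquisitions, while recovering planted 10× whole-injection outliers
essentially always.  Users should expect — as the cap anticipates — to
lose one replicate in roughly half of all condition–block combinations
even on clean data.

**Sparsity.** After everything else, a (compound, condition) cell with
fewer than 3 values is dropped.  With five replicates and the re-checked
60% rule this stage rarely binds; it matters when upstream stages have
reduced the replicate count.

## Repeatability and condition comparison

RSD is `100 · s / x̄` with the n−1 sample standard deviation, computed on
IS-normalized values.  Summaries report class × condition detected counts,
median RSD per measurement type and per class, and the below-threshold
fraction with a *strict* `< 15%` comparison (an RSD of exactly 15 does not
count).  Rendered percentage cells round half away from zero to the
nearest integer.

Small-sample note: at n = 5 the RSD estimator is biased low — the median
of its sampling distribution is ≈ 0.91× the true CV (E[s] < σ), so a
compound with true CV 15% will typically show an estimated RSD near 13.6%.
The acceptance script reports this recovery curve rather than hiding it;
the bias is a property of the estimator, not of the generator.

Conditions are compared by ranking each compound's metric 1..n across
conditions (ties averaged; missing conditions either ignored — the default
— or assigned the worst-rank category, a sensitivity variant that can
markedly change conclusions when missingness is informative).  The
Kruskal–Wallis statistic on the condition columns uses the tie-corrected
form

    H = [12 / (N(N+1)) · Σ nᵢ (R̄ᵢ − (N+1)/2)²] / [1 − Σ(t³−t)/(N³−N)]

with p from χ²(k−1); all values identical gives H = 0, p = 1 by
convention.  For small pooled sizes (N ≤ 10) an exact permutation p is
available by enumerating all group assignments.  Ranking per compound
before testing prevents high-RSD compounds from dominating the statistic;
the composite test is invariant under any strictly monotone transform of
the metric (tested).

The post-hoc comparison is Tukey–Kramer on pooled-rank means: the pair
(i, j) is significant when

    |R̄ᵢ − R̄ⱼ| > q_{α,k,∞} · sqrt( N(N+1)/12 · (1/nᵢ + 1/nⱼ) / 2 )

with the studentized-range quantile at infinite degrees of freedom (the
rank variance N(N+1)/12 is known, not estimated).  At k = 2 this reduces
exactly to the two-group Kruskal–Wallis decision (q = √2·z).  A classic
raw-mean Tukey–Kramer with pooled within-group variance and finite df is
provided for comparison (`use_ranks=False`).  No gating of the post-hoc on
the omnibus p is enforced in code; the sequential procedure is applied at
the reporting level.

## Dilution-series assessment

The relative-concentration ladder is `1/f` for factors
1.2, 1.4, 1.6, 1.8, 2, 3, 5, 7.5, 10, 15, 20, 30, 50, 100, three
injections per level.  Injections are LOD-filtered individually; a level
needs ≥ 2 surviving injections to contribute a mean (one survivor is too
fragile to estimate from).  Fewer than 4 usable levels excludes the
compound.  The linear range is the longest contiguous run of levels,
anchored at the least-diluted usable level, over which level means increase
strictly with concentration and an ordinary least-squares fit of mean
response vs relative concentration keeps R² ≥ 0.9.  Both thresholds are
parameters; the criterion itself is this package's testable reconstruction
of the qualitative requirement that more concentration must mean more
signal.  A compound is fully quantifiable only when that run covers the
entire design ladder — levels lost to the LOD already narrow the usable
range, so they demote the verdict to partial.  A monotone-decreasing
response gives Spearman ρ = −1 and an empty range.  FIA compounds are
assessed when dilution records exist but marked `design_verified=False`,
because the kit ships single-point calibration for them and the ladder
cannot be built from kit standards.

## Synthetic plates

The generator emulates the study design the pipeline assumes: five
biological replicates per condition (6 conditions in the bundled study
scripts: 5/15/25 mg cell mass × 10/20 µL loading volume), ≥ 3 PBS blanks,
4–6 pooled-QC injections, and the dilution ladder.  Signals are log-normal
with `σ² = ln(1 + cv²)` and the mean set so the *arithmetic* mean and CV
equal the configured values exactly — chosen over additive Gaussian noise
because intensities are strictly positive and because it makes CV recovery
a sharp test.  Defaults: compound mean 200 000 counts (comfortably above
the floor), CV 10%, IS mean 100 000 at CV 5%, blank median 2 000 counts at
CV 50% (so the 3× blank rule binds only when blanks are elevated, and the
20 000 floor binds otherwise — both LOD branches get coverage).  The blank
distribution is a modelling choice, not a measured property; it is fully
exposed in `ScenarioConfig`.  A global `sensitivity` scalar multiplies all
drawn signals (compounds, blanks and internal standards) to emulate
between-study instrument-response drift; it deliberately does not scale
the 20 000-count floor.

Planted truth (below-floor compounds, whole-sample outliers with scale ≠ 1,
per-compound/condition CV) is returned as `GroundTruth`.  One seed drives a
single stream with fixed draw order, so equal seeds give bit-identical
plates.

What the generator does **not** model: chromatographic peak shapes,
carry-over, within-plate drift or batch position effects, correlated noise
across compounds (residuals are independent given the injection's IS), or
informative missingness beyond the LOD mechanism.  Passing tests therefore
demonstrate that the pipeline implements its rules correctly and recovers
planted structure under the stated noise model — not that the rules are
optimal for any particular instrument.

## Numerical choices and degenerate inputs

- Detection and below-threshold comparisons are strict at the boundary
  (60% is valid, RSD exactly 15 is not below, value equal to LOD is
  rejected).
- MAD = 0 (all sums equal) collapses the outlier bounds to the median;
  equal values are not flagged, any deviation is.
- RSD is undefined (reported missing) for non-positive means or fewer than
  two values.
- Percent cells use exact integer arithmetic for round-half-away-from-zero.
- Tie handling everywhere is average ranks; the exact-enumeration p counts
  `H ≥ H_obs − 1e−9` to absorb float noise.
- Problem sizes in the bundled tests and the acceptance script (2 000
  Monte-Carlo conditions for RSD recovery, 500 seeded plates for outlier
  rates, 200 randomized plates for the structural invariants, 8-compound
  panels for per-seed work) were chosen to keep sampling error well inside
  the asserted margins while remaining quick on a laptop.

## Known limitations

- The p400-style built-in panel reproduces class counts and measurement
  types exactly, but individual lipid species names are systematic
  placeholders; matching real exports requires a user panel CSV.
- The compound → internal-standard map defaults to one standard per class;
  real kits use finer assignments, which a panel CSV can express.
- The dilution linear-range criterion is a reconstruction; with very noisy
  level means the anchored greedy run can stop early relative to a global
  best-subset search.
- The exact Kruskal–Wallis enumeration is limited to pooled N ≤ 10.
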
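# Methods

## The measurement model

An immuno-MRM assay quantifies a proteotypic peptide through a small set of
transitions (precursor → fragment pairs). For each sample, peptide and label
channel the instrument reports an integrated peak area, a background
estimate, and a retention time. The pipeline's quantitative chain is:

1. **Total intensity** per transition is *peak area + background*. The
   convention is taken at face value (background added, not subtracted);
   its consequence — upward bias of ratios at low analyte signal — is
   modelled, tested, and visible in the worked example's slopes.
2. **Specificity QC.** Light and heavy transitions are paired by transition
   id. A transition is flagged as interfered when the light/heavy
   retention-time difference exceeds `rt_tolerance` (default 0.10 min) or
   the channels' fractional (relative) transition areas differ by more than
   `rel_area_tolerance` (default 0.20, absolute difference of fractions).
   The source convention is qualitative ("same retention times and relative
   transition areas", reviewed manually); the numeric defaults here are
   declared, configurable and logged. Flagged transitions are excluded from
   **both** channels, so the retained transition set is identical in light
   and heavy. If fewer than `min_transitions` (default 2) remain, the
   peptide-sample is reported unquantified rather than quantified on a
   single transition.
3. **Ratio and concentration.** `R = Σ light / Σ heavy` over retained
   transitions (reciprocal orientation for response curves, where the heavy
   standard is the titrated analyte); `ĉ = R · c_heavy · m` with the known
   heavy spike `c_heavy` and the per-peptide spike multiplier
   `m ∈ {1, 10}`. Log2 ratios are carried alongside for downstream
   statistics.

## Figures of merit

* **CV** is always `100 · sd(n−1) / mean` on linear-scale ratios. Log
  transforms are used only for regression and the minimum-input bound.
* **LLOQ**: lowest calibration level with CV < 20% *whose every higher
  level also passes*. The suffix condition guards against an isolated low
  level passing by chance; when it changes the answer relative to the naive
  lowest-passing rule, the event is logged.
* **Linear range**: OLS of log10(mean ratio) on log10(concentration) over
  levels ≥ LLOQ. While R² < 0.90 and more than three levels remain, the
  highest level is dropped (saturation curls the top of the curve; the
  bottom is already handled by the LLOQ rule). ULOQ is the highest retained
  level, marked "minimum estimate" when the top measured level survives.
  "Correlation coefficient greater than 0.9" is read as R² ≥ 0.90 on the
  log–log fit; both the threshold and the reading are configurable.
* **Repeatability**: intra-assay CV = mean of within-day CVs; inter-assay
  CV = CV of per-day mean ratios. This is the simple two-stage scheme, not
  a REML variance decomposition — deliberately, as it is the estimator the
  validation convention defines. A consequence worth knowing: with no
  day-to-day effect the inter-assay CV estimates σ_w/√reps, *below* the
  intra-assay CV; the two do not converge as replicates grow.
* **Stability**: per condition, the replicate CV and
  `pct_diff = 100·|mean(treated) − mean(control)| / mean(control)` against
  the fresh control; stable iff CV ≤ 20% and pct_diff ≤ 20% (both
  config-exposed; the source flags outliers qualitatively).
* **Timecourse**: mean ratios normalized to the maximum timepoint; the
  plateau is the earliest timepoint ≥ (1 − 0.05) of every later mean.

## Panel application

Detection uses strict inequality (ĉ > LLOQ); boundary ties count as below
(conservative). Below-LLOQ cells stay in the matrix as "not detected",
distinct from missing cells (no QC-passing quantification). Clustering
keeps peptides detected in > 50% of samples, z-scores each peptide's log2
ratios over its detected samples (below-LLOQ cells are excluded, never
imputed), and applies average-linkage hierarchical clustering with
euclidean distances; distances over partially missing vectors use shared
coordinates rescaled to full dimension. Rows and columns are sorted
lexicographically before linkage so results are invariant to input order.

**Minimum input.** Signal-to-noise is operationalized as ĉ/LLOQ — an
interpretation, stated prominently: chromatographic S/N does not survive
into a transition report, and ĉ/LLOQ is precisely the margin the detection
rule tests. Per analyte, with n samples at reference mass M₀ (500 µg), the
mean of log S/N and its one-sided 95% t-bound (df = n − 1) define
detectability at mass m through the shift log(m/M₀); the per-analyte
minimum mass is `m* = M₀ · exp(t·s/√n − mean)`. The predicted count at each
grid mass {10, 25, 50, 100, 250, 500} µg is the number of analytes whose
lower endpoint stays above 0; the confidence band re-counts at the lower
and upper endpoints of the mean (so the lower band coincides with the
count — that re-count scheme is this package's definition). The t-bound on
*log* S/N reflects multiplicative noise; a linear-scale variant sits behind
`log_scale=False` for sensitivity analysis.

## The synthetic-data generator

Per transition *t* of a channel at concentration *c*:

    intensity = RF · f_t · c · exp(ε) + b_t

with response factor RF (1000 counts/fmol), fixed fractions f_t
(0.5/0.3/0.2 over three transitions), lognormal noise ε, and background
b_t ~ Normal(μ_b, σ_b) truncated at 0 (rejection-sampled; analytic moments
via the truncated-normal distribution).

Noise placement is the central design choice: day effects
(σ_b,day = 0.09975, i.e. ~10% CV) and replicate effects (σ_w = 0.05, ~5%
CV) are applied to the **analyte** channel only — the titrated heavy
standard in calibration/repeatability designs, the endogenous light
peptide in panel designs — while the reference channel carries signal plus
background. The internal-standard ratio then has within-replicate log-sd
exactly σ_w and day log-sd σ_b,day, giving closed forms the tests check
(e.g. day-mean CV = √(exp(σ_b² + σ_w²/reps) − 1)). Independent noise on
both channels would inflate the ratio sd by √2; fully shared noise would
cancel day effects and collapse inter- onto intra-assay CV. Attributing
the residual variation to the analyte channel is the cleanest model that
reproduces both the validation CV structure and an emergent LLOQ.

The background floor makes the ratio CV rise as the analyte concentration
falls; the analytic CV curve (exact lognormal moments + truncated-normal
background moments, delta method for the ratio) matches empirical CVs
within a percentage point and locates the generator's "true" LLOQ. At the
defaults the crossing sits near 1.28 fmol/mg on the default series
(2000, 200, 20, 8, 3.2, 1.28, 0.512, 0.205 + blank; four replicates per
level; constant 200 fmol/mg light spike; repeatability spikes 10/100/1000
fmol/mg over 5 days in process triplicate).

Other planted structure: per-sample endogenous concentrations are
lognormal (σ_sample = 0.6, ~66% inter-individual CV) around per-peptide
anchors; in truth-recovery mode the anchors are placed so each cell's
*expected estimate* (including the background bias) sits at least a factor
`detect_margin` away from the planted LLOQ on the correct side, making
flag-vs-truth comparison exact under the default noise. Group structure
shifts disjoint signature peptides by `effect · σ_sample` on the log scale
in their group's samples. Stability arms are modelled as repeat injections
of stored aliquots of one prepared capture and carry injection-level noise
(1%) rather than full process noise; a planted recovery factor on the
heavy analyte under one storage condition shifts the light:heavy ratio by
its reciprocal (0.8× → +25%), cleanly separable from the 20% stability
threshold at that noise level. The timecourse plants a saturating recovery
profile (0.55/0.85/1.0/1.0 at 2/6/16/24 h) — a shape, not a kinetic model.

## What the synthetic checks do and do not show

Passing tests establish that every estimator recovers the quantities the
generator planted, at the nominal noise levels, and that all statistics
agree with independent brute-force implementations. They do not establish
performance on real biospecimens: the generator has no chromatographic
drift, carryover, heteroscedastic detector noise, digestion kinetics,
matrix-dependent recovery or correlated interference structure, and the
panel concentration distributions are planted rather than biological. The
committed end-to-end regression (fixed seed, byte-for-byte) pins the whole
pipeline's numeric behavior, not its biological validity.

## Numerical conventions

CSV outputs are canonicalized: sorted keys and either shortest-repr floats
(transition reports, which must round-trip losslessly) or `%.10g`
formatting (analysis tables). Degenerate inputs fail loudly: fewer than
two replicates, non-positive means, zero-denominator channels, zero
variance in z-scoring (dropped with a warning) and unknown design roles or
modification tokens all raise typed errors. Problem sizes in the test and
acceptance runs (1–50 peptides, 12–40 samples, 100-seed calibration loops)
were chosen as the smallest designs at which the Monte-Carlo tolerances of
the closed-form checks hold comfortably.
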
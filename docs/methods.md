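# Methods

`ionkernel` re-implements, as a tested library, the data-processing and
statistical workflow used for single-kernel ionomic profiling of maize:
ICP-MS signal correction, analytical outlier removal, and the
quantitative-genetic analysis of seed elemental concentrations from a
two-year multi-block field trial. Because the original raw instrument
files live behind an external data portal, the package ships a synthetic
data generator that emulates the field design and the instrument-run
structure with known ground truth, so every stage of the pipeline can be
verified end to end.

## Measurement model and corrections

A digested kernel is measured as a solution; the instrument reports a
per-element signal plus an internal-standard (IS) channel (indium, spiked
into the digestion acid at 20 ppb). The forward model used by both the
simulator and the correction chain is multiplicative:

    signal(t) = c_solution x b_run x d(t) x r(t) x noise
    is_signal(t) = IS_nominal x r(t) x noise

where `b_run` is a per-run response factor, `d(t)` is within-run
sensitivity drift as a function of injection position, and `r(t)` is the
sample-introduction/recovery curve. Because the IS travels with every
sample, `r(t)` multiplies analyte and IS channels identically — that is
precisely why dividing by the observed/nominal IS ratio removes it.

Corrections are applied in this order:

1. **Calibration** (optional): per-element ordinary least squares on a
   six-level dilution series, `signal = slope x ppb + intercept`.
   Intercept retained; negative back-calculated concentrations floored at
   zero with a flag; non-positive slopes flag the element.
2. **Internal standard**: each analyte at a position is multiplied by
   `IS_nominal / IS_observed`. Positions with a dead IS channel are
   excluded individually.
3. **Within-run drift**: a matrix-matched control (a pooled bulk of the
   study samples) is injected every tenth position and at both ends of the
   run, so every sample is bracketed. The fractional change between two
   consecutive controls is assumed to accrue linearly across the samples
   between them — the first sample after a control receives one tenth of
   the bracket's drift — and the correction factor is the control
   trajectory interpolated linearly in position, normalized to the run's
   first control. Drift is treated as a *multiplicative* sensitivity
   change (factors, not offsets): this preserves positivity and makes the
   chain invariant to rescaling all channels at a position. Samples
   before the first or after the last control are rejected by default;
   `allow_extrapolation` extends the nearest bracket's line instead.
4. **Between-run drift**: each run is scaled by reference/run control
   level, where the run level is the mean of its drift-corrected controls
   and the reference defaults to the first run's level (the project's
   reference run, assumed accurately calibrated; any miscalibration of
   the reference is an irreducible global scale shared by all samples).
5. **Dilution and weight normalization**: seed ppm (mg/kg) =
   solution ppb x (5.0/0.9 secondary dilution) x 0.010 L digest /
   seed mass in kg / 1000. A 1 ppb solution from a 0.25 g seed is
   0.2222 ppm.

Every multiplicative factor applied to a reading is retained in an audit
table, so `raw x is_factor / drift_factor x run_factor x norm_factor`
reproduces the reported concentration exactly. When simulated drift is
piecewise linear between control positions and noise is zero, the chain
inverts the forward model exactly (round-trip error at machine precision,
asserted at 1e-9 relative); with the default 2% multiplicative noise it is
approximate, which is the realistic regime.

## Outlier removal

Within each group and element independently, a reading is removed when
`|x - median| > k x MAD`, with k = 15 and MAD the raw median absolute
deviation (no 1.4826 consistency factor — the rule counts MADs directly).
One pass only; group statistics are not recomputed after removals. Groups
with MAD = 0 remove nothing, and groups below the minimum size (3) pass
through untouched. Grouping defaults to the plot (line x year x block) for
replicated designs, with line-level grouping available.

A caveat worth stating explicitly: with only ~5 seeds per plot the sample
MAD is extremely noisy, and the probability that a *clean* reading exceeds
15 sample-MADs is of order 1e-2, not ~0 (direct simulation). The rule
behaves as intended — essentially zero false positives — when the group
holds ~20+ readings, which is what line-level grouping provides in this
design (5-6 plots x 4-6 seeds). The verification suite therefore measures
the false-positive rate under line-level grouping, and the contamination
simulator constructs its spikes to exceed the cutoff in the
*post-injection* group statistics (a spike perturbs the very median and
MAD the filter computes; spikes in the same group inflate each other's
MAD, so magnitudes are escalated jointly until every spike clears the
cutoff), which makes "detectable spike" a guarantee rather than an
expectation.

## Genotype/year analysis

Plot means (arithmetic, over kept seeds) are analyzed per element with a
fixed-effects two-way ANOVA: line, year and their interaction. Sums of
squares are Type II, computed by incremental residual-sum-of-squares
comparisons between nested OLS fits on treatment-coded design matrices;
on balanced data this equals the sequential decomposition, and the
implementation is cross-checked in the test suite against brute-force
projection matrices and statsmodels `anova_lm`. F-tests use the residual
mean square; the multiple-testing cutoff is Bonferroni, alpha / number of
elements (0.01/20 = 0.0005 by default).

Heritability is method-of-moments from the expected mean squares on a
line-mean basis, with r the harmonic mean replicate count (6 and 5 blocks
give r = 60/11) and y the number of years:

    s2_G  = (MS_line - MS_LxY) / (r y)      s2_GY = (MS_LxY - MS_res) / r
    single year:  h2 = s2_G / (s2_G + s2_e / r)
    combined:     h2 = s2_G / (s2_G + s2_GY / y + s2_e / (r y))

Components are clamped at zero before forming the ratio, so h2 is always
in [0, 1]. The material is inbred lines, so this line-variance ratio is a
broad-sense quantity even though the output column keeps the customary
"h2" label. Between-year reproducibility is the Pearson correlation of
per-line year means, with the usual t-test on r; fewer than three shared
lines is reported as undefined.

The single-seed jackknife asks how much is lost by measuring one kernel
per plot: each of 100 datasets draws one seed uniformly per plot from the
*unfiltered* seed table (single-seed sampling destroys the within-plot
distribution the outlier rule is defined on), refits the two-year model,
and the per-element p-value and combined-h2 distributions are summarized
at their 5th percentiles (linear interpolation): the value 95% of
single-seed datasets beat. Replication within a jackknife dataset is the
block count, identical in every draw.

## Cob-position and sugary analyses

The cob experiment models one genotype sampled at base/middle/tip of
several ears across farms. The ANOVA is additive — farm, field position,
cob section — and per-term shares of the total sum of squares are
reported; ear identity is deliberately not a model term and enters only
through ear-wise averaging in the descriptive statistics: the within-ear
dynamic range (max/min section mean per ear, averaged over ears) and the
normalized gradient (section means divided by the ear mean, averaged
across ears), which averages to 1 across sections under balanced
sampling. Field position is a plain additive factor (labels shared across
farms); nesting it within farm is possible by recoding labels but is not
the default. The sugary analysis is an additive line + sugary-genotype
ANOVA comparing collapsed su/su kernels with plump Su/+ siblings
segregating in the same plots.

## Synthetic data generator

The generator is first-class, tested code; its defaults emulate the study
conditions rather than convenient ones.

* **Field design**: 26 founder lines of the maize NAM panel in a
  randomized complete block design, 2010 (6 blocks) and 2011 (5 blocks),
  4-6 seeds analyzed per plot. The three low-seed-weight founders
  (IL14H, HP301, P39) are excluded from analysis by default.
* **Effects** are simulated on the log scale by default (concentrations
  are positive and genotype differences fold-like): per-element grand
  mean (realistic kernel ppm values, from ~0.01 ppm Cd/Co/As to
  thousands of ppm P/K) plus independent normal line, year, line x year,
  plot and seed effects. An additive mode with a positive floor is
  provided for sensitivity checks and is used where an exactly linear
  decomposition is needed (e.g. heritability parameter recovery, where
  the expected-mean-squares estimator's analytic target is exact).
* **Default variance components** (log scale): var_g = 0.02,
  var_y = 0.005, var_gy = 0.008, var_plot = 0.02, var_e = 0.06, giving
  single-year h2 ~ 0.75-0.8 and combined h2 ~ 0.7 — the mid-range of
  well-measured elements in this kind of trial. The interference-prone,
  low-abundance elements (B, Na, Al, Se) get a weak-signal profile
  (var_g = 0.005, inflated noise), reproducing their known low
  heritability. The plot-level variance term is our addition: the
  published model has no block term, but field data plainly contain
  plot-to-plot heterogeneity, and without it plot means would be
  unrealistically precise. The within-plot (seed-to-seed) magnitude is
  not stated anywhere and is chosen here as var_e = 0.06 (~25% CV),
  documented as an assumption.
* **Instrument runs**: samples are loaded in order into runs of up to 576,
  with a control opening the run, following every tenth sample, and
  closing the run, so drift interpolation is total. The control pool is
  the grand mean of the samples' solution concentrations, mirroring a
  matrix-matched bulk. Within-run drift is a multiplicative random walk
  sampled at control positions (linear between them, so the correction
  model is exactly right at zero noise), the IS-recovery curve multiplies
  both channels, run factors are lognormal with the first run fixed at
  1.0 (the reference run), and noise is 2% multiplicative by default.
* **Contamination** spikes are rare (probability per reading) and replace
  the reading with median + 25 MADs of the group by default, escalated to
  guaranteed detectability as described above.
* **Cob/sugary defaults**: gradients for the elements with known
  base-to-tip patterns (e.g. Ca 1.25/1.00/0.85, Sr 1.35/1.00/0.80),
  farm-level variance dominating field position (as observed in
  multi-location trials), and a 1.25-fold concentration shift with a
  0.75-fold weight shift for su/su kernels in the nine elements that
  respond to the sugary locus.

What the generator does **not** emulate: isobaric/polyatomic
interferences and detection-limit censoring, calibration-curve
nonlinearity, vendor file formats, spatial field structure beyond the
block label, outcrossing, and any covariance between seed weight and
composition (off by default). Passing tests therefore demonstrate the
correctness of the corrections and estimators under the stated model, not
robustness to those unmodeled artifacts.

## Numerical choices

* Reproducibility: every generator keys `numpy.random.default_rng` on
  (stream id, user seed), so each stage draws from an independent,
  deterministic substream; identical seeds give byte-identical CSVs.
* All corrections in double precision; CSV output at 6 significant
  digits.
* ANOVA degrees of freedom come from fitted ranks, so missing levels and
  collinear terms degrade gracefully (flagged, never silently wrong);
  a saturated interaction is dropped with a warning; a constant response
  reports zero SS and p = 1 with a flag.
* Jackknife quantiles use linear interpolation (NumPy default).
* Problem sizes used in the verification suite: the NAM-scale design
  (23 lines x 11 plots x 5 seeds, runs of 576) for processing checks;
  100 replicate experiments for heritability recovery and for the
  jackknife comparison (100 datasets each); 1e5 clean readings for the
  outlier false-positive rate; 50 random designs plus 1000 null
  simulations for the ANOVA engine.

## Known limitations

* The drift correction is exact only for piecewise-linear sensitivity
  drift; smooth nonlinear drift between controls leaves a residual of
  order the curvature across ten samples.
* The heritability estimator assumes the (possibly unbalanced) two-way
  layout; heavily missing cells would call for REML, which is out of
  scope along with mixed models, spatial field models and QTL mapping.
* Type II SS fractions are an exact partition only on balanced
  (orthogonal) designs; the cob experiment is balanced by construction.
* With one observation per cell the interaction cannot be separated from
  error; the model reduces to main effects with a warning.
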
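# Methods

## The model

The package treats a compiled set of substitution-rate estimates as draws
from a power-law decay of the estimated rate with the age of the calibration
used to obtain it. On the log10 scale that is a straight line,

    log10(rate_i) = alpha + beta * log10(t_i) + e_i,   e_i ~ N(0, sigma^2),

with `rate` in substitutions/site/year and the calibration time `t` in
years. `beta` is the quantity of scientific interest: `beta = 0` means no
time-dependence; `beta = -1` is the signature of the purely arithmetic
artifact in which the "rate" is nothing but an age-independent genetic
distance divided by the age. Intermediate values mean the estimated rate
genuinely declines with the measurement timescale — the pattern usually
attributed to purifying selection purging transient deleterious mutations at
short timescales and unmodelled mutational saturation depressing estimates
at long ones.

The assumptions are those of ordinary simple regression: independent,
homoscedastic Gaussian errors on the log scale, and an error-free regressor.
Published calibration ages are certainly not error-free and the estimates
are not fully independent (shared markers, shared calibrations), so the
preparation step collapses the most blatant dependence (below) and the
p-values should be read as descriptive, as is conventional for this kind of
meta-analysis.

## Preparation rules

Two reductions prevent single species from dominating the fit:

* **Within-study marker averaging** — when one study reports several
  mitochondrial markers for one species (same marker class, same
  calibration time), the rates are averaged into one record. Groups whose
  members disagree on calibration time are ambiguous and raise an error
  rather than being silently pooled.
* **Point-group pooling** — records matched by a configurable selector
  (e.g. all human pedigree studies) are replaced by a single record at the
  mean rate and mean calibration time.

"Average" is the arithmetic mean on the natural scale by default. Because
the analysis runs on the log scale there is a case for the geometric mean,
and both are implemented (`mean="geometric"`); the default follows the plain
reading of "the average". Pooled records keep their calibration type if it
is uniform across the group and are marked `mixed` otherwise, and their
species/study fields carry the pooling label so provenance stays auditable.
Both operations are idempotent and never increase the record count.

## Regression and inference

Fits use the closed-form simple-regression formulas (slope = Sxy/Sxx,
SE = sqrt(RSS/(n−2)/Sxx)) with two-sided Student-t p-values on n − 2 df,
implemented directly because the slope test against an arbitrary null b0 —
in particular b0 = −1 — is the analysis's core statistic. R² is unadjusted.
Base-10 logarithms are used throughout so intercepts read as log10 rate at
1 year and the windows align with powers of ten. A fit requires n ≥ 3;
smaller subsets return a flagged degenerate result (rendered "n/a" in
reports) rather than raising, except that zero variance in log-time is a
hard error ("regression undefined"). Points are unweighted: published rate
estimates come with wildly heterogeneous and often unreported uncertainties,
and the meta-analysis treats each estimate as one observation.

## Time-slice windows

`standard_windows()` returns nine slices in report order: six sliding
windows with upper/lower = 10^4 (10^0–10^4 … 10^5–10^9 years) and three
shrinking windows pinned at 10^9 years (10^6–10^9, 10^7–10^9, 10^8–10^9).
Window bounds are closed on both ends by default — a record exactly at 10^4
years belongs to both 10^0–10^4 and 10^1–10^5. The windows overlap by
construction, so the convention only affects boundary points; a half-open
variant (`closed=False`) exists for disjoint accounting. No minimum-N
filter beyond n ≥ 3 is applied to windows.

## The spurious-self-correlation screen

Each record's implied total genetic distance is d_i = rate_i × t_i
(substitutions/site). One randomization replicate draws a uniform random
permutation of the distances — a shuffle, not a bootstrap, so the marginal
distribution of distances is preserved exactly — rebuilds rates as permuted
distance over original time, and refits the regression. Permutation is done
within the analysed subset, matching a per-subset screen. Because the
regressor never changes across replicates, each null slope reduces to
−1 + xc·(log10 d_perm − mean)/Sxx with xc the centered log-times; the B
replicates are computed in one vectorized pass (the tests assert this equals
per-replicate refits, and centering the log-distances makes the
all-equal-distance limit exactly −1 rather than −1 plus round-off).

The observed slope is located in the null distribution by a centered
two-sided empirical p-value with the +1 correction:

    p = (1 + #{b : |slope_b − m| ≥ |observed − m|}) / (B + 1),

m the mean of the B null slopes; the attainable floor is 1/(B+1). A
parametric t-test of slope = −1 runs alongside, and a subset is reported as
inconsistent with pure self-correlation only when both p-values fall below
the threshold (default 0.05; 0.005 and 0.0005 are the conventional stricter
tiers). B defaults to 10,000 and the seed is recorded in every result, so
any null distribution can be regenerated bit-identically.

## The synthetic generator

Calibration times are drawn log-uniformly over a configurable range
(default 10^0–10^9 years), matching the roughly even order-of-magnitude
spread of published calibrations and guaranteeing every window is exercised.
Three scenarios generate rates:

* `time_dependent`: the model above; defaults beta = −0.3, alpha = −7
  (log10 subs/site/year at 1 year), sigma = 0.5 — decay and scatter of the
  magnitude seen in coding-marker compilations (beta near −0.5 with a higher
  intercept is a reasonable noncoding-like setting).
* `ssc_null`: distances d ~ LogNormal(mu = −3, sigma = 1) (natural-log
  parameters; median distance ≈ 0.05 subs/site, inside the range implied by
  compiled rate × time products) drawn independently of time; rate = d/t.
  True slope −1: everything the regression sees is artifact.
* `no_dependence`: log10 rate = alpha + noise; true slope 0.

Metadata are synthetic labels chosen to exercise the subsetting machinery
(taxa round-robin; calibration types by age stratum: pedigree-like < 10^2
years, ancient-DNA-like < 10^6, fossil/biogeographic above). The generator
reproduces the *statistical* pattern only: there is no sequence evolution,
no purifying selection or saturation mechanism, no among-taxon rate
heterogeneity, no correlation structure from shared calibrations, and no
publication bias. Passing tests therefore demonstrate that the estimators
and screens behave correctly under the assumed generative structure, not
that real compilations satisfy that structure.

`recovery_experiment` repeats simulate + fit over consecutive seeds and
reports slope bias, RMSE and nominal-95% CI coverage; with n = 200,
sigma = 0.5 the slope is recovered with |bias| < 0.02 and coverage within
binomial error of nominal, as standard OLS theory predicts.

## Numerical and design choices

* Empirical p centered on the null mean rather than on −1: the finite-B
  null mean is the natural center and the choice matters only at the third
  decimal for wide time spans.
* CI coverage in `recovery_experiment` uses a 1e-10 relative tolerance so a
  noiseless fit (SE ≈ 0 with the slope equal to beta up to round-off)
  counts as covered.
* Degenerate replicates cannot occur in the randomization (the regressor is
  fixed with positive variance, which is checked once up front).
* Enum-valued metadata are normalized case-insensitively through an alias
  table ("non-coding", "NC" → noncoding; "aDNA" → ancient_dna, …) because
  literature tables are inconsistent; rows with missing rate or time are
  rejected, not imputed — both enter the log-log regression and there is no
  defensible default.
* Problem sizes in the test suite and acceptance script (n = 200 datasets,
  B = 10,000 permutations for headline quantities, B = 999 inside the
  200-dataset calibration experiments) keep the full suite in the
  seconds-to-minutes range while leaving Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

* The regression ignores estimation error on both axes and non-independence
  among estimates beyond the two preparation rules; a hierarchical or
  errors-in-variables model is out of scope.
* The screen's two tests are reported jointly but are not independent, and
  the empirical p-value's resolution is bounded by 1/(B+1).
* Reproducing a specific published compilation's numbers can depend on the
  original authors' (often unstated) pooling conventions — hence the
  arithmetic/geometric switch.
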
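# Methods

## Statistical model

The pipeline treats the longer *HTT* CAG allele length as a continuous
per-sample covariate and each probe's log2 expression as the response.
Two analyses are run over the same matrix:

**Continuous.** For each probe, the Pearson correlation r between
expression and `cag_long` over all samples (HD and control together), with
the two-sided p-value from the exact t transform
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. Spearman's ρ is computed
alongside on mid-ranks (average ranks at ties) with the same t
approximation; significance calls rank by the Pearson p only. Only the
longer allele is used — the shorter allele does not modify HD onset and is
carried solely as sample metadata.

**Dichotomous.** For each probe, a two-sample Student's t-test of HD
(CAG>35) versus control (CAG<36) samples. The classical pooled-variance
form with df = n₁+n₂−2 is the default; the name "Student's t-test" is taken
literally, but the Welch–Satterthwaite form is available (`welch=True`)
because many analysis environments default to it and the choice is not
always recorded in practice. The signed fold change is derived from the
log2 mean difference Δ: fc = 2^Δ for Δ ≥ 0 and −2^(−Δ) otherwise. This
convention makes fc an odd-symmetric function of Δ with |fc| ≥ 1: +2 means
doubled in HD, −2 halved. Other conventions (ratio-of-means on the linear
scale, unsigned log ratios) exist; this one is pinned because it is exactly
invertible from the log2 means the t-test already uses.

Significance in both analyses is a nominal (uncorrected) p < α with α =
0.01 by default, using a strict inequality; this matches the screening
character of the comparison — the object of study is the *relationship
between the two significant sets*, not any individual gene call. No
multiple-testing correction or covariate adjustment is applied, and
zero-variance probes yield flagged rows (statistic NaN, p = 1) rather than
aborting a genome-wide scan.

## Concordance metrics

With C the continuous-significant set and D the dichotomous-significant
set:

* detection rate = 100·|C∩D|/|C| — how much of the CAG-length-correlated
  signal the dichotomous design recovers;
* continuous-missed rate = 100 − detection rate;
* shared-of-dichotomous rate = 100·|C∩D|/|D|;
* non-CAG call rate = 100 − shared-of-dichotomous rate — the fraction of
  dichotomous hits that are not CAG-length-correlated.

The complementary pairs hold exactly by construction and are enforced by
tests on random set systems. Rates are carried at full precision and
rounded to one decimal only for reporting. A zero denominator (an empty
significant set, as on null data) leaves the pair of rates NaN — explicitly
undefined rather than silently 0 or 100.

The direction cross-tab classifies probes by (sign r, sign Δ). Probes with
exactly zero r or Δ carry no direction and are excluded from the quadrant
percentages (renormalised over signed probes) — a measure-zero event on
continuous data.

## Subsampling power simulation

The reference set is fixed once: the continuous-significant set from the
*full* panel at the same α. For each per-group size n and replicate, n HD
and n control samples are drawn uniformly *without replacement* within
groups (replacement would make the top of the range, n equal to the full
control group, incoherent), the pooled t-test is run on every probe over
that subset, and the two rates are computed against the reference set with
the same concordance code path used everywhere else. Each (n, replicate)
cell derives its own RNG substream from the master seed via
`SeedSequence([seed, n, replicate])`, so the table is reproducible and
independent of execution order.

Both rates are then regressed on n by OLS over all replicate-level points
(not per-n means; with equal replicate counts the slope is identical, and
points preserve the spread for R²). The fitted line is solved for the
per-group n reaching a target rate: n\* = (target − β₀)/β₁, refusing when
the slope sign cannot reach the target. Linearity is a deliberate
convenience — the true metric-vs-n curves must saturate (rates are bounded
by 100%), so any n\* outside the simulated range is returned with an
explicit extrapolation flag and should be read as a lower bound on "more
samples than the design had", not a precise requirement. Nonlinear
(saturating) models are intentionally out of scope.

Defaults: α = 0.01, 1,000 replicates per n over n = 3..41. The test suite
and acceptance script use a coarser grid (n ∈ {5,…,41}, 100–200 replicates,
2,000–10,000 probes), sizes chosen so Monte-Carlo error stays well below the
monotone trends being asserted.

## P-value calibration

QQ tables compare sorted observed p-values with uniform-order-statistic
expectations; the expected quantile for rank i of m is i/(m+1) by default —
the mean of the i-th order statistic, which also avoids −log10(0) at the
extreme rank. i/m and (i−0.5)/m are available as options since QQ plot
conventions differ across tools. Tests are treated as independent when
forming expectations (no effective-test-number correction). The
genomic-control inflation factor λ is the median of χ²₁-quantile-transformed
p-values divided by the theoretical null median 0.4549; λ ≈ 1 indicates
calibrated statistics.

## Synthetic data generator

The generator's role is to provide ground truth for every stage. Its
model: a correlated probe is

    y(s) = baseline + slope·cag_long(s) + ε,   ε ~ N(0, noise_sd²)

with baseline ~ N(baseline_mean, baseline_sd²) per probe and the slope
calibrated as slope = r·noise_sd/(s_cag·√(1−r²)) (s_cag the ddof=1 sd of
the panel's CAG lengths), which makes the target r exactly the correlation
the sample Pearson coefficient estimates on the fixed design. A consequence
worth noting: because the slope scales with noise_sd, the *sample* r is
invariant to the noise scale — shrinking noise_sd does not push r toward 1,
it keeps it pinned at the target with sampling spread (1−r²)/√n. Null
probes are baseline plus noise.

Defaults (chosen once to emulate the study conditions): 10,000 probes, 5%
correlated, target |r| uniform on [0.15, 0.43] with random sign (matching
the observed coefficient range of roughly −0.43 to 0.40), baselines
N(6, 2²) and noise sd 0.5 on the log2 scale. Target correlations with
|r| < 0.02 are excluded as operationally null. An additive per-sample batch
offset can be injected (`batch_sd`) but is off by default; the pipeline
assumes batch-corrected input.

The fixed 107-sample panel is a hand-constructed literal reproducing the
cohort's published marginal statistics exactly — 41 controls (CAG<36) and
66 HD (CAG>35); longer allele min 15, max 92, mean 40.9; shorter-allele
mean 17.6; two donor-duplicate cell-line pairs (107 lines, 105 subjects) —
because the true per-sample genotypes were never published. It is a
conforming stand-in, not the real panel. `generate_panel` draws random
panels instead: control longer alleles ~ rounded N(21, 4²) on [15, 35], HD
~ 36 + rounded Gamma(2.2, 5) capped at 92, a right-skewed shape mimicking
the adult-onset cluster in the low 40s with a juvenile-onset tail.

What the generator does *not* emulate: probe-level array structure (PM/MM
probes, spatial artifacts), gene–gene correlation networks, heavy-tailed or
heteroskedastic noise, and genotype–covariate confounding. Passing tests
therefore demonstrate correctness of the *inference machinery* under a
linear-Gaussian world, not that real lymphoblastoid data meet those
assumptions; in particular the simulated detection rates and extrapolated
sample sizes depend on the assumed effect-size mixture and will differ from
any real cohort's.

## Numerical and interface choices

* Loaders reject duplicates, missing values and sample-set mismatches
  outright; expression/sample joining is by ID, never position.
* Matrices are assumed already normalised (gcRMA-like log2 output);
  normalisation and batch correction are out of scope.
* Degenerate t-tests: both groups constant with equal means → t = 0,
  p = 1; unequal means → ±∞ with p the smallest positive double.
  Correlations against a constant vector are flagged (NaN statistic, p = 1).
* p-values are floored at the smallest positive double so they stay in
  (0, 1] even when |r| = 1 exactly.
* Box summaries in gene reports use linear-interpolation quartiles
  (`numpy.percentile`, method "linear") so exports are bit-stable; report
  statistics are copied from the association table, never recomputed.
* Site export serialises JSON with sorted keys; re-export of identical
  input is byte-identical.

## Known limitations

* The linear metric-vs-n extrapolation ignores saturation; required-n
  estimates beyond the simulated range are flagged extrapolations.
* Pooled-vs-Welch ambiguity is resolved by the literal reading
  ("Student's"); results at these group sizes are insensitive, but the flag
  exists for sensitivity analysis.
* All 107 panel samples are treated as independent observations even though
  two donors contribute two cell lines each, mirroring the emulated design.
* The continuous analysis assumes a linear expression–CAG relationship;
  Spearman's ρ is reported as a monotone-robust companion but does not
  drive significance calls.
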
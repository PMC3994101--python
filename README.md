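# cagnome

Continuous vs dichotomous analysis of *HTT* CAG repeat length–correlated
gene expression.

## The problem

Huntington's disease (HD) is caused by expansion of the CAG trinucleotide
repeat in *HTT*: alleles of ≥36 CAGs cause disease, and longer repeats cause
earlier onset, so the repeat length behaves as a *continuous* genotype.
Most expression studies nevertheless analyse HD *dichotomously* — cases
(CAG>35) versus controls (CAG<36) — throwing away the length information.
This package quantifies what that costs. Given a log2-scale expression
matrix (probes × samples) and per-sample CAG genotypes, it:

1. runs a **continuous analysis** — per-probe Pearson (and Spearman)
   correlation of expression with the longer-allele CAG length over *all*
   samples — and a **dichotomous analysis** — per-probe Student's t-test of
   HD vs control, with a signed fold change;
2. checks p-value **calibration** against the Uniform(0,1) null (QQ tables,
   genomic-control λ);
3. computes **concordance** between the two significant sets at nominal
   p < α (default 0.01): Venn counts, the detection rate (% of
   continuous-significant probes found dichotomously), the non-CAG call rate
   (% of dichotomous-significant probes that are not CAG-correlated), and a
   direction-of-change cross-tabulation;
4. runs a **subsampling power simulation**: for per-group sizes n it draws n
   HD + n control samples without replacement, repeats the dichotomous
   analysis, scores it against the full-sample continuous reference set, and
   fits linear models `metric = β₀ + β₁·n` to extrapolate the per-group n
   required to detect 80% of the continuous signal or to cut non-CAG calls
   to 20%;
5. exports a static per-gene **report site** ("CAGnome"): scatter data
   (CAG vs expression), HD/control box summaries, and the three statistical
   summaries per probe, as JSON plus a self-contained HTML browse page.

A **synthetic-data module** generates sample panels and expression matrices
with known correlation structure — including a fixed 107-sample panel (41
controls, 66 HD; longer-allele range 15–92, mean 40.9; shorter-allele mean
17.6 CAGs) matching the lymphoblastoid cohort this design emulates — so the
whole pipeline is testable with ground truth and no downloads.

## Core statistics

For probe *g* with expression vector *y* and longer-allele lengths *c*:

* Pearson: r = cov(c,y)/(s_c·s_y), two-sided p from
  t = r·√((n−2)/(1−r²)) on n−2 df; Spearman is the same on mid-ranks.
* Student's t (pooled): t = (ȳ_HD − ȳ_ctrl)/√(s_p²(1/n₁+1/n₂)),
  df = n₁+n₂−2 (Welch available via `welch=True`).
* Signed fold change: Δ = ȳ_HD − ȳ_ctrl (log2 units);
  fc = 2^Δ if Δ ≥ 0 else −2^(−Δ), so |fc| ≥ 1.
* Genomic control: λ = median(χ²₁(p)) / 0.4549.

## Worked example

```python
import cagnome as cg

panel = cg.default_cag_panel()                      # the fixed 107-sample panel
cfg = cg.GeneratorConfig(n_probes=5000, frac_correlated=0.05, seed=42)
matrix, truth = cg.generate_expression(panel, cfg)  # 5% of probes CAG-correlated

cont = cg.run_continuous(matrix, panel)
dich = cg.run_dichotomous(matrix, panel)
cont_set = cg.call_significant(cont.set_index("probe_id")["p_pearson"], 0.01)
dich_set = cg.call_significant(dich.set_index("probe_id")["p_t"], 0.01)
metrics = cg.concordance_metrics(cg.concordance_counts(cont_set, dich_set))
print(f"detection rate: {metrics.detection_rate:.1f}%")

pts = cg.run_power_simulation(matrix, panel, cont_set,
                              [5, 10, 15, 20, 25, 30, 35, 41],
                              n_reps=100, seed=7)
for name, m in cg.fit_power_models(pts).items():
    print(f"{name}: slope {m.slope:+.2f}%/sample, R^2 {m.r_squared:.2f}, "
          f"required n/group {m.required_n:.0f}")
```

prints

```
detection rate: 50.3%
detection_rate: slope +1.12%/sample, R^2 0.90, required n/group 75
dich_noncag_rate: slope -1.57%/sample, R^2 0.87, required n/group 46
```

Here the full-panel dichotomous analysis recovers only half of the probes
the continuous analysis calls significant, and the fitted lines say a
dichotomous design would need ~75 samples per group to reach 80% detection
and ~46 per group to push non-CAG-correlated calls below 20% — both beyond
the 41 controls available, i.e. they are extrapolations (flagged as such by
`extrapolate_required_n`).

The same pipeline is available from a shell via the `cagnome` command
(`simulate`, `associate`, `concord`, `qq`, `power`, `report` subcommands);
run `cagnome --help`.

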
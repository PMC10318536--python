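# raschval

A psychometric validation pipeline for polytomous rating scales,
built around the 14-item / five-category balance-assessment design
(items scored 0–4, totals 0–56) but reusable for similar instruments.
It implements, end to end:

* **Classical & Mokken preliminaries** — Cronbach's alpha (with
  alpha-if-deleted and item-rest Spearman correlations), normed-covariance
  scalability coefficients (H, Hj, Hij) with the automated item selection
  procedure, polychoric correlations, and a one-factor ordinal factor
  analysis (ULS on the polychoric matrix) with residual-based local
  dependence flags.
* **Partial credit Rasch analysis** — conditional maximum likelihood item
  estimation via elementary symmetric functions (Newton iteration with
  analytic gradient and Hessian), ML person measures with the 0.3
  extreme-score adjustment, Wilson–Hilferty fit residuals, item-trait
  chi-square over ability class intervals, threshold-disorder detection,
  residual correlations with the relative local-dependence cut-off
  (LDRC = mean residual correlation + 0.2), and the unidimensionality
  t-test (PST with its binomial confidence bound).
* **Testlet adjustment** — super-item construction for locally dependent
  item clusters (default: items 1–6 & 8–11 vs 7 & 12–14), PCM re-fit,
  subscale indices (c, r, A), and a conditional total fit statistic that
  compares category patterns with their exact distribution given each
  person's total score.
* **DIF analysis** — two-way ANOVA of standardized residuals
  (factor × class interval) with Bonferroni control, and the anchored
  split-impact check (Cohen's d of the paired person-estimate shift).
* **Reliability & targeting** — PSI, alpha, SEM, targeting index,
  floor/ceiling rates, the distribution-free count of distinct levels of
  performance ability (DLPA), and the distribution-independent PSI
  (G²/(1+G²)).
* **Anchored confirmation** — exporting item parameters and re-running
  the full battery on confirmation subsamples with parameters held fixed.
* **Score conversion** — raw-total → logit measure table with SEs, 95%
  CIs, and a 0–100 rescale.
* **Sampling** — the time-dependency-avoiding subsample construction
  (one observation per patient per subsample; A1/A2/B1/B2 + excluded C),
  balance checks, and validation-sample selection by score range.
* **External validity** — Spearman associations with clinical anchors
  (EDSS, ABC, falls), Mann–Whitney / Kruskal–Wallis group comparisons
  with the effect-size conversion chain r = |z|/√N, d = 2r/√(1−r²)
  (η² = (H−k+1)/(n−k) for k groups), and normality assessment.
* **Synthetic data** — a first-class generator producing cohorts with a
  right-skewed (mistargeted) ability law, testlet-structured local
  dependence, optional uniform DIF, 1–3 observations per patient, and
  EDSS/ABC/falls covariates monotonically linked to ability, so every
  stage is testable without any external dataset.

## Command line

The console script `raschval` exposes the pipeline stages:

```bash
raschval simulate --seed 1 --n-patients 800 --out data.csv
raschval split    --in data.csv --seed 1 --out-dir splits/
raschval prelim   --in splits/subsample_B1.csv --out prelim.json
raschval rasch    --in splits/subsample_B1.csv --out-dir rasch_out/
raschval validity --in data.csv --measures rasch_out/conversion_table.csv \
                  --seed 2 --out validity.json
raschval all      --out-dir run/            # full pipeline on synthetic data
```

`raschval all` writes per-stage delimited tables (subsamples, balance
check, item parameters, conversion table), a summary table with one row
per (sample, analysis) plus the recommended-values footer, a verdicts
JSON derived entirely from the configurable `DecisionThresholds`, and a
run log. Identical configs and seeds reproduce byte-identical outputs.

## Package layout

```
src/raschval/
  io_types.py           # records, response matrix, delimited I/O
  synthetic_data.py     # simulation of persons, responses, covariates
  sampling.py           # time-independent splits, balance checks
  classical_scaling.py  # alpha, Mokken, polychoric, ordinal CFA
  rasch_core/
    pcm.py              # PCM probabilities, CML estimation, person measures
    fit.py              # fit residuals, chi-square, residual structure
    testlets.py         # super-items and subscale indices
    dif.py              # residual ANOVA DIF and split impact
    reliability.py      # PSI, SEM, targeting, DLPA, DI-PSI
    andersen.py         # conditional total fit statistic
  external_validity.py  # correlations, group comparisons, normality
  cli_report.py         # pipeline orchestration, verdicts, CLI
```
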
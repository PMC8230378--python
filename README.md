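# panelstrat

White-box construction of biomarker panels for triaging ischemic-stroke
patients at low risk of post-stroke infection. The package reproduces a
complete discovery → validation study design on synthetic cohorts:

- **`panelstrat.synthetic_cohort`** — patient-level cohort generation
  calibrated to published per-class median/IQR summaries and class counts
  (lognormal labs, normal temperature/age, discretized-lognormal NIHSS),
  with exact class counts, seed determinism and a CSV round trip.
- **`panelstrat.calibration`** — the built-in discovery (40 = 19 + 21) and
  validation (243 = 204 + 39) subgroup calibrations.
- **`panelstrat.cohort_stats`** — median/IQR summaries, Mann–Whitney U
  (exact enumeration for small samples), Fisher's exact test, Pearson
  chi-squared, and crosstab percentage rows.
- **`panelstrat.roc_analysis`** — ROC curves with midpoint cutoffs,
  trapezoidal AUC (equal to the tie-corrected concordance), and
  sensitivity-constrained cutoff selection.
- **`panelstrat.rule_mining`** — class-association rules over
  entropy-discretised marker intervals (support / confidence / lift) and an
  ordered rule-set classifier.
- **`panelstrat.decision_tree`** — CART-style trees (Gini, minimum
  terminal-node size, no pruning, triage-safe leaf tie-break).
- **`panelstrat.panel_search`** — exhaustive k-of-n threshold-panel search:
  enumerate marker subsets × cutoff grids × vote counts, maximise
  specificity at a sensitivity floor (high-SE) or vice versa (high-SP).
- **`panelstrat.pipeline`** — orchestration: each method selects markers on
  the discovery subgroup, thresholds/rules/trees are re-estimated on the
  validation subgroup, and SE/SP are reported for both, plus a stability
  ranking.

## CLI

```bash
# synthetic discovery + validation cohorts from the built-in calibration
panelstrat simulate --seed 7 --out cohort.csv

# demographics-table statistics (median/IQR, Mann-Whitney, Fisher/chi2)
panelstrat stats cohort.csv --out table.json

# per-marker ROC table at a 90% sensitivity floor
panelstrat roc cohort.csv --subgroup validation --se-min 0.9 --out roc.json

# class-association rules
panelstrat rules cohort.csv --subgroup discovery --min-confidence 1.0 --out rules.json

# decision tree
panelstrat tree cohort.csv --subgroup discovery --markers saa,pct,nihss --min-leaf 4 --out tree.json

# k-of-n threshold panel (high-SE mode, SE >= 0.95)
panelstrat panel cohort.csv --subgroup validation --markers saa,wbc,nihss \
    --mode high-se --min-se 0.95 --out panel.json

# full discovery -> validation study report
panelstrat run --seed 7 --out report.json
```

Exit code 2 signals a configuration error (bad CSV, bad config).

## Notes

- Markers are drawn independently within class; the published summary
  tables carry no correlation structure.
- The two-parameter lognormal fit reproduces the requested median exactly
  and the quartile ratio q3/q1 exactly; when the printed quartiles are not
  log-symmetric around the median, all three cannot be matched at once.
- All randomness flows through explicit integer seeds; identical seeds give
  byte-identical cohorts and reports.
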
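# ctadx

Staged stenosis/plaque-burden classification rules for detecting ischemic
coronary artery disease from quantitative coronary CTA measures, with the
full surrounding analysis machinery:

- **`ctadx.synth`** — synthetic patient cohorts with the joint structure the
  analysis assumes: a two-component stenosis marginal, a log-linear
  stenosis→PAV (percent atheroma volume) link, a logistic latent-ischemia
  model, and the *selective referral* protocol (PET perfusion imaging only
  when the visually read stenosis reaches a cutoff; unreferred patients are
  labelled non-ischemic — the verification-bias structure of the registry).
  Also ships the published 2×2 count tables as versioned JSON fixtures.
- **`ctadx.pet_rule`** — the reference-standard rule: abnormal stress
  perfusion when hyperaemic MBF ≤ 2.30 mL/min/g in at least two adjacent
  AHA-17 segments, excluding the basal septum (segments 2–3), with a
  documented, injectable polar-map adjacency table.
- **`ctadx.rules`** — the rule family: binary stenosis cutoff (Model 1),
  stenosis gate + PAV threshold (Model 2), and the three-zone staged rule
  (Model 3), all expressed in one algebra (`StagedRule`).
- **`ctadx.metrics`** — Se/Sp/PPV/NPV/accuracy with Wilson CIs, Youden's J,
  two-point-ROC AUC, and paired between-rule tests (exact McNemar for
  Se/Sp, a generalized score statistic for PPV/NPV, paired normal test for
  AUC differences).
- **`ctadx.search`** — Youden-index threshold selection within a stenosis
  subgroup and the exhaustive three-parameter grid search over
  (lower, upper, PAV threshold); the default grid (1–99% × 1–99% by 1%,
  0.1–49.0% by 0.1%) evaluates 2,425,500 rules in seconds via cumulative
  2-D case/control histograms that are bit-identical to naive enumeration.
- **`ctadx.pipeline` / `ctadx.cli`** — end-to-end orchestration and a CLI.

## CLI

```sh
ctadx reproduce-table3                      # published accuracy table from fixtures
ctadx simulate --n 20000 --seed 1 --out cohort.csv
ctadx simulate --n 20000 --seed 1 --planted 30:70:12.0 --flip-prob 0.1 --out planted.csv
ctadx evaluate --cohort cohort.csv --rule model1 --rule 30:70:12.2 --json eval.json
ctadx search --cohort planted.csv --grid default --out search.json
ctadx classify --cohort cohort.csv --rule 50:inf:16.8 --out calls.csv
ctadx label --perfusion perfusion.csv --out labels.csv
ctadx report --config run.json             # full pipeline from a JSON config
```

Rules are written `lower:upper:pav` (`upper` may be `inf`; an empty band,
`upper < lower`, is a plain binary cutoff at `lower`) or referenced by name
(`model1`, `model2`, `model3`).

## Conventions worth knowing

- All threshold comparisons are inclusive (`>=`), band membership is
  inclusive at both ends.
- AUC of a binary classification is defined as its two-point ROC area,
  `(Se + Sp) / 2` — this matches the published AUCs recomputed from the
  count tables.
- Grid-search ties on Youden's J are enumerated exactly (integer count
  arithmetic) and broken toward higher specificity, then narrower band,
  then lower PAV threshold. The one-dimensional subgroup search breaks
  ties toward higher sensitivity, then the largest threshold.
- The segment adjacency of the 17-segment polar map is a documented
  convention (see `ctadx/pet_rule.py`) and can be overridden with a JSON
  edge list.
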
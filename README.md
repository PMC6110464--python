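# seasonniche

Seasonal Grinnellian-niche analysis for migratory species.

Migratory birds either track one set of climatic conditions around their
annual cycle (*niche followers*) or occupy different conditions in the
breeding and wintering grounds (*niche switchers*). Distinguishing the two
— and describing how transit-month records relate to the internal structure
of each seasonal niche — takes a chain of analyses that are usually spread
across several tools: presence-only niche models fitted per season,
transfer of each model onto the other season's climate, a partial-ROC
evaluation, distance-to-centroid structure, polar-coordinate niche breadth,
and a randomization test on Schoener's *D*. `seasonniche` packages that
chain for monthly climate rasters (tmax, tmin, prec) and dated occurrence
records, and ships a synthetic-data generator with known ground truth so
every stage can be validated end to end without any external download.

## What it computes

* **Seasonal rule-set niche models.** For each season a genetic algorithm
  evolves an ordered list of climatic rules (range boxes, negated boxes,
  logistic rules); 100 seeded replicates are fitted and the 10 best kept —
  replicates with training omission ≤ 10 % whose commission (fraction of
  the modeling region predicted present) is closest to the survivors'
  median. The ensemble's per-cell *agreement* (0–10 members voting
  presence) is the suitability surface; a majority consensus gives the
  binary map. Projecting the ensemble onto other months' layers is the
  same prediction call — that is the transferability the design tests.
* **Partial ROC.** Sensitivity vs proportion-of-area curve over agreement
  thresholds, restricted to sensitivity ≥ 1 − *E* (default *E* = 0.05),
  summarized as AUC ratio ∈ [0, 2] (1 = chance) with a bootstrap p-value.
* **Niche structure.** Climate over the predicted-presence cells is
  Z-standardized (mean 0, sd 1, sample convention), so the niche centroid
  is the zero vector; each cell's distance to the centroid
  DC = √Σⱼ z²ⱼ is classified into optimal / suboptimal / marginal zones
  (default breakpoints 1.515 and 2.95, overridable or `"auto"`).
* **Polar-coordinate breadth.** Each variable is a force vector at a fixed
  angle; a cell maps to the vector sum of its min-max-scaled values. The
  alpha-hull of the cloud is the occupied climate area (breadth); two
  stages' hulls are rasterized on a shared lattice for directional percent
  overlap.
* **PCA-env similarity.** A two-axis PCA calibrated on both seasons'
  environmental backgrounds; occurrence densities are kernel-smoothed,
  corrected by availability and compared by Schoener's
  D = 1 − ½ Σ|z₁ − z₂|, with a 100-replicate randomization null drawn from
  the pooled records.

## Worked example

```python
from seasonniche.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(scenario_kind="switcher", delta=6.0, seed=7))

print(summary["seasons"]["breeding"]["partial_roc"]["auc_ratio"])  # 1.895453034
print(summary["inter_prediction"]["breeding_onto_winter"]
      ["projection_to_resident_pct"])                              # 0.0
print(summary["similarity"]["breeding_vs_winter"]["d_observed"])   # 0.002358237
print(summary["migratory_zones"]["winter_structure"]
      ["suboptimal_marginal_fraction"])                            # 0.967391304
```

This simulates a niche switcher whose breeding and winter centroids sit six
standardized units apart on a 120 × 120 monthly climate grid (246 breeding,
83 winter and 96 migratory records), fits both seasonal ensembles, and runs
the full comparison. Reading the numbers: the breeding model is far better
than chance (AUC ratio 1.90); its projection onto winter climate lands on
0 % of the winter model's own area (the seasons do not inter-predict);
observed *D* between the seasonal occurrence densities is ≈ 0 (complete
differentiation); and 97 % of migratory records fall in the suboptimal or
marginal zones of the winter niche — the joint signature of a niche
switcher. Rerunning with `scenario_kind="follower", delta=0.0` inverts
every one of those signals (inter-prediction > 70 %, *D* ≈ 0.8).

The same analysis runs from the shell on files
(`seasonniche simulate | fit | project | evaluate | structure | breadth |
similarity | profile | run-all`);
`seasonniche run-all --config run.yaml --out rundir` writes
ensembles (JSON), agreement maps (ESRI ASCII), the cleaned occurrence CSV
and a machine-readable `summary.json` that is bit-identical across reruns
of one config.

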
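# braingraph

Graph-theoretic analysis of resting-state functional brain networks, from
regional BOLD time series to covariate-adjusted group statistics.

The package targets the common resting-state fMRI workflow in which cohorts
(for example patient groups at different clinical stages versus healthy
controls) are compared on the topology of their functional connectomes. It
implements the full chain:

1. **Time-series cleaning** — discard initial volumes, framewise-displacement
   (FD) scrubbing with spike regressors (threshold 0.2 mm, one volume before
   and two after each bad volume), Friston-24 motion regression plus linear
   trend and white-matter/CSF signals, and an ideal 0.01–0.08 Hz band-pass at
   TR = 2 s.
2. **Network construction** — Pearson correlation between all pairs of the
   116 atlas regions, Fisher Z transform, and binarization at a grid of
   sparsity levels S = 0.05 … 0.50 (step 0.01, 46 levels), where sparsity is
   the fraction of realized edges among R(R−1)/2 possible ones. Edges come
   from one global Z ranking, so edge sets are nested across the grid.
3. **Topological metrics** — clustering coefficient Cp, characteristic path
   length Lp, global and local efficiency (Eg, Eloc), and the small-world
   ratios γ = Cp/Cp_rand, λ = Lp/Lp_rand, σ = γ/λ against degree-preserving
   (Maslov–Sneppen) rewired null networks; nodal degree (DC), betweenness
   (BC), and nodal efficiency (NE). Every metric curve is summarized by its
   area under the curve (AUC) over the sparsity grid.
4. **Group statistics** — ANCOVA-style omnibus F tests of the group factor
   with age, gender and mean FD as covariates, Benjamini–Hochberg FDR within
   metric families, gated pairwise post-hoc contrasts, and partial
   correlations between surviving metrics and clinical variables.

Because such analyses are normally run on patient data that cannot be
shared, the package ships a **synthetic cohort generator**: subjects with
modular ROI correlation structure, group differences expressed purely as a
within-module connectivity scaling, realistic motion traces with scrubbing-
detectable spikes, and clinical covariates tied to a chosen network metric
at a target partial correlation. Every stage of the pipeline is exercised
and tested against this generator.

## Worked example

Simulate a small three-group cohort (12/10/14 subjects, 30 regions in 6
modules, within-module correlation scaled ×1.5 in the complication group and
×1.2 in the no-complication group), run the full pipeline, and test the
group effect:

```python
import numpy as np, pandas as pd
import braingraph as bg
from braingraph.metrics import global_metrics_for_stack, auc_summary
from braingraph.stats import full_inference

spec = bg.CohortSpec(
    groups=(("T2DM-C", 12), ("T2DM-NC", 10), ("HC", 14)),
    n_rois=30, n_modules=6, n_timepoints=200, seed=11,
    r_within=0.3, r_between=0.1,
    group_effect={"T2DM-C": 1.5, "T2DM-NC": 1.2, "HC": 1.0},
    covariate_model={},
)
cohort = bg.simulate_cohort(spec)
root = np.random.SeedSequence(11)
rows = []
for i, s in enumerate(cohort.subjects):
    pre = bg.preprocess_subject(s.timeseries, s.motion, s.wm_signal, s.csf_signal)
    stack = bg.build_stack(bg.fisher_z(bg.correlation_matrix(pre.timeseries)))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,)))
    gdf = global_metrics_for_stack(stack, bg.NullEnsembleSpec(n_null=8, swaps_per_edge=10), rng)
    rows.append({"subject_id": s.subject_id, "group": s.group,
                 "age": s.covariates["age"], "gender": s.covariates["gender"],
                 "mean_fd": pre.mean_fd, **auc_summary(gdf)})
results, _ = full_inference(pd.DataFrame(rows))
print(results.summary())
```

Output (abridged):

```
Group comparison of AUC network metrics
groups: HC, T2DM-C, T2DM-NC   covariates: age, gender, mean_fd   FDR q = 0.05

Omnibus (incremental F of the group factor):
  Eloc_auc                     F =   13.290  p = 7.359e-05  p_fdr = 0.0004951 *
  Cp_auc                       F =   12.084  p = 0.0001415  p_fdr = 0.0004951 *
  Eg_auc                       F =    8.372  p = 0.001291  p_fdr = 0.003013 *
  gamma_auc                    F =    5.238  p = 0.01119  p_fdr = 0.01958 *
  sigma_auc                    F =    4.671  p = 0.01713  p_fdr = 0.02399 *
  lambda_auc                   F =    1.822  p = 0.1792  p_fdr = 0.209
  Lp_auc                       F =    1.489  p = 0.2418  p_fdr = 0.2418

Post-hoc pairwise contrasts (gated by omnibus FDR):
  sigma_auc              HC vs T2DM-C: t =  -2.832  p = 0.009985  p_fdr = 0.01922 *
  Eloc_auc               HC vs T2DM-C: t =  -4.336  p = 0.0002909  p_fdr = 0.001091 *
  ...
```

Reading it: the AUC of local efficiency and of the small-world ratios is
elevated in the groups whose within-module connectivity was scaled up
(negative t for HC minus patient group), while path length and λ do not
differ — exactly the pattern the generator was designed to produce. Omnibus
F values are incremental F tests of the group factor over the covariates;
`p_fdr` is the Benjamini–Hochberg-adjusted p within the 7-metric global
family, and post-hoc contrasts are only run for metrics that survive it.

The same analysis is available from the shell:

```bash
braingraph run-all --config my_config.yaml --seed 11
```

with stages `simulate`, `prep`, `network`, `metrics`, `stats` also runnable
individually on the intermediate TSV/JSON files.

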
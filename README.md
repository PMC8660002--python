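# painconn

Connectome-wide moderation analysis of chronic-pain history: how the
duration of a person's worst musculoskeletal pain, jointly with its
intensity, associates with ROI-to-ROI resting-state functional connectivity
(RSFC) in older adults.

Chronic pain is thought to reshape brain networks gradually, so the number
of years lived with pain — moderated by how severe that pain is — is a
natural predictor of connectivity differences.  `painconn` implements the
full analysis pipeline for that question, aimed at researchers working with
ROI-level resting-state fMRI and pain-history interviews:

* **Denoising and connectivity** — motion/scrubbing/aCompCor/rest-regressor
  nuisance design, percent-signal conversion, 0.008–0.09 Hz band-pass,
  weighted Pearson correlation of every ROI pair, Fisher transformed
  (`z = atanh(r)`; 2,850 edges for the 76-ROI atlas).
* **Edge-wise moderated regression** — at every edge,
  `z ~ WPINT * X + sex + age + pain_med + moca + scanner_pain`, where
  WPINT is worst-pain intensity and X is duration under a log10, linear,
  or ≤5 vs >5-year coding, with stepwise backward elimination
  (interaction first, then WPINT, keeping X) gated by Benjamini–Hochberg
  FDR across all edges at each step.
* **Johnson–Neyman moderation** — for edges retaining `WPINT:X`, the
  moderator values at which the simple slope `β_X + β_int·W` is
  significant, solved in closed form from the coefficient covariance.
* **Pain-vs-control deviation** — the adjusted pain-group prediction along
  a duration grid contrasted with the covariate-adjusted control mean
  (intercept of `z ~ sex + age + moca` with covariates centred at pooled
  means), with Welch-combined standard errors.
* **Synthetic cohorts** — a first-class generator producing covariate
  tables, multivariate AR(1) BOLD series with exactly controlled
  population correlations, motion traces with scrubbing-scale artifacts,
  and WM/CSF noise pools, with known effects planted at chosen edges so
  every stage above is testable end to end.

See `docs/methods.md` for the model, the generator's assumptions, and all
numerical conventions.

## Worked example

Simulate a cohort of 40 pain / 21 control subjects over 8 ROIs with a
known duration-by-intensity interaction planted at one edge, then run the
whole pipeline:

```python
from painconn import (CohortSpec, PlantedEffect, generate_cohort,
                      generate_timeseries, load_config, run_pipeline)
import painconn.io as pio

spec = CohortSpec(n_pain=40, n_control=21, n_rois=8, n_networks=2,
                  n_frames=200, seed=21)
subjects = generate_cohort(spec)
effects = [PlantedEffect(edge=(0, 5), coding="log", baseline_z=0.1,
                         beta_interaction=0.10)]
data, roi_map = generate_timeseries(subjects, effects, spec)
pio.write_cohort(subjects, data, roi_map, "demo_cohort")

cfg = load_config(None, data_dir="demo_cohort", out_dir="demo_results",
                  codings=["log"])
result = run_pipeline(cfg)

ladder = result.ladders["log"]
print("edges by terminal step:",
      {s: len(ladder.edges_at_step(s)) for s in (1, 2, 3)})
res = ladder.edge_results[4]          # canonical index of edge (0, 5)
print(f"planted edge model: {'+'.join(res.surviving_terms)}")
print(f"beta_interaction = {res.fit['WPINT:X']:.4f}  "
      f"(q = {res.qvalues['WPINT:X']:.2e})")
print(result.jn_tables["log"][["moderator", "boundary_1", "boundary_2",
                               "region"]].to_string(index=False))
```

Output:

```
edges by terminal step: {1: 1, 2: 0, 3: 27}
planted edge model: X+WPINT+WPINT:X
beta_interaction = 0.1020  (q = 6.15e-03)
moderator  boundary_1  boundary_2                  region
    WPINT  -12.731614    2.600696 W < -12.73 or W > 2.601
```

Reading this: of the 28 edges, exactly the planted one kept the full
moderated model at step 1 of the elimination ladder (the other 27 fell
through to the duration-only model).  Its interaction coefficient is
recovered near the planted 0.10, surviving edge-wide FDR at q ≈ 6e-3.
The Johnson–Neyman region says the simple effect of log-duration on
connectivity is significant only for intensity ratings above ≈ 2.6 (the
left branch lies outside the 0–10 rating scale): duration matters for
subjects whose pain is intense enough, which is precisely the planted
moderation.

The same run is available from a shell:

```bash
painconn simulate --out demo_cohort --seed 21 --n-rois 8 \
    --plant-edge 0 5 --plant-interaction 0.10 --coding log
painconn all --data-dir demo_cohort --out-dir demo_results
```

Per-stage outputs land in `demo_results/`: `qc.csv`, `edge_z.csv`,
`glm_log.csv` (long-format edge × term table with betas, p, q, f²),
`jn_log.csv`, `deviation_log.csv`, and `run.log`.

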
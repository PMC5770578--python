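# actitraj

Analysis of consumer activity-tracker step data in inflammatory
arthritis cohorts — rheumatoid arthritis (RA) and axial spondyloarthritis
(axSpA) — from raw minute-level step streams to cohort-level inference.
Written for biostatisticians and epidemiologists working with wearable
step data who need the whole chain to be testable: every stage can be
exercised against a synthetic cohort with known ground truth.

The pipeline:

1. **Ingest** minute-level streams (`timestamp,steps` CSV), lay them on a
   90-day observation window starting the first Monday after device
   activation, apply the *full-day* rule (>= 8 h between first and last
   steps) and the adherence rule (>= 60 full days of 90).
2. **Patterns**: per full day, total steps, activity duration (minutes at
   cadence >= 20 steps/min), MVPA duration (>= 100), vigorous duration
   (>= 130), and the morning-step proportion; weekly MVPA and
   recommendation fulfilment (>= 150 min/week moderate or >= 75 min/week
   vigorous; 10,000 and 7,000 steps/day); same-weekday imputation of
   missing days; adherence summaries.
3. **Trajectories**: K-means for longitudinal data (Euclidean distance on
   the whole 90-day vector, multi-start Lloyd, available-case distances
   for missing days), partition quality by the Calinski–Harabasz ratio
   (B/(k−1))/(W/(n−k)), cluster profiles with the low-activity cluster
   flagged.
4. **Inference**: linear mixed models for the RA-vs-axSpA comparison of a
   daily feature over day 1..90 (random intercept and slope per
   participant, optional power-of-the-mean variance function
   Var(e) = σ²|μ|^2θ); adjusted logistic regressions for recommendation
   fulfilment and low-cluster membership (BMI odds ratio per 5 units,
   age dichotomised at 60); and the two-means design sample size
   n = ⌈2 (z₁₋α/₂ + z₁₋β)² (σ/δ)²⌉.

See `docs/methods.md` for model details, the synthetic-cohort design and
its limitations.

## Worked example

```python
from actitraj import (CohortSpec, generate_cohort, build_window,
                      assemble_participant, filter_adherent, features_table,
                      participant_summary, who_status, trajectory_matrix,
                      impute_missing_days, kmeans_longitudinal,
                      sample_size_two_means)

# a 178-participant synthetic cohort with three latent MVPA classes
cohort = generate_cohort(CohortSpec(seed=1))
act = dict(zip(cohort.covariates.participant_id,
               cohort.covariates.activation_date))
assembled = [assemble_participant(s, build_window(act[s.participant_id]))
             for s in cohort.streams]
analyzable, excluded = filter_adherent(assembled, min_days=60)
print(len(analyzable), "analyzable /", len(assembled))

summary = participant_summary(features_table(analyzable))
print(round(summary.steps_total.mean()), "steps/day;",
      round(summary.mvpa_minutes.mean(), 1), "MVPA min/day;",
      f"{100 * who_status(summary).who_met.mean():.1f}% meet the WHO target")

matrix = impute_missing_days(trajectory_matrix(features_table(analyzable)))
model = kmeans_longitudinal(matrix, k=3, n_starts=20, seed=1)
print("cluster sizes:", model.assignments.value_counts().sort_index().tolist())
print("per-group design size:", sample_size_two_means(1500, 3300))
```

Output:

```
158 analyzable / 178
7085 steps/day; 14.9 MVPA min/day; 29.1% meet the WHO target
cluster sizes: [92, 60, 6]
per-group design size: 76
```

158 of 178 simulated participants wore the tracker for at least 60 full
days. They average ~7,100 steps and ~15 MVPA minutes per day, and just
over a quarter meet the weekly WHO recommendation. The three-cluster
trajectory partition splits the cohort into low / moderate / high
activity levels (cluster 0 is always the lowest), and 76 participants
per group is the sample size needed to detect a 1,500 steps/day group
difference with SD 3,300 at 80% power and two-sided α = 5%.

The same pipeline runs end to end from a YAML config, on either real
stream files or a synthetic spec:

```sh
actitraj simulate --n 178 --seed 1 --out data/
actitraj run --config config.yaml          # writes report.md, tables/, manifest.json
actitraj power --delta 1500 --sd 3300      # -> 76
```

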
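# mirounga

Sex-specific foraging strategies, foraging success and at-sea mortality of
northern elephant seals (*Mirounga angustirostris*), reconstructed from
satellite telemetry and time-depth-recorder (TDR) data.

Adult male and female elephant seals split the North Pacific between them:
males shuttle to continental-shelf habitat and feed benthically, females
range across the open ocean on deep pelagic dives. This package implements
the full analysis chain that turns raw biologging records into that
comparison — and, because real deployments of this kind are rarely shared,
it ships a seeded simulator that generates cohorts with the same
statistical structure (ARGOS location classes and error, four dive
archetypes, diel depth modulation, body-composition records, tag-fate
histories), with ground truth retained so every stage can be validated as a
closed loop.

## Analysis stages

| stage | what it does |
|---|---|
| `synthetic_data` | seeded cohorts: tracks, depth series, body records, tag fates, vector geography |
| `track_processing` | trip truncation; speed/distance/angle filter (12 km/h, 160°); continuous-time correlated-random-walk Kalman smoothing to hourly positions |
| `dive_processing` | dive detection (>32 s, >15 m), per-dive metrics (bottom time, efficiency, vertical excursions), hierarchical four-type classification (drift / benthic / pelagic / transit), solar-zenith day/night labels |
| `foraging_analysis` | foraging locations (<2 km/h + foraging dive), proportion of time feeding, 95% UD foraging area, distance to the 200 m isobath, ecoregion / habitat / trip-typology labels, the 31-variable trip profile |
| `bioenergetics` | onshore-fasting mass corrections (female regression, male metabolic model), lipid/protein energy partition, the eight foraging-success metrics |
| `strategy_clustering` | correlation PCA (retain eigenvalue ≥ 1 and ≥ 10% variance), Ward (D2) clustering with silhouette-selected k, Gaussian GLM/AICc discrimination with Tukey contrasts, Welch/Mann-Whitney diel tests |
| `space_overlap` | 2D/3D kernel utilization distributions (plug-in bandwidths), 95%/50% regions, percent overlap and UDOI |
| `mortality_analysis` | tag-fate attribution (resight histories + Mann-Kendall quality trends), last-location metrics, logistic mortality models with AIC ranking and Hosmer-Lemeshow fit |

## Worked example

Run the whole pipeline on a simulated cohort of 12-day trips:

```sh
mirounga all --seed 2 --output-dir runs/demo
```

or from Python:

```python
from mirounga.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=2, output_dir="runs/demo", trip_days=12.0))
s = res["summaries"]
print(s.groupby(["sex", "trip"])[["shelf_distance_km", "prop_benthic_foraging",
                                  "proportion_time_feeding"]].mean().round(2))
print("clusters:", res["clusters"].k)
```

which prints (seed 2):

```
                      shelf_distance_km  prop_benthic_foraging  proportion_time_feeding
sex    trip
female post_breeding             177.56                   0.02                     0.53
       post_moult                308.96                   0.02                     0.22
male   post_breeding              24.83                   0.49                     0.73
clusters: 3
```

— males feeding ~25 km from the shelf edge with half their dives benthic,
females hundreds of km offshore with almost none, and three strategies
(the male strategy plus the two seasonal female strategies) recovered by
the PCA + Ward analysis. The run directory holds the full
`trip_summaries.csv`, `energy_budgets.csv`, `cluster_assignments.csv`,
`overlap.json` and `tag_fate_attribution.csv`.

On the packaged 217-deployment tag-fate cohort, the attribution rules
(resighted → tag failure; degrading location quality → tag failure;
trend-free stop, never resighted → presumed dead) give 25/39 male tags
stopped at sea (64%), 8 mechanical failures (21%), 17 male deaths (44%)
and 22 female deaths (12%); a sex-only logistic model puts the mortality
probability at 0.44 (males) vs 0.12 (females).

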
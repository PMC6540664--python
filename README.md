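# flytrack

Light-level geolocator analysis for migratory songbirds: from a raw
archival-tag light series to daily location posteriors,
stationary-period schedules, spring-migration phenology and
group-level statistics.

Archival light-level geolocators log ambient light against time.  The
instants the light trace crosses a threshold — sunrise and sunset —
encode position: longitude from the twilight midpoint against apparent
solar noon, latitude from day length and solar declination at a
calibrated zenith angle *z* (the sun's angle from vertical at the
crossing).  Twilight times are noisy one-sidedly (shading delays
sunrise and advances sunset), so delays are modelled log-normally and
daily positions **x**₁…**x**ₙ are sampled by Metropolis MCMC from

  log p(**x**) = Σ_d ℓ_twl(**x**_d) + Σ_d log Beta(v_d / v_max; α, β) + mask(**x**_d)

where ℓ_twl is the log-normal delay likelihood and v_d the
great-circle speed between consecutive days.  The daily posteriors are
segmented into stationary periods by natural breaks in the running
posterior mean (scaled by the daily 95% credible-interval width), and
phenology rules are applied: winter begins with the first ≥30-day
stationary period, spring migration starts at the end of the last
≥30-day period, and ends on the first date whose longitude credible
interval contains the breeding-site longitude (floored by census
first-arrival dates where the route runs due north of the site).
Per-individual metrics — migration distance (great-circle, R = 6371
km), duration (inclusive of both endpoints), rate, stopover use — feed
group summaries, treatment-coded Gaussian linear models with
likelihood-ratio backward elimination, and Pearson correlation tests.

The package targets the study system of Fork-tailed Flycatchers
(*Tyrannus s. savana*) breeding at two tropical Brazilian sites (DF,
EEI — intratropical migrants) and two south-temperate Argentinian
sites (RED, RPL — austral migrants), all overwintering near 2–3° N in
northern South America.  It ships the published per-individual
migration-history table (28 birds) as a packaged fixture and a
ground-truthed simulator of annual tracks and light series, so the
entire estimation chain is testable without any data download.

## Worked example

```python
from flytrack import table1_fixture, group_summary, fit_lm, pearson_test
from flytrack.fixtures import day_of_year

df = table1_fixture()
summary = group_summary(df, "group", ["spring_distance_km", "spring_rate_km_per_day"])
print(summary.round(1).to_string(index=False))

fit = fit_lm("spring_distance_km", ["site"], df)
print(fit.to_frame().round(2).to_string(index=False))

eei = df[df.site == "EEI"]
r = pearson_test(day_of_year(eei.spring_initiation), day_of_year(eei.spring_arrival))
print(f"EEI initiation vs arrival: r={r.r:.2f}, t={r.t:.2f}, df={r.df}, p={r.p:.3f}")
```

prints

```
        group               variable  n   mean    sd
      austral     spring_distance_km 17 4438.5 578.6
      austral spring_rate_km_per_day 16  134.3  39.6
intratropical     spring_distance_km 11 3354.7 388.9
intratropical spring_rate_km_per_day 11  143.8  25.7
       term  estimate     se     t    p
  Intercept   2999.25 246.02 12.19 0.00
site[T.EEI]    558.61 308.41  1.81 0.08
site[T.RED]   1321.75 295.68  4.47 0.00
site[T.RPL]   1571.37 301.32  5.22 0.00
EEI initiation vs arrival: r=0.81, t=3.12, df=5, p=0.026
```

Austral migrants flew ~4,440 km in spring against ~3,350 km for
intratropical migrants (the site model: DF birds averaged 2,999 km,
RPL birds 1,571 km more), yet their rates (134 vs 144 km/day) are
statistically indistinguishable; at EEI, birds that left winter later
also arrived later (r = 0.81, p = 0.026).

A full simulated deployment runs from the shell:

```sh
flytrack run -o demo --seed 1          # simulate → … → phenology → stats
flytrack stats --fixture -o out        # summaries of the packaged table
```

Each stage writes an inspectable CSV (`light.csv`, `twilights.csv`,
`posterior_summary.csv`, `schedule.csv`, `phenology.csv`, …) and a
manifest with the configuration hash and seed.

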
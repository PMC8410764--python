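# laketrack

Whole-lake acoustic-telemetry analysis of fish behaviour, built around the
study design used to contrast an ambush apex predator's foraging modes
between a macrophyte-rich ("high structural complexity", HSC) and a
macrophyte-poor ("low structural complexity", LSC) lake. The package turns
raw burst-transmission position estimates into daily behavioural traits per
individual and provides the surrounding habitat, trophic, growth and
repeatability analyses — plus seeded synthetic-data generators that emulate
the whole study, so the entire pipeline is testable without any field data.

## What it computes

**Positioning.** Raw fixes (tag, timestamp, x, y, optional sensor depth) are
de-duplicated, screened against the shoreline and an iterative
neighbour-speed test, and collapsed to *q-positions*: means over clock-aligned
15-min intervals (at most 96 per day). Depth needs a single receiver, so a
q-position may carry depth without coordinates. Gaps are linearly
interpolated only when the bracketing q-positions are < 2 h, < 100 m and
< 2 m of depth apart; tags that go motionless until the end of their series
are flagged as dead or tag-expelling.

**Daily traits.** For each fish and day:

- *dH-KUD* (ha) — area of the 95% highest-density region of a bivariate
  Gaussian kernel utilization distribution, fixed bandwidth *h* = 50 m,
  evaluated on the lake's 10 × 10 m raster, truncated at the shoreline and
  renormalized; reported only for days with more than 12 daytime and 12
  night-time q-positions (day/night = one hour inside civil twilight).
- *dV-KS* (m) — length of the 95% highest-density set of a 1-D Gaussian
  kernel density (bandwidth 0.4 m) over the day's depths.
- horizontal activity (body lengths s⁻¹) and vertical activity (m s⁻¹)
  between consecutive q-positions; daily mean depth (m).
- *TOW* — fraction of q-positions ≥ 5 m above the bottom (open water).

**Habitat.** The Structural Complexity Index
SCI = ⌈height/2 cm⌉ · ⌈coverage %⌉ ∈ [0, 10 000] per transect quadrat, its
depth profiles, and permutation tests (exhaustive or Monte Carlo) for lake
and lake × period differences; gillnet NPUE/BPUE standardization per
1000 m² net-night.

**Trophic & growth.** Littoral reliance from the two-source δ¹³C mixing
model, LR = (δC − δP)/(δL − δP), unclipped with an out-of-range flag; and
Fraser–Lee back-calculation of length-at-age,
L_i = c + (L_c − c)·S_i/S_c, averaged over three scales per fish.

**Repeatability.** R = V_between/(V_between + V_within) with variance
components from one-way random-effects ANOVA (log/sqrt transforms applied
first), Spearman rank consistency of individual monthly trait means, and a
calibration harness that measures bias of the estimator at a known
intraclass correlation.

## Worked example

```python
import pandas as pd
import laketrack as lt

# two contrasting basins, five fish each, one week of tracking
hsc = lt.make_lake(lt.HSC_SCENARIO, seed=1)
lsc = lt.make_lake(lt.LSC_SCENARIO, seed=2)
twilight = lt.make_twilight_table(pd.date_range("2015-06-01", periods=8))

tables = []
for lake, scen, mode, seed in [(hsc, lt.HSC_SCENARIO, "ambush", 10),
                               (lsc, lt.LSC_SCENARIO, "cruise", 20)]:
    fish = lt.make_fish(scen, 5, mode, seed=seed, lake=lake)
    positions = lt.simulate_cohort(lake, fish, "2015-06-01", 7, seed=seed + 1)
    qpos = lt.process_positions(positions, lake)
    traits = lt.compute_daily_traits(qpos, lake, twilight,
                                     {f.tag_id: f.body_length for f in fish})
    tables.append(traits)

traits = pd.concat(tables, ignore_index=True)
summary = traits.assign(mode=traits.tag_id.str.split("-").str[1]) \
                .groupby("mode")[["dH_KUD", "horiz_activity", "TOW"]].mean()
print(summary.round(3))

kud = traits.dropna(subset=["dH_KUD"]).rename(columns={"dH_KUD": "value"})
vc = lt.variance_components(kud, transform="log", trait="dH_KUD")
print(f"\nrepeatability of log dH-KUD: R = {vc.R:.2f} "
      f"({vc.n_groups} fish, {vc.n_obs} fish-days)")
```

Output:

```
        dH_KUD  horiz_activity    TOW
mode
ambush   5.335           0.027  0.000
cruise  47.384           0.179  0.757

repeatability of log dH-KUD: R = 0.92 (10 fish, 70 fish-days)
```

Cruising fish range over ~9× the daily area of ambush fish, swim ~7× faster
relative to body length, and spend three quarters of their q-positions in
open water, while ambush fish essentially never leave the benthic zone —
the qualitative contrast the pipeline is designed to resolve. The high R
reflects strong, stable between-individual differences in this pooled
two-mode cohort.

A `laketrack` console script exposes the same steps
(`simulate`, `process`, `traits`, `sci`, `cpue`, `trophic`, `growth`,
`repeatability`); run `laketrack --help`.

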
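# coalcrop

Wind-direction source attribution of coal power-station NO₂ over cropland,
with translation of the attributable pollution into rice and wheat output
losses and a rank-and-cut prioritization of stations for emissions
reduction.

## The problem

Coal-fired power stations are a major NO₂ source in India, and NO₂
depresses crop growth. Directly attributing the NO₂ column observed by
satellite over a cropland pixel to a nearby power station is confounded:
stations sit near cities, industry and roads. `coalcrop` implements an
identification strategy that exploits year-to-year fluctuations in wind
direction: generation at a station on days when the wind blows *from* the
station *toward* a cropland point delivers pollution there, while the same
generation on days with the opposite wind does not. Within a point, across
seasons, the split of a station's seasonal generation across wind octants
is plausibly random — so the covariance between directional exposure and
the seasonal NO₂ column identifies the station's contribution.

## The model

For cropland point *i* in season *t* (a two-month crop exposure window:
September–October for monsoon/kharif rice, January–February for
winter/rabi wheat), and for each 10-km distance band out to 100 km,
seasonal generation of the in-band stations is split by the wind-from
octant on each day and classified, relative to the point→station bearing,
into upwind, almost-upwind, crosswind, almost-downwind and downwind GWh
totals. The band model is the two-way fixed-effects panel regression

    NO₂ᵢₜ = β_up·Gen_upᵢₜ + β_up′·Gen_up′ᵢₜ + β_cross·Gen_crossᵢₜ
           + β_down′·Gen_down′ᵢₜ + β_down·Gen_downᵢₜ + β_W·Wᵢₜ
           + pᵢ + c_{s,t} + εᵢₜ

with point effects pᵢ, state–season effects c_{s,t}, weather controls W
(seasonal mean temperature, seasonal total precipitation), estimated
separately per season type and distance band on points exposed to exactly
one station in that band, with standard errors clustered by state–season.

Downstream, coal-attributable NO₂ per point is the fitted directional part
summed over all bands on the *full* exposure; yield changes follow from
NO₂→NIRv exposure-response coefficients (0.0006 for rice, 0.0007 for wheat,
with a 0.007 bare-soil NIRv baseline); state output gains scale reported
state output by cropland-fraction-weighted yield changes; station damages
use the exact per-station decomposition of the linear attribution;
monetization uses US$600/t rice, US$350/t wheat and a US$120,000 value of
statistical life. A state–season cluster bootstrap propagates estimation
uncertainty into 95% prediction intervals, and a greedy rank-and-cut
selector targets the highest damage-intensity stations under a generation
budget.

Because the upstream satellite/reanalysis inputs are not bundled, the
package ships a first-class synthetic-data generator (`coalcrop.synth`)
that emulates the full data model with known ground truth, which is how
the estimator, the bootstrap and the policy stage are validated.

## Worked example

```python
from coalcrop import CoalAttributionModel, WorldConfig, generate_world

world = generate_world(WorldConfig(seed=1))        # known ground truth
model = CoalAttributionModel.from_world(world)
results = model.fit()

print(results.band_fits[("monsoon", 0)].summary().round(4))
```

```
                   coef  se_clustered   ci_lo   ci_hi
gen_up           0.0193        0.0029  0.0131  0.0254
gen_almost_up    0.0110        0.0028  0.0049  0.0170
gen_cross        0.0045        0.0029 -0.0018  0.0107
gen_almost_down  0.0009        0.0027 -0.0050  0.0067
gen_down        -0.0008        0.0026 -0.0063  0.0047
temp_c           0.1879        0.0244  0.1356  0.2402
precip_mm        0.0066        0.0011  0.0042  0.0089
```

The 0–10 km monsoon fit recovers the generating coefficients (true
β_up = 0.02 μmol m⁻² GWh⁻¹ in this world, decaying with distance and from
upwind to downwind) with clustered confidence intervals. Attribution,
damages and policy hang off the results object:

```python
summary = results.attribution_summary()
print(summary[summary["season_id"] == "monsoon_2022"].round(3))
```

```
     state     season_id  mean_no2  mean_coal_no2  pct_attributable
4   state0  monsoon_2022    34.884          0.491             1.407
14  state1  monsoon_2022    31.321          0.382             1.219
24  state2  monsoon_2022    34.127         -0.033            -0.097
34  state3  monsoon_2022    29.297          0.467             1.594
```

`mean_coal_no2` is the state-average coal-attributable NO₂ column
(μmol/m²); negative values can occur because all estimated coefficients
are used, not only significant ones. Finally:

```python
scen = results.scenario("combined", budget_fraction=0.10)
print({k: round(v / 1e6, 2) for k, v in scen.benefits.items()})
# {'mortality_usd': 5.88, 'crop_usd': 2.51, 'total_usd': 8.39}
```

selects the stations with the highest combined (mortality + crop) damage
intensity until 10% of annual generation is reached, and reports the
monetized annual benefits of eliminating their emissions, in USD.

## Command-line pipeline

```sh
coalcrop run-all config.yaml          # simulate -> ... -> optimize
coalcrop fit config.yaml --seed 7     # any prefix of the stage chain
```

The YAML config names the input directory (eight CSV tables; see
`coalcrop.io.SCHEMAS`), the output directory, seeds, bootstrap and policy
settings. Artifacts are stamped with a configuration hash; identical
configurations re-run byte-identically.

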
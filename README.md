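# mizscape

Analysis toolkit for predator-driven prey redistribution in a polynya
marginal ice zone (MIZ): the McMurdo Sound fast ice edge, where Adélie
penguins and minke whales forage on crystal krill and Antarctic silverfish.
The package reimplements, as a tested library, the quantitative chain of a
2014–15 field campaign: acoustic preyscape summarization, an edge-vs-interior
permutation test, penguin dive-metric extraction, diel/edge mixed models,
light–depth optics, and diet–preyscape rank correlations — exercised
end-to-end on synthetic data plus the campaign's published summary tables.

## What it computes

**Acoustic preyscape** (`mizscape.echo`). Volume backscattering strength
(S_v, dB re 1 m⁻¹) on a 6-s × 1-m grid; prey aggregations as 4-connected
components above a threshold, kept only if wider than 4 pings; taxon
classification by a depth/S_v rule table; linear-domain means
(s = 10^{S_v/10}) with percentile-bootstrap 95% CIs (10,000 replications) per
5–6-day period, location class and taxon.

**Edge permutation test** (`mizscape.permutation`). Deployments are the
exchangeable units (backscatter is correlated across depths within a
deployment). For each 10-m depth bin in 0–100 m, with X = mean(edge) −
mean(interior) per-deployment linear-domain abundance and x_j the statistic
under B random relabelings holding the 30/54 edge/interior counts fixed,

    p = (1 + Σ_j I(x_j ≤ X)) / (B + 1)

with the complementary upper tail reported alongside so both "interior
greater" and "edge greater" findings are expressible (both tails center on
0.5 for an evenly distributed prey field).

**Dive metrics** (`mizscape.dives`). 1-Hz time-depth-recorder series are
segmented into dives (5-m dive threshold, 1-m surface threshold); undulations
are ascent-to-descent reversals with >1 m of ascent (a prey-capture proxy);
the bottom phase is the span at ≥80% of maximum depth; dives are classed
foraging / exploratory / other; dives are geolocated by temporal proximity to
interpolated satellite fixes (excluded beyond 30 min from a temporally known
position) and given great-circle distances to the dated fast ice edge.

**Mixed models** (`mizscape.models`). Each dive criterion is regressed by
REML on a single fixed covariate — distance to the ice edge, or a daily
cosine cos(2π(t − 14 h)/24 h) peaking at 14:00 local solar time — with a
random intercept per penguin; reported with Wald tests, marginal r², and
variance components.

**Trophic correlations** (`mizscape.trophic`). Observations binned into
5–6-day periods; tie-corrected Kendall τ_b between each preyscape/foraging
variable and the krill fraction of the chick diet, Holm–Bonferroni adjusted.

**Optics** (`mizscape.optics`). Depth of the 1% light level from a
chlorophyll profile under two-component diffuse attenuation
K(z) = K_w + k_chl·chl(z).

**Synthetic data** (`mizscape.synthetic`) generates all of the above inputs
with retrievable ground truth; `mizscape.datasets` ships the campaign's
published period tables.

## Worked example

```python
import numpy as np
from mizscape import datasets
from mizscape.trophic import kendall_tau_b
from mizscape.models import predict_fixed_effect
from mizscape.synthetic import SurveyScenario, gen_echogram_survey
from mizscape.echo import delineate_aggregations, classify_aggregation, \
    aggregation_cells_frame
from mizscape.permutation import permutation_depth_table

# 1. Does whale presence track the diet switch away from krill?
diet = datasets.diet_periods()
tau, p = kendall_tau_b(diet["whale_presence"], diet["pct_krill"])
print(f"tau_b = {tau:.3f}")                 # tau_b = -0.655

# 2. How much shallower do penguins dive 20 km from the ice edge?
coef = datasets.edge_distance_models().set_index("criterion") \
    .loc["max_depth", "coefficient"]        # -0.682 m per km
print(f"{predict_fixed_effect(coef, 20.0):+.1f} m")   # -13.6 m (~14 m shallower)

# 3. Detect a 6-dB krill depletion at the ice edge in a synthetic survey.
grids, stations, _ = gen_echogram_survey(
    SurveyScenario(depletion_effect=6.0, rng_seed=1))
aggs = []
for g in grids:
    for a in delineate_aggregations(g):
        a.taxon = classify_aggregation(a)
        aggs.append(a)
table = permutation_depth_table(aggregation_cells_frame(aggs), stations,
                                taxa=("krill",), seed=1)
print(table[table["depth_lo_m"] == 20.0][["p_value", "greater_at"]].to_string(index=False))
#  p_value greater_at
#   0.0001   interior
```

The τ of −0.655 over 8 periods says krill's share of the diet ranks lower
once whales are present; the −0.682 m km⁻¹ slope integrates to a ~14-m
shallowing of maximum dive depth over the 20-km foraging range; and the
permutation row shows the synthetic edge depletion recovered as
significantly greater interior backscatter at 20–30 m.

A full synthetic run of every stage, with a reproducibility manifest:

```
mizscape run --seed 7 --out bundle/
```

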
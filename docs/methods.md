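# Methods

This note records the models, conventions and design choices behind
`mizscape`, and what the synthetic generators do and do not emulate.

## Acoustic processing

All averaging of volume backscattering strength is performed in the linear
domain (s = 10^{S_v/10}) and reported in dB. This is the standard
fisheries-acoustics convention, it makes means of dB quantities well defined,
and it gives the Jensen property (linear-domain mean ≥ dB arithmetic mean)
asserted in the tests.

Grids are depth-by-time matrices with 1-m bins (top edge 0 m, positive
downward, capped at 200 m — single-beam detectability declines with range)
and 6-s time bins at a nominal 1 ping s⁻¹, so one grid column integrates six
pings. Cells with no samples are missing (NaN), never zero: 0 dB is a
physical value, absence of data is not.

Aggregation delineation replaces a manual procedure with a deterministic
surrogate: 4-connected components of cells at or above a detection threshold
(default −95 dB, above the −105 ± 2 dB synthetic noise floor), retained when
wider than 4 pings (ping width = time-bin span × pings per bin, so the rule
is expressible at any bin width), output ordered by first time bin then
shallowest depth bin. Taxon classification replaces visual ground-truthing
with an ordered rule table on backscatter-weighted depth and mean S_v;
defaults put krill above 60 m and silverfish below, reflecting the two taxa's
distinct depth preferences, and anything matching no rule is `unknown`.
Weighted depth is the linear-backscatter-weighted cell mid-depth.

Period summaries default to cell weighting (every member cell of a
classified aggregation counts equally); aggregation weighting is a config
switch. Confidence intervals are percentile bootstrap (default 10,000
replications, level 95%) resampling aggregations, the sampling unit.

## Edge-vs-interior permutation test

The deployment (one ice-hole station) is the exchangeable unit, because prey
patches span many depth bins and backscatter is therefore strongly dependent
across depths within a deployment. Per deployment and 10-m depth bin the
abundance score is the linear-domain **sum** of classified-aggregation
backscatter (a mean is available by config); deployments with no detections
score zero — a real observation, since most deployments detect nothing in
most bins.

The statistic is X = mean(edge) − mean(interior). Labels are reassigned
uniformly at random holding class sizes fixed (30 edge / 54 interior at the
default design), the observed labeling is not forcibly included, and the
lower-tail p-value is (1 + Σ I(x_j ≤ X))/(B + 1) with B = 10,000 by default;
the +1 terms give the standard validity guarantee. Small lower-tail p means
backscatter is greater in the interior; the complementary upper tail
(I(x_j ≥ X)) expresses "greater at the edge", and the reported p is the tail
matching the observed sign, flagged with its direction. Tail comparisons use
a tolerance of 10⁻¹² times the data scale so exactly-exchangeable inputs
(e.g. constant data) count as ties in both tails. Permutations are drawn
after sorting deployments by id, so results do not depend on input row
order for a fixed seed. Significance stars follow the 95% (p ≤ 0.05) and
90% (p ≤ 0.10) convention.

## Dive processing

Defaults (the upstream dive-summary software's internals are unpublished,
so these are declared, configurable choices): dive threshold 5 m, surface
threshold 1 m, shallow-dive class threshold 10 m, bottom phase = span from
first to last sample at ≥ 80% of maximum depth. Undulations are
ascent-to-descent reversals whose cumulative ascent (plateaus do not reset
it) strictly exceeds 1 m; both whole-dive and bottom-phase counts are kept,
with the whole-dive count reported as "dive undulations". Classification:
`other` below the shallow threshold; `foraging` when the bottom phase holds
at least one undulation; `exploratory` otherwise — so `foraging` implies at
least one undulation, asserted on every output. Gaps under 10 s are
interpolated to the 1-s grid; larger gaps split the series. An optional
zero-offset correction subtracts the per-hour modal near-surface depth
before segmentation (sensor drift).

Light is treated as arbitrary logger counts: the 5-m summary averages
samples at 4–6 m on descent and ascent, the bottom summary averages the
bottom phase, and log transforms (with +offset for zeros) are applied at
model time, not here.

Geolocation: each dive takes the temporally nearest fix on the interpolated
15-min grid; dives whose nearest fix lies more than 30 min from a temporally
known position keep a missing location and drop out of spatial models.
Distance to the dated ice edge is the minimum distance to the polyline in
force on the dive's date, computed on a local tangent-plane projection
(equirectangular, metre-true at the query point; error ≪ 1% at the
tens-of-km scales involved).

## Mixed models

One fixed effect per model, matching the campaign's analysis: criterion ~
covariate + (1 | penguin), REML via `statsmodels.MixedLM`. The diel
covariate is cos(2π(t − 14 h)/24 h) on local solar time (the study longitude
166° E is UTC+11.07 h), peaking at 14:00 exactly. Light criteria and edge
distance are log-transformed (natural log, offset 0.1 for zero-capable
quantities). Reported: Wald z = coef/SE and its normal p-value; marginal
r² = var(xβ)/(var(xβ) + σ²_id + σ²_res); variance components; and the lag-1
within-individual residual autocorrelation. Fits with essentially zero
random-intercept variance are flagged `singular`, not silently zeroed.
A "number of dives" criterion is interpreted as dives per penguin-hour
(`dives_per_hour_table`), since a per-dive response is not defined for it.

`predict_fixed_effect` multiplies an untransformed-criterion slope by a
covariate change: the −0.682 m km⁻¹ depth slope over the 20-km foraging
range gives a 13.6 ≈ 14 m shallowing; the −0.098 undulation slope gives a
drop of ≈ 2 per dive.

## Optics

Irradiance follows dE/dz = −(K_w + k_chl·chl(z))E — a two-component diffuse
attenuation standing in for a full snow/ice/water radiative-transfer model,
whose inputs are not available here. Defaults: K_w = 0.046 m⁻¹ (clear
seawater), k_chl = 0.016 m² (mg Chl-a)⁻¹; both configurable. The optical
depth is accumulated by the trapezoid rule and inverted linearly; the 1%
depth is relative to just-below-surface light, so surface transmittance
(open water vs <1% under snow-covered fast ice) scales absolute light
without moving the depth. Profiles ending before 1% return the bottom depth
with a `reached=False` flag. Published per-period 1% light depths derive
from field fluorescence profiles that are not reconstructable from the
summary tables, so they are carried as data, not recomputed.

## Rank correlations

Observations are binned into the campaign's 5–6-day periods (half-open
intervals between period starts; the last extends 6 days). Kendall τ_b
(tie-corrected in both margins, via `scipy.stats.kendalltau`) is computed
between each preyscape/foraging variable and the krill diet fraction on
pairwise-complete periods, so n varies by variable; periods where a taxon
was not detected are missing, not zero (a detection-floor substitution is a
config flag). Holm–Bonferroni adjustment is applied across the family. An
all-tied margin leaves τ undefined and is flagged rather than forced to 0.

## Synthetic generators

Every generator is a pure function of its scenario dataclass, including the
seed; reruns are byte-identical.

**Survey**: 30 edge + 54 interior stations (the study design), Gaussian
background noise (−105 ± 2 dB) far below the detection threshold, and
Poisson-many rectangular patches per station (mean 2) placed by a marked
point process: uniform in time, taxon from a 60/40 krill/silverfish mix,
depth from taxon-specific Gaussians (krill 30 ± 15 m, silverfish 90 ± 20 m —
shallow krill, deep silverfish, as in the campaign's detections), cell S_v
drawn at −75 ± 3 dB. These magnitudes are chosen to be realistic for the
system; the published tables give no per-station distributions, so
calibration is approximate by design. Edge depletion subtracts a stated dB
amount from all edge cells in a stated depth interval (default 10–40 m),
which scales linear abundance by exactly 10^(−d/10); a patch-thinning
alternative with the same linear-equivalent retention is a config flag.
Deployment dates cycle through the survey window so edge and interior
stations share periods.

**Dives**: the statistical layer (`gen_dive_table`) draws per-dive maximum
depth as depth_mean + slope·distance + diel·cos + b_penguin + ε with the
campaign-scale defaults (18 birds, ~2,000 dives, slope −0.682 m km⁻¹,
between-bird SD 12.3 m, residual SD 15.4 m) and records every true
covariate. The series layer (`gen_dive_dataset`) renders each dive as a
1-Hz profile — descent, a bottom phase carrying the dive's undulation count
as reversals of 1.5–3 m amplitude, ascent — floored at 12 m of depth so the
profile can physically carry its wiggles; light is a surface diel sinusoid
times exponential depth decay in arbitrary counts; fixes sit on a 15-min
grid with every third fix a known position, placed at the dive's true
distance north of a straight synthetic edge. The statistical layer is
deliberately un-truncated (it is the stated data-generating process for
recovery tests); the series layer is the input for dive-metric recovery.

What the generators do **not** emulate: ocean physics, acoustic beam
geometry and target strength, prey movement between stations, ARGOS error
structure, weather gaps, or tag failure. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
assumed data-generating process, not field performance on real echograms or
tag records.

## Simulation sizes and numerical choices

Type-I error: 1,000 full generator→delineation→classification→test
replicates (one 20–30-m krill test each) in the test suite; 400 in the
acceptance script. Power: the 6-dB 10–40-m depletion scenario at 30/54
stations, 150 replicates (script: 100), requiring each 10-m bin flagged
"interior greater" at p ≤ 0.05. Per-replicate permutation count is 999
(p-resolution 1/1,000, decisions at α = 0.05 unchanged versus B = 10,000,
which is used wherever a single test's p-value is itself the quantity of
interest). Mixed-model recovery: 200 replicates (script: 100) at the default
scenario, checking the estimate lies within 2 SE of truth. Bootstrap
coverage: 1,000 (script: 500) normal samples of n = 100 at 10,000
replications each. dB/linear round-trips are exact to 10⁻¹² dB.

## Known limitations

- Delineation and classification thresholds substitute for manual expert
  judgment; their defaults are tuned to the synthetic scenario's separation,
  and real echograms would need threshold review and a noise-floor estimate.
- The permutation test's conservative behaviour under heavy zero-inflation
  (prey absent from nearly all deployments in a bin) shrinks power in deep
  bins; this mirrors the sparsity of real detections.
- Bottom-phase and dive-threshold conventions differ between TDR packages;
  absolute undulation counts are comparable only within one convention.
- The optics module resolves no spectral or snow/ice radiative transfer;
  its 1% depths are relative euphotic depths under the stated attenuation.
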
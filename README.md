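# guilddiet

Diet-niche analysis for guilds of sympatric predators, built for the kind
of quasi-meta-analytical dataset assembled from published owl-pellet
studies: a long-format table of prey counts (location × predator species ×
prey genus), site coordinates with pre-extracted environmental covariates,
and genus-level body masses. The motivating system is a Mediterranean
foraging guild of three owls — long-eared owl (`LEO`), tawny owl (`TAW`)
and eagle owl (`EEO`) — but predators are an open, config-declared set.

The package answers the questions such compilations are built for: do the
guild members differ in diet, how does each species' diet vary along
geographic and environmental gradients, and does a species' diet shift
when it lives in sympatry with a competitor?

## What it computes

For each spatially pooled site (locations of the same predator closer
than 20 km are merged into clusters; counts summed, coordinates replaced
by the centroid; sites below 90 terrestrial-mammal items on the mainland
or 50 on islands are excluded), diet metrics at the genus level on
terrestrial mammals:

- Shannon diversity **H** = −Σ pᵢ ln pᵢ (nats),
- Levins' niche breadth **B** = 1 / Σ pᵢ²,
- Shannon/Pielou evenness **J** = H / ln G,
- count-weighted mean prey body mass Σ nᵢ mᵢ / Σ nᵢ (g),
- proportion of terrestrial-mammal items over all vertebrate items,

where pᵢ is the proportion of the i-th genus, G the number of genera with
nᵢ > 0, and mᵢ the genus mean body mass. Downstream stages:

- **guild comparison** — one-way ANOVA per metric and all-pairs
  pooled-variance t tests with Bonferroni correction;
- **geographic/environmental models** — per-species OLS on z-standardized
  predictors (latitude, longitude, elevation, island factor / temperature,
  precipitation, tree cover, with a |r| > 0.65 collinearity screen), prey
  size log₁₀- and mammal proportion logit-transformed; Moran's I on
  residuals with inverse-distance weights, and an exponential-correlation
  GLS refit (C(d) = exp(−d/ρ), ρ by profile maximum likelihood) where
  autocorrelation is significant;
- **effect sizes** — partial correlations r = t/√(t² + df), Fisher
  Z_r = atanh(r) with 95% CIs, assembled into a cross-species forest
  table;
- **sympatry analysis** — 0/1 competition coding by point-in-polygon
  against competitor range polygons, factor models with and without
  logit-tree-cover adjustment, and a Freedman–Lane randomization test
  that permutes the residuals of a latitude/longitude nuisance model to
  separate sympatry effects from geographic position;
- **synthetic data** — a generator of full guild datasets with known
  ground truth (Dirichlet-multinomial genus preferences, environmental
  gradients, spatially correlated effects, rectangular ranges), used as
  the test substrate for every stage.

## Worked example

```python
import guilddiet as gd

params = gd.scenario_presets("specialist_generalist")
ds = gd.generate_guild_dataset(params, seed=42)
kept, excluded, clusters = gd.pooled_filtered_diets(ds.prey, ds.sites, ds.traits)
mt = gd.metrics_table(kept, ds.traits)
print(f"{len(kept)} pooled sites kept, {len(excluded)} excluded")
print(mt.groupby("predator")[["H", "J", "mean_prey_size_g", "prop_mammals"]].mean().round(3))
res = gd.oneway_anova({sp: g["H"].to_numpy() for sp, g in mt.groupby("predator")})
print(f"H index ANOVA: F{res.df_between},{res.df_within} = {res.F:.2f}, p = {res.p:.2e}")
```

prints

```
177 pooled sites kept, 1 excluded
              H      J  mean_prey_size_g  prop_mammals
predator
EEO       2.325  0.936            51.954         0.702
LEO       1.366  0.634             8.236         0.901
TAW       1.883  0.769            18.252         0.802
H index ANOVA: F2,174 = 4805.62, p = 5.60e-153
```

The simulated guild reproduces the qualitative structure of the real one:
the small specialist (`LEO`) has the least diverse, most mammal-dominated
diet of the smallest prey; diversity and prey size rise and the mammal
share falls toward the large generalist (`EEO`), and the among-species
ANOVA on H is overwhelming at these sample sizes.

The same stages are available from a shell:

```sh
guilddiet simulate --preset specialist_generalist --seed 42 --out data/
guilddiet pool    --prey data/prey.csv --sites data/sites.csv --traits data/traits.csv --out out/
guilddiet compare --prey data/prey.csv --sites data/sites.csv --traits data/traits.csv --out out/
guilddiet sympatry --prey data/prey.csv --sites data/sites.csv --traits data/traits.csv \
    --ranges data/ranges.geojson --focal LEO --competitor TAW \
    --permutations 9999 --seed 42 --out out/
```

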
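# occutrends

Long-term species-richness trends from unstructured historical records.

Natural history collections hold centuries of presence records — specimens
with a species, a place and a year — but no survey design: effort is sparse,
bursty and uneven across regions and eras, and a year without records says
nothing by itself about absence. `occutrends` turns such records into
regional richness trajectories the way a modern museum-collection analysis
does, and ships a synthetic-study generator with full latent truth so every
step can be validated against a known process. It is aimed at ecologists and
biodiversity-change researchers working with digitized collections (e.g.
tropical butterfly records spanning 150+ years across a few well-collected
regions).

## The model

Each species' presence in region r and year t is a latent two-state Markov
chain fitted by maximum likelihood (forward algorithm):

- ψ₁ — initial occupancy, fixed at 1 with the first years discarded as
  burn-in (nothing is known about true occupancy when a historical series
  starts);
- γ_t — colonization, ε_t — extinction, logit-linear in one covariate chosen
  by AIC among {constant, year, temperature, forest cover};
- p_t — detection, logit-linear in standardized log recording effort (total
  records of the taxon in that region-year); no false positives.

Goodness-of-fit is screened by a refitting parametric bootstrap
(Freeman–Tukey discrepancy); poorly fitting species are excluded, with an
optional sensitivity rerun. Regional species richness is the summed
occurrence probability over species, SR(r,t) = Σ_s Pr(z_s,r,t = 1 | data).
Richness series are then analysed with five Gaussian trend models —
SR ~ Region, SR ~ Year + Region, SR ~ Year × Region, SR ~ s(Year) + Region,
SR ~ s(Year, by Region) + Region, smooths being penalized cubic regression
splines with GCV — compared by AIC and approximate F-tests. Slopes are
reported per decade (annual slope × 10) with a direction call: increasing or
decreasing when slope ± SE excludes zero, stable otherwise. The best smooth
fit is segmented into maximal runs of constant derivative sign (multi-decadal
periods), trends are refitted on trailing 10–150-year windows, and series can
be stratified by species traits (endemism, forest dependence, host-plant
specificity). See `docs/methods.md` for conventions and limitations.

## Worked example

```python
from occutrends import (PipelineConfig, SimConfig, report, run_pipeline)

cfg = PipelineConfig(
    out_dir="scratch/demo", seed=11,
    sim=SimConfig(n_species=10, n_regions=3, n_years=80, start_year=1940,
                  seed=11),
    n_restarts=2, gof_n_sim=49,
)
run_pipeline(cfg)
print(report("scratch/demo"))
```

prints (abridged):

```
== TaxonA ==
best richness model: intercept_only (k=5)
long-term change per decade (linear interaction model):
  region 1: -0.102 +/- 0.091 [down]
  region 2: +0.063 +/- 0.097 [-]
  region 3: +0.169 +/- 0.113 [up]
window sensitivity (slope per decade by series length):
  past 10 y, region 1: -1.410 +/- 1.159 [down]
  past 25 y, region 1: +0.125 +/- 0.499 [-]
  past 50 y, region 1: +0.213 +/- 0.135 [up]
  past full y, region 1: -0.102 +/- 0.091 [down]
trait endemism: best=nonlinear_interaction, interaction F=2.28 (p=0.000656)
  endemic, region 1: -0.060 +/- 0.050 [down]
  non-endemic, region 1: -0.042 +/- 0.050 [-]
```

Reading it: over the full 76 analysed years richness changed by about
−0.1 to +0.17 species per decade depending on region — one declining, one
stable, one increasing call under the SE-overlap rule — while the trailing
windows for region 1 swing from a steep apparent 10-year decline to a
significant 50-year increase before settling on the weak full-span decline:
short windows of the same series tell different stories. The trait block
reports that the endemic and non-endemic richness curves differ — true for
this community, where each class is a distinct random set of species with
its own drawn dynamics.

The same run is available from the shell:

```bash
occutrends run-all -c config.yaml   # or stagewise: simulate/prepare/fit/richness/trends
occutrends report scratch/demo
```

`examples/` contains one narrative script per capability: generating a
synthetic study, fitting and selecting occupancy models for a species,
richness/trend/segmentation/window analyses, and the full pipeline.

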
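# endemica

Conservation analytics for *Asperula naufraga*, a critically restricted
chasmophyte endemic to the sea cliffs of western Zakynthos (Ionian Islands,
Greece). The package turns raw field inputs — subpopulation census tables,
per-individual reproductive measurements, occurrence coordinates, microsatellite
genotypes — into the quantities a Red List assessment and a recovery plan need:

- **Geography** — extent of occurrence (EOO, minimum convex polygon on an
  equal-area projection), area of occupancy (AOO, occupied 1×1 km grid cells),
  and plant densities per subpopulation.
- **Demography** — census trajectories, stage structure, year-on-year growth
  ratios, per-individual flower/fruit/seed production, relative reproductive
  success, binomial survival confidence intervals, generation length, and
  heuristic effective population size.
- **Population genetics** — allele frequencies and diversity statistics,
  polymorphism information content, Hardy–Weinberg tests, Nei and
  Weir–Cockerham F-statistics with permutation tests, Nei's unbiased genetic
  distance, gene flow, null-allele estimation (EM) with an ENA-corrected FST,
  AMOVA on an allele-mismatch distance, principal coordinates analysis, and
  Evanno's ΔK for choosing the number of genetic clusters.
- **Population viability analysis** — a stochastic count-based projection with
  lognormal environmental noise and optional demographic stochasticity,
  reporting cumulative quasi-extinction risk with confidence intervals.
- **IUCN Red List engine** — criteria B (geographic range), D (very small
  population), and E (quantitative risk), producing category-plus-code strings
  such as `CR B1ab(i,ii,iii,v)c(i,ii,iv)`.
- **Synthetic data generator** — a fully seeded simulator (Balding–Nichols
  allele frequencies, inbreeding, null alleles, shared environmental year
  effects) used to validate every estimator against known truth.

All stages are deterministic given a seed and run comfortably on a single CPU.

## Worked example

The package ships the published monitoring, reproduction and coordinate
summaries as bundled datasets.

```python
from endemica import demography, geo, iucn, pva
from endemica.datasets import load_monitoring, load_reproduction_summary

# --- census trajectory -----------------------------------------------------
monitoring = load_monitoring()
totals = demography.census_totals(monitoring)
print(totals["n_mature"].to_dict())
# {2014: 130, 2015: 109, 2016: 68, 2017: 79, 2018: 110}

# --- reproduction (2014 tagged cohort) ---------------------------------------
repro = load_reproduction_summary().set_index("year")
flowers = demography.flowers_per_individual(
    repro.loc[2014, "Fl"], repro.loc[2014, "St"]
)
fruits = demography.fruits_per_individual(flowers, repro.loc[2014, "fruit_set"])
seeds = demography.fecundity(repro.loc[2014, "S"], repro.loc[2014, "St"])
print(f"{flowers:.2f} flowers, {fruits:.2f} fruits, {seeds:.1f} seeds / individual")
# 221.32 flowers, 64.18 fruits, 137.2 seeds / individual

# --- density and effective size ---------------------------------------------
print(geo.format_density(geo.density(9, 12.9)))   # 9 plants on 12.9 m2
# 0.7
print(demography.effective_size(130))
# [{'ratio': 0.4, 'ne': 52, 'flag_below_50': False},
#  {'ratio': 0.1, 'ne': 13, 'flag_below_50': True}]

# --- population viability ----------------------------------------------------
fit = pva.fit_growth(totals["n_mature"].to_numpy())
print(f"growth mean {fit['mean']:.4f}, sd {fit['sd']:.4f}")
# growth mean 1.0041, sd 0.3404
result = pva.simulate(pva.PVAConfig(
    n0=130, horizon_years=50, n_replicates=20000,
    growth_mean=fit["mean"], growth_sd=fit["sd"],
    extinction_threshold=10, seed=1,
))
print(f"P(quasi-extinct) by year 10: {result.risk[10]:.4f}, by year 50: {result.risk[50]:.4f}")
# P(quasi-extinct) by year 10: 0.0678, by year 50: 0.6883

# --- Red List assessment ------------------------------------------------------
assessment = iucn.assess(iucn.AssessmentInput(
    eoo_km2=28.7, aoo_km2=8.0, severely_fragmented=True,
    continuing_decline=frozenset({"i", "ii", "iii", "v"}),
    extreme_fluctuations=frozenset({"i", "ii", "iv"}),
    n_mature=130,
))
print(assessment)
# CR B1ab(i,ii,iii,v)c(i,ii,iv) B2ab(i,ii,iii,v)c(i,ii,iv)
```

Every printed value above is the actual output of the code as shipped.

### Command line

```bash
# generate a synthetic four-file input bundle
endemica simulate-data --seed 4 --out data/

# geographic range metrics from a coordinates file
endemica geo --coordinates data/coordinates.csv --out geo.json

# full pipeline from a YAML config (geo, demography, popgen, pva, assessment)
endemica run --config config.yaml
```

`endemica run` writes one JSON file per stage plus a human-readable
`summary.txt` to the configured output directory and is byte-identical across
reruns with the same seed.

## Reproducing results

```bash
pip install --no-build-isolation -e .
python -m pytest -o addopts= -p no:cacheprovider -q tests/   # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline published quantities
(per-individual flower, fruit and seed production for the 2014 cohort, and the
minimum and maximum subpopulation densities) from the bundled datasets through
the public API and writes them as JSON.

## Layout

```
src/endemica/
  datamodel.py   validated record types and run configuration
  io.py          CSV/YAML readers and writers (GenAlEx, long, STRUCTURE formats)
  geo.py         projection, EOO/AOO, densities
  demography.py  census, reproduction, survival, generation length, Ne
  popgen.py      diversity, F-statistics, nulls, AMOVA, PCoA, Evanno
  pva.py         stochastic projection and extinction risk
  iucn.py        Red List criteria B, D, E
  synth.py       seeded synthetic-data generator
  pipeline.py    orchestration; cli.py  command line
  datasets/      bundled published summaries
docs/methods.md  methods note
```
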
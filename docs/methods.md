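# Methods note

This note records the statistical models, parameter conventions and numerical
choices behind `endemica`, and the scope and limitations of each stage.

## Geography

Occurrence points (WGS84 lon/lat) are projected with a spherical Lambert
azimuthal equal-area projection centred on the points' mean coordinate, using
an authalic Earth radius of 6371.0088 km. Equal-area projection is the correct
choice because both range metrics are areas: EOO is the area of the minimum
convex polygon of the projected points (Shapely convex hull; degenerate hulls
— fewer than three distinct points or collinear points — are flagged and
reported with zero area), and AOO counts occupied cells of a 1×1 km grid
anchored at a configurable origin with half-open cell membership, so a point on
a cell edge belongs to exactly one cell. For a handful of points spanning a few
tens of kilometres the spherical projection differs from an ellipsoidal one by
far less than GPS positional error. Densities are reported as plants per m²
with a formatting helper that prints trailing-zero-free decimals ("0.003",
"0.7").

## Demography

Census tables hold per-subpopulation, per-year counts of mature, seedling,
non-reproductive and dead plants; stage structure excludes the dead. Growth
ratios are R_t = N(t+1)/N(t) on mature totals. Reproduction follows the
per-tagged-individual chain: flowers per individual F = Fl × St (flowering
stems × flowers per stem), fruits per individual = F × fruit set, and fecundity
(sound seeds per individual) = S × St with S sound seeds per stem. Relative
reproductive success is seeds / (flowers × 2 ovules), clipped to [0, 1].
Survival confidence intervals are exact Clopper–Pearson (beta quantiles).
Generation length uses the standard approximation α + 1/(1 − s_a) with age at
first reproduction α and adult survival s_a. Effective population size uses the
common heuristic ratios Ne/Nc ∈ {0.4, 0.1}, flagging results below 50; these
are order-of-magnitude screens, not pedigree estimates.

## Population genetics

Allele frequencies are direct counts over non-missing calls (allele code 0 =
missing; half-missing genotypes are rejected at validation). Diversity
statistics use the usual unbiased expected heterozygosity (2n/(2n−1) correction).
F-statistics follow Nei's variance decomposition, satisfying the identity
(1 − F_IT) = (1 − F_IS)(1 − F_ST) exactly; Weir–Cockerham θ is also provided,
and both come with permutation tests that shuffle individuals among
subpopulations. Genetic distance is Nei's unbiased distance, which can be
slightly negative for small samples — that is a property of the estimator, not
a bug. Gene flow uses the island-model transform Nm = (1 − F_ST)/(4 F_ST).
Hardy–Weinberg tests are chi-square with df = k(k−1)/2 over observed alleles,
flagging cells with expected counts below 5.

Null alleles are estimated per locus by an expectation–maximisation algorithm
that treats the null as a hidden (k+1)-th allele whose homozygote is observed
as missing data and whose heterozygotes are observed as visible homozygotes.
The ENA-corrected F_ST ("excluding null alleles") recomputes θ from the EM's
visible-allele frequencies **without renormalising them to sum to one**:
renormalisation would redistribute the null's frequency mass proportionally and
reintroduce exactly the homozygote excess the correction is meant to remove.
The correction's effect is validated on synthetic data where truth is known —
across replicates, raw θ is biased upward by about +0.025 under 6–25% null
rates while the corrected estimate is within 0.004 of truth.

AMOVA is a two-level (among / within subpopulations) analysis on a per-locus
allele-mismatch distance (number of allele copies not shared between two
genotypes, summed over loci, halved), with Φ_ST and a permutation test.
Sums of squares use the pairwise-distance identity SS = Σ d²/n, so no explicit
allele coding is needed. PCoA uses Gower double-centring of the squared
distance matrix, keeping positive eigenvalues. Evanno's ΔK consumes a table of
replicate log-probabilities per K and reports |L''(K)| / sd(K); K values
without replicates or with zero standard deviation are flagged rather than
silently producing infinities.

## Population viability analysis

The projection is count-based ("diffusion-style") with multiplicative
environmental noise: each year each replicate draws a lognormal growth
multiplier whose **arithmetic** mean and standard deviation equal the
configured values (μ, σ of the underlying normal are solved from the moment
equations, not set to log-mean/log-sd — a common source of bias when growth
statistics are computed on the ratio scale). Demographic stochasticity
(default on) resolves the expected next size into Binomial survivors (when a
survival rate is given) plus Poisson recruits, or a single Poisson draw
otherwise. Quasi-extinction at or below the threshold is absorbing. The
simulator is validated against an exact oracle: with n0 = 1, σ = 0 and
subcritical mean m, the model is a Poisson Galton–Watson branching process
whose cumulative extinction probabilities obey the probability generating
function recursion q(t+1) = exp(m(q(t) − 1)); simulated curves match the
recursion within Monte Carlo error at 100 000 replicates. `fit_growth` reports
the sample mean and sample standard deviation (ddof = 1) of observed growth
ratios, plus the log-scale sd for users who prefer a stochastic-Gompertz
parameterisation. Default replicate counts (20 000 for headline risks) were
chosen so that the binomial standard error of a mid-range risk is below 0.004;
they are a package choice and can be raised freely.

## Red List engine

Criteria B, D and E are implemented with strict "<" thresholds (a value exactly
at a boundary does not qualify for the more threatened category). Criterion B
requires at least two of conditions (a) fragmentation/locations, (b) continuing
decline and (c) extreme fluctuations, and emits canonical code strings such as
`B1ab(i,ii,iii,v)c(i,ii,iv)`. The overall category is the most severe across
criteria, listing only the codes that support it. An NT heuristic is applied
when a range metric falls within 10% of a VU threshold. The engine is checked
by a fuzz test: for thousands of random inputs, worsening any input never makes
the assessed category less severe (monotonicity).

## Synthetic data generator

`SynthSpec` drives a seeded simulator used both for test oracles and for the
`simulate-data` command:

- **Genotypes** — ancestral allele frequencies are drawn from a Dirichlet with
  concentration controlled by `ancestral_evenness`; subpopulation frequencies
  follow the Balding–Nichols model Dirichlet(p(1 − F)/F) with F = `target_fst`;
  genotypes are drawn with inbreeding coefficient f (with probability f the
  individual is autozygous); null alleles are a hidden (k+1)-th allele state —
  null homozygotes become missing, null heterozygotes become visible
  homozygotes.
- **Monitoring** — subpopulation trajectories share a lognormal year effect
  (environmental correlation) on top of independent demographic noise.
- **Reproduction** — a Negative-Binomial → Binomial → Poisson → Binomial
  hierarchy generates stems, flowering stems, flowers, fruits and sound seeds
  per tagged individual, guaranteeing internal consistency (e.g. flowering
  stems ≤ stems, fruit set ∈ [0, 1]).

Estimator recovery is measured on a fixed reference panel (5 subpopulations ×
15 genotyped individuals, 10 loci × 12 alleles, evenness 5.0, f = 0, no nulls).
Panel size is a package choice balancing statistical resolution against runtime
on one CPU. With that panel, Weir–Cockerham θ recovers weak-to-moderate
targets (F_ST 0.05 and 0.16) to within ±0.03 in ≥ 90% of replicates. At strong
differentiation (F_ST 0.3) the replicate-to-replicate sd of the *realised* F_ST
under Balding–Nichols sampling is ≈ 0.025 at 10 loci, so a per-replicate ±0.03
window cannot be guaranteed by any estimator; there the validated property is
unbiasedness of the mean estimate.

## Numerical and I/O choices

- CSV floats are written with shortest-round-trip `repr` formatting and read
  with pandas' `float_precision="round_trip"`, so write→read is exactly
  lossless (pandas' default fast parser is not).
- All stochastic code takes explicit seeds (`numpy.random.default_rng`);
  pipeline outputs are byte-identical across reruns with the same
  configuration.
- JSON outputs are written with sorted keys and fixed float formatting.

## Limitations

- EOO for the full species requires the complete occurrence set; the bundled
  coordinates are subpopulation centroids plus recorded per-subpopulation AOO
  cell counts, which reproduce AOO but only approximate the full-survey EOO.
- Effective population size uses ratio heuristics, not linkage-disequilibrium
  or temporal estimators.
- The PVA is unstructured (no stage matrix) and treats the census total as the
  state variable; catastrophes, density dependence and rescue effects are out
  of scope.
- The null-allele EM assumes Hardy–Weinberg within subpopulations apart from
  nulls; true inbreeding inflates estimated null rates.
- Evanno's ΔK cannot evaluate K = 1 and is known to favour the uppermost
  hierarchical level of structure.
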
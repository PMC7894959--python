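"""Synthetic-data generator for all pipeline inputs.

Emulates the statistical structure of a five-subpopulation cliff endemic
monitored over five seasons: tiny censuses (a few to a few dozen mature
plants) sharing one interannual fluctuation pattern, a hierarchical
stem → flower → fruit → seed reproduction chain, three SSR loci with a few
alleles each, moderate differentiation among subpopulations (Balding–Nichols
at a target FST), a within-subpopulation heterozygote deficit injected at
the genotype draw, per-locus null alleles, and occurrences strung along a
linear coastline.

Defaults mirror the magnitudes of the motivating field study: 5
subpopulations of ~2–46 plants, FST ≈ 0.16, inbreeding f ≈ 0.46, null-allele
rates 0.06–0.25, two ovules per flower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    GenotypeTable,
    MonitoringRecord,
    OccurrencePoint,
    ReproSample,
)

__all__ = ["SynthSpec", "generate_monitoring", "generate_reproduction",
           "generate_genotypes", "generate_coordinates", "generate_bundle"]


@dataclass
class SynthSpec:
    """Parameters of the synthetic study system."""

    n_subpops: int = 5
    subpop_initial_sizes: tuple[int, ...] = (28, 30, 46, 20, 6)
    n_years: int = 5
    start_year: int = 2014
    env_sd: float = 0.25  # sd of the shared log growth multiplier
    growth_mean: float = 1.0
    survival_sa: float = 0.85
    recruitment_rate: float = 0.15  # expected recruits per adult per year
    seedling_rate: float = 0.08  # seedlings per adult
    nonreproductive_rate: float = 0.2
    local_eoo_m2: tuple[float, ...] = (9100.9, 961.6, 44642.0, 16713.0, 12.9)
    # reproduction hierarchy
    n_tagged: int = 20
    stems_mean: float = 22.0
    stems_dispersion: float = 8.0  # negative-binomial size parameter
    p_flowering_stem: float = 0.7
    flowers_per_stem_mean: float = 18.0
    fruit_set: float = 0.33
    p_seed_per_ovule: float = 0.33  # each fruit carries two ovules
    # genetics
    n_individuals_genotyped: tuple[int, ...] = (13, 15, 17, 13, 5)
    n_loci: int = 3
    alleles_per_locus: tuple[int, ...] = (4, 4, 4)
    allele_size_base: int = 150
    ancestral_evenness: float = 1.0  # Dirichlet concentration for ancestral freqs
    target_fst: float = 0.16
    inbreeding_f: float = 0.46
    null_rates: tuple[float, ...] = (0.06, 0.20, 0.25)
    # geography
    coast_length_km: float = 30.0
    coast_origin: tuple[float, float] = (20.63, 37.86)  # lon, lat
    coast_bearing_deg: float = 160.0  # roughly south-southeast
    jitter_km: float = 0.15
    points_per_subpop: int = 4
    seed: int = 0
    subpop_names: tuple[str, ...] = field(
        default=("SP1", "SP2", "SP3", "SP4", "SP5")
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError("target_fst must lie in (0, 1)")
        for name in ("survival_sa", "p_flowering_stem", "fruit_set",
                     "p_seed_per_ovule", "inbreeding_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(not 0.0 <= r <= 1.0 for r in self.null_rates):
            raise ValueError("null rates must lie in [0, 1]")
        if len(self.subpop_names) < self.n_subpops:
            raise ValueError("not enough subpopulation names")


def _pops(spec: SynthSpec) -> list[str]:
    return list(spec.subpop_names[: spec.n_subpops])


def generate_monitoring(
    spec: SynthSpec, rng: Optional[np.random.Generator] = None
) -> list[MonitoringRecord]:
    """Censuses with one shared environmental multiplier per year.

    Each year draws a single lognormal deviate applied to every
    subpopulation's expected size; realised adult counts are Binomial
    survivors plus Poisson recruits, so subpopulations fluctuate in step.
    """
    rng = rng or np.random.default_rng(spec.seed)
    pops = _pops(spec)
    sizes = np.array(spec.subpop_initial_sizes[: spec.n_subpops], dtype=float)
    records: list[MonitoringRecord] = []
    mu = np.log(spec.growth_mean) - spec.env_sd**2 / 2
    current = sizes.copy()
    for t in range(spec.n_years):
        year = spec.start_year + t
        if t > 0:
            shared_R = float(np.exp(rng.normal(mu, spec.env_sd)))
            new = np.empty_like(current)
            deaths = np.empty(len(pops), dtype=int)
            for i, n in enumerate(current):
                n_int = int(round(n))
                p_surv = min(spec.survival_sa * shared_R, 1.0)
                survivors = rng.binomial(n_int, p_surv) if n_int > 0 else 0
                recruits = rng.poisson(
                    max(shared_R * spec.recruitment_rate, 0.0) * n_int
                )
                new[i] = survivors + recruits
                deaths[i] = n_int - survivors
            current = new
        else:
            deaths = np.zeros(len(pops), dtype=int)
        for i, pop in enumerate(pops):
            n_mature = int(round(current[i]))
            records.append(
                MonitoringRecord(
                    subpopulation=pop,
                    year=year,
                    n_mature=n_mature,
                    n_seedlings=int(rng.poisson(spec.seedling_rate * n_mature)),
                    n_nonreproductive=int(
                        rng.poisson(spec.nonreproductive_rate * n_mature)
                    ),
                    n_dead=int(deaths[i]),
                    local_eoo_m2=float(spec.local_eoo_m2[i]),
                )
            )
    return records


def generate_reproduction(
    spec: SynthSpec,
    monitoring: Sequence[MonitoringRecord],
    rng: Optional[np.random.Generator] = None,
) -> list[ReproSample]:
    """Hierarchical per-individual reproduction draws.

    stems ~ NegBinom, flowering stems ~ Binomial(stems, p), flowers per stem
    ~ Poisson, fruits ~ Binomial(flowers, fruit set), sound seeds ~
    Binomial(2·fruits, p_seed), next-season survival ~ Bernoulli(Sa).
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    years = sorted({r.year for r in monitoring})
    pops = _pops(spec)[:3]  # tag the most accessible subpopulations
    samples: list[ReproSample] = []
    size = spec.stems_dispersion
    p_nb = size / (size + spec.stems_mean)
    for year in years:
        for k in range(spec.n_tagged):
            pop = pops[k % len(pops)]
            stems = int(rng.negative_binomial(size, p_nb)) + 1
            flowering = int(rng.binomial(stems, spec.p_flowering_stem))
            n_flowers = (
                int(rng.poisson(spec.flowers_per_stem_mean * flowering))
                if flowering
                else 0
            )
            fl_per_stem = n_flowers / flowering if flowering else 0.0
            n_fruits = int(rng.binomial(n_flowers, spec.fruit_set)) if n_flowers else 0
            fruit_frac = n_fruits / n_flowers if n_flowers else 0.0
            n_seeds = (
                int(rng.binomial(2 * n_fruits, spec.p_seed_per_ovule))
                if n_fruits
                else 0
            )
            seeds_per_fruit = n_seeds / n_fruits if n_fruits else 0.0
            samples.append(
                ReproSample(
                    individual_id=f"{pop}-tag{k:02d}",
                    subpopulation=pop,
                    year=year,
                    n_stems=stems,
                    n_flowering_stems=flowering,
                    flowers_per_stem=fl_per_stem,
                    fruits_per_flower=fruit_frac,
                    sound_seeds_per_fruit=seeds_per_fruit,
                    seeds_per_stem=n_seeds / flowering if flowering else 0.0,
                    alive_next_season=bool(rng.random() < spec.survival_sa),
                )
            )
    return samples


def generate_genotypes(
    spec: SynthSpec, rng: Optional[np.random.Generator] = None
) -> GenotypeTable:
    """Balding–Nichols genotypes with inbreeding and null alleles.

    Ancestral frequencies ~ symmetric Dirichlet; subpopulation frequencies ~
    Dirichlet(p_anc (1−FST)/FST). Genotypes are drawn with inbreeding
    coefficient f: with probability f the two gene copies are identical by
    descent. One null allele per locus (frequency from ``null_rates``)
    renders visible/null heterozygotes as visible homozygotes and null/null
    genotypes as missing.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    pops = _pops(spec)
    sizes = spec.n_individuals_genotyped[: spec.n_subpops]
    fst = spec.target_fst
    theta = (1.0 - fst) / fst
    loci = [f"L{j + 1}" for j in range(spec.n_loci)]
    individuals: list[tuple[str, str]] = []
    for pop, n in zip(pops, sizes):
        individuals += [(f"{pop}-{i:02d}", pop) for i in range(n)]
    n_total = len(individuals)
    calls = np.zeros((n_total, spec.n_loci, 2), dtype=np.int64)
    null_rates = list(spec.null_rates) + [0.0] * spec.n_loci
    for j in range(spec.n_loci):
        k = spec.alleles_per_locus[j % len(spec.alleles_per_locus)]
        allele_codes = spec.allele_size_base + 25 * j + 5 * np.arange(k + 1)
        # last code stands for the null allele (never written to output)
        r_null = null_rates[j]
        p_anc = rng.dirichlet(np.full(k, spec.ancestral_evenness))
        p_anc = p_anc * (1.0 - r_null)
        freq_anc = np.append(p_anc, r_null)
        row = 0
        for pop, n in zip(pops, sizes):
            alpha = freq_anc * theta
            alpha = np.clip(alpha, 1e-6, None)
            p_pop = rng.dirichlet(alpha)
            for _ in range(n):
                first = rng.choice(k + 1, p=p_pop)
                if rng.random() < spec.inbreeding_f:
                    second = first
                else:
                    second = rng.choice(k + 1, p=p_pop)
                a, b = allele_codes[first], allele_codes[second]
                null_code = allele_codes[k]
                if a == null_code and b == null_code:
                    calls[row, j, :] = 0  # null homozygote: no amplification
                elif a == null_code:
                    calls[row, j, :] = (b, b)  # scored as visible homozygote
                elif b == null_code:
                    calls[row, j, :] = (a, a)
                else:
                    calls[row, j, :] = (a, b)
                row += 1
    return GenotypeTable(individuals, loci, calls)


def generate_coordinates(
    spec: SynthSpec, rng: Optional[np.random.Generator] = None
) -> list[OccurrencePoint]:
    """Occurrences jittered around centres spaced along a linear coastline."""
    rng = rng or np.random.default_rng(spec.seed + 3)
    pops = _pops(spec)
    bearing = np.radians(spec.coast_bearing_deg)
    lon0, lat0 = spec.coast_origin
    km_per_deg_lat = 111.195
    points: list[OccurrencePoint] = []
    spacing = spec.coast_length_km / max(len(pops) - 1, 1)
    for i, pop in enumerate(pops):
        d = i * spacing
        north = d * np.cos(bearing)
        east = d * np.sin(bearing)
        clat = lat0 + north / km_per_deg_lat
        clon = lon0 + east / (km_per_deg_lat * np.cos(np.radians(clat)))
        for _ in range(spec.points_per_subpop):
            jn = rng.normal(0.0, spec.jitter_km)
            je = rng.normal(0.0, spec.jitter_km)
            lat = clat + jn / km_per_deg_lat
            lon = clon + je / (km_per_deg_lat * np.cos(np.radians(clat)))
            points.append(OccurrencePoint(pop, float(lon), float(lat)))
    return points


def generate_bundle(spec: SynthSpec) -> dict:
    """Generate every pipeline input from one seeded spec."""
    rng = np.random.default_rng(spec.seed)
    monitoring = generate_monitoring(spec, rng)
    reproduction = generate_reproduction(spec, monitoring, rng)
    genotypes = generate_genotypes(spec, rng)
    coordinates = generate_coordinates(spec, rng)
    return {
        "monitoring": monitoring,
        "reproduction": reproduction,
        "genotypes": genotypes,
        "coordinates": coordinates,
    }
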
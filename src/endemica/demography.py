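"""Census aggregation, stage structure, growth, and reproductive metrics.

Reproductive bookkeeping follows the standard monitoring chain for a
hermaphrodite perennial: flowering stems per individual (St), flowers per
stem (Fl), flowers per individual (F = Fl × St), fruit set (fruits per
flower), seeds per stem (S), fecundity (seeds per individual = S × St),
relative reproductive success (sound seeds over ovules), seed rain
(seeds per m² of occupied habitat), adult survival (Sa) and generation
length α + 1/(1 − Sa).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MonitoringRecord, ReproSample

logger = logging.getLogger(__name__)

__all__ = [
    "StageStructure",
    "ReproSummary",
    "census_totals",
    "stage_structure",
    "growth_ratios",
    "flowers_per_individual",
    "fruits_per_individual",
    "fecundity",
    "rrs",
    "seed_rain",
    "survival_rate",
    "generation_length",
    "effective_size",
    "summarise_reproduction",
]

OVULES_PER_FLOWER = 2  # schizocarp of two one-seeded mericarps


@dataclass(frozen=True)
class StageStructure:
    """Stage-class proportions for one scope-year (dead excluded)."""

    year: int
    scope: str
    p_mature: float
    p_nonreproductive: float
    p_seedlings: float

    def __post_init__(self) -> None:
        total = self.p_mature + self.p_nonreproductive + self.p_seedlings
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"stage proportions must sum to 1, got {total}")


@dataclass
class ReproSummary:
    """Per-year reproductive summary with the internal product identities."""

    year: int
    n: int
    St: float
    St_se: float
    Fl: float
    Fl_se: float
    F: float
    fruit_set: float
    fruit_set_se: float
    fruits_per_individual: float
    S: float
    S_se: float
    fecundity: float
    rrs: float
    rrs_se: float
    Sa: Optional[float] = None
    seed_rain_by_subpop: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        assert abs(self.F - self.Fl * self.St) < 1e-9
        assert abs(self.fecundity - self.S * self.St) < 1e-9
        assert abs(self.fruits_per_individual - self.F * self.fruit_set) < 1e-9
        assert 0.0 <= self.rrs <= 1.0


def census_totals(records: Sequence[MonitoringRecord]) -> pd.DataFrame:
    """Per-year totals across subpopulations, indexed by year."""
    df = pd.DataFrame(
        [
            {
                "year": r.year,
                "n_mature": r.n_mature,
                "n_seedlings": r.n_seedlings,
                "n_nonreproductive": r.n_nonreproductive,
                "n_dead": r.n_dead,
            }
            for r in records
        ]
    )
    return df.groupby("year").sum().sort_index()


def stage_structure(
    records: Sequence[MonitoringRecord], year: int, scope: str = "TOTAL"
) -> StageStructure:
    """Proportions of mature / non-reproductive / seedlings in a scope-year.

    Dead individuals are excluded from the denominator (they are reported
    separately in the census).
    """
    rows = [
        r
        for r in records
        if r.year == year and (scope == "TOTAL" or r.subpopulation == scope)
    ]
    m = sum(r.n_mature for r in rows)
    nr = sum(r.n_nonreproductive for r in rows)
    s = sum(r.n_seedlings for r in rows)
    total = m + nr + s
    if total == 0:
        raise ValueError(f"no individuals in scope {scope!r}, year {year}")
    return StageStructure(
        year=year,
        scope=scope,
        p_mature=m / total,
        p_nonreproductive=nr / total,
        p_seedlings=s / total,
    )


def growth_ratios(mature_totals: Sequence[float]) -> np.ndarray:
    """Annual growth multipliers R_t = N(t+1)/N(t) for a census series."""
    totals = np.asarray(mature_totals, dtype=float)
    if totals.size < 2:
        raise ValueError("need at least two census years")
    if (totals[:-1] <= 0).any():
        raise ValueError("zero census in a non-final year: ratios undefined")
    return totals[1:] / totals[:-1]


def flowers_per_individual(Fl: float, St: float) -> float:
    """F = Fl × St (mean flowers per stem × mean flowering stems)."""
    if Fl < 0 or St < 0:
        raise ValueError("Fl and St must be >= 0")
    return Fl * St


def fruits_per_individual(F: float, fruit_set: float) -> float:
    """Mean fruits per individual = flowers per individual × fruit set."""
    if not 0.0 <= fruit_set <= 1.0:
        raise ValueError(f"fruit_set must lie in [0, 1], got {fruit_set}")
    return F * fruit_set


def fecundity(S: float, St: float) -> float:
    """Mean sound seeds per individual = seeds per stem × flowering stems."""
    if S < 0 or St < 0:
        raise ValueError("S and St must be >= 0")
    return S * St


def rrs(
    sound_seeds_per_individual: float,
    flowers_per_ind: float,
    ovules_per_flower: int = OVULES_PER_FLOWER,
) -> float:
    """Relative reproductive success: sound seeds over potential seeds.

    The potential maximum is flowers × ovules per flower. Values above 1
    (possible with noisy per-stem means) are clipped to 1 with a warning.
    """
    if flowers_per_ind <= 0:
        raise ValueError("flowers_per_individual must be > 0")
    value = sound_seeds_per_individual / (flowers_per_ind * ovules_per_flower)
    if value > 1.0:
        logger.warning("RRS %.3f > 1 clipped to 1 (sampling noise)", value)
        value = 1.0
    return value


def seed_rain(fecundity_value: float, n_mature: int, local_eoo_m2: float) -> float:
    """Seeds per m²: fecundity × mature individuals / local EOO."""
    if not local_eoo_m2 > 0:
        raise ValueError("local_eoo_m2 must be > 0")
    return fecundity_value * n_mature / local_eoo_m2


def survival_rate(
    n_alive_next: int, n_tagged: int, ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Adult survival Sa with an exact (Clopper–Pearson) binomial interval."""
    if n_tagged <= 0:
        raise ValueError("n_tagged must be > 0")
    if not 0 <= n_alive_next <= n_tagged:
        raise ValueError("n_alive_next must lie in [0, n_tagged]")
    p = n_alive_next / n_tagged
    alpha = 1.0 - ci_level
    lo = (
        0.0
        if n_alive_next == 0
        else stats.beta.ppf(alpha / 2, n_alive_next, n_tagged - n_alive_next + 1)
    )
    hi = (
        1.0
        if n_alive_next == n_tagged
        else stats.beta.ppf(1 - alpha / 2, n_alive_next + 1, n_tagged - n_alive_next)
    )
    return p, (float(lo), float(hi))


def generation_length(alpha: float, Sa: float) -> float:
    """Generation length α + 1/(1 − Sa), α = age at first reproduction."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not 0.0 <= Sa < 1.0:
        raise ValueError(f"Sa must lie in [0, 1), got {Sa}")
    return alpha + 1.0 / (1.0 - Sa)


def effective_size(
    Nc: int, ratios: Sequence[float] = (0.4, 0.1), flag_below: int = 50
) -> list[dict]:
    """Heuristic effective sizes Ne = ratio × Nc, flagged when below 50.

    Ne/Nc ratios of 0.4 and 0.1 bracket the commonly observed range; Ne
    below 50 signals short-term inbreeding risk.
    """
    if Nc < 0:
        raise ValueError("Nc must be >= 0")
    out = []
    for r in ratios:
        ne = round(r * Nc)
        out.append({"ratio": r, "ne": int(ne), "flag_below_50": ne < flag_below})
    return out


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan"), float("nan")
    se = values.std(ddof=1) / math.sqrt(values.size) if values.size > 1 else 0.0
    return float(values.mean()), float(se)


def summarise_reproduction(
    samples: Sequence[ReproSample],
    year: int,
    monitoring: Optional[Sequence[MonitoringRecord]] = None,
) -> ReproSummary:
    """Aggregate tagged-individual measurements into a per-year summary.

    Means over tagged individuals are unweighted arithmetic means with
    standard errors sd/√n. Seed rain is computed per subpopulation when the
    matching census records are supplied.
    """
    rows = [s for s in samples if s.year == year]
    if not rows:
        raise ValueError(f"no reproductive samples for year {year}")
    St, St_se = _mean_se(np.array([s.n_flowering_stems for s in rows]))
    Fl, Fl_se = _mean_se(np.array([s.flowers_per_stem for s in rows]))
    fruit_set, fruit_set_se = _mean_se(np.array([s.fruits_per_flower for s in rows]))
    S, S_se = _mean_se(np.array([s.seeds_per_stem for s in rows]))
    F = flowers_per_individual(Fl, St)
    fec = fecundity(S, St)
    # per-individual RRS, then averaged (each tagged plant is one unit)
    rrs_vals = [
        rrs(s.seeds_per_stem * s.n_flowering_stems, f_ind)
        for s in rows
        if (f_ind := s.flowers_per_stem * s.n_flowering_stems) > 0
    ]
    rrs_mean, rrs_se = _mean_se(np.array(rrs_vals)) if rrs_vals else (0.0, 0.0)
    tagged = [s for s in rows if s.alive_next_season is not None]
    Sa = None
    if tagged:
        Sa, _ = survival_rate(
            sum(1 for s in tagged if s.alive_next_season), len(tagged)
        )
    rain = None
    if monitoring is not None:
        rain = {}
        for rec in monitoring:
            if rec.year == year:
                rain[rec.subpopulation] = seed_rain(
                    fec, rec.n_mature, rec.local_eoo_m2
                )
    return ReproSummary(
        year=year,
        n=len(rows),
        St=St,
        St_se=St_se,
        Fl=Fl,
        Fl_se=Fl_se,
        F=F,
        fruit_set=fruit_set,
        fruit_set_se=fruit_set_se,
        fruits_per_individual=fruits_per_individual(F, min(fruit_set, 1.0)),
        S=S,
        S_se=S_se,
        fecundity=fec,
        rrs=min(rrs_mean, 1.0),
        rrs_se=rrs_se,
        Sa=Sa,
        seed_rain_by_subpop=rain,
    )
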
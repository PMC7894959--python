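"""Core domain types shared by all analysis stages.

The package models a small, fragmented plant population monitored over a
handful of seasons: per-subpopulation censuses, per-individual reproductive
measurements, georeferenced occurrences, and codominant diploid SSR
genotypes. Each type validates its own invariants on construction so that
downstream stages can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MonitoringRecord",
    "ReproSample",
    "OccurrencePoint",
    "GenotypeTable",
    "RunConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


@dataclass(frozen=True)
class MonitoringRecord:
    """One subpopulation-year census row.

    Counts cover the three life stages recorded in the field (mature,
    seedling, non-reproductive) plus deaths; ``local_eoo_m2`` is the minimum
    area actually occupied by the subpopulation's individuals, in m².
    """

    subpopulation: str
    year: int
    n_mature: int
    n_seedlings: int
    n_nonreproductive: int
    n_dead: int
    local_eoo_m2: float

    def __post_init__(self) -> None:
        for name in ("n_mature", "n_seedlings", "n_nonreproductive", "n_dead"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if not self.local_eoo_m2 > 0:
            raise ValidationError(
                f"local_eoo_m2 must be > 0, got {self.local_eoo_m2}"
            )


@dataclass(frozen=True)
class ReproSample:
    """Reproductive measurements for one tagged individual in one season.

    The fruit is a schizocarp of two one-seeded mericarps, so a flower
    carries exactly two ovules and ``sound_seeds_per_fruit`` cannot
    exceed 2.
    """

    individual_id: str
    subpopulation: str
    year: int
    n_stems: int
    n_flowering_stems: int
    flowers_per_stem: float
    fruits_per_flower: float
    sound_seeds_per_fruit: float
    seeds_per_stem: float
    alive_next_season: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.n_flowering_stems > self.n_stems:
            raise ValidationError(
                "n_flowering_stems cannot exceed n_stems "
                f"({self.n_flowering_stems} > {self.n_stems})"
            )
        if not 0.0 <= self.fruits_per_flower <= 1.0:
            raise ValidationError(
                f"fruits_per_flower must lie in [0, 1], got {self.fruits_per_flower}"
            )
        if self.sound_seeds_per_fruit > 2.0:
            raise ValidationError(
                "sound_seeds_per_fruit cannot exceed 2 (two ovules per flower), "
                f"got {self.sound_seeds_per_fruit}"
            )
        for name in ("n_stems", "n_flowering_stems"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("flowers_per_stem", "sound_seeds_per_fruit", "seeds_per_stem"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class OccurrencePoint:
    """A WGS84 occurrence point labelled with its subpopulation."""

    subpopulation: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"lon out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"lat out of range: {self.lat}")


MISSING = 0  # allele code for a failed call (GenAlEx convention)


class GenotypeTable:
    """Diploid codominant multilocus genotypes with subpopulation labels.

    Calls are stored as an ``(n_individuals, n_loci, 2)`` integer array of
    allele codes (fragment sizes in bp); 0 marks a missing allele. A call
    with one missing allele is treated as fully missing, since
    heterozygosity cannot be scored on half a call.
    """

    def __init__(
        self,
        individuals: Sequence[tuple[str, str]],
        loci: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(loci), 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"({len(individuals)}, {len(loci)}, 2)"
            )
        if (calls < 0).any():
            raise ValidationError("allele codes must be non-negative (0 = missing)")
        # half-missing calls are zeroed out entirely
        half = (calls == MISSING).any(axis=2) & (calls != MISSING).any(axis=2)
        if half.any():
            calls = calls.copy()
            calls[half] = MISSING
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.calls = calls

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def subpopulations(self) -> list[str]:
        """Distinct subpopulation labels in first-appearance order."""
        seen: dict[str, None] = {}
        for _, pop in self.individuals:
            seen.setdefault(pop, None)
        return list(seen)

    def pop_indices(self, subpopulation: str) -> np.ndarray:
        return np.array(
            [i for i, (_, p) in enumerate(self.individuals) if p == subpopulation],
            dtype=int,
        )

    def is_missing(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, indices: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(indices, dtype=int)
        return GenotypeTable(
            [self.individuals[i] for i in idx], self.loci, self.calls[idx]
        )

    def with_labels(self, labels: Sequence[str]) -> "GenotypeTable":
        """Return a copy with subpopulation labels replaced (same order)."""
        if len(labels) != self.n_individuals:
            raise ValidationError("label count mismatch")
        individuals = [(ind, lab) for (ind, _), lab in zip(self.individuals, labels)]
        return GenotypeTable(individuals, self.loci, self.calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeTable(n_individuals={self.n_individuals}, "
            f"n_loci={self.n_loci}, subpopulations={self.subpopulations})"
        )


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Paths are optional: a stage whose inputs are absent is skipped with a
    logged warning rather than aborting the run.
    """

    random_seed: int = 0
    n_permutations: int = 999
    aoo_cell_km: float = 1.0
    aoo_origin: tuple[float, float] = (0.0, 0.0)
    monitoring_path: Optional[str] = None
    reproduction_path: Optional[str] = None
    coordinates_path: Optional[str] = None
    genotypes_path: Optional[str] = None
    genotype_dialect: str = "long"
    lnk_path: Optional[str] = None
    output_dir: str = "results"
    pva: dict = field(default_factory=dict)
    assessment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not self.aoo_cell_km > 0:
            raise ValidationError("aoo_cell_km must be > 0")
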
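"""Readers and writers for the package's CSV dialects.

All tables are comma-separated UTF-8 with a header row. Genotypes are read
in two dialects: a GenAlEx-style layout (three header rows, two columns per
locus) and a simple long format (one row per individual × locus). Missing
alleles are coded 0 in both.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    GenotypeTable,
    MonitoringRecord,
    OccurrencePoint,
    ReproSample,
    RunConfig,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_monitoring",
    "write_monitoring",
    "read_reproduction",
    "write_reproduction",
    "read_coordinates",
    "write_coordinates",
    "read_genotypes",
    "write_genotypes",
    "read_lnk_table",
    "load_config",
]


class SchemaError(ValueError):
    """Raised when an input file does not match its documented schema."""


def _exact_float(v) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(v))


MONITORING_COLUMNS = [
    "subpopulation",
    "year",
    "n_mature",
    "n_seedlings",
    "n_nonreproductive",
    "n_dead",
    "local_eoo_m2",
]

REPRODUCTION_COLUMNS = [
    "individual_id",
    "subpopulation",
    "year",
    "n_stems",
    "n_flowering_stems",
    "flowers_per_stem",
    "fruits_per_flower",
    "sound_seeds_per_fruit",
    "seeds_per_stem",
    "alive_next_season",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_monitoring(path) -> list[MonitoringRecord]:
    """Read subpopulation-year census rows, preserving file order."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, MONITORING_COLUMNS, path)
    records = []
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        try:
            rec = MonitoringRecord(
                subpopulation=str(row["subpopulation"]),
                year=int(row["year"]),
                n_mature=int(row["n_mature"]),
                n_seedlings=int(row["n_seedlings"]),
                n_nonreproductive=int(row["n_nonreproductive"]),
                n_dead=int(row["n_dead"]),
                local_eoo_m2=float(row["local_eoo_m2"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
        key = (rec.subpopulation, rec.year)
        if key in seen:
            raise ValidationError(f"{path}: duplicate (subpopulation, year) {key}")
        seen.add(key)
        records.append(rec)
    logger.info("read %d monitoring records from %s", len(records), path)
    return records


def write_monitoring(records: Sequence[MonitoringRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=MONITORING_COLUMNS).to_csv(
        path, index=False, float_format=_exact_float
    )


def read_reproduction(path) -> list[ReproSample]:
    """Read per-tagged-individual reproductive measurements."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, REPRODUCTION_COLUMNS[:-1], path)
    samples = []
    for i, row in df.iterrows():
        alive = row.get("alive_next_season")
        if alive is None or (isinstance(alive, float) and np.isnan(alive)):
            alive_val = None
        else:
            alive_val = bool(alive)
        try:
            samples.append(
                ReproSample(
                    individual_id=str(row["individual_id"]),
                    subpopulation=str(row["subpopulation"]),
                    year=int(row["year"]),
                    n_stems=int(row["n_stems"]),
                    n_flowering_stems=int(row["n_flowering_stems"]),
                    flowers_per_stem=float(row["flowers_per_stem"]),
                    fruits_per_flower=float(row["fruits_per_flower"]),
                    sound_seeds_per_fruit=float(row["sound_seeds_per_fruit"]),
                    seeds_per_stem=float(row["seeds_per_stem"]),
                    alive_next_season=alive_val,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    logger.info("read %d reproduction samples from %s", len(samples), path)
    return samples


def write_reproduction(samples: Sequence[ReproSample], path) -> None:
    pd.DataFrame([vars(s) for s in samples], columns=REPRODUCTION_COLUMNS).to_csv(
        path, index=False, float_format=_exact_float
    )


def read_coordinates(path) -> list[OccurrencePoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subpopulation", "lon", "lat"], path)
    return [
        OccurrencePoint(str(r["subpopulation"]), float(r["lon"]), float(r["lat"]))
        for _, r in df.iterrows()
    ]


def write_coordinates(points: Sequence[OccurrencePoint], path) -> None:
    pd.DataFrame(
        [vars(p) for p in points], columns=["subpopulation", "lon", "lat"]
    ).to_csv(path, index=False, float_format=_exact_float)


# -- genotypes ---------------------------------------------------------------


def read_genotypes(path, dialect: str = "long") -> GenotypeTable:
    """Read a diploid genotype table.

    ``dialect='genalex'``: row 1 = n_loci, n_samples, n_pops, pop sizes;
    row 2 = title then pop names; row 3 = header (sample, pop, 2 cols/locus).
    ``dialect='long'``: header individual_id,subpopulation,locus,allele1,allele2.
    """
    if dialect == "genalex":
        return _read_genalex(path)
    if dialect == "long":
        return _read_long(path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_genalex(path) -> GenotypeTable:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise SchemaError(f"{path}: GenAlEx file needs 3 header rows")
    meta = [f for f in lines[0].split(",")]
    try:
        n_loci, n_samples, n_pops = (int(meta[i]) for i in range(3))
        pop_sizes = [int(x) for x in meta[3 : 3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise SchemaError(f"{path}: malformed GenAlEx meta row") from exc
    if sum(pop_sizes) != n_samples:
        raise SchemaError(
            f"{path}: pop sizes {pop_sizes} do not sum to n_samples {n_samples}"
        )
    header = lines[2].split(",")
    allele_cols = [c for c in header[2:] if c.strip() != ""]
    if len(allele_cols) != 2 * n_loci and len(header) - 2 < 2 * n_loci:
        raise SchemaError(
            f"{path}: expected {2 * n_loci} allele columns, found {len(header) - 2}"
        )
    # locus names sit in every other column of the header
    loci = [header[2 + 2 * j].strip() for j in range(n_loci)]
    individuals: list[tuple[str, str]] = []
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    body = [ln for ln in lines[3:] if ln.strip(", ") != ""]
    if len(body) != n_samples:
        raise SchemaError(f"{path}: expected {n_samples} sample rows, got {len(body)}")
    for i, ln in enumerate(body):
        parts = ln.split(",")
        if len(parts) < 2 + 2 * n_loci:
            raise SchemaError(f"{path}: sample row {i + 4} too short")
        individuals.append((parts[0].strip(), parts[1].strip()))
        for j in range(n_loci):
            a = parts[2 + 2 * j].strip()
            b = parts[3 + 2 * j].strip()
            calls[i, j, 0] = int(a) if a else 0
            calls[i, j, 1] = int(b) if b else 0
    return GenotypeTable(individuals, loci, calls)


def write_genotypes(table: GenotypeTable, path, dialect: str = "long") -> None:
    if dialect == "genalex":
        _write_genalex(table, path)
    elif dialect == "long":
        _write_long(table, path)
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _write_genalex(table: GenotypeTable, path) -> None:
    pops = table.subpopulations
    sizes = [len(table.pop_indices(p)) for p in pops]
    with open(path, "w", encoding="utf-8") as fh:
        meta = [str(table.n_loci), str(table.n_individuals), str(len(pops))] + [
            str(s) for s in sizes
        ]
        fh.write(",".join(meta) + "\n")
        fh.write(",".join(["genotypes", ""] + pops) + "\n")
        header = ["sample", "pop"]
        for locus in table.loci:
            header += [locus, ""]
        fh.write(",".join(header) + "\n")
        # GenAlEx groups samples by population
        for pop in pops:
            for i in table.pop_indices(pop):
                row = [table.individuals[i][0], pop]
                for j in range(table.n_loci):
                    row += [str(table.calls[i, j, 0]), str(table.calls[i, j, 1])]
                fh.write(",".join(row) + "\n")


def _read_long(path) -> GenotypeTable:
    df = pd.read_csv(path)
    _require_columns(
        df, ["individual_id", "subpopulation", "locus", "allele1", "allele2"], path
    )
    loci = list(dict.fromkeys(df["locus"].astype(str)))
    individuals = list(
        dict.fromkeys(
            zip(df["individual_id"].astype(str), df["subpopulation"].astype(str))
        )
    )
    ind_index = {ind_id: k for k, (ind_id, _) in enumerate(individuals)}
    locus_index = {loc: j for j, loc in enumerate(loci)}
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    for _, row in df.iterrows():
        i = ind_index[str(row["individual_id"])]
        j = locus_index[str(row["locus"])]
        calls[i, j, 0] = int(row["allele1"])
        calls[i, j, 1] = int(row["allele2"])
    return GenotypeTable(individuals, loci, calls)


def _write_long(table: GenotypeTable, path) -> None:
    rows = []
    for i, (ind_id, pop) in enumerate(table.individuals):
        for j, locus in enumerate(table.loci):
            rows.append(
                {
                    "individual_id": ind_id,
                    "subpopulation": pop,
                    "locus": locus,
                    "allele1": int(table.calls[i, j, 0]),
                    "allele2": int(table.calls[i, j, 1]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_structure(table: GenotypeTable, path) -> None:
    """Export genotypes in STRUCTURE's two-rows-per-individual text format.

    Missing alleles are recoded -9 (STRUCTURE convention). Populations are
    coded as 1-based integers in first-appearance order.
    """
    pop_code = {p: k + 1 for k, p in enumerate(table.subpopulations)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(table.loci) + "\n")
        for i, (ind_id, pop) in enumerate(table.individuals):
            for a in range(2):
                alleles = [
                    str(int(x)) if x != 0 else "-9" for x in table.calls[i, :, a]
                ]
                fh.write("\t".join([ind_id, str(pop_code[pop])] + alleles) + "\n")


def read_lnk_table(path) -> pd.DataFrame:
    """Read replicate clustering log-probabilities: columns K, lnp."""
    df = pd.read_csv(path)
    _require_columns(df, ["K", "lnp"], path)
    return df[["K", "lnp"]].astype({"K": int, "lnp": float})


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    if "aoo_origin" in raw:
        raw["aoo_origin"] = tuple(raw["aoo_origin"])
    return RunConfig(**raw)
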
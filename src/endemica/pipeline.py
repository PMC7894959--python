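"""Pipeline orchestrator: run every stage over a set of input files.

Stages run in order geo → demography → popgen → pva → assessment; a stage
whose inputs are missing is skipped with a logged warning. Each stage writes
one JSON document; a run with the same seed and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import demography, geo, io, iucn, popgen, pva
from .datamodel import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so JSON output is byte-stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def _write_json(doc: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_floats(doc), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return {stage: document} and write JSON files."""
    out_dir = Path(config.output_dir)
    results: dict[str, dict] = {}
    logger.info("pipeline start: seed=%d", config.random_seed)

    points = None
    if config.coordinates_path:
        points = io.read_coordinates(config.coordinates_path)

    monitoring = None
    if config.monitoring_path:
        monitoring = io.read_monitoring(config.monitoring_path)

    # -- geo
    if points:
        try:
            local_eoo = None
            if monitoring:
                local_eoo = {}
                for rec in monitoring:
                    local_eoo[rec.subpopulation] = rec.local_eoo_m2
            metrics = geo.range_metrics(
                points,
                cell_km=config.aoo_cell_km,
                origin=config.aoo_origin,
                local_eoo_m2_by_subpop=local_eoo,
            )
            doc = metrics.to_dict()
            if local_eoo:
                doc["local_eoo_m2_by_subpop"] = local_eoo
            results["geo"] = doc
            _write_json(doc, out_dir / "geo.json")
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise StageError("geo", exc) from exc
    else:
        logger.warning("geo stage skipped: no coordinates")

    # -- demography
    if monitoring:
        try:
            totals = demography.census_totals(monitoring)
            years = list(totals.index)
            structures = {
                int(y): vars(demography.stage_structure(monitoring, int(y)))
                for y in years
            }
            ratios = demography.growth_ratios(totals["n_mature"].to_numpy())
            ne = demography.effective_size(int(totals["n_mature"].iloc[0]))
            doc = {
                "census_totals": {
                    str(y): {k: int(v) for k, v in row.items()}
                    for y, row in totals.iterrows()
                },
                "stage_structure": structures,
                "growth_ratios": ratios.tolist(),
                "effective_size": ne,
            }
            if config.reproduction_path:
                samples = io.read_reproduction(config.reproduction_path)
                summaries = {}
                for year in sorted({s.year for s in samples}):
                    summary = demography.summarise_reproduction(
                        samples, year, monitoring
                    )
                    summaries[str(year)] = {
                        k: v for k, v in vars(summary).items()
                    }
                doc["reproduction"] = summaries
            results["demography"] = doc
            _write_json(doc, out_dir / "demography.json")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("demography", exc) from exc
    else:
        logger.warning("demography stage skipped: no monitoring data")

    # -- popgen
    if config.genotypes_path:
        try:
            g = io.read_genotypes(config.genotypes_path, config.genotype_dialect)
            div = popgen.diversity(g)
            fstats = popgen.f_statistics(
                g, n_permutations=config.n_permutations, seed=config.random_seed
            )
            nei = popgen.nei_unbiased_distance(g)
            ena = popgen.fst_ena(
                g, n_bootstrap=min(config.n_permutations * 10, 10_000),
                seed=config.random_seed,
            )
            am = popgen.amova(
                g, n_permutations=config.n_permutations, seed=config.random_seed
            )
            af = popgen.allele_frequencies(g)
            pics = {locus: popgen.pic(af.pooled(locus)) for locus in g.loci}
            doc = {
                "diversity_by_subpop": div.by_subpop.to_dict(orient="records"),
                "f_statistics": {
                    "per_locus": fstats.per_locus.to_dict(orient="records"),
                    "mean": fstats.mean,
                    "p_fst": fstats.p_fst,
                    "p_fis": fstats.p_fis,
                },
                "nei_distance": nei.to_dict(),
                "fst_ena": {
                    k: v
                    for k, v in ena.items()
                    if k not in ("null_r_hat",)
                } | {
                    "null_r_hat": {
                        f"{pop}|{locus}": r
                        for (pop, locus), r in ena["null_r_hat"].items()
                    }
                },
                "gene_flow_nm": (
                    popgen.gene_flow(fstats.mean["FST"])
                    if fstats.mean["FST"] > 0
                    else None
                ),
                "amova": vars(am),
                "pic": pics,
            }
            if config.lnk_path:
                dk = popgen.evanno_delta_k(io.read_lnk_table(config.lnk_path))
                doc["evanno"] = {
                    "table": dk.to_dict(orient="records"),
                    "best_k": dk.attrs.get("best_k"),
                }
            results["popgen"] = doc
            _write_json(doc, out_dir / "popgen.json")
        except Exception as exc:  # noqa: BLE001
            raise StageError("popgen", exc) from exc
    else:
        logger.warning("popgen stage skipped: no genotype path configured")

    # -- pva
    if monitoring:
        try:
            totals = demography.census_totals(monitoring)
            growth = pva.fit_growth(totals["n_mature"].to_numpy())
            pva_cfg = dict(config.pva)
            cfg = pva.PVAConfig(
                n0=int(pva_cfg.pop("n0", totals["n_mature"].iloc[0])),
                growth_mean=float(pva_cfg.pop("growth_mean", growth["mean"])),
                growth_sd=float(pva_cfg.pop("growth_sd", growth["sd"])),
                seed=int(pva_cfg.pop("seed", config.random_seed)),
                **pva_cfg,
            )
            result = pva.simulate(cfg)
            doc = {
                "growth_fit": {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in growth.items()
                },
                "projection": result.to_dict(),
                "risk_10y": result.risk[min(10, cfg.horizon_years)],
                "risk_horizon": result.risk[-1],
            }
            results["pva"] = doc
            _write_json(doc, out_dir / "pva.json")
        except Exception as exc:  # noqa: BLE001
            raise StageError("pva", exc) from exc

    # -- assessment
    try:
        facts = dict(config.assessment)
        if "eoo_km2" not in facts and "geo" in results:
            facts["eoo_km2"] = results["geo"]["eoo_km2"]
        if "aoo_km2" not in facts and "geo" in results:
            facts["aoo_km2"] = results["geo"]["aoo_km2"]
        if "n_mature" not in facts and "demography" in results:
            first_year = sorted(results["demography"]["census_totals"])[0]
            facts["n_mature"] = results["demography"]["census_totals"][first_year][
                "n_mature"
            ]
        if facts:
            inp = iucn.AssessmentInput(
                eoo_km2=facts.get("eoo_km2"),
                aoo_km2=facts.get("aoo_km2"),
                n_locations=facts.get("n_locations"),
                severely_fragmented=bool(facts.get("severely_fragmented", False)),
                continuing_decline=frozenset(facts.get("continuing_decline", ())),
                extreme_fluctuations=frozenset(
                    facts.get("extreme_fluctuations", ())
                ),
                n_mature=facts.get("n_mature"),
                extinction_probability=(
                    tuple(facts["extinction_probability"])
                    if facts.get("extinction_probability")
                    else None
                ),
            )
            res = iucn.assess(inp)
            doc = {
                "category": res.category,
                "codes": res.codes,
                "per_criterion": res.per_criterion,
            }
            results["assessment"] = doc
            _write_json(doc, out_dir / "assessment.json")
        else:
            logger.warning("assessment stage skipped: no facts available")
    except Exception as exc:  # noqa: BLE001
        raise StageError("assessment", exc) from exc

    # human-readable summary
    summary_lines = [f"pipeline seed {config.random_seed}"]
    for stage in ("geo", "demography", "popgen", "pva", "assessment"):
        summary_lines.append(
            f"{stage}: {'ok' if stage in results else 'skipped'}"
        )
    if "assessment" in results:
        summary_lines.append(
            "category: "
            + results["assessment"]["category"]
            + " "
            + " ".join(results["assessment"]["codes"])
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return results
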
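"""Bundled reference tables from the published monitoring of the Zakynthos
cliff endemic *Asperula naufraga*: five-year censuses per subpopulation,
per-year reproductive summaries of the tagged individuals, and subpopulation
coordinates with their occupied 1-km grid-cell counts."""

from importlib import resources

import pandas as pd

from ..datamodel import MonitoringRecord, OccurrencePoint

__all__ = [
    "load_monitoring",
    "load_reproduction_summary",
    "load_coordinates",
]


def _path(name: str):
    return resources.files(__package__) / name


def load_monitoring() -> list[MonitoringRecord]:
    """Subpopulation-year censuses (5 subpopulations × 5 years)."""
    from .. import io

    with resources.as_file(_path("monitoring.csv")) as p:
        return io.read_monitoring(p)


def load_reproduction_summary() -> pd.DataFrame:
    """Per-year reproductive summary statistics of the tagged individuals.

    Columns: St (flowering stems/individual), Fl (flowers/stem), fruit_set
    (fruits/flower), S (seeds/stem), Sa (adult survival), RRS (%), with
    standard errors.
    """
    with resources.as_file(_path("reproduction_summary.csv")) as p:
        return pd.read_csv(p)


def load_coordinates() -> tuple[list[OccurrencePoint], dict[str, int]]:
    """Subpopulation centre coordinates and occupied grid-cell counts."""
    with resources.as_file(_path("coordinates.csv")) as p:
        df = pd.read_csv(p)
    points = [
        OccurrencePoint(str(r["subpopulation"]), float(r["lon"]), float(r["lat"]))
        for _, r in df.iterrows()
    ]
    cells = {str(r["subpopulation"]): int(r["aoo_cells"]) for _, r in df.iterrows()}
    return points, cells
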
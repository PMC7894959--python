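"""IUCN Red List (v3.1) rule engine for criteria B, D and E.

Criterion B classifies restricted-range taxa: B1 from the extent of
occurrence (EOO) and B2 from the area of occupancy (AOO), each requiring at
least two of three supporting conditions — (a) severe fragmentation or few
locations, (b) continuing decline, (c) extreme fluctuations. Criterion D
uses the mature-individual count and criterion E a quantitative extinction
probability. Thresholds are strict ("less than"), so EOO = 100 km² does not
qualify as CR under B1. Conditions (a)–(c) are caller-supplied facts; a
helper flags extreme fluctuation from a census series under the
order-of-magnitude guidance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AssessmentInput",
    "AssessmentResult",
    "Category",
    "assess_criterion_b",
    "assess_criterion_d",
    "assess_criterion_e",
    "assess",
    "parse_criterion_code",
    "fluctuation_flag_from_census",
]

CATEGORIES = ["LC", "NT", "VU", "EN", "CR"]
SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}

DECLINE_FLAGS = ("i", "ii", "iii", "iv", "v")
FLUCTUATION_FLAGS = ("i", "ii", "iii", "iv")

# area thresholds (km²), most severe first
B1_EOO = [("CR", 100.0), ("EN", 5_000.0), ("VU", 20_000.0)]
B2_AOO = [("CR", 10.0), ("EN", 500.0), ("VU", 2_000.0)]
LOCATION_LIMIT = {"CR": 1, "EN": 5, "VU": 10}
D_THRESHOLDS = [("CR", 50), ("EN", 250), ("VU", 1_000)]


class Category(str):
    """A Red List category label; compare severity via SEVERITY."""


@dataclass
class AssessmentInput:
    """Quantitative facts feeding the rule engine."""

    eoo_km2: Optional[float] = None
    aoo_km2: Optional[float] = None
    n_locations: Optional[int] = None
    severely_fragmented: bool = False
    continuing_decline: frozenset = frozenset()
    extreme_fluctuations: frozenset = frozenset()
    n_mature: Optional[int] = None
    extinction_probability: Optional[tuple[float, Optional[float], Optional[float]]] = (
        None  # (probability, years, generations)
    )

    def __post_init__(self) -> None:
        self.continuing_decline = frozenset(self.continuing_decline)
        self.extreme_fluctuations = frozenset(self.extreme_fluctuations)
        bad = self.continuing_decline - set(DECLINE_FLAGS)
        if bad:
            raise ValueError(f"unknown continuing-decline flags: {sorted(bad)}")
        bad = self.extreme_fluctuations - set(FLUCTUATION_FLAGS)
        if bad:
            raise ValueError(f"unknown extreme-fluctuation flags: {sorted(bad)}")
        for name in ("eoo_km2", "aoo_km2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AssessmentResult:
    """Overall category with the coded criteria that triggered it."""

    category: str
    codes: list[str]
    per_criterion: dict[str, str] = field(default_factory=dict)

    def __str__(self) -> str:
        return f"{self.category} {' '.join(self.codes)}" if self.codes else self.category


def _flag_list(flags: frozenset, order: Sequence[str]) -> str:
    present = [f for f in order if f in flags]
    return ",".join(present)


def _conditions_met(inp: AssessmentInput, category: str) -> list[str]:
    """Which of conditions a/b/c hold at a given category's severity."""
    met = []
    loc_ok = (
        inp.n_locations is not None and inp.n_locations <= LOCATION_LIMIT[category]
    )
    if inp.severely_fragmented or loc_ok:
        met.append("a")
    if inp.continuing_decline:
        met.append("b")
    if inp.extreme_fluctuations:
        met.append("c")
    return met


def _b_code(sub: str, inp: AssessmentInput, conditions: list[str]) -> str:
    code = f"B{sub}"
    for cond in conditions:
        if cond == "a":
            code += "a"
        elif cond == "b":
            code += f"b({_flag_list(inp.continuing_decline, DECLINE_FLAGS)})"
        elif cond == "c":
            code += f"c({_flag_list(inp.extreme_fluctuations, FLUCTUATION_FLAGS)})"
    return code


def _near_threshold(area: float, vu_threshold: float) -> bool:
    return area < vu_threshold * 1.10


def assess_criterion_b(inp: AssessmentInput) -> dict[str, tuple[str, Optional[str]]]:
    """Evaluate B1 (EOO) and B2 (AOO).

    Returns ``{"B1": (category, code), "B2": (category, code)}``. A category
    requires the area threshold plus at least two of conditions a/b/c at
    that severity. NT is assigned heuristically when the area lies within
    10% of the VU threshold with the condition count met.
    """
    if inp.eoo_km2 is None and inp.aoo_km2 is None:
        raise ValueError("criterion B needs an EOO or AOO")
    out: dict[str, tuple[str, Optional[str]]] = {}
    for sub, area, table in (("1", inp.eoo_km2, B1_EOO), ("2", inp.aoo_km2, B2_AOO)):
        if area is None:
            continue
        category, code = "LC", None
        for cat, threshold in table:
            conditions = _conditions_met(inp, cat)
            if area < threshold and len(conditions) >= 2:
                category = cat
                code = _b_code(sub, inp, conditions)
                break
        if category == "LC":
            conditions = _conditions_met(inp, "VU")
            if len(conditions) >= 2 and _near_threshold(area, table[-1][1]):
                category = "NT"
                logger.info(
                    "B%s: NT heuristic (within 10%% of the VU threshold)", sub
                )
        out[f"B{sub}"] = (category, code)
    return out


def assess_criterion_d(n_mature: int) -> str:
    """Very-small-population criterion: CR < 50, EN < 250, VU < 1000."""
    if n_mature < 0:
        raise ValueError("n_mature must be >= 0")
    for cat, threshold in D_THRESHOLDS:
        if n_mature < threshold:
            return cat
    return "LC"


def assess_criterion_e(
    probability: float,
    years: Optional[float] = None,
    generations: Optional[float] = None,
) -> str:
    """Quantitative-analysis criterion from an extinction probability.

    CR: ≥50% within 10 years or 3 generations; EN: ≥20% within 20 years or
    5 generations; VU: ≥10% within 100 years.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    yr = years if years is not None else float("inf")
    gen = generations if generations is not None else float("inf")
    if probability >= 0.5 and (yr <= 10 or gen <= 3):
        return "CR"
    if probability >= 0.2 and (yr <= 20 or gen <= 5):
        return "EN"
    if probability >= 0.1 and yr <= 100:
        return "VU"
    return "LC"


def assess(inp: AssessmentInput) -> AssessmentResult:
    """Evaluate every criterion with available inputs; report the most severe."""
    per: dict[str, str] = {}
    codes: list[str] = []
    evaluated = False
    if inp.eoo_km2 is not None or inp.aoo_km2 is not None:
        b = assess_criterion_b(inp)
        evaluated = True
        for name, (cat, code) in b.items():
            per[name] = cat
        worst_b = max((cat for cat, _ in b.values()), key=SEVERITY.get, default="LC")
        for _, (cat, code) in sorted(b.items()):
            if code and cat == worst_b and SEVERITY[cat] >= SEVERITY["VU"]:
                codes.append(code)
    if inp.n_mature is not None:
        per["D"] = assess_criterion_d(inp.n_mature)
        evaluated = True
        if SEVERITY[per["D"]] >= SEVERITY["VU"]:
            codes.append("D")
    if inp.extinction_probability is not None:
        p, yr, gen = inp.extinction_probability
        per["E"] = assess_criterion_e(p, yr, gen)
        evaluated = True
        if SEVERITY[per["E"]] >= SEVERITY["VU"]:
            codes.append("E")
    if not evaluated:
        raise ValueError("no criterion evaluable from the provided inputs")
    overall = max(per.values(), key=SEVERITY.get)
    # only codes of criteria reaching the overall category are listed
    final_codes = []
    for code in codes:
        crit = "B1" if code.startswith("B1") else (
            "B2" if code.startswith("B2") else code[0]
        )
        if per.get(crit) == overall:
            final_codes.append(code)
    return AssessmentResult(category=overall, codes=final_codes, per_criterion=per)


_CODE_RE = re.compile(
    r"^B(?P<sub>[12])(?P<a>a)?(?:b\((?P<b>[ivx,]*)\))?(?:c\((?P<c>[ivx,]*)\))?$"
)


def parse_criterion_code(code: str) -> dict:
    """Parse a B-criterion code back into its condition flag sets."""
    m = _CODE_RE.match(code)
    if not m:
        raise ValueError(f"unparseable criterion code: {code!r}")
    return {
        "sub": m.group("sub"),
        "a": m.group("a") is not None,
        "decline": frozenset(filter(None, (m.group("b") or "").split(","))),
        "fluctuations": frozenset(filter(None, (m.group("c") or "").split(","))),
    }


def fluctuation_flag_from_census(
    census: Sequence[float], ratio_threshold: float = 10.0
) -> bool:
    """Flag extreme fluctuation when max/min census ratio ≥ one magnitude.

    IUCN guidance reserves "extreme fluctuations" for roughly order-of-
    magnitude swings; assessors sometimes assert the condition on smaller
    ratios, so this helper is advisory and the engine accepts the caller's
    flag either way.
    """
    vals = [v for v in census if v > 0]
    if not vals:
        return True
    ratio = max(vals) / min(vals)
    if ratio < ratio_threshold:
        logger.warning(
            "census ratio %.2f below the %.0fx fluctuation guidance", ratio,
            ratio_threshold,
        )
    return ratio >= ratio_threshold
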
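"""Sex- and age-stratified disproportionality and relative RORs.

For each preferred term with enough reports in both strata, the ratio of
stratum RORs (the relative ROR) is computed with a combined Woolf CI:

    exp( ln(ROR1/ROR2) ± z * sqrt( V1 + V2 ) ),   Vk = 1/a + 1/b + 1/c + 1/d

over the two stratum 2x2 tables.  A term is classified as more likely to
be reported in a stratum when that stratum's own ROR CI lower bound
exceeds 1 *and* the relative-ROR CI lower bound (oriented toward that
stratum) exceeds 1 — a dual criterion, with no interaction p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .bundle import ReportBundle
from .disproportionality import SignalResult, _zvalue, ror
from .preprocessing import CASE, NON_CASE, build_all_contingencies

STRATUM1_HIGHER = "stratum1_higher"
STRATUM2_HIGHER = "stratum2_higher"
NO_DIFFERENCE = "no_difference"
NOT_EVALUABLE = "not_evaluable"

#: days per unit when converting reported age to years
_AGE_UNIT_PER_YEAR = {
    "YR": 1.0, "DEC": 0.1, "MON": 12.0, "WK": 52.14, "DY": 365.25, "HR": 8766.0,
}


@dataclass(frozen=True)
class StratifiedComparison:
    """Paired stratum RORs for one PT with the relative ROR and its verdict."""

    pt: str
    stratum1: str
    stratum2: str
    result1: SignalResult | None
    result2: SignalResult | None
    rel_ror: float
    rel_ci_low: float
    rel_ci_high: float
    classification: str
    exclusive_stratum: str | None = None  # signal in exactly one stratum's own ROR


def age_in_years(age: object, age_unit: object) -> float | None:
    """Convert a reported (age, unit) pair to years; unknown units are missing."""
    try:
        value = float(str(age).strip())
    except (TypeError, ValueError):
        return None
    unit = str(age_unit).strip().upper() or "YR"
    per_year = _AGE_UNIT_PER_YEAR.get(unit)
    if per_year is None:
        return None
    return value / per_year


def stratify(
    bundle: ReportBundle,
    flags: pd.Series,
    variable: str,
    age_years_only: bool = True,
) -> dict[str, pd.Series]:
    """Partition case/non-case flags into two strata of ``variable``.

    ``sex``: F vs M, missing excluded.  ``age_group``: adults (18-64)
    vs older adults (>= 65); with ``age_years_only`` (the default) only
    reports whose age was recorded in years enter the age strata.
    Reports outside both strata are dropped from the stratified analysis
    only — the main analysis is untouched.
    """
    demo = bundle.demo.set_index("primaryid")
    if variable == "sex":
        sex = demo["sex"].astype(str).str.strip().str.upper()
        masks = {"female": sex == "F", "male": sex == "M"}
    elif variable == "age_group":
        if age_years_only:
            unit = demo["age_unit"].astype(str).str.strip().str.upper()
            years = demo.apply(
                lambda r: age_in_years(r["age"], r["age_unit"]), axis=1
            ).where(unit == "YR")
        else:
            years = demo.apply(lambda r: age_in_years(r["age"], r["age_unit"]), axis=1)
        masks = {
            "adults": (years >= 18) & (years <= 64),
            "older_adults": years >= 65,
        }
    else:
        raise ValueError(f"unknown stratification variable {variable!r}")

    out: dict[str, pd.Series] = {}
    for label, mask in masks.items():
        stratum_pids = set(mask.index[mask.fillna(False)])
        sub = flags.copy()
        keep = sub.index.isin(stratum_pids)
        sub = sub[keep]
        out[label] = sub[sub.isin([CASE, NON_CASE])]
    return out


def relative_ror(
    r1: SignalResult,
    r2: SignalResult,
    ci_level: float = 0.95,
    stratum1: str = "stratum1",
    stratum2: str = "stratum2",
    min_reports: int = 5,
) -> StratifiedComparison:
    """Relative ROR (stratum1 / stratum2) with the combined-variance CI.

    Computed from the unrounded stratum RORs.  Either stratum below the
    report floor, or any zero cell, makes the comparison not evaluable.
    """
    pt = r1.pt or r2.pt
    if (r1.a < min_reports or r2.a < min_reports
            or not r1.estimable or not r2.estimable):
        return StratifiedComparison(pt, stratum1, stratum2, r1, r2,
                                    float("nan"), float("nan"), float("nan"),
                                    NOT_EVALUABLE)
    rel = r1.ror / r2.ror
    var = sum(1 / x for x in (r1.a, r1.b, r1.c, r1.d)) + \
        sum(1 / x for x in (r2.a, r2.b, r2.c, r2.d))
    half = _zvalue(ci_level) * math.sqrt(var)
    lo, hi = math.exp(math.log(rel) - half), math.exp(math.log(rel) + half)

    sig1 = r1.ci_low > 1.0
    sig2 = r2.ci_low > 1.0
    if sig1 and lo > 1.0:
        cls = STRATUM1_HIGHER
    elif sig2 and (1.0 / hi) > 1.0:  # relative ROR oriented toward stratum2
        cls = STRATUM2_HIGHER
    else:
        cls = NO_DIFFERENCE
    exclusive = None
    if sig1 != sig2:
        exclusive = stratum1 if sig1 else stratum2
    return StratifiedComparison(pt, stratum1, stratum2, r1, r2, rel, lo, hi, cls,
                                exclusive_stratum=exclusive)


def classify_all(
    bundle: ReportBundle,
    flags: pd.Series,
    variable: str,
    ci_level: float = 0.95,
    min_reports: int = 5,
    age_years_only: bool = True,
) -> list[StratifiedComparison]:
    """Stratified comparison for every PT meeting the report floor in both strata."""
    strata = stratify(bundle, flags, variable, age_years_only=age_years_only)
    (label1, flags1), (label2, flags2) = strata.items()
    if variable == "age_group":
        # convention: report the older stratum first, mirroring the field's tables
        (label1, flags1), (label2, flags2) = (("older_adults", strata["older_adults"]),
                                              ("adults", strata["adults"]))
    tables1 = {t.pt.casefold(): t for t in build_all_contingencies(bundle, flags1)}
    tables2 = {t.pt.casefold(): t for t in build_all_contingencies(bundle, flags2)}
    out = []
    for key in sorted(set(tables1) & set(tables2)):
        t1, t2 = tables1[key], tables2[key]
        if t1.a < min_reports or t2.a < min_reports:
            continue
        cmp = relative_ror(ror(t1, ci_level), ror(t2, ci_level), ci_level,
                           stratum1=label1, stratum2=label2, min_reports=min_reports)
        out.append(cmp)
    return out


def comparisons_to_frame(comparisons: list[StratifiedComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "pt": c.pt,
            "stratum1": c.stratum1, "stratum2": c.stratum2,
            "n1": c.result1.a if c.result1 else 0,
            "n2": c.result2.a if c.result2 else 0,
            "ror1": c.result1.ror if c.result1 else float("nan"),
            "ror1_ci_low": c.result1.ci_low if c.result1 else float("nan"),
            "ror1_ci_high": c.result1.ci_high if c.result1 else float("nan"),
            "ror2": c.result2.ror if c.result2 else float("nan"),
            "ror2_ci_low": c.result2.ci_low if c.result2 else float("nan"),
            "ror2_ci_high": c.result2.ci_high if c.result2 else float("nan"),
            "rel_ror": c.rel_ror,
            "rel_ci_low": c.rel_ci_low, "rel_ci_high": c.rel_ci_high,
            "classification": c.classification,
            "exclusive_stratum": c.exclusive_stratum or "",
        })
    return pd.DataFrame(rows)


def forest_plot_data(comparisons: list[StratifiedComparison]) -> pd.DataFrame:
    """Per-PT relative ROR and CI for forest plotting, differences only."""
    keep = [c for c in comparisons
            if c.classification in (STRATUM1_HIGHER, STRATUM2_HIGHER)]
    return pd.DataFrame({
        "pt": [c.pt for c in keep],
        "rel_ror": [c.rel_ror for c in keep],
        "ci_low": [c.rel_ci_low for c in keep],
        "ci_high": [c.rel_ci_high for c in keep],
        "direction": [c.classification for c in keep],
    })
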
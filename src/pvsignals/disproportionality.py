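"""Disproportionality measures for case/non-case signal screening.

The reporting odds ratio (ROR) compares the odds of a given adverse
event among reports of the target drug with the same odds among all
other reports:

    ROR = (a/c) / (b/d) = ad / bc

with the 95% CI from Woolf's log-variance,

    exp( ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d) ).

A preferred term is screened as a signal when it has at least
``min_reports`` case reports and the CI lower bound exceeds 1 (strict).
No continuity correction is applied to zero cells — the report floor
already suppresses the unstable tables — and results with a zero cell
are carried with a ``non-estimable`` flag rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .bundle import ReportBundle
from .preprocessing import (
    CASE, CaseDefinition, ContingencyTable, build_all_contingencies, flag_cases,
)


@dataclass(frozen=True)
class SignalResult:
    """One PT's disproportionality estimate and screening verdict."""

    pt: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    measure: str = "ROR"
    estimable: bool = True

    @property
    def n_reports(self) -> int:
        return self.a

    def is_signal(self, min_reports: int = 5) -> bool:
        return self.estimable and self.a >= min_reports and self.ci_low > 1.0


def _zvalue(ci_level: float) -> float:
    """Normal critical value, rounded to two decimals (1.96 at the 95% level) —
    the convention of published disproportionality tables."""
    return round(float(stats.norm.ppf(0.5 + ci_level / 2.0)), 2)


def ror(table: ContingencyTable, ci_level: float = 0.95) -> SignalResult:
    """Reporting odds ratio with Woolf confidence interval.

    With a zero cell the result is flagged non-estimable: the point
    estimate is 0 when a=0, NaN when only c=0, and the CI is undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        point = 0.0 if a == 0 and min(b, c) > 0 else float("nan")
        return SignalResult(table.pt, a, b, c, d, point, float("nan"), float("nan"),
                            ci_level, "ROR", estimable=False)
    estimate = (a * d) / (b * c)
    z = _zvalue(ci_level)
    half = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(estimate)
    return SignalResult(
        table.pt, a, b, c, d, estimate,
        math.exp(log_ror - half), math.exp(log_ror + half), ci_level, "ROR",
    )


def prr(table: ContingencyTable) -> SignalResult:
    """Proportional reporting ratio: [a/(a+b)] / [c/(c+d)].

    Used as the building block of the combination risk ratio; no CI is
    attached.  c = 0 (or an empty margin) is non-estimable; a = 0 gives
    a well-defined PRR of 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or c == 0:
        return SignalResult(table.pt, a, b, c, d, float("nan"), float("nan"),
                            float("nan"), measure="PRR", estimable=False)
    estimate = (a / (a + b)) / (c / (c + d))
    return SignalResult(table.pt, a, b, c, d, estimate, float("nan"), float("nan"),
                        measure="PRR")


def screen_signals(
    tables: list[ContingencyTable],
    min_reports: int = 5,
    ci_level: float = 0.95,
) -> list[SignalResult]:
    """ROR screening over per-PT tables, keeping PTs at or above the report floor.

    Returns one result per retained PT, sorted by ROR descending
    (non-estimable last, then by PT for a stable order).
    """
    results = [ror(t, ci_level) for t in tables if t.a >= min_reports]
    return sorted(
        results,
        key=lambda r: (-(r.ror if r.estimable else -math.inf), r.pt),
    )


def comparator_analysis(
    bundle: ReportBundle,
    target: CaseDefinition,
    comparator_ingredient: str,
    min_reports: int = 5,
    ci_level: float = 0.95,
    keep_coexposed_as_cases: bool = True,
) -> list[SignalResult]:
    """Sensitivity screening against an active comparator drug.

    The non-case population is restricted to reports carrying the
    comparator (same eligible roles) without the target; reports
    co-exposed to both count as cases by default.
    """
    comp = comparator_ingredient.strip().casefold()
    drug = bundle.drug
    ing = drug["ingredient"].astype(str).str.strip().str.casefold()
    comp_rows = (ing == comp) & drug["role_code"].isin(target.eligible_roles)
    comp_pids = set(drug.loc[comp_rows, "primaryid"])
    if not comp_pids:
        raise ValueError(
            f"comparator ingredient {comparator_ingredient!r} yields an empty population"
        )

    flags = flag_cases(bundle, target)
    case_pids = set(flags.index[flags == CASE])
    if not keep_coexposed_as_cases:
        case_pids -= comp_pids
    noncase_pids = comp_pids - set(
        drug.loc[ing == target.target_ingredient.strip().casefold(), "primaryid"]
    )
    if not noncase_pids:
        raise ValueError(
            f"comparator population for {comparator_ingredient!r} is empty after "
            "removing target co-reports"
        )
    restricted = flags.copy()
    restricted[:] = "other"
    restricted.loc[restricted.index.isin(case_pids)] = CASE
    restricted.loc[restricted.index.isin(noncase_pids)] = "non_case"
    tables = build_all_contingencies(bundle, restricted)
    return screen_signals(tables, min_reports=min_reports, ci_level=ci_level)


def signals_to_frame(results: list[SignalResult], min_reports: int = 5) -> pd.DataFrame:
    """Tabular view of screening results (one row per PT)."""
    return pd.DataFrame(
        {
            "pt": [r.pt for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "ror": [r.ror for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "is_signal": [r.is_signal(min_reports) for r in results],
        }
    )
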
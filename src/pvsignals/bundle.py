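"""Core data model for spontaneous-report bundles.

A :class:`ReportBundle` holds the six linked tables of a FAERS-style
quarterly extract (demographics, drugs, reactions, outcomes, therapy
dates, indications) plus the deleted-case list.  The unit of analysis
throughout the package is one report, keyed by ``primaryid``; a patient
case is keyed by ``caseid`` and may be represented by several report
versions before deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

#: canonical column sets, in canonical order
DEMO_COLUMNS = [
    "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_unit",
    "weight", "country_code", "reporter_qualification", "report_year",
]
DRUG_COLUMNS = ["primaryid", "drug_seq", "role_code", "drug_name", "ingredient"]
REAC_COLUMNS = ["primaryid", "pt"]
OUTC_COLUMNS = ["primaryid", "outcome_code"]
THER_COLUMNS = ["primaryid", "drug_seq", "start_dt", "end_dt"]
INDI_COLUMNS = ["primaryid", "drug_seq", "indication_pt"]

ROLE_CODES = frozenset({"PS", "SS", "I", "C"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


@dataclass(frozen=True)
class PartialDate:
    """A date known to year, month, or day precision (or not at all).

    FAERS dates are 4-, 6-, or 8-digit strings; missing trailing
    components are simply absent, so a date can be partially known.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        if self.year is not None:
            return "year"
        return "missing"

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day requires month")
        if self.month is not None and self.year is None:
            raise ValueError("month requires year")


_DAYS_IN_MONTH = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def parse_partial_date(raw: object) -> PartialDate:
    """Parse a FAERS date string into a :class:`PartialDate`.

    Total function: any input maps to exactly one PartialDate; anything
    that is not a 4/6/8-digit string with in-range components yields the
    fully-missing date.  February is accepted up to day 29 without a
    leap-year check, matching how permissively these fields are filled
    upstream.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return PartialDate()
    s = str(raw).strip()
    if s.endswith(".0"):  # numeric passthrough from CSV readers
        s = s[:-2]
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return PartialDate()
    year = int(s[:4])
    if not (1900 <= year <= 2100):
        return PartialDate()
    if len(s) == 4:
        return PartialDate(year=year)
    month = int(s[4:6])
    if not (1 <= month <= 12):
        return PartialDate()
    if len(s) == 6:
        return PartialDate(year=year, month=month)
    day = int(s[6:8])
    if not (1 <= day <= _DAYS_IN_MONTH[month - 1]):
        return PartialDate()
    return PartialDate(year=year, month=month, day=day)


@dataclass(frozen=True)
class IngredientDictionary:
    """Brand/verbatim drug name → active ingredient lookup.

    Keys are case-folded and stripped before matching, mirroring how
    verbatim FAERS drug names are recorded.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for raw, ing in self.mapping.items():
            key = raw.strip().casefold()
            if not key:
                continue
            if not str(ing).strip():
                raise ValueError(f"empty ingredient for name {raw!r}")
            folded[key] = str(ing).strip()
        object.__setattr__(self, "mapping", folded)

    def lookup(self, raw_name: object) -> str | None:
        if raw_name is None:
            return None
        return self.mapping.get(str(raw_name).strip().casefold())

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class ReportBundle:
    """The six linked report tables plus the deleted-case list."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    deleted: list[str] = field(default_factory=list)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def primaryids(self) -> pd.Series:
        return self.demo["primaryid"]

    def filter_primaryids(self, keep: Iterable[str]) -> "ReportBundle":
        """Return a bundle restricted to the given primaryids (all six tables)."""
        keep_set = set(keep)
        return ReportBundle(
            demo=self.demo[self.demo["primaryid"].isin(keep_set)].reset_index(drop=True),
            drug=self.drug[self.drug["primaryid"].isin(keep_set)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(keep_set)].reset_index(drop=True),
            outc=self.outc[self.outc["primaryid"].isin(keep_set)].reset_index(drop=True),
            ther=self.ther[self.ther["primaryid"].isin(keep_set)].reset_index(drop=True),
            indi=self.indi[self.indi["primaryid"].isin(keep_set)].reset_index(drop=True),
            deleted=list(self.deleted),
        )

    def copy(self) -> "ReportBundle":
        return ReportBundle(
            demo=self.demo.copy(), drug=self.drug.copy(), reac=self.reac.copy(),
            outc=self.outc.copy(), ther=self.ther.copy(), indi=self.indi.copy(),
            deleted=list(self.deleted),
        )

    def validate(self) -> None:
        """Assert referential integrity and vocabulary restrictions."""
        for name, cols in (("demo", DEMO_COLUMNS), ("drug", DRUG_COLUMNS),
                           ("reac", REAC_COLUMNS), ("outc", OUTC_COLUMNS),
                           ("ther", THER_COLUMNS), ("indi", INDI_COLUMNS)):
            table = getattr(self, name)
            missing = [c for c in cols if c not in table.columns]
            if missing:
                raise ValueError(f"{name} table missing columns {missing}")
        if self.demo["primaryid"].duplicated().any():
            raise ValueError("duplicate primaryid in demo")
        pids = set(self.demo["primaryid"])
        for name in ("drug", "reac", "outc", "ther", "indi"):
            table = getattr(self, name)
            if not table["primaryid"].isin(pids).all():
                raise ValueError(f"{name} references primaryid absent from demo")
        drug_keys = set(zip(self.drug["primaryid"], self.drug["drug_seq"]))
        for name in ("ther", "indi"):
            table = getattr(self, name)
            keys = set(zip(table["primaryid"], table["drug_seq"]))
            if not keys <= drug_keys:
                raise ValueError(f"{name} references (primaryid, drug_seq) absent from drug")
        bad_roles = set(self.drug["role_code"]) - ROLE_CODES
        if bad_roles:
            raise ValueError(f"unknown role codes {sorted(bad_roles)}")
        bad_outc = set(self.outc["outcome_code"]) - OUTCOME_CODES
        if bad_outc:
            raise ValueError(f"unknown outcome codes {sorted(bad_outc)}")
        if (self.reac["pt"].astype(str).str.strip() == "").any():
            raise ValueError("empty PT string in reac")

    def equals(self, other: "ReportBundle") -> bool:
        """Field-level equality after canonical sorting (order-insensitive)."""

        def canon(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
            out = df[cols].astype(str)
            return out.sort_values(cols).reset_index(drop=True)

        pairs = (
            (self.demo, other.demo, DEMO_COLUMNS),
            (self.drug, other.drug, DRUG_COLUMNS),
            (self.reac, other.reac, REAC_COLUMNS),
            (self.outc, other.outc, OUTC_COLUMNS),
            (self.ther, other.ther, THER_COLUMNS),
            (self.indi, other.indi, INDI_COLUMNS),
        )
        if sorted(map(str, self.deleted)) != sorted(map(str, other.deleted)):
            return False
        return all(canon(a, c).equals(canon(b, c)) for a, b, c in pairs)


def empty_bundle() -> ReportBundle:
    """A bundle with all six tables present but empty."""
    return ReportBundle(
        demo=pd.DataFrame(columns=DEMO_COLUMNS),
        drug=pd.DataFrame(columns=DRUG_COLUMNS),
        reac=pd.DataFrame(columns=REAC_COLUMNS),
        outc=pd.DataFrame(columns=OUTC_COLUMNS),
        ther=pd.DataFrame(columns=THER_COLUMNS),
        indi=pd.DataFrame(columns=INDI_COLUMNS),
        deleted=[],
    )
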
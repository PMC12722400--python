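"""Report cleaning and case/non-case definition.

Spontaneous-report databases carry two kinds of duplicates: multiple
versions of the same case (same ``caseid``, successive ``primaryid``
submissions) and distinct cases that are evidently the same patient
event reported twice.  Cleaning order is: keep the latest version per
caseid, remove cases from the deleted-case lists, then collapse
field-match duplicates.  Removing deleted cases before the field-match
step avoids a deleted report surviving as the tiebreak winner of a
duplicate group.

The case/non-case design then partitions the cleaned reports: a report
is a *case* when the target drug appears in an eligible suspect role and
none of its indications matches the exclusion lists; reports mentioning
the target drug in any other way are excluded from the analysis
entirely; everything else is a *non-case*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import ReportBundle
from .faers_io import RunLog

#: flag values
CASE = "case"
NON_CASE = "non_case"
EXCLUDED = "excluded"

DEFAULT_INDICATION_KEYWORDS = frozenset(
    {"anaesthesia", "anesthesia", "sedation", "pain", "analgesia", "anaesthetic"}
)


@dataclass(frozen=True)
class CaseDefinition:
    """What makes a report a case for the target drug."""

    target_ingredient: str
    eligible_roles: frozenset[str] = frozenset({"PS", "SS"})
    excluded_indication_pts: frozenset[str] = frozenset()
    excluded_indication_keywords: frozenset[str] = DEFAULT_INDICATION_KEYWORDS

    def __post_init__(self) -> None:
        if not self.target_ingredient.strip():
            raise ValueError("target_ingredient must be non-empty")
        if not self.eligible_roles:
            raise ValueError("eligible_roles must be non-empty")
        object.__setattr__(self, "eligible_roles", frozenset(self.eligible_roles))
        object.__setattr__(
            self, "excluded_indication_pts",
            frozenset(s.strip().casefold() for s in self.excluded_indication_pts),
        )
        object.__setattr__(
            self, "excluded_indication_keywords",
            frozenset(s.strip().casefold() for s in self.excluded_indication_keywords),
        )


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case 2x2 counts for one preferred term.

    a: cases with the PT; b: cases without it; c: non-cases with the PT;
    d: non-cases without it.
    """

    a: int
    b: int
    c: int
    d: int
    pt: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_noncases(self) -> int:
        return self.c + self.d


def dedup_caseid(bundle: ReportBundle, log: RunLog | None = None) -> ReportBundle:
    """Keep one report per caseid: latest fda_dt, ties broken by highest primaryid."""
    log = log if log is not None else RunLog()
    demo = bundle.demo
    if demo.empty:
        return bundle.copy()
    fda = pd.to_numeric(demo["fda_dt"], errors="coerce").fillna(-1)
    pid = pd.to_numeric(demo["primaryid"], errors="coerce")
    # non-numeric primaryids sort lexicographically after numeric ones
    order = pd.DataFrame({
        "caseid": demo["caseid"], "fda": fda,
        "pid_num": pid.fillna(-np.inf), "pid_str": demo["primaryid"].astype(str),
    }, index=demo.index)
    order = order.sort_values(["caseid", "fda", "pid_num", "pid_str"])
    keep_idx = order.groupby("caseid", sort=False).tail(1).index
    removed = len(demo) - len(keep_idx)
    log.bump("caseid_duplicates_removed", removed)
    return bundle.filter_primaryids(demo.loc[keep_idx, "primaryid"])


def remove_deleted(bundle: ReportBundle, deleted: list[str] | None = None,
                   log: RunLog | None = None) -> ReportBundle:
    """Drop reports whose caseid appears in the deleted-case lists."""
    log = log if log is not None else RunLog()
    deleted_set = set(map(str, deleted if deleted is not None else bundle.deleted))
    if not deleted_set:
        return bundle.copy()
    keep = ~bundle.demo["caseid"].astype(str).isin(deleted_set)
    log.bump("deleted_cases_removed", int((~keep).sum()))
    return bundle.filter_primaryids(bundle.demo.loc[keep, "primaryid"])


def _sorted_join(series: pd.Series, pids: pd.Series) -> pd.Series:
    """Per-report sorted tuple of values, aligned to the demo primaryid order."""
    grouped = series.astype(str).groupby(series.index).agg(lambda v: "|".join(sorted(v)))
    return pids.map(grouped).fillna("")


def fieldmatch_key(bundle: ReportBundle) -> pd.Series:
    """The 7-field duplicate key: sex, age, country, event date, PT set,
    ingredient set, indication set.  Missing values are a distinct value that
    matches other missing values; dates match at their stored precision."""
    demo = bundle.demo
    pids = demo["primaryid"]

    def agg(table: pd.DataFrame, col: str) -> pd.Series:
        s = table.set_index("primaryid")[col]
        s = s.astype(str).str.strip().str.casefold()
        return _sorted_join(s, pids)

    key = (
        demo["sex"].astype(str).str.strip().str.upper().replace("", "<NA>") + "\x1f"
        + demo["age"].astype(str).str.strip().replace("", "<NA>") + "\x1f"
        + demo["country_code"].astype(str).str.strip().str.upper().replace("", "<NA>") + "\x1f"
        + demo["event_dt"].astype(str).str.strip().replace("", "<NA>") + "\x1f"
        + agg(bundle.reac, "pt") + "\x1f"
        + agg(bundle.drug, "ingredient") + "\x1f"
        + agg(bundle.indi, "indication_pt")
    )
    key.index = demo.index
    return key


def dedup_fieldmatch(bundle: ReportBundle, log: RunLog | None = None) -> ReportBundle:
    """Collapse reports identical on the 7-field key, keeping the highest primaryid."""
    log = log if log is not None else RunLog()
    demo = bundle.demo
    if demo.empty:
        return bundle.copy()
    key = fieldmatch_key(bundle)
    pid_num = pd.to_numeric(demo["primaryid"], errors="coerce").fillna(-np.inf)
    order = pd.DataFrame({
        "key": key, "pid_num": pid_num, "pid_str": demo["primaryid"].astype(str)
    }, index=demo.index).sort_values(["key", "pid_num", "pid_str"])
    keep_idx = order.groupby("key", sort=False).tail(1).index
    log.bump("fieldmatch_duplicates_removed", len(demo) - len(keep_idx))
    return bundle.filter_primaryids(demo.loc[keep_idx, "primaryid"])


def clean(bundle: ReportBundle, log: RunLog | None = None) -> ReportBundle:
    """Full cleaning sequence: caseid dedup, deleted-case removal, field-match dedup."""
    log = log if log is not None else RunLog()
    out = dedup_caseid(bundle, log)
    out = remove_deleted(out, log=log)
    out = dedup_fieldmatch(out, log)
    return out


def flag_cases(bundle: ReportBundle, cd: CaseDefinition,
               log: RunLog | None = None) -> pd.Series:
    """Three-way report flags: case / excluded / non_case, indexed by primaryid.

    A report is a case when the target ingredient appears with an eligible
    role and no indication attached to a target-drug entry matches the
    exclusion lists (exact PT match or case-insensitive keyword substring).
    Reports carrying the target only in ineligible roles, or with an
    excluded indication, are flagged ``excluded`` and take no part in the
    case/non-case comparison.  All remaining reports are non-cases.
    """
    log = log if log is not None else RunLog()
    target = cd.target_ingredient.strip().casefold()
    drug = bundle.drug
    ing = drug["ingredient"].astype(str).str.strip().str.casefold()
    is_target = ing == target
    if not is_target.any():
        log.bump("target_ingredient_absent")
    eligible = is_target & drug["role_code"].isin(cd.eligible_roles)

    target_pids = set(drug.loc[is_target, "primaryid"])
    eligible_pids = set(drug.loc[eligible, "primaryid"])

    # indications attached to target-drug entries
    tkeys = set(zip(drug.loc[is_target, "primaryid"], drug.loc[is_target, "drug_seq"]))
    indi = bundle.indi
    attached = [k in tkeys for k in zip(indi["primaryid"], indi["drug_seq"])]
    tindi = indi[pd.Series(attached, index=indi.index)] if len(indi) else indi
    ipt = tindi["indication_pt"].astype(str).str.strip().str.casefold()
    bad_exact = ipt.isin(cd.excluded_indication_pts)
    bad_kw = pd.Series(False, index=ipt.index)
    for kw in cd.excluded_indication_keywords:
        bad_kw |= ipt.str.contains(kw, regex=False)
    bad_pids = set(tindi.loc[bad_exact | bad_kw, "primaryid"])

    flags = pd.Series(NON_CASE, index=bundle.demo["primaryid"].values, name="flag")
    flags.loc[flags.index.isin(target_pids)] = EXCLUDED
    case_pids = (eligible_pids - bad_pids)
    flags.loc[flags.index.isin(case_pids)] = CASE

    log.bump("reports_flagged_case", int((flags == CASE).sum()))
    log.bump("reports_flagged_excluded", int((flags == EXCLUDED).sum()))
    log.bump("reports_excluded_role_only",
             len(target_pids - eligible_pids - bad_pids))
    log.bump("reports_excluded_indication", len(bad_pids & eligible_pids))
    return flags


def pt_membership(bundle: ReportBundle, flags: pd.Series) -> pd.DataFrame:
    """Distinct (primaryid, pt_casefolded) pairs restricted to case/non-case reports."""
    reac = bundle.reac.copy()
    reac["pt_key"] = reac["pt"].astype(str).str.strip().str.casefold()
    reac = reac[["primaryid", "pt_key"]].drop_duplicates()
    status = flags.reindex(reac["primaryid"]).values
    reac["flag"] = status
    return reac[reac["flag"].isin([CASE, NON_CASE])]


def build_contingency(bundle: ReportBundle, flags: pd.Series, pt: str) -> ContingencyTable:
    """2x2 for one PT: report-level counts, duplicate PT listings count once."""
    n_cases = int((flags == CASE).sum())
    n_noncases = int((flags == NON_CASE).sum())
    mem = pt_membership(bundle, flags)
    key = pt.strip().casefold()
    hit = mem[mem["pt_key"] == key]
    a = int((hit["flag"] == CASE).sum())
    c = int((hit["flag"] == NON_CASE).sum())
    return ContingencyTable(a=a, b=n_cases - a, c=c, d=n_noncases - c, pt=pt.strip())


def build_all_contingencies(bundle: ReportBundle, flags: pd.Series,
                            min_case_reports: int = 1) -> list[ContingencyTable]:
    """One 2x2 per PT observed among cases (at least ``min_case_reports`` case reports)."""
    n_cases = int((flags == CASE).sum())
    n_noncases = int((flags == NON_CASE).sum())
    mem = pt_membership(bundle, flags)
    counts = mem.groupby("pt_key")["flag"].value_counts().unstack(fill_value=0)
    for col in (CASE, NON_CASE):
        if col not in counts.columns:
            counts[col] = 0
    # preserve one representative original spelling per key
    spelling = (
        bundle.reac.assign(pt_key=bundle.reac["pt"].astype(str).str.strip().str.casefold())
        .groupby("pt_key")["pt"].first()
    )
    out = []
    for pt_key, row in counts.iterrows():
        a = int(row[CASE])
        if a < min_case_reports:
            continue
        c = int(row[NON_CASE])
        out.append(ContingencyTable(
            a=a, b=n_cases - a, c=c, d=n_noncases - c,
            pt=str(spelling.get(pt_key, pt_key)).strip(),
        ))
    return out
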
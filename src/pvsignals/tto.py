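"""Time-to-onset and seriousness analyses.

Time-to-onset (TTO) is the number of days from the start of therapy with
the target drug to the onset of the event.  Only day-precision dates can
yield a defined difference, so partial dates are counted as unavailable;
negative differences indicate data errors and are excluded with a
counter.  Seriousness follows the regulatory definition: a report is
serious when it carries at least one outcome code among death (DE),
life-threatening (LT), hospitalization (HO), disability (DS), congenital
anomaly (CA), required intervention (RI) or other serious outcome (OT).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import OUTCOME_CODES, PartialDate, ReportBundle, parse_partial_date
from .faers_io import RunLog
from .preprocessing import CASE


@dataclass(frozen=True)
class TTORecord:
    primaryid: str
    start_date: PartialDate
    event_date: PartialDate
    tto_days: int | None


@dataclass(frozen=True)
class SeriousnessLabel:
    primaryid: str
    serious: bool
    outcome_codes: frozenset[str]


def _to_date(p: PartialDate) -> dt.date | None:
    if p.precision != "day":
        return None
    try:
        return dt.date(p.year, p.month, p.day)
    except ValueError:
        return None


def compute_tto(
    bundle: ReportBundle,
    flags: pd.Series,
    target_ingredient: str,
    log: RunLog | None = None,
) -> list[TTORecord]:
    """One TTO record per case report; days defined only for day-precision dates.

    The therapy start is the earliest day-precision start date among the
    target drug's therapy rows; the event date comes from demographics.
    Same-day onset is 0 days; negative differences are excluded and
    counted.
    """
    log = log if log is not None else RunLog()
    target = target_ingredient.strip().casefold()
    drug = bundle.drug
    is_target = drug["ingredient"].astype(str).str.strip().str.casefold() == target
    tkeys = set(zip(drug.loc[is_target, "primaryid"], drug.loc[is_target, "drug_seq"]))

    ther = bundle.ther
    linked = [k in tkeys for k in zip(ther["primaryid"], ther["drug_seq"])]
    tther = ther[pd.Series(linked, index=ther.index)] if len(ther) else ther

    starts: dict[str, PartialDate] = {}
    for pid, raw in zip(tther["primaryid"], tther["start_dt"]):
        p = parse_partial_date(raw)
        d = _to_date(p)
        if d is None:
            continue
        prev = starts.get(pid)
        if prev is None or d < _to_date(prev):
            starts[pid] = p

    demo = bundle.demo.set_index("primaryid")
    case_pids = [pid for pid in demo.index if flags.get(pid) == CASE]
    records: list[TTORecord] = []
    for pid in case_pids:
        event = parse_partial_date(demo.at[pid, "event_dt"])
        start = starts.get(pid, PartialDate())
        ed, sd = _to_date(event), _to_date(start)
        if ed is None or sd is None:
            log.bump("tto_unavailable")
            records.append(TTORecord(pid, start, event, None))
            continue
        days = (ed - sd).days
        if days < 0:
            log.bump("tto_negative_excluded")
            records.append(TTORecord(pid, start, event, None))
            continue
        records.append(TTORecord(pid, start, event, days))
    return records


def classify_serious(bundle: ReportBundle, log: RunLog | None = None) -> list[SeriousnessLabel]:
    """Serious iff the report has at least one recognized serious outcome code;
    reports with no outcome row are non-serious."""
    log = log if log is not None else RunLog()
    outc = bundle.outc
    known = outc["outcome_code"].isin(OUTCOME_CODES)
    log.bump("outc_unknown_code_ignored", int((~known).sum()))
    codes = outc[known].groupby("primaryid")["outcome_code"].agg(frozenset)
    labels = []
    for pid in bundle.demo["primaryid"]:
        cs = codes.get(pid, frozenset())
        labels.append(SeriousnessLabel(pid, bool(cs), cs))
    return labels


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    summary1: float
    summary2: float
    evaluable: bool = True


def compare_groups(
    values1,
    values2,
    test: str = "mann_whitney",
) -> GroupComparison:
    """Two-group contrast: Mann-Whitney U for continuous values (tie-corrected
    normal approximation, two-sided), Pearson chi-squared for binary ones.

    For the chi-squared test the inputs are 0/1 indicator sequences and the
    summaries are group proportions; otherwise summaries are medians.
    """
    v1 = np.asarray([v for v in values1 if v is not None and not pd.isna(v)], dtype=float)
    v2 = np.asarray([v for v in values2 if v is not None and not pd.isna(v)], dtype=float)
    if len(v1) == 0 or len(v2) == 0:
        return GroupComparison(test, float("nan"), float("nan"), len(v1), len(v2),
                               float("nan"), float("nan"), evaluable=False)
    if test == "mann_whitney":
        res = stats.mannwhitneyu(v1, v2, alternative="two-sided", method="asymptotic")
        return GroupComparison(test, float(res.statistic), float(res.pvalue),
                               len(v1), len(v2),
                               float(np.median(v1)), float(np.median(v2)))
    if test == "chi_squared":
        obs = np.array([
            [np.sum(v1 == 1), np.sum(v1 == 0)],
            [np.sum(v2 == 1), np.sum(v2 == 0)],
        ])
        if (obs.sum(axis=0) == 0).any():
            return GroupComparison(test, float("nan"), float("nan"), len(v1), len(v2),
                                   float(np.mean(v1)), float(np.mean(v2)),
                                   evaluable=False)
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
        return GroupComparison(test, float(chi2), float(p), len(v1), len(v2),
                               float(np.mean(v1)), float(np.mean(v2)))
    raise ValueError(f"unknown test {test!r}")


def seriousness_contrasts(
    bundle: ReportBundle,
    flags: pd.Series,
    tto_records: list[TTORecord],
    labels: list[SeriousnessLabel],
) -> pd.DataFrame:
    """Serious vs non-serious contrasts among cases: age, weight, TTO
    (Mann-Whitney) and sex (chi-squared), one row per variable."""
    serious = {lab.primaryid for lab in labels if lab.serious}
    demo = bundle.demo.set_index("primaryid")
    case_pids = [pid for pid in demo.index if flags.get(pid) == CASE]
    tto_by_pid = {r.primaryid: r.tto_days for r in tto_records}

    def split(getter):
        g1, g2 = [], []  # serious, non-serious
        for pid in case_pids:
            v = getter(pid)
            (g1 if pid in serious else g2).append(v)
        return g1, g2

    from .stratified import age_in_years

    def age_of(pid):
        return age_in_years(demo.at[pid, "age"], demo.at[pid, "age_unit"])

    def weight_of(pid):
        try:
            return float(str(demo.at[pid, "weight"]).strip())
        except (TypeError, ValueError):
            return None

    def sex_of(pid):
        s = str(demo.at[pid, "sex"]).strip().upper()
        return {"F": 1.0, "M": 0.0}.get(s)

    rows = []
    for name, getter, test in (
        ("age_years", age_of, "mann_whitney"),
        ("weight_kg", weight_of, "mann_whitney"),
        ("tto_days", tto_by_pid.get, "mann_whitney"),
        ("female", sex_of, "chi_squared"),
    ):
        g_serious, g_nonserious = split(getter)
        cmpres = compare_groups(g_serious, g_nonserious, test=test)
        rows.append({
            "variable": name, "test": cmpres.test,
            "statistic": cmpres.statistic, "p_value": cmpres.p_value,
            "n_serious": cmpres.n1, "n_nonserious": cmpres.n2,
            "serious_summary": cmpres.summary1,
            "nonserious_summary": cmpres.summary2,
        })
    return pd.DataFrame(rows)


def sex_tto_contrast(
    bundle: ReportBundle, flags: pd.Series, tto_records: list[TTORecord]
) -> GroupComparison:
    """TTO in women vs men among cases (Mann-Whitney)."""
    demo = bundle.demo.set_index("primaryid")
    women, men = [], []
    for r in tto_records:
        if r.tto_days is None or flags.get(r.primaryid) != CASE:
            continue
        sex = str(demo.at[r.primaryid, "sex"]).strip().upper()
        if sex == "F":
            women.append(r.tto_days)
        elif sex == "M":
            men.append(r.tto_days)
    return compare_groups(women, men, test="mann_whitney")
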
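"""Shared fixtures: a compact hand-written report builder and session-scoped
synthetic bundles reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

from pvsignals.bundle import (
    DEMO_COLUMNS, DRUG_COLUMNS, INDI_COLUMNS, OUTC_COLUMNS, REAC_COLUMNS,
    THER_COLUMNS, ReportBundle,
)
from pvsignals.preprocessing import CaseDefinition
from pvsignals.simulate import SimConfig, generate


def make_bundle(reports: list[dict]) -> ReportBundle:
    """Build a bundle from compact per-report dicts.

    Each dict: primaryid (required), caseid, fda_dt, event_dt, sex, age,
    age_unit, weight, country, qualification, drugs (list of dicts with
    seq/role/ingredient and optional drug_name/indication/start_dt/end_dt),
    pts (list of str), outcomes (list of codes).
    """
    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = [], [], [], [], [], []
    for r in reports:
        pid = str(r["primaryid"])
        demo_rows.append({
            "primaryid": pid,
            "caseid": str(r.get("caseid", pid)),
            "fda_dt": str(r.get("fda_dt", "20230101")),
            "event_dt": str(r.get("event_dt", "")),
            "sex": r.get("sex", ""),
            "age": str(r.get("age", "")),
            "age_unit": r.get("age_unit", "YR" if r.get("age") else ""),
            "weight": str(r.get("weight", "")),
            "country_code": r.get("country", "US"),
            "reporter_qualification": r.get("qualification", "MD"),
            "report_year": str(r.get("event_dt", r.get("fda_dt", "20230101")))[:4],
        })
        for d in r.get("drugs", []):
            seq = str(d.get("seq", 1))
            ing = d["ingredient"]
            drug_rows.append({
                "primaryid": pid, "drug_seq": seq,
                "role_code": d.get("role", "PS"),
                "drug_name": d.get("drug_name", ing.upper()),
                "ingredient": ing,
            })
            if d.get("start_dt") or d.get("end_dt"):
                ther_rows.append({
                    "primaryid": pid, "drug_seq": seq,
                    "start_dt": str(d.get("start_dt", "")),
                    "end_dt": str(d.get("end_dt", "")),
                })
            if d.get("indication"):
                indi_rows.append({
                    "primaryid": pid, "drug_seq": seq,
                    "indication_pt": d["indication"],
                })
        for pt in r.get("pts", []):
            reac_rows.append({"primaryid": pid, "pt": pt})
        for code in r.get("outcomes", []):
            outc_rows.append({"primaryid": pid, "outcome_code": code})

    def frame(rows, cols):
        return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)

    return ReportBundle(
        demo=frame(demo_rows, DEMO_COLUMNS),
        drug=frame(drug_rows, DRUG_COLUMNS),
        reac=frame(reac_rows, REAC_COLUMNS),
        outc=frame(outc_rows, OUTC_COLUMNS),
        ther=frame(ther_rows, THER_COLUMNS),
        indi=frame(indi_rows, INDI_COLUMNS),
        deleted=[],
    )


@pytest.fixture
def esketamine_cd() -> CaseDefinition:
    return CaseDefinition("esketamine")


@pytest.fixture(scope="session")
def null_bundle_20k():
    """20,000 reports with no planted effects and no duplicate injection."""
    cfg = SimConfig(n_reports=20_000, seed=42, caseid_dup_rate=0.0,
                    fieldmatch_dup_rate=0.0, deleted_rate=0.0)
    bundle, truth = generate(cfg)
    return bundle, truth


@pytest.fixture(scope="session")
def planted_bundle_50k():
    """50,000 reports with a planted odds-x10 signal at 5% exposure, 1% baseline."""
    cfg = SimConfig(
        n_reports=50_000, seed=7,
        planted_signals=(("esketamine", "Blood pressure increased", 10.0),),
    )
    bundle, truth = generate(cfg)
    return bundle, truth
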
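"""Synthetic spontaneous-report generator with known ground truth.

The generator emulates the structure of a FAERS-style quarterly extract:
reports carrying one or more preferred terms, one or more drugs with
role codes, partial dates, sex/age/country demographics, outcome codes,
injected duplicate reports and deleted cases.  Every planted effect is
recorded in a :class:`GroundTruth` object so pipeline estimates can be
checked against what was simulated.

Effect plumbing
---------------
Single-drug signals and sex effects act on the *odds* of each preferred
term (so at a low baseline the reporting odds ratio recovered by the
pipeline approximates the planted multiplier).  Drug-pair interactions
act on the *risk* scale, because the additive and multiplicative
interaction scores are risk-scale quantities: for reports exposed to
both drugs the joint risk is set to

* additive scale:       p11 = p10 + p01 − p00 + strength
* multiplicative scale: p11 = strength · p10 · p01 / p00

where p00 is the baseline risk and p10/p01 the single-drug risks.

Defaults mirror the marginal structure of esketamine reporting: sex
58.5% female / 32.5% male / 9% missing, median onset age around 48
years, mostly US reports, log-normal time-to-onset with medians of 60
days for serious and 2 days for non-serious reports, and event dates
within the 2014-2024 reporting window.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import (
    DEMO_COLUMNS, DRUG_COLUMNS, INDI_COLUMNS, OUTC_COLUMNS, REAC_COLUMNS,
    THER_COLUMNS, ReportBundle,
)
from .faers_io import write_quarter


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: marginal exposure probability and role mix."""

    ingredient: str
    exposure_prob: float
    role_probs: tuple[tuple[str, float], ...] = (("PS", 0.7), ("SS", 0.1),
                                                 ("I", 0.05), ("C", 0.15))

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposure_prob <= 1.0:
            raise ValueError("exposure_prob must be in [0, 1]")
        total = sum(p for _, p in self.role_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("role probabilities must sum to 1")


DEFAULT_PT_CATALOG: tuple[tuple[str, float], ...] = (
    ("Dissociation", 0.002), ("Sedation", 0.004), ("Nausea", 0.05),
    ("Dizziness", 0.03), ("Headache", 0.06), ("Vomiting", 0.025),
    ("Anxiety", 0.015), ("Hypertension", 0.012), ("Vertigo", 0.006),
    ("Agitation", 0.004), ("Somnolence", 0.012), ("Fatigue", 0.04),
    ("Insomnia", 0.02), ("Euphoric mood", 0.001), ("Suicidal ideation", 0.004),
    ("Blood pressure increased", 0.01), ("Rash", 0.03), ("Diarrhoea", 0.04),
    ("Drug ineffective", 0.08), ("Feeling abnormal", 0.013),
)

DEFAULT_DRUG_CATALOG: tuple[DrugSpec, ...] = (
    DrugSpec("esketamine", 0.05, (("PS", 0.85), ("SS", 0.06), ("I", 0.02), ("C", 0.07))),
    DrugSpec("venlafaxine", 0.04),
    DrugSpec("bupropion", 0.03),
    DrugSpec("quetiapine", 0.03),
    DrugSpec("risperidone", 0.02),
    DrugSpec("clonazepam", 0.03),
    DrugSpec("paracetamol", 0.10, (("PS", 0.3), ("SS", 0.2), ("I", 0.05), ("C", 0.45))),
    DrugSpec("metformin", 0.08, (("PS", 0.4), ("SS", 0.2), ("I", 0.05), ("C", 0.35))),
)


@dataclass
class SimConfig:
    """Everything the generator needs; defaults are the study-like conditions."""

    n_reports: int = 5000
    seed: int = 0
    pt_catalog: tuple[tuple[str, float], ...] = DEFAULT_PT_CATALOG
    drug_catalog: tuple[DrugSpec, ...] = DEFAULT_DRUG_CATALOG
    #: (ingredient, pt, odds multiplier)
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    #: (ingredient A, ingredient B, pt, scale in {additive, multiplicative}, strength)
    planted_interactions: tuple[tuple[str, str, str, str, float], ...] = ()
    #: (pt, female odds multiplier)
    sex_effects: tuple[tuple[str, float], ...] = ()
    sex_probs: tuple[float, float, float] = (0.585, 0.325, 0.09)  # F, M, missing
    age_mean: float = 48.0
    age_sd: float = 16.0
    age_missing_rate: float = 0.30
    country_us_prob: float = 0.78
    serious_prob: float = 0.5
    #: log-normal TTO: {serious: (median_days, sigma), nonserious: ...}
    tto_median_serious: float = 60.0
    tto_median_nonserious: float = 2.0
    tto_sigma: float = 1.2
    event_date_missing_rate: float = 0.25
    ther_start_missing_rate: float = 0.20
    weight_missing_rate: float = 0.80
    caseid_dup_rate: float = 0.02
    fieldmatch_dup_rate: float = 0.01
    deleted_rate: float = 0.01
    #: fraction of target-drug reports given an excluded (non-psychiatric) indication
    target_excluded_indication_rate: float = 0.02

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for pt, p in self.pt_catalog:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline probability out of range for {pt!r}")
        for rate in (self.caseid_dup_rate, self.fieldmatch_dup_rate,
                     self.deleted_rate, self.age_missing_rate,
                     self.event_date_missing_rate, self.serious_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be probabilities")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ValueError("sex_probs must sum to 1")
        names = [d.ingredient for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ingredient in drug catalog")
        for _, _, m in self.planted_signals:
            if m <= 0:
                raise ValueError("signal odds multipliers must be positive")
        for _, _, _, scale, s in self.planted_interactions:
            if scale not in ("additive", "multiplicative"):
                raise ValueError(f"unknown interaction scale {scale!r}")
            if s <= 0:
                raise ValueError("interaction strengths must be positive")


@dataclass
class GroundTruth:
    """What was planted and injected, for checking pipeline recoveries."""

    n_base_reports: int
    planted_signals: list
    planted_interactions: list
    sex_effects: list
    #: (source primaryid, clone primaryid) per injected duplicate
    caseid_dup_pairs: list[tuple[str, str]]
    fieldmatch_dup_pairs: list[tuple[str, str]]
    deleted_caseids: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


_EFFECT_ROLES = ("PS", "SS", "I")  # roles through which planted effects act


def _apply_odds(p: np.ndarray, multiplier: float | np.ndarray) -> np.ndarray:
    odds = p / (1.0 - p)
    new = odds * multiplier
    return new / (1.0 + new)


def generate(config: SimConfig) -> tuple[ReportBundle, GroundTruth]:
    """Draw one synthetic bundle; byte-identical for identical (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    primaryid = np.array([str(10_000_000 + i) for i in range(n)])
    caseid = np.array([str(20_000_000 + i) for i in range(n)])

    sex = rng.choice(np.array(["F", "M", ""]), size=n, p=list(config.sex_probs))
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, size=n)), 12, 95)
    age_str = age.astype(int).astype(str)
    age_str[rng.random(n) < config.age_missing_rate] = ""
    country = np.where(rng.random(n) < config.country_us_prob, "US",
                       rng.choice(np.array(["GB", "FR", "DE", "JP", "CA"]), size=n))
    weight = np.round(rng.lognormal(np.log(78), 0.2, size=n), 1).astype(str)
    weight[rng.random(n) < config.weight_missing_rate] = ""
    qualif = rng.choice(np.array(["MD", "HP", "PH", "CN", "OT"]), size=n,
                        p=[0.32, 0.36, 0.02, 0.29, 0.01])

    # --- drug exposures and roles -------------------------------------------
    drugs = list(config.drug_catalog)
    exposure = np.column_stack([rng.random(n) < d.exposure_prob for d in drugs])
    # every report carries at least one drug: fall back to the last catalog drug
    none = ~exposure.any(axis=1)
    exposure[none, -1] = True
    roles = np.empty((n, len(drugs)), dtype=object)
    for j, d in enumerate(drugs):
        labels = np.array([r for r, _ in d.role_probs])
        probs = [p for _, p in d.role_probs]
        roles[:, j] = rng.choice(labels, size=n, p=probs)
    effective = exposure & np.isin(roles, _EFFECT_ROLES)

    drug_index = {d.ingredient: j for j, d in enumerate(drugs)}

    # --- per-report, per-PT event probabilities -----------------------------
    pt_names = [pt for pt, _ in config.pt_catalog]
    base = np.array([p for _, p in config.pt_catalog])
    prob = np.tile(base, (n, 1))

    for ingredient, pt, mult in config.planted_signals:
        j = drug_index[ingredient]
        k = pt_names.index(pt)
        mask = effective[:, j]
        prob[mask, k] = _apply_odds(prob[mask, k], mult)
    for pt, fmult in config.sex_effects:
        k = pt_names.index(pt)
        mask = sex == "F"
        prob[mask, k] = _apply_odds(prob[mask, k], fmult)
    for ing_a, ing_b, pt, scale, strength in config.planted_interactions:
        ja, jb = drug_index[ing_a], drug_index[ing_b]
        k = pt_names.index(pt)
        p00 = base[k]
        pa = float(_apply_odds(np.array([p00]), _signal_mult(config, ing_a, pt))[0])
        pb = float(_apply_odds(np.array([p00]), _signal_mult(config, ing_b, pt))[0])
        both = effective[:, ja] & effective[:, jb]
        only_a = effective[:, ja] & ~effective[:, jb]
        only_b = effective[:, jb] & ~effective[:, ja]
        prob[only_a, k] = pa
        prob[only_b, k] = pb
        if scale == "additive":
            p11 = pa + pb - p00 + strength
        else:
            p11 = strength * pa * pb / p00
        prob[both, k] = min(p11, 0.99)

    events = rng.random((n, len(pt_names))) < prob
    # a report must carry at least one PT
    none_pt = ~events.any(axis=1)
    filler = pt_names.index("Drug ineffective") if "Drug ineffective" in pt_names else 0
    events[none_pt, filler] = True

    # --- seriousness and dates ----------------------------------------------
    serious = rng.random(n) < config.serious_prob
    window_start = dt.date(2014, 7, 1)
    window_days = (dt.date(2024, 6, 30) - window_start).days
    start_offset = rng.integers(0, window_days, size=n)
    medians = np.where(serious, config.tto_median_serious, config.tto_median_nonserious)
    tto = np.round(rng.lognormal(np.log(medians), config.tto_sigma)).astype(int)
    start_dates = np.array([window_start + dt.timedelta(days=int(o)) for o in start_offset])
    event_dates = np.array([s + dt.timedelta(days=int(t)) for s, t in zip(start_dates, tto)])
    fda_lag = rng.integers(5, 120, size=n)
    fda_dates = np.array([e + dt.timedelta(days=int(l)) for e, l in zip(event_dates, fda_lag)])

    def fmt(d: dt.date) -> str:
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"

    event_dt = np.array([fmt(d) for d in event_dates], dtype=object)
    event_dt[rng.random(n) < config.event_date_missing_rate] = ""
    start_dt = np.array([fmt(d) for d in start_dates], dtype=object)
    fda_dt = np.array([fmt(d) for d in fda_dates])

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt,
        "event_dt": event_dt, "sex": sex, "age": age_str,
        "age_unit": np.where(age_str == "", "", "YR"),
        "weight": weight, "country_code": country,
        "reporter_qualification": qualif,
        "report_year": [d[:4] if d else f[:4] for d, f in zip(event_dt, fda_dt)],
    })

    # --- long tables ---------------------------------------------------------
    # the first catalog entry is the target drug by convention: it gets a
    # psychiatric indication, or an excluded one at the configured rate
    drug_rows, ther_rows, indi_rows = [], [], []
    ther_missing = rng.random(n) < config.ther_start_missing_rate
    excl_indication = rng.random(n) < config.target_excluded_indication_rate
    other_indication = rng.random((n, len(drugs))) < 0.4
    for i in range(n):
        seq = 0
        for j, d in enumerate(drugs):
            if not exposure[i, j]:
                continue
            seq += 1
            drug_rows.append((primaryid[i], str(seq), roles[i, j],
                              d.ingredient.upper(), d.ingredient))
            if not ther_missing[i]:
                ther_rows.append((primaryid[i], str(seq), start_dt[i], ""))
            if j == 0:
                indication = ("Anaesthesia" if excl_indication[i]
                              else "Treatment resistant depression")
                indi_rows.append((primaryid[i], str(seq), indication))
            elif other_indication[i, j]:
                indi_rows.append((primaryid[i], str(seq), "Product used for unknown indication"))

    reac_rows = [
        (primaryid[i], pt_names[k])
        for i in range(n) for k in np.flatnonzero(events[i])
    ]
    serious_idx = np.flatnonzero(serious)
    outc_codes = rng.choice(np.array(["HO", "OT", "LT", "DS", "DE"]),
                            size=len(serious_idx), p=[0.5, 0.3, 0.1, 0.05, 0.05])
    outc_rows = list(zip(primaryid[serious_idx], outc_codes))

    bundle = ReportBundle(
        demo=demo,
        drug=pd.DataFrame(drug_rows, columns=DRUG_COLUMNS),
        reac=pd.DataFrame(reac_rows, columns=REAC_COLUMNS),
        outc=pd.DataFrame(outc_rows, columns=OUTC_COLUMNS),
        ther=pd.DataFrame(ther_rows, columns=THER_COLUMNS),
        indi=pd.DataFrame(indi_rows, columns=INDI_COLUMNS),
        deleted=[],
    )

    # --- duplicate injection -------------------------------------------------
    n_caseid_dups = int(round(config.caseid_dup_rate * n))
    n_field_dups = int(round(config.fieldmatch_dup_rate * n))
    total_dups = n_caseid_dups + n_field_dups
    dup_sources = (rng.choice(n, size=total_dups, replace=False)
                   if total_dups <= n else np.arange(n))
    clone_specs = []  # (source idx, new pid, new cid or None, later fda_dt)
    for k, idx in enumerate(dup_sources[:n_caseid_dups]):
        clone_specs.append((int(idx), str(10_000_000 + n + k), None, True))
    for k, idx in enumerate(dup_sources[n_caseid_dups:]):
        clone_specs.append((int(idx), str(10_000_000 + n + n_caseid_dups + k),
                            str(20_000_000 + n + k), False))
    caseid_dup_pairs = [(primaryid[s[0]], s[1]) for s in clone_specs if s[2] is None]
    field_dup_pairs = [(primaryid[s[0]], s[1]) for s in clone_specs if s[2] is not None]

    if clone_specs:
        demo_clones = []
        for idx, new_pid, new_cid, later in clone_specs:
            row = bundle.demo.iloc[[idx]].copy()
            row["primaryid"] = new_pid
            if new_cid is not None:
                row["caseid"] = new_cid
            if later:
                old = dt.datetime.strptime(row["fda_dt"].iloc[0], "%Y%m%d").date()
                row["fda_dt"] = fmt(old + dt.timedelta(days=30))
                if not row["event_dt"].iloc[0]:
                    row["report_year"] = row["fda_dt"].str.slice(0, 4)
            demo_clones.append(row)
        bundle.demo = pd.concat([bundle.demo, *demo_clones], ignore_index=True)
        pid_map = {primaryid[idx]: new_pid for idx, new_pid, _, _ in clone_specs}
        for name in ("drug", "reac", "outc", "ther", "indi"):
            t = getattr(bundle, name)
            child = t[t["primaryid"].isin(pid_map)].copy()
            child["primaryid"] = child["primaryid"].map(pid_map)
            setattr(bundle, name, pd.concat([t, child], ignore_index=True))

    n_deleted = int(round(config.deleted_rate * n))
    deleted_idx = rng.choice(n, size=n_deleted, replace=False)
    deleted_ids = sorted(caseid[i] for i in deleted_idx)
    bundle.deleted = deleted_ids

    truth = GroundTruth(
        n_base_reports=n,
        planted_signals=[list(t) for t in config.planted_signals],
        planted_interactions=[list(t) for t in config.planted_interactions],
        sex_effects=[list(t) for t in config.sex_effects],
        caseid_dup_pairs=[(str(a), str(b)) for a, b in caseid_dup_pairs],
        fieldmatch_dup_pairs=[(str(a), str(b)) for a, b in field_dup_pairs],
        deleted_caseids=deleted_ids,
    )
    return bundle, truth


def _signal_mult(config: SimConfig, ingredient: str, pt: str) -> float:
    for ing, p, m in config.planted_signals:
        if ing == ingredient and p == pt:
            return m
    return 1.0


def write_fixture(bundle: ReportBundle, directory: str | Path,
                  truth: GroundTruth | None = None) -> None:
    """Emit the six $-delimited tables plus the deleted-case file (and the
    ground truth as JSON when given)."""
    directory = Path(directory)
    write_quarter(bundle, directory)
    if truth is not None:
        truth.to_json(directory / "ground_truth.json")
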
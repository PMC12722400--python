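"""Reading and writing FAERS-style quarterly ASCII extracts.

The public FAERS quarterly extracts are ``$``-delimited text tables with a
header row, one file per entity (DEMO/DRUG/REAC/OUTC/THER/INDI), plus
newline-delimited deleted-case files.  Column spellings drifted across
eras; a *dialect* maps each canonical column to the spelling used in the
files at hand, with a bundled default for the modern (post-2014) layout.

Real extracts are dirty: rows failing referential integrity or carrying
out-of-vocabulary codes are dropped with a counter rather than aborting
the run.  All counters accumulate in a :class:`RunLog` that is emitted as
JSON beside the analysis outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bundle import (
    DEMO_COLUMNS, DRUG_COLUMNS, INDI_COLUMNS, OUTC_COLUMNS, OUTCOME_CODES,
    REAC_COLUMNS, ROLE_CODES, THER_COLUMNS, IngredientDictionary, ReportBundle,
)

DELIM = "$"

#: canonical column -> column name in the file, per table, modern spelling
DEFAULT_DIALECT: dict[str, dict[str, str]] = {
    "demo": {
        "primaryid": "primaryid", "caseid": "caseid", "fda_dt": "fda_dt",
        "event_dt": "event_dt", "sex": "sex", "age": "age", "age_unit": "age_cod",
        "weight": "wt", "occurrence_country": "occr_country",
        "reporter_country": "reporter_country", "reporter_qualification": "occp_cod",
    },
    "drug": {
        "primaryid": "primaryid", "drug_seq": "drug_seq", "role_code": "role_cod",
        "drug_name": "drugname", "ingredient": "prod_ai",
    },
    "reac": {"primaryid": "primaryid", "pt": "pt"},
    "outc": {"primaryid": "primaryid", "outcome_code": "outc_cod"},
    "ther": {
        "primaryid": "primaryid", "drug_seq": "dsg_drug_seq",
        "start_dt": "start_dt", "end_dt": "end_dt",
    },
    "indi": {
        "primaryid": "primaryid", "drug_seq": "indi_drug_seq",
        "indication_pt": "indi_pt",
    },
}

TABLE_FILES = {
    "demo": "DEMO", "drug": "DRUG", "reac": "REAC",
    "outc": "OUTC", "ther": "THER", "indi": "INDI",
}


@dataclass
class RunLog:
    """Accumulator for drop/skip counters emitted with every run."""

    counters: dict[str, int] = field(default_factory=dict)

    def bump(self, key: str, n: int = 1) -> None:
        if n:
            self.counters[key] = self.counters.get(key, 0) + int(n)

    def get(self, key: str) -> int:
        return self.counters.get(key, 0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.counters, indent=2, sort_keys=True))


class MissingTableError(FileNotFoundError):
    """A mandatory quarterly table file is absent."""


def _find_table_file(directory: Path, stem: str) -> Path:
    candidates = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.name.upper().startswith(stem) and p.suffix.lower() in {".txt", ".tsv", ""}
    )
    if not candidates:
        raise MissingTableError(f"mandatory table file {stem}* not found in {directory}")
    return candidates[0]


def _read_table(path: Path, colmap: dict[str, str], log: RunLog, table: str) -> pd.DataFrame:
    # UTF-8 with replacement: legacy extracts contain stray bytes
    raw = pd.read_csv(
        path, sep=DELIM, dtype=str, engine="python",
        encoding="utf-8", encoding_errors="replace",
        keep_default_na=False, on_bad_lines="skip",
    )
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [src for src in colmap.values() if src not in raw.columns]
    # primaryid is the join key and must exist; other columns may be absent
    if colmap["primaryid"] not in raw.columns:
        raise ValueError(f"unparseable header in {path}: no {colmap['primaryid']} column")
    out = pd.DataFrame(index=raw.index)
    for canonical, src in colmap.items():
        if src in raw.columns:
            out[canonical] = raw[src].astype(str).str.strip()
        else:
            out[canonical] = ""
    if missing:
        log.bump(f"{table}_missing_columns", len(missing))
    return out


def read_deleted_cases(paths: list[str | Path], log: RunLog | None = None) -> list[str]:
    """Union of caseids across deleted-case files; missing files warn and contribute nothing."""
    log = log or RunLog()
    ids: set[str] = set()
    for p in paths:
        p = Path(p)
        if not p.exists():
            log.bump("deleted_files_missing")
            continue
        for line in p.read_text(encoding="utf-8", errors="replace").splitlines():
            line = line.strip()
            if line and line.lower() != "caseid":
                ids.add(line)
    return sorted(ids)


def normalize_ingredients(
    drug_table: pd.DataFrame,
    dictionary: IngredientDictionary,
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Fill the ingredient column from the brand-name dictionary.

    A verbatim name matches case-insensitively after trimming; unmatched
    names keep whatever ingredient the file carried (the verbatim name
    itself when that was empty) and are counted.
    """
    log = log or RunLog()
    out = drug_table.copy()
    if len(dictionary) == 0:
        log.bump("ingredient_dict_empty")
        out["ingredient"] = out["ingredient"].where(
            out["ingredient"].astype(str).str.strip() != "", out["drug_name"]
        )
        return out
    keys = out["drug_name"].astype(str).str.strip().str.casefold()
    mapped = keys.map(dictionary.mapping)
    hit = mapped.notna()
    existing = out["ingredient"].astype(str).str.strip()
    out["ingredient"] = mapped.where(hit, existing.where(existing != "", out["drug_name"]))
    log.bump("ingredients_mapped", int(hit.sum()))
    log.bump("ingredients_unmapped", int((~hit).sum()))
    return out


def read_ingredient_dictionary(path: str | Path, sep: str = "\t") -> IngredientDictionary:
    """Load a 2-column (raw_name, ingredient) delimited text dictionary."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns[:2])
    return IngredientDictionary(dict(zip(df[cols[0]], df[cols[1]])))


def read_quarter(
    directory: str | Path,
    dialect: dict[str, dict[str, str]] | None = None,
    deleted_paths: list[str | Path] | None = None,
    log: RunLog | None = None,
) -> ReportBundle:
    """Read one quarterly extract directory into a validated :class:`ReportBundle`.

    Rows violating referential integrity (child rows whose report is not
    in DEMO, therapy/indication rows whose drug entry is absent) and rows
    with out-of-vocabulary role or outcome codes are dropped and counted
    in the run log.  Missing mandatory table files raise.
    """
    directory = Path(directory)
    dialect = dialect or DEFAULT_DIALECT
    log = log if log is not None else RunLog()

    tables: dict[str, pd.DataFrame] = {}
    for table, stem in TABLE_FILES.items():
        path = _find_table_file(directory, stem)
        tables[table] = _read_table(path, dialect[table], log, table)

    demo = tables["demo"]
    dropped = demo["primaryid"].astype(str).str.strip() == ""
    log.bump("demo_rows_dropped", int(dropped.sum()))
    demo = demo[~dropped]
    dup = demo["primaryid"].duplicated(keep="first")
    log.bump("demo_duplicate_primaryid_dropped", int(dup.sum()))
    demo = demo[~dup].reset_index(drop=True)

    # occurrence country preferred, reporter country as fallback
    occ = demo.pop("occurrence_country")
    rep = demo.pop("reporter_country")
    demo["country_code"] = occ.where(occ != "", rep)
    demo["report_year"] = demo["event_dt"].str.slice(0, 4).where(
        demo["event_dt"].str.len() >= 4, demo["fda_dt"].str.slice(0, 4)
    )
    demo = demo[DEMO_COLUMNS]

    pids = set(demo["primaryid"])
    for table in ("drug", "reac", "outc", "ther", "indi"):
        t = tables[table]
        orphan = ~t["primaryid"].isin(pids)
        log.bump(f"{table}_orphan_rows_dropped", int(orphan.sum()))
        tables[table] = t[~orphan].reset_index(drop=True)

    drug = tables[table := "drug"]
    bad = ~drug["role_code"].str.upper().isin(ROLE_CODES)
    log.bump("drug_bad_role_dropped", int(bad.sum()))
    drug = drug[~bad].reset_index(drop=True)
    drug["role_code"] = drug["role_code"].str.upper()
    tables["drug"] = drug[DRUG_COLUMNS]

    outc = tables["outc"]
    bad = ~outc["outcome_code"].str.upper().isin(OUTCOME_CODES)
    log.bump("outc_bad_code_dropped", int(bad.sum()))
    outc = outc[~bad].reset_index(drop=True)
    outc["outcome_code"] = outc["outcome_code"].str.upper()
    tables["outc"] = outc[OUTC_COLUMNS]

    reac = tables["reac"]
    reac["pt"] = reac["pt"].str.strip()
    empty = reac["pt"] == ""
    log.bump("reac_empty_pt_dropped", int(empty.sum()))
    tables["reac"] = reac[~empty].reset_index(drop=True)[REAC_COLUMNS]

    drug_keys = set(zip(tables["drug"]["primaryid"], tables["drug"]["drug_seq"]))
    for table in ("ther", "indi"):
        t = tables[table]
        ok = pd.Series(
            [k in drug_keys for k in zip(t["primaryid"], t["drug_seq"])],
            index=t.index, dtype=bool,
        )
        log.bump(f"{table}_unlinked_rows_dropped", int(len(t) - ok.sum()))
        cols = THER_COLUMNS if table == "ther" else INDI_COLUMNS
        tables[table] = t.loc[ok, cols].reset_index(drop=True)

    deleted = read_deleted_cases(deleted_paths or [], log)
    bundle = ReportBundle(
        demo=demo, drug=tables["drug"], reac=tables["reac"], outc=tables["outc"],
        ther=tables["ther"], indi=tables["indi"], deleted=deleted,
    )
    bundle.validate()
    return bundle


def write_quarter(bundle: ReportBundle, directory: str | Path) -> None:
    """Write a bundle back out in the quarterly ASCII dialect read by :func:`read_quarter`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dialect = DEFAULT_DIALECT
    for table, stem in TABLE_FILES.items():
        df = getattr(bundle, table).copy()
        if table == "demo":
            df = df.rename(columns={
                "age_unit": "age_cod", "weight": "wt",
                "country_code": "occr_country", "reporter_qualification": "occp_cod",
            })
            df["reporter_country"] = df["occr_country"]
            df = df.drop(columns=["report_year"])
        else:
            inverse = {canon: src for canon, src in dialect[table].items()}
            df = df.rename(columns=inverse)
        df.to_csv(directory / f"{stem}.txt", sep=DELIM, index=False)
    (directory / "DELETED.txt").write_text(
        "\n".join(map(str, bundle.deleted)) + ("\n" if bundle.deleted else "")
    )


def write_result_table(df: pd.DataFrame, path: str | Path, decimals: int = 2) -> None:
    """Write a result table as TSV, rendering floats half-away-from-zero."""
    from .rounding import round_half_away

    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{round_half_away(v, decimals):.{decimals}f}"
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)
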
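"""One-command orchestration of the full signal-detection analysis.

Stages: ingest → dedup/clean → case flagging → disproportionality
screening (+ comparator sensitivity) → sex/age-stratified relative RORs
→ time-to-onset and seriousness contrasts → drug-drug-interaction
scoring.  Outputs are tab-separated tables plus a JSON run manifest
echoing the configuration, the drop/skip counters and the seed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bundle import ReportBundle
from .ddi import (
    DEFAULT_AE_EXCLUSIONS, ddi_to_frame, screen_ddi, select_eligible_triples,
)
from .disproportionality import comparator_analysis, screen_signals, signals_to_frame
from .faers_io import (
    RunLog, read_ingredient_dictionary, read_quarter, normalize_ingredients,
    write_result_table,
)
from .preprocessing import (
    CaseDefinition, DEFAULT_INDICATION_KEYWORDS, build_all_contingencies, clean,
    flag_cases,
)
from .stratified import classify_all, comparisons_to_frame, forest_plot_data
from .tto import (
    classify_serious, compute_tto, seriousness_contrasts, sex_tto_contrast,
)

OUTPUT_FILES = (
    "signals.tsv", "signals_comparator.tsv", "stratified_sex.tsv",
    "stratified_age.tsv", "tto.tsv", "seriousness.tsv", "ddi.tsv",
    "run_manifest.json",
)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    target_ingredient: str = "esketamine"
    eligible_roles: tuple[str, ...] = ("PS", "SS")
    excluded_indication_pts: tuple[str, ...] = ()
    excluded_indication_keywords: tuple[str, ...] = tuple(sorted(DEFAULT_INDICATION_KEYWORDS))
    deleted_paths: tuple[str, ...] = ()
    dictionary_path: str | None = None
    ci_level: float = 0.95
    min_reports: int = 5
    comparator: str | None = "venlafaxine"
    stratify_sex: bool = True
    stratify_age: bool = True
    age_years_only: bool = True
    ddi_universe: str = "case_reports"
    ddi_min_co_cases: int = 3
    ddi_ae_exclusions: tuple[str, ...] = tuple(sorted(DEFAULT_AE_EXCLUSIONS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reports < 1 or self.ddi_min_co_cases < 1:
            raise ValueError("report thresholds must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("eligible_roles", "excluded_indication_pts",
                    "excluded_indication_keywords", "deleted_paths",
                    "ddi_ae_exclusions"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def case_definition(self) -> CaseDefinition:
        return CaseDefinition(
            target_ingredient=self.target_ingredient,
            eligible_roles=frozenset(self.eligible_roles),
            excluded_indication_pts=frozenset(self.excluded_indication_pts),
            excluded_indication_keywords=frozenset(self.excluded_indication_keywords),
        )


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage in its message."""


def run_pipeline(config: RunConfig, bundle: ReportBundle | None = None) -> Path:
    """Run the full analysis; returns the output directory.

    A pre-loaded bundle may be passed instead of reading ``input_dir``.
    On a stage failure, partial outputs are removed and a stage-named
    error raised.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    stage = "ingest"
    try:
        if bundle is None:
            bundle = read_quarter(config.input_dir, deleted_paths=list(config.deleted_paths),
                                  log=log)
        if config.dictionary_path:
            dictionary = read_ingredient_dictionary(config.dictionary_path)
            bundle.drug = normalize_ingredients(bundle.drug, dictionary, log)
        n_raw = bundle.n_reports

        stage = "clean"
        bundle = clean(bundle, log)
        log.bump("reports_after_cleaning", bundle.n_reports)

        stage = "flag_cases"
        cd = config.case_definition()
        flags = flag_cases(bundle, cd, log)

        stage = "signals"
        tables = build_all_contingencies(bundle, flags)
        log.bump("pts_tested", len([t for t in tables if t.a >= config.min_reports]))
        signals = screen_signals(tables, config.min_reports, config.ci_level)
        write_result_table(signals_to_frame(signals, config.min_reports),
                           out_dir / "signals.tsv")

        stage = "comparator"
        if config.comparator:
            comp = comparator_analysis(bundle, cd, config.comparator,
                                       config.min_reports, config.ci_level)
            write_result_table(signals_to_frame(comp, config.min_reports),
                               out_dir / "signals_comparator.tsv")
        else:
            write_result_table(signals_to_frame([], config.min_reports),
                               out_dir / "signals_comparator.tsv")

        stage = "stratified"
        for variable, fname, enabled in (
            ("sex", "stratified_sex.tsv", config.stratify_sex),
            ("age_group", "stratified_age.tsv", config.stratify_age),
        ):
            comparisons = classify_all(
                bundle, flags, variable, config.ci_level, config.min_reports,
                age_years_only=config.age_years_only,
            ) if enabled else []
            write_result_table(comparisons_to_frame(comparisons), out_dir / fname)
            if enabled and variable == "sex":
                write_result_table(forest_plot_data(comparisons),
                                   out_dir / "forest_sex.tsv")

        stage = "tto"
        tto_records = compute_tto(bundle, flags, config.target_ingredient, log)
        labels = classify_serious(bundle, log)
        import pandas as pd
        tto_df = pd.DataFrame({
            "primaryid": [r.primaryid for r in tto_records],
            "tto_days": [r.tto_days if r.tto_days is not None else ""
                         for r in tto_records],
        })
        write_result_table(tto_df, out_dir / "tto.tsv")
        contrasts = seriousness_contrasts(bundle, flags, tto_records, labels)
        sex_tto = sex_tto_contrast(bundle, flags, tto_records)
        contrasts = pd.concat([contrasts, pd.DataFrame([{
            "variable": "tto_days_female_vs_male", "test": sex_tto.test,
            "statistic": sex_tto.statistic, "p_value": sex_tto.p_value,
            "n_serious": sex_tto.n1, "n_nonserious": sex_tto.n2,
            "serious_summary": sex_tto.summary1,
            "nonserious_summary": sex_tto.summary2,
        }])], ignore_index=True)
        write_result_table(contrasts, out_dir / "seriousness.tsv", decimals=4)

        stage = "ddi"
        triples = select_eligible_triples(
            bundle, flags, signals, config.target_ingredient,
            frozenset(config.ddi_ae_exclusions), config.ddi_min_co_cases,
            config.min_reports,
        )
        ddi_results = screen_ddi(bundle, flags, triples, universe=config.ddi_universe)
        write_result_table(ddi_to_frame(ddi_results), out_dir / "ddi.tsv")

        stage = "manifest"
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
            "counters": log.counters,
            "n_raw_reports": n_raw,
            "n_analyzed_reports": bundle.n_reports,
            "version": __version__,
            "seed": config.seed,
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        for f in OUTPUT_FILES + ("forest_sex.tsv",):
            p = out_dir / f
            if p.exists():
                p.unlink()
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out_dir
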
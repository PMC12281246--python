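"""End-to-end orchestration: ingest → dedup → screen → reanalysis → descriptives.

One validated configuration drives the whole run and every artifact is a
deterministic function of (inputs, config): ``cases.tsv`` (canonical case
table), ``signals.tsv`` (ranked disproportionality statistics),
``signals_adjusted.tsv`` (confounder-exclusion reanalysis),
``descriptives.md`` (demographic strata of event cases) and
``run_log.json`` (stage-by-stage record and exclusion counts).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from . import confounder_adjustment, descriptives, disproportionality, faers_io, vocabulary

STAGE_ORDER = ["ingest", "assemble", "deduplicate", "screen", "adjust", "describe"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class PipelineConfig(BaseModel):
    """Single source of truth for one pipeline run."""

    demo_path: Optional[str] = None
    drug_path: Optional[str] = None
    reac_path: Optional[str] = None
    indi_path: Optional[str] = None
    cases_path: Optional[str] = None  # pre-assembled canonical case table
    drug_dictionary_path: Optional[str] = None  # bundled N06A dictionary if unset
    term_set_path: Optional[str] = None  # bundled seizure skeleton if unset
    term_set_name: str = vocabulary.SEIZURE_SET_NAME
    confounder_catalog_path: Optional[str] = None  # bundled synthetic catalog if unset
    sep: str = "$"
    role_filter: list[str] = Field(default_factory=lambda: ["PS"])
    min_cases: int = Field(default=3, ge=1)
    continuity: bool = False
    out_dir: str = "pvscreen_out"

    def validate_paths(self) -> None:
        if self.cases_path is None:
            quarter = (self.demo_path, self.drug_path, self.reac_path, self.indi_path)
            if any(p is None for p in quarter):
                raise PipelineError(
                    "config: provide either cases_path or all four quarter files"
                )
        for label, p in [
            ("demo_path", self.demo_path), ("drug_path", self.drug_path),
            ("reac_path", self.reac_path), ("indi_path", self.indi_path),
            ("cases_path", self.cases_path),
            ("drug_dictionary_path", self.drug_dictionary_path),
            ("term_set_path", self.term_set_path),
            ("confounder_catalog_path", self.confounder_catalog_path),
        ]:
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {label} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _load_vocabularies(config: PipelineConfig):
    dictionary = (
        vocabulary.load_drug_dictionary(config.drug_dictionary_path)
        if config.drug_dictionary_path
        else vocabulary.default_drug_dictionary()
    )
    if config.term_set_path:
        term_set = vocabulary.load_term_sets(config.term_set_path)[config.term_set_name]
    else:
        term_set = vocabulary.default_seizure_term_set()
    catalog = (
        vocabulary.load_confounder_catalog(config.confounder_catalog_path)
        if config.confounder_catalog_path
        else vocabulary.default_confounder_catalog()
    )
    return dictionary, term_set, catalog


def ingest(config: PipelineConfig, dictionary) -> tuple[list[faers_io.CaseReport], dict]:
    """Parse, assemble and deduplicate; returns cases plus stage counts."""
    if config.cases_path is not None:
        cases = faers_io.read_cases(config.cases_path)
        return cases, {"cases_loaded": len(cases)}
    parsed = faers_io.read_quarter(
        config.demo_path, config.drug_path, config.reac_path, config.indi_path,
        faers_io.Dialect(config.sep),
    )
    assembly = faers_io.assemble_cases(
        parsed.records,
        normalize_drug=lambda raw: vocabulary.normalize_drug(raw, dictionary),
    )
    deduped = faers_io.deduplicate(assembly.cases)
    counts = {
        "raw_records": len(parsed.records),
        "rejected_rows": len(parsed.rejects),
        "demo_rows": assembly.n_demo_rows,
        "assembled_cases": len(assembly.cases),
        "excluded_no_event": assembly.n_no_event,
        "excluded_no_drug": assembly.n_no_drug,
        "orphan_rows": assembly.n_orphan_rows,
        "deduplicated_cases": len(deduped),
        "duplicate_versions_removed": len(assembly.cases) - len(deduped),
    }
    return deduped, counts


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run log written to disk."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    role_filter = frozenset(config.role_filter)
    log: dict = {"config": config.model_dump(), "stages": {}}

    try:
        dictionary, term_set, catalog = _load_vocabularies(config)
    except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
        raise PipelineError(f"vocabulary: {exc}") from exc

    try:
        cases, counts = ingest(config, dictionary)
        log["stages"]["ingest"] = counts
        faers_io.write_cases(cases, out / "cases.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"ingest: {exc}") from exc

    try:
        screen = disproportionality.run_screen(
            cases, dictionary, term_set, role_filter, config.min_cases, config.continuity
        )
        disproportionality.write_signal_table(screen, dictionary, out / "signals.tsv")
        log["stages"]["screen"] = {
            "drugs_with_cases": len(screen.signals),
            "drugs_without_cases": len(screen.zero_case_drugs),
            "signals": sum(s.is_signal for s in screen.signals),
            "per_drug_cells": {
                s.drug: {"a": s.a, "b": s.b, "c": s.c, "d": s.d} for s in screen.signals
            },
        }
    except Exception as exc:
        raise PipelineError(f"screen: {exc}") from exc

    try:
        reanalysis = confounder_adjustment.reanalyze(
            cases, dictionary, term_set, catalog, role_filter,
            config.min_cases, config.continuity,
        )
        confounder_adjustment.adjusted_frame(reanalysis, dictionary).to_csv(
            out / "signals_adjusted.tsv", sep="\t", index=False
        )
        log["stages"]["adjust"] = {
            "excluded_cases": reanalysis.n_excluded,
            "analyzed_cases": reanalysis.n_cases - reanalysis.n_excluded,
            "verdicts": {
                v: sum(1 for s in reanalysis.adjusted_signals if s.verdict == v)
                for v in (
                    confounder_adjustment.ROBUST_SIGNAL,
                    confounder_adjustment.FALSE_SIGNAL,
                    confounder_adjustment.NO_PRIMARY_SIGNAL,
                )
            },
        }
    except Exception as exc:
        raise PipelineError(f"adjust: {exc}") from exc

    try:
        event_cases = [c for c in cases if not c.event_pts.isdisjoint(term_set.included_pts)]
        blocks = []
        if event_cases:
            for dim in descriptives.DIMENSIONS:
                blocks.append(descriptives.render_markdown(descriptives.summarize(event_cases, dim)))
        text = f"# Event-case descriptives ({len(event_cases)} cases)\n\n" + "\n".join(blocks)
        (out / "descriptives.md").write_text(text)
        log["stages"]["describe"] = {"event_cases": len(event_cases)}
    except Exception as exc:
        raise PipelineError(f"describe: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
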
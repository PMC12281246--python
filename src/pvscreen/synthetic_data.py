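"""Synthetic FAERS-like report streams with analytic ground truth.

The generator emits a de-identified spontaneous-report stream that mimics
the structure of a real quarterly extract: demographic strata (sex, age
band, reporter occupation, region), one Primary Suspected antidepressant
per case drawn from a background frequency table, per-PT adverse-event
background rates, and three planted mechanisms —

* **relative reporting rate λ** per (drug, term set): the probability of
  each term-set PT is multiplied by λ for cases on that drug, so λ > 1
  plants a genuine disproportionality signal and λ = 1 is the null;
* **duplicate versions**: with probability ``duplicate_rate`` a case emits
  an additional *earlier* report version (same ``caseid``, lower version
  ordinal, truncated event list) that deduplication must discard;
* **confounding by indication**: for configured (drug, category) pairs the
  case carries a confounder-category PT as a drug indication *and* a
  term-set event PT — an apparent signal that should dissolve when
  confounded reports are excluded.

Because every mechanism is an independent Bernoulli/categorical draw, the
expected 2×2 cells — and hence the reporting odds ratio each screen should
recover — have closed forms (:func:`expected_cells`, :func:`expected_ror`);
recovery tests compare the screened estimates against these, not against
another simulation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .faers_io import CaseReport, Dialect, DrugEntry
from .vocabulary import SEIZURE_SET_NAME

#: deterministic representative country written for each region stratum
REGION_COUNTRY = {
    "Europe": "GB", "NorthAmerica": "US", "Asia": "JP",
    "Oceania": "AU", "SouthAmerica": "BR", "Africa": "ZA", "unknown": "",
}
REPORTER_CODE = {"health_professional": "MD", "non_health_professional": "CN", "unknown": ""}
SEX_CODE = {"female": "F", "male": "M", "unknown": ""}
AGE_RANGES = {"<18": (2, 18), "18-65": (18, 65), ">=65": (65, 90)}


class SyntheticConfig(BaseModel):
    """Full generative specification of one synthetic report stream."""

    n_cases: int = Field(gt=0)
    seed: int = Field(ge=0)
    sex_probs: dict[str, float]
    age_band_probs: dict[str, float]
    reporter_probs: dict[str, float]
    region_probs: dict[str, float]
    drug_background: dict[str, float]
    event_background: dict[str, float]
    term_set_pts: dict[str, list[str]]
    planted_lambda: dict[str, dict[str, float]] = Field(default_factory=dict)
    duplicate_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    confounded_pairs: dict[str, dict[str, float]] = Field(default_factory=dict)
    confounder_pts: dict[str, list[str]] = Field(default_factory=dict)
    confounded_event_set: str = SEIZURE_SET_NAME
    fallback_pt: str = "90090001"
    indication_background_pt: str = "90080001"
    #: verbatim drug name emitted in the DRUG table for each ATC code; an
    #: unlisted code falls back to the lowercased code itself
    drug_names: dict[str, str] = Field(default_factory=dict)

    @field_validator("sex_probs", "age_band_probs", "reporter_probs", "region_probs", "drug_background")
    @classmethod
    def _sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("negative probability")
        return v

    @field_validator("event_background")
    @classmethod
    def _valid_probs(cls, v: dict[str, float]) -> dict[str, float]:
        if any(not (0 <= p <= 1) for p in v.values()):
            raise ValueError("event probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_lambdas(self) -> "SyntheticConfig":
        for drug, sets in self.planted_lambda.items():
            for set_name, lam in sets.items():
                if not np.isfinite(lam) or lam < 0:
                    raise ValueError(f"λ for ({drug}, {set_name}) must be finite and ≥ 0")
                for pt in self.term_set_pts.get(set_name, []):
                    p = self.event_background.get(pt, 0.0)
                    if p * lam > 1.0:
                        raise ValueError(
                            f"p·λ = {p * lam:.3g} > 1 for PT {pt} under ({drug}, {set_name})"
                        )
        for drug, cats in self.confounded_pairs.items():
            for cat, q in cats.items():
                if not 0 <= q <= 1:
                    raise ValueError(f"confounding probability for ({drug}, {cat}) outside [0, 1]")
        return self

    def lam(self, drug: str, set_name: str) -> float:
        return self.planted_lambda.get(drug, {}).get(set_name, 1.0)


@dataclass
class GroundTruth:
    """Per-case truth table and bookkeeping for one generated stream."""

    config: SyntheticConfig
    case_frame: pd.DataFrame  # one row per distinct case
    n_distinct_cases: int
    n_report_versions: int
    record_counts: dict[str, int]  # rows per quarter table

    def seizure_case_count(self) -> int:
        return int(self.case_frame["has_event"].sum())


# ---------------------------------------------------------------------------
# analytic expectations

def event_probability(config: SyntheticConfig, drug: str, set_name: str) -> float:
    """P(case on ``drug`` reports ≥1 included PT of ``set_name``).

    Combines the independent per-PT Bernoulli draws (λ-scaled for the
    drug) with the forced event from the confounding mechanism.
    """
    miss = 1.0
    lam = config.lam(drug, set_name)
    for pt in config.term_set_pts.get(set_name, []):
        p = config.event_background.get(pt, 0.0)
        miss *= 1.0 - min(p * lam, 1.0)
    p_noconf = 1.0 - miss
    if set_name != config.confounded_event_set:
        return p_noconf
    q_miss = 1.0
    for q in config.confounded_pairs.get(drug, {}).values():
        q_miss *= 1.0 - q
    return 1.0 - (1.0 - p_noconf) * q_miss


def expected_cells(config: SyntheticConfig, drug: str, set_name: str) -> tuple[float, float, float, float]:
    """Expected (a, b, c, d) report counts implied by the generative model."""
    n = config.n_cases
    pi = config.drug_background.get(drug, 0.0)
    s_d = event_probability(config, drug, set_name)
    a = n * pi * s_d
    b = n * pi * (1.0 - s_d)
    c = n * sum(
        p * event_probability(config, other, set_name)
        for other, p in config.drug_background.items()
        if other != drug
    )
    return a, b, c, n - a - b - c


def expected_ror(config: SyntheticConfig, drug: str, set_name: str) -> float:
    """Closed-form reporting odds ratio implied by the generative probabilities."""
    a, b, c, d = expected_cells(config, drug, set_name)
    if a == 0.0:
        return 0.0
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# generation

def _categorical(rng: np.random.Generator, labels: list[str], probs: list[float], n: int) -> np.ndarray:
    return rng.choice(len(labels), size=n, p=np.asarray(probs) / np.sum(probs))


def generate_reports(config: SyntheticConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Draw the report stream; returns all report versions plus ground truth.

    Fully reproducible: a single root seed drives every draw in a fixed
    order.  Duplicate cases appear as two versions — the earlier one keeps
    only the lexicographically first event PT, so retaining the wrong
    version is detectable downstream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    sex_labels = list(config.sex_probs)
    age_labels = list(config.age_band_probs)
    rep_labels = list(config.reporter_probs)
    reg_labels = list(config.region_probs)
    drug_labels = list(config.drug_background)

    sex_i = _categorical(rng, sex_labels, list(config.sex_probs.values()), n)
    age_i = _categorical(rng, age_labels, list(config.age_band_probs.values()), n)
    age_vals = rng.integers(0, 10**6, size=n)  # folded below into band ranges
    rep_i = _categorical(rng, rep_labels, list(config.reporter_probs.values()), n)
    reg_i = _categorical(rng, reg_labels, list(config.region_probs.values()), n)
    drug_i = _categorical(rng, drug_labels, list(config.drug_background.values()), n)

    # per-PT Bernoulli event draws, λ-scaled per (drug, term set)
    pt_in_set: dict[str, str] = {}
    for set_name, pts in config.term_set_pts.items():
        for pt in pts:
            pt_in_set[pt] = set_name
    lam_by_drug: dict[str, np.ndarray] = {}
    for set_name in config.term_set_pts:
        lam_by_drug[set_name] = np.array(
            [config.lam(d, set_name) for d in drug_labels]
        )[drug_i]
    events: list[list[str]] = [[] for _ in range(n)]
    for pt, p in config.event_background.items():
        set_name = pt_in_set.get(pt)
        p_eff = p * lam_by_drug[set_name] if set_name is not None else p
        hits = np.nonzero(rng.random(n) < p_eff)[0]
        for i in hits:
            events[i].append(pt)

    # confounding by indication: forced term-set event + confounder indication
    confounded = np.zeros(n, dtype=bool)
    indications: list[list[str]] = [[config.indication_background_pt] for _ in range(n)]
    conf_set_pts = config.term_set_pts.get(config.confounded_event_set, [])
    for drug, cats in sorted(config.confounded_pairs.items()):
        if drug not in drug_labels:
            continue
        on_drug = drug_i == drug_labels.index(drug)
        for cat, q in sorted(cats.items()):
            hit = on_drug & (rng.random(n) < q)
            idx = np.nonzero(hit)[0]
            if len(idx) == 0:
                continue
            cat_pts = config.confounder_pts.get(cat)
            if not cat_pts:
                raise ValueError(f"confounded pair references category {cat!r} with no PTs configured")
            ind_choice = rng.integers(0, len(cat_pts), size=len(idx))
            ev_choice = rng.integers(0, len(conf_set_pts), size=len(idx))
            for k, i in enumerate(idx):
                indications[i].append(cat_pts[ind_choice[k]])
                events[i].append(conf_set_pts[ev_choice[k]])
            confounded[idx] = True

    dup = rng.random(n) < config.duplicate_rate

    event_set_pts = {s: frozenset(pts) for s, pts in config.term_set_pts.items()}
    seizure_pts = event_set_pts.get(config.confounded_event_set, frozenset())

    reports: list[CaseReport] = []
    truth_rows = []
    n_reac = n_indi = 0
    for i in range(n):
        case_id = f"{10000001 + i}"
        band = age_labels[age_i[i]]
        if band in AGE_RANGES:
            lo, hi = AGE_RANGES[band]
            age: Optional[float] = float(lo + age_vals[i] % (hi - lo))
        else:
            age = None
        evt = frozenset(events[i]) or frozenset({config.fallback_pt})
        ind = frozenset(indications[i])
        latest_version = 2 if dup[i] else 1
        latest = CaseReport(
            case_id=case_id,
            primary_id=f"{case_id}{latest_version}",
            receipt_sequence=latest_version,
            sex=sex_labels[sex_i[i]],
            age_years=age,
            reporter=rep_labels[rep_i[i]],
            region=reg_labels[reg_i[i]],
            drugs=(
                DrugEntry(
                    config.drug_names.get(drug_labels[drug_i[i]], drug_labels[drug_i[i]].lower()),
                    "PS",
                    drug_labels[drug_i[i]],
                ),
            ),
            event_pts=evt,
            indication_pts=ind,
        )
        if dup[i]:
            early_evt = frozenset({min(evt)})
            reports.append(
                CaseReport(
                    case_id=case_id, primary_id=f"{case_id}1", receipt_sequence=1,
                    sex=latest.sex, age_years=age, reporter=latest.reporter,
                    region=latest.region, drugs=latest.drugs,
                    event_pts=early_evt, indication_pts=ind,
                )
            )
            n_reac += 1
            n_indi += len(ind)
        reports.append(latest)
        n_reac += len(evt)
        n_indi += len(ind)
        truth_rows.append({
            "case_id": case_id,
            "drug": drug_labels[drug_i[i]],
            "has_event": not evt.isdisjoint(seizure_pts),
            "confounded": bool(confounded[i]),
            "sex": latest.sex,
            "age_band": band,
            "reporter": latest.reporter,
            "region": latest.region,
            "duplicate": bool(dup[i]),
        })

    n_versions = len(reports)
    truth = GroundTruth(
        config=config,
        case_frame=pd.DataFrame(truth_rows),
        n_distinct_cases=n,
        n_report_versions=n_versions,
        record_counts={"DEMO": n_versions, "DRUG": n_versions, "REAC": n_reac, "INDI": n_indi},
    )
    return reports, truth


def latest_cases(reports: list[CaseReport]) -> list[CaseReport]:
    """Ground-truth deduplicated view (latest version per case), in case order."""
    best: dict[str, CaseReport] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None or r.receipt_sequence > cur.receipt_sequence:
            best[r.case_id] = r
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# quarter-file emission

_HEADERS = {
    "DEMO": ["primaryid", "caseid", "caseversion", "sex", "age", "age_cod", "occp_cod", "occr_country"],
    "DRUG": ["primaryid", "caseid", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "INDI": ["primaryid", "caseid", "indi_pt"],
}
_FILENAMES = {"DEMO": "demo.txt", "DRUG": "drug.txt", "REAC": "reac.txt", "INDI": "indi.txt"}


def write_quarter(
    reports: list[CaseReport], outdir: str | Path, dialect: Dialect | None = None
) -> dict[str, Path]:
    """Write the report versions as the four quarter tables."""
    dialect = dialect or Dialect()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {t: outdir / _FILENAMES[t] for t in _HEADERS}
    handles = {t: open(p, "w", newline="") for t, p in paths.items()}
    try:
        writers = {
            t: csv.writer(fh, delimiter=dialect.sep, quoting=csv.QUOTE_NONE, lineterminator="\n")
            for t, fh in handles.items()
        }
        for t, w in writers.items():
            w.writerow(_HEADERS[t])
        for r in reports:
            age = "" if r.age_years is None else f"{r.age_years:g}"
            writers["DEMO"].writerow([
                r.primary_id, r.case_id, r.receipt_sequence, SEX_CODE[r.sex], age,
                "YR" if age else "", REPORTER_CODE[r.reporter], REGION_COUNTRY[r.region],
            ])
            for d in r.drugs:
                writers["DRUG"].writerow([r.primary_id, r.case_id, d.role, d.raw_name])
            for pt in sorted(r.event_pts):
                writers["REAC"].writerow([r.primary_id, r.case_id, pt])
            for pt in sorted(r.indication_pts):
                writers["INDI"].writerow([r.primary_id, r.case_id, pt])
    finally:
        for fh in handles.values():
            fh.close()
    return paths


def generate(
    config: SyntheticConfig, outdir: str | Path, dialect: Dialect | None = None
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a stream and write it as quarter files plus ground truth."""
    reports, truth = generate_reports(config)
    paths = write_quarter(reports, outdir, dialect)
    truth.case_frame.to_csv(Path(outdir) / "ground_truth.tsv", sep="\t", index=False)
    return paths, truth


# ---------------------------------------------------------------------------
# study-conditions default

#: drug-background weights: per-drug report totals of the eight most-reported
#: antidepressants in the source database (bupropion, duloxetine, venlafaxine,
#: mirtazapine, vortioxetine, sertraline, citalopram, fluoxetine)
_DRUG_WEIGHTS = {
    "N06AX12": 25939, "N06AX21": 50946, "N06AX16": 37846, "N06AX11": 16159,
    "N06AX26": 11933, "N06AB06": 46492, "N06AB04": 23058, "N06AB03": 22600,
}
_DRUG_NAMES = {
    "N06AX12": "bupropion", "N06AX21": "duloxetine", "N06AX16": "venlafaxine",
    "N06AX11": "mirtazapine", "N06AX26": "vortioxetine", "N06AB06": "sertraline",
    "N06AB04": "citalopram", "N06AB03": "fluoxetine",
}
#: Table-1 stratum counts (seizure cases, total 7393)
_SEX_W = {"female": 4028, "male": 2263, "unknown": 1102}
_AGE_W = {"<18": 853, "18-65": 3662, ">=65": 799, "unknown": 2079}
_REP_W = {"health_professional": 5172, "non_health_professional": 1933, "unknown": 288}
_REG_W = {
    "Europe": 1583, "NorthAmerica": 647, "Asia": 169, "Oceania": 24,
    "SouthAmerica": 8, "Africa": 2, "unknown": 4960,
}

#: four emitted seizure PTs (subset of the bundled 41-PT skeleton) at a
#: combined ≈2% per-case marginal — the null constituent-ratio level of the
#: non-bupropion drugs in the printed per-drug table
_SEIZURE_PTS = ["90010001", "90010002", "90010003", "90010004"]
_SEIZURE_P = 0.005
_FILLER_PTS = {"90090001": 0.60, "90090002": 0.30, "90090003": 0.15, "90090004": 0.08}


def _norm(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    out = {k: v / total for k, v in weights.items()}
    # absorb float residue so the vector sums to 1 exactly
    first = next(iter(out))
    out[first] += 1.0 - sum(out.values())
    return out


def default_config(
    n_cases: int,
    seed: int,
    planted_lambda: dict[str, dict[str, float]] | None = None,
    confounded_pairs: dict[str, dict[str, float]] | None = None,
    duplicate_rate: float = 0.1,
) -> SyntheticConfig:
    """Study-conditions configuration: Table-1 strata, top-8 drug background,
    ≈2% seizure marginal, 10% duplicate-version rate."""
    event_background = {pt: _SEIZURE_P for pt in _SEIZURE_PTS}
    event_background.update(_FILLER_PTS)
    return SyntheticConfig(
        n_cases=n_cases,
        seed=seed,
        sex_probs=_norm(_SEX_W),
        age_band_probs=_norm(_AGE_W),
        reporter_probs=_norm(_REP_W),
        region_probs=_norm(_REG_W),
        drug_background=_norm(_DRUG_WEIGHTS),
        event_background=event_background,
        term_set_pts={SEIZURE_SET_NAME: list(_SEIZURE_PTS)},
        planted_lambda=planted_lambda or {},
        duplicate_rate=duplicate_rate,
        confounded_pairs=confounded_pairs or {},
        confounder_pts={"seizures_history": ["90030001", "90030002", "90030003"]},
        drug_names=dict(_DRUG_NAMES),
    )
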
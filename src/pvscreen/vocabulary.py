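"""Drug dictionary (ATC N06A antidepressants) and MedDRA PT term sets.

Two controlled vocabularies drive the screen: a dictionary mapping verbatim
drug names to WHO ATC codes within the antidepressant class (N06A), and
named sets of MedDRA preferred terms (PTs) — a seizure SMQ-style set with
explicit exclusions, and a catalog of confounding co-existing-condition
categories.

Genuine MedDRA PT lists are licensed and cannot ship with the package; the
bundled term-set fixtures are *synthetic skeletons* with the documented set
sizes (84 seizure candidates minus 43 exclusions → 41 included; confounder
categories of 81/30/215/115/181 PTs) built on placeholder ``9xxxxxxx``
codes.  The loaders accept user-supplied TSV exports of the real thing in
the same shape.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

SEIZURE_SET_NAME = "seizure_smq_narrow"
SEIZURE_SMQ_CODE = "10039911"

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]")


class VocabularyError(ValueError):
    """A vocabulary file is internally inconsistent."""


def _normalize_name(raw: str) -> str:
    return _WS.sub(" ", _PUNCT.sub(" ", raw.casefold())).strip()


@dataclass
class DrugDictionary:
    """Verbatim-name → ATC lookup restricted to one ATC class prefix."""

    entries: dict[str, str]
    drug_labels: dict[str, str]
    atc_class_prefix: str = "N06A"
    rejected_rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def atc_codes(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def label(self, atc_code: str) -> str:
        return self.drug_labels.get(atc_code, atc_code)


def load_drug_dictionary(path: str | Path, atc_class_prefix: str = "N06A") -> DrugDictionary:
    """Load a TSV drug dictionary (columns raw_name, atc_code, display_name).

    Rows whose ATC code falls outside ``atc_class_prefix`` are rejected and
    reported; a raw name mapped to two conflicting codes is fatal.
    """
    entries: dict[str, str] = {}
    labels: dict[str, str] = {}
    rejected: list[tuple[str, str]] = []
    conflicts: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            raw, atc = row["raw_name"].strip(), row["atc_code"].strip().upper()
            if not atc.startswith(atc_class_prefix):
                rejected.append((raw, atc))
                continue
            key = _normalize_name(raw)
            if key in entries and entries[key] != atc:
                conflicts.append(raw)
                continue
            entries[key] = atc
            labels.setdefault(atc, row.get("display_name", "").strip() or raw)
    if conflicts:
        raise VocabularyError(f"conflicting ATC mappings for raw name(s): {sorted(conflicts)}")
    if rejected:
        logger.warning("drug dictionary: %d row(s) outside %s rejected", len(rejected), atc_class_prefix)
    return DrugDictionary(entries, labels, atc_class_prefix, rejected)


def normalize_drug(raw_name: str, dictionary: DrugDictionary) -> Optional[str]:
    """Exact dictionary lookup after case-folding, whitespace collapsing and
    punctuation stripping; no fuzzy matching — a miss returns ``None``."""
    return dictionary.entries.get(_normalize_name(raw_name))


@dataclass(frozen=True)
class TermSet:
    """A named set of MedDRA PT codes with explicit inclusions and exclusions."""

    name: str
    included_pts: frozenset[str]
    excluded_pts: frozenset[str] = frozenset()
    smq_code: Optional[str] = None
    pt_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.included_pts:
            raise VocabularyError(f"term set {self.name!r} has no included PTs")
        if self.included_pts & self.excluded_pts:
            raise VocabularyError(f"term set {self.name!r}: inclusion/exclusion overlap")


def build_term_set(
    name: str,
    smq_code: Optional[str],
    candidate_pts: Iterable[str],
    exclusions: Iterable[str] = (),
    pt_labels: Mapping[str, str] | None = None,
) -> TermSet:
    """Subtract the exclusion list from the candidate PTs of an SMQ-style set.

    Mirrors how a query's raw term list is narrowed to drug-attributable
    events: ``included = candidates \\ exclusions``.  An empty result is
    fatal — a term set that matches nothing cannot define an endpoint.
    """
    candidates = frozenset(candidate_pts)
    excluded = frozenset(exclusions)
    included = candidates - excluded
    if not included:
        raise VocabularyError(f"term set {name!r}: all candidate PTs excluded")
    logger.info(
        "term set %s: %d candidates, %d excluded, %d included",
        name, len(candidates), len(excluded & candidates), len(included),
    )
    return TermSet(name, included, excluded, smq_code, dict(pt_labels or {}))


def load_term_sets(path: str | Path) -> dict[str, TermSet]:
    """Load TSV term sets (columns set_name, pt_code, pt_label, status).

    ``status`` is ``include`` or ``exclude``; each distinct set_name yields
    one :class:`TermSet` via :func:`build_term_set`.
    """
    candidates: dict[str, set[str]] = {}
    exclusions: dict[str, set[str]] = {}
    labels: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name, pt, status = row["set_name"].strip(), row["pt_code"].strip(), row["status"].strip()
            if status not in ("include", "exclude"):
                raise VocabularyError(f"bad status {status!r} for PT {pt} in set {name}")
            candidates.setdefault(name, set()).add(pt)
            if status == "exclude":
                exclusions.setdefault(name, set()).add(pt)
            labels.setdefault(name, {})[pt] = row.get("pt_label", "").strip()
    return {
        name: build_term_set(
            name,
            SEIZURE_SMQ_CODE if name == SEIZURE_SET_NAME else None,
            cands,
            exclusions.get(name, set()),
            labels[name],
        )
        for name, cands in candidates.items()
    }


@dataclass(frozen=True)
class ConfounderCatalog:
    """Ordered categories of co-existing conditions that can mimic a drug signal."""

    categories: tuple[TermSet, ...]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.categories]

    def category(self, name: str) -> TermSet:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    def all_pts(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.categories:
            out |= c.included_pts
        return frozenset(out)


def load_confounder_catalog(path: str | Path) -> ConfounderCatalog:
    sets = load_term_sets(path)
    return ConfounderCatalog(tuple(sets[name] for name in sets))


# ---------------------------------------------------------------------------
# bundled fixtures

def _data_path(name: str) -> Path:
    return Path(str(resources.files("pvscreen").joinpath("data", name)))


def default_drug_dictionary() -> DrugDictionary:
    """The bundled 65-antidepressant (ATC N06A) dictionary with brand synonyms."""
    return load_drug_dictionary(_data_path("antidepressants_n06a.tsv"))


def default_seizure_term_set() -> TermSet:
    """The bundled synthetic seizure SMQ skeleton (84 candidates → 41 included)."""
    return load_term_sets(_data_path("seizure_smq_synthetic.tsv"))[SEIZURE_SET_NAME]


def default_confounder_catalog() -> ConfounderCatalog:
    """The bundled synthetic five-category confounder catalog (81/30/215/115/181 PTs)."""
    return load_confounder_catalog(_data_path("confounder_catalog_synthetic.tsv"))


def default_country_regions() -> dict[str, str]:
    """Bundled ISO country-code → continent lookup used for Table-1-style strata."""
    out: dict[str, str] = {}
    with open(_data_path("country_regions.tsv"), newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["country_code"].strip().upper()] = row["region"].strip()
    return out
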
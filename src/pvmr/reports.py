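"""Spontaneous adverse-event report store.

Models one report from a spontaneous reporting system (SRS) such as FAERS,
JADER or CVARD at the MedDRA Preferred Term (PT) level: the drugs listed on
the report, the coded adverse events, demographics and outcome.  Provides
delimited-text ingest with a user-supplied column mapping, rule-based
deduplication on the composite key (report id, sex, country), age-band
coding, and a canonical TSV serialization (one row per report x PT).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

OUTCOMES = frozenset(
    {"death", "disability", "hospitalization", "life_threatening", "other", "unknown"}
)

_SEX_ALIASES = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
    "u": "unknown",
    "unk": "unknown",
    "unknown": "unknown",
    "": "unknown",
}

MAX_AGE = 130.0


@dataclass(frozen=True, slots=True)
class ReportRecord:
    """One spontaneous AE report after ingest normalization."""

    report_id: str
    case_version: int = 0
    drugs: frozenset[str] = frozenset()
    pts: frozenset[tuple[int, str]] = frozenset()
    age_years: float | None = None
    sex: str = "unknown"
    country: str | None = None
    outcome: frozenset[str] = frozenset({"unknown"})
    receipt_date: date | None = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be nonempty")
        if self.case_version < 0:
            raise ValueError("case_version must be >= 0")
        if self.age_years is not None and not (0.0 <= self.age_years <= MAX_AGE):
            raise ValueError(f"age_years out of [0, {MAX_AGE}]: {self.age_years}")
        if self.sex not in {"female", "male", "unknown"}:
            raise ValueError(f"invalid sex: {self.sex!r}")
        bad = set(self.outcome) - OUTCOMES
        if bad:
            raise ValueError(f"invalid outcome values: {sorted(bad)}")

    @property
    def pt_codes(self) -> frozenset[int]:
        return frozenset(code for code, _ in self.pts)

    @property
    def dedup_key(self) -> tuple[str, str, str | None]:
        return (self.report_id, self.sex, self.country)

    def has_drug(self, drug: str) -> bool:
        return normalize_drug_name(drug) in self.drugs

    def has_pt(self, pt: int | str) -> bool:
        if isinstance(pt, int):
            return pt in self.pt_codes
        return any(name == pt for _, name in self.pts)


@dataclass(slots=True)
class ReportSet:
    """A collection of reports with source provenance and ingest counters."""

    records: list[ReportRecord]
    provenance: str = "unspecified"
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter_pt(self, pt: int | str) -> "ReportSet":
        kept = [r for r in self.records if r.has_pt(pt)]
        return ReportSet(kept, self.provenance, dict(self.counts))

    def filter_drug(self, drug: str) -> "ReportSet":
        kept = [r for r in self.records if r.has_drug(drug)]
        return ReportSet(kept, self.provenance, dict(self.counts))


def normalize_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Lower-case, collapse internal whitespace, then apply the synonym map."""
    norm = re.sub(r"\s+", " ", name.strip().lower())
    if synonyms:
        norm = synonyms.get(norm, norm)
    return norm


def _parse_age(raw) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "na", "none", "unknown"}:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    if math.isnan(v) or v < 0 or v > MAX_AGE:
        return None
    return v


def _parse_date(raw) -> date | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "na", "none"}:
        return None
    try:
        return date.fromisoformat(s[:10])
    except ValueError:
        return None


def _split_multi(cell, sep: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    return [p.strip() for p in str(cell).split(sep) if p.strip()]


class SchemaError(ValueError):
    """Raised when the column-mapping config does not match the input table."""


#: canonical schema used by :func:`to_tsv` / round-trip ingest
CANONICAL_SCHEMA = {
    "columns": {
        "report_id": "report_id",
        "case_version": "case_version",
        "drug": "drugs",
        "pt_code": "pt_code",
        "pt_name": "pt_name",
        "age": "age_years",
        "sex": "sex",
        "country": "country",
        "outcome": "outcome",
        "date": "receipt_date",
    },
    "list_separator": ";",
}

_REQUIRED = ("report_id", "drug", "pt_code", "sex")


def parse_reports(
    rows: pd.DataFrame | str | Path,
    schema: Mapping,
    provenance: str = "unspecified",
) -> ReportSet:
    """Ingest a delimited-text report table under a column-mapping config.

    ``schema`` keys: ``columns`` (logical name -> source column; logical names
    ``report_id, drug, pt_code, sex`` are required, ``case_version, pt_name,
    age, country, outcome, date`` optional), ``list_separator`` for
    multi-valued drug/PT/outcome cells, and an optional ``drug_synonyms``
    mapping applied after lower-casing (generic-name standardization).

    Rows lacking a report id or any PT code are counted and skipped; an
    unparseable age leaves the field missing but keeps the row.  Rows sharing
    a report id (canonical one-row-per-PT serialization) are merged into a
    single record.
    """
    if not isinstance(rows, pd.DataFrame):
        path = Path(rows)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
        rows = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    cols = dict(schema.get("columns", {}))
    for logical in _REQUIRED:
        if logical not in cols:
            raise SchemaError(f"schema missing required column mapping: {logical!r}")
        if cols[logical] not in rows.columns:
            raise SchemaError(
                f"required column {cols[logical]!r} (for {logical!r}) not in input"
            )
    for logical, source in cols.items():
        if source not in rows.columns:
            raise SchemaError(f"mapped column {source!r} (for {logical!r}) not in input")

    sep = schema.get("list_separator", ";")
    synonyms = {
        normalize_drug_name(k): normalize_drug_name(v)
        for k, v in (schema.get("drug_synonyms") or {}).items()
    }

    def col(logical: str, row) -> str | None:
        src = cols.get(logical)
        return None if src is None else row[src]

    n_skipped = 0
    merged: dict[tuple, dict] = {}
    order: list[tuple] = []
    for _, row in rows.iterrows():
        rid = (col("report_id", row) or "").strip()
        pt_codes_raw = _split_multi(col("pt_code", row), sep)
        pt_codes: list[int] = []
        for c in pt_codes_raw:
            try:
                pt_codes.append(int(float(c)))
            except ValueError:
                pass
        if not rid or not pt_codes:
            n_skipped += 1
            continue
        pt_names = _split_multi(col("pt_name", row), sep) if "pt_name" in cols else []
        pts = {
            (code, pt_names[i] if i < len(pt_names) else "")
            for i, code in enumerate(pt_codes)
        }
        drugs = {
            normalize_drug_name(d, synonyms) for d in _split_multi(col("drug", row), sep)
        }
        try:
            version = int(float(col("case_version", row) or 0))
        except (ValueError, TypeError):
            version = 0
        sex = _SEX_ALIASES.get(str(col("sex", row) or "").strip().lower(), "unknown")
        country = (str(col("country", row) or "").strip() or None) if "country" in cols else None
        outcome = frozenset(
            o.lower() for o in _split_multi(col("outcome", row), sep) if o.lower() in OUTCOMES
        ) or frozenset({"unknown"})
        age = _parse_age(col("age", row)) if "age" in cols else None
        rdate = _parse_date(col("date", row)) if "date" in cols else None

        key = (rid, version, sex, country, rdate)
        if key not in merged:
            merged[key] = {
                "report_id": rid,
                "case_version": version,
                "drugs": set(drugs),
                "pts": set(pts),
                "age_years": age,
                "sex": sex,
                "country": country,
                "outcome": set(outcome),
                "receipt_date": rdate,
            }
            order.append(key)
        else:
            m = merged[key]
            m["drugs"] |= drugs
            m["pts"] |= pts
            m["outcome"] |= outcome
            if m["age_years"] is None:
                m["age_years"] = age

    records = []
    for key in order:
        m = merged[key]
        outcome = set(m["outcome"])
        if len(outcome) > 1:
            outcome.discard("unknown")
        records.append(
            ReportRecord(
                report_id=m["report_id"],
                case_version=m["case_version"],
                drugs=frozenset(m["drugs"]),
                pts=frozenset(m["pts"]),
                age_years=m["age_years"],
                sex=m["sex"],
                country=m["country"],
                outcome=frozenset(outcome),
                receipt_date=m["receipt_date"],
            )
        )
    counts = {"n_ingested": len(records), "n_skipped": n_skipped}
    log.info("parse_reports: %d records ingested, %d rows skipped", len(records), n_skipped)
    return ReportSet(records, provenance, counts)


def deduplicate(rs: ReportSet) -> ReportSet:
    """Collapse records sharing (report_id, sex, country) to one survivor.

    The survivor is the record with the highest case version; ties are broken
    by latest receipt date, then by last occurrence in file order.
    """
    best: dict[tuple, tuple[tuple, int]] = {}
    for idx, rec in enumerate(rs.records):
        rank = (rec.case_version, rec.receipt_date or date.min, idx)
        key = rec.dedup_key
        if key not in best or rank > best[key][0]:
            best[key] = (rank, idx)
    keep = sorted(idx for _, idx in best.values())
    records = [rs.records[i] for i in keep]
    removed = len(rs.records) - len(records)
    counts = dict(rs.counts)
    counts.update({"n_after_dedup": len(records), "n_duplicates_removed": removed})
    log.info("deduplicate: %d survivors, %d removed", len(records), removed)
    return ReportSet(records, rs.provenance, counts)


# age-band schemes: (lower-inclusive, upper-exclusive, label)
_INF = float("inf")
DESCRIPTIVE_BANDS: tuple[tuple[float, float, str], ...] = (
    (0, 12, "0–11"),
    (12, 18, "12–17"),
    (18, 35, "18–34"),
    (35, 65, "35–64"),
    (65, 80, "65–79"),
    (80, _INF, "≥80"),
)
REGRESSION_BANDS: tuple[tuple[float, float, str], ...] = (
    (0, 18, "<18"),
    (18, 45, "18–44"),
    (45, 66, "45–65"),
    (66, _INF, ">65"),
)
AGE_SCHEMES = {"descriptive": DESCRIPTIVE_BANDS, "regression": REGRESSION_BANDS}


def assign_age_band(
    age_years: float | None,
    scheme: str = "descriptive",
    labels: Sequence[str] | None = None,
) -> str:
    """Map an age to its band label under the named scheme.

    Bands are half-open ``[low, high)`` so every age in [0, 130] falls in
    exactly one band.  Missing age maps to ``"unknown"``; negative age is a
    domain error.  ``labels`` overrides the default band labels (same order).
    """
    bands = AGE_SCHEMES.get(scheme)
    if bands is None:
        raise ValueError(f"unknown age-band scheme: {scheme!r}")
    if labels is not None and len(labels) != len(bands):
        raise ValueError("labels length must match number of bands")
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "unknown"
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    for i, (lo, hi, lab) in enumerate(bands):
        if lo <= age_years < hi:
            return labels[i] if labels is not None else lab
    raise AssertionError("unreachable: bands partition [0, inf)")


def demographic_summary(rs: ReportSet) -> pd.DataFrame:
    """Tabulate sex, descriptive age band, outcome and country.

    Returns one row per (section, level) with the count ``n`` and the
    percentage of all reports ``pct`` (0–100 scale).
    """
    n_total = len(rs.records)
    if n_total == 0:
        raise ValueError("empty ReportSet")
    rows = []

    def tally(section: str, values: Iterable[str]) -> None:
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        for level, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append((section, level, n, 100.0 * n / n_total))

    tally("sex", (r.sex for r in rs.records))
    tally("age_band", (assign_age_band(r.age_years, "descriptive") for r in rs.records))
    outcome_vals = []
    for r in rs.records:
        outcome_vals.extend(sorted(r.outcome))
    tally("outcome", outcome_vals)
    tally("country", (r.country or "unknown" for r in rs.records))
    return pd.DataFrame(rows, columns=["section", "level", "n", "pct"])


def to_tsv(rs: ReportSet, path: str | Path, sidecar: bool = True) -> None:
    """Write the canonical serialization: one row per (report, PT) plus a
    JSON sidecar (``<path>.json``) of provenance counts."""
    path = Path(path)
    rows = []
    for r in rs.records:
        for code, name in sorted(r.pts):
            rows.append(
                {
                    "report_id": r.report_id,
                    "case_version": r.case_version,
                    "drugs": ";".join(sorted(r.drugs)),
                    "pt_code": code,
                    "pt_name": name,
                    "age_years": "" if r.age_years is None else repr(r.age_years),
                    "sex": r.sex,
                    "country": r.country or "",
                    "outcome": ";".join(sorted(r.outcome)),
                    "receipt_date": r.receipt_date.isoformat() if r.receipt_date else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {"provenance": rs.provenance, "counts": rs.counts}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def from_tsv(path: str | Path) -> ReportSet:
    """Read the canonical serialization written by :func:`to_tsv`."""
    provenance = "unspecified"
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", provenance)
    return parse_reports(Path(path), CANONICAL_SCHEMA, provenance=provenance)
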
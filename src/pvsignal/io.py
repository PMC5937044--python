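"""Ingest of the four case tables and case-level exclusion rules.

Spontaneous-report extracts arrive as four linked CSVs keyed by case ID:
demographics (sex, decade-binned age), drugs (name + involvement role),
reactions (PT + outcome) and primary disease. Reports with a blank sex, a
blank or "subjective" age category (tokens like "youth"/"elderly" instead of
a decade bin), or no primary-disease information are excluded before
analysis; every included case is assigned an age stratum (elderly = decade
bin 60s and above). Exclusion reasons are attributed by a fixed priority
order — missing sex, then unusable age, then missing primary disease — so
the exclusion log is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import pandas as pd

from pvsignal.errors import InputError
from pvsignal.hierarchy import TermHierarchy

DEFAULT_SUBJECTIVE_TOKENS = frozenset({"youth", "elderly"})
ELDERLY_DECADE_THRESHOLD = 60

REQUIRED_COLUMNS = {
    "demo": ("case_id", "sex", "age"),
    "drug": ("case_id", "drug_name", "role"),
    "reac": ("case_id", "pt", "outcome"),
    "hist": ("case_id", "primary_disease"),
}


@dataclass(frozen=True)
class ParsedAge:
    """Result of parsing one raw age-category token."""

    kind: Literal["decade", "subjective", "missing"]
    decade: int | None = None


@dataclass
class CaseRecord:
    """One report, fully joined across the four tables."""

    case_id: str
    sex: str | None
    age_category: str
    stratum: Literal["elderly", "non_elderly", "excluded"]
    drugs: list[tuple[str, str]]          # (name, role)
    reactions: list[tuple[str, str]]      # (pt, outcome)
    has_primary_disease: bool


@dataclass
class RawTables:
    """The four tables as read, rows preserved verbatim."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame


@dataclass
class AnalysisDataset:
    """Included cases with stratum labels plus the exclusion audit log."""

    demo: pd.DataFrame                     # case_id, sex, age, decade, stratum
    drugs: pd.DataFrame                    # restricted to included cases
    reactions: pd.DataFrame                # restricted to included cases
    exclusion_log: dict[str, int]
    n_raw: int

    @property
    def n_elderly(self) -> int:
        return int((self.demo["stratum"] == "elderly").sum())

    @property
    def n_non_elderly(self) -> int:
        return int((self.demo["stratum"] == "non_elderly").sum())

    @property
    def n_included(self) -> int:
        return len(self.demo)

    def case_records(self) -> Iterator[CaseRecord]:
        """Yield joined CaseRecord views (intended for small datasets/audits)."""
        drugs_by_case: dict[str, list[tuple[str, str]]] = {}
        for cid, name, role in self.drugs[["case_id", "drug_name", "role"]].itertuples(index=False):
            drugs_by_case.setdefault(cid, []).append((name, role))
        reac_by_case: dict[str, list[tuple[str, str]]] = {}
        for cid, pt, outcome in self.reactions[["case_id", "pt", "outcome"]].itertuples(index=False):
            reac_by_case.setdefault(cid, []).append((pt, outcome))
        for cid, sex, age, stratum in self.demo[["case_id", "sex", "age", "stratum"]].itertuples(index=False):
            yield CaseRecord(
                case_id=cid,
                sex=sex or None,
                age_category=age,
                stratum=stratum,
                drugs=drugs_by_case.get(cid, []),
                reactions=reac_by_case.get(cid, []),
                has_primary_disease=True,
            )


def _read_one(path: str | Path, table: str, encoding: str,
              column_map: dict[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{table} table not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding=encoding)
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = set(REQUIRED_COLUMNS[table]) - set(frame.columns)
    if missing:
        raise InputError(
            f"{table} table {path} lacks required columns {sorted(missing)}; "
            f"found {list(frame.columns)}"
        )
    return frame[list(REQUIRED_COLUMNS[table])]


def load_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path,
    encoding: str = "utf-8",
    column_maps: dict[str, dict[str, str]] | None = None,
) -> RawTables:
    """Read the four CSVs; columns are matched by name, not position.

    ``column_maps`` optionally maps canonical column names to the actual
    headers per table (``{"demo": {"case_id": "識別番号", ...}, ...}``), so
    real extracts with localized headers can be ingested unchanged. Use
    ``encoding="cp932"`` for Shift-JIS extracts.
    """
    column_maps = column_maps or {}
    return RawTables(
        demo=_read_one(demo_path, "demo", encoding, column_maps.get("demo")),
        drug=_read_one(drug_path, "drug", encoding, column_maps.get("drug")),
        reac=_read_one(reac_path, "reac", encoding, column_maps.get("reac")),
        hist=_read_one(hist_path, "hist", encoding, column_maps.get("hist")),
    )


def load_data_dir(
    data_dir: str | Path,
    encoding: str = "utf-8",
    column_maps: dict[str, dict[str, str]] | None = None,
) -> tuple[RawTables, TermHierarchy]:
    """Convenience loader for a directory written by the generator."""
    d = Path(data_dir)
    tables = load_tables(
        d / "demo.csv", d / "drug.csv", d / "reac.csv", d / "hist.csv",
        encoding=encoding, column_maps=column_maps,
    )
    return tables, TermHierarchy.read(d / "hierarchy.tsv", encoding=encoding)


def parse_age_category(
    token: str,
    subjective_tokens: frozenset[str] | set[str] = DEFAULT_SUBJECTIVE_TOKENS,
) -> ParsedAge:
    """Parse a raw age token into a decade lower bound, or flag it unusable.

    Decade bins are written "20s" ... "80s", with "90s+" for the open top
    bin; the numeric prefix is the bin's lower bound. Blank tokens are
    missing; configured subjective tokens — and any token that is not a
    decade bin — are treated as subjective (unusable), which is how they
    enter the exclusion log.
    """
    token = (token or "").strip()
    if not token:
        return ParsedAge("missing")
    if token in subjective_tokens:
        return ParsedAge("subjective")
    stem = token.rstrip("+")
    if stem.endswith("s") and stem[:-1].isdigit():
        return ParsedAge("decade", int(stem[:-1]))
    return ParsedAge("subjective")


def assign_stratum(decade: int) -> Literal["elderly", "non_elderly"]:
    """Elderly = decade bin 60s and above; below is non-elderly.

    Ages come decade-binned, so the boundary is drawn at bin level: the 60s
    bin and every higher bin count as elderly.
    """
    return "elderly" if decade >= ELDERLY_DECADE_THRESHOLD else "non_elderly"


def filter_quarters(tables: RawTables, start: str, end: str,
                    column: str = "quarter") -> RawTables:
    """Optional report-quarter window filter (e.g. "2004Q1".."2015Q4").

    Applied only when the demographics table carries the quarter column;
    lexicographic comparison is correct for the "YYYYQn" format.
    """
    if column not in tables.demo.columns:
        return tables
    keep = tables.demo[column].between(start, end)
    kept_ids = set(tables.demo.loc[keep, "case_id"])
    return RawTables(
        demo=tables.demo[keep].reset_index(drop=True),
        drug=tables.drug[tables.drug["case_id"].isin(kept_ids)].reset_index(drop=True),
        reac=tables.reac[tables.reac["case_id"].isin(kept_ids)].reset_index(drop=True),
        hist=tables.hist[tables.hist["case_id"].isin(kept_ids)].reset_index(drop=True),
    )


def apply_exclusions(
    tables: RawTables,
    subjective_tokens: frozenset[str] | set[str] = DEFAULT_SUBJECTIVE_TOKENS,
) -> AnalysisDataset:
    """Drop unusable reports and stratify the rest by age.

    A case is excluded iff its sex is blank, its age is blank/subjective, or
    it has no row in the primary-disease table; each exclusion is attributed
    to the first matching reason in that order. Included + excluded always
    equals the raw case count.
    """
    demo = tables.demo.copy()
    n_raw = len(demo)

    parsed = demo["age"].map(lambda t: parse_age_category(t, subjective_tokens))
    demo["decade"] = [p.decade for p in parsed]
    age_bad = pd.Series([p.kind != "decade" for p in parsed], index=demo.index)
    sex_missing = demo["sex"].str.strip() == ""
    has_hist = demo["case_id"].isin(set(tables.hist["case_id"]))

    excl_sex = sex_missing
    excl_age = ~sex_missing & age_bad
    excl_hist = ~sex_missing & ~age_bad & ~has_hist
    included = ~(excl_sex | excl_age | excl_hist)

    log = {
        "missing_sex": int(excl_sex.sum()),
        "missing_or_subjective_age": int(excl_age.sum()),
        "missing_primary_disease": int(excl_hist.sum()),
    }

    demo = demo[included].reset_index(drop=True)
    demo["decade"] = demo["decade"].astype(int)
    demo["stratum"] = demo["decade"].map(assign_stratum)
    ids = set(demo["case_id"])
    return AnalysisDataset(
        demo=demo,
        drugs=tables.drug[tables.drug["case_id"].isin(ids)].reset_index(drop=True),
        reactions=tables.reac[tables.reac["case_id"].isin(ids)].reset_index(drop=True),
        exclusion_log=log,
        n_raw=n_raw,
    )
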
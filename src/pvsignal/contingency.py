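"""HLGT-level 2x2 contingency tables of drug exposure x event occurrence.

The counting unit is the CASE: a case is exposed if at least one of its drug
rows matches the target drug set under the configured role filter
(suspected-drug rows only, by default), and it has an event if at least one
of its reactions maps to the HLGT — multiple PTs of one case that fall into
the same HLGT count once. For each (stratum, HLGT) the cells are

    a (n11): exposed cases with the event      b: exposed without it
    c: unexposed cases with the event          d: unexposed without it

so a+b+c+d equals the stratum's case count. The event universe is every
HLGT with at least one report in either stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from pvsignal.hierarchy import TermHierarchy
from pvsignal.io import AnalysisDataset, CaseRecord

DEFAULT_TARGET_DRUGS = frozenset({"zolpidem", "eszopiclone", "zopiclone"})


def normalize_drug_name(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class ExposureDefinition:
    """Which drug rows constitute exposure.

    The three Z-drugs are pooled into one exposure class by default, and
    only rows with a "suspected" involvement role count. ``synonyms`` maps
    normalized spellings (brand names etc.) onto canonical names before
    matching.
    """

    drug_names: frozenset[str] = DEFAULT_TARGET_DRUGS
    roles: frozenset[str] = frozenset({"suspected"})
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.drug_names:
            raise ValueError("exposure definition needs a non-empty drug set")

    def matches(self, name: str, role: str) -> bool:
        canon = normalize_drug_name(name)
        canon = self.synonyms.get(canon, canon)
        return canon in {normalize_drug_name(d) for d in self.drug_names} and role in self.roles


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure x event cells; ``corrected`` marks the +0.5 adjustment."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def map_events_to_hlgt(case: CaseRecord, hierarchy: TermHierarchy) -> set[str]:
    """Deduplicated set of HLGTs a case's reactions map to.

    Unmapped PTs are dropped from counting with a warning.
    """
    out: set[str] = set()
    for pt, _outcome in case.reactions:
        hlgt = hierarchy.hlgt_of(pt)
        if hlgt is None:
            warnings.warn(f"PT {pt!r} not present in the hierarchy; reaction dropped")
            continue
        out.add(hlgt)
    return out


def exposed_case_ids(dataset: AnalysisDataset, exposure: ExposureDefinition) -> set[str]:
    drugs = dataset.drugs
    if drugs.empty:
        return set()
    mask = [exposure.matches(n, r) for n, r in zip(drugs["drug_name"], drugs["role"])]
    return set(drugs.loc[mask, "case_id"])


def case_hlgt_pairs(
    dataset: AnalysisDataset, hierarchy: TermHierarchy
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Unique (case_id, hlgt) pairs plus a log of unmapped PT counts."""
    reac = dataset.reactions
    if reac.empty:
        return pd.DataFrame(columns=["case_id", "hlgt"]), {}
    hlgt = reac["pt"].map(hierarchy.pt_to_hlgt)
    unmapped = reac.loc[hlgt.isna(), "pt"]
    unmapped_log = unmapped.value_counts().to_dict()
    if unmapped_log:
        warnings.warn(f"{int(unmapped.size)} reactions with unmapped PTs dropped")
    pairs = (
        pd.DataFrame({"case_id": reac["case_id"], "hlgt": hlgt})
        .dropna()
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return pairs, unmapped_log


def build_table(
    dataset: AnalysisDataset,
    stratum: str,
    hlgt: str,
    exposure: ExposureDefinition | None = None,
    hierarchy: TermHierarchy | None = None,
) -> ContingencyTable:
    """2x2 table for one (stratum, HLGT)."""
    if stratum not in ("elderly", "non_elderly"):
        raise ValueError(f"unknown stratum {stratum!r}")
    if hierarchy is None:
        raise ValueError("a TermHierarchy is required to map PTs to HLGTs")
    exposure = exposure or ExposureDefinition()
    ids = dataset.demo.loc[dataset.demo["stratum"] == stratum, "case_id"]
    stratum_ids = set(ids)
    exposed = exposed_case_ids(dataset, exposure) & stratum_ids
    pairs, _ = case_hlgt_pairs(dataset, hierarchy)
    with_event = set(pairs.loc[pairs["hlgt"] == hlgt, "case_id"]) & stratum_ids
    a = len(exposed & with_event)
    b = len(exposed) - a
    c = len(with_event) - a
    d = len(stratum_ids) - a - b - c
    return ContingencyTable(a, b, c, d)


def count_all(
    dataset: AnalysisDataset,
    exposure: ExposureDefinition | None = None,
    hierarchy: TermHierarchy | None = None,
) -> pd.DataFrame:
    """All (stratum, HLGT) cell counts in one pass.

    Returns a frame with columns stratum, hlgt, a, b, c, d covering every
    HLGT reported at least once in either stratum (the event universe).
    """
    if hierarchy is None:
        raise ValueError("a TermHierarchy is required to map PTs to HLGTs")
    exposure = exposure or ExposureDefinition()
    exposed = exposed_case_ids(dataset, exposure)
    pairs, _ = case_hlgt_pairs(dataset, hierarchy)
    demo = dataset.demo[["case_id", "stratum"]]
    pairs = pairs.merge(demo, on="case_id", how="inner")
    pairs["exposed"] = pairs["case_id"].isin(exposed)

    universe = sorted(pairs["hlgt"].unique())
    rows = []
    for stratum in ("elderly", "non_elderly"):
        stratum_ids = set(demo.loc[demo["stratum"] == stratum, "case_id"])
        n_exp = len(exposed & stratum_ids)
        n_tot = len(stratum_ids)
        sub = pairs[pairs["stratum"] == stratum]
        counts = sub.groupby("hlgt")["exposed"].agg(["sum", "count"])
        for hlgt in universe:
            if hlgt in counts.index:
                a = int(counts.loc[hlgt, "sum"])
                n_event = int(counts.loc[hlgt, "count"])
            else:
                a, n_event = 0, 0
            rows.append(
                {
                    "stratum": stratum,
                    "hlgt": hlgt,
                    "a": a,
                    "b": n_exp - a,
                    "c": n_event - a,
                    "d": n_tot - n_exp - (n_event - a),
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "hlgt", "a", "b", "c", "d"])


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Audit TSV of the raw cell counts."""
    counts.to_csv(path, sep="\t", index=False)


def corrected(table: ContingencyTable) -> ContingencyTable:
    """Convenience: +0.5 on every cell (delegates to the disproportionality op)."""
    from pvsignal.disproportionality import haldane_correct

    return haldane_correct(table)


__all__ = [
    "ContingencyTable",
    "ExposureDefinition",
    "DEFAULT_TARGET_DRUGS",
    "build_table",
    "case_hlgt_pairs",
    "count_all",
    "exposed_case_ids",
    "map_events_to_hlgt",
    "normalize_drug_name",
    "write_counts",
]
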
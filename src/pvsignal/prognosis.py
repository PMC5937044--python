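"""Elderly vs non-elderly prognosis comparison per HLGT.

Reaction outcomes are classified as good ("recovery", "light") or poor
("death", "with-sequelae", "unrecovered"); anything else (e.g. "unknown")
is excluded from the prognosis arm. For each HLGT the exposed cases with
the event form a 2x2 table of stratum x prognosis; a case with several
reactions in the HLGT contributes once, with the worst (poor) outcome
dominating. The Haldane--Anscombe 1/2 correction is applied to ALL four
cells unconditionally, and on the corrected cells we compute

    RR   = [e_poor / (e_poor + e_good)] / [n_poor / (n_poor + n_good)]
    95%CI = exp( ln RR  +/-  1.96 * sqrt(1/e_poor - 1/(e_poor+e_good)
                                         + 1/n_poor - 1/(n_poor+n_good)) )

(elderly poor-outcome risk in the numerator; RR > 1 marks an event whose
prognosis is worse among elderly reporters) plus the Pearson chi-squared
on the corrected table (no Yates — the blanket +0.5 already regularizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from pvsignal.contingency import ExposureDefinition, exposed_case_ids
from pvsignal.disproportionality import chi2 as _pearson_chi2
from pvsignal.contingency import ContingencyTable
from pvsignal.hierarchy import TermHierarchy
from pvsignal.io import AnalysisDataset

GOOD_LABELS = frozenset({"recovery", "light"})
POOR_LABELS = frozenset({"death", "with-sequelae", "unrecovered"})

Z_95 = 1.96


def classify_outcome(
    label: str, vocabulary: dict[str, str] | None = None
) -> Literal["good", "poor", "excluded"]:
    """Map a raw outcome label to good / poor / excluded.

    ``vocabulary`` translates raw labels (e.g. a Japanese extract's) to the
    canonical terms before classification; labels outside both lists —
    "unknown" included — are excluded from the prognosis comparison.
    """
    raw = (label or "").strip()
    canonical = (vocabulary or {}).get(raw, raw)
    if canonical in GOOD_LABELS:
        return "good"
    if canonical in POOR_LABELS:
        return "poor"
    return "excluded"


@dataclass(frozen=True)
class PrognosisTable:
    """Uncorrected stratum x prognosis counts for one HLGT."""

    e_poor: int
    e_good: int
    n_poor: int
    n_good: int

    def __post_init__(self) -> None:
        if min(self.e_poor, self.e_good, self.n_poor, self.n_good) < 0:
            raise ValueError("prognosis counts must be non-negative")

    def corrected_cells(self) -> tuple[float, float, float, float]:
        """Cells after the unconditional +0.5 correction."""
        return (self.e_poor + 0.5, self.e_good + 0.5, self.n_poor + 0.5, self.n_good + 0.5)


@dataclass(frozen=True)
class PrognosisResult:
    hlgt: str
    rr: float
    ci_low: float
    ci_high: float
    chi2: float
    noted: bool   # RR > 1: worse prognosis among elderly reporters


def build_prognosis_table(
    dataset: AnalysisDataset,
    hlgt: str,
    hierarchy: TermHierarchy,
    exposure: ExposureDefinition | None = None,
    vocabulary: dict[str, str] | None = None,
    condition_on_exposure: bool = True,
) -> PrognosisTable:
    """Stratum x prognosis counts for one HLGT.

    By default only cases exposed to a suspected target drug contribute
    (the analysis concerns the drug's adverse events); set
    ``condition_on_exposure=False`` to count every case with the event.
    """
    exposure = exposure or ExposureDefinition()
    reac = dataset.reactions
    if reac.empty:
        return PrognosisTable(0, 0, 0, 0)
    in_hlgt = reac["pt"].map(hierarchy.pt_to_hlgt) == hlgt
    sub = reac[in_hlgt]
    if condition_on_exposure:
        exposed = exposed_case_ids(dataset, exposure)
        sub = sub[sub["case_id"].isin(exposed)]
    if sub.empty:
        return PrognosisTable(0, 0, 0, 0)
    cls = sub["outcome"].map(lambda o: classify_outcome(o, vocabulary))
    sub = sub.assign(prognosis=cls)
    sub = sub[sub["prognosis"] != "excluded"]
    if sub.empty:
        return PrognosisTable(0, 0, 0, 0)
    # worst outcome per case: poor dominates good
    worst = sub.groupby("case_id")["prognosis"].agg(
        lambda s: "poor" if (s == "poor").any() else "good"
    )
    strata = dataset.demo.set_index("case_id")["stratum"]
    joined = pd.DataFrame({"prognosis": worst}).join(strata, how="inner")
    return PrognosisTable(
        e_poor=int(((joined["stratum"] == "elderly") & (joined["prognosis"] == "poor")).sum()),
        e_good=int(((joined["stratum"] == "elderly") & (joined["prognosis"] == "good")).sum()),
        n_poor=int(((joined["stratum"] == "non_elderly") & (joined["prognosis"] == "poor")).sum()),
        n_good=int(((joined["stratum"] == "non_elderly") & (joined["prognosis"] == "good")).sum()),
    )


def risk_ratio(table: PrognosisTable, hlgt: str = "") -> PrognosisResult:
    """Continuity-corrected RR with log-normal 95% CI and Pearson chi2."""
    ep, eg, np_, ng = table.corrected_cells()
    rr = (ep / (ep + eg)) / (np_ / (np_ + ng))
    se = math.sqrt(1.0 / ep - 1.0 / (ep + eg) + 1.0 / np_ - 1.0 / (np_ + ng))
    log_rr = math.log(rr)
    ci_low = math.exp(log_rr - Z_95 * se)
    ci_high = math.exp(log_rr + Z_95 * se)
    stat = _pearson_chi2(
        ContingencyTable(ep, eg, np_, ng, corrected=True), yates=False
    )
    return PrognosisResult(
        hlgt=hlgt, rr=rr, ci_low=ci_low, ci_high=ci_high, chi2=stat, noted=rr > 1.0
    )


def prognosis_all(
    dataset: AnalysisDataset,
    hlgts: list[str],
    hierarchy: TermHierarchy,
    exposure: ExposureDefinition | None = None,
    vocabulary: dict[str, str] | None = None,
    condition_on_exposure: bool = True,
) -> pd.DataFrame:
    """Prognosis results (plus audit cells) for a list of HLGTs."""
    rows = []
    for hlgt in hlgts:
        table = build_prognosis_table(
            dataset, hlgt, hierarchy, exposure, vocabulary, condition_on_exposure
        )
        res = risk_ratio(table, hlgt=hlgt)
        ep, eg, np_, ng = table.corrected_cells()
        rows.append(
            {
                "hlgt": hlgt,
                "rr": res.rr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "chi2": res.chi2,
                "noted": res.noted,
                "e_poor_corr": ep,
                "e_good_corr": eg,
                "n_poor_corr": np_,
                "n_good_corr": ng,
            }
        )
    cols = ["hlgt", "rr", "ci_low", "ci_high", "chi2", "noted",
            "e_poor_corr", "e_good_corr", "n_poor_corr", "n_good_corr"]
    return pd.DataFrame(rows, columns=cols)


__all__ = [
    "GOOD_LABELS",
    "POOR_LABELS",
    "PrognosisResult",
    "PrognosisTable",
    "build_prognosis_table",
    "classify_outcome",
    "prognosis_all",
    "risk_ratio",
]
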
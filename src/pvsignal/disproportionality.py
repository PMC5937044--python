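"""PRR / chi-squared disproportionality statistics and the elderly-risk rule.

For one (stratum, HLGT) 2x2 table with cells a (= n11, exposed cases with
the event), b, c, d:

* ``PRR = [a/(a+b)] / [c/(c+d)]`` (Evans' proportional reporting ratio);
* ``chi2`` is the Pearson statistic on the table (a Yates continuity
  correction is available via a flag, but the composite signal value needs
  a strictly positive statistic, and Yates floors weak tables to zero, so
  the plain statistic is the default);
* the composite signal value is ``ln(PRR) + ln(chi2)``;
* a signal is detected when ``n11 >= 3 and PRR >= 2 and chi2 >= 4``
  (Evans' criterion; all three thresholds configurable).

Zero cells make PRR or chi2 degenerate, so when any cell of a table is zero
the whole table receives the Haldane--Anscombe 1/2 correction (+0.5 on all
four cells) before the statistics are computed; tables with all cells
positive are used uncorrected.

Among HLGTs whose signal is detected in the elderly stratum, the
elderly-risk judgment flags those whose non-elderly signal value falls below
half the elderly one:

    (elderly signal value) / 2 - (non-elderly signal value) > 0
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from pvsignal.contingency import ContingencyTable
from pvsignal.errors import DomainError, ZeroMarginError


@dataclass(frozen=True)
class DetectionCriteria:
    """Thresholds of the signal-detection rule (Evans' defaults)."""

    min_n11: float = 3
    min_prr: float = 2.0
    min_chi2: float = 4.0


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality statistics for one (stratum, HLGT)."""

    hlgt: str
    stratum: str
    n11: int
    prr: float
    chi2: float
    signal_value: float
    detected: bool
    corrected: bool


@dataclass(frozen=True)
class RiskJudgment:
    """Stratum comparison for one HLGT detected in the elderly."""

    hlgt: str
    sv_elderly: float
    sv_non_elderly: float
    flagged: bool


def prr(table: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)].

    On uncorrected tables: returns 0.0 when a = 0, and +inf (with a
    warning) when c = 0 with a > 0 — correct the table first when a finite
    signal value is needed.
    """
    a, b, c, d = table.cells()
    if a + b == 0 or c + d == 0:
        raise ZeroMarginError("empty exposure margin; apply haldane_correct first")
    if a == 0:
        return 0.0
    if c == 0:
        warnings.warn("c = 0: PRR is infinite; apply haldane_correct for finite statistics")
        return math.inf
    return (a / (a + b)) / (c / (c + d))


def chi2(table: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-squared on the 2x2, optionally Yates-corrected.

    With Yates, |O - E| is reduced by 0.5 (floored at 0) before squaring,
    which can only shrink the statistic.
    """
    a, b, c, d = table.cells()
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ZeroMarginError(
            "a 2x2 margin is zero; apply haldane_correct before computing chi2"
        )
    stat = 0.0
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        exp = row * col / n
        dev = abs(obs - exp)
        if yates:
            dev = max(dev - 0.5, 0.0)
        stat += dev * dev / exp
    return stat


def haldane_correct(table: ContingencyTable) -> ContingencyTable:
    """Haldane--Anscombe 1/2 correction: +0.5 on all four cells.

    Applying it twice is an error — the correction is a one-shot adjustment,
    not an increment.
    """
    if table.corrected:
        raise ValueError("table already carries the Haldane-Anscombe correction")
    return ContingencyTable(
        table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5, corrected=True
    )


def signal_value(prr_value: float, chi2_value: float) -> float:
    """Composite signal value ln(PRR) + ln(chi2).

    Both inputs must be strictly positive; zero statistics mean the table
    still needs the Haldane--Anscombe correction.
    """
    if not (prr_value > 0 and math.isfinite(prr_value)):
        raise DomainError(f"PRR must be finite and > 0, got {prr_value}")
    if not (chi2_value > 0 and math.isfinite(chi2_value)):
        raise DomainError(f"chi2 must be finite and > 0, got {chi2_value}")
    return math.log(prr_value) + math.log(chi2_value)


def detect_signal(
    n11: float,
    prr_value: float,
    chi2_value: float,
    criteria: DetectionCriteria = DetectionCriteria(),
) -> bool:
    """Evans' rule: n11, PRR and chi2 all at or above their thresholds."""
    return (
        n11 >= criteria.min_n11
        and prr_value >= criteria.min_prr
        and chi2_value >= criteria.min_chi2
    )


def risk_judgment(sv_elderly: float, sv_non_elderly: float) -> bool:
    """Strict half-value rule: sv_elderly / 2 - sv_non_elderly > 0.

    Evaluated only for HLGTs detected in the elderly stratum; an exact tie
    is not flagged.
    """
    return sv_elderly / 2.0 - sv_non_elderly > 0.0


def compute_signal(
    table: ContingencyTable,
    hlgt: str = "",
    stratum: str = "",
    yates: bool = False,
    criteria: DetectionCriteria = DetectionCriteria(),
) -> SignalResult:
    """Full per-table statistics with the zero-cell correction policy.

    Tables with any zero cell are Haldane-corrected before PRR/chi2; the
    reported ``n11`` is always the uncorrected count, and detection is
    evaluated on the statistics actually computed.
    """
    n11 = int(table.a)
    work = table
    if not table.corrected and min(table.cells()) == 0:
        work = haldane_correct(table)
    prr_value = prr(work)
    chi2_value = chi2(work, yates=yates)
    sv = signal_value(prr_value, chi2_value) if prr_value > 0 and chi2_value > 0 else math.nan
    return SignalResult(
        hlgt=hlgt,
        stratum=stratum,
        n11=n11,
        prr=prr_value,
        chi2=chi2_value,
        signal_value=sv,
        detected=detect_signal(n11, prr_value, chi2_value, criteria),
        corrected=work.corrected,
    )


def analyze_counts(
    counts: pd.DataFrame,
    yates: bool = False,
    criteria: DetectionCriteria = DetectionCriteria(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Statistics for every (stratum, HLGT) plus the per-HLGT risk judgment.

    ``counts`` is the frame produced by :func:`pvsignal.contingency.count_all`.
    Returns ``(signals, judgments)``: one row per (stratum, HLGT), and one
    row per HLGT detected in the elderly stratum with its half-value flag.
    """
    records = []
    for row in counts.itertuples(index=False):
        table = ContingencyTable(row.a, row.b, row.c, row.d)
        res = compute_signal(table, hlgt=row.hlgt, stratum=row.stratum,
                             yates=yates, criteria=criteria)
        records.append(res.__dict__)
    signals = pd.DataFrame(records)

    wide = signals.pivot(index="hlgt", columns="stratum",
                         values=["signal_value", "detected"])
    judgments = []
    for hlgt in wide.index:
        try:
            detected_e = bool(wide.loc[hlgt, ("detected", "elderly")])
            sv_e = float(wide.loc[hlgt, ("signal_value", "elderly")])
            sv_ne = float(wide.loc[hlgt, ("signal_value", "non_elderly")])
        except KeyError:
            continue
        if not detected_e:
            continue
        judgments.append(
            RiskJudgment(hlgt, sv_e, sv_ne, risk_judgment(sv_e, sv_ne)).__dict__
        )
    jcols = ["hlgt", "sv_elderly", "sv_non_elderly", "flagged"]
    return signals, pd.DataFrame(judgments, columns=jcols)


__all__ = [
    "DetectionCriteria",
    "RiskJudgment",
    "SignalResult",
    "analyze_counts",
    "chi2",
    "compute_signal",
    "detect_signal",
    "haldane_correct",
    "prr",
    "risk_judgment",
    "signal_value",
]
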
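"""MedDRA-style three-level event term hierarchy (PT -> HLGT -> SOC).

Adverse events arrive in case reports coded at Preferred Term (PT) level.
The analysis aggregates them to High Level Group Terms (HLGT) and rolls
summaries up to System Organ Classes (SOC). The licensed MedDRA dictionary
cannot be redistributed, so the hierarchy is always a user-supplied (or
synthetically generated) table following MedDRA's primary-path convention:
each PT belongs to exactly one HLGT and each HLGT to exactly one SOC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from pvsignal.errors import InputError

HIERARCHY_COLUMNS = ("pt", "hlgt", "soc")


@dataclass(frozen=True)
class TermHierarchy:
    """Immutable PT -> HLGT -> SOC mapping.

    Parameters
    ----------
    pt_to_hlgt
        Maps each preferred term to its (single) high level group term.
    hlgt_to_soc
        Maps each high level group term to its (single) system organ class.
    """

    pt_to_hlgt: dict[str, str]
    hlgt_to_soc: dict[str, str]
    _hlgt_to_pts: dict[str, list[str]] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        missing = {h for h in self.pt_to_hlgt.values() if h not in self.hlgt_to_soc}
        if missing:
            raise InputError(f"HLGTs without a SOC assignment: {sorted(missing)}")
        by_hlgt: dict[str, list[str]] = {h: [] for h in self.hlgt_to_soc}
        for pt, hlgt in self.pt_to_hlgt.items():
            by_hlgt[hlgt].append(pt)
        object.__setattr__(self, "_hlgt_to_pts", by_hlgt)

    @property
    def pts(self) -> list[str]:
        return sorted(self.pt_to_hlgt)

    @property
    def hlgts(self) -> list[str]:
        return sorted(self.hlgt_to_soc)

    @property
    def socs(self) -> list[str]:
        return sorted(set(self.hlgt_to_soc.values()))

    def pts_of(self, hlgt: str) -> list[str]:
        return sorted(self._hlgt_to_pts.get(hlgt, []))

    def hlgt_of(self, pt: str) -> str | None:
        return self.pt_to_hlgt.get(pt)

    def soc_of(self, hlgt: str) -> str | None:
        return self.hlgt_to_soc.get(hlgt)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (pt, hlgt, self.hlgt_to_soc[hlgt])
            for pt, hlgt in sorted(self.pt_to_hlgt.items())
        ]
        return pd.DataFrame(rows, columns=list(HIERARCHY_COLUMNS))

    def write(self, path: str | Path, encoding: str = "utf-8") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding=encoding)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TermHierarchy":
        missing = set(HIERARCHY_COLUMNS) - set(frame.columns)
        if missing:
            raise InputError(f"hierarchy table lacks columns: {sorted(missing)}")
        dup_pt = frame.loc[frame.duplicated("pt", keep=False), "pt"]
        if frame.groupby("pt")["hlgt"].nunique().gt(1).any():
            raise InputError(f"PTs mapped to multiple HLGTs: {sorted(set(dup_pt))}")
        if frame.groupby("hlgt")["soc"].nunique().gt(1).any():
            raise InputError("an HLGT is mapped to multiple SOCs")
        return cls(
            pt_to_hlgt=dict(zip(frame["pt"], frame["hlgt"])),
            hlgt_to_soc=dict(zip(frame["hlgt"], frame["soc"])),
        )

    @classmethod
    def read(cls, path: str | Path, encoding: str = "utf-8") -> "TermHierarchy":
        path = Path(path)
        if not path.exists():
            raise InputError(f"hierarchy file not found: {path}")
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding=encoding)
        return cls.from_frame(frame)
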
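"""Result assembly: signal table, SOC roll-ups, prognosis table, pipeline.

Three entry points:

* :func:`run_pipeline` drives ingest -> contingency -> disproportionality ->
  judgment -> SOC roll-up -> prognosis on a data directory and writes the
  result bundle (TSVs plus a JSON run manifest);
* :func:`replay_signal_table` applies only the detection / half-value
  judgment / roll-up logic to a table of precomputed per-stratum
  (n11, PRR, chi2, signal value) rows — e.g. a published stratified signal
  table — without needing the underlying case database;
* :func:`rollup_by_soc` partitions a list of HLGTs by their System Organ
  Class.

A published Z-drug stratified signal table (28 HLGTs detected in the
elderly stratum of a JADER analysis, with both strata's statistics and SOC
assignments) ships with the package for replay validation; see
:func:`load_reference_signal_table`.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from pvsignal._version import __version__ as _pkg_version
from pvsignal.contingency import ExposureDefinition, count_all, write_counts
from pvsignal.disproportionality import (
    DetectionCriteria,
    analyze_counts,
    detect_signal,
    risk_judgment,
)
from pvsignal.errors import InputError
from pvsignal.hierarchy import TermHierarchy
from pvsignal.io import apply_exclusions, load_data_dir
from pvsignal.prognosis import prognosis_all


@dataclass(frozen=True)
class SocRollup:
    """HLGTs grouped under one System Organ Class."""

    soc: str
    hlgts: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.hlgts)


def rollup_by_soc(
    hlgts: list[str],
    hierarchy: TermHierarchy | None = None,
    soc_map: dict[str, str] | None = None,
) -> list[SocRollup]:
    """Partition HLGTs by SOC, sorted by descending bucket size.

    Accepts either a hierarchy or an explicit HLGT->SOC map; HLGTs missing
    from both land in an "unmapped" bucket. Ties in bucket size break
    alphabetically by SOC.
    """
    if soc_map is None:
        soc_map = hierarchy.hlgt_to_soc if hierarchy is not None else {}
    buckets: dict[str, list[str]] = {}
    for h in hlgts:
        soc = soc_map.get(h, "unmapped")
        buckets.setdefault(soc, []).append(h)
    rollups = [SocRollup(soc, tuple(members)) for soc, members in buckets.items()]
    return sorted(rollups, key=lambda r: (-r.count, r.soc))


REPLAY_COLUMNS = (
    "hlgt", "n11_elderly", "prr_elderly", "chi2_elderly", "sv_elderly",
    "n11_non_elderly", "prr_non_elderly", "chi2_non_elderly", "sv_non_elderly",
)


def load_reference_signal_table() -> pd.DataFrame:
    """The bundled published Z-drug stratified signal table (28 HLGTs)."""
    ref = resources.files("pvsignal").joinpath("data/reference_signal_table.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def replay_signal_table(
    table: pd.DataFrame,
    criteria: DetectionCriteria = DetectionCriteria(),
) -> pd.DataFrame:
    """Detection + half-value judgment on precomputed per-stratum statistics.

    Adds ``detected_elderly`` (Evans' rule on the elderly n11/PRR/chi2) and
    ``flagged`` (half-value rule on the signal-value columns, evaluated only
    where the elderly signal is detected). Non-elderly statistics are taken
    as given — for rows where a zero cell forced the Haldane correction the
    caller supplies the corrected statistics.
    """
    missing = set(REPLAY_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"replay table lacks columns: {sorted(missing)}")
    out = table.copy()
    out["detected_elderly"] = [
        detect_signal(r.n11_elderly, r.prr_elderly, r.chi2_elderly, criteria)
        for r in table.itertuples(index=False)
    ]
    out["flagged"] = [
        bool(det) and risk_judgment(r.sv_elderly, r.sv_non_elderly)
        for det, r in zip(out["detected_elderly"], table.itertuples(index=False))
    ]
    return out


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML file."""

    data_dir: str
    out_dir: str | None = None
    encoding: str = "utf-8"
    column_maps: dict = field(default_factory=dict)
    subjective_age_tokens: tuple[str, ...] = ("youth", "elderly")
    target_drugs: tuple[str, ...] = ("zolpidem", "eszopiclone", "zopiclone")
    exposure_roles: tuple[str, ...] = ("suspected",)
    drug_synonyms: dict = field(default_factory=dict)
    yates: bool = False
    min_n11: float = 3
    min_prr: float = 2.0
    min_chi2: float = 4.0
    outcome_vocabulary: dict = field(default_factory=dict)
    prognosis_condition_on_exposure: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("subjective_age_tokens", "target_drugs", "exposure_roles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def exposure(self) -> ExposureDefinition:
        return ExposureDefinition(
            drug_names=frozenset(self.target_drugs),
            roles=frozenset(self.exposure_roles),
            synonyms=dict(self.drug_synonyms),
        )

    def criteria(self) -> DetectionCriteria:
        return DetectionCriteria(self.min_n11, self.min_prr, self.min_chi2)


@dataclass
class PipelineResult:
    counts: pd.DataFrame
    signals: pd.DataFrame
    judgments: pd.DataFrame
    rollups: list[SocRollup]
    prognosis: pd.DataFrame
    exclusion_log: dict[str, int]
    n_elderly: int
    n_non_elderly: int
    manifest: dict

    @property
    def detected_elderly(self) -> list[str]:
        mask = (self.signals["stratum"] == "elderly") & self.signals["detected"]
        return sorted(self.signals.loc[mask, "hlgt"])

    @property
    def flagged(self) -> list[str]:
        if self.judgments.empty:
            return []
        return sorted(self.judgments.loc[self.judgments["flagged"], "hlgt"])


def _rollup_frame(rollups: list[SocRollup]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"soc": r.soc, "count": r.count, "hlgts": "; ".join(r.hlgts)} for r in rollups],
        columns=["soc", "count", "hlgts"],
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Full run on a data directory; deterministic given its inputs."""
    tables, hierarchy = load_data_dir(
        config.data_dir, encoding=config.encoding, column_maps=config.column_maps
    )
    dataset = apply_exclusions(tables, frozenset(config.subjective_age_tokens))
    exposure = config.exposure()
    criteria = config.criteria()

    counts = count_all(dataset, exposure, hierarchy)
    signals, judgments = analyze_counts(counts, yates=config.yates, criteria=criteria)
    flagged = sorted(judgments.loc[judgments["flagged"], "hlgt"]) if not judgments.empty else []
    rollups = rollup_by_soc(flagged, hierarchy)
    prognosis = prognosis_all(
        dataset,
        sorted(judgments["hlgt"]) if not judgments.empty else [],
        hierarchy,
        exposure,
        dict(config.outcome_vocabulary) or None,
        config.prognosis_condition_on_exposure,
    )
    manifest = {
        "pvsignal_version": _pkg_version,
        "python": platform.python_version(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_raw": dataset.n_raw,
        "n_elderly": dataset.n_elderly,
        "n_non_elderly": dataset.n_non_elderly,
        "exclusion_log": dataset.exclusion_log,
        "n_hlgts_in_universe": int(counts["hlgt"].nunique()),
        "n_detected_elderly": int(
            ((signals["stratum"] == "elderly") & signals["detected"]).sum()
        ),
        "n_flagged": len(flagged),
    }
    result = PipelineResult(
        counts=counts,
        signals=signals,
        judgments=judgments,
        rollups=rollups,
        prognosis=prognosis,
        exclusion_log=dataset.exclusion_log,
        n_elderly=dataset.n_elderly,
        n_non_elderly=dataset.n_non_elderly,
        manifest=manifest,
    )
    if config.out_dir:
        write_result(result, config.out_dir)
    return result


def write_result(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the result bundle: audit counts, signal/judgment/prognosis TSVs,
    SOC roll-up, and the JSON run manifest.

    Machine-readable TSVs keep full precision; a human-readable signal table
    (1-decimal signal values, 2-decimal RR/CI) is written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv" for name in
             ("counts", "signals", "judgments", "rollup", "prognosis")}
    paths["manifest"] = out / "manifest.json"
    paths["signals_pretty"] = out / "signals_pretty.tsv"
    write_counts(result.counts, paths["counts"])
    result.signals.to_csv(paths["signals"], sep="\t", index=False)
    result.judgments.to_csv(paths["judgments"], sep="\t", index=False)
    _rollup_frame(result.rollups).to_csv(paths["rollup"], sep="\t", index=False)
    result.prognosis.to_csv(paths["prognosis"], sep="\t", index=False)

    pretty = result.signals.copy()
    for col in ("prr", "chi2"):
        pretty[col] = pretty[col].round(1)
    pretty["signal_value"] = pretty["signal_value"].round(1)
    pretty.to_csv(paths["signals_pretty"], sep="\t", index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return paths


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SocRollup",
    "load_reference_signal_table",
    "replay_signal_table",
    "rollup_by_soc",
    "run_pipeline",
    "write_result",
]
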
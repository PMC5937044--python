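"""Synthetic spontaneous-report database generator.

Emulates the four-table layout of JADER-like spontaneous reporting systems:
a demographics table (one row per case, with sex and a decade-binned age
category), a drug table (several rows per case, each carrying an involvement
role: suspected / concomitant / interaction), a reaction table (one row per
reported adverse event, coded at PT level with an outcome label), and a
primary-disease table. Real extracts contain blank sex or age fields and
"subjective" age tokens such as "youth" or "elderly"; the generator injects
these at configurable rates and records the injected ground truth so that
downstream exclusion logic can be validated exactly.

Drug-event association strengths are configurable per (HLGT, age stratum),
which lets a scenario spike one event group in the elderly only — the
structure the stratified signal comparison is designed to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pvsignal.errors import ConfigurationError
from pvsignal.hierarchy import TermHierarchy

# Canonical English outcome vocabulary; the ingest side accepts a mapping so
# that other locales (e.g. real JADER's Japanese labels) can be plugged in.
GOOD_OUTCOMES = ("recovery", "light")
POOR_OUTCOMES = ("death", "with-sequelae", "unrecovered")
UNKNOWN_OUTCOME = "unknown"

Z_DRUGS = ("zolpidem", "eszopiclone", "zopiclone")
OTHER_DRUGS = ("etizolam", "famotidine", "amlodipine", "loxoprofen")
PRIMARY_DISEASES = ("insomnia", "depression", "hypertension", "anxiety disorder")

ELDERLY_DECADES = np.array([60, 70, 80, 90])
ELDERLY_DECADE_P = np.array([0.40, 0.35, 0.20, 0.05])
NON_ELDERLY_DECADES = np.array([20, 30, 40, 50])
NON_ELDERLY_DECADE_P = np.array([0.15, 0.25, 0.30, 0.30])

# Alias kept for the generator's public surface: a generated hierarchy is an
# ordinary TermHierarchy.
MockHierarchy = TermHierarchy


def generate_hierarchy(n_soc: int, n_hlgt: int, n_pt: int, seed: int = 0) -> TermHierarchy:
    """Generate a random surjective PT -> HLGT -> SOC hierarchy.

    Every SOC receives at least one HLGT and every HLGT at least one PT;
    the remaining terms are assigned uniformly at random. Deterministic for
    a given ``seed``.
    """
    if not (n_pt >= n_hlgt >= n_soc >= 1):
        raise ConfigurationError(
            f"need n_pt >= n_hlgt >= n_soc >= 1, got ({n_soc}, {n_hlgt}, {n_pt})"
        )
    rng = np.random.default_rng(seed)
    socs = [f"SOC_{i:02d}" for i in range(1, n_soc + 1)]
    hlgts = [f"HLGT_{i:03d}" for i in range(1, n_hlgt + 1)]
    pts = [f"PT_{i:04d}" for i in range(1, n_pt + 1)]

    def surjective_assign(items: list[str], targets: list[str]) -> dict[str, str]:
        # first len(targets) items cover every target (in shuffled order),
        # the rest are uniform draws
        order = rng.permutation(len(items))
        cover = rng.permutation(len(targets))
        out: dict[str, str] = {}
        for rank, idx in enumerate(order):
            if rank < len(targets):
                out[items[idx]] = targets[cover[rank]]
            else:
                out[items[idx]] = targets[rng.integers(len(targets))]
        return out

    return TermHierarchy(
        pt_to_hlgt=surjective_assign(pts, hlgts),
        hlgt_to_soc=surjective_assign(hlgts, socs),
    )


@dataclass(frozen=True)
class MissingnessRates:
    """Per-case probabilities of degraded demographic fields.

    ``age_subjective`` replaces the decade token with "youth"/"elderly";
    ``primary_disease`` drops the case's row from the primary-disease table.
    """

    sex: float = 0.02
    age_blank: float = 0.015
    age_subjective: float = 0.01
    primary_disease: float = 0.03

    def validate(self) -> None:
        for name in ("sex", "age_blank", "age_subjective", "primary_disease"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"missingness rate {name}={v} outside [0, 1]")
        if self.age_blank + self.age_subjective > 1.0:
            raise ConfigurationError("age_blank + age_subjective exceeds 1")

    @classmethod
    def none(cls) -> "MissingnessRates":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class OutcomeModel:
    """Probability model for per-reaction outcome labels.

    A reaction's outcome is "unknown" with probability ``unknown_prob``;
    otherwise it is poor (uniform over death / with-sequelae / unrecovered)
    with the stratum's poor probability — optionally overridden per
    (HLGT, stratum) and scaled by ``exposed_poor_multiplier`` on cases
    exposed to a suspected target drug — and good otherwise.
    """

    poor_prob: dict[str, float] = field(
        default_factory=lambda: {"elderly": 0.20, "non_elderly": 0.20}
    )
    overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    exposed_poor_multiplier: float = 1.0
    unknown_prob: float = 0.10

    def validate(self) -> None:
        for stratum in ("elderly", "non_elderly"):
            if stratum not in self.poor_prob:
                raise ConfigurationError(f"poor_prob lacks stratum {stratum!r}")
        probs = list(self.poor_prob.values()) + list(self.overrides.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("outcome probabilities must lie in [0, 1]")
        if not 0.0 <= self.unknown_prob <= 1.0:
            raise ConfigurationError("unknown_prob outside [0, 1]")
        if self.exposed_poor_multiplier < 0:
            raise ConfigurationError("exposed_poor_multiplier must be >= 0")

    def p_poor(self, hlgt: str, stratum: str, exposed: bool) -> float:
        p = self.overrides.get((hlgt, stratum), self.poor_prob[stratum])
        if exposed:
            p = min(1.0, p * self.exposed_poor_multiplier)
        return p


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic-database scenario.

    ``association_multipliers`` maps (HLGT, stratum) to the factor applied
    to the HLGT's baseline per-case event probability for *exposed* cases of
    that stratum; unlisted pairs default to 1 (no association). Resulting
    probabilities are clipped to [0, 1].
    """

    n_cases: int = 20_000
    elderly_fraction: float = 0.625
    exposure_prevalence: float = 0.05
    baseline_event_rates: dict[str, float] | None = None
    association_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    missingness_rates: MissingnessRates = field(default_factory=MissingnessRates)
    concomitant_drug_prob: float = 0.5
    concomitant_zdrug_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError(f"n_cases must be >= 1, got {self.n_cases}")
        for name in (
            "elderly_fraction",
            "exposure_prevalence",
            "concomitant_drug_prob",
            "concomitant_zdrug_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.baseline_event_rates is not None:
            if any(not 0.0 <= p <= 1.0 for p in self.baseline_event_rates.values()):
                raise ConfigurationError("baseline event rates must lie in [0, 1]")
        if any(m < 0 for m in self.association_multipliers.values()):
            raise ConfigurationError("association multipliers must be >= 0")
        self.outcome_model.validate()
        self.missingness_rates.validate()


@dataclass
class SyntheticDatabase:
    """Generated four-table database plus the injected ground truth."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame
    hierarchy: TermHierarchy
    ground_truth: dict

    def write(self, out_dir: str | Path, encoding: str = "utf-8") -> dict[str, Path]:
        """Write demo/drug/reac/hist CSVs and hierarchy.tsv; return the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "demo": out / "demo.csv",
            "drug": out / "drug.csv",
            "reac": out / "reac.csv",
            "hist": out / "hist.csv",
            "hierarchy": out / "hierarchy.tsv",
        }
        self.demo.to_csv(paths["demo"], index=False, encoding=encoding)
        self.drug.to_csv(paths["drug"], index=False, encoding=encoding)
        self.reac.to_csv(paths["reac"], index=False, encoding=encoding)
        self.hist.to_csv(paths["hist"], index=False, encoding=encoding)
        self.hierarchy.write(paths["hierarchy"], encoding=encoding)
        return paths


def _age_token(decade: int) -> str:
    return "90s+" if decade >= 90 else f"{decade}s"


def _default_rates(hierarchy: TermHierarchy) -> dict[str, float]:
    # deterministic ladder of background reporting rates across HLGTs
    ladder = (0.005, 0.01, 0.02, 0.03)
    return {h: ladder[i % len(ladder)] for i, h in enumerate(hierarchy.hlgts)}


def generate_database(config: ScenarioConfig, hierarchy: TermHierarchy) -> SyntheticDatabase:
    """Generate the four case tables for one scenario.

    Bit-reproducible for a given ``config.seed``: repeated calls return
    byte-identical tables.
    """
    config.validate()
    if not hierarchy.hlgts:
        raise ConfigurationError("hierarchy has no HLGTs")
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    case_ids = np.array([f"C{i:07d}" for i in range(1, n + 1)])

    elderly = rng.random(n) < config.elderly_fraction
    decade = np.where(
        elderly,
        rng.choice(ELDERLY_DECADES, size=n, p=ELDERLY_DECADE_P),
        rng.choice(NON_ELDERLY_DECADES, size=n, p=NON_ELDERLY_DECADE_P),
    )
    sex = rng.choice(np.array(["male", "female"]), size=n)
    exposed = rng.random(n) < config.exposure_prevalence

    # --- degrade demographics ----------------------------------------------
    miss = config.missingness_rates
    sex_blank = rng.random(n) < miss.sex
    u_age = rng.random(n)
    age_blank = u_age < miss.age_blank
    age_subjective = (~age_blank) & (u_age < miss.age_blank + miss.age_subjective)
    hist_missing = rng.random(n) < miss.primary_disease

    age_tokens = np.array([_age_token(d) for d in decade], dtype=object)
    age_tokens[age_blank] = ""
    age_tokens[age_subjective] = np.where(decade[age_subjective] >= 60, "elderly", "youth")
    sex_out = sex.astype(object)
    sex_out[sex_blank] = ""

    demo = pd.DataFrame({"case_id": case_ids, "sex": sex_out, "age": age_tokens})

    # --- drug table --------------------------------------------------------
    drug_rows: list[pd.DataFrame] = []
    zdrug_names = np.array(Z_DRUGS)
    suspected_names = zdrug_names[rng.integers(len(zdrug_names), size=int(exposed.sum()))]
    drug_rows.append(
        pd.DataFrame(
            {
                "case_id": case_ids[exposed],
                "drug_name": suspected_names,
                "role": "suspected",
            }
        )
    )
    conc = rng.random(n) < config.concomitant_drug_prob
    conc_names = np.array(OTHER_DRUGS)[rng.integers(len(OTHER_DRUGS), size=int(conc.sum()))]
    drug_rows.append(
        pd.DataFrame({"case_id": case_ids[conc], "drug_name": conc_names, "role": "concomitant"})
    )
    # concomitant Z-drug rows on otherwise unexposed cases exercise the role filter
    conc_z = (~exposed) & (rng.random(n) < config.concomitant_zdrug_prob)
    conc_z_names = zdrug_names[rng.integers(len(zdrug_names), size=int(conc_z.sum()))]
    drug_rows.append(
        pd.DataFrame({"case_id": case_ids[conc_z], "drug_name": conc_z_names, "role": "concomitant"})
    )
    drug = (
        pd.concat(drug_rows, ignore_index=True)
        .sort_values(["case_id", "role", "drug_name"], kind="stable")
        .reset_index(drop=True)
    )

    # --- reactions ---------------------------------------------------------
    stratum = np.where(elderly, "elderly", "non_elderly")
    rates = config.baseline_event_rates or _default_rates(hierarchy)
    outcome = config.outcome_model
    reac_parts: list[pd.DataFrame] = []
    true_event_counts: dict[tuple[str, str, bool], int] = {}
    for hlgt in hierarchy.hlgts:
        base = rates.get(hlgt, 0.0)
        mult_e = config.association_multipliers.get((hlgt, "elderly"), 1.0)
        mult_ne = config.association_multipliers.get((hlgt, "non_elderly"), 1.0)
        p = np.where(
            exposed,
            np.where(elderly, min(1.0, base * mult_e), min(1.0, base * mult_ne)),
            base,
        )
        hit = rng.random(n) < p
        if not hit.any():
            continue
        idx = np.flatnonzero(hit)
        pts = hierarchy.pts_of(hlgt)
        pt_draw = np.array(pts, dtype=object)[rng.integers(len(pts), size=idx.size)]
        p_poor = np.array(
            [outcome.p_poor(hlgt, stratum[i], bool(exposed[i])) for i in idx]
        )
        u = rng.random(idx.size)
        is_unknown = u < outcome.unknown_prob
        is_poor = (~is_unknown) & (
            (u - outcome.unknown_prob) / max(1e-12, 1 - outcome.unknown_prob) < p_poor
        )
        labels = np.where(
            is_unknown,
            UNKNOWN_OUTCOME,
            np.where(
                is_poor,
                np.array(POOR_OUTCOMES, dtype=object)[rng.integers(3, size=idx.size)],
                np.array(GOOD_OUTCOMES, dtype=object)[rng.integers(2, size=idx.size)],
            ),
        )
        reac_parts.append(
            pd.DataFrame({"case_id": case_ids[idx], "pt": pt_draw, "outcome": labels})
        )
        for s in ("elderly", "non_elderly"):
            for ex in (True, False):
                key = (hlgt, s, ex)
                true_event_counts[key] = int(
                    ((stratum == s) & (exposed == ex) & hit).sum()
                )
    if reac_parts:
        reac = (
            pd.concat(reac_parts, ignore_index=True)
            .sort_values(["case_id", "pt"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        reac = pd.DataFrame(columns=["case_id", "pt", "outcome"])

    # --- primary disease ---------------------------------------------------
    keep = ~hist_missing
    diseases = np.array(PRIMARY_DISEASES, dtype=object)[
        rng.integers(len(PRIMARY_DISEASES), size=int(keep.sum()))
    ]
    hist = pd.DataFrame({"case_id": case_ids[keep], "primary_disease": diseases})

    # --- ground truth for validation ---------------------------------------
    age_bad = age_blank | age_subjective
    excl_sex = sex_blank
    excl_age = (~sex_blank) & age_bad
    excl_hist = (~sex_blank) & (~age_bad) & hist_missing
    included = ~(excl_sex | excl_age | excl_hist)
    ground_truth = {
        "n_cases": n,
        "elderly": elderly,
        "exposed": exposed,
        "excluded_missing_sex": int(excl_sex.sum()),
        "excluded_missing_age": int(excl_age.sum()),
        "excluded_missing_primary_disease": int(excl_hist.sum()),
        "included_elderly": int((included & elderly).sum()),
        "included_non_elderly": int((included & ~elderly).sum()),
        "event_counts": true_event_counts,
    }
    return SyntheticDatabase(demo, drug, reac, hist, hierarchy, ground_truth)


def elderly_risk_scenario(
    hierarchy: TermHierarchy,
    spiked_hlgt: str | None = None,
    multiplier: float = 20.0,
    n_cases: int = 20_000,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """A scenario with one HLGT over-reported among exposed elderly cases only.

    This is the structure the stratified analysis targets: the spiked HLGT
    should be detected in the elderly stratum and flagged by the elderly-risk
    judgment, while all other HLGTs stay null.
    """
    if spiked_hlgt is None:
        spiked_hlgt = hierarchy.hlgts[0]
    return ScenarioConfig(
        n_cases=n_cases,
        association_multipliers={(spiked_hlgt, "elderly"): multiplier},
        seed=seed,
        **overrides,
    )
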
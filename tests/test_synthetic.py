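"""Generator: hierarchy construction, determinism, configured-rate recovery."""

import numpy as np
import pandas as pd
import pytest

from pvsignal.errors import ConfigurationError
from pvsignal.synthetic import (
    MissingnessRates,
    ScenarioConfig,
    elderly_risk_scenario,
    generate_database,
    generate_hierarchy,
)


class TestGenerateHierarchy:
    def test_minimal_single_chain(self):
        h = generate_hierarchy(1, 1, 1, seed=0)
        assert len(h.pts) == 1 and len(h.hlgts) == 1 and len(h.socs) == 1
        assert h.hlgt_of(h.pts[0]) == h.hlgts[0]
        assert h.soc_of(h.hlgts[0]) == h.socs[0]

    def test_surjective_and_deterministic(self):
        h1 = generate_hierarchy(2, 6, 30, seed=1)
        h2 = generate_hierarchy(2, 6, 30, seed=1)
        assert h1 == h2
        assert len(h1.pts) == 30 and len(h1.hlgts) == 6 and len(h1.socs) == 2
        # surjectivity at both levels
        assert set(h1.pt_to_hlgt.values()) == set(h1.hlgts)
        assert set(h1.hlgt_to_soc.values()) == set(h1.socs)

    def test_seed_changes_partition(self):
        h1 = generate_hierarchy(2, 6, 30, seed=1)
        h2 = generate_hierarchy(2, 6, 30, seed=2)
        assert h1 != h2

    @pytest.mark.parametrize("counts", [(0, 1, 1), (2, 1, 3), (3, 2, 1)])
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ConfigurationError):
            generate_hierarchy(*counts, seed=0)


class TestGenerateDatabase:
    def test_bit_reproducible_given_seed(self, tmp_path):
        h = generate_hierarchy(2, 4, 12, seed=5)
        cfg = ScenarioConfig(n_cases=2000, seed=11)
        db1 = generate_database(cfg, h)
        db2 = generate_database(cfg, h)
        for t in ("demo", "drug", "reac", "hist"):
            pd.testing.assert_frame_equal(getattr(db1, t), getattr(db2, t))
        p1 = db1.write(tmp_path / "a")
        p2 = db2.write(tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_structure_and_vocabularies(self):
        h = generate_hierarchy(2, 4, 12, seed=5)
        db = generate_database(ScenarioConfig(n_cases=3000, seed=7), h)
        assert len(db.demo) == 3000
        assert db.demo["case_id"].is_unique
        assert set(db.drug["role"]) <= {"suspected", "concomitant", "interaction"}
        assert set(db.reac["outcome"]) <= {
            "recovery", "light", "death", "with-sequelae", "unrecovered", "unknown"
        }
        # age tokens: decade bins, blanks, or subjective terms
        decades = {f"{d}s" for d in range(20, 90, 10)} | {"90s+"}
        assert set(db.demo["age"]) <= decades | {"", "youth", "elderly"}
        assert set(db.reac["pt"]) <= set(h.pts)

    def test_zero_missingness_injects_nothing(self):
        h = generate_hierarchy(1, 2, 4, seed=0)
        cfg = ScenarioConfig(n_cases=1500, missingness_rates=MissingnessRates.none(), seed=1)
        db = generate_database(cfg, h)
        assert (db.demo["sex"] != "").all()
        assert not db.demo["age"].isin(["", "youth", "elderly"]).any()
        assert set(db.demo["case_id"]) == set(db.hist["case_id"])
        gt = db.ground_truth
        assert gt["excluded_missing_sex"] == 0
        assert gt["excluded_missing_age"] == 0
        assert gt["excluded_missing_primary_disease"] == 0

    def test_configured_fractions_recovered(self):
        # empirical elderly fraction and exposure prevalence within 3 SE
        h = generate_hierarchy(1, 2, 4, seed=0)
        n = 40_000
        cfg = ScenarioConfig(n_cases=n, elderly_fraction=0.625,
                             exposure_prevalence=0.05, seed=3)
        db = generate_database(cfg, h)
        frac_e = db.ground_truth["elderly"].mean()
        se_e = np.sqrt(0.625 * 0.375 / n)
        assert abs(frac_e - 0.625) < 3 * se_e
        frac_x = db.drug.loc[db.drug["role"] == "suspected", "case_id"].nunique() / n
        se_x = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac_x - 0.05) < 3 * se_x

    def test_spiked_scenario_raises_elderly_rate_only(self):
        h = generate_hierarchy(2, 6, 18, seed=2)
        spiked = h.hlgts[0]
        cfg = elderly_risk_scenario(h, spiked_hlgt=spiked, multiplier=20.0,
                                    n_cases=20_000, seed=4)
        db = generate_database(cfg, h)
        counts = db.ground_truth["event_counts"]
        elderly = db.ground_truth["elderly"]
        exposed = db.ground_truth["exposed"]
        rate = lambda s, ex: counts[(spiked, s, ex)] / max(
            1, ((elderly == (s == "elderly")) & (exposed == ex)).sum()
        )
        assert rate("elderly", True) > 5 * rate("elderly", False)
        assert rate("non_elderly", True) < 3 * rate("non_elderly", False)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(n_cases=0).validate()
        with pytest.raises(ConfigurationError):
            ScenarioConfig(elderly_fraction=1.5).validate()
        with pytest.raises(ConfigurationError):
            ScenarioConfig(association_multipliers={("H", "elderly"): -1}).validate()


class TestNullScenarioCalibration:
    """With all multipliers = 1 the pipeline sees only sampling noise."""

    @staticmethod
    def _null_signals(n_cases, seed):
        from pvsignal.contingency import count_all
        from pvsignal.disproportionality import analyze_counts
        from pvsignal.io import RawTables, apply_exclusions

        h = generate_hierarchy(2, 12, 24, seed=31)
        cfg = ScenarioConfig(n_cases=n_cases, exposure_prevalence=0.1,
                             baseline_event_rates={x: 0.02 for x in h.hlgts},
                             missingness_rates=MissingnessRates.none(), seed=seed)
        db = generate_database(cfg, h)
        ds = apply_exclusions(RawTables(db.demo.astype(str), db.drug.astype(str),
                                        db.reac.astype(str), db.hist.astype(str)))
        signals, _ = analyze_counts(count_all(ds, hierarchy=h))
        return signals

    def test_prr_centers_on_one(self):
        signals = self._null_signals(20_000, seed=8)
        ln_prr = np.log(signals.loc[signals["prr"] > 0, "prr"])
        assert abs(ln_prr.mean()) < 0.25

    def test_detection_fraction_small_and_shrinking(self):
        frac = {}
        for n in (2000, 20_000):
            hits = total = 0
            for seed in (1, 2, 3):
                signals = self._null_signals(n, seed=seed)
                hits += int(signals["detected"].sum())
                total += len(signals)
            frac[n] = hits / total
        assert frac[20_000] <= 0.05
        assert frac[20_000] <= frac[2000] + 0.02
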
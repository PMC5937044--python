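"""Case-level 2x2 counting: toy enumerations, margins, brute-force oracle."""

import pytest

from conftest import make_dataset
from pvsignal.contingency import (
    ContingencyTable,
    ExposureDefinition,
    build_table,
    count_all,
    map_events_to_hlgt,
)
from pvsignal.io import apply_exclusions, RawTables
from pvsignal.synthetic import ScenarioConfig, generate_database, generate_hierarchy


def brute_force_counts(dataset, hierarchy, exposure):
    """Naive per-case double loop; the oracle the vectorized path must match."""
    out = {}
    hlgts = set()
    records = list(dataset.case_records())
    for case in records:
        hlgts |= map_events_to_hlgt(case, hierarchy)
    for stratum in ("elderly", "non_elderly"):
        for hlgt in sorted(hlgts):
            a = b = c = d = 0
            for case in records:
                if case.stratum != stratum:
                    continue
                exposed = any(exposure.matches(n, r) for n, r in case.drugs)
                has_event = hlgt in map_events_to_hlgt(case, hierarchy)
                if exposed and has_event:
                    a += 1
                elif exposed:
                    b += 1
                elif has_event:
                    c += 1
                else:
                    d += 1
            out[(stratum, hlgt)] = (a, b, c, d)
    return out


class TestMapEventsToHlgt:
    def test_two_pts_same_hlgt_count_once(self, toy_hierarchy):
        ds = make_dataset([{"case_id": "C1", "reactions": [("p1", "recovery"), ("p2", "death")]}])
        case = next(ds.case_records())
        assert map_events_to_hlgt(case, toy_hierarchy) == {"H"}

    def test_no_reactions_empty_set(self, toy_hierarchy):
        ds = make_dataset([{"case_id": "C1"}])
        case = next(ds.case_records())
        assert map_events_to_hlgt(case, toy_hierarchy) == set()

    def test_unmapped_pt_warns_and_drops(self, toy_hierarchy):
        ds = make_dataset([{"case_id": "C1", "reactions": [("mystery", "recovery")]}])
        case = next(ds.case_records())
        with pytest.warns(UserWarning, match="mystery"):
            assert map_events_to_hlgt(case, toy_hierarchy) == set()

    def test_case_count_adds_over_cases(self, toy_hierarchy):
        ds = make_dataset([
            {"case_id": f"C{i}", "reactions": [("p1", "recovery")]} for i in range(3)
        ])
        pairs_count = sum("H" in map_events_to_hlgt(c, toy_hierarchy)
                          for c in ds.case_records())
        assert pairs_count == 3


class TestBuildTable:
    def test_six_case_hand_enumeration(self, toy_hierarchy):
        # 3 exposed (2 with event H), 3 unexposed (1 with H) -> (2,1,1,2)
        cases = [
            {"case_id": "C1", "drugs": [("zolpidem", "suspected")], "reactions": [("p1", "recovery")]},
            {"case_id": "C2", "drugs": [("zopiclone", "suspected")], "reactions": [("p2", "death")]},
            {"case_id": "C3", "drugs": [("zolpidem", "suspected")]},
            {"case_id": "C4", "reactions": [("p1", "light")]},
            {"case_id": "C5"},
            {"case_id": "C6"},
        ]
        ds = make_dataset(cases)
        t = build_table(ds, "elderly", "H", hierarchy=toy_hierarchy)
        assert t.cells() == (2, 1, 1, 2)

    def test_empty_stratum_all_zero(self, toy_hierarchy):
        ds = make_dataset([{"case_id": "C1", "age": "70s"}])
        t = build_table(ds, "non_elderly", "H", hierarchy=toy_hierarchy)
        assert t.cells() == (0, 0, 0, 0)

    def test_unknown_hlgt_gives_empty_event_column(self, toy_hierarchy):
        ds = make_dataset([{"case_id": "C1", "drugs": [("zolpidem", "suspected")]}])
        t = build_table(ds, "elderly", "NOT_A_TERM", hierarchy=toy_hierarchy)
        assert (t.a, t.c) == (0, 0) and t.b == 1

    def test_role_filter_controls_exposure(self, toy_hierarchy):
        cases = [
            {"case_id": "C1", "drugs": [("zolpidem", "concomitant")],
             "reactions": [("p1", "recovery")]},
            {"case_id": "C2", "drugs": [("zolpidem", "suspected")],
             "reactions": [("p1", "recovery")]},
            {"case_id": "C3"},
        ]
        ds = make_dataset(cases)
        strict = build_table(ds, "elderly", "H",
                             ExposureDefinition(roles=frozenset({"suspected"})),
                             toy_hierarchy)
        broad = build_table(ds, "elderly", "H",
                            ExposureDefinition(roles=frozenset({"suspected", "concomitant"})),
                            toy_hierarchy)
        assert strict.a == 1 and broad.a == 2
        assert broad.a - strict.a == 1  # exactly the concomitant-only event case

    def test_name_matching_is_normalized(self, toy_hierarchy):
        ds = make_dataset([
            {"case_id": "C1", "drugs": [("  Zolpidem ", "suspected")],
             "reactions": [("p1", "recovery")]},
        ])
        t = build_table(ds, "elderly", "H", hierarchy=toy_hierarchy)
        assert t.a == 1

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestCountAll:
    def test_margins_are_stratum_constants(self, toy_hierarchy):
        h = generate_hierarchy(2, 5, 15, seed=3)
        db = generate_database(ScenarioConfig(n_cases=3000, seed=3), h)
        ds = apply_exclusions(RawTables(db.demo.astype(str), db.drug.astype(str),
                                        db.reac.astype(str), db.hist.astype(str)))
        counts = count_all(ds, hierarchy=h)
        for stratum, expected_total in (("elderly", ds.n_elderly),
                                        ("non_elderly", ds.n_non_elderly)):
            sub = counts[counts["stratum"] == stratum]
            # a+b (exposed margin) identical across HLGTs; cells sum to stratum size
            assert (sub["a"] + sub["b"]).nunique() == 1
            assert ((sub["a"] + sub["b"] + sub["c"] + sub["d"]) == expected_total).all()

    def test_matches_brute_force_oracle_on_small_datasets(self):
        exposure = ExposureDefinition()
        for seed in range(6):
            h = generate_hierarchy(2, 4, 10, seed=seed)
            cfg = ScenarioConfig(
                n_cases=120 + 10 * seed, exposure_prevalence=0.3,
                baseline_event_rates={x: 0.15 for x in h.hlgts}, seed=seed,
            )
            db = generate_database(cfg, h)
            ds = apply_exclusions(RawTables(db.demo.astype(str), db.drug.astype(str),
                                            db.reac.astype(str), db.hist.astype(str)))
            oracle = brute_force_counts(ds, h, exposure)
            counts = count_all(ds, exposure, h)
            got = {(r.stratum, r.hlgt): (r.a, r.b, r.c, r.d)
                   for r in counts.itertuples(index=False)}
            assert got == oracle
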
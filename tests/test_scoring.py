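import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvsofa.scoring import (
    M2,
    M3,
    NeqExposure,
    ScoreConfig,
    Windows,
    cns_score,
    coag_score,
    cv_sofa_modified,
    cv_sofa_original,
    liver_score,
    neq_exposure,
    neq_rate,
    organ_component,
    renal_score,
    resp_score,
    score_cohort,
    score_stay,
    worst_value,
)

from conftest import make_infusions, make_observations


class TestWorstValue:
    def test_min_of_map(self):
        obs = make_observations([("MAP", 1.0, 80.0), ("MAP", 5.0, 62.0), ("MAP", 9.0, 71.0)])
        assert worst_value(obs, "MAP", (0, 24), "min") == 62.0

    def test_lab_window_reaches_6h_before_admission(self):
        obs = make_observations([("lactate", -5.0, 3.1), ("lactate", 10.0, 2.0)])
        assert worst_value(obs, "lactate", (-6, 24), "max") == 3.1

    def test_outside_window_is_absent(self):
        obs = make_observations([("lactate", -7.0, 3.1)])
        assert worst_value(obs, "lactate", (-6, 24), "max") is None

    def test_half_open_upper_bound(self):
        obs = make_observations([("MAP", 24.0, 40.0), ("MAP", 23.99, 80.0)])
        assert worst_value(obs, "MAP", (0, 24), "min") == 80.0

    @given(
        st.lists(
            st.tuples(
                st.floats(-12, 36),
                st.floats(10, 300, allow_nan=False),
            ),
            min_size=0,
            max_size=30,
        ),
        st.sampled_from(["min", "max"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_full_scan(self, points, direction):
        obs = make_observations([("lactate", t, v) for t, v in points])
        got = worst_value(obs, "lactate", (-6, 24), direction)
        inwin = [v for t, v in points if -6 <= t < 24]
        expected = (min(inwin) if direction == "min" else max(inwin)) if inwin else None
        assert got == expected


class TestNeqRate:
    @pytest.mark.parametrize(
        "drug,rate,units,expected",
        [
            ("norepinephrine", 0.1, "ug_per_kg_min", 0.1),
            ("epinephrine", 0.07, "ug_per_kg_min", 0.07),
            ("dopamine", 5.0, "ug_per_kg_min", 0.05),
            ("phenylephrine", 1.0, "ug_per_kg_min", 0.1),
            ("vasopressin", 0.04, "units_per_min", 0.1),
            ("dobutamine", 5.0, "ug_per_kg_min", 0.0),
        ],
    )
    def test_conversion_table(self, drug, rate, units, expected):
        assert neq_rate(drug, rate, units) == pytest.approx(expected)

    def test_unknown_drug_fatal(self):
        with pytest.raises(ValueError):
            neq_rate("milrinone", 1.0)

    def test_vasopressin_unit_enforced(self):
        with pytest.raises(ValueError):
            neq_rate("vasopressin", 0.04, "ug_per_kg_min")


class TestNeqExposure:
    def test_single_constant_infusion(self):
        inf = make_infusions([("norepinephrine", 0.0, 6.0, 0.3)])
        exp = neq_exposure(inf)
        assert exp.max_sustained_neq == pytest.approx(0.3)
        assert exp.any_vasopressor
        assert exp.per_drug_max_rate == {"norepinephrine": 0.3}

    def test_concurrent_sum_sustained_one_hour(self):
        # norepinephrine 0.2 for [0,3) plus vasopressin 0.04 U/min for [1,2):
        # summed level 0.3 holds for exactly 1 h
        inf = make_infusions(
            [("norepinephrine", 0.0, 3.0, 0.2), ("vasopressin", 1.0, 2.0, 0.04)]
        )
        exp = neq_exposure(inf)
        assert exp.max_sustained_neq == pytest.approx(0.3)

    def test_sub_hour_infusion_does_not_qualify(self):
        inf = make_infusions([("norepinephrine", 0.0, 0.5, 0.5)])
        exp = neq_exposure(inf)
        assert not exp.any_vasopressor
        assert exp.max_sustained_neq == 0.0
        assert exp.per_drug_max_rate == {}

    def test_dobutamine_is_not_a_vasopressor(self):
        inf = make_infusions([("dobutamine", 0.0, 6.0, 5.0)])
        exp = neq_exposure(inf)
        assert not exp.any_vasopressor
        assert exp.max_sustained_neq == 0.0
        assert exp.per_drug_max_rate == {"dobutamine": 5.0}

    def test_clipping_to_infusion_window(self):
        inf = make_infusions([("norepinephrine", -3.0, 0.5, 0.4)])
        exp = neq_exposure(inf)  # only [0, 0.5) remains: below 1 h
        assert exp.max_sustained_neq == 0.0

    def test_max_drug_aggregation(self):
        inf = make_infusions(
            [("norepinephrine", 0.0, 6.0, 0.2), ("vasopressin", 0.0, 6.0, 0.04)]
        )
        assert neq_exposure(inf).max_sustained_neq == pytest.approx(0.3)
        assert neq_exposure(inf, aggregation="max_drug").max_sustained_neq == pytest.approx(0.2)

    def test_matches_one_minute_discretization_oracle(self):
        rng = np.random.default_rng(7)
        drugs = ["norepinephrine", "epinephrine", "phenylephrine", "dopamine",
                 "vasopressin", "dobutamine"]
        from cvsofa.scoring import DEFAULT_NEQ_FACTORS

        for _ in range(40):
            n = rng.integers(1, 11)
            rows = []
            for _ in range(n):
                drug = drugs[rng.integers(0, len(drugs))]
                # minute-aligned endpoints make the discretized oracle exact
                s = rng.integers(-60, 23 * 60) / 60.0
                e = s + rng.integers(10, 18 * 60) / 60.0
                rate = float(rng.uniform(0.01, 0.6))
                rows.append((drug, s, e, rate))
            exp = neq_exposure(make_infusions(rows))

            # oracle: 1-minute grid over [0, 24), same drug prefilter
            grid = np.zeros(24 * 60)
            minutes = (np.arange(24 * 60) + 0.5) / 60.0
            totals = {}
            for drug, s, e, rate in rows:
                lo, hi = max(s, 0.0), min(e, 24.0)
                if hi > lo:
                    totals[drug] = totals.get(drug, 0.0) + (hi - lo)
            for drug, s, e, rate in rows:
                if totals.get(drug, 0.0) >= 1.0 - 1e-9:
                    units = "units_per_min" if drug == "vasopressin" else "ug_per_kg_min"
                    grid[(minutes >= max(s, 0)) & (minutes < min(e, 24))] += neq_rate(
                        drug, rate, units
                    )
            levels = np.unique(grid[grid > 0])
            oracle = 0.0
            for v in levels:
                if (grid >= v - 1e-12).sum() >= 60:
                    oracle = max(oracle, v)
            any_vp = any(
                totals.get(d, 0.0) >= 1.0 - 1e-9 for d in totals if d != "dobutamine"
            )
            if not any_vp:
                oracle = 0.0
            assert exp.max_sustained_neq == pytest.approx(oracle, abs=1e-9)


class TestCvOriginal:
    @pytest.mark.parametrize(
        "rates,map_min,expected",
        [
            ({"dopamine": 3.0}, 65.0, 2),
            ({"norepinephrine": 0.05}, 80.0, 3),
            ({"norepinephrine": 0.1}, 80.0, 3),  # boundary: <=0.1 scores 3
            ({"norepinephrine": 0.2}, 80.0, 4),
            ({"epinephrine": 0.1}, 80.0, 3),
            ({"epinephrine": 0.11}, 80.0, 4),
            ({"dopamine": 5.0}, 80.0, 2),
            ({"dopamine": 5.1}, 80.0, 3),
            ({"dopamine": 15.0}, 80.0, 3),
            ({"dopamine": 16.0}, 80.0, 4),
            ({"dobutamine": 2.0}, 80.0, 2),
            ({}, 65.0, 1),
            ({}, 80.0, 0),
            ({}, None, 0),  # absent MAP treated as normal
            ({"phenylephrine": 2.0}, 80.0, 0),  # not scored by original rules
        ],
    )
    def test_rules(self, rates, map_min, expected):
        neq = NeqExposure(
            max_sustained_neq=0.0,
            any_vasopressor=bool(set(rates) - {"dobutamine"}),
            per_drug_max_rate=rates,
        )
        assert cv_sofa_original(map_min, neq) == expected

    def test_highest_scoring_drug_governs(self):
        neq = NeqExposure(0.0, True, {"dopamine": 3.0, "norepinephrine": 0.2})
        assert cv_sofa_original(70.0, neq) == 4


def _neq(dose):
    return NeqExposure(dose, dose > 0, {"norepinephrine": dose} if dose > 0 else {})


class TestCvModified:
    @pytest.mark.parametrize(
        "map_min,dose,lactate,expected",
        [
            (60.0, 0.0, 1.0, 1),   # hypotension alone
            (80.0, 0.3, 3.0, 3),   # band 2 plus lactate point
            (80.0, 0.6, 1.0, 3),   # top NEq band, lactate below threshold
            (80.0, 0.6, 2.5, 4),   # 4 only as NEq > 0.5 AND lactate >= 2
            (85.0, 0.0, 2.5, 1),   # lactate adds a point at base 0
            (80.0, 0.2, 1.0, 1),   # boundary: NEq <= 0.2 is band 1
            (80.0, 0.21, 1.0, 2),
            (80.0, 0.5, 1.0, 2),   # boundary: NEq <= 0.5 is band 2
            (80.0, 0.51, 1.0, 3),
            (80.0, 0.0, None, 0),  # absent lactate adds nothing
            (None, 0.0, 1.0, 0),   # absent MAP treated as normal
            (69.9, 0.0, 2.0, 2),   # hypotension + lactate
        ],
    )
    def test_m3_rules(self, map_min, dose, lactate, expected):
        assert cv_sofa_modified(map_min, _neq(dose), lactate, M3) == expected

    @pytest.mark.parametrize(
        "map_min,dose,lactate,expected",
        [
            (60.0, 0.0, 3.0, 1),   # lactate 3 below the M2 threshold of 4
            (80.0, 0.15, 2.0, 2),  # 0.1 < NEq <= 0.2
            (80.0, 0.3, 3.9, 3),
            (80.0, 0.3, 4.5, 4),
            (80.0, 0.1, 1.0, 1),   # boundary: NEq <= 0.1 is band 1
            (60.0, 0.0, 4.0, 2),
        ],
    )
    def test_m2_rules(self, map_min, dose, lactate, expected):
        assert cv_sofa_modified(map_min, _neq(dose), lactate, M2) == expected

    @pytest.mark.parametrize("variant", [M3, M2])
    def test_monotone_in_neq_and_lactate(self, variant):
        doses = [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.5, 0.6, 1.0, 2.0]
        lactates = [0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 8.0]
        for map_min in (60.0, 80.0):
            for lac in lactates:
                scores = [
                    cv_sofa_modified(map_min, _neq(d), lac, variant) for d in doses
                ]
                assert scores == sorted(scores)
            for d in doses:
                scores = [
                    cv_sofa_modified(map_min, _neq(d), lac, variant) for lac in lactates
                ]
                assert scores == sorted(scores)

    def test_table_and_prose_encodings_agree_on_grid(self):
        """The banded table with its add-one lactate overlay and the prose
        point list describe the same M3 function."""

        def from_table(map_min, dose, lactate):
            # table rows: 0 MAP>=70; 1 MAP<70 or NEq<=0.2; 2 0.2<NEq<=0.5;
            # 3 NEq>0.5; 4 NEq>0.5 and lactate>=2; add 1 if lactate>=2 (rows 0-3)
            if dose > 0.5:
                base = 3
            elif dose > 0.2:
                base = 2
            elif dose > 0 or map_min < 70:
                base = 1
            else:
                base = 0
            if lactate >= 2:
                return 4 if base == 3 else base + 1
            return base

        def from_prose(map_min, dose, lactate):
            # 1 point for hypotension or NEq <= 0.2; 2 for 0.2 < NEq <= 0.5;
            # 3 for NEq > 0.5; 4 for NEq > 0.5 and lactate >= 2;
            # plus the lactate criterion adding 1 to scores 0-3
            if dose > 0.5 and lactate >= 2:
                return 4
            if dose > 0.5:
                score = 3
            elif 0.2 < dose <= 0.5:
                score = 2
            elif (0 < dose <= 0.2) or map_min < 70:
                score = 1
            else:
                score = 0
            if lactate >= 2 and score <= 3:
                score += 1
            return min(score, 4)

        for map_min in (60.0, 80.0):
            for dose in (0.0, 0.1, 0.2, 0.21, 0.5, 0.51, 1.0):
                for lactate in (1.0, 2.0, 5.0):
                    got = cv_sofa_modified(map_min, _neq(dose), lactate, M3)
                    assert got == from_table(map_min, dose, lactate)
                    assert got == from_prose(map_min, dose, lactate)


class TestOrganComponents:
    @pytest.mark.parametrize(
        "component,values,vent,expected",
        [
            ("coag", {"platelets": 155.0}, False, 0),
            ("coag", {"platelets": 149.0}, False, 1),
            ("coag", {"platelets": 90.0}, False, 2),
            ("coag", {"platelets": 45.0}, False, 3),
            ("coag", {"platelets": 15.0}, False, 4),
            ("liver", {"bilirubin": 1.0}, False, 0),
            ("liver", {"bilirubin": 1.2}, False, 1),
            ("liver", {"bilirubin": 3.7}, False, 2),
            ("liver", {"bilirubin": 7.0}, False, 3),
            ("liver", {"bilirubin": 12.0}, False, 4),
            ("cns", {"gcs": 15.0}, False, 0),
            ("cns", {"gcs": 13.0}, False, 1),
            ("cns", {"gcs": 10.0}, False, 2),
            ("cns", {"gcs": 6.0}, False, 3),
            ("cns", {"gcs": 5.0}, False, 4),
            ("renal", {"creatinine": 1.1}, False, 0),
            ("renal", {"creatinine": 1.2}, False, 1),
            ("renal", {"creatinine": 2.5}, False, 2),
            ("renal", {"creatinine": 4.0}, False, 3),
            ("renal", {"creatinine": 5.0}, False, 4),
            ("renal", {"creatinine": 1.0, "urine_24h": 450.0}, False, 3),
            ("renal", {"creatinine": 1.0, "urine_24h": 150.0}, False, 4),
            ("resp", {"pf_ratio": 420.0}, False, 0),
            ("resp", {"pf_ratio": 350.0}, False, 1),
            ("resp", {"pf_ratio": 250.0}, False, 2),
            ("resp", {"pf_ratio": 150.0}, True, 3),
            ("resp", {"pf_ratio": 150.0}, False, 2),  # no support caps at 2
            ("resp", {"pf_ratio": 90.0}, True, 4),
            ("resp", {}, False, 0),
            ("coag", {}, False, 0),  # missing scores zero
        ],
    )
    def test_standard_cutoffs(self, component, values, vent, expected):
        assert organ_component(values, component, ventilated=vent) == expected


class TestScoreStay:
    def test_worked_example(self, toy_bundle):
        panel = score_stay(toy_bundle, "stay4")
        assert panel.cv_original == 4
        assert panel.cv_m3 == 3
        assert panel.cv_m2 == 3
        assert panel.coag == 2
        assert panel.total_original == 6
        assert panel.total_m3 == 5
        assert panel.map_min == 60.0
        assert panel.lactate_max == 3.0
        assert panel.neq.max_sustained_neq == pytest.approx(0.3)

    def test_no_data_stay_scores_zero(self, toy_bundle):
        panel = score_stay(toy_bundle, "stay5")
        assert panel.total_original == 0
        assert panel.total_m3 == 0
        assert panel.cv_original == 0

    def test_total_identity(self, toy_bundle):
        for sid in ("stay4", "stay5", "stay6"):
            p = score_stay(toy_bundle, sid)
            assert p.total_m3 - p.total_original == p.cv_m3 - p.cv_original
            assert p.total_m2 - p.total_original == p.cv_m2 - p.cv_original

    def test_unknown_stay_raises(self, toy_bundle):
        with pytest.raises(KeyError):
            score_stay(toy_bundle, "nope")


class TestScoreCohort:
    def test_score_bounds_on_synthetic_data(self, small_bundle):
        bundle, _ = small_bundle
        scores = score_cohort(bundle)
        for comp in ("resp", "coag", "liver", "cns", "renal",
                     "cv_original", "cv_m2", "cv_m3"):
            assert scores[comp].between(0, 4).all()
        for total in ("total_original", "total_m2", "total_m3"):
            assert scores[total].between(0, 24).all()
        base = scores[["resp", "coag", "liver", "cns", "renal"]].sum(axis=1)
        assert (scores["total_m3"] == base + scores["cv_m3"]).all()

    def test_deterministic_output_bytes(self, small_bundle, tmp_path):
        from cvsofa.scoring import write_scores
        from cvsofa.cohort import build_cohort

        bundle, _ = small_bundle
        cohort = build_cohort(bundle)
        for name in ("a.csv", "b.csv"):
            write_scores(score_cohort(bundle, cohort), tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_empty_cohort(self, toy_bundle):
        scores = score_cohort(toy_bundle, [])
        assert len(scores) == 0
        assert list(scores.columns)[:3] == ["stay_id", "resp", "coag"]
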
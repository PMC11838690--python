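"""Screening rules, baseline windowing, outcome derivation and encodings."""

import numpy as np
import pandas as pd
import pytest

from mddpredict.cohort_prep import (
    CONTINUOUS_COLUMNS,
    ContractError,
    RACE_INDICATOR_COLUMNS,
    ScreeningConfig,
    baseline_window,
    derive_outcome,
    encode_features,
    screen_participants,
    standardize,
)
from mddpredict.synthetic_data import RawCohortTable, SimConfig, generate_cohort

from .conftest import zero_missing_config


def _tiny_raw(rows):
    """Raw table from a list of dicts with baseline fields only."""
    defaults = dict(
        age=30,
        gender="female",
        race_ethnicity="Asian",
        working=1,
        married_partnered=0,
        education_beyond_hs=1,
        income_satisfaction="comfortable",
        arm="iPST",
        lithium_history=0,
        mania_medication_history=0,
        bipolar_diagnosis=0,
    )
    recs = []
    for i, r in enumerate(rows):
        rec = {"participant_id": f"P{i:03d}", **defaults, **r}
        recs.append(rec)
    baseline = pd.DataFrame(recs)
    responses = pd.DataFrame(
        {"participant_id": pd.Series(dtype=str), "instrument": pd.Series(dtype=str),
         "day_offset": pd.Series(dtype="int64"), "score": pd.Series(dtype="int64")}
    )
    followup = pd.DataFrame({"participant_id": pd.Series(dtype=str),
                             "week": pd.Series(dtype="int64"),
                             "phq9": pd.Series(dtype="Int64")})
    return RawCohortTable(baseline, responses, followup)


class TestScreening:
    def test_exclusion_rules(self):
        raw = _tiny_raw(
            [
                {"baseline_phq9": 9},  # below severity screen
                {"baseline_phq9": 15, "lithium_history": 1},
                {"baseline_phq9": 12, "mania_medication_history": 1},
                {"baseline_phq9": 20, "bipolar_diagnosis": 1},
                {"baseline_phq9": 10},  # boundary: retained ("below 10" excluded)
                {"baseline_phq9": 27},
            ]
        )
        screened, log = screen_participants(raw)
        assert list(screened["participant_id"]) == ["P004", "P005"]
        assert log["excluded_low_baseline_phq9"] == 1
        assert log["excluded_bipolar_history"] == 3
        assert log["n_retained"] == 2

    def test_missing_bipolar_flags_treated_as_not_endorsed(self):
        raw = _tiny_raw([{"baseline_phq9": 14, "lithium_history": None}])
        raw.baseline["lithium_history"] = pd.array([pd.NA], dtype="Int64")
        screened, _ = screen_participants(raw)
        assert len(screened) == 1

    def test_screening_idempotent(self):
        cohort = generate_cohort(SimConfig(n_participants=200, bipolar_flag_rate=0.1, rng_seed=3))
        screened, _ = screen_participants(cohort)
        kept = set(screened["participant_id"])
        pruned = RawCohortTable(
            cohort.baseline[cohort.baseline["participant_id"].isin(kept)].reset_index(drop=True),
            cohort.responses[cohort.responses["participant_id"].isin(kept)].reset_index(drop=True),
            cohort.followup[cohort.followup["participant_id"].isin(kept)].reset_index(drop=True),
        )
        again, log = screen_participants(pruned)
        assert list(again["participant_id"]) == list(screened["participant_id"])
        assert log["excluded_low_baseline_phq9"] == 0
        assert log["excluded_bipolar_history"] == 0

    def test_exclude_baseline_only_sensitivity(self):
        cohort = generate_cohort(SimConfig(n_participants=800, rng_seed=6))
        _, log_main = screen_participants(cohort)
        screened, log = screen_participants(
            cohort, ScreeningConfig(exclude_baseline_only=True)
        )
        assert log["excluded_baseline_only"] > 0
        assert log["n_retained"] == log_main["n_retained"] - log["excluded_baseline_only"]
        # survivors have at least one questionnaire or follow-up score
        score_cols = ["gad7", "sds", "auditc"] + [c for c in screened if c.startswith("phq9_week_")]
        assert screened[score_cols].notna().any(axis=1).all()


class TestBaselineWindow:
    @pytest.mark.parametrize(
        "records,expected",
        [
            ([(2, 12), (4, 9)], 12.0),  # earliest wins, not lowest
            ([(6, 7)], float("nan")),  # outside the 5-day window
            ([(0, 3)], 3.0),
            ([(5, 8)], 8.0),  # day 5 inclusive
        ],
    )
    def test_windowing(self, records, expected):
        df = pd.DataFrame(records, columns=["day_offset", "score"])
        got = baseline_window(df)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_negative_day_offset_rejected(self):
        df = pd.DataFrame([(-1, 5)], columns=["day_offset", "score"])
        with pytest.raises(ValueError):
            baseline_window(df)


class TestOutcome:
    @pytest.mark.parametrize(
        "baseline,followup,expected",
        [
            (20, 9, 1),
            (18, 9, 1),  # exactly 50% reduction qualifies
            (12, 9, 0),  # below 10 but reduction only 25%
            (24, 11, 0),  # 50% met but still >= 10
            (10, 5, 1),
            (10, 6, 0),
        ],
    )
    def test_response_criteria(self, baseline, followup, expected):
        assert derive_outcome(baseline, followup) == expected

    def test_missing_followup_gives_missing_outcome(self):
        assert derive_outcome(15, None) is None
        assert derive_outcome(15, float("nan")) is None

    def test_unscreened_baseline_rejected(self):
        with pytest.raises(ContractError):
            derive_outcome(9, 4)

    def test_monotone_in_followup(self):
        for b in (10, 17, 27):
            vals = [derive_outcome(b, f) for f in range(28)]
            assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_matches_latent_labels_on_complete_data(self):
        cohort = generate_cohort(zero_missing_config(n_participants=2000, rng_seed=8))
        screened, _ = screen_participants(cohort)
        table = encode_features(screened)
        got = table.data["outcome"].to_numpy(dtype=int)
        want = cohort.truth["improved"].to_numpy().astype(int)
        assert (got == want).all()


class TestEncoding:
    def test_income_binarization(self):
        raw = _tiny_raw(
            [
                {"baseline_phq9": 12, "income_satisfaction": "can't make ends meet"},
                {"baseline_phq9": 12, "income_satisfaction": "comfortable"},
                {"baseline_phq9": 12, "income_satisfaction": "have enough to get along"},
                {"baseline_phq9": 12, "income_satisfaction": None},
            ]
        )
        screened, _ = screen_participants(raw)
        enc = encode_features(screened).data
        assert list(enc["income_satisfaction"][:3]) == [1, 0, 0]
        assert enc["income_satisfaction"].isna().tolist() == [False, False, False, True]

    def test_race_collapsing(self):
        raw = _tiny_raw(
            [
                {"baseline_phq9": 12, "race_ethnicity": "More than one"},
                {"baseline_phq9": 12, "race_ethnicity": "American Indian/Alaskan Native"},
                {"baseline_phq9": 12, "race_ethnicity": "Non-Hispanic White"},
            ]
        )
        enc = encode_features(screen_participants(raw)[0]).data
        assert enc.loc[0, "race_multiracial_other"] == 1
        assert enc.loc[1, "race_multiracial_other"] == 1
        assert enc.loc[2, "race_non_hispanic_white"] == 1
        assert (enc[list(RACE_INDICATOR_COLUMNS)].sum(axis=1) == 1).all()

    def test_arm_one_hot(self):
        raw = _tiny_raw([{"baseline_phq9": 12, "arm": a} for a in ("EVO", "iPST", "HealthTips")])
        enc = encode_features(screen_participants(raw)[0]).data
        assert enc[["arm_evo", "arm_ipst", "arm_healthtips"]].to_numpy().tolist() == [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
        ]

    def test_unknown_level_rejected(self):
        raw = _tiny_raw([{"baseline_phq9": 12, "race_ethnicity": "Martian"}])
        with pytest.raises(ValueError, match="race"):
            encode_features(screen_participants(raw)[0])


class TestStandardize:
    def test_hand_computed_population_scaling(self):
        df = pd.DataFrame({"gad7": [10.0, 12.0, 14.0], "gender": [0, 1, 1]})
        out = standardize(df)
        expected = [-1.224744871391589, 0.0, 1.224744871391589]
        assert np.allclose(out["gad7"], expected)
        assert out["gender"].tolist() == [0, 1, 1]  # categorical untouched

    def test_zero_variance_column_centered_with_unit_scale(self):
        df = pd.DataFrame({"age": [5.0, 5.0, 5.0]})
        assert standardize(df)["age"].tolist() == [0.0, 0.0, 0.0]

    def test_apply_rows_use_train_statistics(self):
        train = pd.DataFrame({"sds": [0.0, 10.0]})
        apply = pd.DataFrame({"sds": [5.0, 20.0]})
        out = standardize(train, apply)
        assert np.allclose(out["sds"], [0.0, 3.0])  # mean 5, pop SD 5

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"age": []}))
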
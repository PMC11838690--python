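"""Screening, baseline windowing, outcome derivation and feature encoding.

Turns raw trial tables into a per-participant analysis matrix:

* retain participants with baseline PHQ-9 >= 10 and no endorsed bipolar
  history (missing history counts as not endorsed);
* baseline questionnaire score = earliest response within 5 days of
  enrollment, otherwise missing;
* binary improvement outcome = follow-up PHQ-9 < 10 AND reduced by >= 50%
  from baseline, evaluated with exact integer arithmetic;
* encodings: gender female=1; race/ethnicity as five collapsed indicator
  columns treated as a single selectable feature; marital status,
  education and income satisfaction binarized; one indicator per
  treatment arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import BIPOLAR_FLAG_COLUMNS, RawCohortTable

__all__ = [
    "ScreeningConfig",
    "AnalysisTable",
    "screen_participants",
    "baseline_window",
    "derive_outcome",
    "derive_outcome_vector",
    "encode_features",
    "standardize",
    "FEATURE_ORDER",
    "FEATURE_GROUPS",
    "CONTINUOUS_COLUMNS",
]

#: Collapsing of raw race/ethnicity response options into the five
#: analysis categories (small groups pooled into "Multiracial/other").
RACE_COLLAPSE = {
    "African-American/Black": "African-American/Black",
    "Asian": "Asian",
    "Hispanic/Latino": "Hispanic/Latino",
    "Non-Hispanic White": "Non-Hispanic White",
    "Native Hawaiian/other Pacific Islander": "Multiracial/other",
    "American Indian/Alaskan Native": "Multiracial/other",
    "More than one": "Multiracial/other",
    "Multiracial/other": "Multiracial/other",
}

RACE_CATEGORIES = (
    "African-American/Black",
    "Asian",
    "Hispanic/Latino",
    "Multiracial/other",
    "Non-Hispanic White",
)

RACE_INDICATOR_COLUMNS = tuple(
    "race_" + c.lower().replace("-", "_").replace("/", "_").replace(" ", "_")
    for c in RACE_CATEGORIES
)

INCOME_DISTRESS_RESPONSE = "can't make ends meet"
KNOWN_INCOME_RESPONSES = {
    "can't make ends meet",
    "have enough to get along",
    "comfortable",
}

#: Selectable features in their canonical listing order (demographics,
#: questionnaire scores, treatment-arm indicators).  Race/ethnicity is a
#: single selectable unit backed by five indicator columns; each arm
#: indicator is individually selectable.
FEATURE_ORDER: tuple[str, ...] = (
    "age",
    "gender",
    "race_ethnicity",
    "working",
    "married_partnered",
    "education_beyond_hs",
    "income_satisfaction",
    "baseline_phq9",
    "gad7",
    "sds",
    "auditc",
    "arm_evo",
    "arm_ipst",
    "arm_healthtips",
)

FEATURE_GROUPS: Mapping[str, tuple[str, ...]] = {
    **{f: (f,) for f in FEATURE_ORDER if f != "race_ethnicity"},
    "race_ethnicity": RACE_INDICATOR_COLUMNS,
}

#: Non-categorical model columns, rescaled to mean 0 / SD 1 before fitting.
CONTINUOUS_COLUMNS = ("age", "baseline_phq9", "gad7", "sds", "auditc")

ARM_INDICATORS = {"EVO": "arm_evo", "iPST": "arm_ipst", "HealthTips": "arm_healthtips"}


class ContractError(ValueError):
    """An operation was called outside its contract (e.g. unscreened input)."""


@dataclass(frozen=True)
class ScreeningConfig:
    min_baseline_phq9: int = 10
    max_baseline_window_days: int = 5
    outcome_week: int = 4
    exclude_baseline_only: bool = False

    def validate(self) -> None:
        if not 0 <= self.min_baseline_phq9 <= 27:
            raise ValueError("min_baseline_phq9 must be in [0, 27]")
        if self.outcome_week < 1:
            raise ValueError("outcome_week must be >= 1")
        if self.max_baseline_window_days < 0:
            raise ValueError("max_baseline_window_days must be >= 0")

    def with_(self, **kwargs) -> "ScreeningConfig":
        return replace(self, **kwargs)


@dataclass
class AnalysisTable:
    """One row per retained participant.

    ``data`` holds the encoded feature columns (see :data:`FEATURE_GROUPS`),
    the raw follow-up PHQ-9 columns ``phq9_week_<k>`` (nullable ints), the
    derived ``outcome`` (nullable 0/1) and the ``arm`` label kept for
    subgroup analyses.  Missing cells use pandas NA.
    """

    data: pd.DataFrame
    outcome_week: int = 4
    screening_log: dict = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        return [c for g in FEATURE_ORDER for c in FEATURE_GROUPS[g]]

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    def validate(self, min_baseline_phq9: int = 10) -> None:
        df = self.data
        if df["participant_id"].duplicated().any():
            raise ValueError("duplicate participant_id")
        if (df["baseline_phq9"] < min_baseline_phq9).any():
            raise ValueError("participant below the baseline PHQ-9 screen retained")
        arm_sum = df[list(ARM_INDICATORS.values())].sum(axis=1)
        if (arm_sum != 1).any():
            raise ValueError("arm indicators are not one-hot")


def baseline_window(
    responses: pd.DataFrame, cfg: ScreeningConfig | None = None
) -> float:
    """Earliest response within the enrollment window for one
    participant/instrument; NaN if none qualifies.

    ``responses`` needs columns ``day_offset`` and ``score``; day 5 itself is
    inside the default window (only responses *more than* 5 days out are
    discarded).
    """
    cfg = cfg or ScreeningConfig()
    if len(responses) == 0:
        return float("nan")
    if (responses["day_offset"] < 0).any():
        raise ValueError("day_offset must be non-negative")
    eligible = responses[responses["day_offset"] <= cfg.max_baseline_window_days]
    if len(eligible) == 0:
        return float("nan")
    return float(eligible.loc[eligible["day_offset"].idxmin(), "score"])


def derive_outcome(baseline_phq9: int, followup_phq9) -> int | None:
    """Treatment response at the outcome week: follow-up PHQ-9 < 10 AND
    <= half the baseline (exact integer comparison, so 18 -> 9 counts).

    Returns 1/0, or None when the follow-up score is missing.
    """
    if baseline_phq9 < 10:
        raise ContractError("derive_outcome requires baseline PHQ-9 >= 10 (screen first)")
    if followup_phq9 is None or (isinstance(followup_phq9, float) and np.isnan(followup_phq9)) or followup_phq9 is pd.NA:
        return None
    f = int(followup_phq9)
    return int(f < 10 and 2 * f <= int(baseline_phq9))


def derive_outcome_vector(baseline: pd.Series, followup: pd.Series) -> pd.Series:
    """Vectorized :func:`derive_outcome`; missing follow-up -> pd.NA."""
    if (baseline < 10).any():
        raise ContractError("derive_outcome requires baseline PHQ-9 >= 10 (screen first)")
    fu = pd.array(followup, dtype="Int64")
    base = np.asarray(baseline, dtype=int)
    out = pd.array(
        [
            pd.NA if f is pd.NA else int(int(f) < 10 and 2 * int(f) <= int(b))
            for f, b in zip(fu, base)
        ],
        dtype="Int64",
    )
    return pd.Series(out, index=baseline.index, name="outcome")


def _windowed_scores(raw: RawCohortTable, cfg: ScreeningConfig) -> pd.DataFrame:
    """Per-participant windowed baseline questionnaire scores (wide)."""
    out = pd.DataFrame({"participant_id": raw.baseline["participant_id"]})
    for inst, col in (("GAD7", "gad7"), ("SDS", "sds"), ("AUDITC", "auditc")):
        sub = raw.responses[raw.responses["instrument"] == inst]
        sub = sub[sub["day_offset"] <= cfg.max_baseline_window_days]
        if len(sub):
            earliest = (
                sub.sort_values(["participant_id", "day_offset"], kind="stable")
                .groupby("participant_id", sort=False)
                .first()["score"]
            )
        else:
            earliest = pd.Series(dtype="int64")
        out[col] = out["participant_id"].map(earliest).astype("Int64")
    return out


def screen_participants(
    raw: RawCohortTable, cfg: ScreeningConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the inclusion criteria and assemble the wide screened table.

    Returns ``(screened, log)`` where ``log`` counts per-criterion
    exclusions.  The screened frame still carries raw category levels; run
    :func:`encode_features` next.  Missing bipolar-history flags are treated
    as not endorsed.
    """
    cfg = cfg or ScreeningConfig()
    cfg.validate()
    base = raw.baseline.copy()
    n_input = len(base)

    low_phq = base["baseline_phq9"] < cfg.min_baseline_phq9
    flags = base[list(BIPOLAR_FLAG_COLUMNS)].fillna(0).astype(int)
    bipolar = flags.any(axis=1)

    log = {
        "n_input": int(n_input),
        "excluded_low_baseline_phq9": int(low_phq.sum()),
        "excluded_bipolar_history": int((bipolar & ~low_phq).sum()),
    }
    keep = ~low_phq & ~bipolar

    screened = base[keep].reset_index(drop=True)
    scores = _windowed_scores(raw, cfg)
    screened = screened.merge(scores, on="participant_id", how="left")

    fu = raw.followup.pivot_table(
        index="participant_id", columns="week", values="phq9", aggfunc="first"
    )
    weeks = sorted(set(raw.followup["week"])) if len(raw.followup) else []
    for w in weeks:
        col = f"phq9_week_{w}"
        screened[col] = screened["participant_id"].map(fu[w] if w in fu else pd.Series(dtype="Int64")).astype("Int64")

    if cfg.exclude_baseline_only:
        score_cols = ["gad7", "sds", "auditc"] + [f"phq9_week_{w}" for w in weeks]
        baseline_only = screened[score_cols].isna().all(axis=1)
        log["excluded_baseline_only"] = int(baseline_only.sum())
        screened = screened[~baseline_only].reset_index(drop=True)
    log["n_retained"] = int(len(screened))
    return screened, log


def encode_features(
    screened: pd.DataFrame, cfg: ScreeningConfig | None = None
) -> AnalysisTable:
    """Encode the screened table into the analysis matrix and derive the
    outcome at ``cfg.outcome_week`` (missing where follow-up is missing)."""
    cfg = cfg or ScreeningConfig()
    df = pd.DataFrame({"participant_id": screened["participant_id"]})
    df["age"] = screened["age"].astype(float)

    gender = screened["gender"]
    unknown = set(gender.dropna()) - {"female", "male", 0, 1}
    if unknown:
        raise ValueError(f"unknown gender level(s): {sorted(map(str, unknown))}")
    df["gender"] = pd.array(
        [pd.NA if pd.isna(g) else int(g == "female" if isinstance(g, str) else g) for g in gender],
        dtype="Int64",
    )

    race = screened["race_ethnicity"].map(RACE_COLLAPSE)
    bad = screened["race_ethnicity"].notna() & race.isna()
    if bad.any():
        raise ValueError(
            f"unknown race/ethnicity level(s): {sorted(set(screened['race_ethnicity'][bad]))}"
        )
    for cat, col in zip(RACE_CATEGORIES, RACE_INDICATOR_COLUMNS):
        df[col] = pd.array(
            [pd.NA if pd.isna(r) else int(r == cat) for r in race], dtype="Int64"
        )

    for col in ("working", "married_partnered", "education_beyond_hs"):
        df[col] = pd.array(screened[col], dtype="Int64")

    inc = screened["income_satisfaction"]
    unknown_inc = {v for v in inc.dropna() if isinstance(v, str)} - KNOWN_INCOME_RESPONSES
    if unknown_inc:
        raise ValueError(f"unknown income-satisfaction level(s): {sorted(unknown_inc)}")
    df["income_satisfaction"] = pd.array(
        [
            pd.NA
            if pd.isna(v)
            else int(v == INCOME_DISTRESS_RESPONSE if isinstance(v, str) else v)
            for v in inc
        ],
        dtype="Int64",
    )

    df["baseline_phq9"] = screened["baseline_phq9"].astype(int)
    for col in ("gad7", "sds", "auditc"):
        df[col] = pd.array(screened[col], dtype="Int64")

    unknown_arm = set(screened["arm"]) - set(ARM_INDICATORS)
    if unknown_arm:
        raise ValueError(f"unknown arm level(s): {sorted(unknown_arm)}")
    for arm, col in ARM_INDICATORS.items():
        df[col] = (screened["arm"] == arm).astype("Int64")
    df["arm"] = screened["arm"]

    week_cols = sorted(
        (c for c in screened.columns if c.startswith("phq9_week_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    for c in week_cols:
        df[c] = pd.array(screened[c], dtype="Int64")

    fu_col = f"phq9_week_{cfg.outcome_week}"
    if fu_col in df.columns:
        df["outcome"] = derive_outcome_vector(df["baseline_phq9"], df[fu_col])
    else:
        df["outcome"] = pd.array([pd.NA] * len(df), dtype="Int64")

    table = AnalysisTable(df, outcome_week=cfg.outcome_week)
    table.validate(min_baseline_phq9=cfg.min_baseline_phq9)
    return table


def feature_schema() -> dict:
    """Machine-readable description of the analysis-table columns: the
    selectable feature groups, their member columns, and whether each
    column is continuous or categorical."""
    return {
        "feature_groups": {g: list(cols) for g, cols in FEATURE_GROUPS.items()},
        "column_types": {
            c: ("continuous" if c in CONTINUOUS_COLUMNS else "categorical")
            for g in FEATURE_ORDER
            for c in FEATURE_GROUPS[g]
        },
        "outcome": "outcome",
        "instrument_ranges": {"gad7": [0, 21], "sds": [0, 30], "auditc": [0, 12], "phq9": [0, 27]},
    }


def standardize(
    train: pd.DataFrame,
    apply_to: pd.DataFrame | None = None,
    columns: Sequence[str] = CONTINUOUS_COLUMNS,
) -> pd.DataFrame:
    """Rescale non-categorical columns to mean 0 / SD 1 using statistics of
    ``train`` only (population SD; zero-variance columns are centered with
    scale 1).  Returns a scaled copy of ``apply_to`` (default: of train)."""
    if len(train) == 0:
        raise ValueError("train must be non-empty")
    target = train if apply_to is None else apply_to
    out = target.copy()
    cols = [c for c in columns if c in target.columns]
    for c in cols:
        x = train[c].astype(float)
        mu = float(x.mean())
        sd = float(x.std(ddof=0))
        if not np.isfinite(sd) or sd == 0.0:
            sd = 1.0
        out[c] = (target[c].astype(float) - mu) / sd
    return out


def standardize_array(
    train: np.ndarray, apply_to: np.ndarray, continuous_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Array fast path used by the CV engine; same semantics as
    :func:`standardize` (population SD, zero-variance -> scale 1)."""
    mu = train[:, continuous_mask].mean(axis=0)
    sd = train[:, continuous_mask].std(axis=0)
    sd[sd == 0.0] = 1.0
    tr = train.copy()
    ap = apply_to.copy()
    tr[:, continuous_mask] = (tr[:, continuous_mask] - mu) / sd
    ap[:, continuous_mask] = (ap[:, continuous_mask] - mu) / sd
    return tr, ap
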
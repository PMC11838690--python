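"""Synthetic cohort generator for a remote MDD effectiveness trial.

Produces raw data tables with the statistical structure the downstream
analysis assumes: a depressed cohort (baseline PHQ-9 >= 10) randomized to
three smartphone-delivered interventions, baseline anxiety (GAD-7),
disability (SDS) and alcohol-use (AUDIT-C) questionnaires collected in the
days after enrollment, weekly follow-up PHQ-9, and heavy, structured
missingness: a "block-missing" subgroup with nothing beyond demographics
and baseline PHQ-9, item missingness on baseline questionnaires, and
week-specific follow-up missingness.

The improvement outcome is generated from a logistic model in which
crossing a GAD-7 threshold multiplies the odds of improvement by a
configurable factor; follow-up PHQ-9 trajectories are then constructed to
be exactly consistent with the drawn improvement status under the response
criteria (follow-up PHQ-9 < 10 and <= 50% of baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "RawCohortTable",
    "SimConfigError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "implied_improvement_rate",
]

ARMS = ("EVO", "iPST", "HealthTips")

INSTRUMENT_RANGES: Mapping[str, tuple[int, int]] = {
    "PHQ9": (0, 27),
    "GAD7": (0, 21),
    "SDS": (0, 30),
    "AUDITC": (0, 12),
}

# Raw response options; the analysis later collapses the last three.
RACE_LEVELS_RAW = (
    "African-American/Black",
    "Asian",
    "Hispanic/Latino",
    "Non-Hispanic White",
    "Native Hawaiian/other Pacific Islander",
    "American Indian/Alaskan Native",
    "More than one",
)

INCOME_RESPONSES = (
    "can't make ends meet",
    "have enough to get along",
    "comfortable",
)

BIPOLAR_FLAG_COLUMNS = (
    "lithium_history",
    "mania_medication_history",
    "bipolar_diagnosis",
)


class SimConfigError(ValueError):
    """Raised when a SimConfig field is outside its admissible range."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic cohort.

    Score distributions are discretized truncated normals; the GAD-7/SDS
    pair is driven by a latent bivariate normal whose Pearson correlation
    is chosen so the integerized scores hit ``gad7_sds_correlation`` on
    the Spearman scale.

    ``followup_missing_rates`` are *overall* marginal missingness targets
    per follow-up week (the block-missing subgroup counts toward them);
    ``item_missing_rate`` is the per-questionnaire rate among non-block
    participants, so the overall baseline-questionnaire missingness is
    ``block + (1 - block) * item``.
    """

    n_participants: int = 638
    arm_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # Baseline PHQ-9: discretized normal truncated to [10, 27].
    baseline_phq9_mean: float = 15.0
    baseline_phq9_sd: float = 4.0
    gad7_mean: float = 10.0
    gad7_sd: float = 5.0
    sds_mean: float = 16.0
    sds_sd: float = 7.0
    auditc_mean: float = 3.0
    auditc_sd: float = 2.5
    gad7_sds_correlation: float = 0.67
    block_missing_rate: float = 0.41
    item_missing_rate: float = 0.10
    income_missing_rate: float = 0.53
    followup_missing_rates: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.52, 2: 0.58, 3: 0.59, 4: 0.60}
    )
    true_threshold: int = 11
    true_or: float = 0.18
    base_improvement_rate: float = 0.58
    weeks: tuple[int, ...] = (1, 2, 3, 4)
    block_mechanism: str = "mcar"  # "mcar" | "mar"
    mar_strength: float = 1.0  # log-odds of block missingness per SD of baseline PHQ-9
    # Share of non-improved trajectories that fail via follow-up >= 10 (the
    # rest fail via reduction < 50%, only reachable for baseline <= 17).
    nonimproved_high_mode_frac: float = 0.5
    bipolar_flag_rate: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise SimConfigError("n_participants must be positive")
        if len(self.arm_probabilities) != 3:
            raise SimConfigError("arm_probabilities must have length 3")
        if any(p < 0 for p in self.arm_probabilities):
            raise SimConfigError("arm_probabilities must be non-negative")
        if abs(sum(self.arm_probabilities) - 1.0) > 1e-12:
            raise SimConfigError("arm_probabilities must sum to 1")
        if not -1.0 <= self.gad7_sds_correlation <= 1.0:
            raise SimConfigError("gad7_sds_correlation must be in [-1, 1]")
        for name in ("block_missing_rate", "item_missing_rate", "income_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SimConfigError(f"{name} must be in [0, 1)")
        for week, rate in self.followup_missing_rates.items():
            if not 0.0 <= rate < 1.0:
                raise SimConfigError(f"followup_missing_rates[{week}] must be in [0, 1)")
        if self.true_or <= 0:
            raise SimConfigError("true_or must be positive")
        if not 0.0 < self.base_improvement_rate < 1.0:
            raise SimConfigError("base_improvement_rate must be in (0, 1)")
        if not INSTRUMENT_RANGES["GAD7"][0] <= self.true_threshold <= INSTRUMENT_RANGES["GAD7"][1]:
            raise SimConfigError("true_threshold must be on the GAD-7 scale")
        if self.block_mechanism not in ("mcar", "mar"):
            raise SimConfigError("block_mechanism must be 'mcar' or 'mar'")
        if not self.weeks:
            raise SimConfigError("weeks must be non-empty")
        if any(w not in self.followup_missing_rates for w in self.weeks):
            raise SimConfigError("followup_missing_rates must cover every week in weeks")
        if not 0.0 <= self.nonimproved_high_mode_frac <= 1.0:
            raise SimConfigError("nonimproved_high_mode_frac must be in [0, 1]")
        if not 0.0 <= self.bipolar_flag_rate < 1.0:
            raise SimConfigError("bipolar_flag_rate must be in [0, 1)")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class RawCohortTable:
    """Raw trial export: baseline/demographics (wide), questionnaire
    responses (long), weekly follow-up PHQ-9 (long, explicit NaN for
    missing weeks).  ``truth`` carries the latent generative state for
    validation and is never serialized.
    """

    baseline: pd.DataFrame
    responses: pd.DataFrame
    followup: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> None:
        ids = self.baseline["participant_id"]
        if ids.duplicated().any():
            raise ValueError("participant_id not unique")
        id_set = set(ids)
        for df, name in ((self.responses, "responses"), (self.followup, "followup")):
            extra = set(df["participant_id"]) - id_set
            if extra:
                raise ValueError(f"{name} references unknown participants: {sorted(extra)[:5]}")
        for instrument, group in self.responses.groupby("instrument"):
            lo, hi = INSTRUMENT_RANGES[str(instrument)]
            scores = group["score"].dropna()
            if ((scores < lo) | (scores > hi)).any():
                raise ValueError(f"{instrument} score outside [{lo}, {hi}]")
        phq = self.followup["phq9"].dropna()
        if ((phq < 0) | (phq > 27)).any():
            raise ValueError("follow-up PHQ-9 outside [0, 27]")

    def __eq__(self, other: object) -> bool:  # truth excluded: raw-data identity only
        if not isinstance(other, RawCohortTable):
            return NotImplemented
        return (
            self.baseline.equals(other.baseline)
            and self.responses.equals(other.responses)
            and self.followup.equals(other.followup)
        )


def _latent_pearson_for_spearman(rho_s: float) -> float:
    """Invert the bivariate-normal Spearman relation rho_s = (6/pi) asin(r/2).

    Rounding the latent scores to integer questionnaire scales is monotone
    up to ties, so the discretized Spearman tracks the latent one to well
    within sampling noise at the scales used here.
    """
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _discretized_truncnorm_probs(mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    grid = np.arange(lo, hi + 1)
    p = norm.pdf((grid - mean) / sd)
    return p / p.sum()


def _improve_probability(gad7: np.ndarray, cfg: SimConfig) -> np.ndarray:
    base_logit = math.log(cfg.base_improvement_rate / (1 - cfg.base_improvement_rate))
    logit = base_logit + math.log(cfg.true_or) * (gad7 >= cfg.true_threshold)
    return 1.0 / (1.0 + np.exp(-logit))


def implied_improvement_rate(cfg: SimConfig) -> float:
    """Marginal P(improvement) implied by the generative model, by direct
    integration over the latent (pre-clipping) GAD-7 distribution."""
    # round(mean + sd*z) >= t  <=>  z >= (t - 0.5 - mean) / sd ; clipping at the
    # scale ends never moves a score across the threshold for 0 < t <= 21.
    p_high = norm.sf((cfg.true_threshold - 0.5 - cfg.gad7_mean) / cfg.gad7_sd)
    base = cfg.base_improvement_rate
    odds_high = cfg.true_or * base / (1 - base)
    p_imp_high = odds_high / (1 + odds_high)
    return (1 - p_high) * base + p_high * p_imp_high


def _followup_trajectory(
    baseline: int,
    improved: bool,
    weeks: Sequence[int],
    rng: np.random.Generator,
    high_mode_frac: float,
) -> dict[int, int]:
    """Weekly PHQ-9 scores consistent with the improvement label at the
    final listed week (the outcome week)."""
    final_week = max(weeks)
    if improved:
        # needs final < 10 and 2*final <= baseline
        upper = min(9, baseline // 2)
        final = int(rng.integers(0, upper + 1))
    else:
        shallow_possible = baseline // 2 + 1 <= 9  # an integer in (b/2, 10) exists
        if shallow_possible and rng.random() >= high_mode_frac:
            final = int(rng.integers(baseline // 2 + 1, 10))  # <10 but <50% drop
        else:
            final = int(rng.integers(10, min(baseline + 3, 27) + 1))  # still >= 10
    out: dict[int, int] = {}
    for w in weeks:
        if w == final_week:
            out[w] = final
        else:
            frac = w / final_week
            interp = baseline + frac * (final - baseline)
            noisy = int(round(interp + rng.normal(0.0, 1.5)))
            out[w] = int(np.clip(noisy, 0, 27))
    return out


def generate_cohort(config: SimConfig) -> RawCohortTable:
    """Draw one raw cohort under ``config``.

    Order of operations: complete data first (scores, outcome, trajectories),
    then block missingness, then item/follow-up missingness — so the latent
    truth is always defined and missingness never alters it.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_participants
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    arm = rng.choice(ARMS, size=n, p=np.asarray(config.arm_probabilities, dtype=float))

    phq_lo, phq_hi = 10, 27
    phq_probs = _discretized_truncnorm_probs(
        config.baseline_phq9_mean, config.baseline_phq9_sd, phq_lo, phq_hi
    )
    baseline_phq9 = rng.choice(np.arange(phq_lo, phq_hi + 1), size=n, p=phq_probs)

    r = _latent_pearson_for_spearman(config.gad7_sds_correlation)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]], size=n)
    gad7 = np.clip(np.round(config.gad7_mean + config.gad7_sd * z[:, 0]), 0, 21).astype(int)
    sds = np.clip(np.round(config.sds_mean + config.sds_sd * z[:, 1]), 0, 30).astype(int)
    auditc = np.clip(
        np.round(rng.normal(config.auditc_mean, config.auditc_sd, size=n)), 0, 12
    ).astype(int)

    age = np.clip(np.round(rng.normal(34, 10, size=n)), 18, 80).astype(int)
    gender = rng.choice(["female", "male"], size=n, p=[0.76, 0.24])
    race = rng.choice(
        RACE_LEVELS_RAW, size=n, p=[0.13, 0.06, 0.21, 0.50, 0.02, 0.02, 0.06]
    )
    working = (rng.random(n) < 0.60).astype(int)
    married = (rng.random(n) < 0.35).astype(int)
    education = (rng.random(n) < 0.75).astype(int)
    income = rng.choice(INCOME_RESPONSES, size=n, p=[0.30, 0.45, 0.25])
    flags = {c: (rng.random(n) < config.bipolar_flag_rate).astype(int) for c in BIPOLAR_FLAG_COLUMNS}

    p_improve = _improve_probability(gad7, config)
    improved = rng.random(n) < p_improve

    traj = [
        _followup_trajectory(
            int(baseline_phq9[i]), bool(improved[i]), config.weeks, rng,
            config.nonimproved_high_mode_frac,
        )
        for i in range(n)
    ]

    # --- missingness -----------------------------------------------------
    if config.block_mechanism == "mcar":
        block = rng.random(n) < config.block_missing_rate
    else:  # MAR: block probability rises with baseline severity
        zb = (baseline_phq9 - baseline_phq9.mean()) / max(baseline_phq9.std(), 1e-9)
        eta = math.log(config.block_missing_rate / (1 - config.block_missing_rate))
        p_block = 1.0 / (1.0 + np.exp(-(eta + config.mar_strength * zb)))
        block = rng.random(n) < p_block

    item_miss = {
        inst: ~block & (rng.random(n) < config.item_missing_rate)
        for inst in ("GAD7", "SDS", "AUDITC")
    }
    income_missing = rng.random(n) < config.income_missing_rate

    followup_missing: dict[int, np.ndarray] = {}
    blk = float(block.mean()) if n else 0.0
    for w in config.weeks:
        target = config.followup_missing_rates[w]
        cond = 0.0 if blk >= 1.0 else max(0.0, (target - blk) / (1.0 - blk))
        followup_missing[w] = block | (rng.random(n) < cond)

    day_offsets = {inst: rng.integers(0, 4, size=n) for inst in ("GAD7", "SDS", "AUDITC")}

    baseline_df = pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "gender": gender,
            "race_ethnicity": race,
            "working": working,
            "married_partnered": married,
            "education_beyond_hs": education,
            "income_satisfaction": np.where(income_missing, None, income),
            "baseline_phq9": baseline_phq9,
            "arm": arm,
            **flags,
        }
    )

    resp_rows = []
    scores = {"GAD7": gad7, "SDS": sds, "AUDITC": auditc}
    for inst in ("GAD7", "SDS", "AUDITC"):
        keep = ~block & ~item_miss[inst]
        for i in np.flatnonzero(keep):
            resp_rows.append((ids[i], inst, int(day_offsets[inst][i]), int(scores[inst][i])))
    responses_df = pd.DataFrame(
        resp_rows, columns=["participant_id", "instrument", "day_offset", "score"]
    ).astype({"day_offset": "int64", "score": "int64"}) if resp_rows else pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "instrument": pd.Series(dtype=str),
            "day_offset": pd.Series(dtype="int64"),
            "score": pd.Series(dtype="int64"),
        }
    )

    fu_rows = []
    for i in range(n):
        for w in config.weeks:
            val = None if followup_missing[w][i] else traj[i][w]
            fu_rows.append((ids[i], w, val))
    followup_df = pd.DataFrame(fu_rows, columns=["participant_id", "week", "phq9"])
    followup_df["phq9"] = followup_df["phq9"].astype("Int64")

    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "improved": improved,
            "p_improve": p_improve,
            "gad7": gad7,
            "sds": sds,
            "auditc": auditc,
            "block_missing": block,
        }
    )
    table = RawCohortTable(baseline_df, responses_df, followup_df, truth)
    table.validate()
    return table


# --- CSV round trip -------------------------------------------------------

_BASELINE_INT_COLS = (
    "age",
    "working",
    "married_partnered",
    "education_beyond_hs",
    "baseline_phq9",
) + BIPOLAR_FLAG_COLUMNS


def write_cohort(table: RawCohortTable, out_dir: str | Path) -> dict[str, Path]:
    """Serialize to ``baseline.csv``, ``responses.csv``, ``followup.csv``
    (RFC-4180, UTF-8, missing cells as empty fields)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "baseline": out / "baseline.csv",
        "responses": out / "responses.csv",
        "followup": out / "followup.csv",
    }
    table.baseline.to_csv(paths["baseline"], index=False)
    table.responses.to_csv(paths["responses"], index=False)
    table.followup.to_csv(paths["followup"], index=False)
    return paths


def read_cohort(in_dir: str | Path) -> RawCohortTable:
    p = Path(in_dir)
    baseline = pd.read_csv(p / "baseline.csv", dtype={"participant_id": str})
    for col in _BASELINE_INT_COLS:
        if col in baseline.columns:
            baseline[col] = baseline[col].astype("int64")
    # empty fields come back as NaN; normalize to None to match generation
    baseline["income_satisfaction"] = baseline["income_satisfaction"].where(
        baseline["income_satisfaction"].notna(), None
    )
    responses = pd.read_csv(p / "responses.csv", dtype={"participant_id": str})
    if len(responses):
        responses = responses.astype({"day_offset": "int64", "score": "int64"})
    else:
        responses = responses.astype(
            {"participant_id": str, "instrument": str, "day_offset": "int64", "score": "int64"}
        )
    followup = pd.read_csv(p / "followup.csv", dtype={"participant_id": str})
    followup["week"] = followup["week"].astype("int64") if len(followup) else followup.get(
        "week", pd.Series(dtype="int64")
    )
    followup["phq9"] = followup["phq9"].astype("Int64")
    table = RawCohortTable(baseline, responses, followup)
    table.validate()
    return table
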
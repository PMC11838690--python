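"""Multiple imputation by chained random forests with predictive mean
matching (PMM).

Each of M imputation streams starts from a random draw of observed values,
then performs a fixed number of chained sweeps.  Within a sweep, variables
with missingness are visited in ascending order of missingness fraction; a
random forest regresses the variable on all other analysis columns using
the rows where it is observed.  For integer/continuous variables the
missing entries are filled by PMM — each takes the observed value of one
of the ``pmm_donors`` rows whose forest-predicted mean is nearest (distance
ties enlarge the donor pool) — which keeps every imputed value inside the
observed support, hence inside the instrument range.  Binary variables are
drawn from the forest's predicted class probabilities.

Follow-up PHQ-9 is imputed on the raw score scale and the binary
improvement outcome is re-derived per completed dataset, so outcome
uncertainty propagates through Rubin pooling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .cohort_prep import (
    ARM_INDICATORS,
    AnalysisTable,
    FEATURE_GROUPS,
    derive_outcome_vector,
)

__all__ = ["ImputationConfig", "ImputedStack", "impute"]

#: columns that can carry missingness and how they are modeled
_BINARY_VARS = {"gender", "working", "married_partnered", "education_beyond_hs", "income_satisfaction"}


@dataclass(frozen=True)
class ImputationConfig:
    m_imputations: int = 100
    chain_iterations: int = 5
    pmm_donors: int = 5
    trees_per_forest: int = 100
    rng_seed: int = 0
    variables_to_impute: tuple[str, ...] | None = None  # None -> autodetect

    def validate(self) -> None:
        for name in ("m_imputations", "chain_iterations", "pmm_donors", "trees_per_forest"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def with_(self, **kwargs) -> "ImputationConfig":
        return replace(self, **kwargs)


@dataclass
class ImputedStack:
    """M completed copies of the analysis table sharing all observed cells.

    ``mask`` is True where the original cell was missing (i.e. imputed).
    """

    tables: list[pd.DataFrame]
    mask: pd.DataFrame
    config: ImputationConfig
    outcome_week: int = 4

    @property
    def m(self) -> int:
        return len(self.tables)

    def validate(self, original: AnalysisTable | None = None) -> None:
        ref = self.tables[0]
        value_cols = [c for c in self.mask.columns]
        for t in self.tables:
            if t[value_cols].isna().any().any():
                raise ValueError("missing cells remain after imputation")
            obs = ~self.mask
            for c in value_cols:
                same = t.loc[obs[c].to_numpy(), c].to_numpy() == ref.loc[obs[c].to_numpy(), c].to_numpy()
                if not np.all(same):
                    raise ValueError(f"observed cells of '{c}' differ across imputations")
        if original is not None:
            for c in value_cols:
                obs_rows = ~self.mask[c].to_numpy()
                orig = original.data[c].to_numpy()[obs_rows]
                if not np.array_equal(ref[c].to_numpy()[obs_rows].astype(float), orig.astype(float)):
                    raise ValueError(f"observed cells of '{c}' differ from the input")


def _pmm_draw(
    pred_obs: np.ndarray,
    y_obs: np.ndarray,
    pred_mis: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each missing prediction, draw the observed value of one of the
    ``donors`` nearest predicted means; ties at the cut distance all enter
    the donor pool."""
    out = np.empty(len(pred_mis), dtype=y_obs.dtype)
    k = min(donors, len(pred_obs))
    for j, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        kth = np.partition(d, k - 1)[k - 1]
        pool = np.flatnonzero(d <= kth)
        out[j] = y_obs[rng.choice(pool)]
    return out


def _model_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for g in FEATURE_GROUPS.values() for c in g]
    cols += [c for c in df.columns if c.startswith("phq9_week_")]
    return cols


def impute(table: AnalysisTable, cfg: ImputationConfig | None = None) -> ImputedStack:
    """Produce ``cfg.m_imputations`` completed datasets.

    Stream m is driven by an RNG seeded from ``(rng_seed, m)`` only, so any
    subset of streams reproduces in isolation.  A table without missing
    cells returns M identical copies.
    """
    cfg = cfg or ImputationConfig()
    cfg.validate()
    df = table.data
    model_cols = _model_columns(df)

    mask = df[model_cols].isna()
    if cfg.variables_to_impute is not None:
        to_impute = list(cfg.variables_to_impute)
        for v in to_impute:
            if v not in model_cols:
                raise ValueError(f"unknown variable to impute: {v!r}")
    else:
        to_impute = [c for c in model_cols if mask[c].any()]

    for v in to_impute:
        n_obs = int((~mask[v]).sum())
        if n_obs == 0:
            raise ValueError(f"variable {v!r} has no observed values; cannot impute")
        if n_obs < 2:
            raise ValueError(f"variable {v!r} has fewer than 2 observed rows")

    if not to_impute or not mask.to_numpy().any():
        tables = []
        for _ in range(cfg.m_imputations):
            tables.append(df.copy())
        return ImputedStack(tables, mask, cfg, outcome_week=table.outcome_week)

    # ascending missingness order, fixed for all sweeps
    order = sorted(to_impute, key=lambda v: (float(mask[v].mean()), model_cols.index(v)))

    base = df[model_cols].astype(float).to_numpy()
    col_ix = {c: i for i, c in enumerate(model_cols)}
    mis_rows = {v: np.flatnonzero(mask[v].to_numpy()) for v in order}
    obs_rows = {v: np.flatnonzero(~mask[v].to_numpy()) for v in order}

    tables: list[pd.DataFrame] = []
    for m in range(cfg.m_imputations):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, m)))
        x = base.copy()
        # initialize by sampling observed values
        for v in order:
            j = col_ix[v]
            x[mis_rows[v], j] = rng.choice(x[obs_rows[v], j], size=len(mis_rows[v]))

        for _sweep in range(cfg.chain_iterations):
            for v in order:
                j = col_ix[v]
                others = [i for i in range(len(model_cols)) if i != j]
                X_obs = x[np.ix_(obs_rows[v], others)]
                y_obs = x[obs_rows[v], j]
                X_mis = x[np.ix_(mis_rows[v], others)]
                seed = int(rng.integers(2**31 - 1))
                if v in _BINARY_VARS:
                    if len(np.unique(y_obs)) < 2:
                        x[mis_rows[v], j] = y_obs[0]
                        continue
                    clf = RandomForestClassifier(
                        n_estimators=cfg.trees_per_forest, random_state=seed, n_jobs=1
                    ).fit(X_obs, y_obs.astype(int))
                    proba = clf.predict_proba(X_mis)
                    cum = np.cumsum(proba, axis=1)
                    u = rng.random(len(X_mis))[:, None]
                    drawn = clf.classes_[(u > cum).sum(axis=1)]
                    x[mis_rows[v], j] = drawn.astype(float)
                else:
                    reg = RandomForestRegressor(
                        n_estimators=cfg.trees_per_forest, random_state=seed, n_jobs=1
                    ).fit(X_obs, y_obs)
                    pred_obs = reg.predict(X_obs)
                    pred_mis = reg.predict(X_mis)
                    x[mis_rows[v], j] = _pmm_draw(
                        pred_obs, y_obs, pred_mis, cfg.pmm_donors, rng
                    )

        out = df.copy()
        for v in order:
            filled = x[:, col_ix[v]]
            if pd.api.types.is_integer_dtype(df[v].dtype) or str(df[v].dtype) == "Int64":
                out[v] = pd.array(np.round(filled).astype(int), dtype="Int64")
            else:
                out[v] = filled
        fu_col = f"phq9_week_{table.outcome_week}"
        if fu_col in out.columns:
            out["outcome"] = derive_outcome_vector(out["baseline_phq9"], out[fu_col])
        tables.append(out)

    stack = ImputedStack(tables, mask, cfg, outcome_week=table.outcome_week)
    return stack


def write_stack(stack: ImputedStack, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(stack.tables):
        t.to_csv(out / f"imputed_{i:03d}.csv", index=False)
    stack.mask.to_csv(out / "mask.csv", index=False)
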
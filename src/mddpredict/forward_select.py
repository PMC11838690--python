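"""Greedy forward feature selection under the paired delta-AUC test.

A feature joins the model only if (i) its delta-AUC p-value survives
Benjamini-Hochberg FDR control over the comparisons accumulated for the
model family and (ii) the mean AUC improvement is at least
``min_delta_auc`` (default 0.02) — a practical-significance floor that
keeps the model parsimonious.  Selection stops the first time no candidate
passes both gates.  For the tree-based families the whole selection is
swept over maximum depths 1-5 and the depth with the best final AUC wins
(ties to the shallower, more interpretable tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cohort_prep import FEATURE_ORDER
from .model_eval import (
    CVConfig,
    CVResult,
    DeltaAUCResult,
    ModelSpec,
    delta_auc_test,
    mc_cv,
)

__all__ = [
    "SelectionConfig",
    "SelectionTrace",
    "CandidateRecord",
    "bh_adjust",
    "forward_select",
    "depth_sweep",
]


def bh_adjust(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure.

    Returns a boolean rejection flag per input p-value: hypotheses with the
    k* smallest p-values are rejected, where k* = max{i : p_(i) <= i q / m}
    (empty if no such i).
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) * q) / m
    passed = np.flatnonzero(p[order] <= thresholds)
    flags = np.zeros(m, dtype=bool)
    if len(passed):
        k_star = passed[-1] + 1
        flags[order[:k_star]] = True
    return flags


@dataclass(frozen=True)
class SelectionConfig:
    fdr_q: float = 0.05
    min_delta_auc: float = 0.02
    depth_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    cv: CVConfig = field(default_factory=CVConfig)
    bh_scope: str = "cumulative"  # "cumulative" | "per_step"

    def validate(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.min_delta_auc < 0:
            raise ValueError("min_delta_auc must be >= 0")
        if self.bh_scope not in ("cumulative", "per_step"):
            raise ValueError("bh_scope must be 'cumulative' or 'per_step'")
        self.cv.validate()

    def with_(self, **kwargs) -> "SelectionConfig":
        return replace(self, **kwargs)


@dataclass
class CandidateRecord:
    feature: str
    delta: DeltaAUCResult
    raw_p: float
    bh_rejected: bool = False
    accepted: bool = False


@dataclass
class StepRecord:
    step: int
    candidates: list[CandidateRecord]
    chosen: str | None


@dataclass
class SelectionTrace:
    """Ordered record of a forward-selection run for one model spec."""

    model: ModelSpec
    steps: list[StepRecord] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    final_result: CVResult | None = None

    @property
    def final_mean_auc(self) -> float:
        return self.final_result.mean_auc if self.final_result is not None else 0.5

    def to_dict(self) -> dict:
        return {
            "family": self.model.family,
            "max_depth": self.model.max_depth,
            "selected": list(self.selected),
            "final_auc_mean": self.final_mean_auc,
            "final_auc_ci95": list(self.final_result.auc_ci95()) if self.final_result else None,
            "final_accuracy_mean": (
                self.final_result.mean_accuracy if self.final_result else None
            ),
            "steps": [
                {
                    "step": s.step,
                    "chosen": s.chosen,
                    "candidates": [
                        {
                            "feature": c.feature,
                            "mean_delta_auc": c.delta.mean_delta,
                            "delta_ci95": list(c.delta.ci95),
                            "p_value": c.raw_p,
                            "bh_rejected": bool(c.bh_rejected),
                            "accepted": bool(c.accepted),
                            "candidate_auc_mean": c.delta.candidate_mean_auc,
                        }
                        for c in s.candidates
                    ],
                }
                for s in self.steps
            ],
        }


def _order_key(feature: str) -> int:
    try:
        return FEATURE_ORDER.index(feature)
    except ValueError:
        return len(FEATURE_ORDER)


def forward_select(
    stack,
    features: Sequence[str],
    model: ModelSpec,
    cfg: SelectionConfig,
    _p_accumulator: list[float] | None = None,
) -> SelectionTrace:
    """Run forward selection for one model spec.

    At each step every not-yet-selected feature (group) is evaluated by
    paired MC-CV against the current best model (the 0.5 chance level at
    step 0).  BH control is applied across all comparisons accumulated for
    the family (``bh_scope='cumulative'``, re-adjusted as comparisons
    accrue; ``'per_step'`` limits the family to the current step).  Among
    candidates passing both gates the highest mean AUC wins; ties break by
    the canonical feature listing order.

    ``_p_accumulator`` lets :func:`depth_sweep` share one BH family across
    depths of the same model type.
    """
    if not features:
        raise ValueError("at least one candidate feature is required")
    cfg.validate()
    trace = SelectionTrace(model=model)
    remaining = list(features)
    selected: list[str] = []
    reference_aucs: np.ndarray | float = 0.5
    reference_result: CVResult | None = None
    accumulated: list[float] = _p_accumulator if _p_accumulator is not None else []

    step = 0
    while remaining:
        candidates: list[CandidateRecord] = []
        for feat in remaining:
            res = mc_cv(selected + [feat], model, stack, cfg.cv)
            delta = delta_auc_test(res.aucs, reference_aucs, accuracy_mean=res.mean_accuracy)
            candidates.append(CandidateRecord(feature=feat, delta=delta, raw_p=delta.p_value))
            candidates[-1]._cv_result = res  # kept for promoting the winner
        step_ps = [c.raw_p for c in candidates]
        if cfg.bh_scope == "cumulative":
            accumulated.extend(step_ps)
            flags = bh_adjust(accumulated, cfg.fdr_q)[-len(step_ps):]
        else:
            flags = bh_adjust(step_ps, cfg.fdr_q)
        for c, f in zip(candidates, flags):
            c.bh_rejected = bool(f)

        eligible = [
            c for c in candidates if c.bh_rejected and c.delta.mean_delta >= cfg.min_delta_auc
        ]
        chosen: CandidateRecord | None = None
        if eligible:
            best_auc = max(c.delta.candidate_mean_auc for c in eligible)
            tied = [c for c in eligible if c.delta.candidate_mean_auc == best_auc]
            chosen = min(tied, key=lambda c: _order_key(c.feature))
            chosen.accepted = True

        trace.steps.append(
            StepRecord(step=step, candidates=candidates, chosen=chosen.feature if chosen else None)
        )
        if chosen is None:
            break
        selected.append(chosen.feature)
        remaining.remove(chosen.feature)
        reference_result = chosen._cv_result
        reference_aucs = reference_result.aucs
        step += 1

    trace.selected = selected
    trace.final_result = reference_result
    return trace


def depth_sweep(
    stack,
    features: Sequence[str],
    family: str,
    cfg: SelectionConfig,
    base_spec_kwargs: dict | None = None,
) -> tuple[int, SelectionTrace, dict[int, SelectionTrace]]:
    """Forward selection per maximum tree depth; returns the winning depth,
    its trace, and all traces.  The winner is the depth whose final model
    has the highest mean AUC (an empty selection scores 0.5); ties go to
    the smaller depth."""
    if family not in ("decision_tree", "random_forest"):
        raise ValueError("depth_sweep applies to tree-based families only")
    cfg.validate()
    kwargs = base_spec_kwargs or {}
    shared_ps: list[float] | None = [] if cfg.bh_scope == "cumulative" else None
    traces: dict[int, SelectionTrace] = {}
    for depth in cfg.depth_range:
        spec = ModelSpec(family=family, max_depth=depth, **kwargs)
        traces[depth] = forward_select(stack, features, spec, cfg, _p_accumulator=shared_ps)
    best_depth = min(
        traces,
        key=lambda d: (-traces[d].final_mean_auc, d),
    )
    return best_depth, traces[best_depth], traces
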
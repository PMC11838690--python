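"""End-to-end orchestration: simulate (or load) -> screen/encode ->
impute -> forward-select per model family -> threshold + pooled ORs.

A single master seed fans out to fixed, named substreams (simulation,
imputation, cross-validation) so one integer reproduces a full run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort_prep import (
    FEATURE_ORDER,
    ScreeningConfig,
    encode_features,
    feature_schema,
    screen_participants,
)
from .forward_select import SelectionConfig, depth_sweep, forward_select
from .mice_rf import ImputationConfig, impute, write_stack
from .model_eval import CVConfig, MODEL_FAMILIES, ModelSpec
from .synthetic_data import SimConfig, generate_cohort, read_cohort, write_cohort
from .threshold_inference import extract_threshold, spearman_rho, subgroup_ors

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

# fixed substream tags hung off the master seed
_STREAM_SIM = 11
_STREAM_IMPUTE = 23
_STREAM_CV = 37


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def _substream_seed(master: int, tag: int) -> int:
    return int(np.random.SeedSequence((master, tag)).generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    seed: int = 0
    sim: SimConfig | None = field(default_factory=SimConfig)
    input_dir: str | None = None  # alternative to simulation: CSV trio
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    families: tuple[str, ...] = MODEL_FAMILIES
    features: tuple[str, ...] = FEATURE_ORDER
    threshold_feature: str | None = None  # None -> feature chosen by the depth-1 tree
    write_artifacts: bool = True

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of sim / input_dir must be set")
        for f in self.families:
            if f not in MODEL_FAMILIES:
                raise ValueError(f"unknown model family {f!r}")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Reduced-scale profile: 500 CV iterations, 10 imputations."""
        cfg = cls(
            seed=seed,
            imputation=ImputationConfig(m_imputations=10, trees_per_forest=30),
            selection=SelectionConfig(cv=CVConfig(n_iterations=500)),
            **overrides,
        )
        return cfg

    @classmethod
    def paper_scale(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Full-scale profile: 10,000 CV iterations, 100 imputations."""
        return cls(
            seed=seed,
            imputation=ImputationConfig(m_imputations=100),
            selection=SelectionConfig(cv=CVConfig(n_iterations=10_000)),
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if raw.get("input_dir"):
            kwargs["input_dir"] = str(raw["input_dir"])
            kwargs["sim"] = None
        elif "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if "screening" in raw:
            kwargs["screening"] = ScreeningConfig(**raw["screening"])
        if "imputation" in raw:
            kwargs["imputation"] = ImputationConfig(**raw["imputation"])
        if "selection" in raw:
            sel = dict(raw["selection"])
            if "cv" in sel:
                sel["cv"] = CVConfig(**sel["cv"])
            if "depth_range" in sel:
                sel["depth_range"] = tuple(sel["depth_range"])
            kwargs["selection"] = SelectionConfig(**sel)
        if "families" in raw:
            kwargs["families"] = tuple(raw["families"])
        if "features" in raw:
            kwargs["features"] = tuple(raw["features"])
        return cls(**kwargs)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and return (and optionally write) the results
    bundle.  Any stage failure raises :class:`PipelineError` naming the
    stage."""
    cfg.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log: dict = {"seed": cfg.seed, "version": __version__}

    # --- stage 1: raw cohort ---------------------------------------------
    try:
        if cfg.sim is not None:
            sim_cfg = cfg.sim.with_(rng_seed=_substream_seed(cfg.seed, _STREAM_SIM))
            raw = generate_cohort(sim_cfg)
            if out is not None and cfg.write_artifacts:
                write_cohort(raw, out / "cohort")
        else:
            raw = read_cohort(cfg.input_dir)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate/load", str(e)) from e

    # --- stage 2: screening + encoding -----------------------------------
    try:
        screened, screen_log = screen_participants(raw, cfg.screening)
        table = encode_features(screened, cfg.screening)
        log["screening"] = screen_log
        if out is not None and cfg.write_artifacts:
            table.data.to_csv(out / "analysis_table.csv", index=False)
            (out / "analysis_schema.json").write_text(json.dumps(feature_schema(), indent=2))
            (out / "screening_log.json").write_text(json.dumps(screen_log, indent=2))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cohort_prep", str(e)) from e

    # --- stage 3: imputation ----------------------------------------------
    try:
        imp_cfg = cfg.imputation.with_(rng_seed=_substream_seed(cfg.seed, _STREAM_IMPUTE))
        stack = impute(table, imp_cfg)
        if out is not None and cfg.write_artifacts:
            write_stack(stack, out / "imputed")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("mice_rf", str(e)) from e

    # --- stage 4: forward selection per family ---------------------------
    selection_results: dict[str, dict] = {}
    sel_cfg = cfg.selection.with_(
        cv=cfg.selection.cv.with_(rng_seed=_substream_seed(cfg.seed, _STREAM_CV))
    )
    try:
        for family in cfg.families:
            if family in ("decision_tree", "random_forest"):
                best_depth, trace, traces = depth_sweep(stack, list(cfg.features), family, sel_cfg)
                selection_results[family] = {
                    "best_depth": best_depth,
                    "trace": trace.to_dict(),
                    "depth_auc": {d: t.final_mean_auc for d, t in traces.items()},
                }
            else:
                spec = ModelSpec(family=family)
                trace = forward_select(stack, list(cfg.features), spec, sel_cfg)
                selection_results[family] = {"trace": trace.to_dict()}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("forward_select", str(e)) from e

    # --- stage 5: threshold + pooled odds ratios --------------------------
    try:
        threshold_report = None
        feature = cfg.threshold_feature
        if feature is None and "decision_tree" in selection_results:
            sel = selection_results["decision_tree"]["trace"]["selected"]
            if sel:
                feature = sel[0]
        if feature is None:
            feature = "gad7"
        rule = extract_threshold(stack, feature)
        ors = subgroup_ors(stack, rule)
        threshold_report = {
            "rule": rule.to_dict(),
            "odds_ratios": {k: v.to_dict() for k, v in ors.items()},
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("threshold_inference", str(e)) from e

    # post-hoc: observed-pairs rank correlation between anxiety and disability
    try:
        gx = table.data["gad7"].astype(float).to_numpy()
        gy = table.data["sds"].astype(float).to_numpy()
        spearman = spearman_rho(gx, gy).to_dict()
    except ValueError:
        spearman = None

    imp_rates = [float(t["outcome"].mean()) for t in stack.tables]
    results = {
        "config": {
            "seed": cfg.seed,
            "families": list(cfg.families),
            "m_imputations": imp_cfg.m_imputations,
            "cv_iterations": sel_cfg.cv.n_iterations,
            "outcome_week": cfg.screening.outcome_week,
            "exclude_baseline_only": cfg.screening.exclude_baseline_only,
        },
        "log": log,
        "n_participants": int(len(table.data)),
        "improvement_rate_mean": float(np.mean(imp_rates)),
        "selection": selection_results,
        "threshold_report": threshold_report,
        "spearman_gad7_sds": spearman,
    }
    if out is not None:
        (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    return results
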
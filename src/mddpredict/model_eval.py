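"""Classifier registry and the Monte-Carlo cross-validated, paired
delta-AUC engine.

Each CV iteration draws (an imputed dataset, an 80/20 participant split)
from an RNG stream indexed only by (seed, iteration).  Two models
evaluated under the same :class:`CVConfig` therefore see *identical*
resamples, which is the pairing contract the empirical delta-AUC test
relies on: per-iteration AUC differences are differences on the same data.

Significance of an AUC improvement is the empirical probability
p = P(dAUC <= 0) over iterations, computed with the add-one estimator
(#{dAUC <= 0} + 1)/(N + 1) so a finite sample never yields p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .cohort_prep import CONTINUOUS_COLUMNS, FEATURE_GROUPS, standardize_array

__all__ = [
    "ModelSpec",
    "CVConfig",
    "CVResult",
    "DeltaAUCResult",
    "MODEL_FAMILIES",
    "compute_auc",
    "mc_cv",
    "delta_auc_test",
]

MODEL_FAMILIES = (
    "logistic_regression",
    "linear_svm",
    "decision_tree",
    "random_forest",
    "knn",
)

_TREE_FAMILIES = {"decision_tree", "random_forest"}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with its (default) hyperparameters.

    ``max_depth`` applies only to the tree-based families; the other
    families reject it.
    """

    family: str
    max_depth: int | None = None
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family in _TREE_FAMILIES:
            if self.max_depth is None:
                raise ValueError(f"{self.family} requires max_depth")
            if not 1 <= self.max_depth:
                raise ValueError("max_depth must be >= 1")
        elif self.max_depth is not None:
            raise ValueError(f"max_depth is not applicable to {self.family}")

    def build(self, random_state: int):
        hp = dict(self.hyperparameters)
        if self.family == "logistic_regression":
            return LogisticRegression(**hp)
        if self.family == "linear_svm":
            hp.setdefault("dual", "auto")
            return LinearSVC(**hp)
        if self.family == "decision_tree":
            return DecisionTreeClassifier(max_depth=self.max_depth, random_state=random_state, **hp)
        if self.family == "random_forest":
            return RandomForestClassifier(
                max_depth=self.max_depth, random_state=random_state, n_jobs=1, **hp
            )
        return KNeighborsClassifier(**hp)


@dataclass(frozen=True)
class CVConfig:
    n_iterations: int = 10_000
    train_fraction: float = 0.8
    rng_seed: int = 0
    max_split_redraws: int = 100

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    def with_(self, **kwargs) -> "CVConfig":
        return replace(self, **kwargs)


@dataclass
class CVResult:
    aucs: np.ndarray
    accuracies: np.ndarray
    n_redraws: int
    draws: list | None = None  # (imputation index, train indices) per iteration, if recorded

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    def auc_ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.aucs, [2.5, 97.5])
        return float(lo), float(hi)

    def accuracy_ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accuracies, [2.5, 97.5])
        return float(lo), float(hi)


@dataclass
class DeltaAUCResult:
    """Empirical distribution of paired AUC differences for one
    candidate-vs-reference comparison."""

    delta_samples: np.ndarray
    mean_delta: float
    ci95: tuple[float, float]
    p_value: float
    candidate_mean_auc: float
    reference_mean_auc: float
    accuracy_mean: float | None = None


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC with midrank tie handling: the fraction of
    (positive, negative) pairs ordered correctly, ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("compute_auc requires both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _score_estimator(est, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Continuous scores plus the family's default decision threshold
    (0.5 on probabilities, 0 on margins)."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1], 0.5
    return est.decision_function(X), 0.0


def feature_columns(feature_groups: Sequence[str]) -> list[str]:
    cols: list[str] = []
    for g in feature_groups:
        cols.extend(FEATURE_GROUPS.get(g, (g,)))  # unknown names pass through as columns
    return cols


def mc_cv(
    feature_groups: Sequence[str],
    model: ModelSpec,
    stack,
    cfg: CVConfig,
    record_draws: bool = False,
) -> CVResult:
    """Monte-Carlo CV of ``model`` on the named feature groups over an
    :class:`~mddpredict.mice_rf.ImputedStack`.

    Per iteration: pick one imputed dataset uniformly, split participants
    80/20, standardize continuous features on the training fold only, fit,
    and score the held-out fold (AUC + accuracy at the family's default
    decision rule).  A held-out fold containing a single outcome class is
    redrawn within the iteration (counted in ``n_redraws``).
    """
    if not feature_groups:
        raise ValueError("feature_groups must be non-empty")
    cfg.validate()
    cols = feature_columns(feature_groups)
    continuous = np.array([c in CONTINUOUS_COLUMNS for c in cols])

    mats = [t[cols].to_numpy(dtype=float) for t in stack.tables]
    ys = [t["outcome"].to_numpy(dtype=int) for t in stack.tables]
    n = mats[0].shape[0]
    n_train = int(round(cfg.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    m = len(mats)

    root = np.random.SeedSequence(cfg.rng_seed)
    children = root.spawn(cfg.n_iterations)

    aucs = np.empty(cfg.n_iterations)
    accs = np.empty(cfg.n_iterations)
    draws: list | None = [] if record_draws else None
    redraws = 0
    for i in range(cfg.n_iterations):
        rng = np.random.default_rng(children[i])
        imp = int(rng.integers(m))
        y = ys[imp]
        for _attempt in range(cfg.max_split_redraws + 1):
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            if 0 < y[va].sum() < len(va) and 0 < y[tr].sum() < len(tr):
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a two-class split; outcome nearly constant")
        fit_seed = int(rng.integers(2**31 - 1))  # drawn for every family: keeps streams aligned
        if draws is not None:
            draws.append((imp, tr.copy()))
        X = mats[imp]
        Xtr, Xva = standardize_array(X[tr], X[va], continuous)
        est = model.build(random_state=fit_seed).fit(Xtr, y[tr])
        scores, thr = _score_estimator(est, Xva)
        aucs[i] = compute_auc(scores, y[va])
        accs[i] = float(((scores > thr).astype(int) == y[va]).mean())
    return CVResult(aucs, accs, redraws, draws)


def delta_auc_test(
    candidate_aucs: np.ndarray,
    reference_aucs: np.ndarray | float = 0.5,
    accuracy_mean: float | None = None,
) -> DeltaAUCResult:
    """Paired empirical test of a candidate model against a reference
    (another model's paired AUC vector, or the 0.5 chance level)."""
    cand = np.asarray(candidate_aucs, dtype=float)
    if np.isscalar(reference_aucs):
        ref = np.full_like(cand, float(reference_aucs))
    else:
        ref = np.asarray(reference_aucs, dtype=float)
        if ref.shape != cand.shape:
            raise ValueError("candidate and reference AUC vectors differ in length (pairing broken)")
    delta = cand - ref
    n = len(delta)
    p = (int((delta <= 0).sum()) + 1) / (n + 1)
    lo, hi = np.percentile(delta, [2.5, 97.5])
    return DeltaAUCResult(
        delta_samples=delta,
        mean_delta=float(delta.mean()),
        ci95=(float(lo), float(hi)),
        p_value=float(p),
        candidate_mean_auc=float(cand.mean()),
        reference_mean_auc=float(ref.mean()),
        accuracy_mean=accuracy_mean,
    )
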
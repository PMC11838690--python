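"""Interpretable threshold extraction and Rubin-pooled odds ratios.

The clinical deliverable of the pipeline is a depth-1 decision rule on a
single questionnaire score ("score >= c predicts non-improvement").  The
cut point is read off a depth-1 tree refit on each completed (imputed)
dataset; the real-valued split (a midpoint between adjacent integers) is
integerized by ceiling, and the reported cut is the median across
imputations.  Association strength is the 2x2 odds ratio of improvement
for high vs. low scorers, computed per imputation on the log scale (Wald
variance, Haldane-Anscombe 0.5 correction when a cell is empty) and
combined across imputations with Rubin's rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ThresholdRule",
    "PooledEstimate",
    "SpearmanResult",
    "extract_threshold",
    "odds_ratio_2x2",
    "pool_rubin",
    "subgroup_ors",
    "spearman_rho",
]


class ThresholdExtractionError(RuntimeError):
    pass


@dataclass
class ThresholdRule:
    feature: str
    cut_value: int
    per_imputation_cuts: list[int]
    direction: str = ">= cut_value predicts non-improvement"

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "cut_value": self.cut_value,
            "direction": self.direction,
            "per_imputation_cuts": list(self.per_imputation_cuts),
        }


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation log-scale estimates."""

    estimates: np.ndarray
    variances: np.ndarray
    q_bar: float
    u_bar: float
    b: float
    t: float
    df: float
    point: float  # exp(q_bar): odds-ratio scale
    ci95: tuple[float, float]
    p_value: float

    def to_dict(self) -> dict:
        return {
            "or": self.point,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "log_or": self.q_bar,
            "within_variance": self.u_bar,
            "between_variance": self.b,
            "total_variance": self.t,
            "df": self.df if math.isfinite(self.df) else None,
            "m": len(self.estimates),
        }


@dataclass
class SpearmanResult:
    rho: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    method: str = "fisher"

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "n": self.n,
            "method": self.method,
        }


def _integer_cut(split: float) -> int:
    # sklearn splits integer data at midpoints; "x <= 10.5" becomes ">= 11".
    return int(math.ceil(split))


def extract_threshold(stack, feature: str) -> ThresholdRule:
    """Fit a depth-1 tree of outcome on ``feature`` over every completed
    dataset and return the median integerized cut (lower median on even M)."""
    cuts: list[int] = []
    for idx, table in enumerate(stack.tables):
        X = table[feature].to_numpy(dtype=float).reshape(-1, 1)
        y = table["outcome"].to_numpy(dtype=int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        if tree.tree_.node_count < 3:
            raise ThresholdExtractionError(
                f"depth-1 tree found no split in imputation {idx} (constant feature or outcome)"
            )
        cuts.append(_integer_cut(float(tree.tree_.threshold[0])))
    ordered = sorted(cuts)
    cut_value = ordered[(len(ordered) - 1) // 2]
    return ThresholdRule(feature=feature, cut_value=cut_value, per_imputation_cuts=cuts)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio of improvement for the high group from the 2x2 table
    (a=high&improved, b=high&not, c=low&improved, d=low&not).

    Returns (or, log_or, var_log_or) with the Wald variance
    1/a + 1/b + 1/c + 1/d; any zero cell triggers the Haldane-Anscombe
    +0.5 correction on all four cells.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("a group (high or low) is absent from the table")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    log_or = math.log(or_)
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return float(or_), float(log_or), float(var)


def pool_rubin(estimates: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Rubin's rules on log-scale estimates.

    T = U_bar + (1 + 1/M) B; df = (M - 1)(1 + U_bar / ((1 + 1/M) B))^2;
    with B = 0 the t reference degenerates to the normal.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances differ in length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires at least 2 imputations")
    q_bar = float(q.mean())
    u_bar = float(u.mean())
    b = float(q.var(ddof=1))
    t = u_bar + (1 + 1 / m) * b
    if b == 0.0:
        df = math.inf
        crit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(q_bar) / math.sqrt(t))
    else:
        df = (m - 1) * (1 + u_bar / ((1 + 1 / m) * b)) ** 2
        crit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(q_bar) / math.sqrt(t), df)
    half = crit * math.sqrt(t)
    return PooledEstimate(
        estimates=q,
        variances=u,
        q_bar=q_bar,
        u_bar=u_bar,
        b=b,
        t=float(t),
        df=float(df),
        point=math.exp(q_bar),
        ci95=(math.exp(q_bar - half), math.exp(q_bar + half)),
        p_value=float(p),
    )


def _tables_2x2(table, rule: ThresholdRule) -> tuple[int, int, int, int]:
    high = table[rule.feature].to_numpy(dtype=float) >= rule.cut_value
    y = table["outcome"].to_numpy(dtype=int) == 1
    a = int(np.sum(high & y))
    b = int(np.sum(high & ~y))
    c = int(np.sum(~high & y))
    d = int(np.sum(~high & ~y))
    return a, b, c, d


def subgroup_ors(
    stack, rule: ThresholdRule, arm_column: str = "arm"
) -> dict[str, PooledEstimate]:
    """Pooled odds ratio of improvement given the rule, overall and within
    each treatment arm."""
    arms = list(dict.fromkeys(stack.tables[0][arm_column]))
    for arm in arms:
        if not (stack.tables[0][arm_column] == arm).any():
            raise ValueError(f"arm {arm!r} is empty")
    out: dict[str, PooledEstimate] = {}
    groups = [("overall", None)] + [(str(a), a) for a in arms]
    for name, arm in groups:
        logs, variances = [], []
        for table in stack.tables:
            sub = table if arm is None else table[table[arm_column] == arm]
            if len(sub) == 0:
                raise ValueError(f"arm {name!r} is empty")
            _, log_or, var = odds_ratio_2x2(*_tables_2x2(sub, rule))
            logs.append(log_or)
            variances.append(var)
        out[name] = pool_rubin(logs, variances)
    return out


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "fisher",
    n_bootstrap: int = 2000,
    rng_seed: int = 0,
) -> SpearmanResult:
    """Spearman rank correlation with a 95% CI.

    ``method='fisher'`` uses the z-transform CI with SE 1/sqrt(n-3);
    ``'bootstrap'`` resamples pairs.  Pairs with a missing member are
    dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in a vector")
    rho, _ = stats.spearmanr(x, y)
    rho = float(rho)
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    p = 2 * stats.norm.sf(abs(z) / se)
    if method == "fisher":
        ci = (math.tanh(z - 1.959963984540054 * se), math.tanh(z + 1.959963984540054 * se))
    elif method == "bootstrap":
        rng = np.random.default_rng(rng_seed)
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        rhos = np.array([stats.spearmanr(x[i], y[i])[0] for i in idx])
        lo, hi = np.nanpercentile(rhos, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        raise ValueError("method must be 'fisher' or 'bootstrap'")
    return SpearmanResult(rho=rho, ci95=ci, p_value=float(p), n=n, method=method)
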
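"""Fixed- and random-effects meta-analysis of per-study odds ratios.

Studies enter as OR with a 95% confidence interval; the interval is
converted back to a log-OR standard error assuming Wald construction
(z = 1.959964). Pooling is inverse-variance fixed-effects, with
Cochran's Q / I-squared heterogeneity and the DerSimonian-Laird moment
estimator of tau-squared for random effects. Model selection follows
the rule: random effects iff I2 > 50% and Q p-value < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

Z_95 = 1.959964


@dataclass(frozen=True)
class StudyEffect:
    label: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValueError(f"{self.label}: log_or must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.label}: se must be positive and finite")


@dataclass(frozen=True)
class MetaResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    q_p: float
    i2: float
    tau2: float
    model: str
    k: int


def se_from_ci(or_: float, ci_low: float, ci_high: float, label: str = "") -> StudyEffect:
    """Recover log-OR and its SE from an OR with 95% Wald CI bounds."""
    if not (0 < ci_low <= or_ <= ci_high):
        raise ValueError(
            f"need 0 < ci_low <= or <= ci_high, got ({or_}, {ci_low}, {ci_high})"
        )
    if ci_low == ci_high:
        raise ValueError("degenerate confidence interval (zero width)")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return StudyEffect(label=label, log_or=math.log(or_), se=se)


def _pool(effects: Sequence[StudyEffect], weights: Sequence[float]) -> tuple[float, float]:
    sw = sum(weights)
    theta = sum(w * e.log_or for w, e in zip(weights, effects)) / sw
    return theta, 1.0 / math.sqrt(sw)


def _z_p(theta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(theta) / se))


def pool_fixed(effects: Sequence[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effects pooled OR with 95% CI and z-test p."""
    if not effects:
        raise ValueError("need at least one study")
    w = [1.0 / (e.se * e.se) for e in effects]
    theta, se = _pool(effects, w)
    k = len(effects)
    if k >= 2:
        q, q_p, i2 = heterogeneity(effects)
    else:
        q, q_p, i2 = 0.0, 1.0, 0.0
    return MetaResult(
        pooled_or=math.exp(theta),
        ci_low=math.exp(theta - Z_95 * se),
        ci_high=math.exp(theta + Z_95 * se),
        p=_z_p(theta, se),
        q=q,
        q_p=q_p,
        i2=i2,
        tau2=0.0,
        model="fixed",
        k=k,
    )


def heterogeneity(effects: Sequence[StudyEffect]) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square(k-1) upper-tail p, and I2 in percent."""
    k = len(effects)
    if k < 2:
        raise ValueError("heterogeneity requires at least two studies")
    w = [1.0 / (e.se * e.se) for e in effects]
    theta, _ = _pool(effects, w)
    q = sum(wi * (e.log_or - theta) ** 2 for wi, e in zip(w, effects))
    q_p = float(stats.chi2.sf(q, k - 1))
    i2 = 0.0 if q == 0.0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, q_p, i2


def dl_tau2(effects: Sequence[StudyEffect]) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance."""
    k = len(effects)
    if k < 2:
        raise ValueError("tau2 requires at least two studies")
    w = [1.0 / (e.se * e.se) for e in effects]
    q, _, _ = heterogeneity(effects)
    sw = sum(w)
    c = sw - sum(wi * wi for wi in w) / sw
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def pool_random_dl(effects: Sequence[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooled OR with 95% CI and p."""
    k = len(effects)
    if k < 2:
        raise ValueError("random-effects pooling requires at least two studies")
    tau2 = dl_tau2(effects)
    w_star = [1.0 / (e.se * e.se + tau2) for e in effects]
    theta, se = _pool(effects, w_star)
    q, q_p, i2 = heterogeneity(effects)
    return MetaResult(
        pooled_or=math.exp(theta),
        ci_low=math.exp(theta - Z_95 * se),
        ci_high=math.exp(theta + Z_95 * se),
        p=_z_p(theta, se),
        q=q,
        q_p=q_p,
        i2=i2,
        tau2=tau2,
        model="random",
        k=k,
    )


def meta_analyze(effects: Sequence[StudyEffect]) -> MetaResult:
    """Pool with the model-selection rule: random effects iff I2 > 50
    and the Q test p-value < 0.05, otherwise fixed effects."""
    if not effects:
        raise ValueError("need at least one study")
    if len(effects) >= 2:
        _, q_p, i2 = heterogeneity(effects)
        if i2 > 50.0 and q_p < 0.05:
            return pool_random_dl(effects)
    return pool_fixed(effects)
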
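"""Fixed-effect meta-analysis of causal estimates across outcome cohorts and
statistical power for two-sample MR with a binary outcome.

Pooling is inverse-variance weighting on the log odds-ratio scale. Study
estimates may be supplied either as beta/SE or as a published odds ratio
with its 95% interval, from which the SE is recovered as
(ln hi - ln lo) / (2 z_0.975).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrResult, Z975, _normal_p

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyEstimate:
    """One cohort's causal estimate, on both OR and log scales."""

    label: str
    or_: float
    ci_low: float
    ci_high: float
    beta: float
    se: float

    def __post_init__(self):
        if not self.ci_low <= self.or_ <= self.ci_high:
            raise ValueError(f"{self.label}: OR outside its interval")
        if self.se < 0:
            raise ValueError(f"{self.label}: negative SE")

    @classmethod
    def from_or_ci(cls, label: str, or_: float, ci_low: float, ci_high: float):
        """Build from a published odds ratio and 95% CI."""
        return cls(label, or_, ci_low, ci_high, float(np.log(or_)),
                   ci_to_se(or_, ci_low, ci_high))

    @classmethod
    def from_result(cls, label: str, result: MrResult):
        return cls(label, result.or_, result.ci_low, result.ci_high,
                   result.beta, result.se)


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance pooled estimate across cohorts (fixed effect)."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    weights: tuple[float, ...]  # normalized, sum to 1
    model: str = "fixed"


@dataclass(frozen=True)
class PowerConfig:
    """Inputs for the binary-outcome power approximation."""

    n_out: int
    case_fraction: float
    r2: float
    or_: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0.0 <= self.r2 < 1.0:
            raise ValueError("r2 must be in [0, 1)")
        if self.or_ <= 0 or self.n_out <= 0 or not 0.0 < self.alpha < 1.0:
            raise ValueError("invalid power configuration")


def ci_to_se(or_: float, ci_low: float, ci_high: float) -> float:
    """Standard error of ln OR recovered from a 95% confidence interval."""
    if ci_low <= 0 or ci_high <= 0 or or_ <= 0:
        raise ValueError("OR and CI bounds must be positive")
    if not ci_low <= or_ <= ci_high:
        raise ValueError("OR must lie within its interval")
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * Z975)
    if se == 0.0:
        warnings.warn("degenerate interval (ci_low == ci_high) gives SE 0")
    mid = 0.5 * (np.log(ci_high) + np.log(ci_low))
    if abs(np.log(or_) - mid) > 0.01:
        warnings.warn(
            f"ln(OR) {np.log(or_):.4f} is off the log-interval midpoint "
            f"{mid:.4f}: published rounding may distort the recovered SE"
        )
    return float(se)


def meta_fixed(studies: Sequence[StudyEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooling on the log-OR scale."""
    if len(studies) == 0:
        raise ValueError("meta-analysis requires at least one study")
    beta = np.array([s.beta for s in studies])
    se = np.array([s.se for s in studies])
    if (se <= 0).any():
        raise ValueError("all study SEs must be positive for pooling")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    return MetaResult(
        beta=pooled,
        se=pooled_se,
        or_=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z975 * pooled_se)),
        ci_high=float(np.exp(pooled + Z975 * pooled_se)),
        pvalue=_normal_p(pooled, pooled_se),
        weights=tuple(float(x) for x in w / w.sum()),
    )


def meta_frame(studies: Sequence[StudyEstimate], result: MetaResult) -> pd.DataFrame:
    """Forest-plot-ready table: per-study rows plus the pooled row."""
    rows = [
        {
            "label": s.label,
            "or": s.or_,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "weight": result.weights[i],
        }
        for i, s in enumerate(studies)
    ]
    rows.append(
        {
            "label": "pooled (fixed)",
            "or": result.or_,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight": 1.0,
        }
    )
    return pd.DataFrame(rows)


def power_binary(cfg: PowerConfig) -> float:
    """Two-sided power of a two-sample MR test with a binary outcome.

    Normal approximation in the style of the mRnd calculator: the
    noncentrality is nu = |ln OR| sqrt(n_out R^2 K (1 - K)) and
    power = 1 - Phi(z_{1-a/2} - nu) + Phi(-z_{1-a/2} - nu). With R^2 = 0
    the test has power equal to its size alpha.
    """
    if cfg.r2 == 0.0:
        warnings.warn("r2 = 0: no instrument signal, power equals alpha")
        return cfg.alpha
    nu = abs(np.log(cfg.or_)) * np.sqrt(
        cfg.n_out * cfg.r2 * cfg.case_fraction * (1.0 - cfg.case_fraction)
    )
    z = stats.norm.ppf(1.0 - cfg.alpha / 2.0)
    return float(stats.norm.sf(z - nu) + stats.norm.cdf(-z - nu))
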
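"""Causal-effect estimators for two-sample summary-data MR.

Implements the Wald ratio for a single instrument and, for multiple
instruments, inverse-variance weighted (IVW) regression through the origin
under fixed or multiplicative random effects, MR-Egger regression with a
free intercept, and the weighted and simple median estimators with
parametric-bootstrap standard errors.

All estimators operate on harmonized variants: the exposure effect bx and
outcome effect by of each variant refer to the same effect allele, and every
estimator is invariant to relabeling that allele (a simultaneous sign flip
of bx and by).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedVariant

log = logging.getLogger(__name__)

#: Exact 0.975 standard-normal quantile used for every 95% interval.
Z975 = float(stats.norm.ppf(0.975))

METHOD_WALD = "Wald ratio"
METHOD_IVW_FE = "Inverse variance weighted (fixed effects)"
METHOD_IVW_MRE = "Inverse variance weighted (multiplicative random effects)"
METHOD_EGGER = "MR Egger"
METHOD_WEIGHTED_MEDIAN = "Weighted median"
METHOD_SIMPLE_MEDIAN = "Simple median"


@dataclass(frozen=True)
class MrResult:
    """One estimator's causal estimate on the log-odds scale."""

    method: str
    nsnp: int
    beta: float
    se: float
    pvalue: float
    label: str | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z975 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z975 * self.se))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.method}: OR {self.or_:.2f} "
            f"({self.ci_low:.2f}, {self.ci_high:.2f}), p={self.pvalue:.4g}"
        )


@dataclass(frozen=True)
class EggerResult(MrResult):
    """MR-Egger slope plus the pleiotropy intercept term."""

    intercept: float = 0.0
    intercept_se: float = 0.0
    intercept_p: float = 1.0
    residual_scale: float = 1.0


#: Below this, an SE is treated as an exact zero (exact-fit degeneracy).
_SE_TOL = 1e-12


def _normal_p(beta: float, se: float) -> float:
    if se < _SE_TOL:
        return 1.0 if abs(beta) < _SE_TOL else 0.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _t_p(est: float, se: float, df: int) -> float:
    if se < _SE_TOL:
        return 1.0 if abs(est) < _SE_TOL else 0.0
    return float(2.0 * stats.t.sf(abs(est / se), df))


def _arrays(vs: Sequence[HarmonizedVariant]):
    bx = np.array([v.beta_exp for v in vs], dtype=float)
    by = np.array([v.beta_out for v in vs], dtype=float)
    sx = np.array([v.se_exp for v in vs], dtype=float)
    sy = np.array([v.se_out for v in vs], dtype=float)
    return bx, by, sx, sy


def wald_ratio(v: HarmonizedVariant) -> MrResult:
    """Single-instrument causal estimate by / bx with delta-method SE."""
    if v.beta_exp == 0.0:
        raise ValueError(f"variant {v.rsid}: Wald ratio undefined for beta_exp = 0")
    beta = v.beta_out / v.beta_exp
    se = v.se_out / abs(v.beta_exp)
    return MrResult(METHOD_WALD, 1, beta, se, _normal_p(beta, se))


def ivw(
    vs: Sequence[HarmonizedVariant],
    effects_model: str = "fixed",
) -> MrResult:
    """Inverse-variance weighted estimate.

    Weighted regression of by on bx through the origin with weights
    1/se_out^2. Under the multiplicative random-effects model the standard
    error is scaled by the residual dispersion phi = sqrt(RSS_w / (L - 1))
    with no flooring at 1, so underdispersion narrows the interval.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model: {effects_model!r}")
    if len(vs) == 0:
        raise ValueError("IVW requires at least one variant")
    if len(vs) == 1:
        log.info("single instrument: IVW reduces to the Wald ratio")
        return wald_ratio(vs[0])
    bx, by, _, sy = _arrays(vs)
    w = 1.0 / sy**2
    s_den = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / s_den
    se = 1.0 / np.sqrt(s_den)
    method = METHOD_IVW_FE
    if effects_model == "multiplicative_random":
        rss = float(np.sum(w * (by - beta * bx) ** 2))
        phi = np.sqrt(rss / (len(vs) - 1))
        se *= phi
        method = METHOD_IVW_MRE
    return MrResult(method, len(vs), beta, float(se), _normal_p(beta, se))


def _orient(bx, by):
    """Flip variants so every exposure effect is positive (Egger convention)."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def egger(vs: Sequence[HarmonizedVariant]) -> EggerResult:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect, and its p-value (t, L - 2 df) tests for
    directional horizontal pleiotropy. Standard errors carry the unfloored
    multiplicative residual scale, as in random-effects IVW.
    """
    if len(vs) < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    bx, by, _, sy = _arrays(vs)
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = (float(p) for p in fit.params)
    se_int, se_slope = (float(s) for s in fit.bse)
    df = len(vs) - 2
    return EggerResult(
        method=METHOD_EGGER,
        nsnp=len(vs),
        beta=slope,
        se=se_slope,
        pvalue=_t_p(slope, se_slope, df),
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=_t_p(intercept, se_int, df),
        residual_scale=float(np.sqrt(fit.scale)),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50th percentile of ratios under cumulative weights.

    Sorted ratios receive percentile positions 100 (S_j - w_j/2) / S_L where
    S_j is the cumulative weight; the median is linearly interpolated at 50.
    """
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w)
    perc = 100.0 * (cum - w / 2.0) / cum[-1]
    return float(np.interp(50.0, perc, r))


def median_estimator(
    vs: Sequence[HarmonizedVariant],
    kind: str = "weighted",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Weighted or simple median of per-variant Wald ratios.

    The weighted median is consistent when valid instruments carry a
    majority of the weight. Its standard error comes from a parametric
    bootstrap: bx and by are resampled from normal distributions at their
    standard errors and the median recomputed ``n_boot`` times.
    """
    if kind not in ("weighted", "simple"):
        raise ValueError(f"unknown median kind: {kind!r}")
    if len(vs) < 3:
        raise ValueError("median estimators require at least 3 variants")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable median standard errors")
    dropped = [v.rsid for v in vs if v.beta_exp == 0.0]
    if dropped:
        log.warning("median estimator: excluded zero-beta_exp variant(s) %s", dropped)
        vs = [v for v in vs if v.beta_exp != 0.0]
    bx, by, sx, sy = _arrays(vs)

    def weights_for(bx_, by_):
        if kind == "simple":
            return np.full(bx_.shape, 1.0 / bx_.shape[-1])
        se_ratio = sy / np.abs(bx_)  # first-order delta method
        return 1.0 / se_ratio**2

    beta = _weighted_median(by / bx, weights_for(bx, by))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0.0
        boots[b] = _weighted_median(
            by_b[ok] / bx_b[ok], weights_for(bx_b[ok], by_b[ok])
        )
    se = float(np.std(boots, ddof=1))
    method = METHOD_WEIGHTED_MEDIAN if kind == "weighted" else METHOD_SIMPLE_MEDIAN
    return MrResult(method, len(vs), beta, se, _normal_p(beta, se))
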
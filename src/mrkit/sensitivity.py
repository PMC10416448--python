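"""Heterogeneity, pleiotropy, outlier, directionality and influence
diagnostics for a set of harmonized instruments.

Covers Cochran's Q and I^2 heterogeneity of the per-variant causal ratios,
the MR-Egger intercept test for directional pleiotropy, the MR-PRESSO
resampling global/outlier test, per-variant Steiger directionality checks,
and leave-one-out influence analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerResult, MrResult, egger, ivw
from .summary_io import HarmonizedVariant

log = logging.getLogger(__name__)

#: Two-sided significance level used for heterogeneity/pleiotropy flags.
FLAG_ALPHA = 0.05


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global and outlier test results."""

    rss_obs: float
    global_p: float
    outlier_p: np.ndarray  # Bonferroni-adjusted per-variant p-values
    outlier_indices: tuple[int, ...]
    estimate_outliers_removed: MrResult | None
    n_sim: int
    seed: int | None


@dataclass(frozen=True)
class SensitivityReport:
    """Bundle of all sensitivity diagnostics for one exposure-outcome pair."""

    q: float
    df: int
    q_pvalue: float
    i2: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso: PressoResult | None
    steiger: pd.DataFrame | None
    steiger_overall_p: float | None
    loo: list[MrResult] = field(default_factory=list)

    @property
    def heterogeneous(self) -> bool:
        return self.q_pvalue < FLAG_ALPHA

    @property
    def pleiotropic(self) -> bool:
        return self.egger_intercept_p < FLAG_ALPHA

    def summary(self) -> str:
        lines = [
            "Sensitivity analysis",
            "=" * 56,
            f"Cochran's Q          {self.q:10.4f}  (df {self.df}, p {self.q_pvalue:.4f})",
            f"I^2                  {self.i2:10.0f} %",
            f"Egger intercept      {self.egger_intercept:10.4f}  "
            f"(SE {self.egger_intercept_se:.4f}, p {self.egger_intercept_p:.4f})",
        ]
        if self.presso is not None:
            lines.append(
                f"MR-PRESSO global p   {self.presso.global_p:10.4f}  "
                f"({len(self.presso.outlier_indices)} outlier(s), "
                f"{self.presso.n_sim} simulations)"
            )
        if self.steiger is not None:
            n_bad = int((~self.steiger["direction_ok"]).sum())
            lines.append(
                f"Steiger filtering    {n_bad:10d}  variant(s) with reversed direction"
            )
        return "\n".join(lines)


def cochran_q(vs: Sequence[HarmonizedVariant]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of per-variant Wald ratios.

    Q = sum_j w_j (r_j - beta_IVW)^2 with r_j = by_j/bx_j and
    w_j = (bx_j/se_yj)^2; this equals the weighted residual sum of squares
    of the fixed-effect IVW fit. df = L - 1; p is the upper chi-square tail.
    """
    if len(vs) < 2:
        raise ValueError("Cochran's Q requires at least 2 variants")
    bx = np.array([v.beta_exp for v in vs])
    by = np.array([v.beta_out for v in vs])
    sy = np.array([v.se_out for v in vs])
    if (bx == 0).any():
        raise ValueError("Cochran's Q undefined with a zero exposure effect")
    ratios = by / bx
    w = (bx / sy) ** 2
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = len(vs) - 1
    return q, df, q_pvalue(q, df)


def q_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-square p-value for a heterogeneity statistic."""
    if q < 0 or df < 1:
        raise ValueError("need q >= 0 and df >= 1")
    return float(stats.chi2.sf(q, df))


def i_squared(q: float, df: int) -> float:
    """I^2 heterogeneity percentage, 100 (Q - df)/Q, truncated at 0."""
    if q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be at least 1")
    if q == 0.0:
        return 0.0
    return 100.0 * max(0.0, (q - df) / q)


def egger_intercept_test(e: EggerResult) -> float:
    """p-value of the MR-Egger intercept (t test, L - 2 df).

    A small p flags directional horizontal pleiotropy: the instruments'
    average direct effect on the outcome differs from zero.
    """
    return e.intercept_p


def _loo_slopes(bx, by, w):
    """Leave-one-out fixed-effect IVW slopes, vectorized over variants."""
    s_num = np.sum(w * bx * by)
    s_den = np.sum(w * bx**2)
    return (s_num - w * bx * by) / (s_den - w * bx**2)


def mr_presso(
    vs: Sequence[HarmonizedVariant],
    n_sim: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO residual-sum-of-squares global and outlier tests.

    The observed RSS uses leave-one-out IVW slopes, RSS_obs =
    sum_j w_j (by_j - beta_(-j) bx_j)^2, so each variant is judged against
    a fit that excludes it. The null distribution is built by simulating
    by*_j ~ Normal(beta_(-j) bx_j, se_yj) and recomputing the statistic
    (leave-one-out slopes included) ``n_sim`` times. The global p is the
    empirical tail (1 + k)/(1 + n_sim); per-variant outlier p-values are
    the empirical tails of each variant's weighted squared residual,
    Bonferroni-multiplied by L and flagged at ``alpha``. When outliers are
    flagged, the fixed-effect IVW is recomputed without them.
    """
    L = len(vs)
    if L < 4:
        raise ValueError("MR-PRESSO requires at least 4 variants")
    bx = np.array([v.beta_exp for v in vs])
    by = np.array([v.beta_out for v in vs])
    sy = np.array([v.se_out for v in vs])
    w = 1.0 / sy**2

    beta_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, L))
    s_num = (w * bx * by_sim).sum(axis=1, keepdims=True)
    s_den = float(np.sum(w * bx**2))
    beta_loo_sim = (s_num - w * bx * by_sim) / (s_den - w * bx**2)
    res_sim = w * (by_sim - beta_loo_sim * bx) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    per_p = (1 + np.sum(res_sim >= res_obs, axis=0)) / (n_sim + 1)
    outlier_p = np.minimum(1.0, L * per_p)
    outliers = tuple(int(i) for i in np.flatnonzero(outlier_p < alpha))

    corrected = None
    if outliers:
        keep = [v for i, v in enumerate(vs) if i not in outliers]
        if len(keep) >= 1:
            corrected = ivw(keep, "fixed")
        log.info("MR-PRESSO flagged outlier indices %s", outliers)
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outlier_indices=outliers,
        estimate_outliers_removed=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def steiger_filter(
    vs: Sequence[HarmonizedVariant],
    n_exp: int,
    n_out: int,
    case_fraction: float | None = None,
) -> pd.DataFrame:
    """Per-variant Steiger directionality test.

    Compares the variance each variant explains in the exposure with the
    variance it explains in the outcome; a valid instrument should explain
    more of the exposure (direction_ok). The outcome-side r^2 uses the same
    frequency/beta/se formula on the log-odds scale with the total outcome
    sample size — an approximation for binary traits (``case_fraction`` is
    carried for provenance only). The p-value is a two-sample z test on
    Fisher-transformed |r|:
    z = (atanh|r_exp| - atanh|r_out|) / sqrt(1/(n_exp-3) + 1/(n_out-3)).
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("Steiger test requires sample sizes above 3")
    rows = []
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    for v in vs:
        eaf_out = v.eaf_out if np.isfinite(v.eaf_out) else v.eaf_exp
        r2_exp = _r2_from_stats(v.eaf_exp, v.beta_exp, v.se_exp, n_exp)
        r2_out = _r2_from_stats(eaf_out, v.beta_out, v.se_out, n_out)
        z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / denom
        rows.append(
            {
                "rsid": v.rsid,
                "r2_exp": r2_exp,
                "r2_out": r2_out,
                "direction_ok": r2_exp > r2_out,
                "steiger_p": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(rows)


def _r2_from_stats(eaf: float, beta: float, se: float, n: int) -> float:
    v = 2.0 * eaf * (1.0 - eaf)
    num = v * beta**2
    return num / (num + v * se**2 * n)


def steiger_overall(table: pd.DataFrame, n_exp: int, n_out: int) -> float:
    """Aggregate Steiger test over all instruments.

    Uses the combined variance explained (sum of per-variant r^2, capped
    just below 1) on each side in the same Fisher-z comparison.
    """
    r_exp = np.sqrt(min(float(table["r2_exp"].sum()), 1.0 - 1e-12))
    r_out = np.sqrt(min(float(table["r2_out"].sum()), 1.0 - 1e-12))
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / denom
    return float(2.0 * stats.norm.sf(abs(z)))


def leave_one_out(vs: Sequence[HarmonizedVariant]) -> list[MrResult]:
    """Fixed-effect IVW with each instrument removed in turn.

    Returns L results labeled by the omitted rsid, plus the all-instrument
    estimate as a reference row labeled ``"all"`` (length L + 1).
    """
    if len(vs) < 3:
        raise ValueError("leave-one-out requires at least 3 variants")
    results = []
    for i, v in enumerate(vs):
        rest = [u for j, u in enumerate(vs) if j != i]
        r = ivw(rest, "fixed")
        results.append(
            MrResult(r.method, r.nsnp, r.beta, r.se, r.pvalue, label=v.rsid)
        )
    full = ivw(list(vs), "fixed")
    results.append(
        MrResult(full.method, full.nsnp, full.beta, full.se, full.pvalue, label="all")
    )
    return results


def loo_frame(results: Sequence[MrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "excluded_rsid": r.label,
                "nsnp": r.nsnp,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pvalue": r.pvalue,
            }
            for r in results
        ]
    )


def full_report(
    vs: Sequence[HarmonizedVariant],
    n_exp: int | None = None,
    n_out: int | None = None,
    case_fraction: float | None = None,
    n_sim: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run the whole sensitivity suite on one instrument set.

    MR-PRESSO is skipped (None) below 4 variants and the Steiger test below
    valid sample sizes; everything else requires >= 3 variants.
    """
    q, df, q_p = cochran_q(vs)
    e = egger(vs)
    presso = mr_presso(vs, n_sim=n_sim, seed=seed, alpha=alpha) if len(vs) >= 4 else None
    steiger = overall_p = None
    if n_exp and n_out and n_exp > 3 and n_out > 3:
        steiger = steiger_filter(vs, n_exp, n_out, case_fraction)
        overall_p = steiger_overall(steiger, n_exp, n_out)
    return SensitivityReport(
        q=q,
        df=df,
        q_pvalue=q_p,
        i2=i_squared(q, df),
        egger_intercept=e.intercept,
        egger_intercept_se=e.intercept_se,
        egger_intercept_p=e.intercept_p,
        presso=presso,
        steiger=steiger,
        steiger_overall_p=overall_p,
        loo=leave_one_out(vs),
    )
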
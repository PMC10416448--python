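"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the study conditions of a microbiome-exposure / binary-outcome MR
design: a continuous exposure measured in ~18,000 subjects whose instruments
collectively explain a few percent of its variance, and case-control outcome
GWAS of ~34,000 subjects with a case fraction near 0.20, with configurable
true causal effect, balanced or directional pleiotropy, planted outliers and
a reverse-causation scenario.

Per variant j with effect-allele frequency eaf_j and variance factor
v_j = 2 eaf_j (1 - eaf_j):

* true exposure effect gamma_j, random sign, scaled so sum(gamma^2 v) equals
  ``exposure_h2``;
* observed exposure effect bx_j ~ Normal(gamma_j, se_xj^2) with the analytic
  se_xj = 1/sqrt(n_exp v_j) of a standardized continuous trait;
* pleiotropic effect alpha_j per ``pleiotropy_mode``;
* observed outcome effect by_j ~ Normal(theta gamma_j + alpha_j, se_yj^2)
  with se_yj = 1/sqrt(n_out K (1-K) v_j) on the log-odds scale;
* planted outliers shift by_j by ``outlier_shift`` outcome SEs.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import GwasRecord, records_to_frame, write_gwas

log = logging.getLogger(__name__)

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")
#: Correlation between pleiotropic and instrument effects in the
#: InSIDE-violating scenario.
_INSIDE_VIOLATING_CORR = 0.7


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration for one simulated exposure-outcome pair.

    Defaults mirror the emulated consortium designs: exposure GWAS of
    18,340 subjects; binary-outcome GWAS of 33,970 subjects with case
    fraction 6692/33970 ~ 0.197; 10 instruments jointly explaining 5% of
    exposure variance (per-instrument F ~ 90, i.e. no weak instruments).
    """

    n_snps: int = 10
    n_exp: int = 18_340
    n_out: int = 33_970
    case_fraction: float = 6692 / 33_970
    theta: float = 0.0
    exposure_h2: float = 0.05
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.02
    pleiotropy_mean: float = 0.05
    outlier_indices: tuple[int, ...] = ()
    outlier_shift: float = 0.0
    reverse_causation: bool = False
    eaf_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be at least 1")
        if not 0.0 < self.exposure_h2 < 1.0:
            raise ValueError("exposure_h2 must be in (0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        object.__setattr__(self, "outlier_indices", tuple(self.outlier_indices))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth stored alongside the generated tables."""

    gamma: np.ndarray  # true per-variant exposure effects
    alpha: np.ndarray  # true per-variant pleiotropic effects
    theta: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [f"rs{j + 1:07d}" for j in range(len(self.gamma))],
                "gamma": self.gamma,
                "alpha": self.alpha,
                "theta": self.theta,
                "seed": self.seed,
            }
        )


def _pleiotropy(cfg: SimConfig, gamma: np.ndarray, rng) -> np.ndarray:
    """Per-variant direct (pleiotropic) outcome effects.

    Directional pleiotropy is defined in the frame where each variant is
    coded by its exposure-increasing allele (the MR-Egger orientation); the
    sign flip by ``sign(gamma)`` maps it back to the stored effect allele.
    Without that flip, instruments of random sign would cancel the mean
    pleiotropic effect and no method could see it.
    """
    if cfg.pleiotropy_mode == "none":
        return np.zeros_like(gamma)
    if cfg.pleiotropy_mode == "balanced":
        return rng.normal(0.0, cfg.pleiotropy_sd, gamma.shape)
    sign = np.where(gamma < 0, -1.0, 1.0)
    if cfg.pleiotropy_mode == "directional":
        return sign * rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, gamma.shape)
    # inside_violating: pleiotropy additionally correlated with instrument
    # strength |gamma|, breaking the InSIDE assumption
    g_std = np.abs(gamma) / max(np.std(np.abs(gamma)), 1e-12)
    noise = rng.standard_normal(gamma.shape)
    mix = _INSIDE_VIOLATING_CORR * g_std + np.sqrt(
        1.0 - _INSIDE_VIOLATING_CORR**2
    ) * noise
    return sign * (cfg.pleiotropy_mean + cfg.pleiotropy_sd * mix)


def generate(cfg: SimConfig) -> tuple[list[GwasRecord], list[GwasRecord], SimTruth]:
    """Generate one exposure table, one outcome table and their truth.

    Deterministic given ``cfg.seed``: the same configuration always yields
    byte-identical tables. In the reverse-causation scenario the variants'
    primary effects act on the outcome and the exposure inherits
    ``theta``-scaled effects, so Steiger filtering should reject them.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snps
    eaf = rng.uniform(*cfg.eaf_range, size=L)
    v = 2.0 * eaf * (1.0 - eaf)
    raw = rng.standard_normal(L)
    gamma = raw * np.sqrt(cfg.exposure_h2 / np.sum(raw**2 * v))
    se_x = 1.0 / np.sqrt(cfg.n_exp * v)
    k = cfg.case_fraction
    se_y = 1.0 / np.sqrt(cfg.n_out * k * (1.0 - k) * v)
    alpha = _pleiotropy(cfg, gamma, rng)

    if cfg.reverse_causation:
        # primary signal on the outcome; exposure effects are downstream
        bx = rng.normal(cfg.theta * gamma, se_x)
        by = rng.normal(gamma + alpha, se_y)
    else:
        bx = rng.normal(gamma, se_x)
        by = rng.normal(cfg.theta * gamma + alpha, se_y)
    for idx in cfg.outlier_indices:
        by[idx] += cfg.outlier_shift * se_y[idx]

    expected_hits = float(
        np.sum(2.0 * stats.norm.sf(stats.norm.isf(5e-6) - np.abs(gamma) / se_x))
    )
    if expected_hits < 1.0:
        warnings.warn(
            f"exposure_h2 {cfg.exposure_h2} yields an expected instrument "
            f"count of only {expected_hits:.2f} at p < 1e-5 and n_exp {cfg.n_exp}"
        )

    exposure, outcome = [], []
    for j in range(L):
        rsid = f"rs{j + 1:07d}"
        chrom = (j % 22) + 1
        pos = 1_000_000 * (j + 1)
        p_x = float(2.0 * stats.norm.sf(abs(bx[j] / se_x[j])))
        p_y = float(2.0 * stats.norm.sf(abs(by[j] / se_y[j])))
        exposure.append(
            GwasRecord(rsid, chrom, pos, "A", "G", float(eaf[j]), float(bx[j]),
                       float(se_x[j]), max(p_x, 5e-324), cfg.n_exp)
        )
        outcome.append(
            GwasRecord(rsid, chrom, pos, "A", "G", float(eaf[j]), float(by[j]),
                       float(se_y[j]), max(p_y, 5e-324), cfg.n_out)
        )
    truth = SimTruth(gamma=gamma, alpha=alpha, theta=cfg.theta, seed=cfg.seed)
    return exposure, outcome, truth


def generate_frames(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    exposure, outcome, truth = generate(cfg)
    return records_to_frame(exposure), records_to_frame(outcome), truth.to_frame()


def write_tables(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Write exposure/outcome tables plus the truth sidecar; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = generate(cfg)
    paths = {
        "exposure": out / "exposure.tsv",
        "outcome": out / "outcome.tsv",
        "truth": out / "truth.tsv",
    }
    write_gwas(exposure, paths["exposure"])
    write_gwas(outcome, paths["outcome"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
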
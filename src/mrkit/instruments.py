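"""Instrument selection: significance/MAF/chromosome filters, greedy LD
clumping, and instrument-strength statistics (variance explained and F).

A genetic variant serves as a valid instrument for an exposure only if it is
robustly associated with it. Candidate variants are screened by p-value
threshold (locus-wide 1e-5 or genome-wide 5e-8), restricted to autosomal
biallelic SNVs with minor-allele frequency >= 1%, pruned for linkage
disequilibrium, and checked for weak-instrument bias via the F statistic
(F < 10 flags a weak instrument).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .summary_io import GwasRecord

log = logging.getLogger(__name__)

#: Order in which removal reasons are tallied (first failing filter counts).
FILTER_ORDER = ("pvalue", "chromosome", "multiallelic", "maf", "excluded")


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument-selection thresholds.

    Defaults follow the locus-wide analysis regime: p < 1e-5, MAF >= 0.01,
    sex chromosome (code 23) excluded, LD clumping at r^2 < 0.01 within a
    10,000 kb window, and weak-instrument cutoff F >= 10.
    """

    p_threshold: float = 1e-5
    maf_min: float = 0.01
    exclude_chrom: frozenset[int] = frozenset({23})
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self):
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must be in [0, 1]")
        object.__setattr__(self, "exclude_chrom", frozenset(self.exclude_chrom))
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


@dataclass(frozen=True)
class InstrumentStats:
    """Per-variant strength: variance explained in the exposure and F."""

    rsid: str
    r2: float
    f_stat: float

    @property
    def is_weak(self) -> bool:
        return self.f_stat < 10.0


class LdMatrix:
    """Symmetric matrix of pairwise squared allelic correlations (r^2)."""

    def __init__(self, rsids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.ndim != 2 or r2.shape[0] != r2.shape[1] or r2.shape[0] != len(rsids):
            raise ValueError("r2 must be square and match the rsid list")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if (r2 < -1e-12).any() or (r2 > 1.0 + 1e-12).any():
            raise ValueError("LD r2 entries must lie in [0, 1]")
        self.rsids = list(rsids)
        self.r2 = r2
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def pair(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read(cls, path) -> "LdMatrix":
        """Read a square tab-delimited table with rsid header row and column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("LD matrix row and column rsids differ")
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            path, sep="\t"
        )


def filter_candidates(
    records: Sequence[GwasRecord], cfg: SelectionConfig
) -> tuple[list[GwasRecord], dict[str, int]]:
    """Apply the five instrument-selection filters.

    Retains records with p-value strictly below ``cfg.p_threshold``, not on
    an excluded chromosome, biallelic single-base alleles, minor-allele
    frequency >= ``cfg.maf_min``, and rsid not on the confounder exclusion
    list. Returns the survivors (input order preserved) and a tally of
    removals keyed by the first failing filter in :data:`FILTER_ORDER`.
    """
    kept: list[GwasRecord] = []
    tally = {name: 0 for name in FILTER_ORDER}
    for rec in records:
        if not rec.pvalue < cfg.p_threshold:
            tally["pvalue"] += 1
        elif rec.chrom in cfg.exclude_chrom:
            tally["chromosome"] += 1
        elif not rec.is_biallelic_snv:
            tally["multiallelic"] += 1
        elif rec.maf < cfg.maf_min:
            tally["maf"] += 1
        elif rec.rsid in cfg.exclusion_list:
            tally["excluded"] += 1
        else:
            kept.append(rec)
    if not kept:
        log.warning("no records survived instrument filtering (tally %s)", tally)
    else:
        log.info("instrument filters: %d -> %d (%s)", len(records), len(kept), tally)
    return kept, tally


def clump(
    records: Sequence[GwasRecord],
    ld: LdMatrix | None,
    cfg: SelectionConfig,
) -> list[GwasRecord]:
    """Greedy LD clumping: keep the most significant variant per locus.

    Repeatedly takes the unremoved record with the smallest p-value (ties
    broken by chromosome, position, rsid) as an index variant and removes
    every unremoved record on the same chromosome within
    ``cfg.clump_window_kb`` of it (boundary inclusive) whose r^2 with the
    index is >= ``cfg.clump_r2``. Variants absent from the LD matrix are
    treated as independent; with no LD matrix at all, every variant is.
    """
    if ld is None:
        log.warning(
            "no LD matrix supplied: all %d variants treated as mutually "
            "independent, clumping is a no-op", len(records),
        )
        return list(records)
    missing = [r.rsid for r in records if r.rsid not in ld]
    if missing:
        log.warning(
            "%d variant(s) absent from LD matrix treated as independent: %s",
            len(missing), missing[:10],
        )
    order = sorted(records, key=lambda r: (r.pvalue, r.chrom, r.pos, r.rsid))
    removed: set[str] = set()
    index_ids: set[str] = set()
    window_bp = cfg.clump_window_kb * 1000.0
    for idx in order:
        if idx.rsid in removed:
            continue
        index_ids.add(idx.rsid)
        if idx.rsid not in ld:
            continue
        for other in order:
            if other.rsid in removed or other.rsid in index_ids:
                continue
            if other.chrom != idx.chrom or abs(other.pos - idx.pos) > window_bp:
                continue
            if other.rsid in ld and ld.pair(idx.rsid, other.rsid) >= cfg.clump_r2:
                removed.add(other.rsid)
    kept = [r for r in records if r.rsid in index_ids]
    log.info("LD clumping: %d -> %d variants", len(records), len(kept))
    return kept


def variance_explained(rec: GwasRecord) -> float:
    """Variance in the exposure explained by one variant.

    R^2 = v beta^2 / (v beta^2 + v se^2 N) with v = 2 EAF (1 - EAF), the
    standard summary-statistics approximation for a standardized trait.
    """
    if rec.n <= 2:
        raise ValueError(f"variant {rec.rsid}: sample size must exceed 2")
    v = 2.0 * rec.eaf * (1.0 - rec.eaf)
    num = v * rec.beta**2
    return num / (num + v * rec.se**2 * rec.n)


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F statistic, F = R^2 (N - 2) / (1 - R^2)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    return r2 * (n - 2) / (1.0 - r2)


def instrument_strength(records: Iterable[GwasRecord]) -> list[InstrumentStats]:
    """Per-variant R^2 and F for a set of candidate instruments."""
    out = []
    for rec in records:
        r2 = variance_explained(rec)
        out.append(InstrumentStats(rec.rsid, r2, f_statistic(r2, rec.n)))
    return out


def drop_weak(
    records: Sequence[GwasRecord], cfg: SelectionConfig
) -> tuple[list[GwasRecord], list[InstrumentStats]]:
    """Remove variants whose F statistic falls below ``cfg.f_min``."""
    stats_ = instrument_strength(records)
    kept = [r for r, s in zip(records, stats_) if s.f_stat >= cfg.f_min]
    n_weak = len(records) - len(kept)
    if n_weak:
        log.warning("dropped %d weak instrument(s) with F < %g", n_weak, cfg.f_min)
    return kept, stats_


def strength_frame(stats_: Iterable[InstrumentStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.rsid, s.r2, s.f_stat, s.is_weak) for s in stats_],
        columns=["rsid", "r2", "f_stat", "is_weak"],
    )
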
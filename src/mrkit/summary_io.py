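"""Reading, validation and allele harmonization of GWAS summary statistics.

Summary-statistics tables are tab-delimited text with a header row; one row
per variant carrying the variant id, chromosome, position, the two alleles,
the effect-allele frequency, the per-allele effect (SD units for continuous
traits, log-odds for binary ones), its standard error, p-value and sample
size. Gzip-compressed files are accepted transparently.

Harmonization expresses the exposure and outcome effect of each shared
variant on a single effect allele, flipping outcome effects where the allele
labels are swapped and resolving palindromic (A/T, C/G) variants by allele
frequency where the frequency is informative.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

BASES = frozenset("ACGT")
#: Allele pairs that are their own reverse complement and hence strand-ambiguous.
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Canonical field -> default column name in input tables.
DEFAULT_COLUMNS: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}

ACTION_KEPT = "kept-as-is"
ACTION_FLIPPED = "flipped"
ACTION_DROPPED_PALINDROMIC = "dropped-palindromic"
ACTION_DROPPED_INCOMPATIBLE = "dropped-incompatible"
USABLE_ACTIONS = (ACTION_KEPT, ACTION_FLIPPED)

HARMONIZED_FIELDS = (
    "rsid",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "eaf_exp",
    "eaf_out",
    "palindromic",
    "action_taken",
)


@dataclass(frozen=True, slots=True)
class GwasRecord:
    """One variant's summary statistics for one trait.

    ``beta`` is the per-effect-allele association estimate; for a continuous
    trait it is in phenotype SD units, for a binary trait on the log-odds
    scale. ``eaf`` is the effect-allele frequency.
    """

    rsid: str
    chrom: int
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_biallelic_snv(self) -> bool:
        """True when both alleles are distinct single bases."""
        return (
            self.effect_allele in BASES
            and self.other_allele in BASES
            and self.effect_allele != self.other_allele
        )

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS


@dataclass(frozen=True, slots=True)
class HarmonizedVariant:
    """Exposure and outcome effects for one variant on a shared effect allele."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    palindromic: bool
    action_taken: str

    @property
    def usable(self) -> bool:
        return self.action_taken in USABLE_ACTIONS


def normalize_chrom(value) -> int:
    """Normalize a chromosome code to an integer 1-23 (X recoded to 23)."""
    text = str(value).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    if text.upper() == "X":
        return 23
    chrom = int(text)
    if not 1 <= chrom <= 23:
        raise ValueError(f"chromosome code out of range: {value!r}")
    return chrom


def _validate_row(row: Mapping[str, object]) -> tuple[GwasRecord | None, str | None]:
    """Return (record, None) on success or (None, reason) on rejection."""
    try:
        chrom = normalize_chrom(row["chrom"])
    except (ValueError, TypeError):
        return None, "chromosome"
    try:
        pos = int(row["pos"])
        eaf = float(row["eaf"])
        beta = float(row["beta"])
        se = float(row["se"])
        pvalue = float(row["pvalue"])
        n = int(row["n"])
    except (ValueError, TypeError):
        return None, "type"
    ea = str(row["effect_allele"]).strip().upper()
    oa = str(row["other_allele"]).strip().upper()
    if ea not in BASES or oa not in BASES or ea == oa:
        return None, "alleles"
    if pos < 1:
        return None, "position"
    if not 0.0 < eaf < 1.0:
        return None, "eaf"
    if not se > 0.0 or not math.isfinite(se) or not math.isfinite(beta):
        return None, "se"
    if not 0.0 < pvalue <= 1.0:
        return None, "pvalue"
    if n < 1:
        return None, "n"
    rec = GwasRecord(str(row["rsid"]), chrom, pos, ea, oa, eaf, beta, se, pvalue, n)
    # p should roughly match the normal tail of beta/se; warn, never reject.
    p_implied = 2.0 * stats.norm.sf(abs(beta / se))
    if p_implied > 0 and not (0.1 * p_implied <= pvalue <= min(1.0, 10.0 * p_implied)):
        log.warning(
            "variant %s: p-value %.3g inconsistent with beta/se implied %.3g",
            rec.rsid, pvalue, p_implied,
        )
    return rec, None


def read_gwas(path, column_map: Mapping[str, str] | None = None) -> list[GwasRecord]:
    """Read and validate a GWAS summary-statistics table.

    Parameters
    ----------
    path
        Tab-delimited text file with a header row; ``.gz`` accepted.
    column_map
        Mapping from canonical field names (:data:`DEFAULT_COLUMNS` keys) to
        the column names used in this file. Missing entries fall back to the
        defaults.

    Returns
    -------
    list of GwasRecord
        Validated records in file order. Rows failing validation are dropped
        and counted in a logged warning.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = df.rename(columns={v: k for k, v in columns.items()})
    records: list[GwasRecord] = []
    dropped: dict[str, int] = {}
    for row in df.to_dict("records"):
        rec, reason = _validate_row(row)
        if rec is None:
            dropped[reason] = dropped.get(reason, 0) + 1
        else:
            records.append(rec)
    if dropped:
        log.warning(
            "%s: dropped %d invalid row(s): %s", path, sum(dropped.values()), dropped
        )
    return records


def records_to_frame(records: Iterable[GwasRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars_of(r) for r in records], columns=list(DEFAULT_COLUMNS))


def vars_of(rec: GwasRecord) -> dict:
    # dataclass with slots has no __dict__
    return {f: getattr(rec, f) for f in DEFAULT_COLUMNS}


def write_gwas(records: Iterable[GwasRecord], path) -> None:
    """Write records as a tab-delimited table in the default column dialect."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def _check_unique(records: Sequence[GwasRecord], which: str) -> dict[str, GwasRecord]:
    by_id: dict[str, GwasRecord] = {}
    for rec in records:
        if rec.rsid in by_id:
            raise ValueError(f"duplicate rsid in {which} table: {rec.rsid}")
        by_id[rec.rsid] = rec
    return by_id


def harmonize(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    palindromic_eaf_window: float = 0.08,
) -> list[HarmonizedVariant]:
    """Align exposure and outcome effects of shared variants on one allele.

    For each rsid present in both tables the outcome record is compared with
    the exposure record's alleles:

    * identical effect/other alleles -> kept as is;
    * swapped alleles -> the outcome beta is negated and its frequency
      complemented;
    * palindromic variants (A/T or C/G) cannot be resolved by allele labels:
      when the exposure frequency lies within ``palindromic_eaf_window`` of
      0.5 they are dropped as ambiguous, otherwise they are aligned so the
      minor allele agrees between the two studies;
    * any other allele combination is dropped as incompatible.

    Dropped variants are returned too, with ``action_taken`` recording why;
    filter with :attr:`HarmonizedVariant.usable` before estimation. The
    returned list covers every shared rsid exactly once, in exposure order.
    """
    exp_by_id = _check_unique(exposure, "exposure")
    out_by_id = _check_unique(outcome, "outcome")
    harmonized: list[HarmonizedVariant] = []
    for rsid, e in exp_by_id.items():
        if rsid not in out_by_id:
            continue
        o = out_by_id[rsid]
        pal = e.is_palindromic
        beta_out, eaf_out = o.beta, o.eaf
        if pal:
            if abs(e.eaf - 0.5) <= palindromic_eaf_window or not np.isfinite(o.eaf):
                action = ACTION_DROPPED_PALINDROMIC
            elif frozenset((o.effect_allele, o.other_allele)) != frozenset(
                (e.effect_allele, e.other_allele)
            ):
                action = ACTION_DROPPED_INCOMPATIBLE
            elif (e.eaf < 0.5) == (o.eaf < 0.5):
                action = ACTION_KEPT
            else:
                action = ACTION_FLIPPED
                beta_out, eaf_out = -o.beta, 1.0 - o.eaf
        elif (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            action = ACTION_KEPT
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            action = ACTION_FLIPPED
            beta_out, eaf_out = -o.beta, 1.0 - o.eaf
        else:
            action = ACTION_DROPPED_INCOMPATIBLE
        harmonized.append(
            HarmonizedVariant(
                rsid=rsid,
                beta_exp=e.beta,
                se_exp=e.se,
                beta_out=beta_out,
                se_out=o.se,
                eaf_exp=e.eaf,
                eaf_out=eaf_out,
                palindromic=pal,
                action_taken=action,
            )
        )
    counts: dict[str, int] = {}
    for v in harmonized:
        counts[v.action_taken] = counts.get(v.action_taken, 0) + 1
    log.info("harmonized %d shared variants: %s", len(harmonized), counts)
    if any(v.action_taken == ACTION_DROPPED_PALINDROMIC for v in harmonized):
        log.info(
            "palindromic variants with exposure EAF within %.2f of 0.5 were "
            "dropped as strand-ambiguous", palindromic_eaf_window,
        )
    return harmonized


def usable(variants: Iterable[HarmonizedVariant]) -> list[HarmonizedVariant]:
    """The kept/flipped subset that feeds estimation."""
    return [v for v in variants if v.usable]


def harmonized_to_frame(variants: Iterable[HarmonizedVariant]) -> pd.DataFrame:
    rows = [{f: getattr(v, f) for f in HARMONIZED_FIELDS} for v in variants]
    return pd.DataFrame(rows, columns=list(HARMONIZED_FIELDS))


def write_harmonized(variants: Iterable[HarmonizedVariant], path) -> None:
    harmonized_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_harmonized(path) -> list[HarmonizedVariant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        row["palindromic"] = bool(row["palindromic"])
        out.append(HarmonizedVariant(**{f: row[f] for f in HARMONIZED_FIELDS}))
    return out
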
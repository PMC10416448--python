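"""End-to-end orchestration: select instruments, harmonize, estimate,
diagnose, meta-analyze across outcome cohorts, and annotate.

For every exposure-outcome pair the pipeline selects instruments (p-value /
chromosome / biallelic / MAF / exclusion-list filters, LD clumping,
weak-instrument removal), harmonizes alleles, and fits the Wald ratio when
one instrument survives or the five multi-instrument estimators plus the
full sensitivity suite otherwise. Estimates for the same exposure are then
pooled across outcomes by fixed-effect meta-analysis, and all instruments
are mapped to overlapping genes. Outputs are tab-delimited report tables
plus a machine-readable run log with seeds, versions and per-stage counts.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate, annotation_frame, read_gene_intervals
from .instruments import LdMatrix, SelectionConfig, clump, drop_weak, filter_candidates
from .meta_power import StudyEstimate, meta_fixed
from .model import MRModel
from .sensitivity import loo_frame
from .summary_io import GwasRecord, harmonize, read_gwas, usable

log = logging.getLogger(__name__)

DASH = "-"


@dataclass(frozen=True)
class ExposureSpec:
    label: str
    path: str
    column_map: dict | None = None


@dataclass(frozen=True)
class OutcomeSpec:
    label: str
    path: str
    case_fraction: float | None = None
    n: int | None = None
    #: which IVW variant feeds the meta-analysis for this cohort
    ivw_variant: str = "fixed"
    column_map: dict | None = None


@dataclass
class RunConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    ld_path: str | None = None
    gene_path: str | None = None
    palindromic_eaf_window: float = 0.08
    n_boot: int = 1000
    presso_n_sim: int = 5000
    seed: int = 0
    out_dir: str = "mr_output"
    pooled_exposure: bool = False

    def __post_init__(self):
        if not self.exposures or not self.outcomes:
            raise ValueError("need at least one exposure and one outcome")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sel = SelectionConfig(**raw.get("selection", {}))
        return cls(
            exposures=[ExposureSpec(**e) for e in raw["exposures"]],
            outcomes=[OutcomeSpec(**o) for o in raw["outcomes"]],
            selection=sel,
            ld_path=raw.get("ld_matrix"),
            gene_path=raw.get("genes"),
            palindromic_eaf_window=raw.get("palindromic_eaf_window", 0.08),
            n_boot=raw.get("n_boot", 1000),
            presso_n_sim=raw.get("presso_n_sim", 5000),
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir", "mr_output"),
            pooled_exposure=raw.get("pooled_exposure", False),
        )


def _select(
    records: Sequence[GwasRecord], ld: LdMatrix | None, cfg: RunConfig
) -> tuple[list[GwasRecord], dict]:
    filtered, tally = filter_candidates(records, cfg.selection)
    clumped = clump(filtered, ld, cfg.selection)
    strong, _stats = drop_weak(clumped, cfg.selection)
    counts = {
        "candidates": len(records),
        "post_filter": len(filtered),
        "post_clump": len(clumped),
        "post_f": len(strong),
        "filter_tally": tally,
    }
    return strong, counts


def _sensitivity_row(model: MRModel, cfg: RunConfig) -> tuple[dict, pd.DataFrame | None]:
    """Sensitivity columns for one pair; dashes where undefined."""
    row = dict.fromkeys(
        [
            "nsnp", "i2_pct", "q", "q_df", "q_pvalue",
            "egger_intercept", "egger_intercept_se", "egger_intercept_p",
            "presso_global_p", "steiger_overall_p",
        ],
        DASH,
    )
    row["nsnp"] = model.nobs
    if model.nobs < 2:
        return row, None
    if model.nobs < 3:
        from .sensitivity import cochran_q, i_squared

        q, df, q_p = cochran_q(model.variants)
        row.update(q=q, q_df=df, q_pvalue=q_p, i2_pct=round(i_squared(q, df)))
        return row, None
    report = model.sensitivity(n_sim=cfg.presso_n_sim, seed=cfg.seed)
    row.update(
        q=report.q,
        q_df=report.df,
        q_pvalue=report.q_pvalue,
        i2_pct=round(report.i2),
        egger_intercept=report.egger_intercept,
        egger_intercept_se=report.egger_intercept_se,
        egger_intercept_p=report.egger_intercept_p,
    )
    if report.presso is not None:
        row["presso_global_p"] = report.presso.global_p
    if report.steiger_overall_p is not None:
        row["steiger_overall_p"] = report.steiger_overall_p
    return row, loo_frame(report.loo)


def run(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full workflow; write reports under ``cfg.out_dir``.

    Returns the report bundle as DataFrames keyed by table name
    (estimates, sensitivity, leave_one_out, meta, annotation).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ld = LdMatrix.read(cfg.ld_path) if cfg.ld_path else None
    genes = read_gene_intervals(cfg.gene_path) if cfg.gene_path else []

    est_rows, sens_rows, loo_frames, meta_rows = [], [], [], []
    stage_counts: dict[str, dict] = {}
    instrument_coords: dict[str, tuple[int, int]] = {}
    per_exposure_estimates: dict[str, list[StudyEstimate]] = {}
    outcome_cache: dict[str, list[GwasRecord]] = {}

    exposures = list(cfg.exposures)
    exposure_records = {
        e.label: read_gwas(e.path, e.column_map) for e in exposures
    }

    pooled_selected: dict[str, list] = {o.label: [] for o in cfg.outcomes}

    for espec in exposures:
        records = exposure_records[espec.label]
        selected, counts = _select(records, ld, cfg)
        stage_counts[espec.label] = counts
        for rec in selected:
            instrument_coords[rec.rsid] = (rec.chrom, rec.pos)
        for ospec in cfg.outcomes:
            if ospec.path not in outcome_cache:
                outcome_cache[ospec.path] = read_gwas(ospec.path, ospec.column_map)
            pair = f"{espec.label}/{ospec.label}"
            if not selected:
                log.warning("pair %s skipped: no instruments survived selection", pair)
                continue
            harmonized = harmonize(
                selected, outcome_cache[ospec.path], cfg.palindromic_eaf_window
            )
            kept = usable(harmonized)
            stage_counts.setdefault(pair, {})["post_harmonization"] = len(kept)
            if not kept:
                log.warning("pair %s skipped: no variants survived harmonization", pair)
                continue
            pooled_selected[ospec.label].extend(kept)
            model = MRModel(
                kept,
                n_exposure=selected[0].n,
                n_outcome=ospec.n,
                case_fraction=ospec.case_fraction,
            )
            table = model.fit_all(n_boot=cfg.n_boot, seed=cfg.seed)
            table.insert(0, "exposure", espec.label)
            table.insert(0, "data_source", ospec.label)
            est_rows.append(table)
            srow, loo = _sensitivity_row(model, cfg)
            sens_rows.append(
                {"data_source": ospec.label, "exposure": espec.label, **srow}
            )
            if loo is not None:
                loo.insert(0, "exposure", espec.label)
                loo.insert(0, "data_source", ospec.label)
                loo_frames.append(loo)
            variant = "fixed" if model.nobs == 1 else ospec.ivw_variant
            method = "wald" if model.nobs == 1 else (
                "ivw-fe" if variant == "fixed" else "ivw-mre"
            )
            r = model.fit(method)
            per_exposure_estimates.setdefault(espec.label, []).append(
                StudyEstimate.from_result(ospec.label, r.raw)
            )

    if cfg.pooled_exposure:
        for ospec in cfg.outcomes:
            kept = pooled_selected[ospec.label]
            if len(kept) < 2:
                continue
            model = MRModel(kept, n_outcome=ospec.n, case_fraction=ospec.case_fraction)
            table = model.fit_all(n_boot=cfg.n_boot, seed=cfg.seed)
            table.insert(0, "exposure", "Total")
            table.insert(0, "data_source", ospec.label)
            est_rows.append(table)
            srow, _ = _sensitivity_row(model, cfg)
            sens_rows.append(
                {"data_source": ospec.label, "exposure": "Total", **srow}
            )

    for label, studies in per_exposure_estimates.items():
        pooled = meta_fixed(studies)
        for s, wgt in zip(studies, pooled.weights):
            meta_rows.append(
                {
                    "exposure": label, "study": s.label, "or": s.or_,
                    "ci_low": s.ci_low, "ci_high": s.ci_high, "weight": wgt,
                    "pvalue": DASH,
                }
            )
        meta_rows.append(
            {
                "exposure": label, "study": "pooled (fixed)", "or": pooled.or_,
                "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                "weight": 1.0, "pvalue": pooled.pvalue,
            }
        )

    estimates = (
        pd.concat(est_rows, ignore_index=True) if est_rows else pd.DataFrame()
    )
    if not estimates.empty:
        n_tests = max(len({e.label for e in exposures}), 1)
        estimates["pvalue_bonferroni"] = np.minimum(1.0, estimates["pvalue"] * n_tests)
        estimates["significant_0.05"] = estimates["pvalue"] < 0.05
    sensitivity = pd.DataFrame(sens_rows)
    leave_one_out = (
        pd.concat(loo_frames, ignore_index=True) if loo_frames else pd.DataFrame()
    )
    meta = pd.DataFrame(meta_rows)
    annotation = annotation_frame(
        annotate(
            [(rsid, c, p) for rsid, (c, p) in sorted(instrument_coords.items())],
            genes,
        )
    )

    bundle = {
        "estimates": estimates,
        "sensitivity": sensitivity,
        "leave_one_out": leave_one_out,
        "meta": meta,
        "annotation": annotation,
    }
    for name, frame in bundle.items():
        frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    run_log = {
        "mrkit_version": __version__,
        "versions": _versions(),
        "seed": cfg.seed,
        "n_boot": cfg.n_boot,
        "presso_n_sim": cfg.presso_n_sim,
        "palindromic_eaf_window": cfg.palindromic_eaf_window,
        "stage_counts": stage_counts,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    log.info("wrote report bundle to %s", out_dir)
    return bundle


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
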
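"""Model/Results interface over the MR estimators and diagnostics.

:class:`MRModel` holds one harmonized exposure-outcome instrument set;
``fit`` returns an :class:`MRResults` for a chosen estimator, ``fit_all``
the full estimator table, and ``sensitivity`` the diagnostic suite.

>>> model = MRModel.from_harmonized(variants, n_exposure=18340,
...                                 n_outcome=33970, case_fraction=0.197)
>>> res = model.fit("ivw")
>>> print(res.summary())
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import estimators as est
from . import sensitivity as sens
from .estimators import EggerResult, MrResult
from .summary_io import HarmonizedVariant, usable

#: Short method aliases accepted by :meth:`MRModel.fit`.
METHODS = {
    "wald": est.METHOD_WALD,
    "ivw": est.METHOD_IVW_FE,
    "ivw-fe": est.METHOD_IVW_FE,
    "ivw-mre": est.METHOD_IVW_MRE,
    "egger": est.METHOD_EGGER,
    "weighted-median": est.METHOD_WEIGHTED_MEDIAN,
    "simple-median": est.METHOD_SIMPLE_MEDIAN,
}


class MRModel:
    """Two-sample Mendelian randomization model for one instrument set.

    Parameters
    ----------
    variants
        Harmonized variants; dropped ones are filtered out automatically.
    n_exposure, n_outcome, case_fraction
        Cohort sizes used by the Steiger directionality test (optional).
    """

    def __init__(
        self,
        variants: Sequence[HarmonizedVariant],
        n_exposure: int | None = None,
        n_outcome: int | None = None,
        case_fraction: float | None = None,
    ):
        self.variants = usable(variants)
        if not self.variants:
            raise ValueError("no usable harmonized variants")
        self.n_exposure = n_exposure
        self.n_outcome = n_outcome
        self.case_fraction = case_fraction

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_harmonized(cls, variants, **kwargs) -> "MRModel":
        return cls(variants, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MRModel":
        """Build from a frame with beta_exp/se_exp/beta_out/se_out columns.

        Optional columns: rsid, eaf_exp, eaf_out.
        """
        variants = []
        for i, row in df.reset_index(drop=True).iterrows():
            variants.append(
                HarmonizedVariant(
                    rsid=str(row.get("rsid", f"snp{i + 1}")),
                    beta_exp=float(row["beta_exp"]),
                    se_exp=float(row["se_exp"]),
                    beta_out=float(row["beta_out"]),
                    se_out=float(row["se_out"]),
                    eaf_exp=float(row.get("eaf_exp", 0.5)),
                    eaf_out=float(row.get("eaf_out", row.get("eaf_exp", 0.5))),
                    palindromic=False,
                    action_taken="kept-as-is",
                )
            )
        return cls(variants, **kwargs)

    # -- fitting -----------------------------------------------------------
    @property
    def nobs(self) -> int:
        """Number of instruments."""
        return len(self.variants)

    def fit(self, method: str = "ivw", n_boot: int = 1000, seed: int | None = None):
        """Fit one estimator; returns :class:`MRResults`.

        ``method`` is an alias from :data:`METHODS`. A single-instrument
        model always fits the Wald ratio.
        """
        name = METHODS.get(method, method)
        if self.nobs == 1 or name == est.METHOD_WALD:
            result = est.wald_ratio(self.variants[0])
        elif name == est.METHOD_IVW_FE:
            result = est.ivw(self.variants, "fixed")
        elif name == est.METHOD_IVW_MRE:
            result = est.ivw(self.variants, "multiplicative_random")
        elif name == est.METHOD_EGGER:
            result = est.egger(self.variants)
        elif name == est.METHOD_WEIGHTED_MEDIAN:
            result = est.median_estimator(self.variants, "weighted", n_boot, seed)
        elif name == est.METHOD_SIMPLE_MEDIAN:
            result = est.median_estimator(self.variants, "simple", n_boot, seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        if isinstance(result, EggerResult):
            return EggerMRResults(self, result)
        return MRResults(self, result)

    def fit_all(self, n_boot: int = 1000, seed: int | None = None) -> pd.DataFrame:
        """Estimator table shaped like a published MR results table.

        One Wald-ratio row for a single instrument, otherwise the five
        multi-instrument methods (IVW fixed/random, weighted median,
        MR-Egger, simple median).
        """
        if self.nobs == 1:
            methods = ["wald"]
        else:
            methods = ["ivw-fe", "ivw-mre", "weighted-median", "egger", "simple-median"]
        rows = []
        for m in methods:
            r = self.fit(m, n_boot=n_boot, seed=seed)
            rows.append(
                {
                    "method": r.method,
                    "nsnp": r.nobs,
                    "beta": r.params,
                    "se": r.bse,
                    "or": r.odds_ratio,
                    "ci_low": r.conf_int()[0],
                    "ci_high": r.conf_int()[1],
                    "pvalue": r.pvalue,
                }
            )
        return pd.DataFrame(rows)

    def sensitivity(
        self, n_sim: int = 5000, seed: int | None = None, alpha: float = 0.05
    ) -> sens.SensitivityReport:
        """Full diagnostic suite (Q/I^2, Egger intercept, PRESSO, Steiger,
        leave-one-out)."""
        return sens.full_report(
            self.variants,
            n_exp=self.n_exposure,
            n_out=self.n_outcome,
            case_fraction=self.case_fraction,
            n_sim=n_sim,
            seed=seed,
            alpha=alpha,
        )


class MRResults:
    """Fitted causal estimate with statsmodels-flavoured accessors."""

    def __init__(self, model: MRModel, result: MrResult):
        self.model = model
        self._result = result

    @property
    def method(self) -> str:
        return self._result.method

    @property
    def nobs(self) -> int:
        return self._result.nsnp

    @property
    def params(self) -> float:
        """Causal log odds ratio per SD of exposure."""
        return self._result.beta

    @property
    def bse(self) -> float:
        return self._result.se

    @property
    def pvalue(self) -> float:
        return self._result.pvalue

    @property
    def odds_ratio(self) -> float:
        return self._result.or_

    def conf_int(self) -> tuple[float, float]:
        """95% interval on the odds-ratio scale."""
        return (self._result.ci_low, self._result.ci_high)

    @property
    def raw(self) -> MrResult:
        return self._result

    def summary(self) -> str:
        r = self._result
        lines = [
            "Two-sample MR estimate",
            "=" * 56,
            f"Method               {r.method}",
            f"Instruments          {r.nsnp}",
            f"beta (log OR)        {r.beta: .4f}  (SE {r.se:.4f})",
            f"OR (95% CI)          {r.or_:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})",
            f"p-value              {r.pvalue:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<MRResults {self._result}>"


class EggerMRResults(MRResults):
    """MR-Egger results exposing the pleiotropy intercept."""

    @property
    def intercept(self) -> float:
        return self._result.intercept

    @property
    def intercept_se(self) -> float:
        return self._result.intercept_se

    @property
    def intercept_pvalue(self) -> float:
        return self._result.intercept_p

    def summary(self) -> str:
        base = super().summary()
        r = self._result
        return base + (
            f"\nIntercept (theta0)   {r.intercept: .4f}  "
            f"(SE {r.intercept_se:.4f}, p {r.intercept_p:.4f})"
        )
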
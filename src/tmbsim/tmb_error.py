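"""TMB values, per-sample error rates, and cross-sample stability statistics.

TMB is the mutation count per megabase of interrogated region.  The error
rates follow the truth-denominated convention: FPR = FP / (number of true
mutations) and FNR = FN / (number of true mutations).  A single common
denominator keeps FNR a proper fraction and makes the TMB error
decomposition exact:

    TMB_obs - TMB_true = (FP - FN) / region_size_mb

Under this convention FPR can exceed 1 on noisy samples; the conventional
call-denominated false discovery rate FDR = FP / (TP + FP) is emitted
alongside for comparison.

Cross-sample instability is summarized by the coefficient of variation
(CV, percent): 100 x sample SD (n-1 denominator) / mean.  A ruler that reads
differently on every patient is useless for thresholding — a caller with a
large CV of FPR/FNR across a cohort is that ruler.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_sim import ValidationError
from .rule_caller import CallResult

__all__ = [
    "ErrorSummary",
    "CohortErrorStats",
    "summarize_errors",
    "coefficient_of_variation",
    "cohort_error_stats",
]


@dataclass(frozen=True)
class ErrorSummary:
    """Per-sample detection counts, error rates and TMB values.

    ``fpr``/``fnr`` are NaN (flagged undefined) when the sample has no true
    mutations.
    """

    sample_id: str
    n_true: int
    tp: int
    fp: int
    fn: int
    fpr: float
    fnr: float
    fdr: float
    tmb_true: float
    tmb_obs: float
    region_size_mb: float


def summarize_errors(result: CallResult, region_size_mb: float) -> ErrorSummary:
    """Compute the error summary of one call result.

    The identity ``tmb_obs - tmb_true == (fp - fn) / region_size_mb`` holds
    to machine precision by construction.
    """
    if region_size_mb <= 0:
        raise ValidationError("region_size_mb must be > 0")
    n_true = result.n_true
    if n_true > 0:
        fpr = result.fp / n_true
        fnr = result.fn / n_true
    else:
        fpr = math.nan
        fnr = math.nan
    n_called = result.tp + result.fp
    fdr = result.fp / n_called if n_called > 0 else math.nan
    return ErrorSummary(
        sample_id=result.sample_id,
        n_true=n_true, tp=result.tp, fp=result.fp, fn=result.fn,
        fpr=fpr, fnr=fnr, fdr=fdr,
        tmb_true=n_true / region_size_mb,
        tmb_obs=(result.tp + result.fp) / region_size_mb,
        region_size_mb=region_size_mb,
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: 100 x sample SD (ddof=1) / mean.

    Returns NaN (flagged undefined) when the mean is zero; requires at least
    two values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValidationError("coefficient of variation needs >= 2 values")
    if not np.isfinite(vals).all():
        raise ValidationError("values must be finite")
    mean = vals.mean()
    if mean == 0.0:
        return math.nan
    return float(100.0 * vals.std(ddof=1) / mean)


@dataclass
class CohortErrorStats:
    """Per-sample summaries plus cohort-level FPR/FNR stability."""

    summaries: list[ErrorSummary]
    cv_fpr: float
    cv_fnr: float
    mean_fpr: float
    sd_fpr: float
    mean_fnr: float
    sd_fnr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.summaries])

    def to_csv(self, path) -> None:
        """One row per sample plus a footer row holding the CVs (percent)."""
        df = self.to_frame()
        footer = {c: "" for c in df.columns}
        footer.update({"sample_id": "CV%", "fpr": self.cv_fpr,
                       "fnr": self.cv_fnr})
        out = pd.concat([df, pd.DataFrame([footer])], ignore_index=True)
        out.to_csv(path, index=False, float_format="%.6g")

    def to_json(self, path) -> None:
        payload = {
            "cv_fpr_percent": self.cv_fpr,
            "cv_fnr_percent": self.cv_fnr,
            "mean_fpr": self.mean_fpr, "sd_fpr": self.sd_fpr,
            "mean_fnr": self.mean_fnr, "sd_fnr": self.sd_fnr,
            "samples": [s.__dict__ for s in self.summaries],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def cohort_error_stats(results: Sequence[CallResult],
                       region_size_mb: float) -> CohortErrorStats:
    """Summarize every sample and the cohort-level CV of FPR and FNR."""
    if len(results) < 2:
        raise ValidationError("cohort statistics need >= 2 samples")
    summaries = [summarize_errors(r, region_size_mb) for r in results]
    fprs = np.array([s.fpr for s in summaries])
    fnrs = np.array([s.fnr for s in summaries])
    return CohortErrorStats(
        summaries=summaries,
        cv_fpr=coefficient_of_variation(fprs),
        cv_fnr=coefficient_of_variation(fnrs),
        mean_fpr=float(fprs.mean()), sd_fpr=float(fprs.std(ddof=1)),
        mean_fnr=float(fnrs.mean()), sd_fnr=float(fnrs.std(ddof=1)),
    )
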
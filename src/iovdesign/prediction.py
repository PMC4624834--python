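"""Predicted individual standard errors and eta-shrinkage from FIMs.

For one prior draw the predicted posterior SD of the individual
parameters is ``sqrt(diag((FIM_i + Prior)^-1))`` (the Cramer-Rao bound
on the MAP estimator).  Shrinkage of the EBE distribution is predicted
either from the averaged MAP FIM,

    SH_var = diag(FIM_MAP^-1 Prior),

or from the expected posterior covariance (the per-draw inverses are
averaged before multiplying by the prior), reported on the variance
scale and on the pharmacometric SD scale
``SH = 1 - sqrt(1 - SH_var)``.  For the ``mapocc`` method the eta
sub-block of each full inverse is used against ``Omega^-1``, i.e. the
marginal (not conditional-on-kappa) uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fim_map import FIMResult, PriorSpec

__all__ = [
    "PredictionReport",
    "predict_ise",
    "shrinkage_from_fimmap",
    "shrinkage_expected_cov",
    "prediction_report",
]


def _matrices(per_draw):
    return [f.matrix if isinstance(f, FIMResult) else np.asarray(f) for f in per_draw]


def _eta_labels(prior: PriorSpec):
    return [prior.labels[i] for i in prior.interesting]


@dataclass(frozen=True)
class PredictionReport:
    """iSE table (one row per draw) plus summaries and shrinkage vectors."""

    ise: pd.DataFrame
    summary: pd.DataFrame  # per eta parameter: median, IQR
    sh_var_fimmap: pd.Series  # averaged-FIM form, variance scale
    sh_var: pd.Series  # expected-covariance form, variance scale
    sh_sd: pd.Series  # expected-covariance form, SD scale
    method: str
    n_failed: int = 0


def predict_ise(per_draw, prior: PriorSpec) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-draw predicted SDs and their median/IQR summaries.

    Draws whose ``FIM_i + Prior`` is not invertible are flagged (row of
    NaN) and excluded from the summaries; the count is returned.
    Summaries cover the eta parameters only; kappa columns (mapocc) stay
    in the table.
    """
    mats = _matrices(per_draw)
    rows = np.full((len(mats), prior.dim), np.nan)
    failed = 0
    for i, fim in enumerate(mats):
        M = fim + prior.precision
        try:
            cov = np.linalg.inv(M)
            d = np.diag(cov)
            if np.any(d < 0):
                raise np.linalg.LinAlgError
            rows[i] = np.sqrt(d)
        except np.linalg.LinAlgError:
            failed += 1
    table = pd.DataFrame(rows, columns=list(prior.labels))
    eta_cols = _eta_labels(prior)
    ok = table[eta_cols].dropna()
    summary = pd.DataFrame(
        {
            "median": ok.median(),
            "iqr": ok.quantile(0.75) - ok.quantile(0.25),
        }
    )
    return table, summary, failed


def _sd_scale(sh_var: np.ndarray) -> np.ndarray:
    inner = 1.0 - sh_var
    neg = inner < 0
    if np.any(neg):
        if np.any(inner < -1e-10):
            raise FloatingPointError(
                "shrinkage variance exceeds 1 beyond rounding tolerance"
            )
        warnings.warn("clamping negative rounding artifact in shrinkage sqrt")
        inner = np.clip(inner, 0.0, None)
    return 1.0 - np.sqrt(inner)


def shrinkage_from_fimmap(fim_map: np.ndarray, prior: PriorSpec) -> pd.Series:
    """Variance-scale shrinkage ``diag(FIM_MAP^-1 Prior)`` over eta.

    Equals 1 when no information is gained (``FIM_MAP`` = prior) and
    tends to 0 as the design becomes infinitely informative.
    """
    cov = np.linalg.inv(fim_map)
    idx = prior.interesting
    sub = cov[np.ix_(idx, idx)] @ prior.precision[np.ix_(idx, idx)]
    return pd.Series(np.diag(sub), index=_eta_labels(prior))


def shrinkage_expected_cov(per_draw, prior: PriorSpec) -> tuple[pd.Series, pd.Series]:
    """Expected-covariance shrinkage, variance and SD scales.

    The per-draw posterior covariances are averaged first, which
    accounts for each draw's own information loss before the comparison
    with the prior.
    """
    mats = _matrices(per_draw)
    idx = prior.interesting
    acc = np.zeros((idx.size, idx.size))
    for i, fim in enumerate(mats):
        cov = np.linalg.inv(fim + prior.precision)
        acc += cov[np.ix_(idx, idx)]
    acc /= len(mats)
    sh_var = np.diag(acc @ prior.precision[np.ix_(idx, idx)])
    labels = _eta_labels(prior)
    return (
        pd.Series(sh_var, index=labels),
        pd.Series(_sd_scale(sh_var), index=labels),
    )


def prediction_report(per_draw, prior: PriorSpec, method: str | None = None) -> PredictionReport:
    """Bundle iSE and shrinkage predictions for one design/method."""
    table, summary, failed = predict_ise(per_draw, prior)
    mats = _matrices(per_draw)
    fim_map = np.mean(mats, axis=0) + prior.precision
    sh15 = shrinkage_from_fimmap(fim_map, prior)
    sh_var, sh_sd = shrinkage_expected_cov(per_draw, prior)
    return PredictionReport(
        ise=table,
        summary=summary,
        sh_var_fimmap=sh15,
        sh_var=sh_var,
        sh_sd=sh_sd,
        method=method or prior.method,
        n_failed=failed,
    )
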
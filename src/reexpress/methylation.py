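"""Probe-level methylation computation.

Beta values (``M / (U + M)``), M values (``log2(M / U)``), background
detection p-values against negative-control probes, NA-masking at a
detection threshold, treatment-vs-mock beta differences, and per-sample
demethylation summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import IntensityTable, MethMatrix

__all__ = [
    "compute_beta",
    "compute_mvalue",
    "detection_pvalues",
    "mask_low_confidence",
    "delta_beta",
    "demethylation_summary",
]

log = logging.getLogger(__name__)

#: Relative floor applied to a degenerate (zero) negative-control SD,
#: as a fraction of the control mean.
_SD_FLOOR_FRACTION = 1e-6


def compute_beta(intensities: IntensityTable) -> MethMatrix:
    """Beta value per cell: M / (U + M), the methylated fraction of
    total signal. Cells with zero total signal are masked (NaN)."""
    m = intensities.methylated.to_numpy(dtype=float)
    u = intensities.unmethylated.to_numpy(dtype=float)
    total = m + u
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    return MethMatrix(
        pd.DataFrame(beta, index=intensities.probes, columns=intensities.samples),
        scale_tag="beta",
    )


def compute_mvalue(intensities: IntensityTable) -> MethMatrix:
    """M value per cell: log2(M / U). Cells where either channel is
    zero are masked rather than producing infinities."""
    m = intensities.methylated.to_numpy(dtype=float)
    u = intensities.unmethylated.to_numpy(dtype=float)
    ok = (m > 0) & (u > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mval = np.where(ok, np.log2(np.where(ok, m, 1.0) / np.where(ok, u, 1.0)), np.nan)
    return MethMatrix(
        pd.DataFrame(mval, index=intensities.probes, columns=intensities.samples),
        scale_tag="mvalue",
    )


def detection_pvalues(intensities: IntensityTable) -> pd.DataFrame:
    """One-sided p-value that a probe's total signal (M + U) exceeds
    background, under a normal background model with per-sample
    negative-control mean and SD.

    A probe whose total signal equals the control mean gets p = 0.5;
    strong signal drives p toward 0.
    """
    ctrl = intensities.negative_controls
    if len(ctrl) < 2:
        raise ValueError("need at least 2 negative-control probes per sample")
    mu = ctrl.mean(axis=0).to_numpy()
    sd = ctrl.std(axis=0, ddof=1).to_numpy()
    floor = np.maximum(np.abs(mu) * _SD_FLOOR_FRACTION, np.finfo(float).tiny)
    if (sd <= 0).any():
        log.warning("zero negative-control variance in %d sample(s); SD floored",
                    int((sd <= 0).sum()))
    sd = np.where(sd > 0, sd, floor)
    total = intensities.total.to_numpy(dtype=float)
    z = (total - mu[None, :]) / sd[None, :]
    p = stats.norm.sf(z)
    return pd.DataFrame(p, index=intensities.probes, columns=intensities.samples)


def mask_low_confidence(values: MethMatrix, pvals: pd.DataFrame,
                        alpha: float = 0.05) -> MethMatrix:
    """Mask (set NaN) every cell whose detection p-value is strictly
    greater than ``alpha``; a cell at exactly ``alpha`` is retained."""
    if values.values.shape != pvals.shape:
        raise ValueError("value matrix and p-value matrix shapes differ")
    if not values.values.index.equals(pvals.index) or not values.values.columns.equals(pvals.columns):
        raise ValueError("value matrix and p-value matrix indexes differ")
    out = values.values.mask(pvals > alpha)
    return MethMatrix(out, scale_tag=values.scale_tag)


def delta_beta(beta_treated: MethMatrix, beta_mock: MethMatrix) -> pd.DataFrame:
    """Cellwise beta difference, treated − mock. Negative values mean
    demethylation under treatment. Masked if either side is masked."""
    if beta_treated.scale_tag != "beta" or beta_mock.scale_tag != "beta":
        raise ValueError("delta_beta requires beta-scale matrices on both sides")
    t, m = beta_treated.values, beta_mock.values
    if not t.index.equals(m.index) or not t.columns.equals(m.columns):
        raise ValueError("treated and mock matrices must share indexes")
    return t - m


def demethylation_summary(deltas: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) of unmasked beta
    differences per sample — the distribution drawn as a per-cell-line
    demethylation boxplot."""
    rows = {}
    for sample in deltas.columns:
        col = deltas[sample].dropna()
        if col.empty:
            log.warning("sample %s has no unmasked delta-beta values; summary missing", sample)
            rows[sample] = dict.fromkeys(("min", "q1", "median", "q3", "max"), np.nan)
            continue
        q = np.quantile(col.to_numpy(), [0.0, 0.25, 0.5, 0.75, 1.0])
        rows[sample] = dict(zip(("min", "q1", "median", "q3", "max"), q))
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(deltas.columns)]
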
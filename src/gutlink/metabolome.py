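"""Serum metabolite feature-matrix quality control.

The QC chain mirrors standard untargeted LC-MS practice: drop features
with excessive missingness in the biological or pooled-QC injections,
correct intensity drift against the pooled-QC trend over injection order,
drop features whose QC relative standard deviation exceeds 30%, and
restrict to confidently annotated compounds (MSI level 1/2) for the
association analyses. Intensity 0 means missing throughout.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import MetaboFeatureMatrix

log = logging.getLogger(__name__)


def missingness_filter(matrix: MetaboFeatureMatrix,
                       max_test_missing: float = 0.80,
                       max_qc_missing: float = 0.50,
                       min_test_presence: float = 0.50) -> MetaboFeatureMatrix:
    """Remove features missing in more than 80% of biological samples or
    more than 50% of QC injections, then keep only features detected in
    more than 50% of biological samples. The two presence rules are applied
    sequentially; without QC samples the QC clause is skipped with a warning.
    """
    test = matrix.test_data().to_numpy()
    miss_test = (test == 0).mean(axis=0)
    keep = miss_test <= max_test_missing
    if matrix.n_qc > 0:
        miss_qc = (matrix.qc_data().to_numpy() == 0).mean(axis=0)
        keep &= miss_qc <= max_qc_missing
    else:
        warnings.warn("no QC samples; skipping the QC missingness clause", stacklevel=2)
    keep &= (1.0 - miss_test) > min_test_presence
    return matrix.select_features(np.asarray(matrix.feature_ids)[keep])


def _qc_rsd(values: np.ndarray) -> float:
    """RSD = sd/mean over the nonzero entries; NaN with <2 nonzero values."""
    v = values[values > 0]
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / v.mean())


def qc_rsd(matrix: MetaboFeatureMatrix) -> pd.Series:
    qc = matrix.qc_data().to_numpy()
    return pd.Series([_qc_rsd(qc[:, j]) for j in range(qc.shape[1])],
                     index=matrix.feature_ids)


def drift_correct(matrix: MetaboFeatureMatrix, frac: float = 0.75,
                  min_qc: int = 5) -> MetaboFeatureMatrix:
    """Divide out the pooled-QC intensity trend over injection order.

    Per feature, a LOWESS curve f(order) is fit to the log of the nonzero
    QC intensities and every intensity is divided by f(order)/median(QC),
    with constant extrapolation beyond the first/last QC. Zeros stay zero.
    If the correction would raise a feature's QC RSD (a pathological fit),
    that feature falls back to the constant median factor, so the QC RSD is
    never increased. With fewer than ``min_qc`` usable QC injections the
    whole matrix falls back to median scaling with a warning.
    """
    data = matrix.data.to_numpy(dtype=float).copy()
    orders = matrix.injection_order.to_numpy(dtype=float)
    qc_mask = matrix.is_qc.to_numpy()
    n_feat = data.shape[1]

    if qc_mask.sum() < 2:
        raise ValueError("drift correction needs at least 2 QC injections")
    global_fallback = qc_mask.sum() < min_qc
    if global_fallback:
        warnings.warn(
            f"only {int(qc_mask.sum())} QC injections; falling back to median scaling",
            stacklevel=2)

    corrected = data.copy()
    for j in range(n_feat):
        col = data[:, j]
        qc_vals = col[qc_mask]
        nz = qc_vals > 0
        if nz.sum() < 2:
            continue  # nothing to anchor on; leave the feature untouched
        med = np.median(qc_vals[nz])
        if global_fallback or nz.sum() < min_qc:
            factor = np.full_like(col, 1.0)  # constant med/med
        else:
            qc_orders = orders[qc_mask][nz]
            fit = sm.nonparametric.lowess(np.log(qc_vals[nz]), qc_orders,
                                          frac=frac, return_sorted=True)
            f = np.exp(np.interp(orders, fit[:, 0], fit[:, 1]))
            factor = f / med
        new_col = np.where(col > 0, col / factor, 0.0)
        rsd_before = _qc_rsd(qc_vals)
        rsd_after = _qc_rsd(new_col[qc_mask])
        if np.isfinite(rsd_after) and rsd_after <= rsd_before + 1e-12:
            corrected[:, j] = new_col
        else:
            # constant factor: preserves the QC RSD exactly
            corrected[:, j] = np.where(col > 0, col / 1.0, 0.0)
            log.debug("feature %s: smoother rejected (RSD %.3f -> %.3f)",
                      matrix.feature_ids[j], rsd_before, rsd_after)
    return matrix.with_data(pd.DataFrame(corrected, index=matrix.data.index,
                                         columns=matrix.data.columns))


def rsd_filter(matrix: MetaboFeatureMatrix, max_rsd: float = 0.30) -> MetaboFeatureMatrix:
    """Drop features whose QC RSD exceeds ``max_rsd`` (strictly more than;
    a feature sitting exactly on the threshold is retained). Features with
    fewer than two nonzero QC values cannot be assessed and are dropped."""
    if matrix.n_qc < 2:
        raise ValueError("RSD filter needs at least 2 QC samples")
    rsd = qc_rsd(matrix)
    dropped_na = rsd.index[rsd.isna()]
    if len(dropped_na):
        log.info("dropping %d features with <2 nonzero QC values", len(dropped_na))
    keep = rsd.notna() & (rsd <= max_rsd + 1e-12)
    return matrix.select_features(rsd.index[keep])


def select_annotated(matrix: MetaboFeatureMatrix,
                     msi_levels: set[int] = frozenset({1, 2})) -> MetaboFeatureMatrix:
    """Keep features whose MSI annotation level is in ``msi_levels``."""
    lvl = matrix.annotation["msi_level"]
    keep = lvl.isin(list(msi_levels))
    return matrix.select_features(lvl.index[keep])


def transform_metabolite(values, impute: str = "min") -> np.ndarray:
    """Model-ready transform of one feature: impute missing (zero) entries
    at the observed minimum (or half-minimum), log10, then z-standardize.

    Returns the standardized vector; raises on an all-missing feature.
    """
    v = np.asarray(values, dtype=float).copy()
    if (v < 0).any():
        raise ValueError("intensities must be non-negative")
    observed = v > 0
    if not observed.any():
        raise ValueError("all-missing feature cannot be transformed")
    vmin = v[observed].min()
    fill = vmin if impute == "min" else vmin / 2.0
    v[~observed] = fill
    logged = np.log10(v)
    sd = logged.std()
    if sd == 0:
        return np.zeros_like(logged)
    return (logged - logged.mean()) / sd


def transform_matrix(data: pd.DataFrame, impute: str = "min") -> pd.DataFrame:
    """Column-wise :func:`transform_metabolite` over a samples x features frame."""
    out = {c: transform_metabolite(data[c].to_numpy(), impute=impute)
           for c in data.columns}
    return pd.DataFrame(out, index=data.index)
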
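"""Directed effective connectivity via pairwise time-domain Granger causality.

For a candidate driver x and target y at model order p, the restricted
model regresses y_t on its own p lags (plus intercept) and the full
model adds the p lags of x.  The Granger strength is the log variance
ratio ln(RSS_restricted / RSS_full); the significance test is the
standard nested-OLS F test

    F = ((RSS_r - RSS_f) / p) / (RSS_f / (T_eff - 2p - 1)),

with T_eff = T - p usable rows and p-value from the F(p, T_eff - 2p - 1)
upper tail.  The directed e-CM collects the strengths for all ordered
ROI pairs and is thresholded with a Bonferroni family of R(R-1) ordered
pairs (each direction is a separate test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ConnectivityMatrix, ROISignalSet


@dataclass
class GCResult:
    gc_matrix: ConnectivityMatrix  # entry (i, j): strength of i -> j
    f_matrix: np.ndarray
    p_matrix: np.ndarray
    order: int


def _lag_design(y: np.ndarray, order: int) -> np.ndarray:
    """Columns y_{t-1} .. y_{t-p} for t = p .. T-1."""
    return np.column_stack([y[order - k : len(y) - k] for k in range(1, order + 1)])


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def granger_pair(
    x: np.ndarray, y: np.ndarray, order: int = 1
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Granger causality in both directions for one series pair.

    Returns ``((gc_xy, F_xy, p_xy), (gc_yx, F_yx, p_yx))`` where the
    first triple tests whether past x improves the prediction of y.
    A noiseless deterministic relation drives RSS_full toward 0 and the
    statistics toward infinity; that limit is reported, not an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    T = len(x)
    p = int(order)
    if p < 1:
        raise ValueError("order must be >= 1")
    if T <= 2 * p + 2:
        raise ValueError(f"series too short (T={T}) for order {p}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant series: regressors are collinear")

    out = []
    for target, driver in ((y, x), (x, y)):
        tgt = target[p:]
        own = _lag_design(target, p)
        other = _lag_design(driver, p)
        ones = np.ones((len(tgt), 1))
        rss_r = _ols_rss(np.hstack([ones, own]), tgt)
        rss_f = _ols_rss(np.hstack([ones, own, other]), tgt)
        t_eff = len(tgt)
        df_den = t_eff - 2 * p - 1
        if rss_f <= 0:
            gc, F, pval = np.inf, np.inf, 0.0
        else:
            gc = max(float(np.log(rss_r / rss_f)), 0.0)
            F = ((rss_r - rss_f) / p) / (rss_f / df_den)
            F = max(float(F), 0.0)
            pval = float(stats.f.sf(F, p, df_den))
        out.append((gc, F, pval))
    return out[0], out[1]


def effective_cm(
    signals: ROISignalSet, order: int = 1, alpha: float = 0.05
) -> tuple[GCResult, ConnectivityMatrix, ConnectivityMatrix]:
    """Directed Granger matrices over all ordered ROI pairs.

    Returns ``(result, binary_ecm, bidirectional)``: the binary e-CM
    thresholds p at alpha / (R(R-1)); ``bidirectional`` marks pairs
    where both directions survive.
    """
    R = signals.n_rois
    if R < 2:
        raise ValueError("need at least 2 ROIs")
    gc = np.zeros((R, R))
    F = np.zeros((R, R))
    P = np.ones((R, R))
    vals = signals.values
    for i in range(R):
        for j in range(i + 1, R):
            (gc_ij, f_ij, p_ij), (gc_ji, f_ji, p_ji) = granger_pair(
                vals[i], vals[j], order=order
            )
            gc[i, j], F[i, j], P[i, j] = gc_ij, f_ij, p_ij
            gc[j, i], F[j, i], P[j, i] = gc_ji, f_ji, p_ji
    alpha_eff = alpha / (R * (R - 1))
    binary = (P < alpha_eff).astype(float)
    np.fill_diagonal(binary, 0.0)
    both = np.minimum(binary, binary.T)
    result = GCResult(
        gc_matrix=ConnectivityMatrix(
            values=gc, roi_ids=list(signals.roi_ids), modality="e",
            directed=True, weight_kind="gc",
        ),
        f_matrix=F,
        p_matrix=P,
        order=order,
    )
    b_cm = ConnectivityMatrix(
        values=binary, roi_ids=list(signals.roi_ids), modality="e",
        directed=True, weight_kind="binary",
    )
    bidir = ConnectivityMatrix(
        values=both, roi_ids=list(signals.roi_ids), modality="e",
        directed=False, weight_kind="binary",
    )
    return result, b_cm, bidir
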
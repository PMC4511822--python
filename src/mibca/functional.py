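"""Functional (BOLD) and metabolic (PET) connectivity.

f-CM: Pearson correlation between ROI time series, with two-sided
p-values from the t transform (t = r sqrt((n-2)/(1-r^2)), n-2 degrees
of freedom), thresholded at a 5% significance level with Bonferroni
correction over the R(R-1)/2 unique ROI pairs.

PET: dynamic frames are summed to a 3D volume for regional standardized
uptake values (SUV, optionally normalized to a reference region ->
rSUV); the PET connectivity matrix correlates per-ROI time-activity
curves across frames with the same p-value machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConnectivityMatrix, Parcellation, ROISignalSet


@dataclass
class CorrelationResult:
    r_matrix: ConnectivityMatrix
    p_matrix: np.ndarray
    n_samples: int
    alpha_effective: float | None = None


def extract_roi_timeseries(
    series_4d: np.ndarray, parc: Parcellation, sampling: float = 2.0,
    modality: str = "bold",
) -> ROISignalSet:
    """Spatial mean over each ROI's voxels, per frame."""
    data = np.asarray(series_4d, dtype=float)
    if data.ndim != 4:
        raise ValueError("series must be 4D (X, Y, Z, T)")
    if data.shape[:3] != parc.labels.shape:
        raise ValueError(
            f"grid mismatch: series {data.shape[:3]} vs labels {parc.labels.shape}"
        )
    T = data.shape[3]
    values = np.empty((parc.n_rois, T))
    for i, rid in enumerate(parc.roi_ids):
        mask = parc.labels == rid
        values[i] = data[mask].mean(axis=0)
    return ROISignalSet(
        values=values, roi_ids=parc.roi_ids, sampling=sampling, modality=modality
    )


def _pearson_with_p(
    values: np.ndarray, modality: str, roi_ids: list[int] | None = None
) -> CorrelationResult:
    R, T = values.shape
    if T < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sd = values.std(axis=1)
    dead = np.where(sd == 0)[0]
    if len(dead):
        names = [roi_ids[i] for i in dead] if roi_ids else dead.tolist()
        raise ValueError(f"zero-variance series for ROI(s) {names}")
    r = np.corrcoef(values)
    np.clip(r, -1.0, 1.0, out=r)
    df = T - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(p, 1.0)
    return CorrelationResult(
        r_matrix=ConnectivityMatrix(
            values=r, roi_ids=list(range(1, R + 1)), modality=modality,
            weight_kind="correlation",
        ),
        p_matrix=p,
        n_samples=T,
    )


def pearson_fc(signals: ROISignalSet) -> CorrelationResult:
    """Pairwise Pearson correlation of BOLD ROI time series."""
    res = _pearson_with_p(signals.values, modality="f", roi_ids=signals.roi_ids)
    res.r_matrix.roi_ids = list(signals.roi_ids)
    return res


def threshold_bonferroni(
    result: CorrelationResult, alpha: float = 0.05
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Binary and masked-weighted matrices after Bonferroni correction.

    The correction family is the R(R-1)/2 unique off-diagonal pairs; an
    edge survives iff p < alpha / family size (strict).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cm = result.r_matrix
    R = cm.n_rois
    if R < 2:
        raise ValueError("need at least 2 ROIs")
    n_tests = R * (R - 1) // 2
    alpha_eff = alpha / n_tests
    result.alpha_effective = alpha_eff
    binary = (result.p_matrix < alpha_eff).astype(float)
    np.fill_diagonal(binary, 0.0)
    binary = np.maximum(binary, binary.T)  # p symmetric by construction
    b_cm = cm.copy_with(binary, weight_kind="binary")
    masked = cm.copy_with(cm.values * binary)
    return b_cm, masked


def sum_pet_frames(
    pet_4d: np.ndarray, frame_durations: np.ndarray | None = None
) -> np.ndarray:
    """Voxelwise sum of dynamic PET frames into one 3D volume."""
    data = np.asarray(pet_4d, dtype=float)
    if data.ndim != 4 or data.shape[3] < 1:
        raise ValueError("PET series must be 4D with >= 1 frame")
    if frame_durations is not None and len(frame_durations) != data.shape[3]:
        raise ValueError("frame_durations length must match frame count")
    return data.sum(axis=3)


def roi_suv(
    summed_volume: np.ndarray,
    parc: Parcellation,
    reference_roi: int | None = None,
    dose_mbq: float = 1.0,
    body_weight_kg: float = 1.0,
) -> pd.DataFrame:
    """Regional mean uptake (SUV) and reference-normalized rSUV.

    SUV is the ROI mean of the summed volume scaled by body weight over
    injected dose (both default to 1, i.e. raw regional means); rSUV
    divides by the reference region's SUV (e.g. cerebellum).
    """
    vol = np.asarray(summed_volume, dtype=float)
    if vol.shape != parc.labels.shape:
        raise ValueError("grid mismatch between summed volume and parcellation")
    scale = body_weight_kg / dose_mbq
    rows = []
    for rid in parc.roi_ids:
        rows.append((rid, float(vol[parc.labels == rid].mean()) * scale))
    df = pd.DataFrame(rows, columns=["label_id", "SUV"])
    if reference_roi is not None:
        ref = df.loc[df["label_id"] == int(reference_roi), "SUV"]
        if ref.empty:
            raise ValueError(f"reference ROI {reference_roi} not in parcellation")
        ref_val = float(ref.iloc[0])
        if ref_val == 0:
            raise ValueError("reference ROI mean is zero")
        df["rSUV"] = df["SUV"] / ref_val
    return df


def pet_cm(tacs: ROISignalSet) -> CorrelationResult:
    """PET connectivity: Pearson correlation of time-activity curves.

    Correlates across dynamic frames within subject; with few frames
    (e.g. 8) the t test has very low degrees of freedom, so a warning is
    raised below 10 frames.
    """
    if tacs.n_samples < 3:
        raise ValueError("need at least 3 frames for TAC correlation")
    if tacs.n_samples < 10:
        warnings.warn(
            f"TAC correlation with {tacs.n_samples} frames: p-values have "
            f"only {tacs.n_samples - 2} degrees of freedom",
            stacklevel=2,
        )
    res = _pearson_with_p(tacs.values, modality="pet", roi_ids=tacs.roi_ids)
    res.r_matrix.roi_ids = list(tacs.roi_ids)
    return res


def suv_group_cm(suv_by_subject: pd.DataFrame) -> CorrelationResult:
    """Alternative PET mode: correlate regional SUVs across subjects.

    ``suv_by_subject`` is subjects x ROIs (columns = label_ids).
    """
    values = suv_by_subject.to_numpy(dtype=float).T
    res = _pearson_with_p(values, modality="pet")
    res.r_matrix.roi_ids = [int(c) for c in suv_by_subject.columns]
    return res
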
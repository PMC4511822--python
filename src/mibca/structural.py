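"""Structural connectivity from tractography streamlines.

Streamlines are assigned to ROI pairs by their two endpoints: each
endpoint is mapped through the inverse parcellation affine, floored to a
0-based voxel index, and takes that voxel's label (background or
out-of-volume -> unassigned).  The fiber-count matrix is the structural
connectivity matrix s-CM; mean length (arc length, mm) and mean
end-to-end orientation matrices are built from the same assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ConnectivityMatrix, Parcellation, Tractogram


@dataclass
class StreamlineAssignment:
    roi_start: int | None
    roi_end: int | None
    length_mm: float
    unit_direction: np.ndarray
    assigned: bool


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _canonical_direction(vec: np.ndarray) -> np.ndarray:
    """Unit end-to-end vector, sign-flipped so the first nonzero component
    is positive (streamlines have no intrinsic orientation)."""
    norm = np.linalg.norm(vec)
    if norm == 0:
        return np.zeros(3)
    u = vec / norm
    for c in u:
        if c != 0:
            return u if c > 0 else -u
    return u


def assign_streamlines(
    tract: Tractogram, parc: Parcellation
) -> list[StreamlineAssignment]:
    """Map each streamline's endpoints to ROI labels.

    A streamline is *assigned* iff both endpoints land in nonzero-label
    voxels.  Raises on a space_id mismatch between tractogram and
    parcellation.
    """
    if tract.space_id != parc.space_id:
        raise ValueError(
            f"frame mismatch: tractogram {tract.space_id!r} vs "
            f"parcellation {parc.space_id!r}"
        )
    out = []
    if len(tract) == 0:
        return out
    endpoints = np.array([[sl[0], sl[-1]] for sl in tract.streamlines])
    starts = parc.label_at_mm(endpoints[:, 0])
    ends = parc.label_at_mm(endpoints[:, 1])
    for sl, s, e in zip(tract.streamlines, starts, ends):
        assigned = bool(s != 0 and e != 0)
        out.append(
            StreamlineAssignment(
                roi_start=int(s) if s != 0 else None,
                roi_end=int(e) if e != 0 else None,
                length_mm=_polyline_length(sl),
                unit_direction=_canonical_direction(sl[-1] - sl[0]),
                assigned=assigned,
            )
        )
    return out


def structural_cm(
    assignments: list[StreamlineAssignment], roi_ids: list[int]
) -> tuple[ConnectivityMatrix, ConnectivityMatrix, np.ndarray, dict]:
    """Fiber-count (s-CM), mean-length and mean-orientation matrices.

    Returns ``(s_cm, length_cm, orientation, qc)`` where ``orientation``
    is an (R, R, 3) array of normalized mean sign-aligned unit vectors
    (zero where no streamline connects the pair) and ``qc`` counts
    unassigned streamlines and same-ROI loops (loops are excluded from
    the matrices, which carry a zero diagonal).
    """
    index = {int(r): i for i, r in enumerate(roi_ids)}
    R = len(roi_ids)
    counts = np.zeros((R, R))
    length_sum = np.zeros((R, R))
    dir_sum = np.zeros((R, R, 3))
    n_loops = n_unassigned = 0
    for a in assignments:
        if not a.assigned:
            n_unassigned += 1
            continue
        i, j = index[a.roi_start], index[a.roi_end]
        if i == j:
            n_loops += 1
            continue
        for p, q in ((i, j), (j, i)):
            counts[p, q] += 1
            length_sum[p, q] += a.length_mm
            dir_sum[p, q] += a.unit_direction
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = np.where(counts > 0, length_sum / np.maximum(counts, 1), 0.0)
        norms = np.linalg.norm(dir_sum, axis=2, keepdims=True)
        orientation = np.where(norms > 0, dir_sum / np.maximum(norms, 1e-300), 0.0)
    s_cm = ConnectivityMatrix(
        values=counts, roi_ids=list(roi_ids), modality="s", weight_kind="count"
    )
    length_cm = ConnectivityMatrix(
        values=mean_len, roi_ids=list(roi_ids), modality="s",
        weight_kind="mean_length_mm",
    )
    qc = {"n_unassigned": n_unassigned, "n_loops": n_loops,
          "n_assigned": int(counts.sum() // 2)}
    return s_cm, length_cm, orientation, qc


def roi_scalar_means(
    scalar: np.ndarray | pd.DataFrame, parc: Parcellation, column: str | None = None
) -> pd.Series:
    """Per-ROI mean of a scalar map (FA, MD, ...).

    Accepts either a 3D volume on the parcellation grid or a per-ROI
    table with ``label_id`` plus the named column; returns a Series
    indexed by label_id in canonical order.
    """
    if isinstance(scalar, pd.DataFrame):
        if column is None:
            raise ValueError("column name required for table input")
        sub = scalar.set_index("label_id")[column]
        missing = [r for r in parc.roi_ids if r not in sub.index]
        if missing:
            raise ValueError(f"table missing ROIs {missing}")
        return sub.loc[parc.roi_ids]
    vol = np.asarray(scalar, dtype=float)
    if vol.shape != parc.labels.shape:
        raise ValueError(
            f"grid mismatch: scalar {vol.shape} vs labels {parc.labels.shape}"
        )
    means = {}
    for rid in parc.roi_ids:
        mask = parc.labels == rid
        means[rid] = float(vol[mask].mean())
    return pd.Series(means, name=column or "mean")
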
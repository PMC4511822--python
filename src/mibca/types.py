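"""Core in-memory containers shared by every analysis module.

All geometry is expressed in millimetre "world" coordinates via the
parcellation affine; voxel indices are 0-based.  The canonical ROI
ordering used throughout the package (and by the matrix visualization
block scheme) is:

    I.   subcortical regions, left/right interleaved
    II.  left-hemisphere cortical regions
    III. right-hemisphere cortical regions

with alphabetical ordering by ROI name inside each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "none")
TISSUE_CLASSES = ("cortical", "subcortical")
MODALITIES = ("a", "s", "f", "e", "pet", "sf", "custom")
WEIGHT_KINDS = (
    "count",
    "mean_length_mm",
    "orientation_vector",
    "correlation",
    "ratio",
    "gc",
    "binary",
    "probability",
)

_HEMI_RANK = {"left": 0, "right": 1, "none": 2}


def canonical_sort_key(row) -> tuple:
    """Sort key implementing the subcortical / left-cortical / right-cortical
    block scheme; alphabetical by name within blocks, left before right for
    subcortical pairs sharing a name (interleaving)."""
    if row["tissue_class"] == "subcortical":
        return (0, str(row["name"]), _HEMI_RANK[row["hemisphere"]])
    block = 1 if row["hemisphere"] == "left" else 2
    return (block, str(row["name"]), 0)


def sort_roi_table(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Return ``roi_table`` re-ordered into the canonical block ordering.

    The ordering is a pure function of table content (hemisphere, tissue
    class, name) and never of input row order.
    """
    required = {"label_id", "name", "hemisphere", "tissue_class"}
    missing = required - set(roi_table.columns)
    if missing:
        raise ValueError(f"roi_table missing columns: {sorted(missing)}")
    bad_h = set(roi_table["hemisphere"]) - set(HEMISPHERES)
    if bad_h:
        raise ValueError(f"unknown hemisphere values: {sorted(bad_h)}")
    bad_c = set(roi_table["tissue_class"]) - set(TISSUE_CLASSES)
    if bad_c:
        raise ValueError(f"unknown tissue_class values: {sorted(bad_c)}")
    if roi_table["label_id"].duplicated().any():
        raise ValueError("duplicate label_ids in roi_table")
    if (roi_table["label_id"] <= 0).any():
        raise ValueError("label_ids must be positive")
    keys = roi_table.apply(canonical_sort_key, axis=1)
    order = sorted(range(len(roi_table)), key=lambda i: keys.iloc[i])
    return roi_table.iloc[order].reset_index(drop=True)


@dataclass
class Parcellation:
    """Integer label volume plus ROI lookup table.

    Attributes
    ----------
    labels : (X, Y, Z) integer array, 0 = background.
    voxel_to_mm : 4x4 affine mapping 0-based voxel indices to mm.
    roi_table : DataFrame with columns label_id, name, hemisphere,
        tissue_class, already in canonical order.
    space_id : identifier tying tractograms/series to this frame.
    """

    labels: np.ndarray
    voxel_to_mm: np.ndarray
    roi_table: pd.DataFrame
    space_id: str = "native"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        self.voxel_to_mm = np.asarray(self.voxel_to_mm, dtype=float)
        if self.voxel_to_mm.shape != (4, 4):
            raise ValueError("voxel_to_mm must be a 4x4 affine")
        self.roi_table = sort_roi_table(self.roi_table)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.roi_table["label_id"])
        orphans = present - known
        if orphans:
            raise ValueError(
                f"labels present in volume but missing from table: {sorted(orphans)}"
            )

    @property
    def roi_ids(self) -> list[int]:
        return [int(i) for i in self.roi_table["label_id"]]

    @property
    def n_rois(self) -> int:
        return len(self.roi_table)

    def roi_names(self) -> list[str]:
        return list(self.roi_table["name"])

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (N, 3) mm points to 0-based voxel indices (floor)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.voxel_to_mm)
        homog = np.c_[pts, np.ones(len(pts))]
        vox = homog @ inv.T
        return np.floor(vox[:, :3] + 1e-9).astype(int)

    def label_at_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Label value at each mm point; 0 for background or out-of-volume."""
        idx = self.mm_to_voxel(points_mm)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        inside = np.all((idx >= 0) & (idx < self.labels.shape), axis=1)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def roi_centroids_mm(self) -> dict[int, np.ndarray]:
        """Mean mm coordinate of each ROI's voxels (voxel centers)."""
        centroids = {}
        for rid in self.roi_ids:
            vox = np.argwhere(self.labels == rid).astype(float)
            homog = np.c_[vox, np.ones(len(vox))]
            mm = homog @ self.voxel_to_mm.T
            centroids[rid] = mm[:, :3].mean(axis=0)
        return centroids


@dataclass
class Tractogram:
    """Streamlines as 3D polylines in mm, sharing a parcellation frame."""

    streamlines: list[np.ndarray]
    space_id: str = "native"

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (N, 3) polyline")
            if len(arr) < 2:
                raise ValueError(f"streamline {i} has <2 points")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite points")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class ROISignalSet:
    """ROI x time matrix (BOLD series or PET time-activity curves)."""

    values: np.ndarray
    roi_ids: list[int]
    sampling: float | np.ndarray
    modality: str = "bold"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be ROI x T")
        if self.values.shape[0] != len(self.roi_ids):
            raise ValueError("row count must match roi_ids")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if self.modality not in ("bold", "pet"):
            raise ValueError("modality must be 'bold' or 'pet'")
        self.roi_ids = [int(r) for r in self.roi_ids]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Square ROI x ROI connectivity matrix with weight semantics."""

    values: np.ndarray
    roi_ids: list[int]
    modality: str = "custom"
    directed: bool = False
    weight_kind: str = "count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.roi_ids)
        if self.values.shape != (r, r):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {r} roi_ids"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.weight_kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}")
        np.fill_diagonal(self.values, 0.0)
        if not self.directed and not np.allclose(
            self.values, self.values.T, atol=1e-8, equal_nan=True
        ):
            raise ValueError("undirected matrix must be symmetric")
        if self.weight_kind == "binary":
            uniq = set(np.unique(self.values))
            if not uniq <= {0.0, 1.0}:
                raise ValueError("binary matrix entries must be 0/1")
        if self.weight_kind == "correlation":
            if np.nanmax(np.abs(self.values)) > 1 + 1e-9:
                raise ValueError("correlation entries must lie in [-1, 1]")
        self.roi_ids = [int(r) for r in self.roi_ids]

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def is_binary(self) -> bool:
        return bool(set(np.unique(self.values)) <= {0.0, 1.0})

    def index_of(self, roi_id: int) -> int:
        try:
            return self.roi_ids.index(int(roi_id))
        except ValueError:
            raise KeyError(f"roi_id {roi_id} not in matrix") from None

    def copy_with(self, values: np.ndarray, **overrides) -> "ConnectivityMatrix":
        kw = dict(
            roi_ids=list(self.roi_ids),
            modality=self.modality,
            directed=self.directed,
            weight_kind=self.weight_kind,
        )
        kw.update(overrides)
        return ConnectivityMatrix(values=np.array(values, dtype=float), **kw)


@dataclass
class SubjectStack:
    """Per-subject matrices of one modality plus group covariates.

    ``matrices`` maps subject_id -> ConnectivityMatrix; all must share
    roi_ids, modality and directedness.  ``covariates`` is indexed by
    subject_id with columns such as age / sex / group.
    """

    subject_ids: list[str]
    matrices: dict[str, ConnectivityMatrix]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.subject_ids:
            raise ValueError("empty subject stack")
        missing = [s for s in self.subject_ids if s not in self.matrices]
        if missing:
            raise ValueError(f"matrices missing for subjects: {missing}")
        first = self.matrices[self.subject_ids[0]]
        for sid in self.subject_ids:
            cm = self.matrices[sid]
            if cm.roi_ids != first.roi_ids:
                raise ValueError(f"subject {sid}: roi_ids differ")
            if cm.directed != first.directed or cm.modality != first.modality:
                raise ValueError(f"subject {sid}: modality/directedness differ")

    @property
    def roi_ids(self) -> list[int]:
        return self.matrices[self.subject_ids[0]].roi_ids

    def __len__(self) -> int:
        return len(self.subject_ids)

    def as_array(self) -> np.ndarray:
        """(n_subjects, R, R) stacked values in subject_ids order."""
        return np.stack([self.matrices[s].values for s in self.subject_ids])
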
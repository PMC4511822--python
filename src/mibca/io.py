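"""Readers/writers and study-tree discovery.

External formats: NIfTI-1 volumes (via nibabel), TrackVis ``.trk``
tractograms (via nibabel.streamlines) plus a plain-text streamline
dialect, 4-column TSV label tables, TSV morphometry tables, and a
text-based matrix container (commented key:value header + dense body).

Study layout follows the ``Study/Subject/Acquisition/Run`` convention;
acquisition kinds are inferred case-insensitively from folder names.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import ConnectivityMatrix, Parcellation, Tractogram, sort_roi_table

logger = logging.getLogger("mibca")

#: acquisition-kind synonyms, matched case-insensitively against folder names
ACQUISITION_KINDS = {
    "smri": ("smri", "anat", "amri", "t1"),
    "dti": ("dti", "dwi", "dmri"),
    "fmri": ("fmri", "bold", "rest"),
    "pet": ("pet",),
}


@dataclass
class StudyIndex:
    """Discovered study tree: subject -> acquisition kind -> run paths."""

    study_root: Path
    subjects: list[tuple[str, dict[str, list[Path]]]]

    def subject_ids(self) -> list[str]:
        return [s for s, _ in self.subjects]


def _classify_acquisition(name: str) -> str | None:
    low = name.lower()
    for kind, synonyms in ACQUISITION_KINDS.items():
        if any(low == s or low.startswith(s) for s in synonyms):
            return kind
    return None


def discover_study_tree(root: str | Path) -> StudyIndex:
    """Index a ``Study/Subject/Acquisition/Run`` directory tree.

    Each immediate subdirectory of ``root`` is a subject; acquisition
    folders beneath are classified by name (smri/anat, dti/dwi, fmri/
    bold/rest, pet); run folders (or the acquisition folder itself when
    it holds files directly) are listed beneath.  Output order is
    sorted, hence deterministic and idempotent.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(f"study root {root} is not a directory")
    subject_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not subject_dirs:
        raise ValueError("no subjects found")
    subjects = []
    for sdir in subject_dirs:
        acqs: dict[str, list[Path]] = {}
        for adir in sorted(p for p in sdir.iterdir() if p.is_dir()):
            kind = _classify_acquisition(adir.name)
            if kind is None:
                continue
            runs = sorted(p for p in adir.iterdir() if p.is_dir())
            acqs.setdefault(kind, []).extend(runs if runs else [adir])
        if not acqs:
            logger.warning("subject %s: no recognized acquisitions", sdir.name)
        subjects.append((sdir.name, acqs))
    return StudyIndex(study_root=root, subjects=subjects)


# ---------------------------------------------------------------------------
# parcellation

def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a 4-column TSV label table: id, name, hemisphere, class."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    tab.columns = [c.strip().lower() for c in tab.columns]
    rename = {"id": "label_id", "class": "tissue_class"}
    tab = tab.rename(columns=rename)
    return tab[["label_id", "name", "hemisphere", "tissue_class"]]


def write_label_table(tab: pd.DataFrame, path: str | Path) -> None:
    out = tab.rename(columns={"label_id": "id", "tissue_class": "class"})
    out[["id", "name", "hemisphere", "class"]].to_csv(path, sep="\t", index=False)


def read_label_volume(
    path: str | Path, table_path: str | Path | None = None, space_id: str = "native"
) -> Parcellation:
    """Read a 3D integer NIfTI label volume plus its label table.

    The table is either given explicitly or resolved by convention as
    ``<stem>_labels.tsv`` next to the volume.  The returned ROI table is
    restricted to labels actually present in the volume and sorted into
    the canonical block ordering.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: voxel data is not integer-valued")
    labels = np.round(data).astype(np.int32)
    if table_path is None:
        stem = re.sub(r"\.nii(\.gz)?$", "", path.name)
        table_path = path.parent / f"{stem}_labels.tsv"
    if not Path(table_path).exists():
        raise FileNotFoundError(f"label table not found: {table_path}")
    tab = read_label_table(table_path)
    present = set(int(v) for v in np.unique(labels)) - {0}
    if not present:
        raise ValueError(f"{path}: no ROIs (all-zero label volume)")
    orphans = present - set(int(i) for i in tab["label_id"])
    if orphans:
        raise ValueError(f"{path}: labels missing from table: {sorted(orphans)}")
    tab = tab[tab["label_id"].isin(present)].reset_index(drop=True)
    return Parcellation(
        labels=labels, voxel_to_mm=img.affine, roi_table=sort_roi_table(tab),
        space_id=space_id,
    )


def write_label_volume(parc: Parcellation, path: str | Path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.voxel_to_mm)
    nib.save(img, str(path))
    stem = re.sub(r"\.nii(\.gz)?$", "", Path(path).name)
    write_label_table(parc.roi_table, Path(path).parent / f"{stem}_labels.tsv")


# ---------------------------------------------------------------------------
# tractograms

def read_tractogram(path: str | Path, space_id: str = "native") -> Tractogram:
    """Read a tractogram from ``.trk`` or the plain-text polyline dialect.

    The text dialect holds one streamline per block of ``x y z`` lines,
    blocks separated by blank lines; ``#`` starts a comment.
    """
    path = Path(path)
    if path.suffix.lower() == ".trk":
        trk = nib.streamlines.load(str(path))
        streamlines = [np.asarray(s, dtype=float) for s in trk.streamlines]
        return Tractogram(streamlines=streamlines, space_id=space_id)
    return _read_text_streamlines(path, space_id)


def _read_text_streamlines(path: Path, space_id: str) -> Tractogram:
    streamlines: list[np.ndarray] = []
    block: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                if block:
                    _flush_block(block, streamlines, lineno)
                    block = []
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'x y z', got {raw!r}")
            try:
                block.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric point") from exc
    if block:
        _flush_block(block, streamlines, lineno)
    return Tractogram(streamlines=streamlines, space_id=space_id)


def _flush_block(block, streamlines, lineno) -> None:
    if len(block) < 2:
        raise ValueError(f"streamline with <2 points ending at line {lineno}")
    streamlines.append(np.array(block, dtype=float))


def write_tractogram(tract: Tractogram, path: str | Path) -> None:
    """Write ``.trk`` (via nibabel, identity voxel-to-mm) or the text dialect."""
    path = Path(path)
    if path.suffix.lower() == ".trk":
        tractogram = nib.streamlines.Tractogram(
            tract.streamlines, affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(tractogram, str(path))
        return
    with open(path, "w") as fh:
        fh.write("# mibca streamlines (mm); one 'x y z' line per point,\n")
        fh.write("# blank line between streamlines\n")
        for sl in tract.streamlines:
            for p in sl:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# matrix container

_BOOL = {"true": True, "false": False}


def write_matrix(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Persist a connectivity matrix as commented header + dense text body."""
    with open(path, "w") as fh:
        fh.write("# mibca-matrix 1\n")
        fh.write(f"# modality: {cm.modality}\n")
        fh.write(f"# directed: {str(cm.directed).lower()}\n")
        fh.write(f"# weight_kind: {cm.weight_kind}\n")
        fh.write("# roi_ids: " + " ".join(str(i) for i in cm.roi_ids) + "\n")
        for row in cm.values:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    header[key.strip()] = val.strip()
                continue
            rows.append([float(v) for v in line.split()])
    for key in ("modality", "directed", "weight_kind", "roi_ids"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
    roi_ids = [int(v) for v in header["roi_ids"].split()]
    values = np.array(rows, dtype=float)
    if values.shape != (len(roi_ids), len(roi_ids)):
        raise ValueError(
            f"{path}: body shape {values.shape} does not match "
            f"{len(roi_ids)} header ROIs"
        )
    return ConnectivityMatrix(
        values=values,
        roi_ids=roi_ids,
        modality=header["modality"],
        directed=_BOOL[header["directed"].lower()],
        weight_kind=header["weight_kind"],
    )


# ---------------------------------------------------------------------------
# tables and 4D series

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(tab: pd.DataFrame, path: str | Path) -> None:
    tab.to_csv(path, sep="\t", index=False)


def read_series_4d(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D NIfTI series; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D series, got {data.ndim}D")
    return data, img.affine


def write_series_4d(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
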
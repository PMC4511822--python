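"""Synthetic study generation with planted ground truth.

Every generator is a pure function of its arguments including the seed,
so fixtures are reproducible and the planted truth (fiber counts per ROI
pair, VAR coupling, group effects) can be asserted exactly downstream.
Noise is Gaussian throughout; the toy parcellation uses mirrored boxes
so left/right symmetry behaviour is exercisable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .types import Parcellation, ROISignalSet, Tractogram, sort_roi_table

__all__ = [
    "PlantedTruth",
    "make_toy_parcellation",
    "make_streamlines",
    "make_var_timeseries",
    "make_group_morphometry",
    "make_pet_tacs",
    "write_synthetic_study",
]


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic study."""

    pair_fiber_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    var_coefficients: np.ndarray | None = None
    group_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> dict:
        return {
            "pair_fiber_counts": {
                f"{a}-{b}": int(k) for (a, b), k in self.pair_fiber_counts.items()
            },
            "var_coefficients": (
                None
                if self.var_coefficients is None
                else np.asarray(self.var_coefficients).tolist()
            ),
            "group_effects": {
                m: {str(r): float(v) for r, v in d.items()}
                for m, d in self.group_effects.items()
            },
            "seed": int(self.seed),
        }


def make_toy_parcellation(
    n_rois: int,
    shape: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    subcortical_pairs: int | None = None,
    voxel_size_mm: float = 2.0,
) -> Parcellation:
    """Disjoint labeled boxes mirrored left/right across the mid-sagittal plane.

    ``n_rois`` must be even: ROIs come in hemisphere pairs sharing a base
    name, with hemispheres assigned by the sign of the x coordinate in mm.
    The first ``subcortical_pairs`` pairs (default: one when n_rois >= 4,
    else zero) are tagged subcortical and sit nearest the midline.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if n_rois % 2 != 0:
        raise ValueError("n_rois must be even (left/right hemisphere pairing)")
    n_pairs = n_rois // 2
    if subcortical_pairs is None:
        subcortical_pairs = 1 if n_rois >= 4 else 0
    if subcortical_pairs > n_pairs:
        raise ValueError("more subcortical pairs than pairs available")

    box, gap = 3, 1
    step = box + gap
    half_x = shape[0] // 2
    nx = max((half_x - gap) // step, 0)
    ny = max((shape[1] - gap) // step, 0)
    nz = max((shape[2] - gap) // step, 0)
    if nx * ny * nz < n_pairs:
        raise ValueError(
            f"shape {shape} too small for {n_pairs} mirrored boxes "
            f"(capacity {nx * ny * nz})"
        )

    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    slots = [(ix, iy, iz) for iz in range(nz) for iy in range(ny) for ix in range(nx)]
    for pair in range(n_pairs):
        ix, iy, iz = slots[pair]
        # left-hemisphere box; x slot 0 sits nearest the midline
        x0 = half_x - (ix + 1) * step + gap
        y0, z0 = gap + iy * step, gap + iz * step
        left_id, right_id = 2 * pair + 1, 2 * pair + 2
        labels[x0 : x0 + box, y0 : y0 + box, z0 : z0 + box] = left_id
        xm0 = shape[0] - (x0 + box)  # mirror across the mid-sagittal plane
        labels[xm0 : xm0 + box, y0 : y0 + box, z0 : z0 + box] = right_id
        tissue = "subcortical" if pair < subcortical_pairs else "cortical"
        base = f"{tissue[:3]}_region{pair:02d}"
        rows.append((left_id, base, "left", tissue))
        rows.append((right_id, base, "right", tissue))

    roi_table = sort_roi_table(
        pd.DataFrame(rows, columns=["label_id", "name", "hemisphere", "tissue_class"])
    )
    # affine centers x=0 on the mid-sagittal plane so hemisphere = sign(x)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[0, 3] = -voxel_size_mm * (shape[0] / 2.0)
    return Parcellation(
        labels=labels, voxel_to_mm=affine, roi_table=roi_table,
        space_id=f"toy-{n_rois}-{seed}",
    )


def _random_point_in_roi(
    parc: Parcellation, roi_id: int, rng: np.random.Generator
) -> np.ndarray:
    vox = np.argwhere(parc.labels == roi_id)
    if len(vox) == 0:
        raise ValueError(f"ROI {roi_id} has no voxels")
    v = vox[rng.integers(len(vox))].astype(float)
    # jitter within the voxel's continuous-index cell [v, v+1)
    cont = v + rng.uniform(0.05, 0.95, size=3)
    return (parc.voxel_to_mm @ np.append(cont, 1.0))[:3]


def _random_background_point(
    parc: Parcellation, rng: np.random.Generator
) -> np.ndarray:
    bg = np.argwhere(parc.labels == 0)
    v = bg[rng.integers(len(bg))].astype(float)
    cont = v + rng.uniform(0.05, 0.95, size=3)
    return (parc.voxel_to_mm @ np.append(cont, 1.0))[:3]


def make_streamlines(
    parc: Parcellation,
    pair_fiber_counts: dict[tuple[int, int], int],
    seed: int = 0,
    n_orphans: int = 0,
    n_interior_points: int = 3,
) -> Tractogram:
    """Plant exactly ``pair_fiber_counts[(a, b)]`` streamlines per ROI pair.

    Each planted streamline starts inside an ``a``-labeled voxel and ends
    inside a ``b``-labeled voxel; interior points are jittered along the
    chord (they carry no assignment meaning).  ``n_orphans`` extra
    streamlines get at least one endpoint in background.
    """
    known = set(parc.roi_ids)
    for a, b in pair_fiber_counts:
        if a not in known or b not in known:
            raise ValueError(f"pair ({a}, {b}) references unknown ROI")
    rng = np.random.default_rng(seed)
    streamlines = []
    for (a, b), count in sorted(pair_fiber_counts.items()):
        for _ in range(int(count)):
            p0 = _random_point_in_roi(parc, a, rng)
            p1 = _random_point_in_roi(parc, b, rng)
            ts = np.linspace(0, 1, n_interior_points + 2)[1:-1]
            interior = p0 + np.outer(ts, p1 - p0) + rng.normal(0, 0.5, (len(ts), 3))
            streamlines.append(np.vstack([p0, interior, p1]))
    for _ in range(int(n_orphans)):
        p0 = _random_background_point(parc, rng)
        p1 = _random_background_point(parc, rng)
        streamlines.append(np.vstack([p0, (p0 + p1) / 2, p1]))
    return Tractogram(streamlines=streamlines, space_id=parc.space_id)


def make_var_timeseries(
    n_rois: int,
    T: int,
    coupling: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    roi_ids: list[int] | None = None,
    repetition_time_s: float = 2.0,
    burn_in: int = 100,
) -> ROISignalSet:
    """Realization of the lag-1 vector autoregression X_t = C X_{t-1} + eps.

    ``coupling`` is the R x R lag-1 matrix C with entry (i, j) coupling
    x_j(t-1) -> x_i(t); it must be stationary (spectral radius < 1).
    The first ``burn_in`` samples are discarded.
    """
    if T < 10:
        raise ValueError("T must be >= 10")
    if coupling is None:
        coupling = np.zeros((n_rois, n_rois))
    coupling = np.asarray(coupling, dtype=float)
    if coupling.shape != (n_rois, n_rois):
        raise ValueError("coupling must be R x R")
    radius = np.max(np.abs(np.linalg.eigvals(coupling)))
    if radius >= 1:
        raise ValueError(f"non-stationary coupling (spectral radius {radius:.3f})")
    rng = np.random.default_rng(seed)
    total = T + burn_in
    x = np.zeros((n_rois, total))
    eps = rng.normal(0.0, noise_sd, size=(n_rois, total))
    for t in range(1, total):
        x[:, t] = coupling @ x[:, t - 1] + eps[:, t]
    if roi_ids is None:
        roi_ids = list(range(1, n_rois + 1))
    return ROISignalSet(
        values=x[:, burn_in:], roi_ids=roi_ids,
        sampling=repetition_time_s, modality="bold",
    )


_CORTICAL_MEASURES = {"CT": 2.5, "SA": 1200.0, "GMV": 3000.0}
_SUBCORT_MEASURES = {"volume": 1500.0}
_DIFFUSION_MEASURES = {"FA": 0.45, "MD": 8e-4}


def make_group_morphometry(
    parc: Parcellation,
    n_per_group: tuple[int, int] = (15, 20),
    baseline: dict[str, float] | None = None,
    group_effects: dict[str, dict[int, float]] | None = None,
    noise_sd: float | dict[str, float] = 0.2,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[str]]:
    """Two groups of per-ROI morphometry tables with planted group shifts.

    Defaults mirror the two-group ageing comparison regime: groups of 15
    and 20 subjects.  ``group_effects`` maps measure -> {roi_id: additive
    shift applied to group 2}.  Returns (tables, group labels), tables in
    group order with per-subject Gaussian noise added per measure.
    """
    n1, n2 = n_per_group
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    base = dict(_CORTICAL_MEASURES, **_SUBCORT_MEASURES, **_DIFFUSION_MEASURES)
    if baseline:
        base.update(baseline)
    if any(v < 0 for v in base.values()):
        raise ValueError("baseline measures must be non-negative")
    group_effects = group_effects or {}
    rng = np.random.default_rng(seed)
    tab = parc.roi_table
    cortical = tab["tissue_class"] == "cortical"

    def noise_for(measure: str) -> float:
        if isinstance(noise_sd, dict):
            return noise_sd.get(measure, 0.0)
        # scale a single relative sd by the measure's baseline magnitude
        return noise_sd * max(base[measure], 1e-12)

    tables, groups = [], []
    for gi, n in enumerate((n1, n2)):
        for _ in range(n):
            df = pd.DataFrame({"label_id": tab["label_id"].to_numpy()})
            for measure in base:
                applies = (
                    cortical.to_numpy()
                    if measure in _CORTICAL_MEASURES
                    else ~cortical.to_numpy()
                    if measure in _SUBCORT_MEASURES
                    else np.ones(len(tab), bool)
                )
                vals = np.full(len(tab), np.nan)
                mean = np.full(len(tab), base[measure])
                if gi == 1:
                    for rid, shift in group_effects.get(measure, {}).items():
                        mean[tab["label_id"].to_numpy() == rid] += shift
                draw = mean + rng.normal(0.0, noise_for(measure), size=len(tab))
                vals[applies] = np.clip(draw[applies], 0.0, None)
                if measure == "FA":
                    vals = np.clip(vals, None, 1.0)
                df[measure] = vals
            tables.append(df)
            groups.append("group1" if gi == 0 else "group2")
    return tables, groups


def make_pet_tacs(
    parc: Parcellation,
    n_frames: int = 8,
    kinetic_profiles: np.ndarray | None = None,
    profile_assignment: list[int] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    frame_duration_s: float = 225.0,
) -> ROISignalSet:
    """Per-ROI time-activity curves: assigned kinetic profile + Gaussian noise.

    Defaults to 8 frames, matching a short dynamic acquisition.  If no
    profiles are given, two canonical shapes (fast uptake with washout,
    slow monotonic uptake) are alternated over ROIs.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t = np.linspace(0.5, 1.0 * n_frames, n_frames)
    if kinetic_profiles is None:
        kinetic_profiles = np.vstack(
            [t * np.exp(-t / 2.0) * 4.0, 2.0 * (1.0 - np.exp(-t / 3.0))]
        )
    kinetic_profiles = np.atleast_2d(np.asarray(kinetic_profiles, dtype=float))
    if kinetic_profiles.shape[1] != n_frames:
        raise ValueError("profiles must have n_frames samples")
    R = parc.n_rois
    if profile_assignment is None:
        profile_assignment = [i % len(kinetic_profiles) for i in range(R)]
    rng = np.random.default_rng(seed)
    values = np.empty((R, n_frames))
    for i in range(R):
        values[i] = kinetic_profiles[profile_assignment[i]] + rng.normal(
            0.0, noise_sd, size=n_frames
        )
    return ROISignalSet(
        values=values, roi_ids=parc.roi_ids,
        sampling=np.full(n_frames, frame_duration_s), modality="pet",
    )


def write_synthetic_study(
    root: str | Path,
    n_subjects: int = 10,
    n_rois: int = 8,
    T_bold: int = 200,
    seed: int = 0,
    coupling: np.ndarray | None = None,
    pair_fiber_counts: dict[tuple[int, int], int] | None = None,
    group_effects: dict[str, dict[int, float]] | None = None,
) -> PlantedTruth:
    """Write a complete Study/Subject/Acquisition/Run tree of text fixtures.

    Per subject: a streamline file (dti), a BOLD ROI x time TSV (fmri), a
    PET TAC TSV (pet) and a morphometry TSV (smri); study-level files are
    the shared parcellation, a participants table (age/sex/group) and a
    ``truth.json`` manifest of everything planted.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    parc = make_toy_parcellation(n_rois, seed=seed)
    mio.write_label_volume(parc, root / "parcellation.nii.gz")

    ids = parc.roi_ids
    if pair_fiber_counts is None:
        pair_fiber_counts = {}
        for k in range(0, len(ids) - 1, 2):
            pair_fiber_counts[(ids[k], ids[k + 1])] = int(rng.integers(2, 8))
    if coupling is None:
        coupling = np.zeros((n_rois, n_rois))
        coupling[1, 0] = 0.6  # planted directed drive roi[0] -> roi[1]
        np.fill_diagonal(coupling, 0.2)
    if group_effects is None:
        tab = parc.roi_table
        first_cortical = int(
            tab.loc[tab["tissue_class"] == "cortical", "label_id"].iloc[0]
        )
        group_effects = {"CT": {first_cortical: -0.5}}

    n1 = n_subjects // 2
    ages = np.concatenate(
        [rng.integers(20, 40, size=n1), rng.integers(41, 75, size=n_subjects - n1)]
    )
    sexes = rng.choice(["M", "F"], size=n_subjects)
    morph_tables, _ = make_group_morphometry(
        parc, (max(n1, 2), max(n_subjects - n1, 2)),
        group_effects=group_effects, seed=seed + 7,
    )
    subjects = []
    for si in range(n_subjects):
        sid = f"sub{si + 1:02d}"
        subjects.append(sid)
        sdir = root / sid
        (sdir / "dti" / "run1").mkdir(parents=True, exist_ok=True)
        (sdir / "fmri" / "run1").mkdir(parents=True, exist_ok=True)
        (sdir / "pet" / "run1").mkdir(parents=True, exist_ok=True)
        (sdir / "smri" / "run1").mkdir(parents=True, exist_ok=True)

        tract = make_streamlines(
            parc, pair_fiber_counts, seed=seed + 100 + si, n_orphans=2
        )
        mio.write_tractogram(tract, sdir / "dti" / "run1" / "streamlines.txt")

        bold = make_var_timeseries(
            n_rois, T_bold, coupling=coupling, seed=seed + 200 + si, roi_ids=ids
        )
        df = pd.DataFrame(bold.values, index=pd.Index(ids, name="label_id"))
        df.reset_index().to_csv(
            sdir / "fmri" / "run1" / "bold_roi.tsv", sep="\t", index=False
        )

        tacs = make_pet_tacs(parc, seed=seed + 300 + si)
        df = pd.DataFrame(tacs.values, index=pd.Index(ids, name="label_id"))
        df.reset_index().to_csv(
            sdir / "pet" / "run1" / "tacs.tsv", sep="\t", index=False
        )

        mio.write_table(
            morph_tables[si], sdir / "smri" / "run1" / "morphometry.tsv"
        )

    participants = pd.DataFrame(
        {
            "subject_id": subjects,
            "age": ages,
            "sex": sexes,
            "group": ["young" if a < 40 else "old" for a in ages],
        }
    )
    mio.write_table(participants, root / "participants.tsv")

    truth = PlantedTruth(
        pair_fiber_counts=dict(pair_fiber_counts),
        var_coefficients=coupling,
        group_effects=group_effects,
        seed=seed,
    )
    with open(root / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return truth
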
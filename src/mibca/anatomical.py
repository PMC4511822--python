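"""Anatomical connectivity (a-CM) from morphometric measures.

An a-CM entry relates two ROIs by the ratio of a morphometric measure
(cortical thickness CT in mm, surface area SA in mm^2, gray-matter
volume GMV in mm^3, or subcortical volume in mm^3).  The ratio is taken
as min/max so the matrix is symmetric with entries in (0, 1]; a raw
directional ratio m_i / m_j is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ConnectivityMatrix, Parcellation

CORTICAL_MEASURES = ("CT", "SA", "GMV")
SUBCORTICAL_MEASURES = ("volume",)


def measure_roi_ids(parc: Parcellation, measure: str) -> list[int]:
    """ROIs over which ``measure`` is defined (tissue-class restricted)."""
    tab = parc.roi_table
    if measure in CORTICAL_MEASURES:
        mask = tab["tissue_class"] == "cortical"
    elif measure in SUBCORTICAL_MEASURES:
        mask = tab["tissue_class"] == "subcortical"
    else:
        mask = pd.Series(True, index=tab.index)
    return [int(i) for i in tab.loc[mask, "label_id"]]


def anatomical_cm(
    morph: pd.DataFrame,
    measure: str,
    parc: Parcellation | None = None,
    symmetric: bool = True,
) -> ConnectivityMatrix:
    """Build an a-CM from one morphometric measure.

    Parameters
    ----------
    morph : per-ROI table with a ``label_id`` column and one column per
        measure (NaN where a measure does not apply to a tissue class).
    measure : one of CT, SA, GMV, volume (or any column of ``morph``).
    parc : optionally restricts/reorders ROIs to the canonical ordering
        of the tissue class the measure applies to.
    symmetric : min/max ratio (default) versus directional m_i / m_j.
    """
    if measure not in morph.columns:
        raise ValueError(f"measure {measure!r} not in morphometry table")
    sub = morph[["label_id", measure]].dropna(subset=[measure])
    if parc is not None:
        wanted = measure_roi_ids(parc, measure)
        have = set(int(i) for i in sub["label_id"])
        missing = [r for r in wanted if r not in have]
        if missing:
            raise ValueError(f"measure {measure!r} missing for ROIs {missing}")
        sub = sub.set_index("label_id").loc[wanted].reset_index()
        roi_ids = wanted
    else:
        roi_ids = [int(i) for i in sub["label_id"]]
    m = sub[measure].to_numpy(dtype=float)
    bad = np.asarray(roi_ids)[m <= 0]
    if len(bad):
        raise ValueError(f"non-positive {measure} for ROIs {bad.tolist()}")
    if symmetric:
        values = np.minimum.outer(m, m) / np.maximum.outer(m, m)
    else:
        values = np.outer(m, 1.0 / m)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=values,
        roi_ids=roi_ids,
        modality="a",
        directed=not symmetric,
        weight_kind="ratio",
    )
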
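"""Static renderers: block-ordered matrix heatmap, multi-ring connectogram,
and 3D brain graph.

All renderers are pure functions of their inputs: figures use a pinned
SVG hash salt and no timestamps, so identical inputs give identical
vector output.  Each returns a metadata dict (chord/edge counts, tick
order) so structural properties are testable without parsing images.

Color conventions: matrices use the jet colormap (cold = low, warm =
high); group-difference edges default to red = significant increase and
blue = decrease; direct/mediated hybrid edges default to red = direct,
blue = mediated (both conventions are configurable).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .types import ConnectivityMatrix, Parcellation

_SVG_KW = dict(metadata={"Date": None})


def _new_figure(figsize):
    plt.rcParams["svg.hashsalt"] = "mibca"
    return plt.figure(figsize=figsize)


def _block_bounds(parc: Parcellation) -> list[int]:
    """Indices where the subcortical / left-cortical / right-cortical
    blocks of the canonical ordering change."""
    tab = parc.roi_table
    blocks = [
        0 if c == "subcortical" else (1 if h == "left" else 2)
        for c, h in zip(tab["tissue_class"], tab["hemisphere"])
    ]
    return [i for i in range(1, len(blocks)) if blocks[i] != blocks[i - 1]]


def matrix_plot(
    cm: ConnectivityMatrix, parc: Parcellation, out_path: str | Path
) -> dict:
    """Heatmap of a connectivity matrix in canonical block order."""
    if cm.roi_ids != parc.roi_ids:
        raise ValueError("matrix ordering does not match the parcellation's "
                         "canonical ordering")
    fig = _new_figure((6, 5))
    ax = fig.add_subplot(111)
    im = ax.imshow(cm.values, cmap="jet", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.85)
    names = parc.roi_names()
    ax.set_xticks(range(len(names)))
    ax.set_yticks(range(len(names)))
    ax.set_xticklabels(names, rotation=90, fontsize=6)
    ax.set_yticklabels(names, fontsize=6)
    for b in _block_bounds(parc):
        ax.axhline(b - 0.5, color="white", lw=1.0)
        ax.axvline(b - 0.5, color="white", lw=1.0)
    ax.set_title(f"{cm.modality}-CM ({cm.weight_kind})")
    fig.tight_layout()
    _save(fig, out_path)
    return {
        "tick_order": names,
        "block_bounds": _block_bounds(parc),
        "vmin": float(cm.values.min()),
        "vmax": float(cm.values.max()),
    }


def connectogram(
    edge_matrix: ConnectivityMatrix,
    parc: Parcellation,
    out_path: str | Path,
    rings: dict[str, dict[int, float]] | None = None,
    edge_color_mode: str = "by_weight",
    class_matrix: ConnectivityMatrix | None = None,
    direct_color: str = "red",
    mediated_color: str = "blue",
    increase_color: str = "red",
    decrease_color: str = "blue",
) -> dict:
    """Circular connectogram: ROI sectors, concentric metric rings, chords.

    ``rings`` maps ring name -> {roi_id: value}, drawn outer to inner.
    ``edge_color_mode``:
      * ``by_weight`` — chord color from the jet map over edge weights;
      * ``by_sign`` — increase_color for positive entries, decrease_color
        for negative ones (group-difference encoding);
      * ``by_class`` — direct_color where ``class_matrix`` is nonzero,
        mediated_color elsewhere (hybrid decomposition encoding).
    """
    rings = rings or {}
    ids = edge_matrix.roi_ids
    if ids != parc.roi_ids:
        raise ValueError("edge matrix must be in the parcellation's ordering")
    for ring_name, ring in rings.items():
        missing = [r for r in ids if r not in ring]
        if missing:
            raise ValueError(f"ring {ring_name!r} missing ROIs {missing}")
    if edge_color_mode == "by_class" and class_matrix is None:
        raise ValueError("by_class mode needs a class_matrix")
    R = len(ids)
    theta = 2 * np.pi * (np.arange(R) + 0.5) / R
    fig = _new_figure((7, 7))
    ax = fig.add_subplot(111)
    ax.set_aspect("equal")
    ax.axis("off")

    # hemisphere-shaded outer sectors plus labels
    hemis = list(parc.roi_table["hemisphere"])
    names = parc.roi_names()
    shade = {"left": "0.75", "right": "0.55", "none": "0.9"}
    for i, (th, h) in enumerate(zip(theta, hemis)):
        wedge = plt.matplotlib.patches.Wedge(
            (0, 0), 1.45, np.degrees(th) - 180.0 / R, np.degrees(th) + 180.0 / R,
            width=0.12, color=shade[h],
        )
        ax.add_patch(wedge)
        ax.text(
            1.52 * np.cos(th), 1.52 * np.sin(th), names[i], fontsize=6,
            ha="center", va="center",
            rotation=np.degrees(th) + (180 if np.cos(th) < 0 else 0),
            rotation_mode="anchor",
        )
    # metric rings, outer to inner, jet-mapped per ring
    r0 = 1.3
    for ring_name, ring in rings.items():
        vals = np.array([ring[r] for r in ids], dtype=float)
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        norm = (vals - lo) / (hi - lo) if hi > lo else np.full(R, 0.5)
        cmap = plt.get_cmap("jet")
        for th, v in zip(theta, norm):
            wedge = plt.matplotlib.patches.Wedge(
                (0, 0), r0, np.degrees(th) - 170.0 / R, np.degrees(th) + 170.0 / R,
                width=0.09, color=cmap(v),
            )
            ax.add_patch(wedge)
        r0 -= 0.11

    # chords
    vals = edge_matrix.values
    sym = np.maximum(np.abs(vals), np.abs(vals).T)
    chord_counts: dict[str, int] = {}
    vmax = np.max(np.abs(vals)) or 1.0
    n_chords = 0
    for i in range(R):
        for j in range(i + 1, R):
            if vals[i, j] == 0 and vals[j, i] == 0:
                continue
            w = vals[i, j] if vals[i, j] != 0 else vals[j, i]
            if edge_color_mode == "by_sign":
                color = increase_color if w > 0 else decrease_color
                key = "increase" if w > 0 else "decrease"
            elif edge_color_mode == "by_class":
                is_direct = class_matrix.values[i, j] != 0
                color = direct_color if is_direct else mediated_color
                key = "direct" if is_direct else "mediated"
            else:
                color = plt.get_cmap("jet")(abs(w) / vmax)
                key = "weighted"
            chord_counts[key] = chord_counts.get(key, 0) + 1
            n_chords += 1
            p0 = np.array([np.cos(theta[i]), np.sin(theta[i])]) * (r0 + 0.02)
            p1 = np.array([np.cos(theta[j]), np.sin(theta[j])]) * (r0 + 0.02)
            mid = (p0 + p1) * 0.25  # pull the chord toward the center
            bez_t = np.linspace(0, 1, 40)[:, None]
            curve = ((1 - bez_t) ** 2) * p0 + 2 * bez_t * (1 - bez_t) * mid + bez_t**2 * p1
            ax.plot(curve[:, 0], curve[:, 1], color=color, lw=0.8,
                    alpha=min(1.0, 0.3 + 0.7 * sym[i, j] / vmax))
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.8, 1.8)
    _save(fig, out_path)
    return {"n_chords": n_chords, "chord_counts": chord_counts,
            "n_rings": len(rings)}


def graph3d(
    cm: ConnectivityMatrix,
    node_coords: dict[int, np.ndarray] | None = None,
    parc: Parcellation | None = None,
    node_metric: dict[int, float] | None = None,
    out_path: str | Path = "graph3d.svg",
) -> dict:
    """3D graph: nodes at ROI centroids, marker size monotone in a metric.

    Directed edges render as red-to-blue gradient segments (red at the
    source); pairs significant in both directions render as solid black.
    """
    if node_coords is None:
        if parc is None:
            raise ValueError("need node_coords or a parcellation for centroids")
        node_coords = parc.roi_centroids_mm()
    missing = [r for r in cm.roi_ids if r not in node_coords]
    if missing:
        raise ValueError(f"missing coordinates for ROIs {missing}")
    ids = cm.roi_ids
    pts = np.array([node_coords[r] for r in ids])
    if node_metric is None:
        deg = (np.maximum(cm.values, cm.values.T) > 0).sum(axis=1).astype(float)
        node_metric = {r: float(d) for r, d in zip(ids, deg)}
    metric = np.array([node_metric[r] for r in ids], dtype=float)
    lo, hi = metric.min(), metric.max()
    sizes = 30 + 170 * (metric - lo) / (hi - lo) if hi > lo else np.full(len(ids), 80.0)

    fig = _new_figure((7, 6))
    ax = fig.add_subplot(111, projection="3d")
    ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=sizes, c="0.3",
               depthshade=False)
    n_bidir = n_directed = n_undirected = 0
    vals = cm.values
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            fwd, back = vals[i, j] != 0, vals[j, i] != 0
            if not (fwd or back):
                continue
            if cm.directed and fwd and back:
                n_bidir += 1
                ax.plot(*zip(pts[i], pts[j]), color="black", lw=1.2)
            elif cm.directed:
                n_directed += 1
                src, dst = (i, j) if fwd else (j, i)
                seg = np.linspace(pts[src], pts[dst], 12)
                cmap = plt.get_cmap("coolwarm_r")  # red at source -> blue at sink
                for k in range(len(seg) - 1):
                    ax.plot(*zip(seg[k], seg[k + 1]),
                            color=cmap(k / (len(seg) - 2)), lw=1.0)
            else:
                n_undirected += 1
                ax.plot(*zip(pts[i], pts[j]), color="0.5", lw=0.8)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    _save(fig, out_path)
    return {
        "n_bidirectional": n_bidir,
        "n_directed": n_directed,
        "n_undirected": n_undirected,
        "marker_sizes": {r: float(s) for r, s in zip(ids, sizes)},
    }


def adjacency_report(cm: ConnectivityMatrix) -> dict[int, list[int]]:
    """Per-ROI list of connected ROIs (static stand-in for hover views)."""
    sym = np.maximum(np.abs(cm.values), np.abs(cm.values).T)
    ids = cm.roi_ids
    return {
        ids[i]: [ids[j] for j in np.nonzero(sym[i])[0]] for i in range(len(ids))
    }


def _save(fig, out_path: str | Path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    kw = _SVG_KW if out_path.suffix.lower() == ".svg" else {}
    try:
        fig.savefig(out_path, **kw)
    finally:
        plt.close(fig)
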
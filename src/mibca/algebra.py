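"""Subject-stack matrix algebra.

Group-level constructions over per-subject connectivity matrices:

* ``mean_cm`` — elementwise mean of weighted matrices (connection strength);
* ``robustness_cm`` — elementwise mean of binary matrices (fraction of
  subjects showing each connection);
* ``combined_cm`` — mean matrix masked where robustness exceeds a strict
  threshold, ``combined = mean * (robustness > tau)`` with tau = 0.8 by
  default;
* ``hybrid_sf`` — elementwise product of structural and functional
  matrices (sf-CM);
* ``decompose_direct_mediated`` — split functional edges into *direct*
  (also structurally connected) and *mediated* (functionally correlated
  without a direct axonal edge);
* ``mediated_path`` — fewest-intermediate-regions structural path
  explaining a mediated functional edge (breadth-first search with
  deterministic lexicographic tie-breaking).
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .types import ConnectivityMatrix, SubjectStack


def binarize(
    cm: ConnectivityMatrix,
    rule: str = "positive_count",
    p_matrix: np.ndarray | None = None,
    alpha: float = 0.05,
    family: int | None = None,
) -> ConnectivityMatrix:
    """Binarize a weighted matrix.

    ``positive_count``: entry > 0 (the fiber-count rule).
    ``p_threshold``: p < alpha / family with family defaulting to the
    unique-pair (undirected) or ordered-pair (directed) count.
    """
    if rule == "positive_count":
        values = (cm.values > 0).astype(float)
    elif rule == "p_threshold":
        if p_matrix is None:
            raise ValueError("p_threshold rule requires a p_matrix")
        R = cm.n_rois
        if family is None:
            family = R * (R - 1) if cm.directed else R * (R - 1) // 2
        values = (np.asarray(p_matrix) < alpha / family).astype(float)
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    np.fill_diagonal(values, 0.0)
    if not cm.directed:
        values = np.maximum(values, values.T)
    return cm.copy_with(values, weight_kind="binary")


def mean_cm(stack: SubjectStack) -> ConnectivityMatrix:
    """Elementwise mean of the stack's weighted matrices."""
    arr = stack.as_array()
    first = stack.matrices[stack.subject_ids[0]]
    # a mean of binary matrices is a fraction, no longer binary
    kind = "probability" if first.weight_kind == "binary" else first.weight_kind
    return first.copy_with(arr.mean(axis=0), weight_kind=kind)


def variance_cm(stack: SubjectStack) -> ConnectivityMatrix:
    """Elementwise (population) variance across subjects."""
    arr = stack.as_array()
    first = stack.matrices[stack.subject_ids[0]]
    return first.copy_with(arr.var(axis=0), weight_kind="probability")


def robustness_cm(stack: SubjectStack) -> ConnectivityMatrix:
    """Fraction of subjects in which each connection is present.

    All stack matrices must be binary; a robustness of 0.1 means 10% of
    subjects show the connection, 0.9 means 90% do.
    """
    for sid in stack.subject_ids:
        if not stack.matrices[sid].is_binary():
            raise ValueError(f"subject {sid}: matrix is not binary")
    arr = stack.as_array()
    first = stack.matrices[stack.subject_ids[0]]
    return first.copy_with(arr.mean(axis=0), weight_kind="probability")


def combined_cm(
    mean: ConnectivityMatrix, robustness: ConnectivityMatrix, tau: float = 0.8
) -> ConnectivityMatrix:
    """``combined = mean * (robustness > tau)`` with a strict inequality.

    Keeps the mean connection strength only where the connection is
    present in strictly more than ``tau`` of subjects.
    """
    if mean.values.shape != robustness.values.shape:
        raise ValueError("mean and robustness shapes differ")
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    mask = (robustness.values > tau).astype(float)
    return mean.copy_with(mean.values * mask)


def hybrid_sf(s: ConnectivityMatrix, f: ConnectivityMatrix) -> ConnectivityMatrix:
    """Hybrid structural-functional matrix: elementwise product s * f."""
    if s.roi_ids != f.roi_ids:
        raise ValueError("s-CM and f-CM must share the ROI set and order")
    return ConnectivityMatrix(
        values=s.values * f.values, roi_ids=list(s.roi_ids), modality="sf",
        directed=s.directed or f.directed, weight_kind="probability",
    )


def decompose_direct_mediated(
    s_bin: ConnectivityMatrix, f_bin: ConnectivityMatrix
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Split functional edges into direct and mediated classes.

    direct = s AND f (functional edges with a direct axonal edge);
    mediated = f AND NOT s (functionally correlated without one).
    The two classes partition the functional edge set exactly.
    """
    for cm in (s_bin, f_bin):
        if not cm.is_binary():
            raise ValueError("decomposition requires binary matrices")
    if s_bin.roi_ids != f_bin.roi_ids:
        raise ValueError("matrices must share the ROI set and order")
    direct = s_bin.values * f_bin.values
    mediated = f_bin.values * (1.0 - s_bin.values)
    kw = dict(roi_ids=list(f_bin.roi_ids), modality="sf", weight_kind="binary")
    return (
        ConnectivityMatrix(values=direct, **kw),
        ConnectivityMatrix(values=mediated, **kw),
    )


def mediated_path(
    s_bin: ConnectivityMatrix,
    source: int,
    target: int,
    all_shortest: bool = False,
) -> list[int] | list[list[int]] | None:
    """Structural path with the fewest intermediate regions.

    Breadth-first search on the undirected binary structural graph from
    ``source`` to ``target`` (ROI label ids).  Neighbor expansion follows
    the matrix's canonical ROI order, so ties resolve deterministically
    to the lexicographically first shortest path.  Returns the path as a
    list of ROI ids (or all minimum-length paths when ``all_shortest``),
    or None when the regions are disconnected.
    """
    if not s_bin.is_binary():
        raise ValueError("mediated_path requires a binary structural matrix")
    src = s_bin.index_of(source)
    dst = s_bin.index_of(target)
    if src == dst:
        raise ValueError("source and target must differ")
    adj = np.maximum(s_bin.values, s_bin.values.T) > 0
    R = s_bin.n_rois
    # BFS distances to the target; walking them down from the source
    # guarantees every greedy step stays on a shortest path
    dist = np.full(R, -1)
    dist[dst] = 0
    queue = deque([dst])
    while queue:
        u = queue.popleft()
        for v in range(R):
            if adj[u, v] and dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    if dist[src] < 0:
        return None
    ids = s_bin.roi_ids
    if not all_shortest:
        path = [src]
        u = src
        while u != dst:
            for v in range(R):  # canonical order -> deterministic tie-break
                if adj[u, v] and dist[v] == dist[u] - 1:
                    path.append(v)
                    u = v
                    break
        return [ids[i] for i in path]
    paths: list[list[int]] = []
    stack = [[src]]
    while stack:
        partial = stack.pop()
        u = partial[-1]
        if u == dst:
            paths.append([ids[i] for i in partial])
            continue
        for v in range(R - 1, -1, -1):  # reversed so pop yields canonical order
            if adj[u, v] and dist[v] == dist[u] - 1:
                stack.append(partial + [v])
    return paths
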
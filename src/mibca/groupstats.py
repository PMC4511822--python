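"""Between-group statistics on per-ROI metrics and per-edge connectivity.

Two-sample Welch t-tests per target (ROI metric or edge weight), with
optional prior residualization on nuisance covariates and optional
multiplicity correction (Bonferroni or Benjamini-Hochberg FDR).  The
reported direction is the sign of mean(group2) - mean(group1), matching
the red/blue increase/decrease encoding used by the connectogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SubjectStack


@dataclass
class GroupTestResult:
    table: pd.DataFrame  # one row per target: target, t, p, direction, significant
    alpha: float
    correction: str
    test: str = "welch"
    regressed: tuple[str, ...] = ()


def split_groups(
    covariates: pd.DataFrame,
    variable: str,
    threshold: float | None = None,
    label: str | None = None,
) -> tuple[list[str], list[str]]:
    """Partition subjects by a covariate threshold or categorical label.

    With ``threshold``, group 1 is ``variable < threshold`` (e.g. young
    adults under 40) and group 2 the rest; with ``label``, group 1 is
    ``variable == label``.  Returns the two subject-id lists.
    """
    if variable not in covariates.columns:
        raise ValueError(f"covariate {variable!r} not present")
    ids = covariates.index.astype(str)
    if threshold is not None:
        mask = covariates[variable].to_numpy() < threshold
    elif label is not None:
        mask = covariates[variable].astype(str).to_numpy() == str(label)
    else:
        raise ValueError("provide a threshold or a label rule")
    g1, g2 = list(ids[mask]), list(ids[~mask])
    if not g1 or not g2:
        raise ValueError("split produced an empty group")
    return g1, g2


def regress_covariates(
    values: np.ndarray, covariates: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """OLS residuals of a subject vector on covariates plus intercept."""
    y = np.asarray(values, dtype=float).ravel()
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValueError("values and covariates have different lengths")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more subjects than covariates + intercept")
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def _adjust(p: np.ndarray, correction: str, alpha: float) -> np.ndarray:
    """Boolean significance mask after the selected correction."""
    p = np.asarray(p, dtype=float)
    if correction == "none":
        return p < alpha
    if correction == "bonferroni":
        return p < alpha / len(p)
    if correction == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        passed = ranked <= alpha
        sig = np.zeros(len(p), dtype=bool)
        if passed.any():
            kmax = np.max(np.nonzero(passed))
            sig[order[: kmax + 1]] = True
        return sig
    raise ValueError(f"unknown correction {correction!r}")


def groupwise_test(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    correction: str = "none",
    alpha: float = 0.05,
    covariates_a: pd.DataFrame | None = None,
    covariates_b: pd.DataFrame | None = None,
    equal_var: bool = False,
) -> GroupTestResult:
    """Per-target two-sample t-tests between two groups.

    ``values_a``/``values_b`` are subjects x targets frames sharing
    columns (targets are ROI-metric names or edge labels).  Covariates,
    when given, are residualized out of the pooled subject vector before
    testing.  Targets with zero variance in both groups are skipped with
    a warning row (p = NaN).
    """
    if list(values_a.columns) != list(values_b.columns):
        raise ValueError("groups must share the same target columns")
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    regressed: tuple[str, ...] = ()
    if covariates_a is not None:
        if covariates_b is None or list(covariates_a.columns) != list(
            covariates_b.columns
        ):
            raise ValueError("both groups need identical covariate columns")
        regressed = tuple(covariates_a.columns)
    rows = []
    na, nb = len(values_a), len(values_b)
    for target in values_a.columns:
        a = values_a[target].to_numpy(dtype=float)
        b = values_b[target].to_numpy(dtype=float)
        if regressed:
            pooled = np.concatenate([a, b])
            X = pd.concat([covariates_a, covariates_b], axis=0)
            resid = regress_covariates(pooled, X)
            a, b = resid[:na], resid[na:]
        if a.std() == 0 and b.std() == 0:
            rows.append((target, np.nan, np.nan, "none", False))
            continue
        t, p = stats.ttest_ind(b, a, equal_var=equal_var)
        direction = "increase" if b.mean() - a.mean() > 0 else "decrease"
        rows.append((target, float(t), float(p), direction, False))
    table = pd.DataFrame(
        rows, columns=["target", "t", "p", "direction", "significant"]
    )
    valid = table["p"].notna().to_numpy()
    if valid.any():
        sig = _adjust(table.loc[valid, "p"].to_numpy(), correction, alpha)
        table.loc[valid, "significant"] = sig
    return GroupTestResult(
        table=table, alpha=alpha, correction=correction,
        test="student" if equal_var else "welch", regressed=regressed,
    )


def edge_table(stack: SubjectStack) -> pd.DataFrame:
    """Subjects x edges frame of upper-triangle weights, for edge tests.

    Columns are ``"{roi_i}-{roi_j}"`` labels in canonical order.
    """
    ids = stack.roi_ids
    R = len(ids)
    iu = np.triu_indices(R, k=1)
    cols = [f"{ids[i]}-{ids[j]}" for i, j in zip(*iu)]
    data = {
        sid: stack.matrices[sid].values[iu] for sid in stack.subject_ids
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
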
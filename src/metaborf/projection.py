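"""PCA of metabolite profiles with scree-based component selection.

Metabolite abundances span orders of magnitude, so PCA is run on
standardized columns (zero mean, unit sample variance) — the
correlation-matrix convention — with a covariance-based variant behind a
flag. Scores place subjects in component space; loadings give each
metabolite's weight on a component. Component signs are fixed so the
largest-magnitude loading of each component is positive, making outputs
reproducible. The number of retained components comes from the scree
curve: either a manual override (mirroring by-eye scree inspection) or an
automated elbow at the maximum second difference (acceleration) of the
eigenvalue sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ProjectionResult:
    """Eigenvalues, scores and loadings of one PCA, with the retained-k summary.

    ``eigenvalues`` holds all min(n-1, p) components in descending order;
    ``scores``/``loadings`` are truncated to ``k_selected`` columns, while
    ``scores_all``/``loadings_all`` retain everything for reconstruction.
    ``variance_captured`` is the fraction of total variance in the first
    ``k_selected`` eigenvalues.
    """

    eigenvalues: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    k_selected: int
    variance_captured: float
    scores_all: pd.DataFrame
    loadings_all: pd.DataFrame
    total_variance: float
    column_means: np.ndarray
    column_scales: np.ndarray

    def export(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.scores.to_csv(prefix.with_name(prefix.name + "_scores.tsv"), sep="\t")
        self.loadings.to_csv(prefix.with_name(prefix.name + "_loadings.tsv"), sep="\t")
        scree = pd.DataFrame({
            "component": np.arange(1, len(self.eigenvalues) + 1),
            "eigenvalue": self.eigenvalues,
            "variance_fraction": self.eigenvalues / self.total_variance,
        })
        scree.to_csv(prefix.with_name(prefix.name + "_scree.tsv"), sep="\t", index=False)


def pca(
    x,
    k_override: int | None = None,
    standardize: bool = True,
) -> ProjectionResult:
    """Principal-component analysis of a subjects x metabolites matrix.

    ``standardize=True`` (default) z-scores each metabolite before the
    decomposition; a zero-variance metabolite is an error naming it (the
    qualification filter should have removed it). Deterministic up to the
    fixed sign convention.
    """
    if isinstance(x, pd.DataFrame):
        subject_ids, feature_ids = list(x.index), list(x.columns)
        X = x.to_numpy(dtype=float)
    else:
        X = np.asarray(x, dtype=float)
        subject_ids = [f"s{i}" for i in range(X.shape[0])]
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("pca requires >= 2 subjects and >= 1 metabolite")
    if np.isnan(X).any():
        raise ValueError("pca input contains missing values")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if standardize:
        # relative tolerance: a constant column's sample SD is O(eps), not 0
        zero = np.flatnonzero(sds <= 1e-12 * np.maximum(1.0, np.abs(means)))
        if zero.size:
            raise ValueError(
                f"zero-variance metabolite {feature_ids[int(zero[0])]!r}; "
                "remove constant features before PCA"
            )
        Z = (X - means) / sds
        scales = sds
    else:
        Z = X - means
        scales = np.ones(p)

    n_comp = min(n - 1, p)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]
    eigenvalues = S**2 / (n - 1)
    # sign convention: largest-magnitude loading of each component positive
    for c in range(n_comp):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores_all = pd.DataFrame(
        U * S, index=pd.Index(subject_ids, name="subject_id"),
        columns=[f"PC{c + 1}" for c in range(n_comp)],
    )
    loadings_all = pd.DataFrame(
        Vt.T, index=pd.Index(feature_ids, name="metabolite_id"),
        columns=scores_all.columns,
    )
    total = float(np.sum(Z.var(axis=0, ddof=1)))
    k = select_components_scree(eigenvalues, k_override)
    return ProjectionResult(
        eigenvalues=eigenvalues,
        scores=scores_all.iloc[:, :k].copy(),
        loadings=loadings_all.iloc[:, :k].copy(),
        k_selected=k,
        variance_captured=float(eigenvalues[:k].sum() / total),
        scores_all=scores_all,
        loadings_all=loadings_all,
        total_variance=total,
        column_means=means,
        column_scales=scales,
    )


def select_components_scree(eigenvalues, k_override: int | None = None) -> int:
    """Retained-component count from the scree curve.

    With ``k_override`` the manual scree-inspection choice is taken as-is
    (after a range check). Otherwise the elbow is the interior index with
    the maximum second difference of the eigenvalue sequence; the retained
    count is the number of components before that elbow. Degenerate curves
    (fewer than 3 eigenvalues, or no curvature) fall back to 1 with a
    warning.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue sequence")
    if np.any(np.diff(eig) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    if k_override is not None:
        if not 1 <= k_override <= eig.size:
            raise ValueError(f"k_override must be in [1, {eig.size}], got {k_override}")
        return int(k_override)
    if eig.size < 3:
        return 1
    accel = eig[:-2] - 2 * eig[1:-1] + eig[2:]  # second difference at interior points
    if np.allclose(accel, 0.0):
        warnings.warn("flat scree curve: no elbow; retaining 1 component", stacklevel=2)
        return 1
    # accel[j] is curvature at component j+2 (1-based); retain the components
    # before the elbow
    return int(np.argmax(accel)) + 1


def variance_captured(result: ProjectionResult, k: int) -> float:
    """Fraction of total variance in the first k components."""
    if not 1 <= k <= len(result.eigenvalues):
        raise ValueError(f"k must be in [1, {len(result.eigenvalues)}], got {k}")
    return float(result.eigenvalues[:k].sum() / result.total_variance)


def reconstruct(result: ProjectionResult) -> np.ndarray:
    """Inverse projection with all components retained (returns the data scale)."""
    Z = result.scores_all.to_numpy() @ result.loadings_all.to_numpy().T
    return Z * result.column_scales + result.column_means


def separation_ratio(scores: pd.DataFrame, groups: pd.Series, k: int = 2) -> float:
    """Between-group centroid distance over mean within-group spread in PC1..PCk.

    A scale-free summary of how well the first components separate the two
    classes; used to compare qualified- vs refined-profile projections.
    """
    pts = scores.iloc[:, :k].to_numpy()
    labels = groups.loc[scores.index].to_numpy()
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError("separation_ratio requires exactly two groups")
    a, b = (pts[labels == g] for g in uniq)
    between = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
    within = 0.5 * (
        np.mean(np.linalg.norm(a - a.mean(axis=0), axis=1))
        + np.mean(np.linalg.norm(b - b.mean(axis=0), axis=1))
    )
    return float(between / within) if within > 0 else float("inf")
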
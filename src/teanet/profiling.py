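"""Per-feature variability, sample PCA and unsupervised group assignment.

Variability of a feature is its max/min intensity ratio across biological
samples — a dimensionless fold range.  Conserved primary metabolites sit
below 3-fold; downstream secondary metabolites (catechin polymers, flavonoid
glycosides) can exceed 1000-fold.  Tier labels follow those conventions:
``<3``, ``3-5``, ``5-1000`` and ``>1000`` (with a separate flag above
3000-fold); the boundary values 3 and 5 fall in the upper tier, 1000 in
``5-1000`` since ``>1000`` is strict.

PCA runs on log10, autoscaled intensities of the biological samples; QC
samples are passively projected so they can be checked to sit at the centre
of the score plot.  Groups come from k-means on the leading score columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import DomainError, InsufficientDataError, ParameterError
from .tables import AbundanceMatrix

__all__ = [
    "variability",
    "variability_tier",
    "variability_table",
    "VariabilityRecord",
    "PCAResult",
    "run_pca",
    "GroupAssignment",
    "assign_groups",
]

TIER_LABELS = ("<3", "3-5", "5-1000", ">1000")


def variability(values) -> float:
    """Fold range ``max(values) / min(values)`` of a strictly positive vector."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError("variability needs at least 2 observed values")
    if np.any(arr <= 0):
        raise DomainError("variability is defined for strictly positive intensities")
    return float(arr.max() / arr.min())


def variability_tier(v: float) -> str:
    """Tier label for a fold range (see module docstring for boundary rules)."""
    if v < 1:
        raise DomainError("fold range cannot be below 1")
    if v < 3:
        return "<3"
    if v < 5:
        return "3-5"
    if v <= 1000:
        return "5-1000"
    return ">1000"


@dataclass(frozen=True)
class VariabilityRecord:
    feature_id: str
    max_intensity: float
    min_intensity: float
    variability: float
    tier: str
    over_3000: bool


def variability_table(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-feature fold ranges over biological samples, highest first.

    QC injections are excluded.  Ties in the fold range are broken by
    feature id so the ordering is deterministic.  Columns:
    ``feature_id, max_intensity, min_intensity, variability, tier, over_3000``.
    """
    bio = matrix.biological()
    rows = []
    for fid in bio.columns:
        col = bio[fid].to_numpy()
        v = variability(col)
        finite = col[np.isfinite(col)]
        rows.append(
            {
                "feature_id": fid,
                "max_intensity": float(finite.max()),
                "min_intensity": float(finite.min()),
                "variability": v,
                "tier": variability_tier(v),
                "over_3000": bool(v > 3000),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["variability", "feature_id"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores, loadings and explained-variance percentages.

    ``scores`` covers every sample (QC rows are projections, not part of the
    fit); ``fitted_samples`` lists the biological samples the decomposition
    was computed on.  ``variance_pct`` entries are non-increasing and sum to
    at most 100.
    """

    scores: pd.DataFrame  # samples x PC1..PCk
    loadings: pd.DataFrame  # features x PC1..PCk (unit-norm eigenvectors)
    variance_pct: np.ndarray
    fitted_samples: list[str]
    scaling: str
    mean_: np.ndarray
    scale_: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.variance_pct)


def run_pca(
    matrix: AbundanceMatrix,
    scaling: str = "autoscale",
    n_components: int | None = None,
) -> PCAResult:
    """PCA of log10 intensities, fitted on biological samples.

    ``autoscale`` (default) centres and scales every feature to unit
    variance; ``center-only`` just centres.  Constant features are dropped
    with a warning under autoscale (their scaled value is undefined).  QC
    samples are passively projected into the fitted space.
    """
    if scaling not in ("autoscale", "center-only"):
        raise ParameterError(f"scaling must be autoscale or center-only, got {scaling!r}")
    bio = matrix.biological()
    if bio.shape[0] < 3:
        raise InsufficientDataError("PCA needs at least 3 biological samples")
    if bio.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 features")
    log_bio = np.log10(bio)
    sd = log_bio.std(axis=0, ddof=1)
    features = list(log_bio.columns)
    if scaling == "autoscale":
        const = sd.index[sd == 0].tolist()
        if const:
            warnings.warn(f"dropping constant feature(s) from PCA: {const}", stacklevel=2)
            features = [f for f in features if f not in const]
            if len(features) < 2:
                raise InsufficientDataError("fewer than 2 non-constant features")
    X = log_bio[features].to_numpy()
    mean = X.mean(axis=0)
    scale = sd[features].to_numpy() if scaling == "autoscale" else np.ones(len(features))
    Xs = (X - mean) / scale

    max_comp = min(X.shape[0] - 1, len(features))
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores_bio = pca.fit_transform(Xs)

    all_log = np.log10(matrix.values[features]).to_numpy()
    scores_all = ((all_log - mean) / scale) @ pca.components_.T
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(scores_all, index=matrix.values.index, columns=cols)
    scores.loc[bio.index] = scores_bio  # identical up to float noise; keep fit values
    loadings = pd.DataFrame(pca.components_.T, index=features, columns=cols)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_pct=100.0 * pca.explained_variance_ratio_,
        fitted_samples=list(bio.index),
        scaling=scaling,
        mean_=mean,
        scale_=scale,
    )


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    """Sample -> group labels (1..k), k-means metadata attached."""

    labels: pd.Series  # biological sample id -> int 1..k
    k: int
    n_components: int
    seed: int

    def pairs(self) -> list[tuple[int, int]]:
        groups = sorted(set(self.labels))
        return [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]


def assign_groups(
    pca: PCAResult, k: int = 3, n_components: int = 2, seed: int = 0
) -> GroupAssignment:
    """k-means on the leading PCA score columns of the biological samples.

    25 restarts at a fixed seed; clusters are renumbered 1..k by descending
    size (ties by their lexicographically smallest member) so labels are
    deterministic and comparable across runs.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    if n_components > pca.n_components:
        raise ParameterError(
            f"n_components={n_components} exceeds available components ({pca.n_components})"
        )
    scores = pca.scores.loc[pca.fitted_samples].iloc[:, :n_components]
    if k > scores.shape[0]:
        raise ParameterError(f"k={k} exceeds the number of samples ({scores.shape[0]})")
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    raw = km.fit_predict(scores.to_numpy())
    order = sorted(
        range(k),
        key=lambda c: (-(raw == c).sum(), min(scores.index[raw == c])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=scores.index, name="group")
    return GroupAssignment(labels=labels, k=k, n_components=n_components, seed=seed)
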
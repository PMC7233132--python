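"""Tissue-region discovery from neighborhood composition.

Neighborhood feature rows (per-phenotype counts, optionally per-channel MFI
sums) are normalized, clustered with a one-dimensional self-organizing map
(a chain of NR "neurons" that adapt toward the data), and the number of
regions NR is chosen automatically as the minimum of the Davies-Bouldin
index over a sweep of candidate cluster counts.  Regions can then be
manually annotated or merged under composite labels (e.g. ``"TZ+IFZ"``).

Feature modes
-------------
raw
    Per-phenotype cell counts, untouched.
composition
    Each row divided by its total cell count; all-zero (empty) rows stay
    zero and are kept — background neighborhoods legitimately form their
    own region.
standardized
    Each column z-scored (count minus mean, divided by SD) across all
    neighborhoods of the training set; statistics are frozen on the model
    so held-out samples can be projected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neighborhoods import NeighborhoodSet

__all__ = [
    "FeatureMatrix",
    "RegionModel",
    "RegionAssignment",
    "build_features",
    "davies_bouldin",
    "train_som",
    "select_region_count",
    "assign_regions",
    "annotate_regions",
]

logger = logging.getLogger(__name__)

SOM_EPOCHS = 200
SOM_DECAY_EPOCHS = 100


@dataclass
class FeatureMatrix:
    """Neighborhood-by-feature matrix with its normalization mode.

    For ``standardized`` mode, ``column_means``/``column_sds`` hold the
    frozen training statistics used to project new data.
    """

    values: np.ndarray
    mode: str
    feature_names: tuple[str, ...]
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class RegionModel:
    """A trained region model: chosen NR, SOM prototypes, and the DB curve."""

    nr: int
    prototypes: np.ndarray
    db_curve: dict[int, float]
    mode: str
    seed: int
    feature_names: tuple[str, ...] = ()


@dataclass
class RegionAssignment:
    """Region index (1..NR) per neighborhood, plus optional annotations.

    ``neighborhood_ids`` preserves the original row indices when the
    clustered set is a subset (e.g. empty neighborhoods dropped before
    composition clustering); ``None`` means 0..n-1.
    """

    region: np.ndarray
    annotations: dict[int, str] = field(default_factory=dict)
    neighborhood_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=int)
        if self.neighborhood_ids is not None:
            self.neighborhood_ids = np.asarray(self.neighborhood_ids, dtype=int)
            if len(self.neighborhood_ids) != len(self.region):
                raise ValueError("neighborhood_ids length must match region labels")
        if len(self.region) and self.region.min() < 1:
            raise ValueError("region indices are 1-based")
        unknown = set(self.annotations) - set(np.unique(self.region).tolist())
        if unknown:
            raise ValueError(f"annotation keys for unobserved regions: {sorted(unknown)}")

    @property
    def regions(self) -> np.ndarray:
        return np.unique(self.region)

    def labels(self) -> np.ndarray:
        """Composite labels where annotated, else the region index as text."""
        return np.array([self.annotations.get(int(r), str(int(r))) for r in self.region])


def build_features(
    nbhd: NeighborhoodSet,
    mode: str = "composition",
    include_mfi: bool = False,
) -> FeatureMatrix:
    """Assemble and normalize the clustering features of a neighborhood set.

    ``include_mfi`` appends the per-channel summed-MFI columns to the
    per-phenotype counts before normalization (off by default; counts alone
    are the standard region features).
    """
    if nbhd.n == 0:
        raise ValueError("neighborhood set is empty")
    blocks = [nbhd.counts.to_numpy(dtype=float)]
    names = list(map(str, nbhd.counts.columns))
    if include_mfi and len(nbhd.mfi_sums.columns):
        blocks.append(nbhd.mfi_sums.to_numpy(dtype=float))
        names += list(map(str, nbhd.mfi_sums.columns))
    X = np.hstack(blocks)

    means = sds = None
    if mode == "raw":
        pass
    elif mode == "composition":
        totals = X.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(totals > 0, X / np.where(totals > 0, totals, 1.0), 0.0)
    elif mode == "standardized":
        means = X.mean(axis=0)
        # sample SD (N-1 normalization), the flow-cytometry convention
        sds = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
        degenerate = sds == 0
        if degenerate.any():
            logger.warning(
                "zero-variance feature columns set to 0 under standardization: %s",
                [names[i] for i in np.flatnonzero(degenerate)],
            )
        X = np.where(degenerate, 0.0, (X - means) / np.where(degenerate, 1.0, sds))
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    return FeatureMatrix(X, mode, tuple(names), column_means=means, column_sds=sds)


def project_features(features: FeatureMatrix, nbhd: NeighborhoodSet, include_mfi: bool = False) -> FeatureMatrix:
    """Project a held-out neighborhood set with frozen training statistics."""
    new = build_features(nbhd, mode="raw", include_mfi=include_mfi)
    if tuple(new.feature_names) != tuple(features.feature_names):
        raise ValueError("feature names differ between training and projection sets")
    X = new.values
    if features.mode == "composition":
        totals = X.sum(axis=1, keepdims=True)
        X = np.where(totals > 0, X / np.where(totals > 0, totals, 1.0), 0.0)
    elif features.mode == "standardized":
        degenerate = features.column_sds == 0
        X = np.where(
            degenerate, 0.0, (X - features.column_means) / np.where(degenerate, 1.0, features.column_sds)
        )
    return FeatureMatrix(X, features.mode, features.feature_names,
                         column_means=features.column_means, column_sds=features.column_sds)


def davies_bouldin(values: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst ratio of summed
    within-cluster scatters to between-centroid distance (lower is better).

    Scatter s_i is the mean Euclidean distance of cluster members to their
    centroid; separation d_ij is the Euclidean distance between centroids.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin requires >= 2 clusters")
    centroids = np.empty((k, X.shape[1]))
    scatter = np.empty(k)
    for i, lab in enumerate(uniq):
        members = X[labels == lab]
        if len(members) == 0:
            raise ValueError(f"cluster {lab!r} is empty")
        centroids[i] = members.mean(axis=0)
        scatter[i] = np.linalg.norm(members - centroids[i], axis=1).mean()
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / d
    np.fill_diagonal(ratio, -np.inf)
    # coincident centroids with zero scatter contribute 0/0 -> treat as 0
    ratio = np.where(np.isnan(ratio), 0.0, ratio)
    return float(np.max(ratio, axis=1).mean())


def _som_labels(X: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Nearest-prototype labels; ties break to the lowest prototype index."""
    d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def train_som(
    features: FeatureMatrix | np.ndarray,
    nr: int,
    seed: int,
    epochs: int = SOM_EPOCHS,
) -> tuple[np.ndarray, np.ndarray]:
    """Train a 1-D chain SOM of ``nr`` nodes and label each row.

    Batch training: every epoch each row is assigned to its best-matching
    unit (BMU), and each prototype moves to the weighted mean of all rows,
    weighted by a Gaussian kernel over chain distance between the prototype
    and the row's BMU.  The kernel radius decays linearly from ceil(nr/3)
    to 0 over the first half of training, after which updates are
    nearest-only (Lloyd steps).  Prototypes are initialized by sampling
    ``nr`` distinct data rows with ``seed``, so the result is deterministic
    given (data, nr, seed).

    Returns ``(prototypes, labels)`` with labels in ``0..nr-1``.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    n = len(X)
    if nr < 2:
        raise ValueError("nr must be >= 2")
    if nr > n:
        raise ValueError(f"nr={nr} exceeds the number of rows ({n})")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    rng = np.random.default_rng(seed)
    uniq = np.unique(X, axis=0)
    if len(uniq) >= nr:
        prototypes = uniq[rng.choice(len(uniq), size=nr, replace=False)].astype(float)
    else:
        prototypes = X[rng.choice(n, size=nr, replace=False)].astype(float)

    radius0 = math.ceil(nr / 3)
    chain = np.arange(nr)
    for epoch in range(epochs):
        if epoch < SOM_DECAY_EPOCHS:
            radius = radius0 * (1.0 - epoch / SOM_DECAY_EPOCHS)
        else:
            radius = 0.0
        bmu = _som_labels(X, prototypes)
        if radius > 0:
            # Gaussian kernel over chain distance to each row's BMU
            chain_d = chain[:, None] - bmu[None, :]
            weights = np.exp(-(chain_d**2) / (2.0 * radius**2))
        else:
            weights = (chain[:, None] == bmu[None, :]).astype(float)
        weight_sums = weights.sum(axis=1)
        occupied = weight_sums > 0
        prototypes[occupied] = (weights[occupied] @ X) / weight_sums[occupied, None]
    labels = _som_labels(X, prototypes)
    return prototypes, labels


def select_region_count(
    features: FeatureMatrix,
    sweep: tuple[int, int] = (2, 10),
    seed: int = 0,
    epochs: int = SOM_EPOCHS,
) -> RegionModel:
    """Sweep candidate region counts and pick NR at the DB minimum.

    For each candidate k a SOM is trained (same seed) and the DB index of
    its labels recorded; NR is the k minimizing DB, ties broken toward the
    smallest k.  A SOM can leave a prototype unused, in which case DB is
    evaluated over the occupied clusters only.
    """
    n = features.n
    if n < 4:
        raise ValueError("need at least 4 neighborhoods to select a region count")
    lo, hi = sweep
    hi = min(hi, 50, n - 1)
    if not (2 <= lo <= hi):
        raise ValueError(f"invalid sweep range ({lo}, {hi}) for n={n}")

    db_curve: dict[int, float] = {}
    for k in range(lo, hi + 1):
        _, labels = train_som(features, k, seed, epochs=epochs)
        if len(np.unique(labels)) < 2:
            db_curve[k] = float("inf")
        else:
            db_curve[k] = davies_bouldin(features.values, labels)
    nr = min(db_curve, key=lambda k: (db_curve[k], k))
    prototypes, _ = train_som(features, nr, seed, epochs=epochs)
    return RegionModel(
        nr=nr,
        prototypes=prototypes,
        db_curve=db_curve,
        mode=features.mode,
        seed=seed,
        feature_names=features.feature_names,
    )


def assign_regions(model: RegionModel, features: FeatureMatrix) -> RegionAssignment:
    """Label every neighborhood with its nearest prototype (1-based)."""
    if features.values.shape[1] != model.prototypes.shape[1]:
        raise ValueError("feature dimensionality does not match the model")
    labels = _som_labels(features.values, model.prototypes)
    return RegionAssignment(region=labels + 1)


def annotate_regions(assignment: RegionAssignment, mapping: dict[int, str]) -> RegionAssignment:
    """Attach composite labels to regions (merging happens at the label level).

    Mapping keys must be observed region indices; the underlying region
    indices are unchanged, so annotation is non-destructive.
    """
    observed = set(assignment.regions.tolist())
    unknown = set(mapping) - observed
    if unknown:
        raise ValueError(f"unknown region indices in annotation map: {sorted(unknown)}")
    merged = dict(assignment.annotations)
    merged.update({int(k): str(v) for k, v in mapping.items()})
    return RegionAssignment(
        region=assignment.region.copy(),
        annotations=merged,
        neighborhood_ids=None
        if assignment.neighborhood_ids is None
        else assignment.neighborhood_ids.copy(),
    )
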
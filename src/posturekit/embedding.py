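"""Pairwise Riemannian distance matrices and 2-D embeddings.

A dataset's trials can be inspected as points on the SPD manifold: the full
pairwise affine-invariant distance matrix feeds t-SNE (metric precomputed) to
produce a 2-D map in which task clusters -- and, within them, condition
trends -- become visible.  Embedding coordinates are not contractual; only
label-based statistics (e.g. silhouette) should be asserted on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.manifold import TSNE

from posturekit.datamodel_io import Dataset, Device, JointSubset, Trial
from posturekit.spd_geometry import (
    DEFAULT_SHRINKAGE,
    covariance_for_trial,
    riemannian_distance,
)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with its trial keys."""

    labels: tuple[tuple, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 1e-12 or v.min() < 0:
            raise ValueError("distances must be nonnegative with zero diagonal")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


def pairwise_distances(
    dataset: Dataset | Sequence[Trial],
    subset: JointSubset | None = JointSubset.UPPER_16,
    shrinkage: float = DEFAULT_SHRINKAGE,
    device: Device | str = Device.MK2,
) -> DistanceMatrix:
    """Riemannian distance between every pair of same-device trials."""
    device = Device(device)
    trials = [t for t in dataset if t.device is device]
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    if device is Device.KFP:
        subset = None
    covs = [covariance_for_trial(t, subset, shrinkage) for t in trials]
    k = len(covs)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dm[i, j] = dm[j, i] = riemannian_distance(covs[i], covs[j])
    return DistanceMatrix(labels=tuple(t.key for t in trials), values=dm)


def embed_2d(
    dm: DistanceMatrix,
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """t-SNE 2-D embedding of a precomputed Riemannian distance matrix.

    Perplexity is capped at (K-1)/3; if even the capped value is below 1 the
    matrix is too small to embed and an input error is raised.  Deterministic
    under a fixed seed.
    """
    k = len(dm)
    effective = min(float(perplexity), (k - 1) / 3.0)
    if effective < 1.0:
        raise ValueError(
            f"{k} points are too few for perplexity {perplexity} "
            "(need K > 3*perplexity)"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        perplexity=effective,
        init="random",
        random_state=seed,
    )
    return tsne.fit_transform(dm.values)
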
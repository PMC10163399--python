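"""Herb attribute vectors, 2D embedding and pairwise distances.

Each herb is encoded as a 23-dimensional binary vector **P** (Siqi ‖ Wuwei ‖
Guijing, fixed schema order) and projected to a 2D point **p**.  All
similarity computations downstream — the greedy layout ordering and the
color interpolation — use the Euclidean distance d(u, v) = ‖p_u − p_v‖
between *projected* points, not the raw binary vectors: distances in the
projected plane are easier to read off the visualization and produce less
clutter than raw Hamming-like distances in 23 dimensions.

The default projector is UMAP (nonlinear, structure-preserving, fast at
this scale).  A deterministic linear fallback — the first two principal
axes with a fixed sign convention — is provided because the nonlinear
method's exact coordinates are library-version dependent; oracle tests and
any workflow that needs bit-stable coordinates across environments can
select it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .types import AttributeRecord, N_ATTRIBUTES


@dataclass
class EmbeddingConfig:
    """Projection settings.

    method: ``"umap"`` (default) or ``"pca"`` (deterministic linear
    fallback).  ``n_neighbors``/``min_dist`` apply to UMAP only; defaults
    are chosen for herb sets of roughly 30–80 points.
    """

    method: str = "umap"
    n_neighbors: int = 5
    min_dist: float = 0.3
    seed: int = 42


@dataclass
class Embedding:
    """2D coordinates for a set of herbs, in input order."""

    herb_ids: list[str]
    coords: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.herb_ids), 2):
            raise ValueError("coords must be (n_herbs, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")

    def point(self, herb_id: str) -> np.ndarray:
        return self.coords[self.herb_ids.index(herb_id)]

    def __len__(self) -> int:
        return len(self.herb_ids)


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix over herb ids."""

    herb_ids: list[str]
    values: np.ndarray  # (n, n)

    def __post_init__(self) -> None:
        self._index = {h: i for i, h in enumerate(self.herb_ids)}

    def d(self, u: str, v: str) -> float:
        return float(self.values[self._index[u], self._index[v]])

    def __contains__(self, herb_id: str) -> bool:
        return herb_id in self._index


def encode(records: list[AttributeRecord]) -> np.ndarray:
    """Stack attribute records into an (n, 23) binary matrix, schema order."""
    if not records:
        return np.zeros((0, N_ATTRIBUTES))
    return np.vstack([r.vector() for r in records])


def _pca_2d(X: np.ndarray) -> np.ndarray:
    """First two principal axes with a deterministic sign convention.

    Signs are fixed so each axis's largest-magnitude loading is positive,
    making the projection reproducible across BLAS/LAPACK builds.
    """
    Xc = X - X.mean(axis=0)
    # full SVD is cheap at <=23 columns
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = np.zeros((X.shape[0], 2))
    for k in range(min(2, Vt.shape[0])):
        v = Vt[k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, k] = Xc @ v
    return coords


def embed(
    records: list[AttributeRecord],
    config: EmbeddingConfig | None = None,
) -> Embedding:
    """Project herb attribute vectors to 2D.

    Deterministic for fixed (records, config): UMAP runs with
    ``random_state=config.seed``; the PCA fallback is fully deterministic.

    Raises
    ------
    ValueError
        If fewer herbs than the nonlinear method needs (< 4); the error
        advises the ``pca`` fallback, which works from n = 1.
    """
    config = config or EmbeddingConfig()
    X = encode(records)
    n = X.shape[0]
    herb_ids = [r.herb_id for r in records]
    if config.method == "pca":
        if n == 0:
            return Embedding(herb_ids, np.zeros((0, 2)))
        return Embedding(herb_ids, _pca_2d(X))
    if config.method != "umap":
        raise ValueError(f"unknown embedding method {config.method!r}")
    if n < 4:
        raise ValueError(
            f"UMAP needs at least 4 herbs (got {n}); use the deterministic "
            "fallback projector (method='pca') for tiny inputs"
        )
    import umap  # deferred: numba-backed import is slow

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(config.n_neighbors, n - 1),
        min_dist=config.min_dist,
        metric="euclidean",
        random_state=config.seed,
    )
    coords = reducer.fit_transform(X)
    return Embedding(herb_ids, np.asarray(coords, dtype=float))


def pairwise_distance(embedding: Embedding) -> DistanceMatrix:
    """All-pairs Euclidean distances between embedded points."""
    n = len(embedding)
    if n == 0:
        return DistanceMatrix([], np.zeros((0, 0)))
    values = squareform(pdist(embedding.coords, metric="euclidean"))
    return DistanceMatrix(list(embedding.herb_ids), values)


def distances_to(embedding: Embedding, herb_id: str) -> np.ndarray:
    """Distances from one herb's point to every embedded point."""
    p = embedding.point(herb_id)[None, :]
    return cdist(p, embedding.coords)[0]
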
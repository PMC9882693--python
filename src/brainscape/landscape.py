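"""Embedding-space landscape: dimensionality reduction and neighbor queries.

A :class:`Landscape` holds 2D/3D coordinates per sample plus the method,
seed and an input digest, so any downstream annotation can be traced back
to the exact matrix it was computed from.

PCA is computed internally by exact SVD on gene-centered data and is the
exactly-testable reducer; UMAP and t-SNE are delegated to their reference
implementations through a pluggable interface with the seed forwarded.
Neighbor queries are exact brute-force Euclidean scans — landscape sizes
here are thousands of samples, where an index buys nothing and exactness
makes the radius/tie semantics testable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .matrix import ExpressionMatrix

METHODS = ("pca", "umap", "tsne")


def matrix_digest(m: ExpressionMatrix) -> str:
    """SHA-256 over gene order, sample order and values."""
    h = hashlib.sha256()
    h.update("\x1f".join(m.gene_ids).encode())
    h.update("\x1f".join(m.sample_ids).encode())
    h.update(np.ascontiguousarray(m.values.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()


@dataclass
class Landscape:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x d
    method: str
    seed: int
    provenance: str  # digest of the input matrix

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.sample_ids):
            raise ValueError("one coordinate row per sample required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]

    def coords_of(self, sample_id: str) -> np.ndarray:
        try:
            return self.coordinates[self._index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def diameter(self) -> float:
        """Largest pairwise distance (exact)."""
        from scipy.spatial.distance import pdist

        if len(self.sample_ids) < 2:
            return 0.0
        return float(pdist(self.coordinates).max())

    def to_frame(self) -> pd.DataFrame:
        cols = ["x", "y", "z"][: self.d]
        df = pd.DataFrame(self.coordinates, columns=cols,
                          index=pd.Index(self.sample_ids, name="sample_id"))
        return df


def _pca_coords(x: np.ndarray, d: int) -> np.ndarray:
    # exact SVD on gene-centered data; sign fixed so the largest-|loading|
    # coordinate in each component is positive (determinism across BLAS)
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u[:, :d] * s[:d]
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def _umap_coords(x: np.ndarray, d: int, seed: int, params: dict) -> np.ndarray:
    import umap

    reducer = umap.UMAP(n_components=d, random_state=seed, **params)
    return np.asarray(reducer.fit_transform(x), dtype=float)


def _tsne_coords(x: np.ndarray, d: int, seed: int, params: dict) -> np.ndarray:
    from sklearn.manifold import TSNE

    kwargs = {"init": "pca", "perplexity": min(30.0, (x.shape[0] - 1) / 3.0)}
    kwargs.update(params)
    reducer = TSNE(n_components=d, random_state=seed, **kwargs)
    return np.asarray(reducer.fit_transform(x), dtype=float)


#: Pluggable nonlinear reducers: name -> f(samples x genes, d, seed, params).
REDUCERS: dict[str, Callable[..., np.ndarray]] = {
    "umap": _umap_coords,
    "tsne": _tsne_coords,
}


def embed(
    m: ExpressionMatrix,
    method: str = "umap",
    d: int = 2,
    seed: int = 0,
    params: dict | None = None,
) -> Landscape:
    """Embed corrected expression into ``d`` dimensions.

    ``m`` is samples-in-columns; the reducer sees a samples x genes matrix.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if m.n_samples < d + 1:
        raise ValueError(f"need at least {d + 1} samples for a {d}D embedding")
    params = dict(params or {})
    x = m.values.to_numpy(dtype=float).T
    if method == "pca":
        dd = min(d, min(x.shape[0] - 1, x.shape[1]))
        coords = np.zeros((x.shape[0], d))
        coords[:, :dd] = _pca_coords(x, dd)
    else:
        coords = REDUCERS[method](x, d, seed, params)
    return Landscape(
        sample_ids=m.sample_ids,
        coordinates=coords,
        method=method,
        seed=seed,
        provenance=matrix_digest(m),
    )


def pca_full(m: ExpressionMatrix) -> np.ndarray:
    """All-component PCA scores (samples x min(n-1, genes)); distance-preserving."""
    x = m.values.to_numpy(dtype=float).T
    d = min(x.shape[0] - 1, x.shape[1])
    return _pca_coords(x, d)


def neighbors_within_radius(
    L: Landscape,
    query_sample: str,
    radius: float,
    eligibility: Callable[[str], bool] | None = None,
) -> list[tuple[str, float]]:
    """All eligible samples within ``radius`` (inclusive) of the query.

    Euclidean distance in embedding space; the query itself is excluded;
    results sorted by (distance, sample_id) so ties are deterministic.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = L.coords_of(query_sample)
    dists = np.linalg.norm(L.coordinates - q, axis=1)
    out = []
    for sid, dist in zip(L.sample_ids, dists):
        if sid == query_sample:
            continue
        if eligibility is not None and not eligibility(sid):
            continue
        if dist <= radius:
            out.append((sid, float(dist)))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def k_nearest(
    L: Landscape,
    query_sample: str,
    k: int,
    candidates: Iterable[str] | None = None,
) -> list[tuple[str, float]]:
    """The k nearest candidates (query excluded), ties by sample id."""
    if k <= 0:
        raise ValueError("k must be positive")
    q = L.coords_of(query_sample)
    pool = L.sample_ids if candidates is None else list(candidates)
    scored = []
    for sid in pool:
        if sid == query_sample:
            continue
        scored.append((sid, float(np.linalg.norm(L.coords_of(sid) - q))))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored[:k]


def classify_by_neighbors(
    L: Landscape,
    labels: pd.Series,
    targets: Iterable[str],
    k: int = 15,
) -> pd.DataFrame:
    """Label unlabeled samples by majority vote of their k nearest labeled samples.

    Ties are broken by summed inverse distance of the tied labels' voters,
    then lexicographically by label.  Returns a frame indexed by target with
    ``predicted`` plus one vote-fraction column per label level.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    labels = labels.dropna()
    labeled = [s for s in L.sample_ids if s in set(labels.index)]
    if len(labeled) < k:
        raise ValueError(f"need at least k={k} labeled samples, have {len(labeled)}")
    levels = sorted(labels.unique())
    rows = {}
    for t in targets:
        nn = k_nearest(L, t, k, candidates=labeled)
        votes: dict[str, int] = {lv: 0 for lv in levels}
        inv: dict[str, float] = {lv: 0.0 for lv in levels}
        for sid, dist in nn:
            lab = labels[sid]
            votes[lab] += 1
            inv[lab] += 1.0 / max(dist, 1e-12)
        best = max(votes.values())
        tied = [lv for lv in levels if votes[lv] == best]
        if len(tied) > 1:
            top_inv = max(inv[lv] for lv in tied)
            tied = [lv for lv in tied if inv[lv] == top_inv]
        predicted = sorted(tied)[0]
        row = {"predicted": predicted}
        for lv in levels:
            row[f"frac_{lv}"] = votes[lv] / k
        rows[t] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def cluster_concordance(L: Landscape, labels: pd.Series, seed: int = 0) -> dict[str, float]:
    """Quantify cluster separation of the labels on the landscape.

    Mean silhouette of the labels plus the adjusted Rand index between the
    labels and a k-means partition with k = number of label levels.  Raises
    on degenerate input (a single label level, or all coordinates identical).
    """
    y = pd.Series(labels).loc[L.sample_ids]
    levels = sorted(y.unique())
    if len(levels) < 2:
        raise ValueError("need at least two label levels")
    if np.allclose(L.coordinates, L.coordinates[0]):
        raise ValueError("degenerate landscape: all coordinates identical")
    sil = float(silhouette_score(L.coordinates, y.to_numpy()))
    km = KMeans(n_clusters=len(levels), n_init=10, random_state=seed)
    part = km.fit_predict(L.coordinates)
    ari = float(adjusted_rand_score(y.to_numpy(), part))
    return {"silhouette": sil, "ari": ari, "n_levels": float(len(levels))}
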
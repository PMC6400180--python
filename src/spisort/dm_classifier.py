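"""Diffusion-map embedding and nearest-centroid classification.

The affinity A_ij = exp(-d(x_i, x_j)^2 / eps) is row-normalized into a
diffusion operator P = D^-1 A (computed through its symmetric conjugate
D^-1/2 A D^-1/2 for numerical stability); the eigenvectors of P with the
largest non-trivial eigenvalues are the embedding coordinates.  Labelled
seeds define class centroids in diffusion space, and each pattern's score is
the softmin of its squared centroid distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from sklearn.neighbors import NearestNeighbors

from .containers import LabelSet
from .preprocess import FeatureImage

__all__ = [
    "DiffusionEmbedding",
    "build_affinity",
    "diffusion_embedding",
    "classify_dm",
]

#: above this many patterns the dense eigensolver gives way to ARPACK
_DENSE_LIMIT = 2000


@dataclass
class DiffusionEmbedding:
    """Spectral embedding of the diffusion operator.

    ``coordinates[i]`` is pattern i's vector of the top ``m`` non-trivial
    eigenvector entries, scaled by eigenvalue**t.
    """

    eigenvalues: np.ndarray  # descending, leading value 1
    coordinates: np.ndarray  # (n, m)
    kernel_scale: float
    diffusion_time: float = 1.0
    ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(np.abs(self.eigenvalues) > 1 + 1e-8):
            raise ValueError("diffusion spectrum must lie in [-1, 1]")
        if abs(self.eigenvalues[0] - 1.0) > 1e-6:
            raise ValueError("leading eigenvalue must be 1")


def _as_matrix(features):
    if isinstance(features, np.ndarray):
        return (features.reshape(len(features), -1).astype(float),
                np.arange(len(features)).astype(object))
    x = np.stack([np.ravel(f.values) for f in features]).astype(float)
    ids = np.array([f.pattern_id for f in features], dtype=object)
    return x, ids


def _auto_scale(x: np.ndarray, k: int = 10) -> float:
    """Median squared k-NN distance — a robust kernel bandwidth."""
    k = min(k, len(x) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    med = float(np.median(dist[:, 1:] ** 2))
    return med if med > 0 else 1.0


def build_affinity(features, kernel_scale: Union[float, str] = "auto"
                   ) -> np.ndarray:
    """Dense Gaussian affinity matrix with unit diagonal."""
    x, _ = _as_matrix(features)
    if len(x) < 3:
        raise ValueError("need at least 3 patterns")
    eps = _auto_scale(x) if kernel_scale == "auto" else float(kernel_scale)
    if eps <= 0:
        raise ValueError("kernel_scale must be positive")
    sq = np.sum(x ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    a = np.exp(-d2 / eps)
    np.fill_diagonal(a, 1.0)
    return 0.5 * (a + a.T)


def diffusion_embedding(affinity: np.ndarray, m: int = 5,
                        diffusion_time: float = 1.0,
                        ids: Optional[np.ndarray] = None,
                        kernel_scale: float = np.nan) -> DiffusionEmbedding:
    """Top-m non-trivial eigenvectors of the row-normalized kernel.

    Eigendecomposition runs on the symmetric conjugate
    S = D^-1/2 A D^-1/2 (same spectrum as P = D^-1 A); right eigenvectors of
    P are recovered as D^-1/2 v.  The trivial constant eigenvector
    (eigenvalue 1) is dropped.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    a = np.asarray(affinity, dtype=float)
    n = a.shape[0]
    if m + 1 > n:
        raise ValueError("m exceeds the available spectrum")
    d = a.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("kernel has an isolated vertex")
    dis = 1.0 / np.sqrt(d)
    s = dis[:, None] * a * dis[None, :]
    s = 0.5 * (s + s.T)
    if n <= _DENSE_LIMIT:
        vals, vecs = scipy.linalg.eigh(s)
        vals, vecs = vals[::-1], vecs[:, ::-1]
    else:
        vals, vecs = scipy.sparse.linalg.eigsh(s, k=m + 1, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, -1.0, 1.0)
    phi = dis[:, None] * vecs  # right eigenvectors of P
    # normalize sign and scale for reproducibility
    coords = phi[:, 1:m + 1]
    lam = vals[1:m + 1]
    coords = coords / np.linalg.norm(coords, axis=0, keepdims=True)
    signs = np.sign(coords[np.argmax(np.abs(coords), axis=0),
                           np.arange(coords.shape[1])])
    coords = coords * signs
    coords = coords * np.sign(lam) * np.abs(lam) ** diffusion_time
    return DiffusionEmbedding(eigenvalues=vals, coordinates=coords,
                              kernel_scale=kernel_scale,
                              diffusion_time=diffusion_time, ids=ids)


def classify_dm(embedding: DiffusionEmbedding, seed_labels: Mapping,
                theta: float = 0.5) -> LabelSet:
    """Nearest-centroid labeling in diffusion coordinates.

    score(x) = d0^2 / (d0^2 + d1^2) where d_c is the distance to the class-c
    seed centroid, so a pattern on the class-1 centroid scores 1 and an
    equidistant pattern scores exactly 0.5 (class 0 under the strict
    threshold).
    """
    coords = embedding.coordinates
    n = len(coords)
    ids = (embedding.ids if embedding.ids is not None
           else np.arange(n).astype(object))
    id_to_idx = {pid: i for i, pid in enumerate(ids)}
    idx, lab = [], []
    for key, val in seed_labels.items():
        if key in id_to_idx:
            idx.append(id_to_idx[key])
        elif isinstance(key, (int, np.integer)) and 0 <= key < n:
            idx.append(int(key))
        else:
            raise KeyError(f"seed id {key!r} not among the patterns")
        lab.append(int(val))
    idx = np.asarray(idx)
    lab = np.asarray(lab)
    if not (np.any(lab == 0) and np.any(lab == 1)):
        raise ValueError("need at least one seed of each class")
    c0 = coords[idx[lab == 0]].mean(axis=0)
    c1 = coords[idx[lab == 1]].mean(axis=0)
    d0 = np.sum((coords - c0) ** 2, axis=1)
    d1 = np.sum((coords - c1) ** 2, axis=1)
    tot = d0 + d1
    scores = np.where(tot > 0, d0 / np.where(tot > 0, tot, 1.0), 0.5)
    return LabelSet(ids=ids, scores=scores, threshold=theta)
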
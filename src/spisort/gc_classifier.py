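"""Semi-supervised graph-cut classification.

Patterns are vertices of a sparse k-NN graph with locally scaled RBF edge
weights w_ij = exp(-d(x_i, x_j)^2 / (sigma_i sigma_j)); a labelled seed set
induces a per-vertex class prior (the region force), and the labeling
u in [0,1]^V minimizes the convex Potts-relaxation functional

    E(u) = sum_x [ cost_1(x) u(x) + cost_0(x) (1 - u(x)) ]
         + lambda * sum_(i,j) w_ij |u_i - u_j|,

the unary-plus-weighted-total-variation form of a min-cut problem.  The
minimization is carried out by a Chambolle-Pock-style primal-dual (max-flow)
iteration, and the final labeling thresholds u at 0.5.

The region-force construction (a similarity-weighted vote of the seeds) and
the sigma pairing are reconstructions of choices the method family leaves
open; both are documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import LabelSet
from .preprocess import FeatureImage

__all__ = [
    "SimilarityGraph",
    "RegionForce",
    "LabelingField",
    "build_similarity_graph",
    "compute_region_force",
    "solve_potts_primal_dual",
    "potts_energy",
    "classify_gc",
]

log = logging.getLogger(__name__)

_EPS_PRIOR = 1e-6


@dataclass
class SimilarityGraph:
    """Sparse symmetric k-NN similarity graph over patterns."""

    weights: sp.csr_matrix  # symmetric, zero diagonal, entries in (0, 1]
    neighbor_count: int
    sigma: np.ndarray  # per-vertex local distance scale
    points: np.ndarray  # flattened feature vectors (n, d)
    ids: np.ndarray = None

    def __post_init__(self) -> None:
        w = self.weights
        if (abs(w - w.T) > 1e-12 * max(1.0, abs(w).max())).nnz:
            raise ValueError("similarity graph must be symmetric")
        if w.diagonal().any():
            raise ValueError("no self-loops allowed")
        data = w.data
        if len(data) and (not np.all(np.isfinite(data)) or data.min() <= 0
                          or data.max() > 1 + 1e-12):
            raise ValueError("weights must be finite and in (0, 1]")
        deg = np.diff(w.indptr)
        if np.any(deg < 1):
            raise ValueError("every vertex needs at least one edge")

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique undirected edges (i < j) and their weights."""
        coo = sp.triu(self.weights, k=1).tocoo()
        return coo.row, coo.col, coo.data


@dataclass
class RegionForce:
    """Unary data-fitting term: per-vertex class-1 prior and -log costs."""

    prior_1: np.ndarray
    cost_0: np.ndarray
    cost_1: np.ndarray
    seed_labels: Dict[int, int] = field(default_factory=dict)


@dataclass
class LabelingField:
    """Relaxed labeling u in [0,1]^V with its decision threshold."""

    u: np.ndarray
    threshold: float = 0.5
    iterations: int = 0
    duality_gap: float = np.inf
    converged: bool = True

    def __post_init__(self) -> None:
        if np.any((self.u < -1e-12) | (self.u > 1 + 1e-12)):
            raise ValueError("u must lie in [0, 1]")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    def classes(self) -> np.ndarray:
        return self.u > self.threshold


def _as_matrix(features: Union[np.ndarray, Sequence[FeatureImage]]) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(features, np.ndarray):
        x = features.reshape(len(features), -1).astype(float)
        ids = np.arange(len(features)).astype(object)
        return x, ids
    x = np.stack([np.ravel(f.values) for f in features]).astype(float)
    ids = np.array([f.pattern_id for f in features], dtype=object)
    return x, ids


def build_similarity_graph(features, k: int = 10,
                           sigma_mode: str = "local_scale") -> SimilarityGraph:
    """k-NN graph with locally scaled RBF weights.

    Edges are the union of the k-NN lists and carry
    w_ij = exp(-d_ij^2 / (sigma_i sigma_j)).  The local scale sigma_i is, by
    default, the distance from x_i to its k-th nearest neighbour — the
    classic local-scaling choice, which keeps the exponents O(1) for
    neighbouring pairs regardless of dimensionality.  ``sigma_mode="std"``
    instead uses the population standard deviation of the k neighbour
    distances; on high-dimensional data, where distances concentrate, that
    spread collapses to a tiny fraction of the distances themselves and
    every weight underflows, so it is kept only as an explicit option.
    Duplicate points give sigma = 0, floored at 1e-12 times the median
    neighbour distance (with a warning) so weights stay finite.
    """
    x, ids = _as_matrix(features)
    n = len(x)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k + 1:
        raise ValueError("need at least k + 1 patterns")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    if sigma_mode == "local_scale":
        sigma = dist[:, -1].copy()  # k-th neighbour distance
    elif sigma_mode == "std":
        sigma = dist.std(axis=1)  # population std (ddof=0)
    else:
        raise ValueError("sigma_mode must be 'local_scale' or 'std'")
    med = np.median(dist)
    floor = 1e-12 * (med if med > 0 else 1.0)
    if np.any(sigma < floor):
        log.warning("sigma floor applied to %d vertices (duplicate points?)",
                    int(np.sum(sigma < floor)))
        sigma = np.maximum(sigma, floor)

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    d2 = dist.ravel() ** 2
    # floor keeps far-apart neighbour pairs connected instead of silently
    # dropping the edge through exp underflow
    w = np.maximum(np.exp(-d2 / (sigma[rows] * sigma[cols])), 1e-30)
    adj = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)  # symmetrize by union of neighbourhoods
    adj.setdiag(0)
    adj.eliminate_zeros()
    return SimilarityGraph(weights=adj, neighbor_count=k, sigma=sigma,
                           points=x, ids=ids)


def _seed_similarities(graph: SimilarityGraph, seeds: np.ndarray) -> np.ndarray:
    """Locally-scaled similarities from every vertex to each seed,
    renormalized per vertex (softmax over log-weights) so the vote ratio
    survives even where every raw exp(-d^2 / sigma sigma) underflows."""
    x = graph.points
    sq = np.sum(x ** 2, axis=1)
    sqs = np.sum(x[seeds] ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sqs[None, :] - 2.0 * (x @ x[seeds].T), 0.0)
    expo = -d2 / (graph.sigma[:, None] * graph.sigma[seeds][None, :])
    return np.exp(expo - expo.max(axis=1, keepdims=True))


def compute_region_force(graph: SimilarityGraph,
                         seed_labels: Mapping[int, int]) -> RegionForce:
    """Similarity-weighted seed vote as the class prior.

    prior_1(x) = sum over class-1 seeds of w(x, s) / sum over all seeds of
    w(x, s), clipped away from {0, 1}; a seed's own prior is pinned to its
    label.  Vertices with vanishing similarity to every seed get the
    uninformative prior 0.5.
    """
    seeds = np.fromiter(seed_labels.keys(), dtype=int)
    lab = np.array([seed_labels[s] for s in seeds])
    if not (np.any(lab == 0) and np.any(lab == 1)):
        raise ValueError("need at least one seed of each class")
    w = _seed_similarities(graph, seeds)
    num = w[:, lab == 1].sum(axis=1)
    den = w.sum(axis=1)
    prior = np.full(graph.n_vertices, 0.5)
    ok = den > 0
    prior[ok] = num[ok] / den[ok]
    prior[seeds] = np.where(lab == 1, 1.0 - _EPS_PRIOR, _EPS_PRIOR)
    prior = np.clip(prior, _EPS_PRIOR, 1.0 - _EPS_PRIOR)
    return RegionForce(prior_1=prior,
                       cost_0=-np.log(1.0 - prior),
                       cost_1=-np.log(prior),
                       seed_labels=dict(seed_labels))


def potts_energy(u: np.ndarray, graph: SimilarityGraph, force: RegionForce,
                 lam: float) -> float:
    """E(u) = unary region-force term + lambda * weighted graph TV."""
    i, j, w = graph.edge_list()
    unary = float(np.dot(force.cost_1, u) + np.dot(force.cost_0, 1.0 - u))
    tv = float(np.dot(w, np.abs(u[i] - u[j])))
    return unary + lam * tv


def solve_potts_primal_dual(graph: SimilarityGraph, force: RegionForce,
                            lam: float = 1.0, tol: float = 1e-6,
                            max_iter: int = 2000) -> LabelingField:
    """Primal-dual (max-flow) minimization of the relaxed Potts functional.

    Chambolle-Pock iteration on the weighted incidence operator, with step
    sizes tau = sigma = 0.99 / L, L the operator norm estimated by power
    iteration.  Stops when the relative duality gap drops below ``tol``;
    past ``max_iter`` the best iterate is returned with a warning flag.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n = graph.n_vertices
    i, j, w = graph.edge_list()
    m = len(i)
    c = force.cost_1 - force.cost_0
    offset = float(force.cost_0.sum())

    if m == 0 or lam == 0:
        u = (c < 0).astype(float)
        return LabelingField(u=u, iterations=0, duality_gap=0.0)

    K = sp.coo_matrix(
        (np.concatenate([np.ones(m), -np.ones(m)]),
         (np.concatenate([np.arange(m), np.arange(m)]),
          np.concatenate([i, j]))),
        shape=(m, n)).tocsr()
    Kt = K.T.tocsr()

    # operator norm by power iteration on K^T K
    v = np.random.default_rng(0).standard_normal(n)
    v /= np.linalg.norm(v)
    L = 1.0
    for _ in range(50):
        v = Kt @ (K @ v)
        L = np.linalg.norm(v)
        if L == 0:
            break
        v /= L
    L = max(np.sqrt(L), 1e-12)
    tau = sigma_step = 0.99 / L

    cap = lam * w
    u = np.full(n, 0.5)
    ubar = u.copy()
    p = np.zeros(m)
    best_u, best_e = u.copy(), np.inf
    gap = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(p + sigma_step * (K @ ubar), -cap, cap)
        u_new = np.clip(u - tau * (Kt @ p + c), 0.0, 1.0)
        ubar = 2.0 * u_new - u
        u = u_new
        if it % 10 == 0 or it == max_iter:
            primal = float(c @ u) + float(cap @ np.abs(u[i] - u[j])) + offset
            if primal < best_e:
                best_e, best_u = primal, u.copy()
            resid = Kt @ p + c
            dual = float(np.minimum(resid, 0.0).sum()) + offset
            scale = max(1.0, abs(primal), abs(dual))
            gap = (primal - dual) / scale
            if gap <= tol:
                return LabelingField(u=u, iterations=it, duality_gap=gap)
    log.warning("primal-dual solver hit max_iter=%d with gap %.3g",
                max_iter, gap)
    return LabelingField(u=best_u, iterations=it, duality_gap=gap,
                         converged=False)


def classify_gc(features, seed_labels: Mapping, k: int = 10, lam: float = 1.0,
                theta: float = 0.5, tol: float = 1e-6,
                max_iter: int = 2000) -> LabelSet:
    """Full transductive graph-cut pipeline: graph -> region force ->
    primal-dual solve -> threshold at ``theta``.

    ``seed_labels`` maps pattern ids (or integer indices) to {0, 1}; class 1
    means single hit.  Deterministic: there is no randomness in this path.
    """
    graph = build_similarity_graph(features, k)
    id_to_idx = {pid: n for n, pid in enumerate(graph.ids)}
    seeds = {}
    for key, val in seed_labels.items():
        if key in id_to_idx:
            seeds[id_to_idx[key]] = int(val)
        elif isinstance(key, (int, np.integer)) and 0 <= key < graph.n_vertices:
            seeds[int(key)] = int(val)
        else:
            raise KeyError(f"seed id {key!r} not among the patterns")
    force = compute_region_force(graph, seeds)
    field_ = solve_potts_primal_dual(graph, force, lam, tol, max_iter)
    return LabelSet(ids=graph.ids, scores=np.clip(field_.u, 0.0, 1.0),
                    threshold=theta)
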
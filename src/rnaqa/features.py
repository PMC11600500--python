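"""Invariant input features: nucleotide one-hots, pair descriptors, k-NN locality.

Every feature here depends only on the sequence and on interatomic
distances, so the whole feature block is invariant under global rigid
motions of the input coordinates — the property the attention module
relies on.

Pair features concatenate a 5-bin sequence-separation one-hot with a
Gaussian radial-basis encoding (16 centers on [0, 100] Angstrom) of the
9 anchor-atom distances between the ordered triples (P, C4', N) of the
two nucleotides, giving 5 + 9*16 = 149 values per edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import RNAStructure

CODES = ("A", "C", "G", "U", "X")

RBF_COUNT = 16
RBF_D_MIN = 0.0
RBF_D_MAX = 100.0

N_NODE_FEATURES = 6  # 5 one-hot + relative position
N_PAIR_FEATURES = 5 + 9 * RBF_COUNT

DEFAULT_K = 20


@dataclass(frozen=True)
class NeighborGraph:
    """k-NN locality over C4'-C4' distances.

    ``neighbors[i]`` holds the min(K, L) nearest indices (0-based), self
    first at distance 0, then ascending distance with ties broken by index.
    """

    neighbors: np.ndarray  # (L, min(K, L)) int
    K: int


def nucleotide_features(s: RNAStructure) -> np.ndarray:
    """(L, 6) array: one-hot over (A, C, G, U, X) plus relative position i/L."""
    L = s.L
    out = np.zeros((L, N_NODE_FEATURES))
    for i, nt in enumerate(s.nucleotides):
        out[i, CODES.index(nt.code)] = 1.0
        out[i, 5] = (i + 1) / L
    return out


def seqsep_bin(i: int, j: int) -> int:
    """Sequence-separation bin: 0 self, 1 adjacent, 2 short (2-5),
    3 medium (6-24), 4 long (>24)."""
    sep = abs(i - j)
    if sep == 0:
        return 0
    if sep == 1:
        return 1
    if sep <= 5:
        return 2
    if sep <= 24:
        return 3
    return 4


def rbf_centers(count: int = RBF_COUNT, d_min: float = RBF_D_MIN, d_max: float = RBF_D_MAX):
    """Linearly spaced Gaussian centers including both endpoints; the width
    sigma equals the center spacing."""
    mu = np.linspace(d_min, d_max, count)
    sigma = (d_max - d_min) / (count - 1)
    return mu, sigma


def rbf_encode(d, count: int = RBF_COUNT, d_min: float = RBF_D_MIN, d_max: float = RBF_D_MAX) -> np.ndarray:
    """Gaussian RBF encoding of distances (Angstrom): ``exp(-(d-mu)^2 / (2 sigma^2))``.

    Accepts a scalar or any-shape array; appends a trailing axis of length
    ``count``. All outputs lie in (0, 1].
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("invalid distance: negative")
    mu, sigma = rbf_centers(count, d_min, d_max)
    return np.exp(-((d[..., None] - mu) ** 2) / (2.0 * sigma**2))


def _anchor_coords(s: RNAStructure) -> np.ndarray:
    """(L, 3, 3): for each nucleotide the (P-or-fallback, C4', N) positions, Angstrom."""
    out = np.empty((s.L, 3, 3))
    for i, nt in enumerate(s.nucleotides):
        out[i, 0], out[i, 1], out[i, 2] = s.anchor_triple(nt)
    return out


def pair_features(s: RNAStructure, i: int, j: int) -> np.ndarray:
    """149-vector for the ordered pair (i, j), 1-based indices.

    Layout: seqsep one-hot (5), then RBF blocks for the 9 distances in
    i-atom-major order (P_i, C4'_i, N_i) x (P_j, C4'_j, N_j). Distances are
    raw Angstrom (the 0.1 frame scaling never touches RBF inputs).
    """
    anchors = _anchor_coords(s)
    return _pair_vector(anchors, i - 1, j - 1, seqsep_bin(i, j))


def _pair_vector(anchors: np.ndarray, i0: int, j0: int, bin_idx: int) -> np.ndarray:
    d = cdist(anchors[i0], anchors[j0]).reshape(-1)  # row-major: i-atom major
    out = np.zeros(N_PAIR_FEATURES)
    out[bin_idx] = 1.0
    out[5:] = rbf_encode(d).reshape(-1)
    return out


def knn_graph(s: RNAStructure, K: int = DEFAULT_K) -> NeighborGraph:
    """Locality graph: for each nucleotide the min(K, L) nearest by C4'-C4'
    distance, self included first, ties broken by ascending index."""
    c4 = s.c4_coords()
    D = cdist(c4, c4)
    L = s.L
    k = min(K, L)
    # lexsort: primary key distance, secondary index — deterministic ties.
    # Distances are rounded to 1e-6 A first so that exact geometric ties
    # (common in regular helices) stay tied after a global rigid motion
    # perturbs them at the 1e-13 level; otherwise neighborhood membership,
    # and with it the network output, would not be rotation-invariant.
    idx_grid = np.tile(np.arange(L), (L, 1))
    order = np.lexsort((idx_grid, np.round(D, 6)), axis=1)
    return NeighborGraph(neighbors=order[:, :k].astype(np.int64), K=K)


def edge_features(s: RNAStructure, graph: NeighborGraph) -> np.ndarray:
    """(L, k, 149) pair features for every locality edge (i, neighbors[i])."""
    anchors = _anchor_coords(s)
    L, k = graph.neighbors.shape
    out = np.empty((L, k, N_PAIR_FEATURES))
    for i in range(L):
        for m, j in enumerate(graph.neighbors[i]):
            out[i, m] = _pair_vector(anchors, i, int(j), seqsep_bin(i + 1, int(j) + 1))
    return out
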
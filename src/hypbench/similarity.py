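"""Pairwise site similarity, distances, and UPGMA clustering.

Two windows are compared column by column: residue pairs score by the
substitution matrix (BLOSUM62 by default), while maximal runs of columns in
which either window carries a gap are charged a single affine penalty of
gap_open + (run length − 1) × gap_extend, regardless of which window the gaps
sit in.  Because BLOSUM scores can be zero or negative, "distance as the
inverse of similarity" is realized as the order-reversing affine transform
d(i, j) = S_max − s(i, j), with S_max the largest score in the table
(self-pairs included), so all distances are non-negative and every site is
nearest to itself.

Clustering is average-linkage (UPGMA) with a fixed tie-breaking rule — among
equal-height candidate merges, the pair with the lexicographically smallest
(min cluster id, max cluster id) merges first — so cluster assignments are a
deterministic function of the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform

from hypbench.io import SiteKey
from hypbench.windows import CANONICAL, GAP_CODE, SiteWindow, encode_windows


@dataclass(frozen=True)
class ScoringParams:
    """Substitution-matrix and affine gap-run penalties for window pairs."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError(
                f"gap penalties must satisfy gap_open <= gap_extend <= 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )


@lru_cache(maxsize=4)
def _matrix_array(matrix_name: str) -> np.ndarray:
    """21x21 score array over CANONICAL + gap; gap entries are 0 (the affine
    run penalty, not the matrix, pays for gap columns)."""
    mat = substitution_matrices.load(matrix_name)
    arr = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(CANONICAL):
        for j, b in enumerate(CANONICAL):
            arr[i, j] = mat[a, b]
    return arr


def _gap_run_penalty(gap_union: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Affine penalty for each pair given the per-column gap-union mask.

    ``gap_union`` has shape (..., W); a run is a maximal stretch of True.
    """
    totals = gap_union.sum(axis=-1)
    starts = gap_union[..., 0].astype(np.int64)
    if gap_union.shape[-1] > 1:
        starts = starts + (gap_union[..., 1:] & ~gap_union[..., :-1]).sum(axis=-1)
    return starts * params.gap_open + (totals - starts) * params.gap_extend


def site_score(w1: SiteWindow, w2: SiteWindow, params: ScoringParams = ScoringParams()) -> float:
    """Similarity score of two equal-length windows (symmetric)."""
    if w1.W != w2.W:
        raise ValueError(f"window length mismatch: {w1.W} vs {w2.W}")
    a = encode_windows([w1])[0].astype(np.int64)
    b = encode_windows([w2])[0].astype(np.int64)
    mat = _matrix_array(params.matrix_name)
    gap_union = (a == GAP_CODE) | (b == GAP_CODE)
    sub = mat[a, b][~gap_union].sum()
    return float(sub + _gap_run_penalty(gap_union[None, :], params)[0])


def pairwise_scores(windows: Sequence[SiteWindow], params: ScoringParams = ScoringParams(),
                    block: int = 256) -> np.ndarray:
    """Full symmetric score matrix over a window set (self-pairs included).

    Computed blockwise; for n sites this is an O(n² W) pass kept well within
    memory by never materializing more than block² × W booleans at once.
    """
    if not windows:
        raise ValueError("empty window set")
    widths = {w.W for w in windows}
    if len(widths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(widths)}")
    enc = encode_windows(windows).astype(np.int64)
    n, W = enc.shape
    mat = _matrix_array(params.matrix_name)
    gaps = enc == GAP_CODE
    S = np.empty((n, n), dtype=np.float64)
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for j0 in range(i0, n, block):
            j1 = min(j0 + block, n)
            a, b = enc[i0:i1], enc[j0:j1]
            sub = np.zeros((i1 - i0, j1 - j0), dtype=np.float64)
            gap_union = gaps[i0:i1, None, :] | gaps[j0:j1, None, :].transpose(1, 0, 2)
            for c in range(W):
                col = mat[a[:, c]][:, b[:, c]]
                col[gap_union[:, :, c]] = 0.0
                sub += col
            sub += _gap_run_penalty(gap_union, params)
            S[i0:i1, j0:j1] = sub
            S[j0:j1, i0:i1] = sub.T
    return S


def cross_scores(windows_a: Sequence[SiteWindow], windows_b: Sequence[SiteWindow],
                 params: ScoringParams = ScoringParams(), block: int = 512) -> np.ndarray:
    """Rectangular score matrix between two window sets (shape (na, nb))."""
    if not windows_a or not windows_b:
        raise ValueError("empty window set")
    if {w.W for w in windows_a} != {w.W for w in windows_b}:
        raise ValueError("window length mismatch between sets")
    enc_a = encode_windows(windows_a).astype(np.int64)
    enc_b = encode_windows(windows_b).astype(np.int64)
    W = enc_a.shape[1]
    mat = _matrix_array(params.matrix_name)
    gaps_a, gaps_b = enc_a == GAP_CODE, enc_b == GAP_CODE
    out = np.empty((len(windows_a), len(windows_b)), dtype=np.float64)
    for i0 in range(0, len(windows_a), block):
        i1 = min(i0 + block, len(windows_a))
        gap_union = gaps_a[i0:i1, None, :] | gaps_b[None, :, :]
        sub = np.zeros((i1 - i0, len(windows_b)), dtype=np.float64)
        for c in range(W):
            col = mat[enc_a[i0:i1, c]][:, enc_b[:, c]]
            col[gap_union[:, :, c]] = 0.0
            sub += col
        out[i0:i1] = sub + _gap_run_penalty(gap_union, params)
    return out


@dataclass
class SiteDistanceMatrix:
    """Ordered site keys plus the condensed pairwise distance matrix."""

    keys: list[SiteKey]
    condensed: np.ndarray
    s_max: float

    def __post_init__(self) -> None:
        n = len(self.keys)
        if len(self.condensed) != n * (n - 1) // 2:
            raise ValueError("condensed matrix size does not match key count")

    @property
    def n(self) -> int:
        return len(self.keys)

    def square(self) -> np.ndarray:
        return squareform(self.condensed, checks=False)


def score_to_distance(keys: Sequence[SiteKey], scores: np.ndarray) -> SiteDistanceMatrix:
    """Turn a symmetric score matrix into distances d = S_max − s."""
    n = len(keys)
    if n == 0:
        raise ValueError("empty site set")
    if scores.shape != (n, n):
        raise ValueError(f"score matrix shape {scores.shape} does not match {n} keys")
    s_max = float(scores.max())
    dist = s_max - scores
    np.fill_diagonal(dist, 0.0)
    return SiteDistanceMatrix(keys=list(keys), condensed=squareform(dist, checks=False),
                              s_max=s_max)


@dataclass
class ClusterAssignment:
    """Flat cluster labels (contiguous ids from 1) plus the merge tree."""

    labels: dict[SiteKey, int]
    linkage: np.ndarray  # scipy-format (n-1, 4) merge record
    cut_height: float
    keys: list[SiteKey] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return max(self.labels.values()) if self.labels else 0

    def members(self) -> dict[int, list[SiteKey]]:
        out: dict[int, list[SiteKey]] = {}
        for key in self.keys:
            out.setdefault(self.labels[key], []).append(key)
        return out


def upgma_linkage(condensed: np.ndarray, n: int) -> np.ndarray:
    """Average-linkage merge tree in scipy linkage format.

    Deterministic: equal-height candidate merges are resolved in favour of the
    lexicographically smallest (min cluster id, max cluster id) pair, with
    original observations numbered 0..n−1 and new clusters n, n+1, ...
    """
    Z = np.zeros((max(n - 1, 0), 4), dtype=np.float64)
    if n <= 1:
        return Z
    D = squareform(condensed, checks=False).astype(np.float64)
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances in matrix")
    np.fill_diagonal(D, np.inf)
    cid = np.arange(n, dtype=np.int64)  # current cluster id per slot
    size = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    for step in range(n - 1):
        m = D.min()
        ii, jj = np.nonzero(D == m)
        pairs = sorted(
            (min(cid[i], cid[j]), max(cid[i], cid[j]), i, j)
            for i, j in zip(ii.tolist(), jj.tolist()) if i < j
        )
        _, _, a, b = pairs[0]
        if a > b:
            a, b = b, a
        Z[step] = (min(cid[a], cid[b]), max(cid[a], cid[b]), m, size[a] + size[b])
        # Lance–Williams average update into slot a; slot b retires.
        na, nb = size[a], size[b]
        merged = (na * D[a] + nb * D[b]) / (na + nb)
        D[a, :] = merged
        D[:, a] = merged
        D[a, a] = np.inf
        D[b, :] = np.inf
        D[:, b] = np.inf
        cid[a] = n + step
        size[a] = na + nb
        active[b] = False
    return Z


def cluster_sites(matrix: SiteDistanceMatrix, cut_height: float) -> ClusterAssignment:
    """UPGMA-cluster all sites and cut the tree at ``cut_height``.

    A flat cluster is a maximal subtree whose internal merge heights are all
    ≤ cut_height; ids are renumbered contiguously from 1 in order of first
    appearance along the site list.
    """
    if cut_height < 0:
        raise ValueError(f"cut_height must be non-negative, got {cut_height}")
    if matrix.n == 0:
        raise ValueError("empty distance matrix")
    if not np.isfinite(matrix.condensed).all():
        raise ValueError("non-finite distances in matrix")
    if matrix.n == 1:
        return ClusterAssignment(labels={matrix.keys[0]: 1},
                                 linkage=np.zeros((0, 4)), cut_height=cut_height,
                                 keys=list(matrix.keys))
    Z = upgma_linkage(matrix.condensed, matrix.n)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[SiteKey, int] = {}
    for key, r in zip(matrix.keys, raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[key] = relabel[r]
    return ClusterAssignment(labels=labels, linkage=Z, cut_height=cut_height,
                             keys=list(matrix.keys))


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as a Newick string (heights as distances)."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"
    heights = {i: 0.0 for i in range(n)}
    texts = {i: str(labels[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + step
        # UPGMA heights are cophenetic distances, so on the ultrametric each
        # child hangs at half the merge height.
        la = h / 2 - heights[a] / 2
        lb = h / 2 - heights[b] / 2
        texts[node] = f"({texts[a]}:{la:g},{texts[b]}:{lb:g})"
        heights[node] = h
        del texts[a], texts[b]
    return texts[n + len(Z) - 1] + ";"


def distance_tsv(matrix: SiteDistanceMatrix, path) -> None:
    """Dump the condensed distance matrix for inspection."""
    with open(path, "w") as fh:
        fh.write("key_i\tkey_j\tdistance\n")
        sq = matrix.square()
        for i in range(matrix.n):
            for j in range(i + 1, matrix.n):
                ki, kj = matrix.keys[i], matrix.keys[j]
                fh.write(f"{ki[0]}:{ki[1]}\t{kj[0]}:{kj[1]}\t{sq[i, j]:g}\n")
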
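"""Per-cell CNV scores, Moran's I, patch co-localization, cluster separation.

The CNV score of a cell is the fraction of genes whose inferred copy-number
value falls strictly outside the neutral window (0.9, 1.1) of a matrix
centered at 1.  Moran's I measures global spatial autocorrelation of a field
over a symmetric neighbor weight graph.  Co-localization of two binary masks
is quantified by partitioning the image into k×k non-overlapping patches and
testing channel co-occurrence with Fisher's exact test (one-sided enrichment
by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.metrics import calinski_harabasz_score, silhouette_score


# ---------------------------------------------------------------------------
# CNV score

def cnv_score(cell_values: Sequence[float], lo: float = 0.9, hi: float = 1.1) -> float:
    """Fraction of genes with CNV value strictly outside (lo, hi).

    ``(1/N)·Σ 1[x_i < lo or x_i > hi]`` — the boundary values themselves count
    as neutral (strict inequalities).
    """
    x = np.asarray(cell_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty CNV vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("CNV values must be finite")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return float(np.mean((x < lo) | (x > hi)))


def cnv_scores(matrix: pd.DataFrame, lo: float = 0.9, hi: float = 1.1) -> pd.Series:
    """Per-cell CNV score for a cells × genes matrix centered at 1."""
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] == 0:
        raise ValueError("matrix must have at least one gene")
    out = np.mean((x < lo) | (x > hi), axis=1)
    return pd.Series(out, index=matrix.index, name="cnv_score")


# ---------------------------------------------------------------------------
# Moran's I

def rook_weights(nrows: int, ncols: int) -> sparse.csr_matrix:
    """Rook adjacency (4-neighbor) weights for a full lattice, row-major order."""
    n = nrows * ncols
    rows, cols = [], []
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c
            if c + 1 < ncols:
                rows += [i, i + 1]
                cols += [i + 1, i]
            if r + 1 < nrows:
                j = i + ncols
                rows += [i, j]
                cols += [j, i]
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def knn_weights(coords: np.ndarray, k: int = 6) -> sparse.csr_matrix:
    """Symmetrized k-nearest-neighbor binary weights for spot arrays."""
    from sklearn.neighbors import kneighbors_graph

    g = kneighbors_graph(np.asarray(coords, dtype=float), k, mode="connectivity")
    g = g.maximum(g.T)
    g.setdiag(0)
    g.eliminate_zeros()
    return g.tocsr()


def morans_i(
    values: Sequence[float],
    weights: sparse.spmatrix | np.ndarray,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Global Moran's I with an optional permutation p-value.

    ``I = (n/ΣΣw)·(ΣΣ w_ij z_i z_j)/(Σ z_i²)`` with z the centered values.
    The permutation p (two one-sided folded: upper tail on |I − E[I]|) is
    computed by shuffling values over spots; ``None`` when ``n_perm == 0``.
    """
    z = np.asarray(values, dtype=float)
    if z.size < 2:
        raise ValueError("at least 2 spots required")
    w = sparse.csr_matrix(weights)
    if w.shape != (z.size, z.size):
        raise ValueError("weights shape must match number of spots")
    if (abs(w - w.T) > 1e-12).nnz:
        raise ValueError("weights must be symmetric")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant field: Moran's I undefined")
    w_sum = w.sum()

    def _stat(zv: np.ndarray) -> float:
        return float(z.size / w_sum * (zv @ (w @ zv)) / (zv @ zv))

    i_obs = _stat(z)
    if n_perm <= 0:
        return i_obs, None
    rng = np.random.default_rng(seed)
    e_i = -1.0 / (z.size - 1)
    extreme = 0
    for _ in range(n_perm):
        if abs(_stat(rng.permutation(z)) - e_i) >= abs(i_obs - e_i):
            extreme += 1
    return i_obs, (extreme + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# patch co-localization

class Contingency2x2(NamedTuple):
    a: int  # both channels positive
    b: int  # A only
    c: int  # B only
    d: int  # neither


def _patch_edges(extent: int, k: int) -> np.ndarray:
    return np.array([round(i * extent / k) for i in range(k + 1)], dtype=int)


def patch_cooccurrence(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    k: int,
    min_pixels: int = 1,
    alternative: str = "greater",
) -> tuple[Contingency2x2, float]:
    """Patch-level co-occurrence of two binary masks with Fisher's exact test.

    The image is partitioned into k×k non-overlapping patches with integer
    boundaries at ``round(i·H/k)`` (patch sizes differ by at most one pixel;
    every pixel belongs to exactly one patch).  A patch is positive for a
    channel iff at least ``min_pixels`` of its pixels are set.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("masks must be two same-shape 2-D arrays")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("masks must be binary")
    if k < 2 or k > min(a.shape):
        raise ValueError("k must satisfy 2 <= k <= min(image dimensions)")
    re = _patch_edges(a.shape[0], k)
    ce = _patch_edges(a.shape[1], k)
    both = aonly = bonly = neither = 0
    for i in range(k):
        for j in range(k):
            pa = a[re[i] : re[i + 1], ce[j] : ce[j + 1]].sum() >= min_pixels
            pb = b[re[i] : re[i + 1], ce[j] : ce[j + 1]].sum() >= min_pixels
            if pa and pb:
                both += 1
            elif pa:
                aonly += 1
            elif pb:
                bonly += 1
            else:
                neither += 1
    table = Contingency2x2(both, aonly, bonly, neither)
    return table, fisher_exact_2x2(table, alternative=alternative)


def multiscale_cooccurrence(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    patch_sizes: Sequence[int] = (4, 6, 8, 10),
    min_pixels: int = 1,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Co-localization readout at several patch grids (default 4/6/8/10)."""
    rows = []
    for k in patch_sizes:
        table, p = patch_cooccurrence(mask_a, mask_b, k, min_pixels, alternative)
        rows.append((k, *table, p))
    return pd.DataFrame(rows, columns=["k", "both", "a_only", "b_only", "neither", "p"])


def fisher_exact_2x2(
    table: Contingency2x2 | Sequence[int], alternative: str = "greater"
) -> float:
    """Fisher's exact p for a 2×2 table.

    ``greater`` is the exact hypergeometric upper tail (enrichment of
    co-occurrence); ``two_sided`` uses the point-probability rule.
    """
    a, b, c, d = (int(v) for v in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    alt = {"greater": "greater", "two_sided": "two-sided"}.get(alternative)
    if alt is None:
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alt)[1])


# ---------------------------------------------------------------------------
# cluster separation

def separation_indices(
    embedding: np.ndarray, labels: Sequence
) -> tuple[float, float]:
    """Calinski–Harabasz index and mean Silhouette for labeled points."""
    x = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("at least 2 distinct labels required")
    return (
        float(calinski_harabasz_score(x, labels)),
        float(silhouette_score(x, labels)),
    )


# ---------------------------------------------------------------------------
# I/O helpers

@dataclass
class SpatialField:
    """Spot coordinates, a value per spot, and a spatial weight matrix."""

    coords: np.ndarray  # (n, 2)
    values: np.ndarray  # (n,)
    weights: sparse.csr_matrix

    @classmethod
    def from_lattice(cls, grid: np.ndarray) -> "SpatialField":
        nrows, ncols = grid.shape
        rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        coords = np.column_stack([rr.ravel(), cc.ravel()])
        return cls(coords, np.asarray(grid, dtype=float).ravel(), rook_weights(nrows, ncols))

    def morans_i(self, n_perm: int = 0, seed: int = 0) -> tuple[float, float | None]:
        return morans_i(self.values, self.weights, n_perm=n_perm, seed=seed)


def read_spots_tsv(path: str, k: int = 6) -> SpatialField:
    """Spots TSV with columns x, y, value; k-NN weights."""
    df = pd.read_csv(path, sep="\t")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    return SpatialField(coords, df["value"].to_numpy(dtype=float), knn_weights(coords, k))


def read_mask_tsv(path: str) -> np.ndarray:
    """Binary mask stored as a numeric matrix TSV (no header)."""
    arr = np.loadtxt(path, delimiter="\t")
    return (np.atleast_2d(arr) > 0.5).astype(np.int8)
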
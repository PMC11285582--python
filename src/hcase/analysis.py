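"""Distances, overlap statistics and diagnostics on embedded spaces.

Two distance notions coexist on an embedding. Along the unfolded curve,
compounds are separated by the rank distance d_r = |b_i - b_j| (difference
of bin indices). On the folded 2D grid the perceived distance is the
Chebyshev distance d_C = max(|dx|, |dy|). A good folding keeps the two
correlated, which :func:`distance_correlation` quantifies.

Whole embeddings are compared through their |D|-length per-bin count
vectors with the count-fingerprint form of the Tanimoto coefficient,

    theta(A, B) = sum A_i B_i / (sum A_i^2 + sum B_i^2 - sum A_i B_i),

and visual coverage comes from N x N count (or binarized) matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .embedding import EmbeddedCompound
from .hilbert import GridPoint, grid_dimensions


@dataclass(frozen=True)
class EmbeddingVector:
    """Per-bin compound counts of one embedding at order z."""

    counts: np.ndarray
    z: int
    space_checksum: str = ""

    def __post_init__(self):
        _, d_count = grid_dimensions(self.z)
        if len(self.counts) != d_count:
            raise ValueError(f"vector length must be |D|={d_count}")


def _check_same_space(a: EmbeddedCompound, b: EmbeddedCompound) -> None:
    if a.space_checksum != b.space_checksum:
        raise ValueError("compounds were embedded in different reference spaces")


def rank_distance(a: EmbeddedCompound, b: EmbeddedCompound) -> int:
    """Rank distance d_r: absolute difference of curve bin indices."""
    _check_same_space(a, b)
    return abs(a.b - b.b)


def chebyshev_distance(p: GridPoint, q: GridPoint) -> int:
    """Chebyshev distance d_C: max coordinate-wise absolute difference."""
    return max(abs(p.x - q.x), abs(p.y - q.y))


def embedding_vector(
    embedded: Sequence[EmbeddedCompound], z: int
) -> EmbeddingVector:
    """Condense an embedding into its |D|-length per-bin count vector."""
    _, d_count = grid_dimensions(z)
    counts = np.zeros(d_count, dtype=np.int64)
    checksum = embedded[0].space_checksum if embedded else ""
    for e in embedded:
        if e.z != z:
            raise ValueError(f"compound {e.compound_id} embedded at z={e.z}, not {z}")
        if e.space_checksum != checksum:
            raise ValueError("mixed reference spaces in one embedding vector")
        counts[e.b] += 1
    return EmbeddingVector(counts=counts, z=z, space_checksum=checksum)


def theta_overlap(a: EmbeddingVector, b: EmbeddingVector) -> float:
    """Space-overlap theta of two embedding vectors, in [0, 1].

    The count-vector Tanimoto: 1 iff the vectors are identical and
    nonzero, 0 iff their supports are disjoint. Vectors from different
    orders or spaces are refused — cross-resolution overlap is not a
    defined quantity here.
    """
    if a.z != b.z:
        raise ValueError("embedding vectors have different curve orders")
    if a.space_checksum != b.space_checksum:
        raise ValueError("embedding vectors come from different reference spaces")
    va = a.counts.astype(np.float64)
    vb = b.counts.astype(np.float64)
    cross = float(va @ vb)
    denom = float(va @ va) + float(vb @ vb) - cross
    if denom == 0.0:
        raise ValueError("theta undefined: both embedding vectors are all-zero")
    return cross / denom


def _pair_distances(embedded: Sequence[EmbeddedCompound]) -> tuple[np.ndarray, np.ndarray]:
    bins = np.array([e.b for e in embedded], dtype=np.int64)
    xs = np.array([e.point.x for e in embedded], dtype=np.int64)
    ys = np.array([e.point.y for e in embedded], dtype=np.int64)
    iu = np.triu_indices(len(embedded), k=1)
    d_r = np.abs(bins[:, None] - bins[None, :])[iu]
    d_c = np.maximum(
        np.abs(xs[:, None] - xs[None, :]), np.abs(ys[:, None] - ys[None, :])
    )[iu]
    return d_r, d_c


def _correlate(d_r: np.ndarray, d_c: np.ndarray, method: str) -> float:
    if np.all(d_r == d_r[0]) or np.all(d_c == d_c[0]):
        raise ValueError("correlation undefined: a distance is constant over all pairs")
    if method == "pearson":
        return float(stats.pearsonr(d_r, d_c).statistic)
    if method == "kendall":
        return float(stats.kendalltau(d_r, d_c).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def distance_correlation(
    embedded: Sequence[EmbeddedCompound],
    method: str = "pearson",
    subset_size: Optional[int] = None,
    n_subsets: int = 1,
    seed: Optional[int] = None,
) -> float | tuple[float, float]:
    """Correlation between rank distance and Chebyshev distance.

    Computed over all unordered compound pairs. With ``subset_size`` set,
    ``n_subsets`` non-overlapping random subsets are drawn (seeded,
    without replacement) and the mean and standard deviation of their
    per-subset correlations are returned — the protocol for checking that
    a whole-set correlation is not an artifact of a few heavy chemotypes.
    """
    if len(embedded) < 3:
        raise ValueError("need at least 3 compounds")
    if subset_size is None:
        d_r, d_c = _pair_distances(embedded)
        return _correlate(d_r, d_c, method)
    if subset_size * n_subsets > len(embedded):
        raise ValueError(
            f"{n_subsets} non-overlapping subsets of {subset_size} exceed "
            f"the {len(embedded)} available compounds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(embedded))
    values = []
    for i in range(n_subsets):
        idx = order[i * subset_size : (i + 1) * subset_size]
        d_r, d_c = _pair_distances([embedded[j] for j in idx])
        values.append(_correlate(d_r, d_c, method))
    return float(np.mean(values)), float(np.std(values))


def coverage_matrix(
    embedded: Sequence[EmbeddedCompound], z: int, binarize: bool = False
) -> np.ndarray:
    """N x N heatmap matrix of compound counts at each grid cell.

    ``matrix[y, x]`` counts compounds at (x, y); with ``binarize`` the
    entries collapse to 1 where at least one compound sits, else 0.
    """
    n, _ = grid_dimensions(z)
    mat = np.zeros((n, n), dtype=np.int64)
    for e in embedded:
        if e.z != z:
            raise ValueError(f"compound {e.compound_id} embedded at z={e.z}, not {z}")
        mat[e.point.y, e.point.x] += 1
    if binarize:
        return (mat > 0).astype(np.int64)
    return mat


def save_heatmap(matrix: np.ndarray, path: str, cmap: str = "viridis") -> None:
    """Optional thin rendering layer: write the matrix as an image.

    Row 0 is drawn at the bottom so the image matches grid coordinates.
    Requires matplotlib; the tested contract ends at the matrix values.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.imshow(matrix, origin="lower", cmap=cmap)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
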
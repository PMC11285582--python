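"""Pseudo-Hilbert-curve geometry and the rank-to-bin mechanism.

A pseudo-Hilbert curve (PHC) of order z visits every cell of a
2^z x 2^z grid exactly once, with consecutive curve indices occupying
4-neighbor-adjacent cells. Scaffold ranks are mapped onto curve indices
("bins") by a linear rescaling: with a reference space of |S| scaffolds
and |D| = (2^z)^2 grid cells, the bin size is l = |S| / (|D| - 1) and a
1-based rank r lands in bin b = round(r / l), so rank |S| lands exactly
on the last zero-indexed bin |D| - 1.

The index<->coordinate maps implement the classic bit-interleaving
construction (Gray-code quadrant walk with reflections), entry at (0,0).
The orientation is a frozen convention; all correctness properties
(bijectivity, unit-step adjacency, convergence) are orientation-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class GridPoint:
    """Integer cell coordinates on the N x N grid, 0 <= x, y <= N-1."""

    x: int
    y: int


@dataclass(frozen=True)
class PHCGrid:
    """A PHC configuration tied to a reference space of size ``space_size``."""

    z: int
    space_size: int

    def __post_init__(self):
        if self.z < 1:
            raise ValueError("curve order z must be >= 1")
        if self.space_size < 1:
            raise ValueError("reference space must hold at least one scaffold")

    @property
    def n(self) -> int:
        return 2**self.z

    @property
    def d_count(self) -> int:
        return self.n**2

    @property
    def l(self) -> float:
        return bin_size(self.space_size, self.z)


def grid_dimensions(z: int, dimensions: int = 2) -> tuple[int, int]:
    """Side length N = 2^z and cell count |D| = N^2 for curve order z.

    Only the planar (2D) folding is supported; the dimension argument
    exists for interface symmetry and rejects anything but 2.
    """
    if dimensions != 2:
        raise NotImplementedError("only 2D folding is supported")
    if z < 1:
        raise ValueError("curve order z must be >= 1")
    n = 2**z
    return n, n * n


def hilbert_coords(d: int, z: int) -> GridPoint:
    """Map curve index d (0-based) to its grid cell at order z.

    Bijective onto the N x N grid; consecutive indices are Manhattan
    distance 1 apart.
    """
    n, d_count = grid_dimensions(z)
    if not 0 <= d < d_count:
        raise ValueError(f"curve index {d} outside [0, {d_count - 1}]")
    x = y = 0
    t = d
    s = 1
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        if ry == 0:
            if rx == 1:
                x, y = s - 1 - x, s - 1 - y
            x, y = y, x
        x += s * rx
        y += s * ry
        t //= 4
        s *= 2
    return GridPoint(x=x, y=y)


def hilbert_index(p: GridPoint, z: int) -> int:
    """Inverse of :func:`hilbert_coords`: grid cell to curve index."""
    n, _ = grid_dimensions(z)
    if not (0 <= p.x < n and 0 <= p.y < n):
        raise ValueError(f"point ({p.x}, {p.y}) outside the {n}x{n} grid")
    x, y = p.x, p.y
    d = 0
    s = n // 2
    while s > 0:
        rx = 1 if (x & s) > 0 else 0
        ry = 1 if (y & s) > 0 else 0
        d += s * s * ((3 * rx) ^ ry)
        if ry == 0:
            if rx == 1:
                x, y = s - 1 - x, s - 1 - y
            x, y = y, x
        s //= 2
    return d


def bin_size(space_size: int, z: int) -> float:
    """Bin size l = |S| / (|D| - 1).

    The minus-one term compensates for the zero-indexed curve: it places
    the top-ranked scaffold exactly on the last curve index.
    """
    _, d_count = grid_dimensions(z)
    if d_count < 2:
        raise ValueError("grid must have at least two cells")
    if space_size < 1:
        raise ValueError("space size must be >= 1")
    return space_size / (d_count - 1)


def round_half_up(value: float) -> int:
    """Round to nearest integer, halves away from zero (for positive input).

    Centralized so the bin mechanism has a single, documented tie rule;
    banker's rounding would silently shift every .5 rank ratio.
    """
    return int(math.floor(value + 0.5))


def bin_index(rank: int, l: float) -> int:
    """Curve bin of a 1-based scaffold rank: b = round(rank / l)."""
    if rank < 1:
        raise ValueError("ranks are 1-based")
    if l <= 0:
        raise ValueError("bin size must be positive")
    return round_half_up(rank / l)


def rank_to_point(rank: int, grid: PHCGrid) -> GridPoint:
    """Compose the bin mechanism with the curve folding for one rank."""
    if rank > grid.space_size:
        raise ValueError(f"rank {rank} exceeds space size {grid.space_size}")
    return hilbert_coords(bin_index(rank, grid.l), grid.z)
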
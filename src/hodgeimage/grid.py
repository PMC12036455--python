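"""Cubical cell complexes on Cartesian grids.

A 2D/3D image lives on the vertices of a Cartesian grid.  The grid's
k-cells (vertices, edges, faces, cubes) carry discrete differential
k-forms as k-cochains, and the exterior derivative / Hodge star become
sparse matrices indexed by a deterministic cell ordering.

Cell ordering convention
------------------------
k-cells are grouped by the (sorted) subset of coordinate axes they span,
subsets in lexicographic order (e.g. for 3D edges: x, y, z; for faces:
xy, xz, yz), and within a subset by the anchor (lowest corner) in
row-major (C) order.  Axis 0 is called x, axis 1 y, axis 2 z, matching
the pixel index convention pixel (i, j[, k]) = vertex (i, j[, k]).

Every k-cell is oriented by increasing coordinate axes; boundary signs
follow the standard cubical boundary formula, which makes D_{k+1} D_k = 0
hold exactly in integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import prod

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GridSpec",
    "enumerate_cells",
    "exterior_derivative",
    "hodge_star",
    "export_triplets",
]


@dataclass(frozen=True)
class GridSpec:
    """A Cartesian grid of vertices with unit spacing.

    Parameters
    ----------
    vertex_shape
        Number of vertices along each axis; length 2 or 3, every extent >= 2.
    """

    vertex_shape: tuple[int, ...]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.vertex_shape)
        object.__setattr__(self, "vertex_shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid dimension must be 2 or 3, got {len(shape)}")
        if any(n < 2 for n in shape):
            raise ValueError(f"all vertex extents must be >= 2, got {shape}")

    @property
    def dim(self) -> int:
        return len(self.vertex_shape)

    def axis_subsets(self, k: int) -> list[tuple[int, ...]]:
        """Sorted axis subsets spanned by k-cells, in lexicographic order."""
        self._check_degree(k)
        return list(combinations(range(self.dim), k))

    def cell_block_shape(self, axes: tuple[int, ...]) -> tuple[int, ...]:
        """Anchor-array shape for cells spanning ``axes``."""
        return tuple(
            n - 1 if a in axes else n for a, n in enumerate(self.vertex_shape)
        )

    def block_offsets(self, k: int) -> list[int]:
        """Flat-index offset of each axis-subset block at degree k."""
        offsets, total = [], 0
        for axes in self.axis_subsets(k):
            offsets.append(total)
            total += prod(self.cell_block_shape(axes))
        return offsets

    def n_cells(self, k: int) -> int:
        self._check_degree(k)
        return sum(prod(self.cell_block_shape(a)) for a in self.axis_subsets(k))

    def _check_degree(self, k: int) -> None:
        if not 0 <= k <= self.dim:
            raise ValueError(f"degree k={k} outside 0..{self.dim}")


def enumerate_cells(grid: GridSpec, k: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """List all k-cells as ``(axes, anchor)`` pairs in the canonical order."""
    grid._check_degree(k)
    cells = []
    for axes in grid.axis_subsets(k):
        shape = grid.cell_block_shape(axes)
        for flat in range(prod(shape)):
            anchor = np.unravel_index(flat, shape)
            cells.append((axes, tuple(int(a) for a in anchor)))
    return cells


def exterior_derivative(grid: GridSpec, k: int) -> sp.csr_matrix:
    """Signed incidence matrix D_k mapping k-cochains to (k+1)-cochains.

    The row of a (k+1)-cell holds +-1 on its 2(k+1) boundary k-cells:
    removing the i-th axis (0-based, in the cell's sorted axis tuple)
    gives the upper face (anchor + e_axis) with sign (-1)^i and the lower
    face (same anchor) with sign (-1)^(i+1).
    """
    if not 0 <= k <= grid.dim - 1:
        raise ValueError(f"exterior derivative needs 0 <= k <= {grid.dim - 1}, got {k}")
    sub_subsets = grid.axis_subsets(k)
    sub_offsets = grid.block_offsets(k)
    sub_index = {axes: i for i, axes in enumerate(sub_subsets)}

    rows, cols, vals = [], [], []
    row_offsets = grid.block_offsets(k + 1)
    for s, axes in enumerate(grid.axis_subsets(k + 1)):
        shape = grid.cell_block_shape(axes)
        n_block = prod(shape)
        anchors = np.indices(shape).reshape(len(shape), n_block)
        row_ids = row_offsets[s] + np.arange(n_block)
        for i, axis in enumerate(axes):
            face_axes = tuple(a for a in axes if a != axis)
            fs = sub_index[face_axes]
            face_shape = grid.cell_block_shape(face_axes)
            lower = np.ravel_multi_index(anchors, face_shape)
            upper_anchor = anchors.copy()
            upper_anchor[axis] += 1
            upper = np.ravel_multi_index(upper_anchor, face_shape)
            sign = (-1) ** i
            rows.append(row_ids)
            cols.append(sub_offsets[fs] + upper)
            vals.append(np.full(n_block, sign, dtype=np.int64))
            rows.append(row_ids)
            cols.append(sub_offsets[fs] + lower)
            vals.append(np.full(n_block, -sign, dtype=np.int64))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    D = sp.csr_matrix(
        (vals, (rows, cols)), shape=(grid.n_cells(k + 1), grid.n_cells(k))
    )
    D.sum_duplicates()
    return D


def hodge_star(grid: GridSpec, k: int, mode: str = "identity") -> sp.csr_matrix:
    """Diagonal Hodge star S_k on the full grid.

    ``identity`` (default): unit dual/primal volume ratios on the unit
    grid, i.e. the identity matrix.  ``clipped``: dual-cell volumes are
    clipped against the grid domain [0, n-1] per axis, so entries drop to
    1/2 (or 1/4, 1/8) near the grid boundary.  Both are symmetric
    positive definite; kernel dimensions downstream are unaffected by the
    choice.
    """
    grid._check_degree(k)
    n = grid.n_cells(k)
    if mode == "identity":
        return sp.identity(n, dtype=np.float64, format="csr")
    if mode != "clipped":
        raise ValueError(f"unknown hodge star mode {mode!r}")
    diag = np.empty(n)
    offsets = grid.block_offsets(k)
    for s, axes in enumerate(grid.axis_subsets(k)):
        shape = grid.cell_block_shape(axes)
        block = np.ones(shape)
        for a, n_a in enumerate(grid.vertex_shape):
            if a in axes:
                continue  # primal extent along spanned axes: unit length
            # dual extent along axis a: overlap of [c-1/2, c+1/2] with [0, n_a-1]
            w = np.ones(n_a)
            w[0] = 0.5
            w[-1] = 0.5
            sl = [None] * len(shape)
            sl[a] = slice(None)
            block = block * w[tuple(sl)]
        m = prod(shape)
        diag[offsets[s] : offsets[s] + m] = block.reshape(m)
    return sp.diags(diag, format="csr")


def export_triplets(op: sp.spmatrix, path) -> None:
    """Write a sparse operator as ``row col value`` text lines (debug aid)."""
    coo = sp.coo_matrix(op)
    with open(path, "w") as fh:
        fh.write(f"% shape {coo.shape[0]} {coo.shape[1]} nnz {coo.nnz}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {v:.17g}\n")
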
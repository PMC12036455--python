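"""Discrete manifolds with boundary: foreground segmentation and supports.

An image is turned into a discrete manifold M by thresholding its
vertices.  Two cell subsets of the ambient grid realize the two boundary
conditions of the Hodge-Morrey decomposition:

* normal support: every cell with at least one vertex inside M
  (a dilation-like closure; projected operators carry the normal /
  Dirichlet condition because half-included edges pin the potential to
  zero just outside M);
* tangential support: every cell with at least one vertex of its dual
  cell inside M, where a dual vertex (top-cell center) counts as inside
  iff all 2^m vertices of its top cell are inside (an erosion-like
  interior approximation).

Projection matrices P_{k,b} are the identity with rows of excluded cells
removed, and projected operators are P_{k+1,b} D_k P_{k,b}^T etc.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iterproduct

import numpy as np
import scipy.sparse as sp

from .grid import GridSpec, exterior_derivative, hodge_star

__all__ = [
    "segment_vertices",
    "SupportComplex",
    "normal_support",
    "tangential_support",
    "project",
]


def segment_vertices(image: np.ndarray, threshold: float = 0.0, mode: str = "above") -> np.ndarray:
    """Boolean foreground mask from a scalar image by strict thresholding.

    ``above`` keeps the superlevel set {I > t}; ``below`` the sublevel
    set {I < t}.  The image shape is the grid vertex shape.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D scalar image, got ndim={image.ndim}")
    if mode == "above":
        return image > threshold
    if mode == "below":
        return image < threshold
    raise ValueError(f"mode must be 'above' or 'below', got {mode!r}")


@dataclass
class SupportComplex:
    """Cells of the grid retained under one boundary condition.

    ``included[k]`` is a boolean over the full grid's k-cells in the
    canonical flat order; ``projection(k)`` returns the binary matrix
    P_{k,b} with one row per included cell.
    """

    grid: GridSpec
    boundary: str  # "normal" | "tangential"
    included: list[np.ndarray]

    def __post_init__(self):
        for k, inc in enumerate(self.included):
            if inc.shape != (self.grid.n_cells(k),):
                raise ValueError(f"included[{k}] has wrong length")

    @property
    def dim(self) -> int:
        return self.grid.dim

    def n_cells(self, k: int) -> int:
        return int(self.included[k].sum())

    @property
    def is_empty(self) -> bool:
        return all(self.n_cells(k) == 0 for k in range(self.dim + 1))

    def projection(self, k: int) -> sp.csr_matrix:
        """P_{k,b}: identity with rows of excluded k-cells removed."""
        cols = np.flatnonzero(self.included[k])
        rows = np.arange(cols.size)
        data = np.ones(cols.size)
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(cols.size, self.grid.n_cells(k))
        )

    def derivative(self, k: int) -> sp.csr_matrix:
        """Projected exterior derivative D_{k,b} = P_{k+1} D_k P_k^T."""
        D = exterior_derivative(self.grid, k)
        return self.projection(k + 1) @ D @ self.projection(k).T

    def star(self, k: int, star_mode: str = "identity") -> sp.csr_matrix:
        """Projected Hodge star S_{k,b} = P_k S_k P_k^T (diagonal, positive)."""
        S = hodge_star(self.grid, k, mode=star_mode)
        return self.projection(k) @ S @ self.projection(k).T

    def restrict(self, values: np.ndarray, k: int) -> np.ndarray:
        """Restrict a full-grid k-cochain to the support cells."""
        return np.asarray(values)[self.included[k]]

    def extend(self, values: np.ndarray, k: int) -> np.ndarray:
        """Zero-extend a support k-cochain to the full grid."""
        out = np.zeros(self.grid.n_cells(k), dtype=np.asarray(values).dtype)
        out[self.included[k]] = values
        return out

    def summary(self) -> str:
        lines = [f"{self.boundary} support on grid {self.grid.vertex_shape}:"]
        for k in range(self.dim + 1):
            lines.append(
                f"  {self.n_cells(k)} of {self.grid.n_cells(k)} {k}-cells"
            )
        return "\n".join(lines)


def _included_blocks(grid: GridSpec, k: int, block_fn) -> np.ndarray:
    """Assemble the flat inclusion mask at degree k from a per-subset rule."""
    parts = []
    for axes in grid.axis_subsets(k):
        inc = block_fn(axes)
        parts.append(inc.reshape(-1))
    return np.concatenate(parts) if parts else np.zeros(0, dtype=bool)


def normal_support(grid: GridSpec, mask: np.ndarray) -> SupportComplex:
    """Cells with at least one vertex inside the mask."""
    mask = _check_mask(grid, mask)

    def block(axes):
        shape = grid.cell_block_shape(axes)
        inc = np.zeros(shape, dtype=bool)
        for corner in iterproduct(*(((0, 1) if a in axes else (0,)) for a in range(grid.dim))):
            sl = tuple(
                slice(c, c + s) for c, s in zip(corner, shape)
            )
            inc |= mask[sl]
        return inc

    included = [_included_blocks(grid, k, block) for k in range(grid.dim + 1)]
    return SupportComplex(grid, "normal", included)


def tangential_support(grid: GridSpec, mask: np.ndarray) -> SupportComplex:
    """Cells with at least one incident interior top cell.

    A top cell is interior iff all of its 2^m vertices are inside; its
    center is the dual vertex of the tangential rule.
    """
    mask = _check_mask(grid, mask)
    m = grid.dim
    interior = np.ones(tuple(n - 1 for n in grid.vertex_shape), dtype=bool)
    for corner in iterproduct((0, 1), repeat=m):
        sl = tuple(slice(c, c + n - 1) for c, n in zip(corner, grid.vertex_shape))
        interior &= mask[sl]

    # pad with False so shifted reads outside the top-cell range vanish
    padded = np.pad(interior, 1, constant_values=False)

    def block(axes):
        shape = grid.cell_block_shape(axes)
        inc = np.zeros(shape, dtype=bool)
        free = [a for a in range(m) if a not in axes]
        for deltas in iterproduct((0, 1), repeat=len(free)):
            # top cell anchored at (anchor - delta) on free axes, anchor on spanned axes
            sl = []
            for a in range(m):
                if a in axes:
                    sl.append(slice(1, 1 + shape[a]))
                else:
                    d = deltas[free.index(a)]
                    sl.append(slice(1 - d, 1 - d + shape[a]))
            inc |= padded[tuple(sl)]
        return inc

    included = [_included_blocks(grid, k, block) for k in range(m + 1)]
    return SupportComplex(grid, "tangential", included)


def project(op: sp.spmatrix, support: SupportComplex, k_row: int, k_col: int) -> sp.csr_matrix:
    """Sandwich a full-grid operator between projections: P_row op P_col^T."""
    if op.shape != (support.grid.n_cells(k_row), support.grid.n_cells(k_col)):
        raise ValueError(
            f"operator shape {op.shape} does not match degrees ({k_row}, {k_col})"
        )
    return support.projection(k_row) @ op @ support.projection(k_col).T


def _check_mask(grid: GridSpec, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.vertex_shape:
        raise ValueError(
            f"mask shape {mask.shape} != grid vertex shape {grid.vertex_shape}"
        )
    return mask
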
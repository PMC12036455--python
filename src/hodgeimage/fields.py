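"""Lifting an image to an edge 1-form.

Two-step, noise-resilient construction: first a per-vertex vector field
by centered finite differences of the intensity, then averaging each
component onto the parallel edges of the grid, giving a discrete 1-form
on the support edges.  Border vertices use replicate padding, so the
centered difference degrades gracefully to a half one-sided difference
at the image frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .supports import SupportComplex

__all__ = ["VertexField", "EdgeOneForm", "vertex_gradient", "edge_average"]


@dataclass
class VertexField:
    """Per-vertex vector field; components[a] has the vertex shape."""

    components: np.ndarray  # (m, *vertex_shape)

    @property
    def dim(self) -> int:
        return self.components.shape[0]


@dataclass
class EdgeOneForm:
    """A degree-1 cochain on the included edges of a support complex."""

    support: SupportComplex
    values: np.ndarray  # one value per included edge, canonical order

    def __post_init__(self):
        if self.values.shape != (self.support.n_cells(1),):
            raise ValueError("edge value count does not match support")

    def to_full(self) -> np.ndarray:
        """Zero-extended full-grid edge vector."""
        return self.support.extend(self.values, 1)

    def axis_arrays(self) -> list[np.ndarray]:
        """Per-axis full-grid edge arrays (zeros off the support)."""
        grid = self.support.grid
        full = self.to_full()
        out = []
        for s, axes in enumerate(grid.axis_subsets(1)):
            shape = grid.cell_block_shape(axes)
            off = grid.block_offsets(1)[s]
            n = int(np.prod(shape))
            out.append(full[off : off + n].reshape(shape))
        return out


def scalar_intensity(image: np.ndarray, channel_weights=None) -> np.ndarray:
    """Collapse a channel-last multi-channel 2D image to one scalar field.

    Default: unweighted channel mean; pass luminance-style weights to
    override.  Grayscale inputs pass through unchanged.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3 and image.shape[-1] in (3, 4):
        w = channel_weights
        if w is None:
            w = np.ones(image.shape[-1]) / image.shape[-1]
        return image @ np.asarray(w, dtype=np.float64)
    return image


def vertex_gradient(image: np.ndarray) -> VertexField:
    """Centered-difference gradient at every vertex (divisor 2 interior).

    component a at vertex v: (I(v + e_a) - I(v - e_a)) / 2, with
    replicate padding beyond the frame.
    """
    image = np.asarray(image, dtype=np.float64)
    m = image.ndim
    padded = np.pad(image, 1, mode="edge")
    comps = np.empty((m,) + image.shape)
    for a in range(m):
        hi = [slice(1, 1 + n) for n in image.shape]
        lo = [slice(1, 1 + n) for n in image.shape]
        hi[a] = slice(2, 2 + image.shape[a])
        lo[a] = slice(0, image.shape[a])
        comps[a] = (padded[tuple(hi)] - padded[tuple(lo)]) / 2.0
    return VertexField(comps)


def edge_average(field: VertexField, support: SupportComplex) -> EdgeOneForm:
    """Average each vector component onto the parallel support edges.

    An axis-a edge from vertex v to v + e_a carries
    (field_a(v) + field_a(v + e_a)) / 2.
    """
    grid = support.grid
    if field.components.shape[1:] != grid.vertex_shape:
        raise ValueError("vertex field shape does not match grid")
    parts = []
    for axes in grid.axis_subsets(1):
        a = axes[0]
        comp = field.components[a]
        lo = [slice(None)] * grid.dim
        hi = [slice(None)] * grid.dim
        lo[a] = slice(0, grid.vertex_shape[a] - 1)
        hi[a] = slice(1, grid.vertex_shape[a])
        parts.append(((comp[tuple(lo)] + comp[tuple(hi)]) / 2.0).reshape(-1))
    full = np.concatenate(parts)
    return EdgeOneForm(support, full[support.included[1]])


def lift_image(image: np.ndarray, support: SupportComplex) -> EdgeOneForm:
    """Full two-step lift: vertex gradient then edge averaging."""
    return edge_average(vertex_gradient(scalar_intensity(image)), support)
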
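"""Cube-averaged multi-channel images from decomposed 1-forms.

Each component 1-form eta is re-expressed as a vector field on the top
cells (cubes in 3D, faces in 2D): the axis-a component of a top cell is
the mean of its parallel axis-a edges (4 in 3D, 2 in 2D), with edges
outside the support contributing zero and a fixed divisor — this keeps
the map linear and deterministic.  Stacking the three components gives
the 9-channel (3D) or 6-channel (2D) decomposed image consumed by the
classifier; its spatial extent is one less than the vertex extent per
axis.

Channel order: component-major (curl-free, divergence-free, harmonic),
axis-minor (x, y[, z]).
"""

from __future__ import annotations

from itertools import product as iterproduct

import numpy as np

from .decomposition import DecomposedField
from .fields import EdgeOneForm

__all__ = ["cube_average", "assemble_channels", "CHANNEL_ORDER_2D", "CHANNEL_ORDER_3D"]

CHANNEL_ORDER_2D = [
    "curl_free_x", "curl_free_y",
    "div_free_x", "div_free_y",
    "harmonic_x", "harmonic_y",
]
CHANNEL_ORDER_3D = [
    "curl_free_x", "curl_free_y", "curl_free_z",
    "div_free_x", "div_free_y", "div_free_z",
    "harmonic_x", "harmonic_y", "harmonic_z",
]


def cube_average(eta: EdgeOneForm) -> np.ndarray:
    """Per-top-cell vectors, shape (m, *(vertex_extent - 1)).

    Axis-a component of the top cell anchored at p: the mean over
    shifts delta in {0,1}^(axes != a) of eta(e^a_{p+delta}), missing
    edges reading as zero.
    """
    grid = eta.support.grid
    m = grid.dim
    top_shape = tuple(n - 1 for n in grid.vertex_shape)
    axis_edges = eta.axis_arrays()  # zeros off the support
    out = np.zeros((m,) + top_shape)
    for a in range(m):
        comp = np.zeros(top_shape)
        others = [ax for ax in range(m) if ax != a]
        for deltas in iterproduct((0, 1), repeat=m - 1):
            sl = [slice(0, top_shape[ax]) for ax in range(m)]
            for d, ax in zip(deltas, others):
                sl[ax] = slice(d, d + top_shape[ax])
            comp += axis_edges[a][tuple(sl)]
        out[a] = comp / (2 ** (m - 1))
    return out


def assemble_channels(decomposed: DecomposedField) -> np.ndarray:
    """Stack cube-averaged components into the decomposed image.

    Returns (6, H-1, W-1) in 2D or (9, D-1, H-1, W-1) in 3D, channels in
    CHANNEL_ORDER_* order.
    """
    parts = [
        cube_average(decomposed.omega1),
        cube_average(decomposed.omega2),
        cube_average(decomposed.omega3),
    ]
    return np.concatenate(parts, axis=0)


def channel_names(dim: int) -> list[str]:
    if dim == 2:
        return list(CHANNEL_ORDER_2D)
    if dim == 3:
        return list(CHANNEL_ORDER_3D)
    raise ValueError(f"dim must be 2 or 3, got {dim}")
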
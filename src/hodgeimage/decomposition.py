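"""Discrete Hodge-Morrey decomposition of edge 1-forms.

An edge 1-form omega on a support complex splits orthogonally (in the
S_1 inner product) into

    omega = omega1 + omega2 + omega3,

* omega1 = D_0 W_n:  the curl-free (exact) part.  On the normal support
  the projected derivative carries the Dirichlet condition — edges with
  one endpoint outside the mask pin the scalar potential to zero beyond
  the manifold — so W_n is a normal 0-form potential.
* omega2 = S_1^{-1} D_1^T S_2 W_t:  the divergence-free (coexact) part,
  with a 2-cochain potential free on the support faces; the tangential
  condition holds weakly through the adjoint codifferential.
* omega3 = omega - omega1 - omega2: the harmonic residual, which lies in
  ker L_{1,b}, so its dimension is a Betti number of the manifold
  (beta_1 in 2D; beta_1 for the tangential and beta_2 for the normal
  support in 3D).

Both potentials are obtained by conjugate gradients on the normal
equations from a zero initial guess; the iterates stay in range(A), so
the returned potential is the kernel-orthogonal (gauge-fixed)
representative and the component fields are the unique orthogonal
projections.  Orthogonality of omega1 and omega2 is exact (dd = 0); the
residual's orthogonality is limited only by the solver tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import EdgeOneForm, lift_image
from .grid import GridSpec
from .supports import SupportComplex, normal_support, tangential_support, segment_vertices

__all__ = [
    "DecomposedField",
    "solve_curl_free",
    "solve_div_free",
    "decompose_edge_form",
    "hodge_decompose",
]


@dataclass
class DecomposedField:
    support: SupportComplex
    star_mode: str
    omega: EdgeOneForm
    omega1: EdgeOneForm  # curl-free (exact)
    omega2: EdgeOneForm  # divergence-free (coexact)
    omega3: EdgeOneForm  # harmonic residual
    w_n: np.ndarray      # scalar potential on support vertices
    w_t: np.ndarray      # 2-cochain potential on support faces
    diagnostics: dict = field(default_factory=dict)

    def energies(self) -> dict:
        """S_1 energies of the input and the three components."""
        s = self.support.star(1, self.star_mode).diagonal()

        def e(f):
            return float(f.values @ (s * f.values))

        return {
            "omega": e(self.omega),
            "curl_free": e(self.omega1),
            "div_free": e(self.omega2),
            "harmonic": e(self.omega3),
        }


def _cg(A: sp.spmatrix, b: np.ndarray, tol: float, maxiter: int, scale: float = 0.0):
    """CG from a zero start; ``scale`` is the problem's natural magnitude
    (the norm of omega), so right-hand sides at roundoff level resolve to
    the zero potential instead of a hopeless solve."""
    bnorm = np.linalg.norm(b)
    scale = max(scale, bnorm)
    if bnorm == 0 or A.shape[0] == 0 or bnorm <= 1e-13 * scale:
        return np.zeros(A.shape[1]), 0.0, 0
    it = [0]

    def cb(xk):
        it[0] += 1

    x, info = spla.cg(A, b, x0=np.zeros_like(b), rtol=tol,
                      atol=1e-14 * scale, maxiter=maxiter, callback=cb)
    resid = float(np.linalg.norm(A @ x - b) / bnorm)
    if info > 0 and np.linalg.norm(A @ x - b) > 1e-8 * scale:
        warnings.warn(
            f"CG did not reach tolerance (relative residual {resid:.2e})",
            RuntimeWarning,
        )
    return x, resid, it[0]


def solve_curl_free(
    omega: EdgeOneForm,
    support: SupportComplex | None = None,
    star_mode: str = "identity",
    tol: float = 1e-10,
    maxiter: int | None = None,
) -> tuple[np.ndarray, EdgeOneForm, dict]:
    """Least-squares scalar potential: minimize ||D_0 W - omega||_{S_1}."""
    support = support or omega.support
    D0 = support.derivative(0)
    S1 = support.star(1, star_mode)
    A = (D0.T @ S1 @ D0).tocsr()
    b = D0.T @ (S1 @ omega.values)
    n = A.shape[0]
    w, resid, iters = _cg(A, b, tol, maxiter or max(10 * n, 100),
                          scale=float(np.linalg.norm(omega.values)))
    omega1 = EdgeOneForm(support, D0 @ w)
    return w, omega1, {"residual": resid, "iterations": iters}


def solve_div_free(
    omega: EdgeOneForm,
    support: SupportComplex | None = None,
    star_mode: str = "identity",
    tol: float = 1e-10,
    maxiter: int | None = None,
) -> tuple[np.ndarray, EdgeOneForm, dict]:
    """Least-squares 2-cochain potential for the coexact component.

    Minimizes ||C W - omega||_{S_1} with C = S_1^{-1} D_1^T S_2; the
    normal equations reduce to S_2 D_1 S_1^{-1} D_1^T S_2 W = S_2 D_1 omega.
    """
    support = support or omega.support
    if support.n_cells(2) == 0:
        warnings.warn("empty degree-2 support: divergence-free part is zero",
                      RuntimeWarning)
        zero = EdgeOneForm(support, np.zeros(support.n_cells(1)))
        return np.zeros(0), zero, {"residual": 0.0, "iterations": 0}
    D1 = support.derivative(1)
    S1 = support.star(1, star_mode)
    S2 = support.star(2, star_mode)
    S1_inv = sp.diags(1.0 / S1.diagonal(), format="csr")
    A = (S2 @ D1 @ S1_inv @ D1.T @ S2).tocsr()
    b = S2 @ (D1 @ omega.values)
    n = A.shape[0]
    w, resid, iters = _cg(A, b, tol, maxiter or max(10 * n, 100),
                          scale=float(np.linalg.norm(omega.values)))
    omega2 = EdgeOneForm(support, S1_inv @ (D1.T @ (S2 @ w)))
    return w, omega2, {"residual": resid, "iterations": iters}


def decompose_edge_form(
    omega: EdgeOneForm,
    star_mode: str = "identity",
    tol: float = 1e-10,
    maxiter: int | None = None,
) -> DecomposedField:
    """Split an edge 1-form into curl-free + divergence-free + harmonic.

    The two solves run independently against the same omega (the target
    subspaces are orthogonal) and the harmonic part is the exact
    residual, so reconstruction holds at bit level.
    """
    support = omega.support
    w_n, omega1, d1 = solve_curl_free(omega, support, star_mode, tol, maxiter)
    w_t, omega2, d2 = solve_div_free(omega, support, star_mode, tol, maxiter)
    omega3 = EdgeOneForm(support, omega.values - omega1.values - omega2.values)
    return DecomposedField(
        support=support,
        star_mode=star_mode,
        omega=omega,
        omega1=omega1,
        omega2=omega2,
        omega3=omega3,
        w_n=w_n,
        w_t=w_t,
        diagnostics={"curl_free": d1, "div_free": d2},
    )


def hodge_decompose(
    image: np.ndarray,
    threshold: float = 0.0,
    mode: str = "above",
    boundary: str = "normal",
    star_mode: str = "identity",
    tol: float = 1e-10,
    maxiter: int | None = None,
) -> DecomposedField:
    """End-to-end: segment, lift to an edge 1-form, and decompose.

    ``boundary`` selects the support complex carrying the decomposition:
    ``normal`` (default; harmonic residual counts loops in 2D and voids
    in 3D) or ``tangential`` (loops in both).
    """
    from .fields import scalar_intensity

    scalar = scalar_intensity(image)
    mask = segment_vertices(scalar, threshold, mode)
    if not mask.any():
        raise ValueError(
            f"segmentation with threshold={threshold} mode={mode!r} "
            "produced an empty manifold"
        )
    grid = GridSpec(mask.shape)
    build = normal_support if boundary == "normal" else tangential_support
    support = build(grid, mask)
    omega = lift_image(scalar, support)
    return decompose_edge_form(omega, star_mode, tol, maxiter)
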
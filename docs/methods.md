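# Methods

## Images as discrete manifolds with boundary

A 2D or 3D grayscale image is treated as a scalar field on the vertices
of a unit-spacing Cartesian grid (pixel `(i, j[, k])` = vertex
`(i, j[, k])`, axis 0 called x). Strict thresholding (`I > t` by
default, `I < t` for sublevel sets) marks foreground vertices; the
foreground defines the discrete manifold `M`. Two cell subsets of the
ambient cubical complex realize the two boundary conditions needed for
an orthogonal Hodge–Morrey decomposition on a manifold with boundary:

* **normal support** — every cell with at least one vertex inside `M`
  (a dilation-like closure);
* **tangential support** — every cell incident to an *interior top
  cell*, i.e. a pixel/voxel cell all of whose `2^m` corners are inside
  (an erosion-like interior). This is the dual-vertex rule: a top-cell
  center counts as inside exactly when its cell is interior. It makes
  the tangential support a subset of the normal support and gives the
  two supports the erosion/dilation duality that the kernel theorems
  require; the Betti test suite (spectral vs. combinatorial oracle) is
  the arbiter of this convention and passes on every fixture.

Projection matrices `P_{k,b}` (identity with rows of excluded cells
removed) restrict the full-grid exterior derivative `D_k` and Hodge star
`S_k` to each support: `D_{k,b} = P_{k+1,b} D_k P_{k,b}^T`,
`S_{k,b} = P_{k,b} S_k P_{k,b}^T`.

Cells are ordered lexicographically by spanned-axes subset and then by
anchor in row-major order, and oriented by increasing coordinate axes;
the standard cubical boundary signs make `D_{k+1} D_k = 0` exact in
integer arithmetic, and the same identity survives projection to either
support (an excluded cell's faces never meet an included cell's
coboundary).

## Hodge stars

The default star is the identity (unit grid, unit dual/primal volume
ratios). An optional `clipped` mode weights each diagonal entry by the
dual-cell volume clipped against the grid domain, so entries fall to
1/2, 1/4, 1/8 at grid faces, edges and corners. Kernel dimensions of the
Laplacians — the topological content — are invariant under any positive
diagonal reweighting, which the tests verify; the clipped mode exists
for users who want boundary-aware metric weights.

## Laplacians and the topology guarantee

The degree-k Hodge Laplacian under boundary condition `b` is

    L_{k,b} = D_{k,b}^T S_{k+1,b} D_{k,b}
            + S_{k,b} D_{k-1,b} S_{k-1,b}^{-1} D_{k-1,b}^T S_{k,b},

with the undefined term dropped at `k = 0` and `k = m`. For diagonal
positive stars both terms are congruences, so this matrix is symmetric
positive semidefinite as written; it equals `S_k Δ` with
`Δ = δd + dδ` the operator self-adjoint in the `S_k` inner product.
Spectra are computed on the conjugated form `S^{-1/2} L S^{-1/2}`, which
shares the spectrum of `Δ` — not because symmetrization is needed, but
because its eigenvectors map back to `S_k`-orthonormal cochains.

`dim ker L_{k,t} = β_k` and `dim ker L_{k,n} = β_{m−k}`: kernel
dimensions are Betti numbers of the discrete manifold (components,
loops, voids). Eigenvalues below `1e−8 · max(λ_max, 1)` count as zero
(the spectra show a clean gap of many orders of magnitude on all
fixtures; the cut is configurable). Operators with fewer than 3000 cells
are decomposed densely; larger ones use shift-invert Lanczos with a
fixed start vector, retried densely on non-convergence.

This guarantee holds for *thick* foregrounds: if a structure is about
two cells thin, the eroded tangential support degenerates and no longer
shares the homotopy type of the ideal shape. The fixture generators
therefore keep radial widths of three or more cells.

## Lifting an image to a 1-form

A two-step, noise-resilient lift: centered differences
`(I(v+e_a) − I(v−e_a))/2` give a per-vertex vector field (replicate
padding at the frame, so border differences degrade to half one-sided
values rather than producing spurious frame gradients); each component
is then averaged onto the parallel edges,
`ω(e^a_v) = (f_a(v) + f_a(v+e_a))/2`. Multi-channel 2D images are
collapsed to one scalar by an unweighted channel mean (luminance weights
are accepted as an option). Both steps are linear and axis-equivariant.

## The decomposition

On a single support complex (default: normal), the edge 1-form splits as

    ω = ω₁ + ω₂ + ω₃

* `ω₁ = D_0 W_n` — curl-free. On the normal support the projected
  derivative has "half-edges" (one endpoint outside the mask) whose rows
  pin the scalar potential to zero just beyond `M`; this is the discrete
  Dirichlet (normal) boundary condition on `W_n`.
* `ω₂ = S_1^{-1} D_1^T S_2 W_t` — divergence-free, with a 2-cochain
  potential free on the support faces. The tangential condition on the
  coexact part holds weakly through the adjoint: no extra constraint is
  imposed, exactly as in mixed finite-element treatments of Neumann
  data.
* `ω₃ = ω − ω₁ − ω₂` — harmonic. Because `im D_0 ⊥ im δ` exactly
  (`dd = 0` plus diagonal stars), the residual lies in `ker L_{1,b}`,
  so its dimension is a Betti number: β₁ in 2D (either condition);
  β₁ for the tangential and β₂ for the normal support in 3D. Users who
  want loop-sensitive 3D harmonics should decompose on the tangential
  support.

A design note on the supports: assembling the exact part on the dilated
support while taking the coexact potential from the *eroded* support
looks natural but cannot be complete — counting dimensions, the leftover
space has dimension about the support perimeter (`F_n − F_t − χ`)
rather than β₁, so random fields on a disk would retain a large
"harmonic" residual. The single-support construction used here is the
one for which completeness (`ω₃ = 0` whenever β₁ = 0), exact
orthogonality, and the harmonic-kernel identity all hold, and the test
suite checks each of these against dense pseudoinverse oracles.

Both potentials solve least-squares problems via conjugate gradients on
the normal equations (relative tolerance 1e−10, iteration cap
10·unknowns, zero initial guess, plus an absolute floor of 1e−14 times
the field norm so roundoff-level right-hand sides resolve to the zero
potential). Starting CG from zero keeps every iterate in `range(A)`, so
the returned potential is automatically the kernel-orthogonal (gauge-
fixed) representative; the component fields `ω₁, ω₂` are the unique
orthogonal projections regardless of gauge. The two solves run
independently against the same `ω` (their target subspaces are
orthogonal), so each component is a projection and the decomposition is
idempotent and linear.

## Channel images

Each component 1-form is re-expressed on the top cells: the axis-a value
of a cube is the mean of its four parallel a-edges (Eq.-18-style
averaging); in 2D a face averages its two parallel edges. Edges outside
the support contribute zero *with the divisor fixed* at 4 (3D) / 2 (2D)
— dividing by the number of present edges instead would break linearity
and determinism, so it was rejected. Stacking the three components gives
6 channels in 2D and 9 in 3D, component-major (curl-free,
divergence-free, harmonic), axis-minor; the spatial extent is one less
than the vertex extent per axis and is fed to the classifier without
resampling or padding back to input resolution.

## Classifier

An initialization block (3-kernel convolution to hidden width `C`, batch
norm, ReLU) is followed by `N` encoder layers

    x'   = Norm(x + MultiHeadConv(x))      # post-norm residual
    x''  = Norm(x' + FeedForwardConv(x'))
    x''' = MaxPool(x'')                    # kernel 2, stride 2

then global average pooling and an MLP head (one hidden layer of width
`C` with ReLU). `MultiHeadConv` is a grouped 3-kernel convolution
`C → C·h` with `h` groups, ReLU, and a 1-kernel fusion back to `C`;
`FeedForwardConv` is two grouped 1-kernel convolutions `C → 2C → C`.
Both preserve spatial extents (padding 1 on 3-kernels); each encoder
layer halves every spatial extent. The literal post-norm reading
`Norm(x + f(x))` is implemented; batch normalization (momentum 0.1,
eps 1e−5), convolution biases everywhere. Inputs whose extents are not
divisible by `2^N` are center-padded with zeros.

Reference configurations: 2D `C=72, h=4, g=3` (g=1 for grayscale),
5 layers, 385,857 parameters; 3D `C=64, h=4, g=1`, 5 layers, 741,259
parameters. The MLP head width is a design choice (the budgets above sit
comfortably under 0.56M/0.75M, so a wider head would also fit).

The whole network stack is plain NumPy with hand-written backward
passes (grouped N-d convolution via im2col, batch-norm, max-pool,
linear), an AdamW optimizer (decoupled weight decay 1e−5) and a cosine
one-cycle learning-rate schedule (peak 1e−3, warmup fraction 0.3,
initial division 25, final division 1e4). Training is bit-reproducible
for a fixed seed. Losses: softmax cross-entropy for single-label tasks,
binary cross-entropy with logits for multi-label ones.

The `TransConvClassifier` estimator standardizes each input channel to
zero mean and unit variance on the training set. The decomposed channels
span orders of magnitude (the harmonic part is typically 100× smaller
than the curl-free part), and without rescaling the batch-norm running
variances retain their initialization bias for the length of a short
training run, producing a large train/eval gap. Standardization is part
of the estimator contract and is applied consistently at prediction
time; it can be disabled (`standardize=False`).

## Synthetic fixtures and the independent oracle

Generators produce masks of known topology — disks, annuli, multi-loop
rings, blob pairs, 3D balls, solid tori, hollow shells — plus smooth
intensities (band-limited Gaussian-filtered noise, positive on the mask)
and exactly linear ramps. Every generator is a pure function of
`(spec, seed)`.

Betti numbers come from a combinatorial oracle that never touches the
Laplacian path: connected components by flood fill (8-/26-connectivity),
holes and voids as bounded complement components (4-/6-connectivity),
and in 3D the loop count from the Euler characteristic of the
all-vertices-inside cubical complex (`β₁ = β₀ + β₂ − χ`). The
oracle-equals-spectrum test over twenty fixtures, both boundary
conditions, every degree, is the central cross-validation of the
package.

What the synthetic data does *not* emulate: imaging noise models,
anisotropic voxels, partial-volume effects, texture, or anatomy. Passing
the synthetic benchmark shows the topology and decomposition machinery
is correct and that topological structure is learnable from the
decomposed channels; it says nothing about accuracy on clinical images.

## Problem sizes

Test and benchmark sizes are the package's own defaults: 2D grids of
24–64 per axis and 3D grids of 12–20 per axis (dense eigendecomposition
territory), 200-sample disk-vs-annulus classification on 32×32 images
with a reduced network (`C=24, h=2, g=2`, 3 layers, 10 epochs, batch
32). The full-scale reference configurations are instantiated and
parameter-counted but trained only by users with real datasets (the
MedMNIST-layout NPZ adapter and the `train` CLI accept them directly).

## Known limitations

* The guarantee `dim ker L = β` needs foreground structures at least ~3
  cells thick (see above).
* The decomposition's harmonic space on the normal support counts voids,
  not loops, in 3D; choose the tangential support for loop-sensitive 3D
  work.
* Physical pixel spacing is out of scope: grids are index grids with
  unit spacing.
* Multi-label training is implemented (BCE with logits) but exercised
  only on synthetic targets in the tests.
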
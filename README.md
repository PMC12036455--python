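# hodgeimage

Topology-preserving discrete Hodge decomposition of 2D/3D images on
Cartesian grids, and a lightweight grouped-convolution classifier that
consumes the decomposed representation.

## What it does and for whom

Biomedical images (X-ray, CT, microscopy, MRA, …) are naturally scalar
fields on Cartesian grids, i.e. discretized manifolds. This package
models an image's foreground as a discrete manifold with boundary, lifts
the image to a vector field (an edge 1-form ω), and splits it
orthogonally by the Hodge–Morrey decomposition

    ω = dα_n + δγ_t + η        (curl-free + divergence-free + harmonic)

realized with discrete exterior derivatives `D_k`, Hodge stars `S_k`,
and projection matrices `P_{k,b}` for normal/tangential boundary
conditions on cubical supports. The kernels of the Hodge Laplacians

    L_{k,b} = D_{k,b}^T S_{k+1,b} D_{k,b} + S_{k,b} D_{k−1,b} S_{k−1,b}^{−1} D_{k−1,b}^T S_{k,b}

carry the foreground's topology exactly: `dim ker L_{k,t} = β_k` and
`dim ker L_{k,n} = β_{m−k}` (components, loops, voids). The three
components, averaged onto pixel/voxel centers, form a 6-channel (2D) or
9-channel (3D) image for a small Transformer-encoder-shaped CNN
(grouped-convolution "attention" and "feed-forward" blocks with
post-norm residuals and stride-2 pooling; ≈0.39M parameters in the 2D
reference configuration, ≈0.74M in 3D).

Intended users: researchers in topological/geometric image analysis who
want an exact, testable discrete Hodge stack, and anyone who wants to
feed topology-aware channel images to a compact classifier.

## Worked example

```python
import numpy as np
from hodgeimage import (FixtureSpec, make_intensity, segment_vertices,
                        betti_numbers, hodge_decompose, assemble_channels)

# synthetic image whose foreground is three disjoint rings
img = make_intensity(FixtureSpec("multi_annulus", (64, 64), seed=0))

print("betti:", betti_numbers(segment_vertices(img, 0.0)))
dec = hodge_decompose(img, threshold=0.0)
for name, e in dec.energies().items():
    print(f"{name:>10}: {e:.4f}")
print("channels:", assemble_channels(dec).shape)
```

prints

```
betti: (3, 3)
     omega: 253.4500
 curl_free: 244.2884
  div_free: 9.0941
  harmonic: 0.0675
channels: (6, 63, 63)
```

`betti: (3, 3)` — the Laplacian kernels see three connected components
and three loops, matching the geometry. The energy table is the
Pythagorean split of ω: the lift of a smooth intensity is dominated by
its gradient (curl-free) part, while the small harmonic part lives
exactly in the 3-dimensional kernel of `L_{1,n}` — the signature of the
three rings that a disk image would lack entirely.

Classification composes as a scikit-learn pipeline:

```python
from sklearn.pipeline import Pipeline
from hodgeimage import HodgeDecomposition, TransConvClassifier, make_classification_set

ds = make_classification_set(n=200, kinds=("disk", "annulus"), seed=1)
pipe = Pipeline([("decompose", HodgeDecomposition()),
                 ("classify", TransConvClassifier(epochs=10, seed=0))])
pipe.fit(ds["images"][ds["train"]], ds["labels"][ds["train"]])
print(pipe.score(ds["images"][ds["test"]], ds["labels"][ds["test"]]))  # 1.0
```

There is also a thin CLI: `hodgeimage spectra|decompose|fixtures|train|predict`
(see `hodgeimage --help`); `train` accepts MedMNIST-layout NPZ archives.

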
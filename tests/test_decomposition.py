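"""Orthogonal splitting of edge 1-forms into exact/coexact/harmonic parts."""

import numpy as np
import pytest

from hodgeimage import (
    EdgeOneForm,
    GridSpec,
    decompose_edge_form,
    harmonic_spectrum,
    hodge_decompose,
    laplacian,
    normal_support,
    solve_curl_free,
    solve_div_free,
    tangential_support,
)
from hodgeimage.fixtures import FixtureSpec, make_intensity, make_mask
from conftest import random_mask


def s1_inner(sup, a, b, star_mode="identity"):
    s = sup.star(1, star_mode).diagonal()
    return float(a @ (s * b))


def test_exact_input_is_recovered(disk_support, rng):
    """omega = D_0 f comes back entirely in the curl-free part."""
    sup = disk_support
    f = rng.standard_normal(sup.n_cells(0))
    omega = EdgeOneForm(sup, sup.derivative(0) @ f)
    dec = decompose_edge_form(omega)
    assert np.abs(dec.omega1.values - omega.values).max() < 1e-8
    assert np.abs(dec.omega2.values).max() < 1e-8
    assert np.abs(dec.omega3.values).max() < 1e-8


def test_coexact_input_is_recovered(disk_support, rng):
    sup = disk_support
    g = rng.standard_normal(sup.n_cells(2))
    coexact = sup.derivative(1).T @ g  # identity stars
    omega = EdgeOneForm(sup, coexact)
    dec = decompose_edge_form(omega)
    assert np.abs(dec.omega2.values - omega.values).max() < 1e-8
    assert np.abs(dec.omega1.values).max() < 1e-8


def test_zero_input_gives_zero_parts(disk_support):
    dec = decompose_edge_form(EdgeOneForm(disk_support, np.zeros(disk_support.n_cells(1))))
    for part in (dec.omega1, dec.omega2, dec.omega3):
        assert np.abs(part.values).max() == 0.0


def test_divergence_free_component_is_coclosed(annulus_support, rng):
    """The codifferential of omega2 vanishes: D_0^T S_1 omega2 = 0."""
    sup = annulus_support
    omega = EdgeOneForm(sup, rng.standard_normal(sup.n_cells(1)))
    _, omega2, info = solve_div_free(omega)
    resid = sup.derivative(0).T @ (sup.star(1).diagonal() * omega2.values)
    assert np.abs(resid).max() < 1e-7
    assert info["residual"] < 1e-9


def test_disk_has_no_harmonic_part(disk_support, rng):
    """On a contractible support the two potentials span everything."""
    sup = disk_support
    omega = EdgeOneForm(sup, rng.standard_normal(sup.n_cells(1)))
    dec = decompose_edge_form(omega)
    e = dec.energies()
    assert e["harmonic"] <= 1e-12 * e["omega"]
    assert np.abs(
        dec.omega.values - dec.omega1.values - dec.omega2.values
    ).max() < 1e-6 * np.abs(dec.omega.values).max()


@pytest.mark.parametrize("star_mode", ["identity", "clipped"])
def test_orthogonality_and_pythagoras_random_masks(rng, star_mode):
    """Pairwise S_1 orthogonality and the energy identity on 100 masks."""
    g = GridSpec((12, 12))
    n_checked = 0
    while n_checked < 100:
        mask = random_mask((12, 12), rng, p=0.55)
        sup = normal_support(g, mask)
        if sup.n_cells(1) < 4:
            continue
        omega = EdgeOneForm(sup, rng.standard_normal(sup.n_cells(1)))
        dec = decompose_edge_form(omega, star_mode=star_mode)
        total = s1_inner(sup, omega.values, omega.values, star_mode)
        parts = [dec.omega1.values, dec.omega2.values, dec.omega3.values]
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(s1_inner(sup, parts[i], parts[j], star_mode)) <= 1e-6 * total
        energy_sum = sum(s1_inner(sup, p, p, star_mode) for p in parts)
        assert abs(total - energy_sum) <= 1e-6 * total
        # reconstruction: the residual identity is bit-exact, and any
        # re-association of the sum agrees to a couple of ulps
        assert np.array_equal(
            dec.omega3.values, omega.values - dec.omega1.values - dec.omega2.values
        )
        recon = dec.omega1.values + dec.omega2.values + dec.omega3.values
        scale = np.abs(omega.values).max()
        assert np.abs(recon - omega.values).max() <= 4 * np.finfo(float).eps * scale
        n_checked += 1


def test_agreement_with_dense_pseudoinverse_oracle(rng):
    """Compare against direct lstsq projections on small supports."""
    for kind, shape in [("disk", (10, 10)), ("annulus", (14, 14))]:
        mask, _ = make_mask(FixtureSpec(kind, shape))
        sup = normal_support(GridSpec(shape), mask)
        assert sup.n_cells(1) <= 400
        omega = rng.standard_normal(sup.n_cells(1))
        dec = decompose_edge_form(EdgeOneForm(sup, omega))
        D0 = sup.derivative(0).toarray()
        C = sup.derivative(1).T.toarray()
        w1, *_ = np.linalg.lstsq(D0, omega, rcond=None)
        w2, *_ = np.linalg.lstsq(C, omega, rcond=None)
        scale = np.abs(omega).max()
        assert np.abs(dec.omega1.values - D0 @ w1).max() < 1e-8 * scale
        assert np.abs(dec.omega2.values - C @ w2).max() < 1e-8 * scale


def test_decomposition_is_idempotent(annulus_support, rng):
    sup = annulus_support
    omega = EdgeOneForm(sup, rng.standard_normal(sup.n_cells(1)))
    dec = decompose_edge_form(omega)
    again = decompose_edge_form(dec.omega1)
    scale = max(np.abs(dec.omega1.values).max(), 1e-30)
    assert np.abs(again.omega1.values - dec.omega1.values).max() < 1e-6 * scale
    assert np.abs(again.omega2.values).max() < 1e-6 * scale
    assert np.abs(again.omega3.values).max() < 1e-6 * scale


def test_harmonic_part_lies_in_laplacian_kernel(annulus_support, rng):
    """On an annulus, omega3 sits in the span of the harmonic basis."""
    sup = annulus_support
    omega = EdgeOneForm(sup, rng.standard_normal(sup.n_cells(1)))
    dec = decompose_edge_form(omega)
    spec = harmonic_spectrum(laplacian(sup, 1))
    assert spec.n_zero == 1
    h = dec.omega3.values
    B = spec.basis  # S_1-orthonormal columns
    s = sup.star(1).diagonal()
    proj = B @ (B.T @ (s * h))
    norm = np.sqrt(s1_inner(sup, h, h))
    assert np.linalg.norm(np.sqrt(s) * (h - proj)) <= 1e-6 * max(norm, 1e-30)


def test_linearity_in_the_input(disk_support, rng):
    sup = disk_support
    a = rng.standard_normal(sup.n_cells(1))
    b = rng.standard_normal(sup.n_cells(1))
    d_ab = decompose_edge_form(EdgeOneForm(sup, 2 * a - b))
    d_a = decompose_edge_form(EdgeOneForm(sup, a))
    d_b = decompose_edge_form(EdgeOneForm(sup, b))
    for part in ("omega1", "omega2", "omega3"):
        lhs = getattr(d_ab, part).values
        rhs = 2 * getattr(d_a, part).values - getattr(d_b, part).values
        assert np.abs(lhs - rhs).max() < 1e-7


def test_hodge_decompose_end_to_end_and_errors():
    spec = FixtureSpec("annulus", (24, 24), seed=3)
    img = make_intensity(spec)
    dec = hodge_decompose(img, threshold=0.0)
    assert dec.support.boundary == "normal"
    e = dec.energies()
    assert e["omega"] > 0
    # deterministic for fixed input
    dec2 = hodge_decompose(img, threshold=0.0)
    assert np.array_equal(dec.omega1.values, dec2.omega1.values)
    with pytest.raises(ValueError, match="threshold"):
        hodge_decompose(np.zeros((8, 8)), threshold=5.0)


def test_empty_tangential_degree2_warns():
    """A thin support has no faces: omega2 is zero with a warning."""
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 1:4] = True
    sup = tangential_support(GridSpec((5, 5)), mask)
    assert sup.n_cells(2) == 0
    omega = EdgeOneForm(sup, np.zeros(sup.n_cells(1)))
    with pytest.warns(RuntimeWarning):
        _, omega2, _ = solve_div_free(omega)
    assert omega2.values.size == 0 or np.abs(omega2.values).max() == 0.0
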
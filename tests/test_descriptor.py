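import numpy as np
import pytest

from rbc3d._sphharm import QuadratureError, SphericalHarmonicsBasis, get_basis, real_sph_harm
from rbc3d.descriptor import (
    DescriptorConfig,
    DescriptorError,
    build_descriptor,
    euclid_f0_f2,
    normalize_descriptor,
    sample_spherical_function,
    sh_decompose,
    voxelize_mesh,
)
from rbc3d.mesh import TriangleMesh, random_rotation
from rbc3d.shapes import ShapeSpec, make_canonical_mesh, morph_meshes, remesh_to_grid

# ------------------------------------------------------------------ SH basis oracle


def brute_force_coefficient(f, l, m, n_theta=501, n_phi=64):
    """Independent dense-quadrature oracle for integral(f * Y_lm dOmega):
    Simpson's rule in theta (error O(h^4) ~ 1e-9 at 501 nodes) and an
    equispaced sum in phi (exact for trigonometric polynomials)."""
    from scipy.integrate import simpson

    theta = np.linspace(0, np.pi, n_theta)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    vals = f(tt, pp) * real_sph_harm(l, m, tt, pp) * np.sin(tt)
    inner = simpson(vals, x=theta, axis=0)
    return float(inner.sum() * (2 * np.pi / n_phi))


def test_constant_function_a00():
    basis = get_basis(15)
    a = basis.analyze(np.ones(basis.n_points))
    assert a[basis.index(0, 0)] == pytest.approx(np.sqrt(4 * np.pi), abs=1e-10)
    rest = np.delete(a, basis.index(0, 0))
    assert np.abs(rest).max() < 1e-10


def test_pure_harmonic_recovered():
    basis = get_basis(15)
    f = real_sph_harm(3, 2, basis.theta, basis.phi)
    a = sh_decompose(f, n_freq=16, basis=basis)
    i = basis.index(3, 2)
    assert a[i] == pytest.approx(1.0, abs=1e-10)
    assert np.abs(np.delete(a, i)).max() < 1e-10


def test_decomposition_matches_brute_force_quadrature(rng):
    basis = get_basis(5)
    coeffs = rng.normal(size=basis.n_coeff)
    samples = basis.synthesize(coeffs)

    def f(tt, pp):
        out = np.zeros_like(tt)
        for i, (l, m) in enumerate(basis.lm):
            out += coeffs[i] * real_sph_harm(l, m, tt, pp)
        return out

    a = basis.analyze(samples)
    for l, m in [(0, 0), (1, -1), (2, 0), (3, 3), (4, -2), (5, 4)]:
        oracle = brute_force_coefficient(f, l, m)
        assert a[basis.index(l, m)] == pytest.approx(oracle, abs=1e-8)


def test_parseval(rng):
    basis = get_basis(15)
    coeffs = rng.normal(size=basis.n_coeff)
    f = basis.synthesize(coeffs)
    quad = float((basis.weights * f * f).sum())
    assert quad == pytest.approx((coeffs**2).sum(), abs=1e-8)


def test_parseval_per_band(rng):
    basis = get_basis(15)
    coeffs = rng.normal(size=basis.n_coeff)
    f = basis.synthesize(coeffs)
    a = basis.analyze(f)
    for l in range(16):
        band = basis.band_energies(a, [l])[0]
        manual = np.sqrt(sum(a[basis.index(l, m)] ** 2 for m in range(-l, l + 1)))
        assert band == pytest.approx(manual, abs=1e-10)


def test_reconstruction_exact_for_band_limited(rng):
    basis = get_basis(15)
    coeffs = rng.normal(size=basis.n_coeff)
    f = basis.synthesize(coeffs)
    assert np.abs(basis.analyze(f) - coeffs).max() < 1e-10


def test_quadrature_error_for_coarse_grid():
    with pytest.raises(QuadratureError):
        SphericalHarmonicsBasis(l_max=15, n_theta=8)


# ------------------------------------------------------------------ euclid scalars


def test_euclid_constant_function():
    basis = get_basis(15)
    c = 2.5
    coeffs = np.zeros(basis.n_coeff)
    coeffs[basis.index(0, 0)] = c * np.sqrt(4 * np.pi)  # f == c on the sphere
    out = euclid_f0_f2(coeffs, basis)
    assert np.allclose(out, [c, c, c], atol=1e-10)


def test_euclid_z_squared():
    basis = get_basis(15)
    f = basis.dirs[:, 2] ** 2
    coeffs = basis.analyze(f)
    out = euclid_f0_f2(coeffs, basis)
    assert np.allclose(out, [1.0, 0.0, 0.0], atol=1e-8)


def test_euclid_rotation_invariant_triple(rng):
    basis = get_basis(15)
    Q = rng.normal(size=(3, 3))
    Q = (Q + Q.T) / 2
    R = random_rotation(rng)
    f1 = np.einsum("pi,ij,pj->p", basis.dirs, Q, basis.dirs)
    f2 = np.einsum("pi,ij,pj->p", basis.dirs @ R.T, Q, basis.dirs @ R.T)
    t1 = euclid_f0_f2(basis.analyze(f1), basis)
    t2 = euclid_f0_f2(basis.analyze(f2), basis)
    assert np.allclose(t1, t2, atol=1e-8)


# ------------------------------------------------------------------ normalization


def test_normalize_examples():
    assert np.allclose(normalize_descriptor(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])


def test_normalize_idempotent():
    v = np.array([0.0, 0.3, 1.0])
    assert np.allclose(normalize_descriptor(v), v)


def test_normalize_constant_vector_warns():
    with pytest.warns(UserWarning):
        out = normalize_descriptor(np.array([5.0, 5.0, 5.0]))
    assert np.array_equal(out, np.zeros(3))


# ------------------------------------------------------------------ voxelization


def test_voxelize_solid_sphere_count(sphere_mesh):
    cfg = DescriptorConfig(occupancy_mode="solid")
    occ = voxelize_mesh(sphere_mesh, cfg)
    r_vox = 3.0 / cfg.um_per_voxel
    analytic = 4 / 3 * np.pi * r_vox**3
    assert abs(occ.sum() - analytic) / analytic < 0.05


def test_voxelize_empty_mesh_raises():
    with pytest.raises(DescriptorError):
        voxelize_mesh(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)))


def test_voxelize_translation_invariant(disc_mesh, descriptor_config):
    occ0 = voxelize_mesh(disc_mesh, descriptor_config)
    occ1 = voxelize_mesh(disc_mesh.translated([3.0, -2.0, 1.0]), descriptor_config)
    assert np.allclose(occ0, occ1, atol=1e-12)


def test_voxelize_scale_error_for_oversized_mesh():
    big = make_canonical_mesh(ShapeSpec("spherocyte", diameter_um=11.9))
    with pytest.raises(DescriptorError, match="exceeds"):
        voxelize_mesh(big, DescriptorConfig(um_per_voxel=0.08))


def test_voxelize_fit_to_grid_accepts_any_size():
    big = make_canonical_mesh(ShapeSpec("spherocyte", diameter_um=11.9))
    occ = voxelize_mesh(big, DescriptorConfig(scale_mode="fit_to_grid"))
    assert occ.max() > 0


# ------------------------------------------------------------------ spherical sampling


@pytest.fixture(scope="module")
def solid_ball_grid():
    cfg = DescriptorConfig(occupancy_mode="solid")
    mesh = make_canonical_mesh(ShapeSpec("spherocyte", diameter_um=6.4))  # radius 16 voxels
    return voxelize_mesh(mesh, cfg), cfg


def test_sample_inside_solid_ball_is_one(solid_ball_grid):
    occ, cfg = solid_ball_grid
    f = sample_spherical_function(occ, 8, cfg)
    assert np.allclose(f, 1.0, atol=1e-9)


def test_sample_outside_solid_ball_is_zero(solid_ball_grid):
    occ, cfg = solid_ball_grid
    f = sample_spherical_function(occ, 30, cfg)
    assert np.allclose(f, 0.0, atol=1e-9)


def test_sample_on_shell_close_to_one():
    cfg = DescriptorConfig()  # surface mode
    mesh = make_canonical_mesh(ShapeSpec("spherocyte", diameter_um=4.8))  # radius 12 voxels
    occ = voxelize_mesh(mesh, cfg)
    f = sample_spherical_function(occ, 12, cfg)
    assert np.mean(np.abs(f - 1.0) < 0.25) >= 0.90


def test_sample_radius_bounds(solid_ball_grid):
    occ, cfg = solid_ball_grid
    with pytest.raises(IndexError):
        sample_spherical_function(occ, 0, cfg)
    with pytest.raises(IndexError):
        sample_spherical_function(occ, 33, cfg)


# ------------------------------------------------------------------ full descriptor


def test_descriptor_length_544(sphere_mesh, descriptor_config):
    spec = build_descriptor(sphere_mesh, descriptor_config)
    assert len(spec.vector) == 544
    assert len(spec.normalized_vector) == 544
    assert descriptor_config.vector_length == 544


def test_descriptor_band_degrees_skip_0_and_2(descriptor_config):
    assert descriptor_config.band_degrees == (1, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)
    assert len(descriptor_config.band_degrees) == 14


def test_solid_sphere_descriptor_isotropic(sphere_mesh):
    cfg = DescriptorConfig(occupancy_mode="solid")
    spec = build_descriptor(sphere_mesh, cfg)
    # radius 15 voxels; the anti-aliasing ramp spans roughly 3 voxels
    ramp = np.abs(np.arange(1, 33) - 15) > 4
    assert spec.band_energies[ramp].max() < 1e-6
    assert spec.band_energies.max() < 0.12  # bounded even across the ramp
    inside = np.arange(1, 33) <= 10
    e = spec.euclid_scalars[inside]
    assert np.allclose(e[:, 0], e[:, 2], atol=1e-6)  # a1 == a3 inside


def test_descriptor_euclid_sorted_descending(disc_mesh, descriptor_config):
    spec = build_descriptor(disc_mesh, descriptor_config)
    assert (np.diff(spec.euclid_scalars, axis=1) <= 1e-12).all()


def test_descriptor_band_energies_nonnegative(disc_mesh, descriptor_config):
    spec = build_descriptor(disc_mesh, descriptor_config)
    assert (spec.band_energies >= 0).all()


def test_descriptor_normalized_range(disc_mesh, descriptor_config):
    v = build_descriptor(disc_mesh, descriptor_config).normalized_vector
    assert v.min() == 0.0
    assert v.max() == 1.0


def test_descriptor_rotation_invariance_quick(disc_mesh, descriptor_config, rng):
    v0 = build_descriptor(disc_mesh, descriptor_config).normalized_vector
    for _ in range(3):
        R = random_rotation(rng)
        v1 = build_descriptor(disc_mesh.rotated(R).center_to_bbox(), descriptor_config).normalized_vector
        assert np.linalg.norm(v1 - v0) / np.linalg.norm(v0) < 0.05


def test_descriptor_translation_invariance(disc_mesh, descriptor_config):
    v0 = build_descriptor(disc_mesh, descriptor_config).normalized_vector
    v1 = build_descriptor(disc_mesh.translated([1.0, 2.0, -0.5]), descriptor_config).normalized_vector
    assert np.allclose(v0, v1, atol=1e-12)


def test_descriptor_distance_monotone_along_morph():
    disc = make_canonical_mesh(ShapeSpec("discocyte", diameter_um=7.0))
    sph = make_canonical_mesh(ShapeSpec("spherocyte", diameter_um=7.0))
    cfg = DescriptorConfig()
    ra = remesh_to_grid(disc)
    rb = remesh_to_grid(sph)
    v0 = build_descriptor(ra, cfg).normalized_vector
    dists = []
    for t in np.linspace(0.0, 1.0, 10):
        verts = (1 - t) * ra.vertices + t * rb.vertices
        morph = TriangleMesh(verts, ra.faces).ensure_outward().center_to_bbox()
        vt = build_descriptor(morph, cfg).normalized_vector
        dists.append(np.linalg.norm(vt - v0))
    assert dists == sorted(dists)
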
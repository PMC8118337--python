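import numpy as np
import pytest

from rbc3d.mesh import TriangleMesh
from rbc3d.sde import SDE_CLASSES, canonical_score
from rbc3d.shapes import (
    FieldOfViewError,
    InvalidSpecError,
    MorphError,
    ShapeSpec,
    SphereGrid,
    count_spikes,
    default_specs,
    generate_dataset,
    make_canonical_mesh,
    morph_meshes,
    rasterize_to_stack,
    remesh_to_grid,
)

# --------------------------------------------------------------------- specs


def test_spec_fills_canonical_sde_score():
    assert ShapeSpec("spherocyte").sde_score == -1.0
    assert ShapeSpec("discocyte").sde_score == 0.0
    assert ShapeSpec("echinocyte_III").sde_score == 1.0


def test_spec_rejects_unknown_class():
    with pytest.raises(InvalidSpecError):
        ShapeSpec("torocyte")


def test_spec_rejects_nonpositive_diameter():
    with pytest.raises(InvalidSpecError):
        ShapeSpec("discocyte", diameter_um=-1.0)


def test_spec_rejects_score_on_non_sde():
    with pytest.raises(InvalidSpecError):
        ShapeSpec("knizocyte", sde_score=0.5)


# --------------------------------------------------------------------- canonical meshes


def test_all_canonical_meshes_closed_and_centered(canonical_meshes):
    for cls, mesh in canonical_meshes.items():
        assert mesh.is_closed(), cls
        assert mesh.volume() > 0, cls
        assert np.abs(mesh.bbox_center()).max() < 1e-9, cls


def test_spherocyte_sphericity_within_one_percent(sphere_mesh):
    assert abs(sphere_mesh.sphericity() - 1.0) < 0.01


def test_discocyte_center_thinner_than_rim(disc_mesh):
    # slice through the symmetry axis: thickness profile vs cylinder radius
    v = disc_mesh.vertices
    rho = np.hypot(v[:, 0], v[:, 1])
    bins = np.linspace(0, rho.max() * 1.0001, 25)
    which = np.digitize(rho, bins)
    thickness = []
    for b in range(1, len(bins)):
        sel = which == b
        if sel.sum() > 3:
            thickness.append(v[sel, 2].max() - v[sel, 2].min())
    center_thickness = 2.0 * np.abs(v[np.argmin(rho), 2])
    assert center_thickness < max(thickness)


def test_stomatocyte_depth_ordering():
    sto1 = make_canonical_mesh(default_specs(["stomatocyte_I"])[0])
    sto2 = make_canonical_mesh(default_specs(["stomatocyte_II"])[0])
    # the deeper cup encloses less volume relative to its bounding sphere
    def cup_ratio(m):
        lo, hi = m.bounding_box()
        r = (hi - lo).max() / 2
        return m.volume() / (4 / 3 * np.pi * r**3)

    assert cup_ratio(sto2) < cup_ratio(sto1)


def test_echinocyte_iii_has_more_than_25_spikes(canonical_meshes):
    assert count_spikes(canonical_meshes["echinocyte_III"]) > 25


def test_smooth_shapes_have_no_spikes(canonical_meshes):
    assert count_spikes(canonical_meshes["discocyte"]) == 0
    assert count_spikes(canonical_meshes["spherocyte"]) == 0


def test_spike_count_monotone_in_parameter():
    counts = []
    for n in [8, 16, 24, 36]:
        spec = ShapeSpec(
            "echinocyte_III",
            geometry_params={"spike_count": n, "spike_amplitude": 0.2, "body_blend": 0.85},
        )
        counts.append(count_spikes(make_canonical_mesh(spec)))
    assert counts == sorted(counts)
    assert counts[-1] > counts[0]


def test_knizocyte_threefold_symmetry():
    grid = SphereGrid(25, 48)
    mesh = make_canonical_mesh(default_specs(["knizocyte"])[0], grid)
    # measure about the volume centroid: the bbox centre is not itself
    # invariant under the 3-fold rotation
    verts = mesh.vertices - mesh.volume_centroid()
    ring = np.linalg.norm(verts[1:-1], axis=1).reshape(grid.n_theta - 2, grid.n_phi)
    rolled = np.roll(ring, grid.n_phi // 3, axis=1)
    assert np.allclose(ring, rolled, rtol=1e-9, atol=1e-9)


def test_deterministic_for_fixed_seed():
    a = make_canonical_mesh(ShapeSpec("acanthocyte", seed=7))
    b = make_canonical_mesh(ShapeSpec("acanthocyte", seed=7))
    c = make_canonical_mesh(ShapeSpec("acanthocyte", seed=8))
    assert np.array_equal(a.vertices, b.vertices)
    assert not np.array_equal(a.vertices, c.vertices)


# --------------------------------------------------------------------- morphing


@pytest.fixture(scope="module")
def morph_pair():
    disc = make_canonical_mesh(ShapeSpec("discocyte", diameter_um=7.8))
    sph = make_canonical_mesh(ShapeSpec("spherocyte", diameter_um=7.8))
    return disc, sph


def test_morph_identity(morph_pair):
    disc, _ = morph_pair
    remeshed = remesh_to_grid(disc)
    morphed = morph_meshes(disc, disc, 0.5)
    assert np.allclose(morphed.vertices, remeshed.vertices, atol=1e-9)


def test_morph_endpoints(morph_pair):
    disc, sph = morph_pair
    m0 = morph_meshes(disc, sph, 0.0)
    m1 = morph_meshes(disc, sph, 1.0)
    assert np.allclose(m0.vertices, remesh_to_grid(disc).vertices, atol=1e-9)
    assert np.allclose(m1.vertices, remesh_to_grid(sph).vertices, atol=1e-9)


def test_morph_volume_between_endpoints(morph_pair):
    # equal diameters: the disc lies inside the ball, so the morph volume
    # is monotone and the midpoint volume sits between the endpoints
    disc, sph = morph_pair
    va = remesh_to_grid(disc).volume()
    vb = remesh_to_grid(sph).volume()
    vm = morph_meshes(disc, sph, 0.5).volume()
    assert min(va, vb) <= vm <= max(va, vb)


def test_morph_rejects_bad_t(morph_pair):
    disc, sph = morph_pair
    with pytest.raises(ValueError):
        morph_meshes(disc, sph, 1.5)


def _torus_mesh(R=2.0, r=0.5, nu=24, nv=12):
    u = np.linspace(0, 2 * np.pi, nu, endpoint=False)
    v = np.linspace(0, 2 * np.pi, nv, endpoint=False)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (R + r * np.cos(vv)) * np.cos(uu)
    y = (R + r * np.cos(vv)) * np.sin(uu)
    z = r * np.sin(vv)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    faces = []
    for i in range(nu):
        for j in range(nv):
            a = i * nv + j
            b = i * nv + (j + 1) % nv
            c = ((i + 1) % nu) * nv + j
            d = ((i + 1) % nu) * nv + (j + 1) % nv
            faces.append([a, c, b])
            faces.append([b, c, d])
    return TriangleMesh(verts, np.array(faces)).ensure_outward()


def test_morph_fails_for_non_star_mesh(morph_pair):
    disc, _ = morph_pair
    torus = _torus_mesh()
    with pytest.raises(MorphError, match="mesh_b"):
        morph_meshes(disc, torus, 0.5)


def test_morph_score_linearity():
    # ground-truth rule: score of morph t is the linear interpolation of
    # the endpoint canonical scores
    sa = canonical_score("discocyte")
    sb = canonical_score("echinocyte_I")
    for t in [0.0, 0.25, 0.5, 1.0]:
        assert (1 - t) * sa + t * sb == pytest.approx(t * (1 / 3), abs=1e-12)


# --------------------------------------------------------------------- rasterization


def test_rasterize_sphere_shell_at_analytic_radius(sphere_mesh):
    stack = rasterize_to_stack(sphere_mesh, noise_sd=0.0, seed=0)
    data = stack.intensities
    nz, ny, nx = data.shape
    vs = np.array(stack.voxel_size_xyz) / 1000.0
    peak = data.max()
    zz, yy, xx = np.nonzero(data > 0.995 * peak)
    pos = np.column_stack(
        [
            (xx + 0.5 - nx / 2) * vs[0],
            (yy + 0.5 - ny / 2) * vs[1],
            (zz + 0.5 - nz / 2) * vs[2],
        ]
    )
    radii = np.linalg.norm(pos, axis=1)
    assert np.abs(radii - 3.0).max() < max(vs)  # within one voxel


def test_rasterize_z_count_matches_depth(disc_mesh):
    stack = rasterize_to_stack(disc_mesh, voxel_size_xyz=(110, 110, 300), margin_um=1.2)
    lo, hi = disc_mesh.bounding_box()
    depth_um = (hi - lo)[2] + 2 * 1.2
    assert stack.n_planes == pytest.approx(depth_um * 1000 / 300, abs=1.5)


def test_rasterize_fov_error(disc_mesh):
    with pytest.raises(FieldOfViewError):
        rasterize_to_stack(disc_mesh, fov_um=(3.0, 3.0, 3.0))


def test_rasterize_deterministic(disc_mesh):
    a = rasterize_to_stack(disc_mesh, noise_sd=0.05, seed=42)
    b = rasterize_to_stack(disc_mesh, noise_sd=0.05, seed=42)
    assert np.array_equal(a.intensities, b.intensities)


def test_rasterize_noise_clipped_nonnegative(disc_mesh):
    stack = rasterize_to_stack(disc_mesh, noise_sd=0.3, seed=1)
    assert stack.intensities.min() >= 0.0


# --------------------------------------------------------------------- datasets


def test_generate_dataset_counts():
    data = generate_dataset(default_specs(SDE_CLASSES), n_per_class=10, seed=0)
    assert len(data) == 70
    per_class = {}
    for _mesh, spec in data:
        per_class[spec.shape_class] = per_class.get(spec.shape_class, 0) + 1
    assert set(per_class.values()) == {10}


def test_generate_dataset_deterministic():
    a = generate_dataset(default_specs(["discocyte"]), 3, seed=5)
    b = generate_dataset(default_specs(["discocyte"]), 3, seed=5)
    for (ma, _), (mb, _) in zip(a, b):
        assert np.array_equal(ma.vertices, mb.vertices)


def test_generate_dataset_zero_jitter_rotation_only():
    zero = {k: 0.0 for k in ["diameter", "spike_amplitude", "cup_depth", "spike_count"]}
    data = generate_dataset(default_specs(["acanthocyte"]), 2, jitter=zero, seed=3)
    (m1, _), (m2, _) = data
    assert not np.allclose(m1.vertices, m2.vertices)  # rotations differ
    assert m1.volume() == pytest.approx(m2.volume(), rel=1e-9)
    assert m1.area() == pytest.approx(m2.area(), rel=1e-9)
    n1 = np.sort(np.linalg.norm(m1.vertices - m1.volume_centroid(), axis=1))
    n2 = np.sort(np.linalg.norm(m2.vertices - m2.volume_centroid(), axis=1))
    assert np.allclose(n1, n2, atol=1e-9)


def test_generate_dataset_rejects_empty_specs():
    with pytest.raises(ValueError):
        generate_dataset([], 5)


def test_generate_dataset_all_meshes_valid():
    data = generate_dataset(default_specs(), 2, seed=1)
    for mesh, spec in data:
        assert mesh.is_closed(), spec.shape_class
        assert np.abs(mesh.bbox_center()).max() < 1e-9
        assert mesh.volume() > 0
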
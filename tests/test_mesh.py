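"""Measurement protocol: mesh I/O, cylinder fitting, saddle landmarking,
and the PTS index, validated against generator truth and a brute-force
multi-start cylinder oracle."""

import numpy as np
import pytest
import trimesh

import helpers
from conftest import cylinder_sector_points
from taluscam import mesh as M
from taluscam import synthetic as S


def _talus(offset, radius=3.0, noise=0.0, res=0.1, seed=0):
    spec = S.SyntheticTalusSpec(
        trochlea_radius=radius, shelf_offset=offset,
        mesh_resolution=res, noise_sd=noise, seed=seed,
    )
    return S.make_synthetic_talus(spec)


def _selections(mesh, truth):
    ltf = M.FacetSelection(mesh, truth.facet_vertex_ids, "LTF")
    ffg = M.FacetSelection(mesh, truth.groove_vertex_ids, "FFG")
    return ltf, ffg


# ---------------------------------------------------------------------------
# I/O


def test_mesh_roundtrip_ply(tmp_path, noiseless_talus):
    mesh, _ = noiseless_talus
    path = tmp_path / "t.ply"
    M.write_mesh(mesh, str(path))
    back = M.read_mesh(str(path))
    assert len(back.vertices) == len(mesh.vertices)
    assert len(back.faces) == len(mesh.faces)


def test_stl_duplicated_vertices_merged(tmp_path):
    mesh = trimesh.creation.icosphere(subdivisions=2)
    path = tmp_path / "s.stl"
    mesh.export(str(path))
    raw = trimesh.load(str(path), process=False)
    back = M.read_mesh(str(path))
    assert len(back.vertices) < len(raw.vertices)
    assert len(back.vertices) == len(mesh.vertices)


def test_empty_mesh_rejected(tmp_path):
    path = tmp_path / "empty.ply"
    trimesh.Trimesh(vertices=np.zeros((3, 3)), faces=np.empty((0, 3))
                    ).export(str(path))
    with pytest.raises(ValueError):
        M.read_mesh(str(path))


def test_region_sidecar_roundtrip(tmp_path, noiseless_talus):
    mesh, truth = noiseless_talus
    path = tmp_path / "r.json"
    M.write_regions(
        {"LTF": truth.facet_vertex_ids.tolist(),
         "FFG": truth.groove_vertex_ids.tolist()}, str(path)
    )
    regions = M.read_regions(str(path))
    sel = M.select_region(mesh, "LTF", regions)
    assert np.array_equal(sel.vertex_ids, truth.facet_vertex_ids)


def test_select_region_errors(noiseless_talus):
    mesh, truth = noiseless_talus
    with pytest.raises(KeyError):
        M.select_region(mesh, "nope", {"LTF": [0, 1, 2, 3, 4, 5]})
    with pytest.raises(ValueError):
        M.select_region(mesh, [1, 2, 3])
    with pytest.raises(IndexError):
        M.select_region(mesh, [0, 1, 2, 3, 4, len(mesh.vertices) + 5])


# ---------------------------------------------------------------------------
# cylinder fitting


def test_cylinder_exact_recovery():
    P = cylinder_sector_points(radius=3.0, arc_deg=120.0, n=200)
    sel = M.FacetSelection(
        trimesh.Trimesh(vertices=P, faces=np.empty((0, 3))),
        np.arange(len(P)),
    )
    fit = M.fit_cylinder(sel)
    assert fit.radius == pytest.approx(3.0, abs=1e-6)
    angle = np.degrees(
        np.arccos(np.clip(abs(fit.axis_direction[0]), 0, 1))
    )
    assert angle < 0.01
    assert fit.rms_residual <= 1e-6
    assert fit.n_points == 200


def test_cylinder_noisy_matches_multistart_oracle():
    P = cylinder_sector_points(
        radius=3.0, arc_deg=120.0, n=200, noise_sd=0.01, seed=4
    )
    sel = M.FacetSelection(
        trimesh.Trimesh(vertices=P, faces=np.empty((0, 3))),
        np.arange(len(P)),
    )
    fit = M.fit_cylinder(sel)
    r_oracle, d_oracle, _ = helpers.cylinder_oracle(P, n_restarts=20, seed=1)
    assert abs(fit.radius - 3.0) < 0.02
    assert fit.radius == pytest.approx(r_oracle, abs=1e-4)
    assert abs(abs(fit.axis_direction @ d_oracle) - 1) < 1e-6


def test_cylinder_degenerate_inputs_rejected():
    rng = np.random.default_rng(0)
    plane = np.column_stack(
        [rng.uniform(-1, 1, 50), rng.uniform(-1, 1, 50), np.zeros(50)]
    )
    mesh = trimesh.Trimesh(vertices=plane, faces=np.empty((0, 3)))
    with pytest.raises(ValueError):
        M.fit_cylinder(M.FacetSelection(mesh, np.arange(50)))
    line = np.column_stack([np.linspace(0, 1, 50), np.zeros(50),
                            np.zeros(50)])
    mesh = trimesh.Trimesh(vertices=line, faces=np.empty((0, 3)))
    with pytest.raises(ValueError):
        M.fit_cylinder(M.FacetSelection(mesh, np.arange(50)))


@pytest.mark.parametrize(
    "point, expected",
    [((3, 0, 0), 1.0), ((1.5, 0, 0), -0.5), ((0, 2, 5), 0.0)],
)
def test_signed_distance(point, expected):
    cyl = M.CylinderFit(
        axis_point=np.zeros(3), axis_direction=np.array([0.0, 0.0, 1.0]),
        radius=2.0, rms_residual=0.0, n_points=10,
    )
    assert M.signed_distance_to_cylinder(np.array(point), cyl) == \
        pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# landmarking


def _grid_surface(f, half=1.0, n=41):
    g = np.linspace(-half, half, n)
    U, V = np.meshgrid(g, g, indexing="ij")
    P = np.column_stack([U.ravel(), V.ravel(), f(U, V).ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return trimesh.Trimesh(vertices=P, faces=np.array(faces), process=False)


def test_saddle_landmark_on_analytic_saddle():
    mesh = _grid_surface(lambda u, v: u**2 - v**2)
    sel = M.FacetSelection(mesh, np.arange(len(mesh.vertices)))
    lm = M.locate_ffg_landmark(mesh, sel, mode="saddle")
    edge = float(mesh.edges_unique_length.mean())
    assert np.linalg.norm(lm) <= edge


def test_saddle_landmark_on_synthetic_talus(noiseless_talus):
    mesh, truth = noiseless_talus
    _, ffg = _selections(mesh, truth)
    lm = M.locate_ffg_landmark(mesh, ffg, mode="saddle")
    edge = float(mesh.edges_unique_length.mean())
    assert np.linalg.norm(lm - truth.true_saddle_point) <= edge


def test_convex_groove_signals_and_convex_max_mode():
    mesh = _grid_surface(lambda u, v: u**2 + v**2)
    sel = M.FacetSelection(mesh, np.arange(len(mesh.vertices)))
    with pytest.raises(M.NoSaddleError):
        M.locate_ffg_landmark(mesh, sel, mode="saddle")
    lm = M.locate_ffg_landmark(mesh, sel, mode="convex_max")
    edge = float(mesh.edges_unique_length.mean())
    assert np.linalg.norm(lm) <= 2 * edge


# ---------------------------------------------------------------------------
# full protocol


@pytest.mark.parametrize(
    "offset, lo, hi", [(1.5, 1.47, 1.53), (0.0, 0.98, 1.02)]
)
def test_measure_specimen_recovers_truth(offset, lo, hi):
    mesh, truth = _talus(offset)
    ltf, ffg = _selections(mesh, truth)
    meas = M.measure_specimen(mesh, ltf, ffg, "s", "t")
    assert lo <= meas.pts_index <= hi
    assert meas.axis_to_groove == pytest.approx(
        meas.radius + meas.groove_to_cylinder
    )


def test_measurement_arithmetic_identity():
    meas = M.PTSMeasurement.from_components("s", "t", 2.0, 0.5)
    assert meas.axis_to_groove == 2.5
    assert meas.pts_index == 1.25
    assert meas.ln_pts_index == pytest.approx(np.log(1.25))
    neg = M.PTSMeasurement.from_components("s", "t", 2.0, -2.5)
    assert np.isnan(neg.ln_pts_index)


def test_rigid_motion_invariance():
    mesh, truth = _talus(1.0)
    ltf, ffg = _selections(mesh, truth)
    base = M.measure_specimen(mesh, ltf, ffg).pts_index
    moved = mesh.copy()
    R = trimesh.transformations.rotation_matrix(
        0.7, [0.3, 1.0, 0.2], point=[1.0, -2.0, 0.5]
    )
    moved.apply_transform(R)
    moved.apply_translation([5.0, -3.0, 2.0])
    ltf2, ffg2 = (
        M.FacetSelection(moved, truth.facet_vertex_ids),
        M.FacetSelection(moved, truth.groove_vertex_ids),
    )
    after = M.measure_specimen(moved, ltf2, ffg2).pts_index
    assert abs(after - base) < 1e-6


def test_scale_equivariance():
    mesh, truth = _talus(1.0)
    ltf, ffg = _selections(mesh, truth)
    base = M.measure_specimen(mesh, ltf, ffg)
    scaled = mesh.copy()
    scaled.apply_scale(2.5)
    ltf2 = M.FacetSelection(scaled, truth.facet_vertex_ids)
    ffg2 = M.FacetSelection(scaled, truth.groove_vertex_ids)
    after = M.measure_specimen(scaled, ltf2, ffg2)
    assert abs(after.pts_index - base.pts_index) < 1e-6
    assert after.radius == pytest.approx(2.5 * base.radius, rel=1e-9)


def test_pts_index_monotone_in_shelf_offset():
    measured = []
    for off in (-0.6, 0.0, 0.5, 1.0, 1.5):
        mesh, truth = _talus(off)
        ltf, ffg = _selections(mesh, truth)
        measured.append(M.measure_specimen(mesh, ltf, ffg).pts_index)
    assert np.all(np.diff(measured) > 0)


def test_manual_landmark_override():
    mesh, truth = _talus(1.5)
    ltf, ffg = _selections(mesh, truth)
    vid = int(truth.groove_vertex_ids[0])
    meas = M.measure_specimen(mesh, ltf, ffg, landmark_id=vid)
    expected = M.signed_distance_to_cylinder(
        mesh.vertices[vid], M.fit_cylinder(ltf)
    )
    assert meas.groove_to_cylinder == pytest.approx(expected)
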
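"""Mesh and case-config I/O: parsing, cleaning, round-trips, outputs."""

import json

import numpy as np
import pytest

import trabl
from trabl.errors import ConfigError, DegenerateInputError, MeshFormatError
from trabl.io import TriangleMesh, read_case_config, read_mesh, write_mesh

TET_VERTS = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
TET_FACES = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


def test_binary_stl_tetrahedron_round_trip(tmp_path):
    path = tmp_path / "tet.stl"
    write_mesh(TriangleMesh(TET_VERTS, TET_FACES), path)
    mesh = read_mesh(path)
    assert mesh.n_vertices == 4
    assert mesh.n_faces == 4
    # STL stores float32: coordinates preserved to <= 1e-5 mm
    got = set(map(tuple, np.round(mesh.vertices, 5)))
    want = set(map(tuple, np.round(TET_VERTS, 5)))
    assert got == want


def _ascii_stl(triangles):
    lines = ["solid test"]
    for tri in triangles:
        lines.append(" facet normal 0 0 0\n  outer loop")
        for v in tri:
            lines.append(f"   vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        lines.append("  endloop\n endfacet")
    lines.append("endsolid test")
    return "\n".join(lines)


def test_ascii_stl_drops_zero_area_triangle(tmp_path):
    # a fan of 99 valid triangles plus one degenerate (collinear) triangle
    t = np.linspace(0, np.pi, 100)
    ring = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    apex = np.array([0.0, 0.0, 1.0])
    tris = [(apex, ring[i], ring[i + 1]) for i in range(99)]
    tris.append((ring[0], 0.5 * (ring[0] + ring[1]), ring[1]))  # zero area
    path = tmp_path / "fan.stl"
    path.write_text(_ascii_stl(tris))
    mesh = read_mesh(path)
    assert mesh.n_faces == 99


def test_phantom_shell_stl_round_trip(tmp_path, preset_cache):
    _, reconstructed, _, _ = preset_cache("identity")
    path = tmp_path / "shell.stl"
    write_mesh(reconstructed, path)
    back = read_mesh(path)
    assert back.n_vertices == reconstructed.n_vertices
    assert back.n_faces == reconstructed.n_faces


def test_cleaning_merges_duplicates_and_drops_degenerates():
    verts = np.vstack([TET_VERTS, TET_VERTS[0] + 1e-9])  # near-duplicate of v0
    faces = np.vstack([TET_FACES, [[4, 1, 2]], [[1, 1, 2]]])
    mesh = TriangleMesh.from_arrays(verts, faces)
    assert mesh.n_vertices == 4
    # the near-duplicate face collapses onto face (0,1,2); repeated-index
    # face dropped; the set of non-degenerate triangles is unchanged
    tris = {tuple(sorted(f)) for f in mesh.faces.tolist()}
    assert tris == {tuple(sorted(f)) for f in TET_FACES.tolist()}


def test_read_mesh_errors(tmp_path):
    with pytest.raises(MeshFormatError):
        read_mesh(tmp_path / "absent.stl")
    bad = tmp_path / "bad.stl"
    bad.write_text("this is not an stl file at all")
    with pytest.raises((MeshFormatError, DegenerateInputError)):
        read_mesh(bad)
    # a single triangle cleans to fewer than 4 vertices
    tri = tmp_path / "tri.stl"
    tri.write_text(_ascii_stl([(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
                                np.array([0.0, 1, 0]))]))
    with pytest.raises(DegenerateInputError):
        read_mesh(tri)


def _valid_config_doc():
    t = np.linspace(-np.pi, np.pi, 40, endpoint=False)
    rim = np.stack([24 * np.cos(t), 24 * np.sin(t), np.zeros_like(t)], axis=1)
    region = np.vstack([rim * 0.9, [[0, 0, -24.0]]])
    return {
        "rim_outline": rim.tolist(),
        "acetabular_region": region.tolist(),
        "landmarks": {"asis_left": [0, 0, -80], "asis_right": [0, 0, -20],
                      "pubis": [30, 0, -50]},
        "side": "right",
    }


def test_case_config_valid(tmp_path):
    path = tmp_path / "case.json"
    path.write_text(json.dumps(_valid_config_doc()))
    cfg = read_case_config(path)
    assert cfg.side == "right"
    assert cfg.rim_outline.shape == (40, 3)
    assert np.allclose(cfg.landmarks["pubis"], [30, 0, -50])


@pytest.mark.parametrize("mutate,err", [
    (lambda d: d["landmarks"].pop("pubis"), ConfigError),
    (lambda d: d.update(rim_outline=d["rim_outline"][:2]), ConfigError),
    (lambda d: d.update(side="dorsal"), ConfigError),
    (lambda d: d.update(acetabular_region=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]),
     ConfigError),  # coplanar region points
])
def test_case_config_errors(tmp_path, mutate, err):
    doc = _valid_config_doc()
    mutate(doc)
    path = tmp_path / "case.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(err):
        read_case_config(path)


def test_case_config_index_resolution(tmp_path):
    mesh = TriangleMesh(TET_VERTS, TET_FACES)
    doc = _valid_config_doc()
    doc["acetabular_region"] = {"indices": [0, 1, 2, 3]}
    path = tmp_path / "case.json"
    path.write_text(json.dumps(doc))
    cfg = read_case_config(path, reconstructed=mesh)
    assert np.allclose(cfg.acetabular_region, TET_VERTS)
    with pytest.raises(ConfigError):
        read_case_config(path)  # indices without a mesh


def test_phantom_config_round_trip(tmp_path, preset_cache):
    _, _, config, truth = preset_cache("identity")
    path = tmp_path / "case.json"
    trabl.write_case_config(config, path)
    back = read_case_config(path)
    for name in ("asis_left", "asis_right", "pubis"):
        assert np.allclose(back.landmarks[name], config.landmarks[name])
    assert np.allclose(back.rim_outline, config.rim_outline)


def test_write_outputs_identity_and_grid_rows(tmp_path, pipeline_cache):
    import pandas as pd

    result, state, _ = pipeline_cache("identity")
    paths = trabl.write_outputs(result, state["deviation"], state["grid"],
                                state["planar"], tmp_path / "out")
    ratios = pd.read_csv(paths["ratios"])
    assert len(ratios) == 7
    assert np.allclose(ratios["ratio"], 0.0)
    # re-read values equal the result fields
    overall = ratios[ratios.region == "overall"].iloc[0]
    assert overall["A_rec"] == pytest.approx(result.A_rec)
    assert overall["A_def"] == pytest.approx(result.A_def)
    grid_csv = pd.read_csv(paths["deviation_grid"])
    assert len(grid_csv) == 10000
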
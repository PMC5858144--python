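"""Core types, file round-trips, trilinear sampling and rigid transforms."""

import numpy as np
import pytest
import trimesh

from atriascar.core import (
    OUTSIDE,
    FormatError,
    ImageVolume,
    RigidTransform,
    SurfaceShell,
    apply_rigid,
    read_shell,
    read_volume,
    sample_trilinear,
    write_shell,
    write_volume,
)


def _volume(data, spacing=(1.0, 1.0, 1.0)):
    affine = np.diag([*spacing, 1.0])
    return ImageVolume(data=np.asarray(data, float), spacing=spacing, affine=affine)


class TestVolumeIO:
    def test_round_trip_identity(self, tmp_path):
        vol = _volume(np.full((10, 10, 10), 7.0))
        p = tmp_path / "v.nii.gz"
        write_volume(vol, p)
        back = read_volume(p)
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.affine, vol.affine)

    def test_anisotropic_spacing_preserved(self, tmp_path):
        # typical 3D LGE acquisition voxel: 1.3 x 1.3 x 4 mm
        vol = _volume(np.zeros((8, 8, 4)), spacing=(1.3, 1.3, 4.0))
        p = tmp_path / "v.nii"
        write_volume(vol, p)
        np.testing.assert_allclose(read_volume(p).spacing, [1.3, 1.3, 4.0])

    def test_non_invertible_affine_rejected(self):
        bad = np.diag([1.0, 1.0, 0.0, 1.0])
        with pytest.raises(FormatError):
            ImageVolume(data=np.zeros((4, 4, 4)), spacing=(1, 1, 1), affine=bad)

    def test_non_finite_data_rejected(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(FormatError):
            _volume(data)

    def test_unreadable_file(self, tmp_path):
        p = tmp_path / "junk.nii"
        p.write_text("not a nifti")
        with pytest.raises(FormatError):
            read_volume(p)


class TestShellIO:
    def test_icosahedron_round_trip(self, tmp_path):
        ico = trimesh.creation.icosahedron()
        shell = SurfaceShell(
            vertices=ico.vertices,
            faces=ico.faces,
            face_scalar=np.arange(20, dtype=float) * 0.1,
            face_label=np.arange(20) % 7,
        )
        p = tmp_path / "s.vtk"
        write_shell(shell, p)
        back = read_shell(p)
        np.testing.assert_array_equal(back.faces, shell.faces)
        np.testing.assert_array_equal(back.vertices, shell.vertices)
        np.testing.assert_array_equal(back.face_scalar, shell.face_scalar)
        np.testing.assert_array_equal(back.face_label, shell.face_label)

    def test_phantom_shell_round_trip(self, tmp_path, phantom_shell):
        shell, _ = phantom_shell
        p = tmp_path / "la.vtk"
        write_shell(shell, p)
        back = read_shell(p)
        assert back.n_faces == shell.n_faces
        np.testing.assert_array_equal(back.vertices, shell.vertices)
        np.testing.assert_array_equal(back.face_label, shell.face_label)
        # one scalar per face, areas recomputed from geometry
        assert len(back.face_scalar) == back.n_faces
        np.testing.assert_allclose(back.face_area, shell.face_area)

    def test_quad_cells_rejected(self, tmp_path):
        p = tmp_path / "quad.vtk"
        p.write_text(
            "# vtk DataFile Version 3.0\nquad\nASCII\nDATASET POLYDATA\n"
            "POINTS 4 double\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n"
            "POLYGONS 1 5\n4 0 1 2 3\n"
        )
        with pytest.raises(FormatError, match="triangles"):
            read_shell(p)

    def test_missing_scalar_warns(self, tmp_path):
        p = tmp_path / "noscalar.vtk"
        p.write_text(
            "# vtk DataFile Version 3.0\nbare\nASCII\nDATASET POLYDATA\n"
            "POINTS 3 double\n0 0 0\n1 0 0\n0 1 0\n"
            "POLYGONS 1 4\n3 0 1 2\n"
        )
        with pytest.warns(UserWarning, match="no SI scalar"):
            shell = read_shell(p)
        assert np.isnan(shell.face_scalar).all()


class TestTrilinear:
    def test_constant_volume(self, rng):
        vol = _volume(np.full((6, 6, 6), 3.5))
        pts = rng.uniform(0.5, 4.5, size=(50, 3))
        np.testing.assert_allclose(sample_trilinear(vol, pts), 3.5)

    def test_voxel_centre_exact(self):
        data = np.arange(27, dtype=float).reshape(3, 3, 3)
        vol = _volume(data)
        assert sample_trilinear(vol, [[1.0, 2.0, 0.0]])[0] == data[1, 2, 0]

    def test_midpoint_linearity(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 0.0
        data[2, 1, 1] = 8.0
        vol = _volume(data)
        assert sample_trilinear(vol, [[1.5, 1.0, 1.0]])[0] == pytest.approx(4.0)

    def test_outside_returns_sentinel(self):
        vol = _volume(np.ones((4, 4, 4)))
        out = sample_trilinear(vol, [[-5.0, 0, 0], [100.0, 0, 0]])
        assert (out == OUTSIDE).all()

    def test_matches_convex_combination_oracle(self, rng):
        data = rng.normal(size=(7, 6, 5))
        vol = _volume(data, spacing=(1.1, 0.9, 1.3))
        pts_idx = rng.uniform(0.0, 3.9, size=(200, 3))
        pts = pts_idx * np.array([1.1, 0.9, 1.3])
        got = sample_trilinear(vol, pts)
        # brute-force: weighted sum over the 8 surrounding voxel corners
        for p_idx, val in zip(pts_idx, got):
            base = np.floor(p_idx).astype(int)
            frac = p_idx - base
            acc = 0.0
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        w = (
                            (frac[0] if di else 1 - frac[0])
                            * (frac[1] if dj else 1 - frac[1])
                            * (frac[2] if dk else 1 - frac[2])
                        )
                        acc += w * data[base[0] + di, base[1] + dj, base[2] + dk]
            assert val == pytest.approx(acc, abs=1e-12)


class TestRigidTransform:
    def test_identity_leaves_shell_unchanged(self, phantom_shell):
        shell, _ = phantom_shell
        out = apply_rigid(RigidTransform(), shell)
        np.testing.assert_array_equal(out.vertices, shell.vertices)
        np.testing.assert_array_equal(out.face_scalar, shell.face_scalar)

    def test_inverse_round_trip(self, phantom_shell):
        shell, _ = phantom_shell
        t = RigidTransform(rotation=(10.0, -20.0, 5.0), translation=(4.0, -1.0, 2.5))
        back = apply_rigid(t.inverse(), apply_rigid(t, shell))
        assert np.abs(back.vertices - shell.vertices).max() < 1e-9

    def test_pure_translation_shifts_centroid(self, phantom_shell):
        shell, _ = phantom_shell
        t = RigidTransform(translation=(2.0, 0.0, 0.0))
        moved = apply_rigid(t, shell)
        np.testing.assert_allclose(
            moved.vertices.mean(axis=0) - shell.vertices.mean(axis=0),
            [2.0, 0.0, 0.0],
            atol=1e-12,
        )

    def test_isometry_preserves_distances_and_areas(self, rng):
        pts = rng.normal(size=(40, 3)) * 10
        t = RigidTransform(rotation=(33.0, 12.0, -70.0), translation=(1.0, 2.0, 3.0))
        moved = t.apply_points(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_compose_matches_sequential_application(self, rng):
        a = RigidTransform(rotation=(5.0, 10.0, 15.0), translation=(1.0, -2.0, 0.5))
        b = RigidTransform(rotation=(-3.0, 7.0, 1.0), translation=(0.0, 4.0, -1.0))
        pts = rng.normal(size=(10, 3))
        np.testing.assert_allclose(
            a.compose(b).apply_points(pts), a.apply_points(b.apply_points(pts)),
            atol=1e-10,
        )

    def test_save_load_round_trip(self, tmp_path):
        t = RigidTransform(rotation=(1.5, -0.25, 3.0), translation=(0.1, 0.2, 0.3))
        p = tmp_path / "t.txt"
        t.save(p)
        np.testing.assert_array_equal(RigidTransform.load(p).params, t.params)
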
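"""Shell interrogation, reference ROIs, normalisation and thresholding."""

import numpy as np
import pytest

from atriascar.core import ImageVolume, RigidTransform, apply_rigid
from atriascar.phantom import reference_roi_spec
from atriascar.projection import (
    ProjectionConfig,
    ReferenceStats,
    RoiSpec,
    extract_reference_stats,
    normalise,
    project,
    threshold_scar,
)


def _volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = origin
    return ImageVolume(data=np.asarray(data, float), spacing=spacing, affine=affine)


class TestProject:
    def test_constant_volume_both_modes(self, phantom_shell, default_spec):
        shell, _ = phantom_shell
        lo = shell.vertices.min(axis=0) - 10
        hi = shell.vertices.max(axis=0) + 10
        shape = tuple(np.ceil((hi - lo) / 2.0).astype(int) + 1)
        vol = _volume(np.full(shape, 42.0), spacing=(2.0, 2.0, 2.0), origin=lo)
        for mode in ("max", "mean"):
            out = project(vol, shell, ProjectionConfig(mode=mode))
            np.testing.assert_allclose(out.face_scalar, 42.0)

    def test_bright_voxel_in_band_hits_max_only(self, phantom_shell):
        """A bright voxel 2 mm outside one face raises that face's MIP; the
        mean over the 9-sample slab stays strictly below.  Both aggregates
        are checked against the explicit sample-point set."""
        from atriascar.core import sample_trilinear

        shell, _ = phantom_shell
        face = 100
        c = shell.face_centroid[face]
        n = shell.face_normal[face]
        target = c + 2.0 * n
        lo = shell.vertices.min(axis=0) - 10
        hi = shell.vertices.max(axis=0) + 10
        shape = tuple(np.ceil(hi - lo).astype(int) + 1)
        data = np.zeros(shape)
        data[tuple(np.round(target - lo).astype(int))] = 500.0
        # place the grid so the bright voxel centre lies exactly at `target`
        vol = _volume(data, origin=tuple(target - np.round(target - lo)))
        mx = project(vol, shell, ProjectionConfig(mode="max")).face_scalar[face]
        mn = project(vol, shell, ProjectionConfig(mode="mean")).face_scalar[face]
        assert mx == pytest.approx(500.0)
        assert mn < mx
        # oracle: the nine slab sample points, aggregated by hand
        offsets = np.arange(-1.0, 3.0 + 0.25, 0.5)
        samples = sample_trilinear(vol, c[None, :] + offsets[:, None] * n[None, :])
        assert mx == pytest.approx(samples.max(), abs=1e-12)
        assert mn == pytest.approx(samples.mean(), abs=1e-12)

    def test_bright_voxel_beyond_band_ignored(self, phantom_shell):
        shell, _ = phantom_shell
        face = 100
        c = shell.face_centroid[face]
        n = shell.face_normal[face]
        target = c + 5.0 * n  # outside the -1..+3 mm slab
        lo = shell.vertices.min(axis=0) - 10
        shape = tuple(np.ceil(shell.vertices.max(axis=0) + 10 - lo).astype(int) + 1)
        data = np.zeros(shape)
        data[tuple(np.round(target - lo).astype(int))] = 500.0
        vol = _volume(data, origin=tuple(target - np.round(target - lo)))
        mx = project(vol, shell, ProjectionConfig(mode="max")).face_scalar[face]
        assert mx < 500.0 * 0.5

    def test_max_dominates_mean_facewise(self, phantom_shell, phantom_volume):
        shell, _ = phantom_shell
        mx = project(phantom_volume, shell, ProjectionConfig(mode="max")).face_scalar
        mn = project(phantom_volume, shell, ProjectionConfig(mode="mean")).face_scalar
        ok = np.isfinite(mx) & np.isfinite(mn)
        assert np.all(mx[ok] >= mn[ok] - 1e-12)

    def test_rigid_invariance(self, phantom_shell, phantom_volume):
        """Transforming volume and shell by the same rigid motion leaves the
        projection unchanged."""
        shell, _ = phantom_shell
        t = RigidTransform(rotation=(4.0, -7.0, 2.0), translation=(5.0, 3.0, -2.0))
        moved_shell = apply_rigid(t, shell)
        m = t.matrix
        moved_vol = ImageVolume(
            data=phantom_volume.data,
            spacing=phantom_volume.spacing,
            affine=m @ phantom_volume.affine,
        )
        a = project(phantom_volume, shell).face_scalar
        b = project(moved_vol, moved_shell).face_scalar
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_all_outside_warns_and_marks_missing(self, phantom_shell):
        shell, _ = phantom_shell
        vol = _volume(np.zeros((4, 4, 4)), origin=(500.0, 500.0, 500.0))
        with pytest.warns(UserWarning, match="no in-grid samples"):
            out = project(vol, shell)
        assert np.isnan(out.face_scalar).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ProjectionConfig(step=0.0)
        with pytest.raises(ValueError):
            ProjectionConfig(mode="median")
        with pytest.raises(ValueError):
            ProjectionConfig(inner_depth=-1.0)


class TestReferenceStats:
    def test_uniform_roi(self):
        vol = _volume(np.full((40, 40, 5), 100.0))
        roi = RoiSpec(
            bp_center=np.array([20.0, 20.0, 2.0]),
            myo_center=np.array([10.0, 10.0, 2.0]),
            slice_world_z=2.0,
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            ref = extract_reference_stats(vol, roi)
        assert ref.bp_mean == 100.0
        assert ref.bp_sd == 0.0

    def test_population_sd_convention(self):
        """Half the ROI at 90, half at 110: mean 100, population SD 10."""
        data = np.full((40, 40, 3), 100.0)
        data[:20, :, :] = 90.0
        data[20:, :, :] = 110.0
        vol = _volume(data)
        roi = RoiSpec(
            bp_center=np.array([19.5, 20.0, 1.0]),
            myo_center=np.array([30.0, 30.0, 1.0]),
            slice_world_z=1.0,
        )
        ref = extract_reference_stats(vol, roi)
        vals = []
        r = np.sqrt(200.0 / np.pi)
        for i in range(40):
            for j in range(40):
                if (i - 19.5) ** 2 + (j - 20.0) ** 2 <= r * r:
                    vals.append(data[i, j, 1])
        vals = np.array(vals)
        assert ref.bp_mean == pytest.approx(vals.mean())
        assert ref.bp_sd == pytest.approx(vals.std())  # divisor N

    def test_roi_outside_grid_rejected(self):
        vol = _volume(np.zeros((10, 10, 3)))
        roi = RoiSpec(
            bp_center=np.array([1.0, 1.0, 1.0]),
            myo_center=np.array([5.0, 5.0, 1.0]),
        )
        with pytest.raises(ValueError, match="outside"):
            extract_reference_stats(vol, roi)

    def test_phantom_reference_stats(self, gapped_phantom, gapped_spec):
        """On the noise-free phantom, the ROIs recover the generative
        intensities and the scar search lands on the scar band."""
        shell, truth, vol = gapped_phantom
        roi = reference_roi_spec(shell, truth, gapped_spec)
        with pytest.warns(UserWarning):  # zero variance: noise-free
            ref = extract_reference_stats(vol, roi)
        assert ref.bp_mean == pytest.approx(gapped_spec.bp_mean)
        assert ref.myo_mean == pytest.approx(gapped_spec.myo_mean)
        assert ref.scar_ref == pytest.approx(gapped_spec.scar_mean, rel=0.05)


class TestNormalise:
    REF = ReferenceStats(bp_mean=100.0, bp_sd=10.0, myo_mean=80.0, myo_sd=5.0, scar_ref=150.0)

    def _shell_with(self, phantom_shell, values):
        shell, _ = phantom_shell
        scalar = np.full(shell.n_faces, values if np.isscalar(values) else np.nan)
        return shell.with_scalar(scalar)

    def test_bp_z_and_iir_at_blood_pool_mean(self, phantom_shell):
        sh = self._shell_with(phantom_shell, 100.0)
        assert normalise(sh, self.REF, "BP_Z").face_scalar[0] == 0.0
        assert normalise(sh, self.REF, "BP_IIR").face_scalar[0] == 1.0

    def test_bp_z_at_threshold_value(self, phantom_shell):
        sh = self._shell_with(phantom_shell, 100.0 + 3.3 * 10.0)
        assert normalise(sh, self.REF, "BP_Z").face_scalar[0] == pytest.approx(3.3)

    def test_scar_iir_at_reference(self, phantom_shell):
        sh = self._shell_with(phantom_shell, 150.0)
        assert normalise(sh, self.REF, "SCAR_IIR").face_scalar[0] == 1.0

    def test_vmyo_z(self, phantom_shell):
        sh = self._shell_with(phantom_shell, 90.0)
        assert normalise(sh, self.REF, "VMYO_Z").face_scalar[0] == pytest.approx(2.0)

    def test_zero_sd_rejected_by_name(self, phantom_shell):
        sh = self._shell_with(phantom_shell, 100.0)
        bad = ReferenceStats(bp_mean=100.0, bp_sd=0.0)
        with pytest.raises(ValueError, match="BP_Z"):
            normalise(sh, bad, "BP_Z")

    def test_global_gain_invariance(self, phantom_shell, phantom_volume, default_spec, rng):
        """Scaling the whole volume by c > 0 scales the reference statistics
        with it, so ratios and z-scores are unchanged."""
        shell, truth = phantom_shell
        proj = project(phantom_volume, shell)
        ref = ReferenceStats(bp_mean=100.0, bp_sd=10.0, myo_mean=80.0, myo_sd=5.0, scar_ref=150.0)
        c = 2.7
        proj_scaled = proj.with_scalar(proj.face_scalar * c)
        ref_scaled = ReferenceStats(
            bp_mean=100.0 * c, bp_sd=10.0 * c, myo_mean=80.0 * c,
            myo_sd=5.0 * c, scar_ref=150.0 * c,
        )
        for method in ("BP_Z", "VMYO_Z", "BP_IIR", "SCAR_IIR"):
            a = normalise(proj, ref, method).face_scalar
            b = normalise(proj_scaled, ref_scaled, method).face_scalar
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)


class TestThreshold:
    REF = ReferenceStats(bp_mean=100.0, bp_sd=10.0)

    def test_no_scar_when_all_at_blood_pool(self, phantom_shell):
        shell, _ = phantom_shell
        sh = shell.with_scalar(np.full(shell.n_faces, 100.0))
        assert threshold_scar(sh, self.REF).sum() == 0

    def test_boundary_value_included(self, phantom_shell):
        shell, _ = phantom_shell
        sh = shell.with_scalar(np.full(shell.n_faces, 133.0))
        assert threshold_scar(sh, self.REF).all()

    def test_missing_faces_never_scar(self, phantom_shell):
        shell, _ = phantom_shell
        scalar = np.full(shell.n_faces, 200.0)
        scalar[:10] = np.nan
        sh = shell.with_scalar(scalar)
        mask = threshold_scar(sh, self.REF)
        assert not mask[:10].any() and mask[10:].all()

    def test_raw_rule_needs_cutoff(self, phantom_shell):
        shell, _ = phantom_shell
        with pytest.raises(ValueError):
            threshold_scar(shell, rule="raw")

    def test_unknown_rule_rejected(self, phantom_shell):
        shell, _ = phantom_shell
        with pytest.raises(ValueError, match="unknown"):
            threshold_scar(shell, self.REF, rule="OTSU")

    def test_raw_and_bpz_rules_identical(self, phantom_shell, rng):
        """Thresholding raw SI at bp_mean + 3.3 bp_sd equals thresholding the
        BP-Z-normalised shell at 3.3, exactly."""
        shell, _ = phantom_shell
        for _ in range(10):
            ref = ReferenceStats(
                bp_mean=rng.uniform(50, 200), bp_sd=rng.uniform(1, 30)
            )
            sh = shell.with_scalar(rng.normal(100, 60, size=shell.n_faces))
            raw = threshold_scar(sh, rule="raw", cutoff=ref.bp_mean + 3.3 * ref.bp_sd)
            z_shell = normalise(sh, ref, "BP_Z")
            via_z = threshold_scar(z_shell, rule="BP_Z", scalar_is_normalised=True)
            np.testing.assert_array_equal(raw, via_z)
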
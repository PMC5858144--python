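"""Shell interrogation of the LGE volume, reference ROIs and SI normalisation.

The LGE volume is interrogated along each face's outward normal over a slab
reaching 1 mm inside to 3 mm beyond the endocardial shell, assigning a single
signal intensity per face: the slab maximum (MIP, used for post-ablation scar)
or the slab mean (used by the baseline-fibrosis variant).

Per-face SIs are normalised by four acquisition-specific reference methods:

========  =============================================
BP_Z      (SI - blood-pool mean) / blood-pool SD
VMYO_Z    (SI - septal-myocardium mean) / myocardium SD
BP_IIR    SI / blood-pool mean
SCAR_IIR  SI / best-scar reference SI
========  =============================================

Reference statistics come from ROIs in a single reference slice: a 200 mm^2
disc in the LA blood pool, a 50 mm^2 disc in homogeneous septal myocardium,
and a 5 mm^2 disc placed on the most intense scar found by local search.
ROI statistics use the population SD (divide by N).  Thresholding raw SI at
blood-pool mean + 3.3 blood-pool SD is exactly equivalent to thresholding the
BP_Z shell at 3.3, and the implementation preserves that identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import OUTSIDE, ImageVolume, SurfaceShell, sample_trilinear

__all__ = [
    "ProjectionConfig",
    "ReferenceStats",
    "RoiSpec",
    "NORMALISATION_METHODS",
    "project",
    "extract_reference_stats",
    "normalise",
    "threshold_scar",
]

NORMALISATION_METHODS = ("BP_Z", "VMYO_Z", "BP_IIR", "SCAR_IIR")

#: Histologically anchored scar threshold: 3.3 blood-pool SDs above the
#: blood-pool mean (equivalently BP_Z >= 3.3).
DEFAULT_Z_CUTOFF = 3.3
#: Baseline-fibrosis variant: BP image-intensity ratio 0.97 on a mean
#: intensity projection.
BASELINE_IIR_CUTOFF = 0.97


@dataclass
class ProjectionConfig:
    """Slab geometry for the shell interrogation.

    ``inner_depth``/``outer_depth`` are measured along the outward face
    normal from the face centroid (mm).  Defaults give the 1-mm-inside /
    3-mm-beyond interrogation slab; ``step`` of 0.5 mm yields 9 samples.
    """

    inner_depth: float = 1.0
    outer_depth: float = 3.0
    step: float = 0.5
    mode: str = "max"

    def __post_init__(self) -> None:
        if self.inner_depth < 0 or self.outer_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.step <= 0 or self.step > self.inner_depth + self.outer_depth:
            raise ValueError("step must be positive and within the slab")
        if self.mode not in ("max", "mean"):
            raise ValueError("mode must be 'max' or 'mean'")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(
            -self.inner_depth, self.outer_depth + 0.5 * self.step, self.step
        )


@dataclass
class ReferenceStats:
    """Reference-slice statistics housing every normalisation denominator."""

    bp_mean: float
    bp_sd: float
    myo_mean: float = np.nan
    myo_sd: float = np.nan
    scar_ref: float = np.nan

    def __post_init__(self) -> None:
        if self.bp_sd < 0 or (np.isfinite(self.myo_sd) and self.myo_sd < 0):
            raise ValueError("reference SDs must be non-negative")
        if not np.isfinite(self.bp_mean):
            raise ValueError("blood-pool mean must be finite")
        if np.isfinite(self.scar_ref) and self.scar_ref < self.bp_mean:
            warnings.warn(
                "scar reference SI below blood-pool mean: check ROI placement",
                stacklevel=2,
            )


@dataclass
class RoiSpec:
    """Placement of the reference ROIs, all in world mm.

    The reference slice is the axial (z) slice at ``slice_world_z``.  The
    scar ROI is found by local search: the ``scar_area`` disc with maximal
    mean SI among candidate centres within ``scar_search_radius`` of
    ``scar_center``.
    """

    bp_center: np.ndarray
    myo_center: np.ndarray
    scar_center: np.ndarray | None = None
    slice_world_z: float = 0.0
    bp_area: float = 200.0  # mm^2
    myo_area: float = 50.0
    scar_area: float = 5.0
    scar_search_radius: float = 8.0


def project(vol: ImageVolume, shell: SurfaceShell, cfg: ProjectionConfig | None = None) -> SurfaceShell:
    """Assign one SI value per face by slab projection along face normals.

    Returns a copy of ``shell`` with ``face_scalar`` filled.  Faces whose
    every sample falls outside the image grid get NaN (missing) and a warning
    is emitted if more than 1% of faces are missing.
    """
    cfg = cfg or ProjectionConfig()
    offsets = cfg.offsets
    centroids = shell.face_centroid
    normals = shell.face_normal
    n_faces, n_off = len(centroids), len(offsets)
    pts = (centroids[:, None, :] + offsets[None, :, None] * normals[:, None, :]).reshape(
        -1, 3
    )
    samples = sample_trilinear(vol, pts).reshape(n_faces, n_off)
    valid = samples != OUTSIDE
    any_valid = valid.any(axis=1)
    scalar = np.full(n_faces, np.nan)
    if cfg.mode == "max":
        scalar[any_valid] = samples[any_valid].max(axis=1)
    else:
        s = np.where(valid, samples, 0.0)
        scalar[any_valid] = s[any_valid].sum(axis=1) / valid[any_valid].sum(axis=1)
    n_missing = int((~any_valid).sum())
    if n_missing > 0.01 * n_faces:
        warnings.warn(
            f"projection found no in-grid samples for {n_missing} of {n_faces} faces",
            stacklevel=2,
        )
    return shell.with_scalar(scalar)


# ---------------------------------------------------------------------------
# reference ROIs
# ---------------------------------------------------------------------------


def _slice_coords(vol: ImageVolume, world_z: float):
    """Voxel world coordinates of the axial slice nearest ``world_z``."""
    nz = vol.shape[2]
    idx = np.column_stack(
        [np.zeros(nz), np.zeros(nz), np.arange(nz)]
    )
    zs = vol.index_to_world(idx)[:, 2]
    k = int(np.argmin(np.abs(zs - world_z)))
    ni, nj = vol.shape[:2]
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    sl_idx = np.column_stack([ii.ravel(), jj.ravel(), np.full(ii.size, k)])
    world = vol.index_to_world(sl_idx)
    vals = vol.data[:, :, k].ravel()
    return world, vals


def _disc_values(world: np.ndarray, vals: np.ndarray, center: np.ndarray, area: float) -> np.ndarray:
    r = np.sqrt(area / np.pi)
    d = np.linalg.norm(world[:, :2] - np.asarray(center)[:2], axis=1)
    sel = d <= r
    if not np.any(sel):  # tiny ROI: fall back to the nearest voxel
        sel = d == d.min()
    return vals[sel]


def extract_reference_stats(vol: ImageVolume, roi: RoiSpec) -> ReferenceStats:
    """Blood-pool / myocardial / best-scar statistics from the reference slice.

    Means and SDs are population statistics (divide by N) over the voxels of
    each disc ROI.  The scar reference is the mean of the best-placed
    ``scar_area`` disc within the search neighbourhood.
    """
    world, vals = _slice_coords(vol, roi.slice_world_z)
    for name, center, area in (
        ("blood-pool", roi.bp_center, roi.bp_area),
        ("myocardial", roi.myo_center, roi.myo_area),
    ):
        r = np.sqrt(area / np.pi)
        lo, hi = world[:, :2].min(axis=0), world[:, :2].max(axis=0)
        c = np.asarray(center)[:2]
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(f"{name} ROI extends outside the image grid")

    bp_vals = _disc_values(world, vals, roi.bp_center, roi.bp_area)
    myo_vals = _disc_values(world, vals, roi.myo_center, roi.myo_area)
    bp_sd = float(np.std(bp_vals))
    myo_sd = float(np.std(myo_vals))
    for name, sd in (("blood-pool", bp_sd), ("myocardial", myo_sd)):
        if sd == 0.0:
            warnings.warn(f"zero-variance {name} ROI", stacklevel=2)

    scar_ref = np.nan
    if roi.scar_center is not None:
        best = -np.inf
        c0 = np.asarray(roi.scar_center)[:2]
        # grid of candidate centres at half-voxel pitch
        pitch = 0.5 * float(np.min(vol.spacing[:2]))
        rr = roi.scar_search_radius
        offs = np.arange(-rr, rr + pitch, pitch)
        for dx in offs:
            for dy in offs:
                if dx * dx + dy * dy > rr * rr:
                    continue
                cand = _disc_values(world, vals, c0 + [dx, dy], roi.scar_area)
                m = float(cand.mean())
                if m > best:
                    best = m
        scar_ref = best
    return ReferenceStats(
        bp_mean=float(bp_vals.mean()),
        bp_sd=bp_sd,
        myo_mean=float(myo_vals.mean()),
        myo_sd=myo_sd,
        scar_ref=scar_ref,
    )


# ---------------------------------------------------------------------------
# normalisation and thresholding
# ---------------------------------------------------------------------------


def normalise(shell: SurfaceShell, ref: ReferenceStats, method: str) -> SurfaceShell:
    """Return a copy of ``shell`` with ``face_scalar`` normalised by ``method``."""
    si = shell.face_scalar
    if method == "BP_Z":
        if not ref.bp_sd > 0:
            raise ValueError("BP_Z requires a positive blood-pool SD")
        out = (si - ref.bp_mean) / ref.bp_sd
    elif method == "VMYO_Z":
        if not ref.myo_sd > 0:
            raise ValueError("VMYO_Z requires a positive myocardial SD")
        out = (si - ref.myo_mean) / ref.myo_sd
    elif method == "BP_IIR":
        if not ref.bp_mean > 0:
            raise ValueError("BP_IIR requires a positive blood-pool mean")
        out = si / ref.bp_mean
    elif method == "SCAR_IIR":
        if not (np.isfinite(ref.scar_ref) and ref.scar_ref > 0):
            raise ValueError("SCAR_IIR requires a positive scar reference SI")
        out = si / ref.scar_ref
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    return shell.with_scalar(out)


def threshold_scar(
    shell: SurfaceShell,
    ref: ReferenceStats | None = None,
    rule: str = "BP_Z",
    cutoff: float | None = None,
    scalar_is_normalised: bool = False,
) -> np.ndarray:
    """Boolean per-face scar designation.

    ``rule='BP_Z'`` (default) designates faces at >= 3.3 blood-pool SDs above
    the blood-pool mean; ``rule='BP_IIR'`` with its 0.97 default cutoff is the
    baseline-fibrosis variant (use with a mean projection); ``rule='raw'``
    thresholds the raw scalar at an explicit ``cutoff``.  If the shell already
    carries the normalised scalar, pass ``scalar_is_normalised=True``;
    otherwise the raw SI is normalised here (requiring ``ref``).  The boundary
    value is included (>=).  Missing (NaN) faces are never scar.
    """
    si = shell.face_scalar
    if rule == "raw":
        if cutoff is None:
            raise ValueError("rule='raw' requires an explicit cutoff")
        vals = si
    elif rule in NORMALISATION_METHODS:
        if cutoff is None:
            if rule == "BP_Z":
                cutoff = DEFAULT_Z_CUTOFF
            elif rule == "BP_IIR":
                cutoff = BASELINE_IIR_CUTOFF
            else:
                raise ValueError(f"rule {rule!r} has no default cutoff")
        if scalar_is_normalised:
            vals = si
        else:
            if ref is None:
                raise ValueError(
                    f"rule {rule!r} on raw SI requires reference statistics"
                )
            vals = normalise(shell, ref, rule).face_scalar
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    with np.errstate(invalid="ignore"):
        return np.asarray(vals >= cutoff) & np.isfinite(vals)
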
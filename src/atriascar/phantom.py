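"""Synthetic LA/LGE phantom with ground-truthed WACA-pattern scar.

The phantom emulates the imaging substrate of a post-pulmonary-vein-isolation
study: a left-atrial body (ellipsoid) with four pulmonary-vein stubs and an
appendage stub, voxelised into an LGE-like volume with bright blood pool,
nulled wall, and a hyperintense ablation-scar band encircling each ipsilateral
vein pair.  Gaps of configurable angular position/extent interrupt the band,
giving an exact ground-truth pulmonary-vein encirclement (PVE) and scar-area
fraction against which the measurement pipeline can be scored.

Geometry is defined implicitly (approximate signed distance of the union of an
ellipsoid and five capsules) and triangulated by marching cubes, so the shell
is closed and consistently oriented by construction.  A separate block of
myocardium-intensity tissue away from the LA stands in for the ventricular
septum, so that septal reference statistics can be taken exactly as they would
be from a real reference slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .core import LABELS, ImageVolume, SurfaceShell
from .projection import RoiSpec
from .surface import (
    PAIR_LABELS,
    face_geodesics,
    ostial_rim_vertices,
    ring_coordinate,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomSession",
    "make_shell",
    "voxelise",
    "make_session",
    "reference_roi_spec",
    "scar_width_for_fraction",
    "SESSION_ARMS",
]

# Unit-less direction vectors (normalised at use) for the anatomical stubs.
# +x = patient left, +y = posterior, +z = superior.
_VEIN_DIRS = {
    "lspv": np.array([1.0, 0.55, 0.5]),
    "lipv": np.array([1.0, 0.55, -0.5]),
    "rspv": np.array([-1.0, 0.55, 0.5]),
    "ripv": np.array([-1.0, 0.55, -0.5]),
}
_LAA_DIR = np.array([0.55, -1.0, 0.45])
_MITRAL_DIR = np.array([0.0, -0.55, -1.0])
_MITRAL_HALF_ANGLE = 28.0  # deg; cone of faces labelled as the mitral region

#: Acquisition arms for a second scan session and the contrast-timing arm.
SESSION_ARMS = ("repro", "half_gad", "half_slice", "contrast_time")

#: Scar:blood contrast growth factors standing in for gadolinium-washout
#: kinetics at 10 / 20 / 30 min post-injection.  Monotone by construction;
#: they are a stand-in, not a fitted kinetic model.
CONTRAST_TIME_FACTORS = {10: 0.55, 20: 0.85, 30: 1.0}

#: Contrast scale applied to blood-pool and scar enhancement for a half dose
#: of gadolinium-based contrast agent.
HALF_GAD_FACTOR = 0.5


@dataclass
class PhantomSpec:
    """Parameters of the synthetic LA phantom.

    Intensity defaults put scar at +5 blood-pool SDs and the nulled wall at
    -2 blood-pool SDs (with ``noise_sd`` as the blood-pool SD), i.e. clearly
    separable under the 3.3-SD scar threshold, as in a well-nulled LGE
    acquisition 20-30 min post contrast.
    """

    la_radii: tuple[float, float, float] = (30.0, 25.0, 22.0)  # mm semi-axes
    vein_radius: float = 5.0  # mm
    vein_length: float = 12.0  # mm beyond the ostium
    laa_radius: float = 6.0
    laa_length: float = 10.0
    wall_thickness: float = 3.0  # mm
    scar_band_width: float = 6.0  # mm (geodesic width of the WACA band)
    band_offset: float = 4.0  # mm; band spans [offset, offset+width] from rims
    gap_spec: dict = field(default_factory=dict)  # pair -> [(pos deg, extent deg)]
    bp_mean: float = 100.0
    wall_mean: float = 80.0
    scar_mean: float = 150.0
    myo_mean: float = 80.0
    background_mean: float = 30.0
    noise_sd: float = 10.0
    # reconstructed voxel of the emulated 3D LGE protocol (mm)
    voxel_size: float | tuple[float, float, float] = (0.94, 0.94, 2.0)
    mesh_pitch: float = 2.0  # mm marching-cubes grid
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.la_radii) <= 0):
            raise ValueError("la_radii must be positive")
        for name in ("vein_radius", "vein_length", "wall_thickness",
                     "scar_band_width", "mesh_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if np.any(np.asarray(self.voxel_sizes) <= 0):
            raise ValueError("voxel_size must be positive")
        for pair, gaps in self.gap_spec.items():
            if pair not in PAIR_LABELS:
                raise ValueError(f"unknown vein pair {pair!r}")
            for _, extent in gaps:
                if not 0 <= extent < 360:
                    raise ValueError("gap extents must lie in [0, 360)")

    @property
    def voxel_sizes(self) -> np.ndarray:
        v = self.voxel_size
        if np.isscalar(v):
            return np.array([v, v, v], dtype=float)
        return np.asarray(v, dtype=float)

    @property
    def septum_center(self) -> np.ndarray:
        """Centre of the synthetic septal myocardium block (world mm)."""
        return np.array([0.0, -self.la_radii[1] - 20.0, 0.0])

    @property
    def septum_half(self) -> float:
        return 8.0  # mm half-width of the septal cube


@dataclass
class GroundTruth:
    """Exact per-face scar designation and the derived summary truths."""

    face_scar: np.ndarray  # bool per face
    pve_true: dict  # pair -> fraction in [0, 1]
    la_paas_true: float  # scar area / included (body) area, in [0, 1]

    def __post_init__(self) -> None:
        for v in self.pve_true.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("pve_true must lie in [0, 1]")
        if not 0.0 <= self.la_paas_true <= 1.0:
            raise ValueError("la_paas_true must lie in [0, 1]")


# ---------------------------------------------------------------------------
# implicit geometry
# ---------------------------------------------------------------------------


def _vein_axes(spec: PhantomSpec) -> dict:
    """Ostium anchor point and unit direction for each stub, from the spec."""
    radii = np.asarray(spec.la_radii)
    axes = {}
    items = list(_VEIN_DIRS.items()) + [("laa", _LAA_DIR)]
    for name, d in items:
        u = d / np.linalg.norm(d)
        t = 1.0 / np.linalg.norm(u / radii)  # ellipsoid surface along u
        length = spec.laa_length if name == "laa" else spec.vein_length
        radius = spec.laa_radius if name == "laa" else spec.vein_radius
        axes[name] = {
            "anchor": t * u,  # point on the (unworn) ellipsoid surface
            "dir": u,
            "length": length,
            "radius": radius,
        }
    return axes


def _capsule_sdf(p: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(p - closest, axis=1) - r


def _implicit(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Approximate signed distance (mm) to the endocardial surface, <0 inside."""
    p = np.asarray(points, dtype=np.float64)
    radii = np.asarray(spec.la_radii)
    q = p / radii
    g = np.linalg.norm(q, axis=1)
    grad = np.linalg.norm(q / radii, axis=1)
    f = (g - 1.0) / np.maximum(grad, 1e-12)  # first-order ellipsoid SDF
    for ax in _vein_axes(spec).values():
        a = ax["anchor"] - 2.0 * ax["dir"]  # start slightly inside the body
        b = ax["anchor"] + ax["length"] * ax["dir"]
        f = np.minimum(f, _capsule_sdf(p, a, b, ax["radius"]))
    return f


def _label_faces(spec: PhantomSpec, centroids: np.ndarray) -> np.ndarray:
    labels = np.full(len(centroids), LABELS["body"], dtype=np.int64)
    axes = _vein_axes(spec)
    for name, ax in axes.items():
        rel = centroids - ax["anchor"]
        along = rel @ ax["dir"]
        radial = np.linalg.norm(rel - np.outer(along, ax["dir"]), axis=1)
        sel = (along > 0.0) & (radial < ax["radius"] * 1.6)
        labels[sel] = LABELS[name]
    u = _MITRAL_DIR / np.linalg.norm(_MITRAL_DIR)
    cdir = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    cone = np.degrees(np.arccos(np.clip(cdir @ u, -1, 1))) < _MITRAL_HALF_ANGLE
    labels[cone & (labels == LABELS["body"])] = LABELS["mitral"]
    return labels


def _merge_gaps(gaps: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping circular arcs (position, extent) in degrees."""
    if not gaps:
        return []
    ivals = sorted((np.mod(p, 360.0), np.mod(p, 360.0) + e) for p, e in gaps)
    # duplicate into [360, 720) so arcs wrapping through 0 merge correctly
    expanded = sorted(ivals + [(s + 360.0, e + 360.0) for s, e in ivals])
    merged: list[list[float]] = []
    overlapped = False
    for s, e in expanded:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            overlapped = True
        else:
            merged.append([s, e])
    # arcs starting in [0, 360) cover the circle exactly once
    out = [(s, e) for s, e in merged if s < 360.0]
    if overlapped and len(out) < len(ivals):
        warnings.warn("overlapping gap arcs merged", stacklevel=2)
    return out


def _gap_total(merged: list[tuple[float, float]]) -> float:
    covered = np.zeros(3600, dtype=bool)  # 0.1-degree bins
    for s, e in merged:
        idx = (np.arange(int(round(s * 10)), int(round(e * 10)))) % 3600
        covered[idx] = True
    return covered.sum() / 10.0


def _in_gap(az: np.ndarray, merged: list[tuple[float, float]]) -> np.ndarray:
    hit = np.zeros(len(az), dtype=bool)
    for s, e in merged:
        a = np.mod(az - s, 360.0)
        hit |= a < (e - s)
    return hit


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------


def _grid_bounds(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    radii = np.asarray(spec.la_radii)
    reach = radii.max() + max(spec.vein_length, spec.laa_length) + spec.vein_radius
    lo = np.array([-reach, -reach, -reach])
    hi = np.array([reach, reach, reach])
    lo = np.minimum(lo, spec.septum_center - spec.septum_half)
    hi = np.maximum(hi, spec.septum_center + spec.septum_half)
    margin = spec.wall_thickness + 5.0
    return lo - margin, hi + margin


def make_shell(spec: PhantomSpec) -> tuple[SurfaceShell, GroundTruth]:
    """Triangulate the phantom endocardium and derive the scar ground truth.

    The scar band encircling each PV pair consists of the body faces whose
    geodesic distance from the pair's ostial rims lies in
    ``[band_offset, band_offset + scar_band_width]``, minus the configured
    gap arcs.  Gap positions/extents are expressed in normalised ring-arc
    units (360 = the full centreline length of the WACA ring), so a gap of
    extent g interrupts exactly g/360 of the ring's length and
    ``pve_true = (360 - total gap)/360`` is a length fraction.
    """
    pitch = spec.mesh_pitch
    radii = np.asarray(spec.la_radii)
    reach = radii.max() + max(spec.vein_length, spec.laa_length) + spec.vein_radius + 2 * pitch
    axis_pts = [np.arange(-reach, reach + pitch, pitch) for _ in range(3)]
    gx, gy, gz = np.meshgrid(*axis_pts, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    f = _implicit(spec, pts).reshape(gx.shape)
    verts, faces, _, _ = marching_cubes(f, level=0.0, spacing=(pitch, pitch, pitch))
    verts += np.array([axis_pts[0][0], axis_pts[1][0], axis_pts[2][0]])
    shell = SurfaceShell(vertices=verts, faces=faces)
    if shell.mesh.volume < 0:  # enforce outward winding
        shell = SurfaceShell(vertices=verts, faces=faces[:, ::-1])
    shell.face_label = _label_faces(spec, shell.face_centroid)

    face_scar = np.zeros(shell.n_faces, dtype=bool)
    pve_true = {}
    for pair in PAIR_LABELS:
        rims = ostial_rim_vertices(shell, PAIR_LABELS[pair])
        d = face_geodesics(shell, rims)
        band = (
            (shell.face_label == LABELS["body"])
            & (d >= spec.band_offset)
            & (d <= spec.band_offset + spec.scar_band_width)
        )
        merged = _merge_gaps(list(spec.gap_spec.get(pair, [])))
        total = _gap_total(merged)
        if total >= 360.0:
            pve_true[pair] = 0.0
            continue
        pve_true[pair] = (360.0 - total) / 360.0
        band_idx = np.where(band)[0]
        s = np.full(shell.n_faces, np.nan)
        s[band_idx], _ = ring_coordinate(shell, pair, band_idx)
        scar_sel = band.copy()
        scar_sel[band_idx] &= ~_in_gap(s[band_idx], merged)
        face_scar |= scar_sel

    areas = shell.face_area
    included = shell.face_label == LABELS["body"]
    la_paas_true = areas[face_scar].sum() / areas[included].sum()
    truth = GroundTruth(face_scar=face_scar, pve_true=pve_true, la_paas_true=la_paas_true)
    return shell, truth


def scar_width_for_fraction(spec: PhantomSpec, target: float, iters: int = 4) -> PhantomSpec:
    """Adjust ``scar_band_width`` so the true scar fraction lands near ``target``.

    Secant iteration on the (near-linear) width -> area-fraction map; the
    returned spec's exact ``la_paas_true`` is still taken from its own
    ground truth, so the calibration only needs to be approximate.
    """
    width = spec.scar_band_width
    for _ in range(iters):
        trial = replace(spec, scar_band_width=width)
        _, truth = make_shell(trial)
        frac = truth.la_paas_true
        if abs(frac - target) < 0.004 or frac <= 0:
            break
        width = float(np.clip(width * target / frac, 0.5, 30.0))
    return replace(spec, scar_band_width=width)


# ---------------------------------------------------------------------------
# voxelisation
# ---------------------------------------------------------------------------


def voxelise(shell: SurfaceShell, truth: GroundTruth, spec: PhantomSpec) -> ImageVolume:
    """Render the phantom into an LGE-like volume.

    Voxels inside the endocardium get blood-pool intensity; a wall-thickness
    rind gets nulled-wall intensity except where its nearest shell face is
    scar, which gets scar intensity.  The septal block gets myocardial
    intensity.  Additive white Gaussian noise with ``noise_sd`` is applied
    everywhere, seeded from ``spec.seed``.
    """
    vsz = spec.voxel_sizes
    if np.any(vsz > spec.wall_thickness):
        warnings.warn(
            "voxel size exceeds wall thickness: partial-volume regime", stacklevel=2
        )
    lo, hi = _grid_bounds(spec)
    shape = np.ceil((hi - lo) / vsz).astype(int) + 1
    affine = np.diag([*vsz, 1.0])
    affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * vsz + lo
    f = _implicit(spec, pts)

    data = np.full(pts.shape[0], spec.background_mean)
    data[f < 0] = spec.bp_mean
    wall = (f >= 0) & (f < spec.wall_thickness)
    if np.any(wall):
        tree = cKDTree(shell.face_centroid)
        _, nearest = tree.query(pts[wall])
        scar_vox = truth.face_scar[nearest]
        data[wall] = np.where(scar_vox, spec.scar_mean, spec.wall_mean)
    sept = np.all(np.abs(pts - spec.septum_center) <= spec.septum_half, axis=1)
    data[sept] = spec.myo_mean

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return ImageVolume(data=data.reshape(shape), spacing=vsz, affine=affine)


# ---------------------------------------------------------------------------
# acquisition sessions
# ---------------------------------------------------------------------------


def _with_contrast(spec: PhantomSpec, scar_factor: float, bp_factor: float = 1.0) -> PhantomSpec:
    """Scale contrast enhancement of scar (over blood pool) and blood pool
    (over background)."""
    bg = spec.background_mean
    bp = bg + (spec.bp_mean - bg) * bp_factor
    return replace(
        spec,
        bp_mean=bp,
        scar_mean=bp + (spec.scar_mean - spec.bp_mean) * scar_factor,
    )


@dataclass
class PhantomSession:
    """One subject's shell, ground truth and the session's acquisitions."""

    shell: SurfaceShell
    truth: GroundTruth
    volumes: list
    tags: list  # acquisition tags, e.g. timing in minutes or arm labels
    specs: list  # the per-acquisition PhantomSpec actually rendered


def make_session(spec: PhantomSpec, arm: str) -> PhantomSession:
    """Generate a multi-acquisition session for one synthetic subject.

    Arms mirror a cross-over reproducibility design: ``repro`` re-renders the
    same object with fresh noise; ``half_gad`` halves the contrast
    enhancement; ``half_slice`` halves the z voxel size; ``contrast_time``
    renders 10/20/30-minute-equivalent acquisitions with strictly increasing
    scar:blood contrast.  The shell and ground truth are shared by all
    acquisitions of the session (the common-shell design of the measurement).
    """
    if arm not in SESSION_ARMS:
        raise ValueError(f"unknown arm {arm!r}; choose from {SESSION_ARMS}")
    shell, truth = make_shell(spec)
    specs: list[PhantomSpec] = []
    tags: list[str] = []
    if arm == "repro":
        for i in range(2):
            specs.append(replace(spec, seed=spec.seed + 101 * (i + 1)))
            tags.append(f"repro_{i + 1}")
    elif arm == "half_gad":
        specs.append(replace(spec, seed=spec.seed + 101))
        tags.append("standard")
        half = _with_contrast(spec, HALF_GAD_FACTOR, HALF_GAD_FACTOR)
        specs.append(replace(half, seed=spec.seed + 202))
        tags.append("half_gad")
    elif arm == "half_slice":
        specs.append(replace(spec, seed=spec.seed + 101))
        tags.append("standard")
        vsz = spec.voxel_sizes.copy()
        vsz[2] /= 2.0
        specs.append(replace(spec, voxel_size=tuple(vsz), seed=spec.seed + 202))
        tags.append("half_slice")
    else:  # contrast_time
        for i, (minutes, factor) in enumerate(sorted(CONTRAST_TIME_FACTORS.items())):
            specs.append(
                replace(_with_contrast(spec, factor), seed=spec.seed + 101 * (i + 1))
            )
            tags.append(f"{minutes}min")
    volumes = [voxelise(shell, truth, s) for s in specs]
    return PhantomSession(shell=shell, truth=truth, volumes=volumes, tags=tags, specs=specs)


def reference_roi_spec(shell: SurfaceShell, truth: GroundTruth, spec: PhantomSpec) -> RoiSpec:
    """ROI placement metadata for the phantom's reference slice (z = 0).

    The blood-pool ROI sits at the LA centre, the myocardial ROI at the
    centre of the septal block, and the scar search is seeded at the scar
    face nearest the reference slice.
    """
    scar_faces = np.where(truth.face_scar)[0]
    if len(scar_faces) == 0:
        scar_hint = np.array([spec.la_radii[0], 0.0, 0.0])
    else:
        cz = shell.face_centroid[scar_faces]
        scar_hint = cz[np.argmin(np.abs(cz[:, 2]))]
        scar_hint = np.array([scar_hint[0], scar_hint[1], 0.0])
    return RoiSpec(
        bp_center=np.zeros(3),
        myo_center=spec.septum_center,
        scar_center=scar_hint,
        slice_world_z=0.0,
    )
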
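"""Core domain types and file I/O.

The pipeline works with three kinds of objects: a 3-D late-gadolinium-
enhancement (LGE) image volume, a triangulated left-atrial (LA) endocardial
shell carrying one signal-intensity (SI) value per face, and a six-degree-of-
freedom rigid transform.  All geometry lives in world millimetres; voxel
indices are 0-based and the volume affine maps index -> world mm.

Volumes are stored as NIfTI-1 (.nii / .nii.gz) via nibabel.  Shells are stored
as legacy ASCII VTK polydata with CELL_DATA scalars: one float array for the
per-face SI and one integer array for the anatomical label.  The VTK legacy
format is line-oriented plain text and is read/written directly here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

__all__ = [
    "OUTSIDE",
    "LABELS",
    "LABEL_NAMES",
    "FormatError",
    "ImageVolume",
    "SurfaceShell",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_shell",
    "write_shell",
    "sample_trilinear",
    "apply_rigid",
]

#: Sentinel for samples taken outside the image grid.  -inf can never win a
#: maximum-intensity projection and is easy to mask out of a mean.
OUTSIDE = -np.inf

#: Anatomical face labels.  "body" is the LA body proper; the four pulmonary
#: vein (PV) ostium stubs, the LA appendage (LAA) and the mitral annulus
#: region are excluded from scar-burden denominators.
LABELS = {
    "body": 0,
    "lspv": 1,
    "lipv": 2,
    "rspv": 3,
    "ripv": 4,
    "laa": 5,
    "mitral": 6,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


class FormatError(ValueError):
    """Raised when a file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# ImageVolume
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A 3-D scalar image with voxel spacing and an index->world-mm affine.

    Parameters
    ----------
    data
        3-D array of signal intensities (arbitrary units).
    spacing
        Voxel edge length in mm along each array axis; all entries > 0.
    affine
        4x4 homogeneous matrix mapping 0-based voxel index to world mm.
    """

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError("volume data must be 3-D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise FormatError("spacing must be three positive values")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI-1 volume as an :class:`ImageVolume`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D data, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=np.float64)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: affine is not invertible")
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    return ImageVolume(data=data, spacing=spacing, affine=affine)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# SurfaceShell
# ---------------------------------------------------------------------------


@dataclass
class SurfaceShell:
    """Closed triangle mesh of the LA endocardium with per-face channels.

    ``face_scalar`` holds one SI value per face (NaN where the projection
    found no in-grid sample); ``face_label`` holds the anatomical label codes
    of :data:`LABELS`.  Face areas are recomputed from the geometry, never
    read from file.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_scalar: np.ndarray = field(default=None)  # type: ignore[assignment]
    face_label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be triangles (m, 3)")
        n_faces = len(self.faces)
        if self.face_scalar is None:
            self.face_scalar = np.full(n_faces, np.nan)
        self.face_scalar = np.asarray(self.face_scalar, dtype=np.float64)
        if self.face_label is None:
            self.face_label = np.zeros(n_faces, dtype=np.int64)
        self.face_label = np.asarray(self.face_label, dtype=np.int64)
        if len(self.face_scalar) != n_faces or len(self.face_label) != n_faces:
            raise FormatError("per-face channels must match the face count")
        self._mesh: trimesh.Trimesh | None = None

    # -- geometry (delegated to trimesh, cached) ---------------------------

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._mesh

    @property
    def face_area(self) -> np.ndarray:
        return self.mesh.area_faces

    @property
    def face_normal(self) -> np.ndarray:
        return self.mesh.face_normals

    @property
    def face_centroid(self) -> np.ndarray:
        return self.mesh.triangles_center

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_closed(self) -> bool:
        return bool(self.mesh.is_watertight)

    def copy(self) -> "SurfaceShell":
        return SurfaceShell(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            face_scalar=self.face_scalar.copy(),
            face_label=self.face_label.copy(),
        )

    def with_scalar(self, scalar: np.ndarray) -> "SurfaceShell":
        out = self.copy()
        out.face_scalar = np.asarray(scalar, dtype=np.float64)
        if len(out.face_scalar) != out.n_faces:
            raise FormatError("scalar length must match face count")
        return out


# -- legacy VTK polydata I/O ------------------------------------------------

_SCALAR_NAME = "signal_intensity"
_LABEL_NAME = "anatomical_label"


def write_shell(shell: SurfaceShell, path: str | Path) -> None:
    """Write a shell as legacy ASCII VTK polydata with CELL_DATA arrays."""
    lines: list[str] = [
        "# vtk DataFile Version 3.0",
        "atriascar LA shell",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(shell.vertices)} double",
    ]
    for v in shell.vertices:
        lines.append(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    m = shell.n_faces
    lines.append(f"POLYGONS {m} {4 * m}")
    for f in shell.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    lines.append(f"CELL_DATA {m}")
    lines.append(f"SCALARS {_SCALAR_NAME} double 1")
    lines.append("LOOKUP_TABLE default")
    for s in shell.face_scalar:
        lines.append(f"{s:.17g}")
    lines.append(f"SCALARS {_LABEL_NAME} int 1")
    lines.append("LOOKUP_TABLE default")
    for lab in shell.face_label:
        lines.append(str(int(lab)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_shell(path: str | Path) -> SurfaceShell:
    """Read legacy ASCII VTK polydata into a :class:`SurfaceShell`.

    Non-triangle cells raise :class:`FormatError`.  A missing SI scalar array
    yields NaN scalars with a warning; a missing label array yields all-body
    labels.
    """
    path = Path(path)
    tokens = path.read_text().split("\n")
    # token stream, skipping the 2-line header + title
    flat: list[str] = []
    for ln in tokens[2:]:
        flat.extend(ln.split())
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        out = flat[pos : pos + n]
        if len(out) < n:
            raise FormatError(f"{path}: truncated file")
        pos += n
        return out

    def expect(word: str) -> None:
        got = take(1)[0]
        if got.upper() != word:
            raise FormatError(f"{path}: expected {word!r}, found {got!r}")

    expect("ASCII")
    expect("DATASET")
    expect("POLYDATA")
    expect("POINTS")
    n_pts = int(take(1)[0])
    take(1)  # dtype
    verts = np.array(take(3 * n_pts), dtype=np.float64).reshape(n_pts, 3)
    expect("POLYGONS")
    n_cells = int(take(1)[0])
    n_ints = int(take(1)[0])
    cell_ints = np.array(take(n_ints), dtype=np.int64)
    faces = np.empty((n_cells, 3), dtype=np.int64)
    i = 0
    for c in range(n_cells):
        k = cell_ints[i]
        if k != 3:
            raise FormatError(f"{path}: cell {c} has {k} vertices; triangles required")
        faces[c] = cell_ints[i + 1 : i + 4]
        i += 4
    scalar = None
    label = None
    while pos < len(flat):
        word = take(1)[0].upper()
        if word == "CELL_DATA":
            n = int(take(1)[0])
            if n != n_cells:
                raise FormatError(f"{path}: CELL_DATA size {n} != {n_cells} cells")
        elif word == "SCALARS":
            name = take(1)[0]
            take(1)  # dtype
            # optional numComp then LOOKUP_TABLE
            nxt = take(1)[0]
            if nxt.upper() != "LOOKUP_TABLE":
                expect("LOOKUP_TABLE")
            take(1)  # table name
            vals = take(n_cells)
            if name == _LABEL_NAME:
                label = np.array(vals, dtype=np.int64)
            else:
                scalar = np.array(vals, dtype=np.float64)
        elif word == "POINT_DATA":
            n = int(take(1)[0])
            # skip over point-data arrays we do not use
            pos = len(flat)
        else:
            raise FormatError(f"{path}: unexpected token {word!r}")
    if scalar is None:
        warnings.warn(f"{path}: no SI scalar channel; filling with NaN", stacklevel=2)
    return SurfaceShell(vertices=verts, faces=faces, face_scalar=scalar, face_label=label)


# ---------------------------------------------------------------------------
# RigidTransform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Six-degree-of-freedom rigid transform.

    Rotation is parameterised as intrinsic XYZ Euler angles in degrees,
    applied about the world origin before the translation (in mm):
    ``y = R x + t``.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = Rotation.from_euler("XYZ", self.rotation, degrees=True).as_matrix()
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        rot = Rotation.from_matrix(m[:3, :3]).as_euler("XYZ", degrees=True)
        return cls(rotation=tuple(rot), translation=tuple(m[:3, 3]))

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        """Build from a flat (tx, ty, tz, rx, ry, rz) parameter vector."""
        p = np.asarray(params, dtype=np.float64)
        return cls(rotation=tuple(p[3:6]), translation=tuple(p[0:3]))

    @property
    def params(self) -> np.ndarray:
        return np.array([*self.translation, *self.rotation], dtype=np.float64)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        m = self.matrix
        return pts @ m[:3, :3].T + m[:3, 3]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# rigid transform: tx ty tz (mm) rx ry rz (deg, intrinsic XYZ)\n")
            fh.write(" ".join(f"{v:.17g}" for v in self.params) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        vals = []
        for ln in Path(path).read_text().splitlines():
            if ln.strip().startswith("#") or not ln.strip():
                continue
            vals.extend(float(x) for x in ln.split())
        if len(vals) != 6:
            raise FormatError(f"{path}: expected 6 transform parameters, got {len(vals)}")
        return cls.from_params(np.array(vals))


def apply_rigid(t: RigidTransform, obj: SurfaceShell | np.ndarray):
    """Apply a rigid transform to a shell (returning a new shell) or points.

    Scalar and label channels are carried over untouched.
    """
    if isinstance(obj, SurfaceShell):
        return SurfaceShell(
            vertices=t.apply_points(obj.vertices),
            faces=obj.faces.copy(),
            face_scalar=obj.face_scalar.copy(),
            face_label=obj.face_label.copy(),
        )
    return t.apply_points(obj)


# ---------------------------------------------------------------------------
# Trilinear sampling
# ---------------------------------------------------------------------------


def sample_trilinear(vol: ImageVolume, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate ``vol`` at world-mm ``points``.

    Points whose interpolation stencil falls outside the voxel grid return the
    :data:`OUTSIDE` sentinel (-inf), which can never win a maximum and is
    excluded from means downstream.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    idx = vol.world_to_index(pts)
    shape = np.array(vol.shape)
    inside = np.all((idx >= 0.0) & (idx <= shape - 1), axis=1)
    out = np.full(len(pts), OUTSIDE)
    if np.any(inside):
        coords = idx[inside].T
        out[inside] = map_coordinates(vol.data, coords, order=1, mode="nearest")
    return out
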
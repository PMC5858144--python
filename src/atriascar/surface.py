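"""Surface-geometry helpers shared by the phantom generator and scar metrics.

Geodesic distances are approximated by shortest paths on the mesh edge graph
(Dijkstra with Euclidean edge lengths).  On the meshes used here (edge length
well below every geodesic band width) the graph approximation is accurate to
a fraction of the edge length, which is all the band definitions require.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .core import LABELS, SurfaceShell

__all__ = [
    "edge_graph",
    "vertex_geodesics",
    "face_geodesics",
    "ostial_rim_vertices",
    "pair_axis",
    "face_azimuth",
    "ring_coordinate",
    "PAIR_LABELS",
]

#: Ipsilateral pulmonary-vein pairs targeted by a WACA lesion set.
PAIR_LABELS = {
    "left": (LABELS["lspv"], LABELS["lipv"]),
    "right": (LABELS["rspv"], LABELS["ripv"]),
}


def edge_graph(shell: SurfaceShell):
    """Sparse symmetric vertex-adjacency matrix weighted by edge length."""
    edges = shell.mesh.edges_unique
    lengths = shell.mesh.edges_unique_length
    n = len(shell.vertices)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.concatenate([lengths, lengths])
    return coo_matrix((w, (i, j)), shape=(n, n)).tocsr()


def vertex_geodesics(shell: SurfaceShell, seed_vertices: np.ndarray) -> np.ndarray:
    """Graph-geodesic distance (mm) from the nearest seed vertex to every vertex."""
    graph = edge_graph(shell)
    d = dijkstra(graph, directed=False, indices=np.asarray(seed_vertices))
    if d.ndim == 2:
        d = d.min(axis=0)
    return d


def face_geodesics(shell: SurfaceShell, seed_vertices: np.ndarray) -> np.ndarray:
    """Per-face geodesic distance: mean of the face's vertex distances."""
    dv = vertex_geodesics(shell, seed_vertices)
    return dv[shell.faces].mean(axis=1)


def ostial_rim_vertices(shell: SurfaceShell, labels: tuple[int, ...]) -> np.ndarray:
    """Vertices on the rim between labelled (vein) faces and body faces.

    The rim is where a vein-ostium stub meets the LA body: vertices incident
    to at least one face with a label in ``labels`` and one body face.
    """
    lab = shell.face_label
    vein_faces = np.isin(lab, labels)
    body_faces = lab == LABELS["body"]
    in_vein = np.zeros(len(shell.vertices), dtype=bool)
    in_body = np.zeros(len(shell.vertices), dtype=bool)
    in_vein[np.unique(shell.faces[vein_faces])] = True
    in_body[np.unique(shell.faces[body_faces])] = True
    rim = np.where(in_vein & in_body)[0]
    if len(rim) == 0:
        raise ValueError(f"no ostial rim found for labels {labels}")
    return rim


def pair_axis(shell: SurfaceShell, pair: str) -> np.ndarray:
    """Unit axis from the shell centroid through the PV pair's ostia."""
    labels = PAIR_LABELS[pair]
    sel = np.isin(shell.face_label, labels)
    if not np.any(sel):
        raise ValueError(f"shell has no faces labelled for pair {pair!r}")
    centre = shell.vertices.mean(axis=0)
    axis = shell.face_centroid[sel].mean(axis=0) - centre
    return axis / np.linalg.norm(axis)


def face_azimuth(shell: SurfaceShell, pair: str) -> np.ndarray:
    """Azimuth (deg, [0, 360)) of each face centroid about the pair axis.

    Zero azimuth lies along the projection of +z onto the plane normal to the
    axis; the angle increases right-handedly about the outward axis.  The
    convention is fixed so that configured gap arcs land at reproducible
    locations on the WACA ring.
    """
    u = pair_axis(shell, pair)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ref @ u) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    rel = shell.face_centroid - shell.vertices.mean(axis=0)
    ang = np.degrees(np.arctan2(rel @ e2, rel @ e1))
    return np.mod(ang, 360.0)


def ring_coordinate(
    shell: SurfaceShell, pair: str, band_faces: np.ndarray, bin_deg: float = 2.0
) -> tuple[np.ndarray, float]:
    """Normalised arc-length coordinate along a band's ring, plus ring length.

    The ring encircling a PV pair on the LA surface is generally eccentric,
    so equal azimuth steps do not subtend equal arc lengths.  This maps each
    band face's azimuth to the cumulative centreline arc length of the band
    (computed from azimuth-binned band centroids), rescaled so the full ring
    spans 360 units.  A gap covering g of these units therefore interrupts
    exactly g/360 of the ring's length.  Returns the per-face coordinate in
    [0, 360) and the centreline length in mm.
    """
    az_all = face_azimuth(shell, pair)
    az = az_all[band_faces]
    cent = shell.face_centroid[band_faces]
    nbins = int(round(360.0 / bin_deg))
    idx = np.minimum((az / bin_deg).astype(int), nbins - 1)
    means = np.full((nbins, 3), np.nan)
    for b in range(nbins):
        sel = idx == b
        if np.any(sel):
            means[b] = cent[sel].mean(axis=0)
    filled = np.where(np.all(np.isfinite(means), axis=1))[0]
    if len(filled) < 3:
        raise ValueError("band too sparse for a ring parameterisation")
    pts = means[filled]
    # circular moving average: raw bin means jitter radially across the
    # band's width, which would inflate the centreline length
    win = min(9, len(pts) // 2 * 2 - 1)
    if win >= 3:
        kernel = np.ones(win) / win
        padded = np.vstack([pts[-(win // 2):], pts, pts[: win // 2]])
        pts = np.column_stack(
            [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)]
        )
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    # cumulative length at each filled bin's centre, normalised to 360
    cum = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    total = seg.sum()
    s_bins = 360.0 * cum / total
    bin_az = (filled + 0.5) * bin_deg
    # azimuth and arc coordinate increase together; interpolate across the
    # 0/360 seam by tiling one period
    xp = np.concatenate([bin_az, bin_az + 360.0])
    fp = np.concatenate([s_bins, s_bins + 360.0])
    a = np.where(az < bin_az[0], az + 360.0, az)
    s = np.interp(a, xp, fp)
    return np.mod(s, 360.0), float(total)
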
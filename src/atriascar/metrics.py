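"""Thresholded-scar summary metrics: %LA PAAS, Dice co-location and PVE.

%LA PAAS is the percentage of the LA shell surface area designated scar,
with the PV ostium stubs, appendage and mitral region excluded from the
denominator (the anatomical LA body).  The Dice similarity coefficient
2|A∩B| / (|A| + |B|) measures face-by-face co-location of two scar masks on
a common shell, area-weighted.

Pulmonary-vein encirclement (PVE) quantifies gaps in the wide-area
circumferential ablation (WACA) line around each ipsilateral PV pair.  The
WACA route is defined as the minimum-cost closed cycle through the
peri-ostial band (faces 3-15 mm geodesic from the pair's ostial rims) that
is non-contractible around the pair, where traversing a non-scar face costs
``gap_penalty`` times its length.  The route therefore follows uninterrupted
scar wherever it exists and crosses gaps only where it must; PVE is the
percentage of the route length lying on scar, and the maximal contiguous
non-scar runs are reported as gaps.

Non-contractibility is enforced with a seam construction: a cut from the
ostium to the band's outer boundary, with routes required to cross the seam
an odd number of times (shortest odd-parity cycle in the double cover of the
band's face-adjacency graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .core import LABELS, SurfaceShell
from .surface import (
    PAIR_LABELS,
    face_geodesics,
    ostial_rim_vertices,
    ring_coordinate,
    vertex_geodesics,
)

__all__ = [
    "ScarMask",
    "EncirclementResult",
    "percent_la_paas",
    "dice",
    "compute_pve",
    "EXCLUDED_LABELS",
]

#: Labels excluded from the %LA PAAS denominator (not anatomical LA body).
EXCLUDED_LABELS = (
    LABELS["lspv"],
    LABELS["lipv"],
    LABELS["rspv"],
    LABELS["ripv"],
    LABELS["laa"],
    LABELS["mitral"],
)


@dataclass
class ScarMask:
    """Boolean per-face scar designation tied to the shell it indexes."""

    values: np.ndarray
    shell_ref: SurfaceShell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if len(self.values) != self.shell_ref.n_faces:
            raise ValueError("mask length must equal the shell's face count")


@dataclass
class EncirclementResult:
    """A WACA route around one PV pair with its scar/gap decomposition."""

    route_faces: np.ndarray  # ordered face indices of the closed cycle
    route_points: np.ndarray  # face centroids along the cycle (n, 3)
    segment_length: np.ndarray  # mm contributed by each route face
    segment_scar: np.ndarray  # bool per route face
    pve: float  # percent of route length on scar
    gaps: list  # (start arc-length mm, end arc-length mm) maximal non-scar runs
    route_cost: float  # total penalised cost of the cycle


def _circ_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed circular difference a - b mapped into (-180, 180]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + 180.0, 360.0) - 180.0
    return np.where(d == -180.0, 180.0, d)


def _check_same_shell(a: ScarMask, b: ScarMask) -> None:
    sa, sb = a.shell_ref, b.shell_ref
    if sa is sb:
        return
    if sa.n_faces != sb.n_faces or not np.array_equal(sa.faces, sb.faces):
        raise ValueError("masks do not index an identical shell")


def percent_la_paas(
    mask: ScarMask,
    shell: SurfaceShell | None = None,
    area_weighted: bool = True,
) -> float:
    """Percentage of included LA surface area occupied by scar.

    Included faces are the anatomical body (PV stubs, appendage and mitral
    faces excluded).  ``area_weighted=False`` switches to a face-count
    fraction.
    """
    shell = shell if shell is not None else mask.shell_ref
    if len(mask.values) != shell.n_faces:
        raise ValueError("mask does not index this shell")
    included = ~np.isin(shell.face_label, EXCLUDED_LABELS)
    w = shell.face_area if area_weighted else np.ones(shell.n_faces)
    denom = w[included].sum()
    if denom <= 0:
        raise ValueError("no included surface area")
    return 100.0 * w[included & mask.values].sum() / denom


def dice(mask_a: ScarMask, mask_b: ScarMask, area_weighted: bool = True) -> float:
    """Sørensen-Dice coefficient 2|A∩B| / (|A| + |B|) of two scar masks.

    Area-weighted over faces of the common shell.  Two empty masks are
    identical as sets, so the empty/empty case returns 1.0 by convention.
    """
    _check_same_shell(mask_a, mask_b)
    shell = mask_a.shell_ref
    w = shell.face_area if area_weighted else np.ones(shell.n_faces)
    a, b = mask_a.values, mask_b.values
    denom = w[a].sum() + w[b].sum()
    if denom == 0:
        return 1.0
    return float(2.0 * w[a & b].sum() / denom)


# ---------------------------------------------------------------------------
# PVE
# ---------------------------------------------------------------------------


def _band_faces(
    shell: SurfaceShell, pair: str, d_min: float, d_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Faces of the peri-ostial band and the per-face geodesic distances."""
    rims = ostial_rim_vertices(shell, PAIR_LABELS[pair])
    d = face_geodesics(shell, rims)
    band = (
        (d >= d_min)
        & (d <= d_max)
        & ~np.isin(shell.face_label, list(PAIR_LABELS[pair]))
    )
    return np.where(band)[0], d


def _seam_crossing_edges(
    shell: SurfaceShell, ostium_label: int, pair: str, d_max: float
) -> set:
    """Dual edges (face pairs) whose crossing counts as crossing a seam.

    The seam for one ostium is a vertex path of steepest ascent of the pair's
    geodesic-distance field, from that ostium's rim out beyond the band's
    outer boundary; a route crosses the seam when it steps across one of the
    seam's mesh edges.  A closed route that is non-contractible around the
    ostium crosses its seam an odd number of times.
    """
    pair_rims = ostial_rim_vertices(shell, PAIR_LABELS[pair])
    dv = vertex_geodesics(shell, pair_rims)
    own_rims = ostial_rim_vertices(shell, (ostium_label,))
    neighbours = shell.mesh.vertex_neighbors
    v = int(own_rims[0])
    seam_vertices = [v]
    while dv[v] <= d_max + 1e-9:
        nbrs = [int(n) for n in neighbours[v] if dv[n] > dv[v]]
        if not nbrs:
            break
        v = max(nbrs, key=lambda n: dv[n])
        seam_vertices.append(v)
    seam_edges = {
        tuple(sorted((seam_vertices[i], seam_vertices[i + 1])))
        for i in range(len(seam_vertices) - 1)
    }
    crossings = set()
    adj = shell.mesh.face_adjacency
    adj_edges = shell.mesh.face_adjacency_edges
    for (f1, f2), (v1, v2) in zip(adj, adj_edges):
        if tuple(sorted((int(v1), int(v2)))) in seam_edges:
            crossings.add((int(f1), int(f2)))
            crossings.add((int(f2), int(f1)))
    return crossings


def compute_pve(
    mask: ScarMask,
    shell: SurfaceShell | None = None,
    pair: str = "left",
    d_min: float = 3.0,
    d_max: float = 15.0,
    gap_penalty: float = 10.0,
    min_feature: float = 2.0,
) -> EncirclementResult:
    """Pulmonary-vein encirclement of one PV pair from a thresholded shell.

    Builds the peri-ostial band, finds the minimum-cost non-contractible
    closed route through its face-adjacency graph (non-scar faces penalised
    by ``gap_penalty``), and decomposes the route into scar and gap runs.
    """
    shell = shell if shell is not None else mask.shell_ref
    if pair not in PAIR_LABELS:
        raise ValueError(f"unknown vein pair {pair!r}")
    if not np.any(np.isin(shell.face_label, PAIR_LABELS[pair])):
        raise ValueError(f"shell has no ostium labels for pair {pair!r}")
    band, dists = _band_faces(shell, pair, d_min, d_max)
    if len(band) < 3:
        raise ValueError("no encircling route: peri-ostial band is empty")

    local = {f: i for i, f in enumerate(band)}
    centroids = shell.face_centroid[band]
    scar = mask.values[band]
    penalty = np.where(scar, 1.0, gap_penalty)

    # dual-graph edges within the band
    adj = shell.mesh.face_adjacency
    in_band = np.isin(adj, band)
    both = in_band.all(axis=1)
    pairs = adj[both]
    cross_a = _seam_crossing_edges(shell, PAIR_LABELS[pair][0], pair, d_max)
    cross_b = _seam_crossing_edges(shell, PAIR_LABELS[pair][1], pair, d_max)

    nb = len(band)
    edges = []  # (i, j, weight, flip_a, flip_b)
    for f1, f2 in pairs:
        i, j = local[int(f1)], local[int(f2)]
        d = float(np.linalg.norm(centroids[i] - centroids[j]))
        w = 0.5 * d * (penalty[i] + penalty[j])
        key = (int(f1), int(f2))
        edges.append((i, j, w, key in cross_a, key in cross_b))

    # four-fold cover: node (i, parity_a, parity_b); a route encircling the
    # whole pair flips both parities exactly once
    def node(i: int, pa: int, pb: int) -> int:
        return i + nb * (pa + 2 * pb)

    dr, dc, dw = [], [], []
    for i, j, w, fa, fb in edges:
        for pa in (0, 1):
            for pb in (0, 1):
                qa, qb = pa ^ fa, pb ^ fb
                dr.extend([node(i, pa, pb), node(j, qa, qb)])
                dc.extend([node(j, qa, qb), node(i, pa, pb)])
                dw.extend([w, w])
    graph = coo_matrix((dw, (dr, dc)), shape=(4 * nb, 4 * nb)).tocsr()

    # candidate route faces: those incident to a seam crossing
    sources = sorted(
        {local[f] for e in (cross_a | cross_b) for f in e if f in local}
    )
    if not sources:
        raise ValueError("no encircling route: band does not cross the seams")
    dist_mat, pred = dijkstra(
        graph, directed=True, indices=sources, return_predecessors=True
    )
    goal = np.array(sources) + 3 * nb  # (src, 1, 1)
    costs = dist_mat[np.arange(len(sources)), goal]
    best = int(np.argmin(costs))
    if not np.isfinite(costs[best]):
        raise ValueError("no encircling route: band is disconnected")
    src = sources[best]
    # reconstruct path (src,0,0) -> (src,1,1); node mod nb is the band face
    path = [src + 3 * nb]
    while path[-1] != src:
        p = pred[best, path[-1]]
        if p < 0:
            raise ValueError("no encircling route: path reconstruction failed")
        path.append(int(p))
    cycle_local = [n % nb for n in reversed(path)][:-1]  # drop duplicate src

    route_faces = band[cycle_local]
    route_points = centroids[cycle_local]
    n = len(route_faces)
    # Segment lengths are measured along the ring centreline (each route
    # face's share of the ring-arc coordinate), not along the route polyline:
    # the optimal route may cross a gap slightly inside the nominal ring,
    # and the WACA-line share of a gap is its extent along the line itself.
    s_band, ring_len = ring_coordinate(shell, pair, band)
    s_route = s_band[cycle_local]
    step = _circ_diff(np.roll(s_route, -1), s_route)  # face i -> i+1
    if step.sum() < 0:  # normalise the route's winding direction
        route_faces = route_faces[::-1]
        route_points = route_points[::-1]
        s_route = s_route[::-1]
        step = _circ_diff(np.roll(s_route, -1), s_route)
    seg_len = 0.5 * (step + np.roll(step, 1)) * (ring_len / 360.0)
    seg_scar = mask.values[route_faces]
    total = seg_len.sum()
    pve = 100.0 * seg_len[seg_scar].sum() / total

    gaps = _gap_runs(seg_len, seg_scar, min_feature)
    cost = float(costs[best])
    return EncirclementResult(
        route_faces=route_faces,
        route_points=route_points,
        segment_length=seg_len,
        segment_scar=seg_scar,
        pve=float(pve),
        gaps=gaps,
        route_cost=cost,
    )


def _gap_runs(seg_len: np.ndarray, seg_scar: np.ndarray, min_feature: float = 0.0) -> list:
    """Maximal contiguous non-scar runs as (start, end) arc lengths in mm.

    For reporting, runs are morphologically cleaned at the mesh edge scale:
    scar islands shorter than ``min_feature`` mm do not split a gap, and gaps
    shorter than ``min_feature`` are not reported.  PVE itself is always the
    raw scar-length fraction of the route.
    """
    n = len(seg_scar)
    if seg_scar.all():
        return []
    if not seg_scar.any():
        return [(0.0, float(seg_len.sum()))]
    # rotate so the cycle starts at a scar face, keeping runs contiguous
    start = int(np.argmax(seg_scar))
    order = np.r_[start:n, 0:start]
    lens, scars = seg_len[order], seg_scar[order].copy()
    # close single short scar islands flanked by gap
    runs = []
    i = 0
    while i < n:
        j = i
        while j < n and scars[j] == scars[i]:
            j += 1
        runs.append((scars[i], i, j))
        i = j
    for state, i, j in runs[1:-1]:
        if state and lens[i:j].sum() < min_feature:
            scars[i:j] = False
    arc = np.r_[0.0, np.cumsum(lens)]
    gaps = []
    i = 0
    while i < n:
        if not scars[i]:
            j = i
            while j < n and not scars[j]:
                j += 1
            if arc[j] - arc[i] >= min_feature:
                gaps.append((float(arc[i]), float(arc[j])))
            i = j
        else:
            i += 1
    return gaps
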
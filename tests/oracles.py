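"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the ICC oracle
spells out the two-way ANOVA sums of squares with explicit loops, and the
route oracle searches the parity cover exhaustively with networkx.
"""

import numpy as np


def brute_force_icc(v, form):
    """Two-way single-rater ICC from explicit ANOVA sums of squares."""
    v = np.asarray(v, float)
    n, k = v.shape
    grand = v.sum() / (n * k)
    ssr = 0.0
    for i in range(n):
        ssr += k * (v[i].mean() - grand) ** 2
    ssc = 0.0
    for j in range(k):
        ssc += n * (v[:, j].mean() - grand) ** 2
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (v[i, j] - v[i].mean() - v[:, j].mean() + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_force_route_cost(shell, mask_values, pair, d_min=3.0, d_max=15.0,
                           gap_penalty=10.0):
    """Exhaustive minimum-cost non-contractible cycle on a peri-ostial band.

    Builds the four-state parity cover of the band's face-adjacency graph as
    an explicit networkx graph and takes the minimum over shortest paths from
    every band face's (0,0) node to its (1,1) node.
    """
    import networkx as nx

    from atriascar.metrics import _band_faces, _seam_crossing_edges
    from atriascar.surface import PAIR_LABELS

    band, _ = _band_faces(shell, pair, d_min, d_max)
    local = set(int(f) for f in band)
    cent = shell.face_centroid
    penalty = np.where(mask_values, 1.0, gap_penalty)
    cross_a = _seam_crossing_edges(shell, PAIR_LABELS[pair][0], pair, d_max)
    cross_b = _seam_crossing_edges(shell, PAIR_LABELS[pair][1], pair, d_max)
    g = nx.Graph()
    for f1, f2 in shell.mesh.face_adjacency:
        f1, f2 = int(f1), int(f2)
        if f1 not in local or f2 not in local:
            continue
        d = np.linalg.norm(cent[f1] - cent[f2])
        w = 0.5 * d * (penalty[f1] + penalty[f2])
        fa = (f1, f2) in cross_a
        fb = (f1, f2) in cross_b
        for pa in (0, 1):
            for pb in (0, 1):
                g.add_edge((f1, pa, pb), (f2, pa ^ fa, pb ^ fb), weight=w)
    best = np.inf
    for f in band:
        src, dst = (int(f), 0, 0), (int(f), 1, 1)
        if g.has_node(src) and g.has_node(dst):
            try:
                best = min(best, nx.dijkstra_path_length(g, src, dst))
            except nx.NetworkXNoPath:
                pass
    return best
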
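"""Low-level raster geometry: pixel-region outlines, unit-edge chaining, polygon moments.

All routines operate on integer pixel-corner coordinates ``(row, col)``;
conversion to physical µm coordinates happens in :mod:`gastruquant.tissue_model`.
A "unit edge" is a length-1 segment between two adjacent pixel corners.
"""

from __future__ import annotations

import numpy as np

# Direction vectors (drow, dcol). Turn preference when tracing a directed
# outline: right turn first (hug the interior), then straight, then left.
def _right(d):
    return (d[1], -d[0])


def _left(d):
    return (-d[1], d[0])


def region_outline_loops(mask: np.ndarray) -> list[np.ndarray]:
    """Trace the exact pixel-corner outline of a boolean region.

    Returns a list of closed loops, each an ``(n, 2)`` array of (row, col)
    corner coordinates (first vertex not repeated at the end). The outer loop
    is oriented so its shoelace area is positive in (row, col) axes; holes get
    the opposite sign. Degree-4 pinch corners (diagonal same-region pixels)
    are resolved by always turning toward the interior, so each loop is a
    closed walk that may revisit a vertex but never crosses itself.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    # Directed boundary edges with the interior on the right when rows grow
    # downward: top->E, right->S, bottom->W, left->N.
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def _emit(r0, c0, r1, c1):
        edges.setdefault((r0, c0), []).append((r1, c1))

    rows, cols = np.nonzero(mask)
    up = np.zeros_like(mask)
    up[1:, :] = mask[:-1, :]
    down = np.zeros_like(mask)
    down[:-1, :] = mask[1:, :]
    leftn = np.zeros_like(mask)
    leftn[:, 1:] = mask[:, :-1]
    rightn = np.zeros_like(mask)
    rightn[:, :-1] = mask[:, 1:]

    for r, c in zip(rows.tolist(), cols.tolist()):
        if not up[r, c]:
            _emit(r, c, r, c + 1)
        if not rightn[r, c]:
            _emit(r, c + 1, r + 1, c + 1)
        if not down[r, c]:
            _emit(r + 1, c + 1, r + 1, c)
        if not leftn[r, c]:
            _emit(r + 1, c, r, c)

    loops: list[np.ndarray] = []
    while edges:
        start = min(edges)
        cur = start
        nxt = min(edges[cur])
        _consume(edges, cur, nxt)
        loop = [cur]
        prev, cur = cur, nxt
        while cur != start:
            loop.append(cur)
            d = (cur[0] - prev[0], cur[1] - prev[1])
            cand = edges.get(cur, [])
            chosen = None
            for pref in (_right(d), d, _left(d)):
                target = (cur[0] + pref[0], cur[1] + pref[1])
                if target in cand:
                    chosen = target
                    break
            if chosen is None:  # dead end cannot happen for valid masks
                raise RuntimeError("outline tracing failed: open boundary")
            _consume(edges, cur, chosen)
            prev, cur = cur, chosen
        loops.append(np.asarray(loop, dtype=float))
    return loops


def _consume(edges, a, b):
    lst = edges[a]
    lst.remove(b)
    if not lst:
        del edges[a]


def chain_unit_edges(
    edge_list: list[tuple[tuple[int, int], tuple[int, int]]],
) -> list[np.ndarray]:
    """Chain undirected unit edges into maximal polylines.

    Open paths are walked from degree-1 endpoints; remaining closed loops are
    walked from their smallest vertex. At vertices of degree > 2 the walk
    prefers to continue straight, so a staircase path that pinches at a corner
    stays one chain. Returns ``(n, 2)`` float arrays of (row, col) vertices.
    """
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in edge_list:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    used: set[frozenset] = set()
    chains: list[np.ndarray] = []

    def _walk(start, first):
        used.add(frozenset((start, first)))
        chain = [start, first]
        prev, cur = start, first
        while True:
            d = (cur[0] - prev[0], cur[1] - prev[1])
            options = [
                n for n in adj.get(cur, []) if frozenset((cur, n)) not in used
            ]
            if not options:
                break
            straight = (cur[0] + d[0], cur[1] + d[1])
            nxt = straight if straight in options else sorted(options)[0]
            used.add(frozenset((cur, nxt)))
            chain.append(nxt)
            prev, cur = cur, nxt
        return np.asarray(chain, dtype=float)

    endpoints = sorted(v for v, ns in adj.items() if len(ns) == 1)
    for v in endpoints:
        for n in sorted(adj[v]):
            if frozenset((v, n)) not in used:
                chains.append(_walk(v, n))
    # leftover loops
    remaining = sorted(
        (frozenset((a, b)) for a, b in edge_list if frozenset((a, b)) not in used),
        key=lambda e: sorted(e),
    )
    for e in remaining:
        if e in used:
            continue
        a, b = sorted(e)
        chains.append(_walk(a, b))
    return chains


def polygon_moments(vertices: np.ndarray):
    """Signed area, centroid and second central moment (covariance) matrix
    of a simple polygon, by the standard shoelace/Green's-theorem formulas.

    ``vertices`` is an ``(n, 2)`` array of (x, y) coordinates, closure implied.
    Returns ``(area, (cx, cy), cov)`` where ``cov`` is normalized by area,
    i.e. the covariance of the uniform distribution over the polygon.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("polygon has zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    cov = np.array(
        [
            [ixx / area - cx * cx, ixy / area - cx * cy],
            [ixy / area - cx * cy, iyy / area - cy * cy],
        ]
    )
    return area, (cx, cy), cov


def polygon_self_intersects(vertices: np.ndarray) -> bool:
    """True if any two non-adjacent polygon edges properly cross."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    if n < 4:
        return False
    p = v
    q = np.roll(v, -1, axis=0)

    def orient(a, b, c):
        return (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1]) - (
            b[..., 1] - a[..., 1]
        ) * (c[..., 0] - a[..., 0])

    i, j = np.triu_indices(n, k=2)
    adjacent = (i == 0) & (j == n - 1)
    i, j = i[~adjacent], j[~adjacent]
    a, b = p[i], q[i]
    c, d = p[j], q[j]
    o1 = orient(a, b, c)
    o2 = orient(a, b, d)
    o3 = orient(c, d, a)
    o4 = orient(c, d, b)
    proper = (o1 * o2 < 0) & (o3 * o4 < 0)
    return bool(proper.any())


def polyline_length(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())
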
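"""Notochord-boundary metrics.

The notochord boundary is the interface between axial (notochord) and
paraxial (somitic) mesoderm. This module extracts the two boundary traces
(left/right of the axial strip), measures their straightness (traced length
over endpoint chord — 1.0 for a perfectly straight boundary), classifies
axial cells into boundary-distance rows (edge, −1, −2, ...), and classifies
cell–cell interfaces as Edge (on the boundary), V (ML-aligned,
shrink-competent) or T (AP-aligned) junctions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import chain_unit_edges, polyline_length
from .tissue_model import CellMesh, TrackedTimeLapse


class BoundaryError(ValueError):
    pass


@dataclass
class BoundaryTrace:
    vertices: np.ndarray  # (n, 2) µm (x=ML, y=AP), ordered anterior→posterior
    side: str  # 'left' or 'right'

    @property
    def total_length(self) -> float:
        return polyline_length(self.vertices)

    @property
    def net_length(self) -> float:
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))


def extract_boundary(mesh: CellMesh) -> tuple[BoundaryTrace, BoundaryTrace]:
    """Chain all axial–paraxial interface edges into the two boundary traces.

    Raises if no axial–paraxial contact exists or the border fragments into
    more than two maximal chains.
    """
    comp = {c.id: c.compartment for c in mesh.cells.values()}
    px = mesh.pixel_size
    edges = []
    for iface in mesh.interfaces:
        kinds = {comp[iface.cell_a], comp[iface.cell_b]}
        if kinds == {"axial", "paraxial"}:
            for ch in iface.chains:
                # convert back to corner units for exact chaining across interfaces
                pts = np.round(ch / px).astype(int)
                for k in range(len(pts) - 1):
                    a = (int(pts[k][1]), int(pts[k][0]))  # (row, col)
                    b = (int(pts[k + 1][1]), int(pts[k + 1][0]))
                    edges.append((a, b))
    if not edges:
        raise BoundaryError("no axial–paraxial interface: no boundary to trace")
    chains = chain_unit_edges(edges)
    if len(chains) != 2:
        raise BoundaryError(
            f"boundary fragmented into {len(chains)} chains (expected 2)"
        )
    axial_x = np.mean(
        [c.centroid[0] for c in mesh.cells.values() if c.compartment == "axial"]
    )
    traces = []
    for ch in chains:
        v = np.column_stack([ch[:, 1] * px, ch[:, 0] * px])
        if v[0, 1] > v[-1, 1]:  # anterior (small y) first
            v = v[::-1]
        side = "left" if v[:, 0].mean() < axial_x else "right"
        traces.append(BoundaryTrace(vertices=v, side=side))
    left = [t for t in traces if t.side == "left"]
    right = [t for t in traces if t.side == "right"]
    if len(left) != 1 or len(right) != 1:
        raise BoundaryError("could not assign one boundary trace per side")
    return left[0], right[0]


def straightness(trace: BoundaryTrace | np.ndarray) -> float:
    """Total traced length divided by the endpoint chord (net) length, ≥ 1."""
    v = trace.vertices if isinstance(trace, BoundaryTrace) else np.asarray(trace, float)
    if len(v) < 2:
        raise BoundaryError("trace needs >= 2 vertices")
    net = float(np.linalg.norm(v[-1] - v[0]))
    if net == 0:
        raise BoundaryError("coincident endpoints: net length undefined")
    return polyline_length(v) / net


def straightness_series(tl: TrackedTimeLapse) -> pd.DataFrame:
    """Per-frame, per-side straightness ratios plus the frame mean."""
    rows = []
    for mesh, t in zip(tl.frames, tl.timestamps):
        left, right = extract_boundary(mesh)
        rl, rr = straightness(left), straightness(right)
        for side, trace, ratio in (("left", left, rl), ("right", right, rr)):
            rows.append(
                {
                    "time_min": t,
                    "side": side,
                    "total_length_um": trace.total_length,
                    "net_length_um": trace.net_length,
                    "straightness": ratio,
                    "frame_mean": 0.5 * (rl + rr),
                }
            )
    return pd.DataFrame(rows)


def classify_rows(mesh: CellMesh) -> pd.DataFrame:
    """Boundary-distance row per axial cell.

    Edge cells (row 0) own at least one Edge interface; row k is the
    breadth-first graph distance k from the edge set within the axial
    adjacency subgraph, i.e. distance to the nearest of the two boundaries.
    Axial cells unreachable from the edge set are flagged disconnected.
    """
    comp = {c.id: c.compartment for c in mesh.cells.values()}
    axial = {cid for cid, k in comp.items() if k == "axial"}
    edge_cells = set()
    adj: dict[int, set[int]] = {cid: set() for cid in axial}
    for iface in mesh.interfaces:
        if not iface.adjacent:
            continue
        a, b = iface.cell_a, iface.cell_b
        ka, kb = comp[a], comp[b]
        if {ka, kb} == {"axial", "paraxial"}:
            edge_cells.add(a if ka == "axial" else b)
        elif ka == kb == "axial":
            adj[a].add(b)
            adj[b].add(a)
    dist = {cid: 0 for cid in edge_cells}
    q = deque(sorted(edge_cells))
    while q:
        cur = q.popleft()
        for nb in sorted(adj[cur]):
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                q.append(nb)
    rows = []
    for cid in sorted(axial):
        d = dist.get(cid)
        rows.append(
            {
                "cell_id": cid,
                "row": d if d is not None else -1,
                "row_label": (
                    "disconnected"
                    if d is None
                    else ("edge" if d == 0 else f"-{d}")
                ),
                "disconnected": d is None,
            }
        )
    return pd.DataFrame(rows)


def classify_junctions(mesh: CellMesh, v_half_angle: float = 30.0) -> pd.DataFrame:
    """Edge / V / T classification of cell–cell interfaces.

    Edge: any axial–paraxial interface (it lies on, and comprises, the
    notochord boundary). For axial–axial interfaces the endpoint-chord
    angle w.r.t. the ML axis (folded to [0°, 90°]) decides: V if
    ≤ ``v_half_angle`` (ML-aligned, shrink-competent), T if
    ≥ 90° − ``v_half_angle`` (AP-aligned); near-diagonal interfaces are
    reported as 'oblique' and excluded from V/T contrasts rather than
    silently forced into a class. Interfaces with coincident chord
    endpoints are 'point'; interfaces involving exterior cells are 'other'.
    """
    if not 0 < v_half_angle < 45:
        raise ValueError("v_half_angle must lie in (0, 45) degrees")
    comp = {c.id: c.compartment for c in mesh.cells.values()}
    rows = []
    for idx, iface in enumerate(mesh.interfaces):
        ka, kb = comp[iface.cell_a], comp[iface.cell_b]
        kinds = {ka, kb}
        angle = np.nan
        if kinds == {"axial", "paraxial"}:
            cls = "Edge"
        elif "exterior" in kinds or kinds == {"paraxial"}:
            cls = "other"
        else:  # axial–axial
            chord = iface.polyline[-1] - iface.polyline[0]
            if np.allclose(chord, 0):
                cls = "point"
            else:
                angle = np.degrees(np.arctan2(abs(chord[1]), abs(chord[0])))
                if angle <= v_half_angle:
                    cls = "V"
                elif angle >= 90.0 - v_half_angle:
                    cls = "T"
                else:
                    cls = "oblique"
        rows.append(
            {
                "interface_id": idx,
                "cell_a": iface.cell_a,
                "cell_b": iface.cell_b,
                "junction_class": cls,
                "interface_angle_deg": angle,
                "length_um": iface.length,
            }
        )
    return pd.DataFrame(rows)
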
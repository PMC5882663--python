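"""Tissue data model and I/O.

Converts segmented label images (one integer label per cell, 0 = membrane /
background) into polygonal cell meshes with explicit cell–cell interfaces and
an adjacency relation, the substrate for every tissue-side metric in this
package. Conventions:

* pixels are indexed ``(row, col)``; the anteroposterior (AP) axis runs along
  rows with anterior at row 0, the mediolateral (ML) axis along columns
  (the usual "anterior is up" display convention);
* physical coordinates are µm, ``x = col * pixel_size`` (ML),
  ``y = row * pixel_size`` (AP), polygon vertices sit on pixel corners;
* two cells are adjacent iff they share at least two 4-neighbor border pixel
  pairs — corner-point contacts and single-pixel kisses are excluded, which
  would otherwise create spurious neighbor-exchange signals;
* cells touching the image border are flagged ``clipped`` (shape metrics
  exclude them by default).
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import chain_unit_edges, region_outline_loops

COMPARTMENTS = ("axial", "paraxial", "exterior")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class MeshError(ValueError):
    """Invalid label image or mesh construction failure."""


@dataclass
class AxisConvention:
    """Which image axis carries anterior→posterior."""

    ap_axis: str = "rows"  # anterior at index 0

    def __post_init__(self):
        if self.ap_axis not in ("rows", "cols"):
            raise ValueError(f"ap_axis must be 'rows' or 'cols', got {self.ap_axis!r}")

    @property
    def ml_axis(self) -> str:
        return "cols" if self.ap_axis == "rows" else "rows"


@dataclass
class LabelImage:
    """A single segmented z-plane: integer labels, µm/px scale, minutes."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    frame_time: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise MeshError(
                f"label image must have integer dtype, got {self.pixels.dtype}"
            )
        if self.pixels.ndim != 2:
            raise MeshError("label image must be 2-D")
        if (self.pixels < 0).any():
            raise MeshError("labels must be >= 0 (0 is background)")
        if self.pixel_size <= 0:
            raise MeshError("pixel_size must be positive")


@dataclass
class Cell:
    id: int
    polygon: np.ndarray  # (n, 2) µm, (x=ML, y=AP), pixel-corner outline
    compartment: str
    area: float  # µm², exact pixel count × pixel_size²
    centroid: np.ndarray  # (x, y) µm
    n_pixels: int
    clipped: bool


@dataclass
class Interface:
    cell_a: int
    cell_b: int
    chains: list  # list of (n, 2) µm polylines partitioning the shared border
    length: float  # µm, total shared border length
    n_border_pairs: int  # 4-neighbor pixel pairs straddling the border

    @property
    def adjacent(self) -> bool:
        return self.n_border_pairs >= 2

    @property
    def polyline(self) -> np.ndarray:
        """Longest chain (the interface proper for simply-touching cells)."""
        return max(self.chains, key=len)


@dataclass
class CellMesh:
    cells: dict[int, Cell]
    interfaces: list[Interface]
    pixel_size: float = 1.0
    frame_time: float = 0.0

    @property
    def adjacency(self) -> set[frozenset]:
        return {
            frozenset((i.cell_a, i.cell_b)) for i in self.interfaces if i.adjacent
        }

    def neighbors(self, cell_id: int) -> set[int]:
        out = set()
        for pair in self.adjacency:
            if cell_id in pair:
                out |= pair - {cell_id}
        return out

    def interface_between(self, a: int, b: int) -> Interface | None:
        key = frozenset((a, b))
        for i in self.interfaces:
            if frozenset((i.cell_a, i.cell_b)) == key:
                return i
        return None


@dataclass
class TrackedTimeLapse:
    """Ordered mesh frames with persistent cell identities."""

    frames: list[CellMesh]
    track_maps: list[dict[int, int]]  # per frame: local label -> persistent id
    timestamps: list[float]  # minutes, strictly increasing

    def __post_init__(self):
        if not (len(self.frames) == len(self.track_maps) == len(self.timestamps)):
            raise MeshError("frames, track_maps and timestamps must align")
        ts = np.asarray(self.timestamps, dtype=float)
        if len(ts) > 1 and not (np.diff(ts) > 0).all():
            raise MeshError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.frames)


def build_mesh(
    img: LabelImage,
    compartments: dict[int, str],
    axes: AxisConvention | None = None,
) -> CellMesh:
    """Convert a label image into a polygonal cell mesh.

    Every positive label becomes one cell (rejected if it is not a single
    4-connected component or lacks a compartment entry). Interface polylines
    are the exact chains of shared pixel edges, so they partition the
    inter-label border and interface length is exact.
    """
    axes = axes or AxisConvention()
    lab = img.pixels if axes.ap_axis == "rows" else img.pixels.T
    px = img.pixel_size

    labels = np.unique(lab)
    labels = labels[labels > 0]
    missing = [int(l) for l in labels if int(l) not in compartments]
    if missing:
        raise MeshError(f"labels without compartment entry: {missing}")
    bad_comp = {
        l: compartments[int(l)]
        for l in labels
        if compartments[int(l)] not in COMPARTMENTS
    }
    if bad_comp:
        raise MeshError(f"unknown compartment values: {bad_comp}")

    objects = ndimage.find_objects(lab)
    cells: dict[int, Cell] = {}
    nrows, ncols = lab.shape
    for l in labels:
        l = int(l)
        sl = objects[l - 1]
        mask = lab[sl] == l
        _, ncomp = ndimage.label(mask, structure=_FOUR_CONN)
        if ncomp != 1:
            raise MeshError(
                f"label {l} is split into {ncomp} 4-connected components"
            )
        loops = region_outline_loops(mask)
        outer = max(
            loops,
            key=lambda lp: abs(_shoelace(lp)),
        )
        r0, c0 = sl[0].start, sl[1].start
        poly = np.column_stack(
            [(outer[:, 1] + c0) * px, (outer[:, 0] + r0) * px]
        )
        rr, cc = np.nonzero(mask)
        centroid = np.array(
            [(cc.mean() + 0.5 + c0) * px, (rr.mean() + 0.5 + r0) * px]
        )
        clipped = bool(
            (rr + r0 == 0).any()
            or (rr + r0 == nrows - 1).any()
            or (cc + c0 == 0).any()
            or (cc + c0 == ncols - 1).any()
        )
        cells[l] = Cell(
            id=l,
            polygon=poly,
            compartment=compartments[l],
            area=float(mask.sum()) * px * px,
            centroid=centroid,
            n_pixels=int(mask.sum()),
            clipped=clipped,
        )

    interfaces = _build_interfaces(lab, px)
    return CellMesh(
        cells=cells,
        interfaces=interfaces,
        pixel_size=px,
        frame_time=img.frame_time,
    )


def _shoelace(loop: np.ndarray) -> float:
    x, y = loop[:, 1], loop[:, 0]
    return 0.5 * float(
        (x * np.roll(y, -1) - np.roll(x, -1) * y).sum()
    )


def border_pixel_pairs(lab: np.ndarray) -> dict[frozenset, int]:
    """Count 4-neighbor pixel pairs with two distinct positive labels.

    Independent of mesh construction details; used both by
    :func:`build_mesh` (via :func:`_build_interfaces`) and as the definition
    of the adjacency relation.
    """
    counts: dict[frozenset, int] = {}
    for a, b in _neighbor_pairs(lab):
        counts[frozenset((a, b))] = counts.get(frozenset((a, b)), 0) + 1
    return counts


def adjacency_from_labels(lab: np.ndarray) -> set[frozenset]:
    """Adjacency relation straight from a label array (vectorized).

    Same ≥2-border-pixel-pair rule as :func:`build_mesh`, without building
    polygons — used where only the neighbor graph is needed.
    """
    enc_parts = []
    for aa, bb in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (aa != bb) & (aa > 0) & (bb > 0)
        a, b = aa[m].astype(np.int64), bb[m].astype(np.int64)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        enc_parts.append(lo * 2_000_000 + hi)
    if not enc_parts:
        return set()
    enc = np.concatenate(enc_parts)
    vals, cnts = np.unique(enc, return_counts=True)
    keep = vals[cnts >= 2]
    return {
        frozenset((int(v // 2_000_000), int(v % 2_000_000))) for v in keep
    }


def _neighbor_pairs(lab):
    h_a, h_b = lab[:, :-1], lab[:, 1:]
    v_a, v_b = lab[:-1, :], lab[1:, :]
    for aa, bb in ((h_a, h_b), (v_a, v_b)):
        m = (aa != bb) & (aa > 0) & (bb > 0)
        for a, b in zip(aa[m].tolist(), bb[m].tolist()):
            yield a, b


def _build_interfaces(lab: np.ndarray, px: float) -> list[Interface]:
    # shared unit edges per unordered label pair, in corner coordinates
    seg: dict[frozenset, list] = {}
    h_m = (lab[:, :-1] != lab[:, 1:]) & (lab[:, :-1] > 0) & (lab[:, 1:] > 0)
    for r, c in zip(*np.nonzero(h_m)):
        key = frozenset((int(lab[r, c]), int(lab[r, c + 1])))
        seg.setdefault(key, []).append(((int(r), int(c) + 1), (int(r) + 1, int(c) + 1)))
    v_m = (lab[:-1, :] != lab[1:, :]) & (lab[:-1, :] > 0) & (lab[1:, :] > 0)
    for r, c in zip(*np.nonzero(v_m)):
        key = frozenset((int(lab[r, c]), int(lab[r + 1, c])))
        seg.setdefault(key, []).append(((int(r) + 1, int(c)), (int(r) + 1, int(c) + 1)))

    interfaces = []
    for key, edges in sorted(seg.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        chains_px = chain_unit_edges(edges)
        chains = []
        for ch in chains_px:
            if ch[0, 0] > ch[-1, 0]:  # order anterior -> posterior
                ch = ch[::-1]
            chains.append(np.column_stack([ch[:, 1] * px, ch[:, 0] * px]))
        interfaces.append(
            Interface(
                cell_a=a,
                cell_b=b,
                chains=chains,
                length=len(edges) * px,
                n_border_pairs=len(edges),
            )
        )
    return interfaces


# ---------------------------------------------------------------------------
# tracking validation


@dataclass
class TrackingReport:
    lost: list  # (transition index, persistent ids present at t, absent at t+1)
    appeared: list  # (transition index, ids new at t+1)
    duplicated: list  # (frame index, persistent ids appearing twice)
    timestamp_violations: list
    untracked: list  # (frame index, labels without a track entry)

    @property
    def ok(self) -> bool:
        return not (
            self.lost
            or self.appeared
            or self.duplicated
            or self.timestamp_violations
            or self.untracked
        )


def validate_tracking(tl: TrackedTimeLapse) -> TrackingReport:
    """Report-only integrity check of a tracked time-lapse (no mutation)."""
    duplicated, untracked = [], []
    id_sets = []
    for f_idx, (mesh, tmap) in enumerate(zip(tl.frames, tl.track_maps)):
        labels = set(mesh.cells)
        missing = sorted(labels - set(tmap))
        if missing:
            untracked.append((f_idx, missing))
        pids = [tmap[l] for l in sorted(labels & set(tmap))]
        dupes = sorted({p for p in pids if pids.count(p) > 1})
        if dupes:
            duplicated.append((f_idx, dupes))
        id_sets.append(set(pids))
    lost, appeared = [], []
    for t in range(len(tl) - 1):
        gone = sorted(id_sets[t] - id_sets[t + 1])
        new = sorted(id_sets[t + 1] - id_sets[t])
        if gone:
            lost.append((t, gone))
        if new:
            appeared.append((t, new))
    ts = list(tl.timestamps)
    viol = [
        (i, ts[i], ts[i + 1]) for i in range(len(ts) - 1) if ts[i + 1] <= ts[i]
    ]
    return TrackingReport(lost, appeared, duplicated, viol, untracked)


# ---------------------------------------------------------------------------
# I/O


def read_label_stack(
    path, pixel_size_um: float, frame_interval_min: float
) -> list[LabelImage]:
    """Read a multi-page TIFF of integer label planes."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if not np.issubdtype(arr.dtype, np.integer):
        raise MeshError(f"label TIFF must be integer-valued, got dtype {arr.dtype}")
    return [
        LabelImage(
            pixels=plane.astype(np.int64),
            pixel_size=pixel_size_um,
            frame_time=i * frame_interval_min,
        )
        for i, plane in enumerate(arr)
    ]


def write_label_stack(path, images: list[LabelImage]) -> None:
    import tifffile

    stack = np.stack([im.pixels.astype(np.int32) for im in images])
    tifffile.imwrite(str(path), stack)


def read_tracking_table(path) -> list[dict[int, int]]:
    """Tracking TSV with columns frame, label, persistent_id."""
    df = pd.read_csv(path, sep="\t")
    maps = []
    for f in sorted(df["frame"].unique()):
        sub = df[df["frame"] == f]
        maps.append(dict(zip(sub["label"].astype(int), sub["persistent_id"].astype(int))))
    return maps


def read_compartment_table(path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["label"].astype(int), df["compartment"]))


def _poly_to_str(poly: np.ndarray) -> str:
    return ";".join(f"{x:.6g}:{y:.6g}" for x, y in poly)


def _poly_from_str(s: str) -> np.ndarray:
    pts = [p.split(":") for p in s.split(";")]
    return np.asarray([[float(x), float(y)] for x, y in pts])


def write_mesh_tables(mesh: CellMesh, out_dir, prefix: str = "") -> tuple[Path, Path]:
    """Write cells.tsv and interfaces.tsv; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame(
        [
            {
                "cell_id": c.id,
                "compartment": c.compartment,
                "area_um2": c.area,
                "centroid_x_um": c.centroid[0],
                "centroid_y_um": c.centroid[1],
                "n_pixels": c.n_pixels,
                "clipped": c.clipped,
                "polygon": _poly_to_str(c.polygon),
            }
            for c in sorted(mesh.cells.values(), key=lambda c: c.id)
        ]
    )
    ifaces = pd.DataFrame(
        [
            {
                "cell_a": i.cell_a,
                "cell_b": i.cell_b,
                "length_um": i.length,
                "n_border_pairs": i.n_border_pairs,
                "adjacent": i.adjacent,
                "chains": "|".join(_poly_to_str(ch) for ch in i.chains),
            }
            for i in mesh.interfaces
        ]
    )
    cp = out_dir / f"{prefix}cells.tsv"
    ip = out_dir / f"{prefix}interfaces.tsv"
    cells.to_csv(cp, sep="\t", index=False)
    ifaces.to_csv(ip, sep="\t", index=False)
    return cp, ip


def read_mesh_tables(cells_path, interfaces_path, pixel_size: float = 1.0) -> CellMesh:
    cdf = pd.read_csv(cells_path, sep="\t")
    idf = pd.read_csv(interfaces_path, sep="\t")
    cells = {
        int(r.cell_id): Cell(
            id=int(r.cell_id),
            polygon=_poly_from_str(r.polygon),
            compartment=r.compartment,
            area=float(r.area_um2),
            centroid=np.array([r.centroid_x_um, r.centroid_y_um]),
            n_pixels=int(r.n_pixels),
            clipped=bool(r.clipped),
        )
        for r in cdf.itertuples()
    }
    interfaces = [
        Interface(
            cell_a=int(r.cell_a),
            cell_b=int(r.cell_b),
            chains=[_poly_from_str(s) for s in r.chains.split("|")],
            length=float(r.length_um),
            n_border_pairs=int(r.n_border_pairs),
        )
        for r in idf.itertuples()
    ]
    return CellMesh(cells=cells, interfaces=interfaces, pixel_size=pixel_size)
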
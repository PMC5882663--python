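"""Cell polarity metrics: ellipse-based orientation and elongation.

During convergence & extension, axial mesoderm cells elongate and align
their long axes with the mediolateral (ML) embryonic axis. Per cell we
report:

* ``orientation_deg`` — angle of the best-fit ellipse's major axis with
  respect to the ML axis, folded to [0°, 90°] (0° = ML-aligned,
  90° = AP-aligned); axial symmetry makes θ, −θ and 180°−θ equivalent;
* ``aspect_ratio`` — major/minor axis length ratio (≥ 1).

The "fit ellipse" is the moment-matched ellipse: the eigen-decomposition of
the polygon's second central area moments, identical to the fit-ellipse of
common image-analysis software and deterministic on any simple polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._geometry import polygon_moments, polygon_self_intersects
from .tissue_model import AxisConvention, CellMesh

#: relative eigenvalue-gap tolerance below which a cell is isotropic
DEGENERACY_TOL = 1e-6


class ShapeError(ValueError):
    pass


@dataclass
class EllipseFit:
    orientation_raw: float  # degrees in [-90, 90) w.r.t. ML axis
    aspect_ratio: float  # >= 1
    degenerate: bool


def fit_ellipse(
    polygon: np.ndarray, tol: float = DEGENERACY_TOL, validate: bool = True
) -> EllipseFit:
    """Moment-based ellipse fit of a simple polygon.

    Aspect ratio is ``sqrt(λ_major / λ_minor)`` of the second central area
    moments (for a rectangle L×W the moments are L²/12 and W²/12, giving
    AR = L/W). When the eigenvalue gap is below ``tol`` the shape is
    isotropic: ``degenerate`` is set and orientation is 0 by convention.
    """
    poly = np.asarray(polygon, dtype=float)
    if len(poly) < 3:
        raise ShapeError("polygon needs >= 3 vertices")
    if validate and polygon_self_intersects(poly):
        raise ShapeError("polygon is self-intersecting")
    try:
        _, _, cov = polygon_moments(poly)
    except ValueError as e:
        raise ShapeError(str(e)) from e
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_minor <= 0:
        raise ShapeError("degenerate (zero-width) polygon")
    if lam_major / lam_minor - 1.0 < tol:
        return EllipseFit(orientation_raw=0.0, aspect_ratio=1.0, degenerate=True)
    vx, vy = evecs[:, 1]
    theta = np.degrees(np.arctan2(vy, vx))
    # fold to [-90, 90): the major axis is a line, not a vector
    theta = ((theta + 90.0) % 180.0) - 90.0
    return EllipseFit(
        orientation_raw=float(theta),
        aspect_ratio=float(np.sqrt(lam_major / lam_minor)),
        degenerate=False,
    )


def ml_orientation(
    orientation_raw: float, axes: AxisConvention | None = None
) -> float:
    """Fold a raw major-axis angle to [0°, 90°] relative to the ML axis."""
    AxisConvention() if axes is None else axes  # validates
    theta = abs(((orientation_raw + 90.0) % 180.0) - 90.0)
    return float(theta)


def measure_shapes(
    mesh: CellMesh,
    axes: AxisConvention | None = None,
    include_clipped: bool = False,
) -> pd.DataFrame:
    """Per-cell shape table (one row per cell) for a mesh frame.

    Clipped cells (touching the image border) are excluded from shape
    metrics by default, mirroring how partially imaged cells are dropped
    from manual outlining. Degenerate (isotropic) cells are flagged.
    """
    rows = []
    for cell in sorted(mesh.cells.values(), key=lambda c: c.id):
        if cell.clipped and not include_clipped:
            continue
        fit = fit_ellipse(cell.polygon, validate=False)
        rows.append(
            {
                "cell_id": cell.id,
                "compartment": cell.compartment,
                "centroid_x_um": cell.centroid[0],
                "centroid_y_um": cell.centroid[1],
                "area_um2": cell.area,
                "orientation_raw_deg": fit.orientation_raw,
                "orientation_deg": ml_orientation(fit.orientation_raw, axes),
                "aspect_ratio": fit.aspect_ratio,
                "degenerate": fit.degenerate,
                "clipped": cell.clipped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "compartment",
            "centroid_x_um",
            "centroid_y_um",
            "area_um2",
            "orientation_raw_deg",
            "orientation_deg",
            "aspect_ratio",
            "degenerate",
            "clipped",
        ],
    )


def summarize_polarity(
    shapes: pd.DataFrame,
    rows: pd.DataFrame | None = None,
    grouping: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort summaries: median orientation and mean aspect ratio per group.

    ``rows`` (from ``boundary_metrics.classify_rows``) attaches a
    boundary-distance row label to each cell; ``grouping`` adds extra keys
    (genotype, timepoint, ...) present as columns of ``shapes``. Cells are
    pooled across embryos within a cohort (per-cell dot-plot convention);
    degenerate cells are excluded from orientation medians and counted.
    """
    df = shapes.copy()
    if rows is not None:
        df = df.merge(rows[["cell_id", "row", "row_label"]], on="cell_id", how="left")
    keys = list(grouping or [])
    if rows is not None:
        keys.append("row_label")
    if not keys:
        df["_all"] = "all"
        keys = ["_all"]
    out = []
    for key_vals, sub in df.groupby(keys, dropna=False, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        ok = sub[~sub["degenerate"]]
        rec = dict(zip(keys, key_vals))
        rec.update(
            {
                "n": len(sub),
                "n_degenerate": int(sub["degenerate"].sum()),
                "median_orientation_deg": (
                    float(ok["orientation_deg"].median()) if len(ok) else np.nan
                ),
                "mean_aspect_ratio": (
                    float(sub["aspect_ratio"].mean()) if len(sub) else np.nan
                ),
            }
        )
        out.append(rec)
    res = pd.DataFrame(out)
    return res.drop(columns=["_all"], errors="ignore")


def compare_groups(
    sample_a, sample_b, test: str = "ks"
) -> tuple[float, float]:
    """Two-sided nonparametric comparison of two samples.

    ``test='ks'``: two-sample Kolmogorov–Smirnov, D = sup|ECDF difference|.
    ``test='mann_whitney'``: Mann–Whitney U with midrank ties.
    Exact p-values are used for small tie-free samples, asymptotic
    otherwise. Both tests are two-tailed throughout.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if test == "ks":
        res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (not ties and len(a) + len(b) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}; use 'ks' or 'mann_whitney'")
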
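"""Synthetic inputs with planted ground truth.

Everything the analysis modules consume can be generated here with known
truth, which is the package's principal test surface:

* anisotropic Voronoi tissues — a jittered-lattice seeding scaled √AR* along
  ML and 1/√AR* along AP with per-cell orientation noise (wrapped
  distribution with concentration κ, period 180°), an axial strip flanked by
  paraxial compartments, and an axial/paraxial boundary displaced by
  A·sin(2π·ap/λ) and rasterized exactly;
* scripted T1 time-lapses — neighbor exchanges realized by deterministic
  local seed moves, verified to change the adjacency graph by exactly the
  scripted lost/gained pairs, with perfect tracking;
* ablation recoil series — d(t) = d_pre + L·(1 − e^(−t/τ)) with L
  proportional to a planted per-class tension, plus Gaussian noise;
* genomic counts — NB-distributed bin and expression matrices replicating
  the deposited replicate layout (3 biological DamID replicates per
  condition; 2 biological × 2 technical expression replicates per genotype)
  with planted enrichment/DE overlap (Venn class) structure.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tissue_model import (
    CellMesh,
    LabelImage,
    TrackedTimeLapse,
    adjacency_from_labels,
    build_mesh,
)
from .genomic_targets import CountMatrix, GenomeBins, make_bins, make_gene_models
from .ablation import N_POST_FRAMES, RecoilSeries


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tissue


@dataclass
class TissueParams:
    """Geometry of a synthetic axial/paraxial tissue.

    Defaults emulate late-gastrula axial mesoderm at desk scale: ~12-µm
    cells moderately elongated along ML (AR* = 2), strong ML alignment
    (κ = 8), and a gently sinusoidal notochord boundary (A = 2 µm over
    λ = 60 µm, a straightness ratio close to 1 as in wild type; raising A
    to ~8–10 µm emulates the irregular mutant boundary).
    """

    n_axial_cols: int = 5
    n_paraxial_cols: int = 3  # per side
    n_exterior_cols: int = 1  # per side, outermost
    n_rows: int = 10
    spacing_um: float = 12.0
    aspect_ratio: float = 2.0  # AR* >= 1
    kappa: float = 8.0  # orientation concentration about ML
    boundary_amp_um: float = 2.0  # A
    boundary_wavelength_um: float = 60.0  # λ
    boundary_phase: float = 0.0
    jitter: float = 0.12  # seed jitter, fraction of spacing
    pixel_size: float = 1.0  # µm/px
    seed: int = 0

    def __post_init__(self):
        if self.aspect_ratio < 1:
            raise SimulationError("aspect_ratio must be >= 1")
        if self.boundary_amp_um < 0 or self.boundary_wavelength_um <= 0:
            raise SimulationError("need A >= 0 and λ > 0")
        if self.kappa < 0:
            raise SimulationError("kappa must be >= 0")


@dataclass
class TissueTruth:
    seeds: np.ndarray  # (n, 2) µm (x, y)
    labels: np.ndarray  # label per seed
    compartments: dict[int, str]
    orientations_deg: np.ndarray  # planted per-cell long-axis angle vs ML
    aspect_ratio: float
    boundary_left: np.ndarray  # (n, 2) µm planted polylines, anterior→posterior
    boundary_right: np.ndarray
    params: TissueParams


def _boundary_x(x0: float, y: np.ndarray, p: TissueParams) -> np.ndarray:
    return x0 + p.boundary_amp_um * np.sin(
        2 * np.pi * y / p.boundary_wavelength_um + p.boundary_phase
    )


def _axis_scales(p: TissueParams) -> tuple[float, float]:
    return np.sqrt(p.aspect_ratio), 1.0 / np.sqrt(p.aspect_ratio)


def _layout(p: TissueParams):
    """Column x-centers and the two undisplaced boundary x positions."""
    sx = p.spacing_um * _axis_scales(p)[0]
    n_side = p.n_paraxial_cols + p.n_exterior_cols
    n_cols = p.n_axial_cols + 2 * n_side
    xs = (np.arange(n_cols) + 0.5) * sx
    x_left = xs[n_side - 1 : n_side + 1].mean()  # between last paraxial & first axial
    x_right = xs[n_side + p.n_axial_cols - 1 : n_side + p.n_axial_cols + 1].mean()
    return xs, x_left, x_right, n_cols, n_side, sx


def _make_seeds(p: TissueParams, rng: np.random.Generator):
    xs, x_left, x_right, n_cols, n_side, sx = _layout(p)
    sy = p.spacing_um * _axis_scales(p)[1]
    seeds, angles = [], []
    for r in range(p.n_rows):
        y = (r + 0.5) * sy
        offset = 0.5 * sx if r % 2 else 0.0
        for c in range(n_cols):
            x = xs[c] + offset
            x += rng.uniform(-p.jitter, p.jitter) * sx
            yj = y + rng.uniform(-p.jitter, p.jitter) * sy
            seeds.append((x, yj))
            # axial (period-180°) orientation noise: von Mises on the doubled angle
            if p.kappa > 0:
                theta = 0.5 * np.degrees(rng.vonmises(0.0, p.kappa))
            else:
                theta = rng.uniform(-90.0, 90.0)
            angles.append(theta)
    return np.asarray(seeds), np.asarray(angles)


def _compartment_of_x(x: np.ndarray, y: np.ndarray, p: TissueParams):
    _, x_left0, x_right0, _, n_side, sx = _layout(p)
    xl = _boundary_x(x_left0, y, p)
    xr = _boundary_x(x_right0, y, p)
    ext_left = (p.n_exterior_cols) * sx
    ext_right = ( _layout(p)[3] - p.n_exterior_cols) * sx
    comp = np.where(
        (x > xl) & (x < xr),
        "axial",
        np.where((x <= ext_left) | (x >= ext_right), "exterior", "paraxial"),
    )
    return comp


def generate_tissue(
    params: TissueParams,
) -> tuple[LabelImage, dict[int, str], TissueTruth]:
    """Rasterize one synthetic tissue frame.

    Compartments are decided per pixel against the displaced boundary
    curves, then each pixel takes the label of the nearest same-compartment
    seed under that seed's anisotropic metric (√AR* along its planted long
    axis) — so the rasterized notochord boundary follows the planted
    sinusoid exactly (within one pixel) while cell shapes carry the planted
    elongation and orientation noise.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    xs, x_left0, x_right0, n_cols, n_side, sx = _layout(p)
    sy = p.spacing_um * _axis_scales(p)[1]
    half_strip = 0.5 * p.n_axial_cols * sx
    if p.boundary_amp_um >= half_strip:
        raise SimulationError(
            f"boundary amplitude {p.boundary_amp_um} µm exceeds half the axial "
            f"strip width {half_strip:.1f} µm"
        )
    seeds, angles = _make_seeds(p, rng)
    seed_comp = _compartment_of_x(seeds[:, 0], seeds[:, 1], p)

    width_px = int(round(n_cols * sx / p.pixel_size))
    height_px = int(round(p.n_rows * sy / p.pixel_size))
    img = _rasterize(seeds, angles, seed_comp, p, width_px, height_px)
    img = _clean_components(img, seed_comp)

    labels_present = np.unique(img)
    labels_present = labels_present[labels_present > 0]
    compartments = {
        int(l): str(seed_comp[int(l) - 1]) for l in labels_present
    }
    y_rows = (np.arange(height_px) + 0.5) * p.pixel_size
    truth = TissueTruth(
        seeds=seeds,
        labels=np.arange(1, len(seeds) + 1),
        compartments=compartments,
        orientations_deg=angles,
        aspect_ratio=p.aspect_ratio,
        boundary_left=np.column_stack([_boundary_x(x_left0, y_rows, p), y_rows]),
        boundary_right=np.column_stack([_boundary_x(x_right0, y_rows, p), y_rows]),
        params=p,
    )
    return (
        LabelImage(pixels=img, pixel_size=p.pixel_size, frame_time=0.0),
        compartments,
        truth,
    )


def _rasterize(seeds, angles, seed_comp, p: TissueParams, width_px, height_px):
    px = p.pixel_size
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    X = (xx + 0.5) * px
    Y = (yy + 0.5) * px
    pix_comp = _compartment_of_x(X.ravel(), Y.ravel(), p).reshape(X.shape)

    a, b = _axis_scales(p)  # metric semi-axes along/across the long axis
    th = np.radians(angles)
    ex, ey = np.cos(th), np.sin(th)
    best = np.full(X.shape, np.inf, dtype=np.float64)
    lab = np.zeros(X.shape, dtype=np.int32)
    for i, ((sxm, sym), comp) in enumerate(zip(seeds, seed_comp)):
        dx = X - sxm
        dy = Y - sym
        u = dx * ex[i] + dy * ey[i]
        v = -dx * ey[i] + dy * ex[i]
        d2 = (u / a) ** 2 + (v / b) ** 2
        m = (pix_comp == comp) & (d2 < best)
        best[m] = d2[m]
        lab[m] = i + 1
    if (lab == 0).any():
        # pixel whose compartment has no seed metric coverage cannot happen:
        # distances are finite, so every pixel with a same-compartment seed
        # is labeled; guard for pathological parameter choices
        raise SimulationError("unlabeled pixels: no seed in some compartment")
    return lab


def _clean_components(lab: np.ndarray, seed_comp) -> np.ndarray:
    """Keep each label 4-connected: reassign minor fragments to the
    same-compartment neighbor label with the most shared border."""
    from scipy import ndimage

    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    lab = lab.copy()
    for _ in range(8):
        dirty = False
        for l in np.unique(lab):
            if l == 0:
                continue
            mask = lab == l
            cc, n = ndimage.label(mask, structure=four)
            if n <= 1:
                continue
            dirty = True
            sizes = ndimage.sum(mask, cc, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            comp_l = seed_comp[l - 1]
            for frag in range(1, n + 1):
                if frag == keep:
                    continue
                frag_mask = cc == frag
                dil = ndimage.binary_dilation(frag_mask, structure=four)
                neigh = lab[dil & ~frag_mask]
                neigh = neigh[(neigh > 0) & (neigh != l)]
                same = [
                    v for v in neigh.tolist() if seed_comp[v - 1] == comp_l
                ]
                pool = same if same else neigh.tolist()
                if not pool:
                    continue
                vals, cnts = np.unique(pool, return_counts=True)
                lab[frag_mask] = int(vals[np.argmax(cnts)])
        if not dirty:
            break
    return lab


def tissue_mesh(params: TissueParams) -> tuple[CellMesh, TissueTruth]:
    """Convenience: generate and immediately mesh one tissue frame."""
    img, comp, truth = generate_tissue(params)
    return build_mesh(img, comp), truth


# ---------------------------------------------------------------------------
# time-lapse with scripted T1 flips


@dataclass
class TimeLapseTruth:
    script: list  # (transition, (a, b) lost, (c, d) gained)
    tissue: TissueTruth


#: deterministic ladder of (pull, push) move strengths tried per flip
_FLIP_LADDER = (
    (0.45, 0.18),
    (0.55, 0.25),
    (0.65, 0.32),
    (0.38, 0.12),
    (0.5, 0.1),
    (0.75, 0.4),
    (0.3, 0.06),
)


def _apply_flip(seeds: np.ndarray, flip, pull: float = 0.45, push: float = 0.18):
    """Move quartet seeds so c,d meet between the separating a,b."""
    (a, b), (c, d) = flip
    s = seeds.copy()
    m = 0.5 * (s[a - 1] + s[b - 1])
    for q in (c, d):
        s[q - 1] = s[q - 1] + pull * (m - s[q - 1])
    for q in (a, b):
        s[q - 1] = s[q - 1] + push * (s[q - 1] - m)
    return s


def _axial_adjacency(mesh: CellMesh, compartments) -> set[frozenset]:
    return {
        p
        for p in mesh.adjacency
        if all(compartments.get(i) == "axial" for i in p)
    }


def _raster_mesh(seeds, angles, seed_comp, p, width_px, height_px):
    img = _rasterize(seeds, angles, seed_comp, p, width_px, height_px)
    img = _clean_components(img, seed_comp)
    labels_present = np.unique(img)
    labels_present = labels_present[labels_present > 0]
    comp = {int(l): str(seed_comp[int(l) - 1]) for l in labels_present}
    return img, comp


def _flip_candidates(
    mesh: CellMesh, compartments, used: set, allow_clipped: bool = False
) -> list:
    """Quartets (a,b | c,d): a–b axial-adjacent, c,d common axial neighbors
    of both with c–d not yet adjacent; interior (unclipped) cells preferred
    (``allow_clipped`` admits border-touching quartets — the exact
    adjacency-diff verification still decides acceptance)."""
    adj = _axial_adjacency(mesh, compartments)
    neigh: dict[int, set] = {}
    for pr in adj:
        x, y = tuple(pr)
        neigh.setdefault(x, set()).add(y)
        neigh.setdefault(y, set()).add(x)
    out = []
    for pr in sorted(adj, key=sorted):
        a, b = sorted(pr)
        common = sorted(neigh.get(a, set()) & neigh.get(b, set()))
        for i in range(len(common)):
            for j in range(i + 1, len(common)):
                c, d = common[i], common[j]
                if frozenset((c, d)) in adj:
                    continue
                quartet = {a, b, c, d}
                if quartet & used:
                    continue
                if not allow_clipped and any(
                    mesh.cells[q].clipped for q in quartet
                ):
                    continue
                out.append(((a, b), (c, d)))
    return out


def propose_t1_script(
    params: TissueParams, k: int, seed: int | None = None
) -> list:
    """Find k realizable, mutually disjoint quartet flips.

    Candidate quartets are drawn from the axial adjacency graph (a–b
    adjacent, c and d common neighbors of both, c–d not adjacent); each is
    realized on a scratch copy and kept only if the rasterized adjacency
    diff is exactly {(a, b)} lost / {(c, d)} gained. After each accepted
    flip the candidate list is refreshed from the updated tissue. Flips
    occupy successive transitions (one per transition).
    """
    p = params
    rng = np.random.default_rng(p.seed if seed is None else seed)
    _, _, _, n_cols, n_side, sx = _layout(p)
    sy = p.spacing_um * _axis_scales(p)[1]
    width_px = int(round(n_cols * sx / p.pixel_size))
    height_px = int(round(p.n_rows * sy / p.pixel_size))
    seeds0, angles = _make_seeds(p, np.random.default_rng(p.seed))
    seed_comp = _compartment_of_x(seeds0[:, 0], seeds0[:, 1], p)

    script, used = [], set()
    base = seeds0
    for _round in range(2 * k + 4):
        img, comp = _raster_mesh(base, angles, seed_comp, p, width_px, height_px)
        mesh = build_mesh(LabelImage(img, p.pixel_size), comp)
        base_state = (img, adjacency_from_labels(img))
        progress = False
        for allow_clipped in (False, True):
            candidates = _flip_candidates(
                mesh, comp, used, allow_clipped=allow_clipped
            )
            for idx in rng.permutation(len(candidates)):
                flip = candidates[idx]
                quartet = set(flip[0]) | set(flip[1])
                if quartet & used:
                    continue
                realized = _realize_flip(
                    base, angles, seed_comp, p, width_px, height_px, flip,
                    base=base_state,
                )
                if realized is not None:
                    script.append((len(script), flip[0], flip[1]))
                    used |= quartet
                    base = realized
                    progress = True
                    if len(script) == k:
                        return script
                    break  # refresh candidates from the moved tissue
            if progress:
                break
        if not progress:
            break
    raise SimulationError(
        f"could only realize {len(script)} of {k} requested flips"
    )


def _realize_flip(seeds, angles, seed_comp, p, width_px, height_px, flip, base=None):
    """Try the move-strength ladder; return the new seed array of the first
    strength whose rasterized adjacency diff is exactly the scripted flip.

    ``base`` optionally supplies the precomputed (label image, adjacency) of
    the unmoved seeds to avoid re-rasterizing it per candidate. Verification
    only needs the neighbor graph, so meshes are never built here.
    """
    if base is None:
        img0, _ = _raster_mesh(seeds, angles, seed_comp, p, width_px, height_px)
        adj0 = adjacency_from_labels(img0)
    else:
        img0, adj0 = base
    labels0 = set(np.unique(img0).tolist()) - {0}
    for pull, push in _FLIP_LADDER:
        moved = _apply_flip(seeds, flip, pull=pull, push=push)
        img1, _ = _raster_mesh(moved, angles, seed_comp, p, width_px, height_px)
        if set(np.unique(img1).tolist()) - {0} != labels0:
            continue
        adj1 = adjacency_from_labels(img1)
        if (adj0 - adj1) == {frozenset(flip[0])} and (adj1 - adj0) == {
            frozenset(flip[1])
        }:
            return moved
    return None


def generate_timelapse(
    base: TissueParams,
    t1_script: list,
    n_frames: int | None = None,
    dt_min: float = 4.0,
) -> tuple[TrackedTimeLapse, TimeLapseTruth]:
    """Realize scripted T1 flips as a tracked time-lapse.

    ``t1_script`` entries are ``(transition, (a, b), (c, d))`` with the flip
    applied between frames ``transition`` and ``transition + 1``. Tracking
    is perfect (labels persist). Each flip is re-verified against the
    realized adjacency diff; an unrealizable quartet is rejected with its
    transition index.
    """
    p = base
    transitions = [s[0] for s in t1_script]
    if len(set(transitions)) != len(transitions):
        raise SimulationError("one scripted flip per transition")
    n_frames = n_frames or (max(transitions, default=-1) + 2)
    _, _, _, n_cols, n_side, sx = _layout(p)
    sy = p.spacing_um * _axis_scales(p)[1]
    width_px = int(round(n_cols * sx / p.pixel_size))
    height_px = int(round(p.n_rows * sy / p.pixel_size))
    seeds, angles = _make_seeds(p, np.random.default_rng(p.seed))
    seed_comp = _compartment_of_x(seeds[:, 0], seeds[:, 1], p)
    by_transition = {s[0]: (s[1], s[2]) for s in t1_script}

    frames, track_maps, timestamps = [], [], []
    prev_img, comp = _raster_mesh(seeds, angles, seed_comp, p, width_px, height_px)
    mesh0 = build_mesh(LabelImage(prev_img, p.pixel_size, 0.0), comp)
    frames.append(mesh0)
    track_maps.append({l: l for l in mesh0.cells})
    timestamps.append(0.0)
    for t in range(n_frames - 1):
        if t in by_transition:
            flip = by_transition[t]
            realized = _realize_flip(
                seeds, angles, seed_comp, p, width_px, height_px, flip,
                base=(prev_img, adjacency_from_labels(prev_img)),
            )
            if realized is None:
                raise SimulationError(
                    f"scripted flip at transition {t} could not be realized cleanly"
                )
            seeds = realized
        img, comp = _raster_mesh(seeds, angles, seed_comp, p, width_px, height_px)
        mesh = build_mesh(LabelImage(img, p.pixel_size, (t + 1) * dt_min), comp)
        frames.append(mesh)
        track_maps.append({l: l for l in mesh.cells})
        timestamps.append((t + 1) * dt_min)
        prev_img = img

    img0, comp0, truth0 = generate_tissue(p)
    return (
        TrackedTimeLapse(frames=frames, track_maps=track_maps, timestamps=timestamps),
        TimeLapseTruth(script=list(t1_script), tissue=truth0),
    )


# ---------------------------------------------------------------------------
# ablation recoil


#: planted per-class tensions (≈ asymptotic recoil, µm). Edge junctions sit
#: on the high-tension notochord boundary; V junctions shrink actively;
#: T junctions are the low-tension baseline.
DEFAULT_TENSIONS = {"Edge": 2.0, "V": 1.2, "T": 0.8}


def generate_recoil(
    class_tensions: dict[str, float] | None = None,
    n_per_class: int = 12,
    noise_sd: float = 0.05,
    dt_s: float = 1.0,
    tau_s: float = 3.0,
    genotype: str = "WT",
    seed: int = 0,
) -> tuple[list[RecoilSeries], pd.DataFrame]:
    """Simulate post-ablation vertex recoil per junction class.

    d(t) = d_pre + L·(1 − e^(−t/τ)) with L equal to the planted class
    tension (µm) and additive Gaussian noise of sd ``noise_sd`` µm on each
    of the 10 post frames. Returns the series plus a truth table.
    """
    tensions = dict(DEFAULT_TENSIONS if class_tensions is None else class_tensions)
    if any(v <= 0 for v in tensions.values()):
        raise SimulationError("tensions must be positive")
    rng = np.random.default_rng(seed)
    t = (np.arange(N_POST_FRAMES) + 1) * dt_s
    series, truth = [], []
    for cls in sorted(tensions):
        L = tensions[cls]
        for i in range(n_per_class):
            d_pre = rng.uniform(3.0, 6.0)
            clean = d_pre + L * (1.0 - np.exp(-t / tau_s))
            noisy = clean + rng.normal(0.0, noise_sd, size=N_POST_FRAMES)
            sid = f"{genotype}_{cls}_{i}"
            series.append(
                RecoilSeries(
                    interface_id=sid,
                    junction_class=cls,
                    genotype=genotype,
                    d_pre=float(d_pre),
                    d_post=np.maximum(noisy, 0.0),
                    dt_s=dt_s,
                )
            )
            truth.append(
                {
                    "interface_id": sid,
                    "junction_class": cls,
                    "l_inf_um": L,
                    "tau_s": tau_s,
                    "d_pre_um": float(d_pre),
                }
            )
    return series, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# genomic counts


@dataclass
class GenomicSimParams:
    """Planted-genome design.

    Default scale (2 chromosomes × 5 Mb, 3000 genes) is large enough for
    stable BH behavior while staying desk-sized. Planted Venn class sizes
    and the up/down split default to the published proportions of the DE
    universe scaled to 3000 genes.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_genes: int = 3000
    bin_width: int = 1000
    promoter_len: int = 2000
    min_gene_len: int = 2000  # >= 2×bin − 1 so every body holds a full bin
    max_gene_len: int = 3200
    # enrichment side (DamID): 3 biological replicates per condition
    n_rep_damid: int = 3
    bin_mean: float = 22.0  # control-condition mean reads per bin
    dispersion_damid: float = 0.05
    enriched_fold: float = 6.0
    # expression side: 2 biological × 2 technical replicates per genotype
    n_bio_rep: int = 2
    n_tech_rep: int = 2
    expr_mean_log: float = np.log(150.0)
    expr_mean_sd: float = 0.8
    dispersion_expr: float = 0.1
    de_fold: float = 3.0
    n_de: int = 330  # ≈ 11% of 3000, as in the DE universe proportion
    venn_body_only: int = 55  # 492/2950 of DE genes
    venn_promoter_only: int = 19  # 170/2950
    venn_both: int = 17  # 150/2950
    de_down_fraction: float = 1259.0 / 2950.0  # down-in-mutant share
    #: couple enrichment strength to expression change for positively
    #: regulated direct targets (a shared per-gene strength multiplier),
    #: emulating the observed positive enrichment–expression correlation
    couple_positive_regulation: bool = True
    coupling_spread: float = 0.8  # strength multiplier range [1, e^spread]
    seed: int = 0

    def __post_init__(self):
        n_venn = self.venn_body_only + self.venn_promoter_only + self.venn_both
        if n_venn > self.n_de:
            raise SimulationError("Venn class sizes exceed the planted DE count")
        if self.n_de > self.n_genes:
            raise SimulationError("planted DE count exceeds gene count")
        if self.enriched_fold <= 1 or self.de_fold <= 1:
            raise SimulationError("planted folds must exceed 1")

    @classmethod
    def scaled(cls, n_genes: int, seed: int = 0, **kw) -> "GenomicSimParams":
        """Defaults with the planted DE/Venn design scaled to ``n_genes``,
        preserving the default class proportions."""
        f = n_genes / 3000.0
        return cls(
            n_genes=n_genes,
            seed=seed,
            n_de=max(4, round(330 * f)),
            venn_body_only=max(1, round(55 * f)),
            venn_promoter_only=max(1, round(19 * f)),
            venn_both=max(1, round(17 * f)),
            **kw,
        )


@dataclass
class GenomicTruth:
    genes: pd.DataFrame  # per-gene planted flags
    bins: pd.DataFrame  # per-bin planted enrichment flags


def _place_genes(p: GenomicSimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping genes in per-gene slots, promoter room guaranteed."""
    chroms = list(p.chrom_sizes)
    total = sum(p.chrom_sizes.values())
    per_chrom = {
        c: max(1, int(round(p.n_genes * p.chrom_sizes[c] / total))) for c in chroms
    }
    # fix rounding so the total is exact
    while sum(per_chrom.values()) != p.n_genes:
        c = chroms[0] if sum(per_chrom.values()) < p.n_genes else max(
            per_chrom, key=per_chrom.get
        )
        per_chrom[c] += 1 if sum(per_chrom.values()) < p.n_genes else -1
    rows = []
    gid = 0
    for c in chroms:
        slot = p.chrom_sizes[c] // per_chrom[c]
        margin = p.promoter_len + 200  # promoter room on either side
        max_len = min(p.max_gene_len, slot - 2 * margin)
        if max_len < p.min_gene_len:
            raise SimulationError(
                f"slots of {slot} bp cannot host genes of >= {p.min_gene_len} bp "
                "plus promoters; enlarge chromosomes or reduce gene count"
            )
        for i in range(per_chrom[c]):
            s0 = i * slot
            length = int(rng.integers(p.min_gene_len, max_len + 1))
            start = s0 + margin
            rows.append(
                {
                    "gene_id": f"g{gid:05d}",
                    "chrom": c,
                    "start": start,
                    "end": start + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            gid += 1
    return pd.DataFrame(rows)


def _contained_bin(bins: GenomeBins, chrom: str, start: int, end: int) -> int:
    """Global id of an aligned bin fully inside [start, end); needs the
    interval to span at least 2·width − 1 bp."""
    w = bins.width
    first = -(-start // w)  # ceil
    last = end // w - 1
    if last < first:
        raise SimulationError(
            f"feature [{start}, {end}) on {chrom} holds no full {w}-bp bin"
        )
    mid = (first + last) // 2
    return int(bins.bin_index(chrom, np.array([mid * w]))[0])


def _nb_draw(rng, mean, dispersion, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def generate_genomic(
    params: GenomicSimParams | None = None,
) -> tuple[pd.DataFrame, GenomeBins, CountMatrix, CountMatrix, GenomicTruth]:
    """Generate gene models, bins, DamID and expression count matrices.

    Enriched bins are placed inside the designated gene bodies/promoters so
    the planted Venn class sizes are achievable exactly when calls are
    perfect; DE genes get a ``de_fold`` change in the planted direction.
    Returns ``(gene_models, bins, damid_counts, expression_counts, truth)``.
    """
    p = params or GenomicSimParams()
    rng = np.random.default_rng(p.seed)
    genes = _place_genes(p, rng)
    gene_models = make_gene_models(genes, p.chrom_sizes, p.promoter_len)
    bins = make_bins(p.chrom_sizes, p.bin_width)

    # planted DE labels and Venn membership
    order = rng.permutation(p.n_genes)
    de_idx = order[: p.n_de]
    n_b, n_p, n_bp = p.venn_body_only, p.venn_promoter_only, p.venn_both
    body_idx = set(de_idx[:n_b]) | set(de_idx[n_b + n_p : n_b + n_p + n_bp])
    prom_idx = set(de_idx[n_b : n_b + n_p]) | set(
        de_idx[n_b + n_p : n_b + n_p + n_bp]
    )
    down = rng.random(p.n_de) < p.de_down_fraction

    gene_truth = gene_models.copy()
    gene_truth["de"] = False
    gene_truth.loc[gene_truth.index[de_idx], "de"] = True
    gene_truth["direction"] = "none"
    gene_truth.loc[gene_truth.index[de_idx], "direction"] = np.where(
        down, "down_in_mutant", "up_in_mutant"
    )
    gene_truth["enriched_body"] = [
        i in body_idx for i in range(p.n_genes)
    ]
    gene_truth["enriched_promoter"] = [
        i in prom_idx for i in range(p.n_genes)
    ]

    # per-gene strength multiplier shared between the enrichment fold and
    # the DE fold of positively regulated direct targets (planted
    # enrichment–expression coupling); 1.0 elsewhere
    down_by_gene = dict(zip(de_idx.tolist(), down.tolist()))
    strength = np.ones(p.n_genes)
    if p.couple_positive_regulation:
        target_idx = sorted(body_idx | prom_idx)
        for i in target_idx:
            if down_by_gene.get(i, False):
                strength[i] = float(
                    np.exp(rng.uniform(0.0, p.coupling_spread))
                )

    # plant one enriched bin per designated gene body / promoter, choosing a
    # bin that lies entirely inside the feature so planted enrichment never
    # leaks into a neighboring feature class
    enriched_bins: dict[int, float] = {}
    for i in sorted(body_idx):
        g = gene_models.iloc[i]
        b = _contained_bin(bins, g.chrom, int(g.start), int(g.end))
        enriched_bins[b] = max(2.0, p.enriched_fold * strength[i])
    for i in sorted(prom_idx):
        g = gene_models.iloc[i]
        b = _contained_bin(
            bins, g.chrom, int(g.promoter_start), int(g.promoter_end)
        )
        enriched_bins[b] = max(2.0, p.enriched_fold * strength[i])

    n_bins = len(bins)
    mu = np.full(n_bins, p.bin_mean)
    enriched_arr = np.zeros(n_bins, dtype=bool)
    bin_fold = np.ones(n_bins)
    for b, f in enriched_bins.items():
        enriched_arr[b] = True
        bin_fold[b] = f
    conds = {}
    cols = {}
    for j in range(p.n_rep_damid):
        name = f"control_{j + 1}"
        cols[name] = _nb_draw(rng, mu, p.dispersion_damid, (n_bins,))
        conds[name] = "control"
    mu_f = mu * bin_fold
    for j in range(p.n_rep_damid):
        name = f"fusion_{j + 1}"
        cols[name] = _nb_draw(rng, mu_f, p.dispersion_damid, (n_bins,))
        conds[name] = "fusion"
    damid = CountMatrix(
        counts=pd.DataFrame(cols, index=bins.table["bin_id"].to_numpy()),
        conditions=pd.Series(conds),
    )

    # expression: biological replicate means drawn once, technical = Poisson
    base_mu = np.exp(rng.normal(p.expr_mean_log, p.expr_mean_sd, size=p.n_genes))
    fold = np.ones(p.n_genes)
    de_strength = strength[de_idx]
    fold[de_idx] = np.where(
        down, 1.0 / (p.de_fold * de_strength), p.de_fold
    )
    ecols, econds = {}, {}
    r = 1.0 / p.dispersion_expr
    for genotype, f in (("WT", np.ones(p.n_genes)), ("mutant", fold)):
        for b in range(p.n_bio_rep):
            lam = rng.gamma(shape=r, scale=base_mu * f / r)
            for tch in range(p.n_tech_rep):
                name = f"{genotype}_b{b + 1}t{tch + 1}"
                ecols[name] = rng.poisson(lam)
                econds[name] = genotype
    expr = CountMatrix(
        counts=pd.DataFrame(ecols, index=gene_models["gene_id"].to_numpy()),
        conditions=pd.Series(econds),
    )

    bin_truth = bins.table.copy()
    bin_truth["enriched"] = enriched_arr
    bin_truth["fold"] = bin_fold
    truth = GenomicTruth(genes=gene_truth, bins=bin_truth)
    return gene_models, bins, damid, expr, truth


def simulate_enrichment_bins(
    n_null: int = 10_000,
    n_enriched: int = 200,
    fold: float = 4.5,
    control_mean: float = 22.0,
    dispersion: float = 0.05,
    n_rep: int = 3,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Flat bin-level enrichment simulation with known labels.

    The reference benchmark for the NB test: ``n_null`` null bins plus
    ``n_enriched`` bins at ``fold`` in the fusion condition, NB counts at
    ``control_mean`` with the given dispersion, ``n_rep`` vs ``n_rep``
    replicates. Returns the count matrix and the boolean truth labels.
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_enriched
    truth = np.zeros(n, dtype=bool)
    truth[:n_enriched] = True
    mu_c = np.full(n, control_mean)
    mu_f = np.where(truth, control_mean * fold, control_mean)
    cols, conds = {}, {}
    for j in range(n_rep):
        name = f"control_{j + 1}"
        cols[name] = _nb_draw(rng, mu_c, dispersion, (n,))
        conds[name] = "control"
    for j in range(n_rep):
        name = f"fusion_{j + 1}"
        cols[name] = _nb_draw(rng, mu_f, dispersion, (n,))
        conds[name] = "fusion"
    cm = CountMatrix(counts=pd.DataFrame(cols), conditions=pd.Series(conds))
    return cm, truth


def simulate_de_genes(
    n_null: int = 2000,
    n_de: int = 200,
    fold: float = 3.0,
    mean_log: float = np.log(150.0),
    mean_sd: float = 0.8,
    dispersion: float = 0.1,
    n_rep: int = 4,
    up_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Flat DE benchmark with independent replicates and known labels.

    ``n_de`` genes change by ``fold`` (a fraction ``up_fraction`` upward in
    the mutant), the rest are null; base means are lognormal, counts NB
    with the given dispersion, ``n_rep`` vs ``n_rep`` independent columns.
    Returns the count matrix and a truth table (de, direction).
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_de
    base = np.exp(rng.normal(mean_log, mean_sd, size=n))
    de = np.zeros(n, dtype=bool)
    de[:n_de] = True
    up = rng.random(n) < up_fraction
    factor = np.where(de, np.where(up, fold, 1.0 / fold), 1.0)
    cols, conds = {}, {}
    for j in range(n_rep):
        name = f"WT_{j + 1}"
        cols[name] = _nb_draw(rng, base, dispersion, (n,))
        conds[name] = "WT"
    for j in range(n_rep):
        name = f"mutant_{j + 1}"
        cols[name] = _nb_draw(rng, base * factor, dispersion, (n,))
        conds[name] = "mutant"
    truth = pd.DataFrame(
        {
            "de": de,
            "direction": np.where(
                de, np.where(up, "up_in_mutant", "down_in_mutant"), "none"
            ),
        }
    )
    cm = CountMatrix(counts=pd.DataFrame(cols), conditions=pd.Series(conds))
    return cm, truth
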
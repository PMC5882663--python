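# Methods

This note documents the models, conventions and numerical choices behind
each analysis module, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Tissue model

A segmented frame is an integer label image (0 = membrane/background, one
4-connected component per positive label). Coordinates are 0-based pixel
indices; the AP axis runs along rows with anterior at row 0 and the ML
axis along columns (the "anterior is up" display convention; an
`AxisConvention` swaps this when needed). Physical polygon vertices sit on
pixel corners scaled by `pixel_size` (µm/px), so a cell's polygon is the
exact outline of its pixel set and Σ cell areas equals the nonzero pixel
count × pixel_size² with no pixel lost or double-counted.

**Adjacency rule.** Two cells are adjacent iff they share at least two
4-neighbor border pixel pairs. Corner-point contacts and single-pixel
kisses are excluded deliberately: under rasterization noise they flicker
between frames and would generate spurious neighbor-exchange events.
Interface polylines are the chained shared pixel edges, so interface
length is exact and the polylines partition the inter-label border.

Cells touching the image border are flagged `clipped` and excluded from
shape metrics by default — their outlines are truncated by the field of
view, exactly like partially imaged cells in manual outlining. Tracking is
consumed, never computed: a `TrackedTimeLapse` carries an externally
supplied frame-local-label → persistent-id map, and `validate_tracking`
reports (without mutating) lost/new ids, duplicates and timestamp
violations.

## Cell polarity

The "fit ellipse" is the moment-matched ellipse: the eigen-decomposition
of the polygon's second central area moments, computed in closed form by
Green's-theorem (shoelace) formulas. For an L×W rectangle the moments are
L²/12 and W²/12, so AR = L/W; the fit is deterministic, and exactly
translation-, rotation- and scale-equivariant. Orientation is the major-
axis angle against the ML axis folded to [0°, 90°] (θ, −θ and 180°−θ are
the same axis). Shapes with relative eigenvalue gap below 1e−6 are
isotropic: flagged degenerate, orientation 0 by convention, and excluded
from orientation medians (an isotropic cell has no meaningful axis).

Cohort summaries report the median orientation and mean aspect ratio per
(group, boundary row), pooling cells across embryos as in per-cell dot
plots; per-embryo grouping keys can be added for hierarchy-aware
reanalysis since pooling understates between-embryo variance. Group
comparisons are two-sided nonparametric tests — two-sample
Kolmogorov–Smirnov for distributions and Mann–Whitney with midrank ties —
with exact p-values for small tie-free samples (they then equal exhaustive
permutation enumeration) and asymptotic p otherwise.

## Notochord boundary

All axial–paraxial interface edges are chained into maximal traces; a
healthy tissue yields exactly two (left/right of the axial strip, assigned
by ML position against the mean axial centroid), and any other count is an
error, not a silent guess. Straightness is total traced length over the
endpoint chord, computed per side; the per-frame mean of sides is also
reported since side handling is a free choice. The full visible extent of
each trace is used and the endpoints are recorded.

Because a rasterized trace follows pixel edges, it measures city-block
(L1) length: a straight diagonal line would score √2. Tests therefore
compare rasterized straightness against the L1 arc length of the planted
curve, while analytic polylines (collinear, semicircle, right angle) are
checked against their Euclidean closed forms. Within one condition and
fixed rasterization the statistic is strictly monotone in the planted
boundary amplitude.

Boundary-distance rows are breadth-first distances within the axial
adjacency subgraph from the edge set (axial cells owning ≥ 1 Edge
interface), i.e. distance to the nearest of the two boundaries; rows are
reported as edge/−1/−2 labels. Junction classes use the interface's
endpoint-chord angle folded to [0°, 90°]: V if ≤ 30°, T if ≥ 60°, with the
half-angle config-exposed (symmetric 30° sectors follow the ML/AP sector
convention of the intercalation literature). Near-diagonal interfaces get
an explicit `oblique` class — a hard V/T dichotomy at 45° would
misclassify them — and are counted, never dropped.

## T1 detection

For each frame transition the adjacency diff (over persistent ids present
in both frames) yields lost and gained pairs. A lost pair (a, b) and a
gained pair (c, d) form a T1 event iff they are disjoint and c, d were
each adjacent to both a and b at the earlier frame. Unmatched losses and
gains are reported separately (`loss_non_t1` / `gain_non_t1`): boundary
drift, extrusion and rosette-like (> 4-cell) rearrangements are visible in
that table rather than inflating the T1 count. Events carry the earlier
frame's timestamp. Cells whose persistent id appears or disappears
(divisions break tracking) never enter the diff, so division ≠
intercalation by construction. Rates are normalized linearly to a 90-min
window; movies shorter than half the window are rejected rather than
extrapolated.

## Ablation recoil

A `RecoilSeries` holds the pre-cut inter-vertex distance and exactly ten
post-cut distances (the acquisition protocol records a ten-image burst);
the frame spacing is hardware-bound and therefore a config input, with
post frame k at time (k+1)·dt after the cut. Recoil at frame k is simply
d_post[k] − d_pre, "immediately after" meaning k = 0. The optional
relaxation fit d(t) = d_pre + L∞(1 − e^(−t/τ)) uses least squares with the
deterministic start (L∞₀ = max recoil, τ₀ = half the series span) and
L∞ ≥ 0, τ > 0 bounds; non-convergence produces a flagged record, never an
exception. Class and genotype comparisons use Kruskal–Wallis across groups
plus pairwise two-sided Mann–Whitney with Holm adjustment (the multiplicity
procedure is a package choice); groups with fewer than two observations
are excluded and reported. Recoil is interpreted only as a monotone proxy
for junctional tension — no viscoelastic model beyond the single
exponential is implied.

## Genomic targets

Coordinates are 0-based half-open (BED convention) everywhere; GFF input
(1-based closed) is converted at the reader boundary. Chromosomes are
tiled with contiguous 1000-bp bins (last bin truncated); reads are
assigned to exactly one bin by their 5′ position, so totals are conserved.
Promoters are the 2 kb upstream of the TSS, strand-aware and clipped to
chromosome bounds; for multi-transcript genes the 5′-most start per strand
is the TSS.

**NB Wald test.** The differential machinery is a self-contained
negative-binomial Wald test used for both bin enrichment and expression:

* median-of-ratios size factors (geometric-mean reference; library-size
  fallback for matrices with no all-positive feature);
* per-feature method-of-moments dispersion α from the pooled within-group
  variance, shrunk toward a mean-binned median trend with 10 pseudo-
  observations and floored at 1e−8 — with 3 replicates the raw estimate is
  far too noisy, and pooling across the thousands of features of a binned
  genome is what keeps the null calibrated;
* log2 fold change on normalized group means with pseudocount 0.5, its
  delta-method standard error from Var(q) = µ/s + αµ², two-sided normal
  p-values, Benjamini–Hochberg adjustment; all-zero features get p = 1 and
  an undefined fold change.

Enrichment calls require p_adj ≤ 0.01 **and** ≥ 4-fold in the enrichment
direction; ≥ 4-fold depletion at the same p_adj is reported separately as
`depleted` (loci the fusion avoids), never folded into the enriched set.
DE calls require p_adj ≤ 0.05 and ≥ 2-fold in either direction, with the
direction recorded from the sign (up/down in mutant). Technical replicates
are separate columns by default, matching four-column replicate layouts;
an option collapses them onto biological replicates (summing counts),
which is the statistically safer design since technical columns violate
the independence the test assumes — the default mildly inflates DE calls
and is kept for fidelity to the emulated design.

Region assignment uses precedence promoter > gene body > intergenic with
≥ 1 bp overlap. A gene (promoter) is enriched iff ≥ 1 significant bin
overlaps it; genes without bins are "unassessed" rather than negative. The
Venn integration is purely set-theoretic over the DE universe; the summary
reports class counts, the direct-target total and its percentage of DE
genes (nearest integer), and the positively regulated (down-in-mutant)
fraction per class. The Spearman correlation of enrichment level with
expression change uses midrank ties and, for n ≤ 8, an exact p-value by
exhaustive enumeration over orderings (the asymptotic p is used above
that).

## Synthetic data

The generators are pure functions of (params, seed) and define the study
conditions the tests run under.

**Tissue.** Seeds sit on a hexagonally offset lattice scaled √AR* along ML
and 1/√AR* along AP with 12% jitter; each seed carries an orientation
drawn from a von Mises distribution on the doubled angle (the natural
axial distribution with one concentration knob κ; κ = 8 gives strongly
ML-aligned cells, κ → 0 uniform). Pixels first receive a compartment by
comparing their ML position with the displaced boundary curves
x₀ + A·sin(2π·y/λ), then the label of the nearest same-compartment seed
under that seed's anisotropic metric. The rasterized boundary therefore
follows the planted sinusoid within one pixel, while cell shapes carry the
planted elongation and orientation. Defaults (12-µm spacing, AR* = 2,
κ = 8, A = 2 µm, λ = 60 µm) emulate late-gastrula axial mesoderm with a
near-straight boundary; A ≈ 8 µm emulates the irregular-boundary
phenotype. The amplitude is specified pre-rasterization, so straightness
tolerances include the L1 discretization term discussed above. Minor
disconnected fragments produced by the anisotropic metric are reassigned
to the most-contacted same-compartment neighbor, preserving one component
per label.

**T1 movies.** A scripted flip (a, b → c, d) is realized by moving the c,
d seeds toward the midpoint of the a–b interface and nudging a, b apart,
trying a fixed ladder of move strengths; a move is accepted only if the
rasterized adjacency diff is exactly {(a,b)} lost / {(c,d)} gained, and
`propose_t1_script` searches the axial adjacency graph for k mutually
disjoint realizable quartets (refreshing candidates after each accepted
flip). Tracking is emitted perfect. This guarantees the generator's truth
table is exact, at the cost of refusing geometrically awkward quartets.

**Recoil.** d(t) = d_pre + L(1 − e^(−t/τ)) with L equal to the planted
class tension (defaults Edge 2.0, V 1.2, T 0.8 µm — boundary above
shrinking above passive junctions), τ = 3 s, d_pre ~ U(3, 6) µm, Gaussian
noise per frame (default σ = 0.05 µm).

**Genomic counts.** Two 10-Mb chromosomes host 3000 non-overlapping genes
of 2.0–3.2 kb in fixed slots with promoter room on both sides; 10 Mb
total cannot host 3000 genes once each needs a 2-kb promoter plus a gene
body long enough to contain a full 1000-bp bin, hence the 20-Mb default.
DamID counts are NB (dispersion 0.05) around a 22-read/bin control mean
with 3 replicates per condition; expression counts use 2 biological × 2
technical replicates per genotype, technical replicates sharing their
biological replicate's gamma-distributed mean (so they are correlated, as
real technical replicates are). The planted design places one enriched bin
entirely inside each designated gene body/promoter so the planted Venn
class sizes (defaults: the published class proportions scaled to 3000
genes) are achievable exactly under perfect calls, plants DE at 3-fold
with the published down-in-mutant share, and couples enrichment strength
to expression change for positively regulated direct targets via a shared
per-gene multiplier in [1, e^0.8] — emulating the observed positive
enrichment–expression correlation. Flat benchmark helpers
(`simulate_enrichment_bins`, `simulate_de_genes`) provide the clean
label-recovery simulations used by the test suite.

What the generators do **not** emulate: real segmentation error, z-drift
and mitosis-driven tracking breaks; protrusive cell shapes (Voronoi cells
are convex-ish); GATC-fragment resolution of DamID (the analysis is
bin-level and fragment-agnostic, so reads are placed per bin);
chromosome-scale covariates such as GC or mappability; and any coupling
between the tissue and genomic worlds. Passing tests therefore demonstrate
correctness of the measurement chain under controlled conditions, not
robustness to imaging artifacts.

## Problem sizes

Test-suite simulations use a compact tissue (7 rows, 5 axial + 2×2
paraxial columns, ~60 cells, ~150×60 px), 100 scripted-T1 movies, 100
noisy recoil traces, and the reference enrichment simulation of 10,200
bins × 6 samples over 5 seeds — sizes chosen so the whole suite runs in
about a minute while keeping every statistical check well-powered.

## Known limitations

* The NB test's fold-change point estimate at n = 3 has sd(log2 FC)
  ≈ 0.33 around a 22-read mean; effects close to the 4-fold call threshold
  are recovered with correspondingly partial recall (about two-thirds at a
  planted 4.5-fold), a sampling-noise property of any estimator, not of
  this test — the false-positive side stays controlled throughout.
* Rasterized straightness carries the L1 discretization factor; comparing
  straightness across different pixel sizes requires matched rasterization.
* Pooled cohort medians understate between-embryo variance; use the
  per-embryo outputs for formal inference across embryos.
* The junction classifier uses the endpoint chord, which under-represents
  strongly curved interfaces; these mostly land in the `oblique` class.
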
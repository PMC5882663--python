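# gastruquant

Quantitative analysis of tissue morphogenesis during zebrafish
gastrulation, built for researchers who quantify convergence & extension
(C&E) from segmented membrane-labeled time-lapses and who integrate
DamID-seq chromatin-association profiles with RNA-seq differential
expression.

During C&E the axial mesoderm narrows mediolaterally (ML) and extends
anteroposteriorly (AP), driven by ML cell intercalation. The package
implements the full measurement chain for this process:

* **Cell polarity** — per-cell orientation θ ∈ [0°, 90°] of the fit-ellipse
  major axis with respect to the ML axis (0° = ML-aligned) and aspect
  ratio AR = √(λ₁/λ₂) from the eigenvalues of the polygon's second central
  area moments; cohorts keyed by a cell's distance to the notochord
  boundary (edge, −1, −2, …).
* **Notochord-boundary straightness** — the ratio of a boundary trace's
  total length to its endpoint chord (net length); 1.0 is perfectly
  straight, irregular boundaries score higher.
* **T1 intercalation** — neighbor exchanges in a tracked time-lapse: a
  quartet {a, b, c, d} where the a–b interface collapses and the c–d
  interface opens; counts normalized to events per 90 min.
* **Junction classes and ablation recoil** — interfaces classified as Edge
  (on the axial/paraxial boundary), V (ML-aligned, shrink-competent) or T
  (AP-aligned); post-laser-ablation vertex recoil d_post[k] − d_pre per
  class as a tension proxy, with optional single-exponential relaxation
  fits d(t) = d_pre + L∞(1 − e^(−t/τ)).
* **DamID × RNA-seq direct targets** — 1000-bp genome bins, a negative-
  binomial Wald test of fusion-Dam over control-Dam counts
  (significant: p_adj ≤ 0.01 and ≥ 4-fold), strand-aware 2-kb promoters,
  differential expression at p_adj ≤ 0.05 and ≥ 2-fold, and the Venn
  integration that classifies each differentially expressed gene as
  enriched at the gene body, promoter, both, or neither — genes enriched
  anywhere being putative direct targets — plus the Spearman correlation
  of enrichment level with expression change.

Every analysis is exercised end-to-end on synthetic data with planted
ground truth: anisotropic Voronoi tissues with a controllable sinusoidal
boundary, scripted T1 movies with perfect tracking, exponential recoil
traces, and NB count matrices with planted enrichment/DE overlap.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on synthetic
inputs (written under `results/`):

```bash
python analysis/01_simulate_inputs.py      # tissues, movie, recoil, counts
python analysis/02_boundary_straightness.py
python analysis/03_cell_polarity.py
python analysis/04_intercalation.py
python analysis/05_ablation_recoil.py
python analysis/06_genomic_targets.py
```

`02` compares a control tissue (planted boundary amplitude 2 µm) with a
perturbed one (8 µm):

```
mean straightness: control 1.129, perturbed 1.541 (higher in perturbed)
```

`03` shows the polarity signature — the perturbed tissue (weak orientation
concentration, rounder cells) loses ML alignment, most strongly in
boundary-adjacent edge cells:

```
orientation: control median 6.6° vs perturbed 17.6° (KS D=0.47, p=0.00019)
aspect ratio: control mean 1.84 vs perturbed 1.32 (MW p=1.3e-09)
```

`04` recovers all four scripted neighbor exchanges from the 90-min movie
(`4.0 events / 90 min`), `05` recovers the planted tension ordering
(`Edge > V > T`, Kruskal–Wallis p = 5.3e-09), and `06` integrates DamID
enrichment with expression:

```
direct targets: 84 (22% of DE genes)
Venn classes: {'gene_body_only': 51, 'promoter_only': 17, 'both': 16, 'none': 301}
enrichment~expression (positively regulated, gene body): rho=0.49, p=0.00603
```

The same stages are available as a CLI
(`gastruquant simulate-tissue | measure-polarity | measure-boundary |
analyze-recoil | genomic-targets | run …`); `gastruquant run --seed 3
--out out/` executes the full demo pipeline with a reproducibility
manifest.

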
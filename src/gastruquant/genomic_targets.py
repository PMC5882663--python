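"""DamID-seq binned enrichment and DamID × RNA-seq direct-target integration.

DamID reads a fusion protein's genomic association against an untethered-Dam
control. The analysis here follows the binned-count design: the genome is
tiled into contiguous 1000-bp bins, uniquely mapped reads are counted per
bin and sample, and per-bin enrichment of the fusion over the control is
tested under a negative-binomial (NB) model. Gene bodies and strand-aware
2-kb promoters are called enriched when they overlap at least one
significant bin (padj ≤ 0.01 and ≥ 4-fold). Differential expression uses the
same NB machinery at padj ≤ 0.05 and ≥ 2-fold. A gene that is both
differentially expressed and enriched (gene body, promoter, or both) is a
putative direct target; the Venn split of those classes and the Spearman
correlation between enrichment and expression change are the integration
outputs.

The NB test is a self-contained Wald test: median-of-ratios size factors,
per-feature method-of-moments dispersion shrunk toward a mean-dependent
trend, pseudocount-stabilized (0.5) fold changes on normalized means, and
Benjamini–Hochberg adjustment. Coordinates are 0-based half-open (BED
convention) everywhere; GFF input is converted at the reader boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
ENRICH_PADJ, ENRICH_FC = 0.01, 4.0
DE_PADJ, DE_FC = 0.05, 2.0
PROMOTER_LEN = 2000
BIN_WIDTH = 1000


class GenomicsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# bins, gene models, counting


@dataclass
class GenomeBins:
    """Contiguous fixed-width tiling of every chromosome (last bin short)."""

    table: pd.DataFrame  # bin_id, chrom, start, end
    width: int
    chrom_sizes: dict[str, int]

    def __len__(self):
        return len(self.table)

    def bin_index(self, chrom: str, pos) -> np.ndarray:
        """Global bin id(s) for 0-based position(s) on a chromosome."""
        pos = np.asarray(pos, dtype=np.int64)
        size = self.chrom_sizes[chrom]
        if ((pos < 0) | (pos >= size)).any():
            bad = pos[(pos < 0) | (pos >= size)]
            raise GenomicsError(
                f"position(s) {bad[:5].tolist()} beyond {chrom} of size {size}"
            )
        return self._offsets[chrom] + pos // self.width

    @property
    def _offsets(self) -> dict[str, int]:
        off, total = {}, 0
        for chrom, size in self.chrom_sizes.items():
            off[chrom] = total
            total += -(-size // self.width)
        return off


def make_bins(chrom_sizes: dict[str, int], width: int = BIN_WIDTH) -> GenomeBins:
    """Tile each chromosome with ``width``-bp bins, truncating the last."""
    if width <= 0:
        raise GenomicsError("bin width must be positive")
    rows = []
    bid = 0
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise GenomicsError(f"chromosome {chrom} has non-positive size {size}")
        for start in range(0, size, width):
            rows.append(
                {
                    "bin_id": bid,
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + width, size),
                }
            )
            bid += 1
    return GenomeBins(table=pd.DataFrame(rows), width=width, chrom_sizes=dict(chrom_sizes))


def make_gene_models(
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    promoter_len: int = PROMOTER_LEN,
) -> pd.DataFrame:
    """Attach strand-aware promoters ([TSS − 2 kb, TSS), clipped) to genes.

    ``genes`` needs columns gene_id, chrom, start, end, strand with 0-based
    half-open spans. The TSS is the 5′ span end per strand (start on '+',
    end on '−'); multi-transcript genes should already be collapsed to the
    5′-most start.
    """
    g = genes.copy()
    bad = g[~g["strand"].isin(["+", "-"])]
    if len(bad):
        raise GenomicsError(f"invalid strands: {bad['strand'].unique().tolist()}")
    sizes = g["chrom"].map(chrom_sizes)
    if sizes.isna().any():
        raise GenomicsError("gene on chromosome absent from chrom_sizes")
    plus = g["strand"] == "+"
    g["tss"] = np.where(plus, g["start"], g["end"] - 1)
    g["promoter_start"] = np.where(
        plus, np.maximum(0, g["start"] - promoter_len), g["end"]
    )
    g["promoter_end"] = np.where(
        plus, g["start"], np.minimum(sizes, g["end"] + promoter_len)
    )
    return g


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_genes_bed(path) -> pd.DataFrame:
    """BED file of gene spans (0-based half-open, name = gene id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=range(6),
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def read_genes_gff(path) -> pd.DataFrame:
    """Gene records from a GFF3 file, converted to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            rows.append(
                {
                    "gene_id": gid,
                    "chrom": f[0],
                    "start": int(f[3]) - 1,  # GFF is 1-based closed
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CountMatrix:
    """Features × samples integer counts with per-sample condition labels."""

    counts: pd.DataFrame  # index: feature ids, columns: sample names
    conditions: pd.Series  # sample name -> condition label

    def __post_init__(self):
        self.conditions = pd.Series(self.conditions)
        if list(self.counts.columns) != list(self.conditions.index):
            self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            raise GenomicsError("every sample column needs a condition label")
        if (self.counts.to_numpy() < 0).any():
            raise GenomicsError("counts must be non-negative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def count_reads(
    reads: pd.DataFrame, bins: GenomeBins, conditions: dict[str, str]
) -> CountMatrix:
    """Count 5′ read positions per bin and sample.

    ``reads`` is a long table with columns sample, chrom, pos (0-based 5′
    position of a uniquely mapped read; MAPQ filtering happens upstream).
    Every read lands in exactly one bin, so totals are conserved.
    """
    n_bins = len(bins)
    samples = sorted(reads["sample"].unique())
    mat = np.zeros((n_bins, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        sub = reads[reads["sample"] == s]
        for chrom, grp in sub.groupby("chrom"):
            idx = bins.bin_index(chrom, grp["pos"].to_numpy())
            np.add.at(mat[:, j], idx, 1)
    counts = pd.DataFrame(mat, index=bins.table["bin_id"].to_numpy(), columns=samples)
    return CountMatrix(counts=counts, conditions=pd.Series(conditions))


# ---------------------------------------------------------------------------
# the NB Wald test


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Falls back to library-size ratios when no feature is positive in every
    sample (tiny or very sparse matrices).
    """
    k = np.asarray(counts, dtype=float)
    pos = (k > 0).all(axis=1)
    if pos.sum() >= 1:
        logs = np.log(k[pos])
        ref = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - ref, axis=0))
    else:
        lib = k.sum(axis=0)
        sf = lib / np.exp(np.log(lib[lib > 0]).mean())
    return sf / np.exp(np.log(sf).mean())


def _dispersion_trend(mu: np.ndarray, alpha_raw: np.ndarray, n_bins: int = 20):
    """Median raw dispersion within mean-quantile bins, as a step trend."""
    ok = mu > 0
    if ok.sum() < 10:
        med = float(np.median(alpha_raw[ok])) if ok.any() else DISPERSION_FLOOR
        return np.full_like(alpha_raw, max(med, DISPERSION_FLOOR))
    qs = np.quantile(mu[ok], np.linspace(0, 1, n_bins + 1))
    qs = np.unique(qs)
    which = np.clip(np.searchsorted(qs, mu, side="right") - 1, 0, len(qs) - 2)
    trend = np.full_like(alpha_raw, DISPERSION_FLOOR)
    for b in range(len(qs) - 1):
        m = ok & (which == b)
        if m.any():
            trend[m] = max(float(np.median(alpha_raw[m])), DISPERSION_FLOOR)
    return trend


def nb_wald_test(
    cm: CountMatrix,
    condition_ref: str,
    condition_alt: str,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-feature NB Wald test of ``condition_alt`` vs ``condition_ref``.

    Counts are normalized by median-of-ratios size factors; per-feature
    dispersions are method-of-moments estimates shrunk toward a
    mean-dependent trend (weight ``prior_df`` pseudo-observations), floored
    at 1e-8 — pooling across the many features of a binned genome is what
    keeps the n = 3 null calibrated. The Wald statistic is the pseudocount-
    stabilized log2 fold change over its delta-method standard error;
    p-values are two-sided normal, BH-adjusted. All-zero features get
    p = 1 and an undefined fold change.
    """
    samples_a = cm.samples_of(condition_ref)
    samples_b = cm.samples_of(condition_alt)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise GenomicsError("need >= 2 replicates per condition")
    k = cm.counts[samples_a + samples_b].to_numpy(dtype=float)
    sf = size_factors(k)
    q = k / sf
    na, nb = len(samples_a), len(samples_b)
    qa, qb = q[:, :na], q[:, na:]
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    mu_pool = q.mean(axis=1)

    # method-of-moments dispersion, pooled within-group variance
    var_w = (qa.var(axis=1, ddof=1) * (na - 1) + qb.var(axis=1, ddof=1) * (nb - 1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(
            mu_pool > 0, (var_w - mu_pool) / np.square(mu_pool), DISPERSION_FLOOR
        )
    alpha_raw = np.clip(alpha_raw, DISPERSION_FLOOR, None)
    trend = _dispersion_trend(mu_pool, alpha_raw)
    n_df = na + nb - 2
    alpha = np.clip(
        (n_df * alpha_raw + prior_df * trend) / (n_df + prior_df),
        DISPERSION_FLOOR,
        None,
    )

    lfc = np.log2((mu_b + PSEUDOCOUNT) / (mu_a + PSEUDOCOUNT))
    sf_a, sf_b = sf[:na], sf[:nb + na][na:]
    var_mean_a = (
        np.outer(mu_a, 1.0 / sf_a) + np.outer(alpha * mu_a**2, 1.0 / sf_a**2)
    ).sum(axis=1) / na**2
    var_mean_b = (
        np.outer(mu_b, 1.0 / sf_b) + np.outer(alpha * mu_b**2, 1.0 / sf_b**2)
    ).sum(axis=1) / nb**2
    se_lfc = np.sqrt(
        var_mean_a / np.square(mu_a + PSEUDOCOUNT)
        + var_mean_b / np.square(mu_b + PSEUDOCOUNT)
    ) / np.log(2.0)

    allzero = k.sum(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_lfc > 0, lfc / se_lfc, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[allzero] = 1.0
    lfc = np.where(allzero, np.nan, lfc)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature_id": cm.counts.index,
            "mean_ref": mu_a,
            "mean_alt": mu_b,
            "log2_fc": lfc,
            "dispersion": alpha,
            "se_log2_fc": se_lfc,
            "p": p,
            "p_adj": padj,
        }
    ).set_index("feature_id")


def enrichment_test(
    cm: CountMatrix,
    control_condition: str = "control",
    fusion_condition: str = "fusion",
    padj_cutoff: float = ENRICH_PADJ,
    fc_cutoff: float = ENRICH_FC,
) -> pd.DataFrame:
    """Per-bin fusion-over-control enrichment calls.

    'significant' requires both padj ≤ 0.01 and ≥ 4-fold enrichment in the
    fusion direction; ≥ 4-fold depletion at the same padj is reported
    separately as 'depleted' (open-chromatin loci the fusion avoids), never
    folded into the enriched set.
    """
    res = nb_wald_test(cm, control_condition, fusion_condition)
    lfc_cut = np.log2(fc_cutoff)
    res["significant"] = (res["p_adj"] <= padj_cutoff) & (res["log2_fc"] >= lfc_cut)
    res["depleted"] = (res["p_adj"] <= padj_cutoff) & (res["log2_fc"] <= -lfc_cut)
    return res


def de_test(
    cm: CountMatrix,
    wt_condition: str = "WT",
    mutant_condition: str = "mutant",
    padj_cutoff: float = DE_PADJ,
    fc_cutoff: float = DE_FC,
    collapse_technical: bool = False,
    technical_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression (mutant vs WT).

    Technical replicates are separate columns by default (matching the
    four-column replicate layout); pass ``collapse_technical=True`` with a
    sample → biological-replicate mapping to sum them first. 'significant'
    requires padj ≤ 0.05 and ≥ 2-fold change in either direction;
    'direction' is up_in_mutant / down_in_mutant from the fold-change sign.
    """
    if collapse_technical:
        if not technical_groups:
            raise GenomicsError("collapse_technical requires technical_groups")
        grouped = cm.counts.T.groupby(
            pd.Series(technical_groups).reindex(cm.counts.columns)
        ).sum().T
        cond = {
            g: cm.conditions[[s for s, gg in technical_groups.items() if gg == g][0]]
            for g in grouped.columns
        }
        cm = CountMatrix(counts=grouped, conditions=pd.Series(cond))
    res = nb_wald_test(cm, wt_condition, mutant_condition)
    lfc_cut = np.log2(fc_cutoff)
    res["significant"] = (res["p_adj"] <= padj_cutoff) & (
        res["log2_fc"].abs() >= lfc_cut
    )
    res["direction"] = np.where(res["log2_fc"] > 0, "up_in_mutant", "down_in_mutant")
    res.loc[res["log2_fc"].isna(), "direction"] = "undefined"
    return res


# ---------------------------------------------------------------------------
# feature assignment & target calling


def _interval_bins(bins: GenomeBins, chrom: str, start: int, end: int) -> np.ndarray:
    """Global ids of bins overlapping [start, end) by >= 1 bp."""
    if end <= start:
        return np.array([], dtype=int)
    off = bins._offsets[chrom]
    first = start // bins.width
    last = (end - 1) // bins.width
    n_chrom = -(-bins.chrom_sizes[chrom] // bins.width)
    first, last = max(first, 0), min(last, n_chrom - 1)
    return off + np.arange(first, last + 1)


def assign_region(bins: GenomeBins, gene_models: pd.DataFrame) -> pd.Series:
    """Region per bin: promoter > gene_body > intergenic (≥ 1 bp overlap)."""
    region = np.full(len(bins), "intergenic", dtype=object)
    for r in gene_models.itertuples():
        region[_interval_bins(bins, r.chrom, r.start, r.end)] = "gene_body"
    for r in gene_models.itertuples():
        region[
            _interval_bins(bins, r.chrom, int(r.promoter_start), int(r.promoter_end))
        ] = "promoter"
    return pd.Series(region, index=bins.table["bin_id"].to_numpy(), name="region")


def call_enriched_features(
    enrichment: pd.DataFrame, bins: GenomeBins, gene_models: pd.DataFrame
) -> tuple[set, set, set]:
    """Gene / promoter sets with >= 1 significant enriched bin.

    Returns ``(enriched_genes, enriched_promoters, unassessed)``; a gene on
    a chromosome without bins (tiny contig absent from chrom sizes) is
    unassessed rather than negative.
    """
    sig = set(enrichment.index[enrichment["significant"]])
    enriched_genes, enriched_promoters, unassessed = set(), set(), set()
    for r in gene_models.itertuples():
        if r.chrom not in bins.chrom_sizes:
            unassessed.add(r.gene_id)
            continue
        body = _interval_bins(bins, r.chrom, r.start, r.end)
        prom = _interval_bins(
            bins, r.chrom, int(r.promoter_start), int(r.promoter_end)
        )
        if len(body) == 0 and len(prom) == 0:
            unassessed.add(r.gene_id)
            continue
        if any(int(b) in sig for b in body):
            enriched_genes.add(r.gene_id)
        if any(int(b) in sig for b in prom):
            enriched_promoters.add(r.gene_id)
    return enriched_genes, enriched_promoters, unassessed


def integrate_targets(
    de: pd.DataFrame, enriched_genes: set, enriched_promoters: set
) -> tuple[pd.DataFrame, dict]:
    """Venn integration of DE genes with enrichment loci.

    For every DE-significant gene the enrichment locus is gene_body_only /
    promoter_only / both / none; a direct target is a DE gene enriched
    anywhere. The summary reports class counts, the direct-target total and
    its percentage of DE genes (nearest integer), and the fraction of each
    class that is positively regulated (down in mutant). Enriched ids
    absent from the DE universe are ignored for the Venn and logged.
    """
    universe = set(de.index)
    orphans = sorted((enriched_genes | enriched_promoters) - universe)
    de_sig = de[de["significant"]]
    rows = []
    for gid, r in de_sig.iterrows():
        in_body = gid in enriched_genes
        in_prom = gid in enriched_promoters
        locus = (
            "both"
            if (in_body and in_prom)
            else "gene_body_only"
            if in_body
            else "promoter_only"
            if in_prom
            else "none"
        )
        rows.append(
            {
                "gene_id": gid,
                "enrichment_locus": locus,
                "direction": r["direction"],
                "log2_fc": r["log2_fc"],
                "direct_target": locus != "none",
            }
        )
    cls = pd.DataFrame(
        rows,
        columns=["gene_id", "enrichment_locus", "direction", "log2_fc", "direct_target"],
    ).set_index("gene_id")
    n_de = len(cls)
    counts = {
        k: int((cls["enrichment_locus"] == k).sum())
        for k in ("gene_body_only", "promoter_only", "both", "none")
    }
    total_direct = int(cls["direct_target"].sum())
    pos_frac = {}
    for k in ("gene_body_only", "promoter_only", "both"):
        sub = cls[cls["enrichment_locus"] == k]
        pos_frac[k] = (
            float((sub["direction"] == "down_in_mutant").mean()) if len(sub) else np.nan
        )
    summary = {
        "n_de_genes": n_de,
        "class_counts": counts,
        "total_direct_targets": total_direct,
        "percent_of_de_genes": int(round(100.0 * total_direct / n_de)) if n_de else 0,
        "positively_regulated_fraction": pos_frac,
        "orphan_enriched_ids": orphans,
    }
    return cls, summary


def spearman(
    x, y, exact_max_n: int = 8
) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties, two-sided p.

    For n ≤ ``exact_max_n`` the p-value is computed by exhaustive
    enumeration over all orderings of one vector (the exact permutation
    null); larger samples use the asymptotic p. A constant vector leaves
    rho undefined: (nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


def enrichment_expression_correlation(
    classification: pd.DataFrame,
    enrichment_levels: pd.Series,
    de_log2_fc: pd.Series,
    locus: str = "gene_body_only",
    subset: str = "positively_regulated",
) -> tuple[float, float, int]:
    """Spearman correlation of enrichment level vs expression change.

    ``subset`` restricts to positively regulated (down in mutant),
    negatively regulated (up in mutant) or all direct targets of the given
    locus class; expression change enters as WT-over-mutant (the degree to
    which WT expression exceeds mutant), so a positive rho means the most
    enriched loci are the most strongly positively regulated.
    """
    sel = classification["enrichment_locus"].isin(
        [locus, "both"] if locus != "both" else ["both"]
    )
    if subset == "positively_regulated":
        sel &= classification["direction"] == "down_in_mutant"
    elif subset == "negatively_regulated":
        sel &= classification["direction"] == "up_in_mutant"
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    ids = [g for g in classification.index[sel] if g in enrichment_levels.index]
    x = enrichment_levels.loc[ids].to_numpy(dtype=float)
    y = -de_log2_fc.loc[ids].to_numpy(dtype=float)  # WT over mutant
    rho, p = spearman(x, y)
    return rho, p, len(ids)


def region_level_summary(
    cm: CountMatrix,
    regions: pd.Series,
    control_condition: str = "control",
    fusion_condition: str = "fusion",
) -> pd.DataFrame:
    """Per-region distributions of normalized reads and log2 ratios.

    For each region class (promoter / gene_body / intergenic): median and
    quartiles of size-factor-normalized counts per sample, and of the
    per-bin log2 fusion/control ratio of normalized means (pseudocount-
    stabilized). Empty region classes yield a null (NaN) summary row.
    """
    k = cm.counts.to_numpy(dtype=float)
    sf = size_factors(k)
    q = pd.DataFrame(k / sf, index=cm.counts.index, columns=cm.counts.columns)
    mu_c = q[cm.samples_of(control_condition)].mean(axis=1)
    mu_f = q[cm.samples_of(fusion_condition)].mean(axis=1)
    lfc = np.log2((mu_f + PSEUDOCOUNT) / (mu_c + PSEUDOCOUNT))
    regions = regions.reindex(cm.counts.index)
    rows = []
    for reg in ("promoter", "gene_body", "intergenic"):
        m = (regions == reg).to_numpy()
        rec = {"region": reg, "n_bins": int(m.sum())}
        if m.sum() == 0:
            rec.update(
                {
                    "median_norm_reads": np.nan,
                    "q1_norm_reads": np.nan,
                    "q3_norm_reads": np.nan,
                    "median_log2_fc": np.nan,
                }
            )
        else:
            vals = q.to_numpy()[m].ravel()
            rec.update(
                {
                    "median_norm_reads": float(np.median(vals)),
                    "q1_norm_reads": float(np.quantile(vals, 0.25)),
                    "q3_norm_reads": float(np.quantile(vals, 0.75)),
                    "median_log2_fc": float(np.median(lfc.to_numpy()[m])),
                }
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def rpkm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per feature and sample."""
    lib = counts.sum(axis=0)
    return (
        counts.div(lib / 1e6, axis=1).div(lengths_bp.reindex(counts.index) / 1e3, axis=0)
    )
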
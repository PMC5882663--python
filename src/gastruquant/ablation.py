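"""Laser-ablation recoil analysis.

After a cell interface is cut, the distance between its flanking vertices
increases; the recoil distance is the standard proxy for junctional tension.
Each ablation yields the pre-cut inter-vertex distance and a quick series of
ten post-cut frames. Per junction class (Edge / V / T) we quantify recoil at
a chosen post frame, optionally fit single-exponential relaxation kinetics
d(t) = d_pre + L∞·(1 − e^(−t/τ)), and compare classes/genotypes with
rank-based tests (Kruskal–Wallis across classes, pairwise Mann–Whitney with
Holm adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

N_POST_FRAMES = 10  # the acquisition protocol records ten post-cut images


@dataclass
class RecoilSeries:
    interface_id: str
    junction_class: str  # Edge / V / T
    d_pre: float  # µm, inter-vertex distance before ablation
    d_post: np.ndarray  # µm, 10 post-ablation distances
    dt_s: float  # frame spacing, seconds (hardware-bound, config input)
    genotype: str = "WT"

    def __post_init__(self):
        self.d_post = np.asarray(self.d_post, dtype=float)
        if self.d_pre <= 0:
            raise ValueError("d_pre must be positive")
        if len(self.d_post) != N_POST_FRAMES:
            raise ValueError(
                f"expected {N_POST_FRAMES} post-ablation frames, got {len(self.d_post)}"
            )
        if (self.d_post < 0).any():
            raise ValueError("distances must be >= 0")

    def times_s(self) -> np.ndarray:
        """Post-frame times; frame k is acquired (k+1)·dt after the cut."""
        return (np.arange(N_POST_FRAMES) + 1) * self.dt_s


@dataclass
class RelaxationFit:
    l_inf: float  # asymptotic recoil, µm
    tau: float  # relaxation time, s
    rss: float | None  # None when the fit did not converge
    converged: bool


def recoil(series: RecoilSeries, k: int = 0) -> float:
    """Recoil distance at post frame k (k = 0 is 'immediately after')."""
    if not 0 <= k < N_POST_FRAMES:
        raise ValueError(f"frame index {k} outside 0..{N_POST_FRAMES - 1}")
    return float(series.d_post[k] - series.d_pre)


def fit_relaxation(series: RecoilSeries) -> RelaxationFit:
    """Least-squares single-exponential fit of the post-cut distances.

    Deterministic initialization: L∞₀ = max recoil, τ₀ = half the post
    series span. Non-convergence is a flagged record, never an exception.
    """
    t = series.times_s()
    y = series.d_post - series.d_pre

    def model(t, l_inf, tau):
        return l_inf * (1.0 - np.exp(-t / tau))

    p0 = (max(float(y.max()), 1e-9), 0.5 * float(t[-1]))
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return RelaxationFit(l_inf=np.nan, tau=np.nan, rss=None, converged=False)
    resid = y - model(t, *popt)
    return RelaxationFit(
        l_inf=float(popt[0]),
        tau=float(popt[1]),
        rss=float(np.dot(resid, resid)),
        converged=True,
    )


def recoil_table(series_list, k: int = 0) -> pd.DataFrame:
    """Long-format recoil table (one row per ablated interface)."""
    return pd.DataFrame(
        [
            {
                "interface_id": s.interface_id,
                "junction_class": s.junction_class,
                "genotype": s.genotype,
                "d_pre_um": s.d_pre,
                "recoil_um": recoil(s, k),
            }
            for s in series_list
        ]
    )


def compare_recoil(series_list, k: int = 0, group_by: str = "junction_class"):
    """Rank-based comparison of recoil across groups at post frame k.

    Returns ``(kruskal, pairwise, excluded)``: the across-group
    Kruskal–Wallis H and p, a pairwise Mann–Whitney table with
    Holm-adjusted two-sided p-values, and the list of groups excluded for
    having fewer than two observations.
    """
    df = recoil_table(series_list, k=k)
    groups = {g: sub["recoil_um"].to_numpy() for g, sub in df.groupby(group_by)}
    excluded = sorted(g for g, v in groups.items() if len(v) < 2)
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    if np.ptp(pooled) == 0:  # all observations tied: no rank variation
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*[groups[g] for g in names])
    kruskal = {"H": float(h), "p": float(p), "groups": names}
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "exact" if (not ties and len(a) + len(b) <= 25) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "n_a": len(a),
                    "n_b": len(b),
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "U": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p"], method="holm")[1]
    return kruskal, pairwise, excluded


def read_recoil_table(path) -> list[RecoilSeries]:
    """Read recoil.tsv: interface, class, genotype, d_pre, d_0..d_9, dt_s."""
    df = pd.read_csv(path, sep="\t")
    cols = [f"d_{k}" for k in range(N_POST_FRAMES)]
    return [
        RecoilSeries(
            interface_id=str(r["interface"]),
            junction_class=str(r["class"]),
            genotype=str(r.get("genotype", "WT")),
            d_pre=float(r["d_pre"]),
            d_post=np.array([float(r[c]) for c in cols]),
            dt_s=float(r["dt_s"]),
        )
        for _, r in df.iterrows()
    ]


def write_recoil_table(series_list, path) -> None:
    rows = []
    for s in series_list:
        rec = {
            "interface": s.interface_id,
            "class": s.junction_class,
            "genotype": s.genotype,
            "d_pre": s.d_pre,
            "dt_s": s.dt_s,
        }
        rec.update({f"d_{k}": s.d_post[k] for k in range(N_POST_FRAMES)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
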
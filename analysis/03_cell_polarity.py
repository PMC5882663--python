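"""Mediolateral cell polarity by boundary-distance row.

Per condition: fit-ellipse orientation (vs ML axis) and aspect ratio of
every axial cell, cohorts keyed by row (edge / −1 / −2), and two-sided
nonparametric comparisons between conditions (Kolmogorov–Smirnov for
orientation distributions, Mann–Whitney for aspect ratio), mirroring how
polarity defects are scored in gastrula time-lapses.
"""

from pathlib import Path

import pandas as pd

from gastruquant.boundary_metrics import classify_rows
from gastruquant.polarity_metrics import (
    compare_groups,
    measure_shapes,
    summarize_polarity,
)
from gastruquant.tissue_model import (
    build_mesh,
    read_compartment_table,
    read_label_stack,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def shapes_of(condition: str) -> pd.DataFrame:
    d = ROOT / "sim" / condition
    comp = read_compartment_table(d / "compartments.tsv")
    img = read_label_stack(d / "labels.tif", 1.0, 4.0)[0]
    mesh = build_mesh(img, comp)
    shapes = measure_shapes(mesh)
    rows = classify_rows(mesh)
    out = shapes[shapes["compartment"] == "axial"].merge(
        rows[["cell_id", "row_label"]], on="cell_id"
    )
    out["condition"] = condition
    return out


def main():
    ctrl = shapes_of("control")
    pert = shapes_of("perturbed")
    both = pd.concat([ctrl, pert], ignore_index=True)
    both.to_csv(ROOT / "polarity_shapes.tsv", sep="\t", index=False)

    cohorts = []
    for cond, df in both.groupby("condition"):
        rows_df = df[["cell_id", "row_label"]].assign(row=0)
        c = summarize_polarity(df.drop(columns="row_label"), rows_df)
        c["condition"] = cond
        cohorts.append(c)
    cohorts = pd.concat(cohorts, ignore_index=True)
    cohorts.to_csv(ROOT / "polarity_cohorts.tsv", sep="\t", index=False)
    print(cohorts.to_string(index=False))

    d_ks, p_ks = compare_groups(
        ctrl["orientation_deg"], pert["orientation_deg"], test="ks"
    )
    u, p_mw = compare_groups(
        ctrl["aspect_ratio"], pert["aspect_ratio"], test="mann_whitney"
    )
    tests = pd.DataFrame(
        [
            {"metric": "orientation_deg", "test": "ks", "stat": d_ks, "p": p_ks},
            {"metric": "aspect_ratio", "test": "mann_whitney", "stat": u, "p": p_mw},
        ]
    )
    tests.to_csv(ROOT / "polarity_tests.tsv", sep="\t", index=False)
    print(
        f"\norientation: control median "
        f"{ctrl['orientation_deg'].median():.1f}° vs perturbed "
        f"{pert['orientation_deg'].median():.1f}° (KS D={d_ks:.2f}, p={p_ks:.2g})"
    )
    print(
        f"aspect ratio: control mean {ctrl['aspect_ratio'].mean():.2f} vs "
        f"perturbed {pert['aspect_ratio'].mean():.2f} (MW p={p_mw:.2g})"
    )


if __name__ == "__main__":
    main()
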
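"""Generate every synthetic input used by the downstream analyses.

Two tissue conditions are produced: a 'control' tissue with a straight,
high-concentration geometry (gentle boundary, strong ML alignment) and a
'perturbed' tissue emulating the mutant phenotype (large boundary
amplitude, weak alignment, rounder cells), plus a scripted-T1 time-lapse,
ablation recoil series per junction class, and the genomic count matrices.
Everything lands under results/sim/ in the exact formats the measurement
stages read.
"""

from pathlib import Path

from click.testing import CliRunner

from gastruquant.cli import main

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 0

CONDITIONS = {
    # kappa, AR*, boundary amplitude: control is straight and polarized,
    # perturbed is wavy and poorly aligned
    "control": ["--kappa", "12", "--aspect-ratio", "2.0", "--boundary-amp", "2"],
    "perturbed": ["--kappa", "1.5", "--aspect-ratio", "1.4", "--boundary-amp", "8"],
}


def run(args):
    res = CliRunner().invoke(main, args, catch_exceptions=False)
    assert res.exit_code == 0, res.output


def main_():
    for name, extra in CONDITIONS.items():
        run(
            ["simulate-tissue", "--seed", str(SEED), "--out", str(OUT / name)]
            + extra
        )
    # ten frames at 10-min intervals: a 90-min movie, the standard window
    run(["simulate-timelapse", "--seed", str(SEED), "--n-flips", "4",
         "--n-frames", "10", "--dt-min", "10",
         "--out", str(OUT / "timelapse")])
    run(["simulate-recoil", "--seed", str(SEED), "--n-per-class", "15",
         "--out", str(OUT / "recoil")])
    run(["simulate-genomic", "--seed", str(SEED), "--out", str(OUT / "genomic")])
    print(f"inputs written under {OUT}")


if __name__ == "__main__":
    main_()
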
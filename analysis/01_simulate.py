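#!/usr/bin/env python
"""Generate the reference synthetic glycoproteomic dataset.

Emits a proteome with one 1,199-residue S-layer-like glycoprotein (six
N-X-S/T sequons, five occupied by the 1,650.64 Da hexasaccharide), twenty
background proteins, and 2,000 MS/MS spectra including 631.26 Da
false-modification spectra (off-sequon, no oxonium ions) and noise.
Writes FASTA, MGF and the ground-truth table under results/.
"""

import argparse
import json
from pathlib import Path

from glycopen.digest import write_fasta
from glycopen.simulate import SimConfig, simulate_proteome, simulate_spectra, write_truth
from glycopen.spectra import write_mgf

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

config = SimConfig(seed=args.seed)
proteins, manifest = simulate_proteome(config)
spectra, truths = simulate_spectra(proteins, manifest, config)

write_fasta(proteins, args.outdir / "proteome.fasta")
write_mgf(spectra, args.outdir / "spectra.mgf")
write_truth(truths, args.outdir / "truth.tsv")
(args.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

slayer = manifest["SLP_0001"]
n_glyco = sum(1 for t in truths if t.mod_name == "hexasaccharide")
n_decoy = sum(1 for t in truths if t.mod_name == "false_631")
print(f"proteome: {len(proteins)} proteins; S-layer protein of "
      f"{len(proteins[0].sequence)} residues with sequons at {slayer['sequons']} "
      f"(glycosylated: {slayer['glycosylated']})")
print(f"spectra: {len(spectra)} total; {n_glyco} glycopeptide, "
      f"{n_decoy} false-modification, {len(spectra) - n_glyco - n_decoy} unmodified")
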
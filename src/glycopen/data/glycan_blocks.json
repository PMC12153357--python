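{
  "comment": "Glycan residue blocks (dehydrated monosaccharide units). Formulas are residue compositions; masses are implied by the formula.",
  "blocks": [
    {
      "name": "Hex",
      "formula": "C6H10O5",
      "notes": "hexose residue"
    },
    {
      "name": "HexNAc",
      "formula": "C8H13NO5",
      "notes": "N-acetylhexosamine residue"
    },
    {
      "name": "HexA",
      "formula": "C6H8O6",
      "notes": "hexuronic acid residue"
    },
    {
      "name": "Hex(NAc)2",
      "formula": "C10H16N2O5",
      "notes": "di-N-acetylhexose residue, 244.1059 Da; reducing-end unit of the archaeal chitobiose-like core"
    },
    {
      "name": "HexA(NAc)2",
      "formula": "C10H14N2O6",
      "notes": "di-N-acetylhexuronic acid residue, 258.0852 Da"
    },
    {
      "name": "Hex(NAc)2(CONH2)",
      "formula": "C11H17N3O6",
      "notes": "carboxamide-bearing di-N-acetylhexose residue, 287.1117 Da; the unknown 287.11 Da sugar unit"
    }
  ]
}
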
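"""Theoretical fragment-ion ladders (b/y for HCD, c/z-dot for EThcD)."""

from __future__ import annotations

import numpy as np

from .chem import ATOMIC_MASS, PROTON_MASS, WATER_MASS
from .digest import RESIDUE_MASS, Peptide

NH3_MASS = ATOMIC_MASS["N"] + 3 * ATOMIC_MASS["H"]  # 17.02655
#: z-dot (z+1 radical) offset relative to the y ion: y - NH3 + H.
ZDOT_OFFSET = -NH3_MASS + ATOMIC_MASS["H"]


def residue_masses(peptide: Peptide | str, site_delta: tuple[int, float] | None = None) -> np.ndarray:
    """Per-residue mass array including modifications.

    ``site_delta`` optionally adds an extra delta mass at a 1-based residue
    position (used for a glycan riding on an Asn).
    """
    if isinstance(peptide, str):
        seq, mods = peptide, ()
    else:
        seq, mods = peptide.sequence, peptide.mods
    masses = np.array([RESIDUE_MASS[aa] for aa in seq], dtype=float)
    for pos, _, delta in mods:
        masses[max(pos, 1) - 1] += delta  # N-terminal mods folded into residue 1
    if site_delta is not None:
        pos, delta = site_delta
        masses[pos - 1] += delta
    return masses


def by_ladder(masses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singly protonated b and y ion m/z arrays (lengths n-1 each)."""
    prefix = np.cumsum(masses)
    b = prefix[:-1] + PROTON_MASS
    y = prefix[-1] - prefix[:-1] + WATER_MASS + PROTON_MASS
    return b, y[::-1]  # y ordered y1..y(n-1)


def cz_ladder(masses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singly protonated c and z-dot ion m/z arrays (lengths n-1 each)."""
    b, y = by_ladder(masses)
    return b + NH3_MASS, y + ZDOT_OFFSET
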
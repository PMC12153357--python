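"""Elemental-formula arithmetic and glycan building blocks.

Everything downstream of a precursor-mass discrepancy ultimately reduces to
monoisotopic mass bookkeeping over {C, H, N, O, S}. This module owns that
arithmetic: compositions, ring-plus-double-bond (RDB) counts, constrained
enumeration of compositions that explain an observed delta mass, the registry
of glycan residue blocks, glycoform assembly, and oxonium-ion m/z values used
to flag glycopeptide spectra.
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

ELEMENTS = ("C", "H", "N", "O", "S")

#: Monoisotopic atomic masses (Da), most-abundant isotope.
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
}

PROTON_MASS = 1.00727646
WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]  # 18.010565...

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts per element over the CHNOS alphabet."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula string like ``'C11H17N3O6'``."""
        counts = dict.fromkeys(ELEMENTS, 0)
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos or not match.group(0):
                break
            sym, num = match.group(1), match.group(2)
            if sym not in counts:
                raise ValueError(f"unknown element symbol {sym!r} in {formula!r}")
            counts[sym] += int(num) if num else 1
            pos = match.end()
        if pos != len(formula):
            raise ValueError(f"malformed formula {formula!r}")
        return cls(**counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in ELEMENTS}
        )

    def formula(self) -> str:
        parts = []
        for el in ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    @property
    def atom_count(self) -> int:
        return sum(getattr(self, el) for el in ELEMENTS)


def monoisotopic_mass(formula: ElementalComposition | str) -> float:
    """Monoisotopic mass (Da) of a composition: sum of count x atomic mass."""
    if isinstance(formula, str):
        formula = ElementalComposition.from_formula(formula)
    return sum(getattr(formula, el) * ATOMIC_MASS[el] for el in ELEMENTS)


def unsaturation(formula: ElementalComposition | str) -> float:
    """Rings-plus-double-bonds equivalent: RDB = C - H/2 + N/2 + 1.

    Oxygen and divalent sulfur do not change the ring/double-bond count.
    The value can be half-integer for radical (odd-electron) compositions.
    """
    if isinstance(formula, str):
        formula = ElementalComposition.from_formula(formula)
    return formula.C - formula.H / 2 + formula.N / 2 + 1


@dataclass(frozen=True)
class CompositionConstraints:
    """Search box and chemical-plausibility filters for composition inference.

    The defaults are the constraint set used for unknown prokaryotic sugar
    residues: C5-14, H4-28, N0-5, O2-12, S0-1, C/H in [0, 4], C/(N+O) in
    [0.4, 1.25], RDB in [1, 6], and a +/-0.005 Da mass window.
    """

    min_counts: Mapping[str, int] = field(
        default_factory=lambda: {"C": 5, "H": 4, "N": 0, "O": 2, "S": 0}
    )
    max_counts: Mapping[str, int] = field(
        default_factory=lambda: {"C": 14, "H": 28, "N": 5, "O": 12, "S": 1}
    )
    ch_ratio: tuple[float, float] = (0.0, 4.0)
    c_no_ratio: tuple[float, float] = (0.4, 1.25)
    rdb: tuple[float, float] = (1.0, 6.0)
    tolerance: float = 0.005
    tolerance_unit: str = "Da"  # "Da" or "ppm"
    #: Interpret the C/H bound as H/C instead (both readings admit C11H17N3O6).
    ch_ratio_is_hc: bool = False

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.tolerance_unit not in ("Da", "ppm"):
            raise ValueError("tolerance_unit must be 'Da' or 'ppm'")
        for el in ELEMENTS:
            if self.min_counts[el] > self.max_counts[el]:
                raise ValueError(f"min > max for element {el}")
        for lo, hi in (self.ch_ratio, self.c_no_ratio, self.rdb):
            if lo > hi:
                raise ValueError("lower ratio/RDB bound exceeds upper bound")

    def tolerance_da(self, target_mass: float) -> float:
        if self.tolerance_unit == "ppm":
            return self.tolerance * 1e-6 * target_mass
        return self.tolerance

    def satisfied_by(self, comp: ElementalComposition) -> bool:
        """Re-check every non-mass constraint for a single composition."""
        for el in ELEMENTS:
            if not self.min_counts[el] <= getattr(comp, el) <= self.max_counts[el]:
                return False
        # Ratio bounds. A zero denominator with a non-zero numerator cannot
        # satisfy a finite upper bound and is treated as failing.
        num, den = (comp.H, comp.C) if self.ch_ratio_is_hc else (comp.C, comp.H)
        if den == 0:
            if num > 0:
                return False
        elif not self.ch_ratio[0] <= num / den <= self.ch_ratio[1]:
            return False
        no = comp.N + comp.O
        if no == 0:
            if comp.C > 0:
                return False
        elif not self.c_no_ratio[0] <= comp.C / no <= self.c_no_ratio[1]:
            return False
        return self.rdb[0] <= unsaturation(comp) <= self.rdb[1]


@dataclass(frozen=True)
class CompositionCandidate:
    composition: ElementalComposition
    mass: float
    error: float  # theoretical - target, Da


def enumerate_compositions(
    target_mass: float, constraints: CompositionConstraints | None = None
) -> list[CompositionCandidate]:
    """Enumerate all CHNOS compositions explaining ``target_mass``.

    Walks the full constraint box, keeps compositions whose theoretical mass
    lies within the tolerance of the target and which pass the ratio and RDB
    filters, and returns them sorted by absolute mass error (ties: fewer
    atoms, then formula string). The H loop is solved arithmetically from the
    mass residual rather than iterated, which keeps the search exact while
    pruning the box.
    """
    if target_mass <= 0:
        raise ValueError("target_mass must be positive")
    constraints = constraints or CompositionConstraints()
    tol = constraints.tolerance_da(target_mass)
    lo, hi = constraints.min_counts, constraints.max_counts
    m = ATOMIC_MASS

    out: list[CompositionCandidate] = []
    for c, n, o, s in itertools.product(
        range(lo["C"], hi["C"] + 1),
        range(lo["N"], hi["N"] + 1),
        range(lo["O"], hi["O"] + 1),
        range(lo["S"], hi["S"] + 1),
    ):
        heavy = c * m["C"] + n * m["N"] + o * m["O"] + s * m["S"]
        # H count must place heavy + h*mH inside [target - tol, target + tol]
        h_lo = max(lo["H"], math.ceil((target_mass - tol - heavy) / m["H"] - 1e-12))
        h_hi = min(hi["H"], math.floor((target_mass + tol - heavy) / m["H"] + 1e-12))
        for h in range(h_lo, h_hi + 1):
            comp = ElementalComposition(C=c, H=h, N=n, O=o, S=s)
            if not constraints.satisfied_by(comp):
                continue
            mass = heavy + h * m["H"]
            if abs(mass - target_mass) <= tol:
                out.append(CompositionCandidate(comp, mass, mass - target_mass))
    out.sort(key=lambda cand: (abs(cand.error), cand.composition.atom_count,
                               cand.composition.formula()))
    return out


# ---------------------------------------------------------------------------
# Glycan blocks and glycoforms


@dataclass(frozen=True)
class GlycanBlock:
    """A monosaccharide residue (dehydrated unit) of a polymerised glycan."""

    name: str
    formula: ElementalComposition

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def _load_block_registry() -> dict[str, GlycanBlock]:
    raw = json.loads(
        resources.files("glycopen.data").joinpath("glycan_blocks.json").read_text()
    )
    registry = {}
    for entry in raw["blocks"]:
        block = GlycanBlock(entry["name"], ElementalComposition.from_formula(entry["formula"]))
        registry[block.name] = block
    return registry


BLOCK_REGISTRY: dict[str, GlycanBlock] = _load_block_registry()


def get_block(name: str) -> GlycanBlock:
    try:
        return BLOCK_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unregistered glycan block {name!r}; known: {sorted(BLOCK_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class Glycoform:
    """An ordered list of glycan blocks, reducing end first."""

    blocks: tuple[GlycanBlock, ...] = ()

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "Glycoform":
        return cls(tuple(get_block(n) for n in names))

    @property
    def mass(self) -> float:
        return sum(b.mass for b in self.blocks)


def glycan_mass(glycoform: Glycoform | Iterable[str]) -> float:
    """Total delta mass (Da) of a glycoform; additive over residue blocks."""
    if not isinstance(glycoform, Glycoform):
        glycoform = Glycoform.from_names(glycoform)
    return glycoform.mass


#: The archaeal S-layer hexasaccharide: a chitobiose-like
#: Hex(NAc)2-HexA(NAc)2 core extended by four carboxamide-bearing
#: di-N-acetylhexose units, total delta mass 1650.64 Da (2 dp).
HEXASACCHARIDE = (
    "Hex(NAc)2",
    "HexA(NAc)2",
    "Hex(NAc)2(CONH2)",
    "Hex(NAc)2(CONH2)",
    "Hex(NAc)2(CONH2)",
    "Hex(NAc)2(CONH2)",
)


# ---------------------------------------------------------------------------
# Oxonium ions

#: Neutral (free, hydrated) monosaccharide formulas for oxonium computation.
_OXONIUM_NEUTRALS = {
    "HexNAc": "C8H15NO6",
    "Hex": "C6H12O6",
    "HexA": "C6H10O7",
}

#: Named secondary fragments stored as literature m/z constants: these arise
#: from further water/CH2O losses of the HexNAc oxonium and are registered
#: rather than derived.
_OXONIUM_FRAGMENTS = {
    "HexNAc_frag": 138.0545,  # HexNAc - 2 H2O - CH2O fragment cation
    "HexNAc-H2O": 186.0761,
}


def oxonium_mz(name: str) -> float:
    """m/z of a diagnostic sugar oxonium ion.

    For registered monosaccharides this is the singly protonated, dehydrated
    sugar cation (neutral + proton - water); named secondary fragments return
    their registered constants.
    """
    if name in _OXONIUM_NEUTRALS:
        return monoisotopic_mass(_OXONIUM_NEUTRALS[name]) + PROTON_MASS - WATER_MASS
    if name in _OXONIUM_FRAGMENTS:
        return _OXONIUM_FRAGMENTS[name]
    raise KeyError(
        f"unknown oxonium name {name!r}; known: "
        f"{sorted(_OXONIUM_NEUTRALS) + sorted(_OXONIUM_FRAGMENTS)}"
    )


#: Diagnostic oxonium m/z values scanned for during validation (the HexNAc
#: oxonium and its low-mass fragment, the classic glycopeptide trigger pair).
DIAGNOSTIC_OXONIUM_MZ = (oxonium_mz("HexNAc"), oxonium_mz("HexNAc_frag"))
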
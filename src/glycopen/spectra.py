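"""Centroided MS/MS spectra and MGF I/O (pyteomics-backed)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyteomics import mgf

from .chem import PROTON_MASS


@dataclass
class Spectrum:
    """A centroided peak list with precursor information.

    Peaks are stored sorted by m/z; ``precursor_mz`` is the (possibly
    mass-error-bearing) measured precursor m/z and ``charge`` its charge.
    """

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.mz, kind="stable")
        self.mz = np.asarray(self.mz, dtype=float)[order]
        self.intensity = np.asarray(self.intensity, dtype=float)[order]

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mz * self.charge - self.charge * PROTON_MASS

    def __len__(self) -> int:
        return len(self.mz)


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF: TITLE, PEPMASS (m/z), signed CHARGE, peak pairs."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": f"{s.charge}+",
            },
        }
        for s in spectra
    ]
    mgf.write(entries, output=str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0])
            pepmass = params["pepmass"][0]
            spectra.append(
                Spectrum(
                    spectrum_id=params["title"],
                    precursor_mz=float(pepmass),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra
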
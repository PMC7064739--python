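"""Formulation metrics from absorbance spectra and intensity ratios.

Covers the arithmetic used to characterize liposomal dye formulations:
the J-aggregate-to-monomer absorbance ratio A892/A792 (ICG J-aggregates
absorb at 892 nm, monomeric ICG at 792 nm), encapsulation efficiencies
for the dye (concentration ratio) and for doxorubicin (fluorescence
before/after purification), and peak lookup for stability series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectrumTable", "ija_icg_ratio", "icg_ee", "dox_ee",
           "peak_absorbance", "IJA_PEAK_NM", "ICG_MONOMER_PEAK_NM"]

#: absorbance maximum of the ICG J-aggregate, nm
IJA_PEAK_NM = 892.0
#: absorbance maximum of monomeric ICG, nm
ICG_MONOMER_PEAK_NM = 792.0

#: a wavelength within this distance of a grid point uses the grid value
#: directly (1 nm plate-reader grids hit 892/792 exactly)
_SNAP_NM = 0.5


@dataclass
class SpectrumTable:
    """Absorbance spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbance must be 1-D and equal length")
        if self.wavelengths.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing (and unique)")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        """Read a two-column CSV (wavelength_nm, absorbance); header optional."""
        df = pd.read_csv(path, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (wavelength, absorbance)")
        # tolerate headerless files read with data in the header row
        try:
            float(df.columns[0])
            df = pd.read_csv(path, comment="#", header=None)
        except (TypeError, ValueError):
            pass
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "absorbance": self.absorbance}).to_csv(path, index=False)

    def absorbance_at(self, wavelength: float) -> float:
        """Absorbance at a wavelength: nearest grid point within 0.5 nm,
        else linear interpolation between neighbors."""
        wl = self.wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValueError(
                f"wavelength {wavelength} nm outside the measured range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        nearest = int(np.argmin(np.abs(wl - wavelength)))
        if abs(wl[nearest] - wavelength) <= _SNAP_NM:
            return float(self.absorbance[nearest])
        return float(np.interp(wavelength, wl, self.absorbance))


def ija_icg_ratio(spectrum: SpectrumTable) -> float:
    """J-aggregate-to-monomer absorbance ratio A892/A792.

    Raises when A792 is non-positive (no monomer signal to normalize by).
    """
    a_ija = spectrum.absorbance_at(IJA_PEAK_NM)
    a_mono = spectrum.absorbance_at(ICG_MONOMER_PEAK_NM)
    if a_mono <= 0:
        raise ValueError(
            f"absorbance at {ICG_MONOMER_PEAK_NM:g} nm must be positive, "
            f"got {a_mono}"
        )
    return a_ija / a_mono


def icg_ee(encapsulated_conc: float, initial_conc: float) -> float:
    """Dye encapsulation efficiency in percent.

    100 x (encapsulated concentration / initial concentration); both in
    the same units (typically uM).
    """
    if initial_conc <= 0:
        raise ValueError(f"initial concentration must be positive, got {initial_conc}")
    if encapsulated_conc < 0:
        raise ValueError("encapsulated concentration cannot be negative")
    return 100.0 * encapsulated_conc / initial_conc


def dox_ee(fluor_after_purification: float,
           fluor_before_purification: float) -> float:
    """Doxorubicin encapsulation efficiency in percent.

    100 x (fluorescence after purification / before purification), both
    measured on detergent-solubilized, lipid-matched samples (the caller
    is responsible for matching). Values above 100% are returned but
    flagged as physically implausible.
    """
    if fluor_before_purification <= 0:
        raise ValueError(
            f"pre-purification intensity must be positive, got "
            f"{fluor_before_purification}"
        )
    value = 100.0 * fluor_after_purification / fluor_before_purification
    if value > 100.0:
        warnings.warn(
            f"encapsulation efficiency {value:.2f}% exceeds 100%: "
            "post-purification signal is higher than pre-purification, "
            "which is physically implausible",
            stacklevel=2,
        )
    return value


def peak_absorbance(spectrum: SpectrumTable,
                    window: tuple[float, float]) -> tuple[float, float]:
    """(wavelength, absorbance) of the maximum within a wavelength window.

    Ties are broken toward the lowest wavelength.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be (low, high) with low < high")
    sel = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"window [{lo}, {hi}] nm contains no grid points")
    wl = spectrum.wavelengths[sel]
    ab = spectrum.absorbance[sel]
    k = int(np.argmax(ab))  # argmax returns the first (lowest-wavelength) tie
    return float(wl[k]), float(ab[k])
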
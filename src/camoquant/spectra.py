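"""Spectral data structures, visual-pigment templates, illuminants and quantum catches.

The quantities handled here are the raw material of receptor-noise-limited
visual modelling: reflectance spectra :math:`R(\\lambda)`, illuminant photon
flux :math:`I(\\lambda)` and photoreceptor spectral sensitivities
:math:`S_i(\\lambda)`.  A receptor's quantum catch for a stimulus is the
integral of their product; dividing by the catch of a perfect white under the
same illuminant (von Kries normalization) models chromatic adaptation so a
white surface yields catch 1 in every receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cie import D65_RELATIVE_POWER, D65_WAVELENGTHS_NM

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "govardovskii_sensitivity",
    "standard_illuminant_d65",
    "resample",
    "cone_catch",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

SPECTRUM_KINDS = ("reflectance", "illuminant", "sensitivity", "radiance")


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres.

    Default 300-700 nm at 1 nm covers all built-in cone classes
    (lambda_max 455-553 nm) with a wide margin on both limbs.
    """

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"start must be < stop, got [{self.start}, {self.stop}]")
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


@dataclass
class Spectrum:
    """A sampled spectrum: wavelengths in nm plus unitless values.

    ``kind`` tags the physical meaning: reflectance (fraction of incident
    light, ~[0, 1]), sensitivity (peak-normalized to 1), illuminant
    (relative photon flux) or radiance.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind != "radiance" and np.any(self.values < 0):
            raise ValueError(f"negative values not allowed for kind={self.kind!r}")
        if self.kind == "sensitivity":
            peak = self.values.max()
            if peak <= 0:
                raise ValueError("sensitivity spectrum must have a positive peak")
            self.values = self.values / peak

    @classmethod
    def flat(cls, value: float, grid: WavelengthGrid | None = None,
             kind: str = "reflectance", name: str = "") -> "Spectrum":
        """Spectrally flat spectrum at a constant level."""
        grid = grid or WavelengthGrid()
        wl = grid.wavelengths
        return cls(wl, np.full_like(wl, float(value)), kind=kind, name=name)

    def interp(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation; refuses to extrapolate."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        if wl.min() < self.wavelengths[0] - 1e-9 or wl.max() > self.wavelengths[-1] + 1e-9:
            raise ValueError(
                f"requested range [{wl.min()}, {wl.max()}] nm outside spectrum "
                f"support [{self.wavelengths[0]}, {self.wavelengths[-1]}] nm; "
                "no silent extrapolation"
            )
        return np.interp(wl, self.wavelengths, self.values)


def resample(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Resample a spectrum onto a grid by linear interpolation (no extrapolation)."""
    wl = grid.wavelengths
    vals = spectrum.interp(wl)
    return Spectrum(wl, vals, kind=spectrum.kind, name=spectrum.name)


def govardovskii_sensitivity(lambda_max: float, grid: WavelengthGrid | None = None) -> Spectrum:
    """A1 visual-pigment absorbance template for a cone with peak ``lambda_max``.

    Implements the standard rhodopsin (A1) nomogram: an alpha band
    parameterized in x = lambda_max / lambda plus the beta (cis) band as a
    Gaussian in wavelength.  The returned spectrum is peak-normalized to 1
    at the grid point nearest lambda_max.
    """
    if not 330.0 <= lambda_max <= 650.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside supported range 330-650 nm")
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths

    # alpha band
    x = lambda_max / wl
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)

    # beta band
    A_beta = 0.26
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = A_beta * np.exp(-(((wl - lm_beta) / b_beta) ** 2))

    s = alpha + beta
    return Spectrum(wl, s, kind="sensitivity", name=f"A1({lambda_max:g}nm)")


def standard_illuminant_d65(grid: WavelengthGrid | None = None) -> Spectrum:
    """CIE D65 daylight illuminant as relative *photon flux*, max-normalized.

    The tabulated D65 values are spectral power; quantum catch is photon
    based, so power is weighted by wavelength before normalization.
    """
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths
    if wl[0] < D65_WAVELENGTHS_NM[0] or wl[-1] > D65_WAVELENGTHS_NM[-1]:
        raise ValueError(
            f"grid [{wl[0]}, {wl[-1]}] nm outside D65 tabulation "
            f"[{D65_WAVELENGTHS_NM[0]}, {D65_WAVELENGTHS_NM[-1]}] nm"
        )
    power = np.interp(wl, D65_WAVELENGTHS_NM, D65_RELATIVE_POWER)
    photons = power * wl
    photons = photons / photons.max()
    return Spectrum(wl, photons, kind="illuminant", name="D65")


def cone_catch(reflectance: Spectrum, illuminant: Spectrum, sensitivity: Spectrum,
               von_kries: bool = True) -> float:
    """Quantum catch q = integral of R(l) I(l) S(l) dl (trapezoidal).

    With ``von_kries`` the catch is divided by that of a perfect reflector
    (R == 1) under the same illuminant and sensitivity, so any spectrally
    flat reflectance of level r yields exactly r in every receptor.
    """
    wl = reflectance.wavelengths
    for other in (illuminant, sensitivity):
        if other.wavelengths.shape != wl.shape or not np.allclose(other.wavelengths, wl):
            raise ValueError("spectra must share a common wavelength grid; resample first")
    integrand = reflectance.values * illuminant.values * sensitivity.values
    q = float(np.trapezoid(integrand, wl))
    if von_kries:
        denom = float(np.trapezoid(illuminant.values * sensitivity.values, wl))
        if denom <= 0:
            raise ValueError("illuminant and sensitivity do not overlap; catch undefined")
        q /= denom
    return q


def read_spectrum_csv(path, kind: str = "reflectance", name: str = "") -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV spectrum."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'wavelength_nm' and 'value'")
    return Spectrum(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(),
                    kind=kind, name=name or str(path))


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    import pandas as pd

    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  "value": spectrum.values}).to_csv(path, index=False)
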
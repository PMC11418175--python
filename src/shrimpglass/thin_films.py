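"""Coherent transfer-matrix optics for planar stacks at normal incidence.

The characteristic-matrix method (Born & Wolf) gives exact reflectance
and transmittance of any stack of homogeneous, non-absorbing,
dispersion-free layers.  It serves two roles here: it is the model for
the planar structures (the bare chitin cuticle, the chitin lamellae
stack), and it is the analytic oracle against which the time-domain
solver is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import LayerStack

__all__ = ["Spectrum", "fresnel_power", "tmm_spectrum", "band_average"]

VISIBLE_BAND = (400.0, 700.0)


@dataclass
class Spectrum:
    """Wavelength-resolved fractional reflectance and transmittance.

    ``wavelengths_nm`` must be ascending.  ``meta`` carries solver
    diagnostics (grid, steps, energy balance) when produced by FDTD.
    """

    wavelengths_nm: np.ndarray
    R: np.ndarray
    T: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.wavelengths_nm.ndim != 1 or np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be a strictly ascending 1-D grid")
        if self.R.shape != self.wavelengths_nm.shape or self.T.shape != self.wavelengths_nm.shape:
            raise ValueError("R and T must match the wavelength grid")
        tol = 5e-2  # numerical slop allowed before declaring the spectrum unphysical
        if np.any(self.R < -tol) or np.any(self.R > 1 + tol):
            raise ValueError("reflectance outside [0, 1]")
        if np.any(self.T < -tol) or np.any(self.T > 1 + tol):
            raise ValueError("transmittance outside [0, 1]")

    def band_average(self, lo: float = VISIBLE_BAND[0], hi: float = VISIBLE_BAND[1]):
        """Flat-weighted band means ``(R_bar, T_bar)``."""
        return (
            band_average(self, lo, hi, which="R"),
            band_average(self, lo, hi, which="T"),
        )

    def energy_imbalance(self) -> float:
        """max over wavelengths of |R + T - 1| (non-absorbing media)."""
        return float(np.max(np.abs(self.R + self.T - 1.0)))

    def to_csv(self, path: str | Path) -> None:
        data = np.column_stack([self.wavelengths_nm, self.R, self.T])
        np.savetxt(path, data, delimiter=",", header="wavelength_nm,R,T", comments="", fmt="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, 0], data[:, 1], data[:, 2])


def fresnel_power(n1: float, n2: float) -> float:
    """Normal-incidence power reflectance of a planar interface."""
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    return float(((n1 - n2) / (n1 + n2)) ** 2)


def tmm_spectrum(stack: LayerStack, wavelengths_nm) -> Spectrum:
    """Coherent R(λ), T(λ) of a planar stack at normal incidence.

    Uses the 2x2 characteristic matrix per layer,
    ``[[cos d, i sin d / n], [i n sin d, cos d]]`` with phase thickness
    ``d = 2 pi n t / λ``, multiplied in the order light encounters the
    layers.  Real (non-absorbing) indices only.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    n_a, n_s = stack.ambient_n, stack.substrate_n
    m00 = np.ones_like(wl, dtype=complex)
    m01 = np.zeros_like(wl, dtype=complex)
    m10 = np.zeros_like(wl, dtype=complex)
    m11 = np.ones_like(wl, dtype=complex)
    for t_um, n in stack.layers:
        if t_um <= 0:
            raise ValueError("zero-thickness layer")
        delta = 2.0 * np.pi * n * (t_um * 1000.0) / wl
        c, s = np.cos(delta), np.sin(delta)
        a00, a01, a10, a11 = c, 1j * s / n, 1j * n * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    B = m00 + m01 * n_s
    C = m10 + m11 * n_s
    denom = n_a * B + C
    r = (n_a * B - C) / denom
    R = np.abs(r) ** 2
    T = 4.0 * n_a * n_s / np.abs(denom) ** 2
    return Spectrum(wl, R, T, meta={"method": "tmm"})


def band_average(
    spectrum: Spectrum,
    lo: float = VISIBLE_BAND[0],
    hi: float = VISIBLE_BAND[1],
    which: str = "R",
) -> float:
    """Flat-weighted trapezoidal mean of R (or T) over ``[lo, hi]`` nm."""
    wl = spectrum.wavelengths_nm
    if lo >= hi:
        raise ValueError("need lo < hi")
    if wl[0] > lo + 1e-9 or wl[-1] < hi - 1e-9:
        raise ValueError(f"spectrum [{wl[0]}, {wl[-1]}] nm does not cover [{lo}, {hi}] nm")
    y = spectrum.R if which == "R" else spectrum.T
    inside = (wl > lo) & (wl < hi)
    grid = np.concatenate([[lo], wl[inside], [hi]])
    vals = np.interp(grid, wl, y)
    return float(np.trapezoid(vals, grid) / (hi - lo))
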
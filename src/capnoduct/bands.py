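"""Bloch band structure of the infinite periodic waveguide (Green method).

For the infinite lattice the dispersion relation reduces to the closed form

    cos(K d) = cos(k d1) + (j/2) Z1 y_OC sin(k d1),

with K the Bloch wavevector, k = omega/c, Z1 = rho c / S1 and y_OC the
purely imaginary combined shunt admittance of the open and closed branches.
The right-hand side is therefore real; |cos(K d)| > 1 marks a phononic band
gap (evanescent Bloch waves only).

The same relation can be written through the Green surface functions of the
two resonators, g_R^-1 = g_c^-1 + g_o^-1 with

    g_c^-1 = -j y2 tan(k d2),      g_o^-1 = +j y3 cot(k d3),

y_i = S_i / (rho c), and the prefactor z1 = j omega Z1:

    cos(K d) = cos(k d1) - (1/2) (z1/omega) sin(k d1) g_R^-1.

Both routes are implemented and agree identically; the second is a pure
cross-check of the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .gases import AcousticMedium
from .tmm import (ArrayLike, SensorGeometry, combined_admittance,
                  duct_impedance, _wavenumber, POLE_TOL)

__all__ = [
    "BandStructure",
    "BandGap",
    "green_inverse_closed",
    "green_inverse_open",
    "bloch_dispersion",
    "bloch_dispersion_green",
    "band_structure",
    "band_gaps",
]

#: tolerance on the residual imaginary part of cos(Kd)
_IMAG_TOL = 1e-9


@dataclass(frozen=True)
class BandGap:
    """A forbidden frequency interval, counted from the lowest gap upward."""

    index: int
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError("gap edges must satisfy f_low < f_high")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def width(self) -> float:
        return self.f_high - self.f_low

    def __contains__(self, f: float) -> bool:
        return self.f_low <= f <= self.f_high


@dataclass(frozen=True)
class BandStructure:
    """Sampled dispersion record: frequency, cos(Kd) and the gap flag."""

    frequencies: np.ndarray
    cos_kd: np.ndarray

    @property
    def in_gap(self) -> np.ndarray:
        return np.abs(self.cos_kd) > 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_Hz": self.frequencies,
                             "cos_Kd": self.cos_kd,
                             "in_gap": self.in_gap.astype(int)})


def green_inverse_closed(f: ArrayLike, geom: SensorGeometry,
                         medium: AcousticMedium) -> np.ndarray:
    """Green surface function of the closed resonator, -j y2 tan(k d2)."""
    k = _wavenumber(f, medium)
    c = np.cos(k * geom.d2)
    if np.any(np.abs(c) < POLE_TOL):
        raise ValueError("closed branch pole: cos(k d2) = 0")
    y2 = 1.0 / duct_impedance(medium, geom.S2)
    return -1j * y2 * np.sin(k * geom.d2) / c


def green_inverse_open(f: ArrayLike, geom: SensorGeometry,
                       medium: AcousticMedium) -> np.ndarray:
    """Green surface function of the open resonator, +j y3 cot(k d3)."""
    k = _wavenumber(f, medium)
    s = np.sin(k * geom.d3)
    if np.any(np.abs(s) < POLE_TOL):
        raise ValueError("open branch pole: sin(k d3) = 0")
    y3 = 1.0 / duct_impedance(medium, geom.S3)
    return 1j * y3 * np.cos(k * geom.d3) / s


def bloch_dispersion(f: ArrayLike, geom: SensorGeometry,
                     medium: AcousticMedium) -> np.ndarray:
    """Real dispersion value cos(Kd) = cos(k d1) + (j/2) Z1 y_OC sin(k d1)."""
    k = _wavenumber(f, medium)
    z1 = duct_impedance(medium, geom.S1)
    y = combined_admittance(f, geom, medium)
    val = np.cos(k * geom.d1) + 0.5j * z1 * y * np.sin(k * geom.d1)
    if np.any(np.abs(val.imag) > _IMAG_TOL):
        raise FloatingPointError("cos(Kd) acquired an imaginary part")
    return val.real


def bloch_dispersion_green(f: ArrayLike, geom: SensorGeometry,
                           medium: AcousticMedium) -> np.ndarray:
    """cos(Kd) via the Green-surface route (cross-check of bloch_dispersion)."""
    k = _wavenumber(f, medium)
    z1 = duct_impedance(medium, geom.S1)
    g_r = green_inverse_closed(f, geom, medium) + green_inverse_open(f, geom, medium)
    # z1_green / omega = j Z1: inertial prefactor relating the two notations
    val = np.cos(k * geom.d1) - 0.5 * (1j * z1) * np.sin(k * geom.d1) * g_r
    if np.any(np.abs(val.imag) > _IMAG_TOL):
        raise FloatingPointError("cos(Kd) acquired an imaginary part")
    return val.real


def band_structure(geom: SensorGeometry, medium: AcousticMedium,
                   f_start: float = 0.5, f_stop: float = 3000.0,
                   resolution: float = 0.25) -> BandStructure:
    """Sample cos(Kd) on a uniform grid, nudging samples off branch poles."""
    if not (0 < f_start < f_stop):
        raise ValueError("need 0 < f_start < f_stop")
    f = np.arange(f_start, f_stop + resolution / 2, resolution)
    k = 2 * np.pi * f / medium.sound_speed
    bad = (np.abs(np.sin(k * geom.d3)) < POLE_TOL) | \
          (np.abs(np.cos(k * geom.d2)) < POLE_TOL)
    if np.any(bad):
        f = f.copy()
        f[bad] = np.nextafter(f[bad], np.inf) + 1e-9 * f[bad]
    return BandStructure(f, bloch_dispersion(f, geom, medium))


def band_gaps(geom: SensorGeometry, medium: AcousticMedium,
              f_start: float = 0.5, f_stop: float = 3000.0,
              resolution: float = 0.25, edge_tol: float = 1e-3) -> list[BandGap]:
    """Maximal intervals with |cos(Kd)| > 1, edges refined by bisection.

    A gap truncated by the scan limits keeps the limit as its edge.  Returns
    an empty list when no gap lies in range (e.g. a bare duct).
    """
    bs = band_structure(geom, medium, f_start, f_stop, resolution)
    f, flag = bs.frequencies, bs.in_gap

    def _edge(a: float, b: float) -> float:
        # |cos(Kd)| - 1 changes sign between a sample inside and outside a gap
        g = lambda x: abs(float(bloch_dispersion(x, geom, medium))) - 1.0
        try:
            return brentq(g, a, b, xtol=edge_tol)
        except ValueError:
            return 0.5 * (a + b)

    gaps: list[BandGap] = []
    i = 0
    n = len(f)
    while i < n:
        if not flag[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flag[j + 1]:
            j += 1
        lo = f[i] if i == 0 else _edge(f[i - 1], f[i])
        hi = f[j] if j == n - 1 else _edge(f[j], f[j + 1])
        gaps.append(BandGap(len(gaps) + 1, lo, hi))
        i = j + 1
    return gaps
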
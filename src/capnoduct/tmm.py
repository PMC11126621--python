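"""Acoustic transfer-matrix engine for the resonator-loaded duct.

The sensor is a main duct loaded, once per lattice period d1, by a pair of
shunt side branches: one closed (rigidly terminated, admittance
y_C = j tan(k d2) / Z2) and one open (pressure-release termination,
y_O = -j cot(k d3) / Z3).  A unit cell is the symmetric product

    M_cell = H(d1/2) . [[1, 0], [y_OC, 1]] . H(d1/2),

where H(L) is the plane-wave two-port of a duct segment of length L and
y_OC = y_O + y_C.  A defect guide of length d_d and cross-section S_d sits
between two mirrors of ``n_cells`` unit cells each; the defect two-port is
the square of the half-guide matrix H(d_d/2).  All two-ports are unimodular
(det = 1) because the shunt admittances are purely imaginary (lossless).

Transmission into the semi-infinite terminating ducts of admittance
Y1 = S1/(rho c) is

    t = 2 Y1 / ((A11 + A12 Y1) Y1 + A21 + A22 Y1),   T(%) = 100 |t|^2.

All functions accept scalar or array frequency; matrices are returned as
numpy arrays of shape (..., 2, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from .gases import AcousticMedium

__all__ = [
    "SensorGeometry",
    "BranchPoleError",
    "TransmittanceSpectrum",
    "duct_impedance",
    "duct_segment_matrix",
    "open_branch_admittance",
    "closed_branch_admittance",
    "combined_admittance",
    "unit_cell_matrix",
    "defect_half_matrix",
    "defect_cell_matrix",
    "assemble_total_matrix",
    "transmittance",
    "spectrum",
    "initial_geometry",
    "optimized_geometry",
]

ArrayLike = Union[float, np.ndarray]

#: |sin| / |cos| below this is treated as an exact branch-resonance pole.
POLE_TOL = 1e-12


class BranchPoleError(ValueError):
    """Raised when a frequency coincides with a side-branch resonance pole."""


@dataclass(frozen=True)
class SensorGeometry:
    """All duct and branch dimensions, in SI units (m, m^2).

    ``n_cells`` is the number of unit cells on *each side* of the central
    defect guide, so the full structure is cell^n | defect | cell^n.  The
    lattice period entering cos(K d) is ``d1``.
    """

    d1: float  # main-duct length per cell, m
    d2: float  # closed-branch length, m
    d3: float  # open-branch length, m
    dd: float  # defect-guide length, m
    S1: float  # main-duct cross-section, m^2
    S2: float  # closed-branch cross-section, m^2
    S3: float  # open-branch cross-section, m^2
    Sd: float  # defect-guide cross-section, m^2
    n_cells: int = 10

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3", "dd", "S1", "S2", "S3", "Sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def period(self) -> float:
        return self.d1

    @classmethod
    def from_cm(cls, d1: float, d2: float, d3: float, dd: float,
                S1: float, S2: float, S3: float, Sd: float,
                n_cells: int = 10) -> "SensorGeometry":
        """Build a geometry from lengths in cm and cross-sections in cm^2."""
        return cls(d1 * 1e-2, d2 * 1e-2, d3 * 1e-2, dd * 1e-2,
                   S1 * 1e-4, S2 * 1e-4, S3 * 1e-4, Sd * 1e-4, n_cells)

    def with_(self, **changes) -> "SensorGeometry":
        return replace(self, **changes)


def initial_geometry(n_cells: int = 10) -> SensorGeometry:
    """Starting design: d1=10 cm, d2=d3=6 cm, dd=33 cm, S1=Sd=1 cm^2, S2=S3=0.9 cm^2."""
    return SensorGeometry.from_cm(10, 6, 6, 33, 1, 0.9, 0.9, 1, n_cells)


def optimized_geometry(n_cells: int = 10) -> SensorGeometry:
    """Optimized design: as initial but d1=20 cm and dd=100 cm."""
    return initial_geometry(n_cells).with_(d1=0.20, dd=1.00)


def duct_impedance(medium: AcousticMedium, area: float) -> float:
    """Characteristic acoustic impedance Z = rho c / S of a duct segment."""
    if area <= 0:
        raise ValueError("area must be strictly positive")
    return medium.density * medium.sound_speed / area


def _wavenumber(f: ArrayLike, medium: AcousticMedium) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be strictly positive")
    return 2.0 * np.pi * f / medium.sound_speed


def duct_segment_matrix(f: ArrayLike, length: float, impedance: float,
                        medium: AcousticMedium) -> np.ndarray:
    """Plane-wave two-port of a duct of the given length, shape (..., 2, 2)."""
    k = _wavenumber(f, medium)
    a = np.cos(k * length)
    b = 1j * impedance * np.sin(k * length)
    c = 1j / impedance * np.sin(k * length)
    return np.stack([np.stack([a + 0j, b], axis=-1),
                     np.stack([c, a + 0j], axis=-1)], axis=-2)


def open_branch_admittance(f: ArrayLike, geom: SensorGeometry,
                           medium: AcousticMedium) -> np.ndarray:
    """Shunt admittance y_O = -j cot(k d3) / Z3 of the open side branch.

    Purely imaginary; raises :class:`BranchPoleError` at sin(k d3) = 0 where
    the branch presents an infinite admittance (acoustic short).
    """
    k = _wavenumber(f, geom_medium_check(geom, medium))
    s = np.sin(k * geom.d3)
    if np.any(np.abs(s) < POLE_TOL):
        raise BranchPoleError("open branch pole: sin(k d3) = 0")
    z3 = duct_impedance(medium, geom.S3)
    return -1j / z3 * (np.cos(k * geom.d3) / s)


def closed_branch_admittance(f: ArrayLike, geom: SensorGeometry,
                             medium: AcousticMedium) -> np.ndarray:
    """Shunt admittance y_C = j tan(k d2) / Z2 of the closed side branch."""
    k = _wavenumber(f, geom_medium_check(geom, medium))
    c = np.cos(k * geom.d2)
    if np.any(np.abs(c) < POLE_TOL):
        raise BranchPoleError("closed branch pole: cos(k d2) = 0")
    z2 = duct_impedance(medium, geom.S2)
    return 1j / z2 * (np.sin(k * geom.d2) / c)


def combined_admittance(f: ArrayLike, geom: SensorGeometry,
                        medium: AcousticMedium) -> np.ndarray:
    """Total shunt admittance y_OC = y_O + y_C loading each cell."""
    return (open_branch_admittance(f, geom, medium)
            + closed_branch_admittance(f, geom, medium))


def geom_medium_check(geom: SensorGeometry, medium: AcousticMedium) -> AcousticMedium:
    if not isinstance(geom, SensorGeometry):  # defensive: args are easy to swap
        raise TypeError("expected a SensorGeometry")
    return medium


def _shunt_matrix(y: np.ndarray) -> np.ndarray:
    one = np.ones_like(y)
    zero = np.zeros_like(y)
    return np.stack([np.stack([one, zero], axis=-1),
                     np.stack([y, one], axis=-1)], axis=-2)


def unit_cell_matrix(f: ArrayLike, geom: SensorGeometry,
                     medium: AcousticMedium) -> np.ndarray:
    """Two-port of one lattice period: half duct, shunt pair, half duct."""
    z1 = duct_impedance(medium, geom.S1)
    half = duct_segment_matrix(f, geom.d1 / 2.0, z1, medium)
    y = combined_admittance(f, geom, medium)
    return half @ _shunt_matrix(y) @ half


def defect_half_matrix(f: ArrayLike, geom: SensorGeometry,
                       medium: AcousticMedium) -> np.ndarray:
    """Two-port of half the defect guide (entries with argument k d_d / 2)."""
    zd = duct_impedance(medium, geom.Sd)
    return duct_segment_matrix(f, geom.dd / 2.0, zd, medium)


def defect_cell_matrix(f: ArrayLike, geom: SensorGeometry,
                       medium: AcousticMedium) -> np.ndarray:
    """Two-port of the full defect guide of length d_d (half matrix squared)."""
    half = defect_half_matrix(f, geom, medium)
    return half @ half


def assemble_total_matrix(f: ArrayLike, geom: SensorGeometry,
                          medium: AcousticMedium, *,
                          with_defect: bool = True) -> np.ndarray:
    """Total two-port: n_cells periods, the defect guide, n_cells periods.

    With ``with_defect=False`` the defect-free periodic structure of
    2 * n_cells identical cells is assembled instead.
    """
    cell = unit_cell_matrix(f, geom, medium)
    mirror = np.linalg.matrix_power(cell, geom.n_cells)
    if with_defect:
        return mirror @ defect_cell_matrix(f, geom, medium) @ mirror
    return mirror @ mirror


def transmittance(f: ArrayLike, geom: SensorGeometry, medium: AcousticMedium,
                  *, with_defect: bool = True) -> np.ndarray:
    """Power transmittance T(%) of the full structure between matched ducts."""
    m = assemble_total_matrix(f, geom, medium, with_defect=with_defect)
    y1 = 1.0 / duct_impedance(medium, geom.S1)
    t = 2.0 * y1 / ((m[..., 0, 0] + m[..., 0, 1] * y1) * y1
                    + m[..., 1, 0] + m[..., 1, 1] * y1)
    return 100.0 * np.abs(t) ** 2


@dataclass(frozen=True)
class TransmittanceSpectrum:
    """Frequency-indexed transmittance record (Hz, percent)."""

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        t = np.asarray(self.values, float)
        if f.ndim != 1 or f.shape != t.shape:
            raise ValueError("frequencies and values must be matching 1-D arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(t < -1e-6) or np.any(t > 100 + 1e-6):
            raise ValueError("transmittance outside [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_Hz": self.frequencies,
                             "T_percent": self.values})


def spectrum(geom: SensorGeometry, medium: AcousticMedium,
             f_start: float = 0.1, f_stop: float = 3000.0,
             n_samples: int | None = None, step: float = 0.05,
             *, with_defect: bool = True) -> TransmittanceSpectrum:
    """Transmittance on a uniform frequency grid.

    Samples landing exactly on a side-branch pole are nudged by one grid ulp
    instead of propagating infinities.
    """
    if not (0 < f_start < f_stop):
        raise ValueError("need 0 < f_start < f_stop")
    if n_samples is not None:
        if n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        f = np.linspace(f_start, f_stop, int(n_samples))
    else:
        f = np.arange(f_start, f_stop + step / 2, step)
    # nudge samples that sit on a branch pole
    k = 2 * np.pi * f / medium.sound_speed
    bad = (np.abs(np.sin(k * geom.d3)) < POLE_TOL) | \
          (np.abs(np.cos(k * geom.d2)) < POLE_TOL)
    if np.any(bad):
        f = f.copy()
        f[bad] = np.nextafter(f[bad], np.inf) + 1e-9 * f[bad]
    t = transmittance(f, geom, medium, with_defect=with_defect)
    return TransmittanceSpectrum(f, np.clip(t, 0.0, 100.0))
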
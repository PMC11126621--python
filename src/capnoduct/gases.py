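"""Pure gases, gas mixtures and the effective acoustic medium of exhaled breath.

Dry exhaled breath (DEB) is modelled as an ideal mixture of N2, O2, CO2 and
Ar described by volume fractions.  The effective sound speed of a mixture is
the density-weighted mean of the component speeds,

    c_mix = sum(a_i * rho_i * c_i) / sum(a_i * rho_i),

and the effective mass density is the volume-fraction-weighted sum,

    rho_mix = sum(a_i * rho_i),

where ``a_i`` is the volume fraction of component ``i``.  Because a_i enters
both numerator and denominator, c_mix is invariant under rescaling of the
fractions; rho_mix is not, so fractions are always kept normalized to 1.

CO2 enrichment of breath is expressed in "enrichment units": one unit adds
0.01 volume parts of CO2 to the normal 100 parts of DEB (78 N2 / 16 O2 /
5 CO2 / 1 Ar) without removing any other gas, i.e. the sample is diluted by
the added CO2.  100 units therefore turn the composition into
78/16/6/1 parts out of a 101-part total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "GasSpecies",
    "GasMixture",
    "AcousticMedium",
    "builtin_species",
    "mixture_sound_speed",
    "mixture_density",
    "effective_medium",
    "deb_mixture",
    "NORMAL_DEB_PARTS",
]

#: Normal dry-exhaled-breath composition, volume parts per 100.
NORMAL_DEB_PARTS: Mapping[str, float] = {"N2": 78.0, "O2": 16.0, "CO2": 5.0, "Ar": 1.0}

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class GasSpecies:
    """A pure gas with its room-temperature acoustic constants."""

    name: str
    density: float  # kg m^-3
    sound_speed: float  # m s^-1

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.sound_speed <= 0:
            raise ValueError(f"{self.name}: sound speed must be positive")


@dataclass(frozen=True)
class AcousticMedium:
    """Effective fluid filling the ducts: sound speed c (m/s), density rho (kg/m^3)."""

    sound_speed: float
    density: float

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound speed and density must be strictly positive")


# Room-temperature acoustic constants of the pure gases used for breath.
_BUILTIN = (
    GasSpecies("CO2", 1.8393, 267.0),
    GasSpecies("Ar", 1.661, 319.0),
    GasSpecies("O2", 1.314, 326.0),
    GasSpecies("Air", 1.2047, 343.0),
    GasSpecies("N2", 1.165, 349.0),
)


def builtin_species() -> dict[str, GasSpecies]:
    """Return the built-in pure-gas table as a name -> GasSpecies mapping."""
    return {g.name: g for g in _BUILTIN}


class GasMixture:
    """A gas mixture described by (species, volume fraction) pairs.

    Fractions must be non-negative and sum to 1 within 1e-12.  Use
    :meth:`from_volumes` to build a mixture from un-normalized volume parts.
    """

    def __init__(self, components: Iterable[tuple[GasSpecies, float]]):
        comps = [(g, float(a)) for g, a in components]
        if not comps:
            raise ValueError("mixture must contain at least one component")
        if any(a < 0 for _, a in comps):
            raise ValueError("volume fractions must be non-negative")
        total = sum(a for _, a in comps)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"volume fractions must sum to 1 (got {total!r})")
        self.components: tuple[tuple[GasSpecies, float], ...] = tuple(comps)

    @classmethod
    def from_volumes(cls, parts: Mapping[str, float],
                     species: Mapping[str, GasSpecies] | None = None) -> "GasMixture":
        """Build a mixture from volume parts, normalizing by their total."""
        table = builtin_species() if species is None else dict(species)
        unknown = set(parts) - set(table)
        if unknown:
            raise KeyError(f"unknown gas species: {sorted(unknown)}")
        total = float(sum(parts.values()))
        if total <= 0:
            raise ValueError("total volume must be positive")
        return cls((table[name], v / total) for name, v in parts.items())

    def fractions(self) -> dict[str, float]:
        return {g.name: a for g, a in self.components}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{g.name}:{a:.6g}" for g, a in self.components)
        return f"GasMixture({body})"


def mixture_sound_speed(mix: GasMixture) -> float:
    """Effective sound speed (m/s): density-weighted mean of component speeds."""
    num = sum(a * g.density * g.sound_speed for g, a in mix.components)
    den = sum(a * g.density for g, a in mix.components)
    return num / den


def mixture_density(mix: GasMixture) -> float:
    """Effective mass density (kg/m^3): volume-fraction-weighted sum."""
    return sum(a * g.density for g, a in mix.components)


def effective_medium(mix: GasMixture) -> AcousticMedium:
    """Collapse a mixture into the effective AcousticMedium filling the sensor."""
    return AcousticMedium(mixture_sound_speed(mix), mixture_density(mix))


def deb_mixture(enrichment_units: float = 0.0) -> GasMixture:
    """Dry exhaled breath with CO2 enriched above the normal 5% ratio.

    One enrichment unit adds 0.01 volume parts of CO2 per 100 parts of
    normal DEB; the other gases are untouched and the whole sample is
    renormalized by the enlarged total (dilution).  ``deb_mixture(0)`` is the
    normal composition; ``deb_mixture(100)`` has CO2 parts 6 of 101.
    """
    u = float(enrichment_units)
    if u < 0:
        raise ValueError("enrichment must be non-negative")
    if u > 100:
        warnings.warn("enrichment beyond the studied 0-100 range", stacklevel=2)
    parts = dict(NORMAL_DEB_PARTS)
    parts["CO2"] += u / 100.0
    return GasMixture.from_volumes(parts)
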
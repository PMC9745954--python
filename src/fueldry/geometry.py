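"""Fuel-bed geometry: packing ratio, bulk density, needle mass, fuel load.

A fuel bed is a rectangular layer of dead needles.  Its compaction is
described by the packing ratio

    beta = rho_b / rho_p,

the bulk density of the bed divided by the particle density of the needle
material.  All quantities are SI internally (m, kg); fuel load is reported in
the conventional g m^-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .errors import InvalidInputError

#: Particle density of Masson pine needles (kg m^-3), literature value.
MASSON_PINE_PARTICLE_DENSITY = 543.6


def packing_ratio(bulk_density: float, particle_density: float = MASSON_PINE_PARTICLE_DENSITY) -> float:
    """Packing ratio beta = rho_b / rho_p (dimensionless).

    Parameters
    ----------
    bulk_density : float
        Bed mass per bed volume, kg m^-3.  Must lie in [0, particle_density].
    particle_density : float
        Solid-needle density, kg m^-3.  Must be positive.
    """
    if particle_density <= 0:
        raise InvalidInputError(f"particle_density must be > 0, got {particle_density}")
    if bulk_density < 0 or bulk_density > particle_density:
        raise InvalidInputError(
            f"bulk_density must be in [0, particle_density]; got {bulk_density} vs {particle_density}"
        )
    return bulk_density / particle_density


def needle_mass(beta: float, volume: float, particle_density: float = MASSON_PINE_PARTICLE_DENSITY) -> float:
    """Needle mass w = rho_p * beta * v (kg) filling a bed of volume ``v`` m^3."""
    if beta < 0 or volume < 0 or particle_density < 0:
        raise InvalidInputError("beta, volume and particle_density must be >= 0")
    return particle_density * beta * volume


def fuel_load(beta: float, depth: float, particle_density: float = MASSON_PINE_PARTICLE_DENSITY) -> float:
    """Fuel load per unit bed area, 1000 * rho_p * beta * depth (g m^-2)."""
    if beta < 0 or depth < 0 or particle_density < 0:
        raise InvalidInputError("beta, depth and particle_density must be >= 0")
    return 1000.0 * particle_density * beta * depth


@dataclass(frozen=True)
class FuelBedSpec:
    """Geometry and density of one rectangular fuel bed.

    ``packing_ratio`` is the realized compaction of the bed actually built;
    ``nominal_packing_ratio`` optionally records the design target when the
    two differ (measured loads imply realized values slightly below nominal).

    Derived quantities (volume, bulk density, needle mass, fuel load) are
    exposed as properties so they can never drift out of sync with the
    defining fields.
    """

    packing_ratio: float
    depth: float  # m
    area: float  # m^2
    particle_density: float = MASSON_PINE_PARTICLE_DENSITY  # kg m^-3
    nominal_packing_ratio: float | None = None
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.packing_ratio < 1:
            raise InvalidInputError(f"packing_ratio must be in (0, 1), got {self.packing_ratio}")
        for name in ("depth", "area", "particle_density"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def volume(self) -> float:
        """Bed volume, m^3."""
        return self.depth * self.area

    @property
    def bulk_density(self) -> float:
        """Bed bulk density rho_b = beta * rho_p, kg m^-3."""
        return self.packing_ratio * self.particle_density

    @property
    def needle_mass(self) -> float:
        """Oven-dry needle mass filling the bed, kg."""
        return needle_mass(self.packing_ratio, self.volume, self.particle_density)

    @property
    def fuel_load(self) -> float:
        """Fuel load, g m^-2."""
        return fuel_load(self.packing_ratio, self.depth, self.particle_density)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "packing_ratio": self.packing_ratio,
            "depth_m": self.depth,
            "area_m2": self.area,
            "particle_density_kg_m3": self.particle_density,
            "volume_m3": self.volume,
            "bulk_density_kg_m3": self.bulk_density,
            "needle_mass_kg": self.needle_mass,
            "fuel_load_g_m2": self.fuel_load,
        }
        if self.nominal_packing_ratio is not None:
            d["nominal_packing_ratio"] = self.nominal_packing_ratio
        if self.label:
            d["label"] = self.label
        return d


#: Bed geometry used throughout for the laboratory chamber experiments:
#: a 29 cm x 21 cm tray filled to the field-average depth of 6.9 cm.
CHAMBER_BED_AREA = 0.29 * 0.21  # m^2
CHAMBER_BED_DEPTH = 0.069  # m


def chamber_bed(beta: float, label: str = "") -> FuelBedSpec:
    """A standard laboratory chamber bed at packing ratio ``beta``."""
    return FuelBedSpec(packing_ratio=beta, depth=CHAMBER_BED_DEPTH, area=CHAMBER_BED_AREA, label=label)
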
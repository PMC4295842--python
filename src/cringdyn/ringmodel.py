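"""Geometry of a closed ring of globular protein subunits.

A circular oligomer of n touching spheres of diameter d has its sphere
centers on a circle of circumference n*d, i.e. a center-circle diameter of
n*d/pi (exact for the inscribed polygon in the touching limit, and the
convention under which a 22-subunit C-ring of ~4.3 nm subunits comes out
near 30 nm). The subunit diameter itself is derived from the monomer mass
assuming an anhydrous sphere with the standard partial specific volume of
globular proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# 1 Da * 1 cm^3/g expressed in nm^3: 1.66054e-24 g/Da * 1e21 nm^3/cm^3
_NM3_PER_DA_CM3_G = 1.66054e-3


@dataclass(frozen=True)
class RingModel:
    """A closed ring of ``n_subunits`` touching spheres.

    ``ring_diameter`` is the diameter of the circle through the sphere
    centers; ``outer_diameter`` adds one subunit diameter for the outer
    envelope.
    """

    n_subunits: int
    subunit_diameter: float  # nm
    ring_diameter: float  # nm, through sphere centers
    outer_diameter: float  # nm


def sphere_diameter_from_mass(mass_kda: float, partial_specific_volume: float = 0.73) -> float:
    """Diameter (nm) of a sphere of the given protein mass.

    volume = mass * v_bar (1 Da * 0.73 cm^3/g = 1.212e-3 nm^3);
    diameter = 2 * (3*volume / 4*pi)^(1/3).
    """
    if mass_kda <= 0:
        raise ValueError(f"mass must be positive, got {mass_kda} kDa")
    volume_nm3 = mass_kda * 1e3 * partial_specific_volume * _NM3_PER_DA_CM3_G
    return 2.0 * (3.0 * volume_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def ring_diameter(n_subunits: int, subunit_diameter: float) -> float:
    """Center-circle diameter (nm) of ``n_subunits`` touching spheres: n*d/pi."""
    if n_subunits < 3:
        raise ValueError(f"a closed ring needs >= 3 subunits, got {n_subunits}")
    return n_subunits * subunit_diameter / math.pi


def subunits_from_diameter(ring_diameter_nm: float, subunit_diameter: float) -> float:
    """Real-valued subunit count for a given center-circle diameter (inverse of ring_diameter)."""
    if ring_diameter_nm <= 0 or subunit_diameter <= 0:
        raise ValueError("ring and subunit diameters must be positive")
    return math.pi * ring_diameter_nm / subunit_diameter


def build_ring(n_subunits: int, mass_kda: float,
               partial_specific_volume: float = 0.73) -> RingModel:
    """Full ring model from subunit count and monomer mass."""
    d = sphere_diameter_from_mass(mass_kda, partial_specific_volume)
    ring = ring_diameter(n_subunits, d)
    return RingModel(
        n_subunits=n_subunits,
        subunit_diameter=d,
        ring_diameter=ring,
        outer_diameter=ring + d,
    )
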